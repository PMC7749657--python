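"""End-to-end orchestration: plates -> IC50 profiles -> screen -> overlap.

Each ``run_*`` function consumes the file dialects defined by the other
modules, writes TSV/JSON artifacts atomically into an output directory,
and folds every result-changing warning (non-converged fits, clipped
intensities, dropped transcripts) into the JSON summary so a run is
auditable from its outputs alone.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from pathlib import Path

import pandas as pd

from . import dose_response as dr
from . import motility as mo
from . import overlap as ov
from . import screen as sc
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = [
    "run_simulate",
    "run_ic50",
    "run_screen",
    "run_motility",
    "run_all",
    "read_profile_tsv",
]


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", index=False))


def _write_json(obj, path: Path) -> None:
    _atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_profile_tsv(path) -> dr.IC50Profile:
    df = pd.read_csv(path, sep="\t")
    return dr.IC50Profile(
        cell_lines=list(df["cell_line"].astype(str)),
        values=df["V_uM"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------


def run_simulate(out_dir, seed: int = 0, **overrides) -> dict:
    """Write a full synthetic fixture set (plate, expression, tracks)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plate_cfg = syn.PlateSimConfig(seed=seed, noise_sd=100.0)
    expr_params = {"n_cell_lines": len(plate_cfg.cell_lines)}
    expr_params.update(overrides.get("expression", {}))
    expr_cfg = syn.ExpressionSimConfig(seed=seed + 1, **expr_params)
    track_cfg = syn.TrackSimConfig(seed=seed + 2, dropout_prob=0.02)

    plate = syn.simulate_plate(plate_cfg)
    values, calls, truth = syn.simulate_expression(expr_cfg)
    # keep the fixture set self-consistent: expression columns carry the
    # same cell-line labels as the plate
    values.columns = plate_cfg.cell_lines
    calls.columns = plate_cfg.cell_lines
    tracks = syn.simulate_tracks(track_cfg)

    _atomic_write_text(out / "plate.csv", plate.to_csv(index=False))
    sc.write_expression_tsv(
        sc.ExpressionMatrix(values=values, calls=calls), out / "expression.tsv"
    )
    _write_tsv(truth, out / "truth.tsv")
    _atomic_write_text(out / "tracks.csv", tracks.to_csv(index=False))
    return {
        "plate_rows": int(len(plate)),
        "n_transcripts": int(len(values)),
        "n_tracks": int(tracks["track_id"].nunique()),
    }


def run_ic50(plate_csv, out_dir) -> dict[str, dr.IC50Profile]:
    """Fit Hill curves for every (line, compound, timepoint) in a plate CSV.

    Writes one fit table, per-(compound, timepoint) profiles, and per
    compound the timepoint-averaged profile. Returns the averaged
    profiles keyed by compound.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        plate = pd.read_csv(plate_csv)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed plate CSV {plate_csv}: {exc}") from exc

    fit_rows = []
    captured: list[str] = []
    profiles: dict[str, dr.IC50Profile] = {}
    combos = plate[["compound", "timepoint_h"]].drop_duplicates()
    fits_by_ct: dict[tuple, dict[str, dr.HillFit]] = {}
    for _, row in combos.iterrows():
        comp, tp = row["compound"], row["timepoint_h"]
        lines = sorted(
            plate[(plate["compound"] == comp) & (plate["timepoint_h"] == tp)][
                "cell_line"
            ].unique()
        )
        fits: dict[str, dr.HillFit] = {}
        for line in lines:
            series = dr.series_from_plate(plate, line, comp, tp)
            resp = dr.normalize_viability(series)
            fit = dr.fit_hill(resp)
            fits[line] = fit
            fit_rows.append(
                {
                    "cell_line": line,
                    "compound": comp,
                    "timepoint_h": tp,
                    "min": fit.min,
                    "max": fit.max,
                    "ic50_uM": fit.ic50,
                    "hill": fit.hill_coefficient,
                    "rss": fit.rss,
                    "converged": fit.converged,
                }
            )
            if not fit.converged:
                captured.append(
                    f"non-converged fit: {line}/{comp}/{tp}h"
                )
        fits_by_ct[(comp, tp)] = fits

    _write_tsv(pd.DataFrame(fit_rows), out / "fits.tsv")

    for comp in combos["compound"].unique():
        tp_profiles = []
        for (c, tp), fits in sorted(fits_by_ct.items()):
            if c != comp:
                continue
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                prof = dr.build_profile(fits)
            captured.extend(str(w.message) for w in wlist)
            tp_profiles.append(prof)
            _write_tsv(prof.to_frame(), out / f"profile_{c}_{tp:g}h.tsv")
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            avg = dr.aggregate_timepoints(tp_profiles)
        captured.extend(str(w.message) for w in wlist)
        profiles[comp] = avg
        _write_tsv(avg.to_frame(), out / f"profile_{comp}_avg.tsv")

    _write_json(
        {"n_fits": len(fit_rows), "warnings": captured},
        out / "ic50_summary.json",
    )
    return profiles


def run_screen(
    expression_tsv,
    profile: dr.IC50Profile,
    out_dir,
    gene_sets: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    sidedness: str = "one_sided",
    method: str = "spearman",
    universe: list[str] | None = None,
) -> dict:
    """Detection-filter, screen, and test overlaps against reference sets.

    The universe for overlap testing defaults to the detection-filtered
    transcript set. Returns the JSON-ready summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = sc.read_expression_tsv(expression_tsv)
    filtered = sc.filter_by_detection(matrix)
    result = sc.genome_screen(
        filtered, profile, alpha=alpha, sidedness=sidedness, method=method
    )
    _write_tsv(result.table, out / "correlations.tsv")

    summary = {
        "n_input": result.n_input,
        "n_filtered": result.n_filtered,
        "alpha": alpha,
        "sidedness": sidedness,
        "method": method,
        "n_positive": len(result.positive_set),
        "n_negative": len(result.negative_set),
        "positive_set": sorted(result.positive_set),
        "negative_set": sorted(result.negative_set),
        "overlaps": {},
        "warnings": [],
    }
    uni = universe if universe is not None else list(filtered.transcript_ids)
    for name, ref_set in (gene_sets or {}).items():
        if not ref_set:
            raise ValueError(f"reference gene set {name!r} is empty")
        res = ov.overlap_test(result.positive_set, ref_set, uni)
        summary["overlaps"][name] = {
            "N": res.universe_size,
            "K": res.set_a_size,
            "n": res.set_b_size,
            "k": res.overlap,
            "overlap_fraction_of_b_pct": res.overlap_fraction_of_b,
            "p_upper": res.p_upper,
            "p_point": res.p_point,
        }
    _write_json(summary, out / "screen_summary.json")
    return summary


def run_motility(
    track_csv, out_dir, t_max: float, conditions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-track statistics and per-condition summaries from a track CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(track_csv)
    tracks = mo.tracks_from_table(table, t_max=t_max)
    stats = [mo.track_stats(t) for t in tracks]
    per_track = pd.DataFrame(
        {
            "track_id": [s.track_id for s in stats],
            "speed_um_min": [s.speed for s in stats],
            "persistence": [s.persistence for s in stats],
            "path_length_um": [s.path_length for s in stats],
            "net_displacement_um": [s.net_displacement for s in stats],
            "t_tracked_min": [s.t_tracked for s in stats],
        }
    )
    _write_tsv(per_track, out / "motility_per_track.tsv")
    labels = (
        [conditions.get(t.track_id, "all") for t in tracks] if conditions else None
    )
    summary = mo.summarize_condition(tracks, labels)
    _write_tsv(summary, out / "motility_summary.tsv")
    return summary


def run_all(
    out_dir,
    seed: int = 1,
    alpha: float = 0.05,
    n_transcripts: int = 2000,
    n_planted_positive: int = 50,
    n_planted_negative: int = 30,
    reference_set_size: int = 90,
    reference_overlap: int = 12,
) -> dict:
    """Full synthetic analysis: simulate, fit IC50s, screen, test overlap.

    The expression fixture's planted signature is the simulated panel's
    averaged normalized IC50 profile, so the screen's target pattern and
    the planted pattern coincide by construction. The reference gene set
    shares ``reference_overlap`` members with the planted-positive set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # plates -> profiles
    plate_cfg = syn.PlateSimConfig(seed=seed, noise_sd=100.0)
    plate = syn.simulate_plate(plate_cfg)
    _atomic_write_text(out / "plate.csv", plate.to_csv(index=False))
    profiles = run_ic50(out / "plate.csv", out)
    profile = profiles[plate_cfg.compound]

    # expression planted along the fitted profile
    expr_cfg = syn.ExpressionSimConfig(
        n_transcripts=n_transcripts,
        n_cell_lines=len(profile.cell_lines),
        planted_signature=list(profile.normalized),
        n_planted_positive=n_planted_positive,
        n_planted_negative=n_planted_negative,
        seed=seed + 1,
    )
    values, calls, truth = syn.simulate_expression(expr_cfg)
    values.columns = profile.cell_lines
    calls.columns = profile.cell_lines
    sc.write_expression_tsv(
        sc.ExpressionMatrix(values=values, calls=calls), out / "expression.tsv"
    )
    _write_tsv(truth, out / "truth.tsv")

    planted_pos = list(truth[truth["direction"] == 1]["transcript_id"])
    reference = syn.simulate_gene_set(
        universe=list(values.index),
        include=planted_pos,
        n_total=reference_set_size,
        n_from_include=reference_overlap,
        seed=seed + 2,
    )
    _atomic_write_text(
        out / "reference_set.txt", "\n".join(reference) + "\n"
    )
    screen_summary = run_screen(
        out / "expression.tsv",
        profile,
        out,
        gene_sets={"reference": reference},
        alpha=alpha,
    )

    # motility
    track_cfg = syn.TrackSimConfig(seed=seed + 3, dropout_prob=0.02)
    tracks = syn.simulate_tracks(track_cfg)
    _atomic_write_text(out / "tracks.csv", tracks.to_csv(index=False))
    run_motility(out / "tracks.csv", out, t_max=track_cfg.total_time)

    report = {
        "seed": seed,
        "alpha": alpha,
        "profile": {
            "cell_lines": profile.cell_lines,
            "nV": [float(v) for v in profile.normalized],
            "ranks": [float(r) for r in profile.ranks],
        },
        "screen": {
            k: screen_summary[k]
            for k in ("n_filtered", "n_positive", "n_negative", "overlaps")
        },
    }
    _write_json(report, out / "report.json")
    return report
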