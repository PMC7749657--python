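"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators emulate the study's inputs end to end:

* ``simulate_plate`` — plate-reader fluorescence for dose series across
  cell lines, generated from per-line ground-truth Hill parameters plus
  blank-well background and additive measurement noise;
* ``simulate_expression`` — a transcript x cell-line matrix with a
  planted subset of transcripts whose cross-line ordering follows (or
  opposes) a planted susceptibility signature, plus P/M/A detection
  calls; the planted truth is returned so screen recall/precision can
  be measured;
* ``simulate_tracks`` — persistent-random-walk cell trajectories with
  variable tracking duration (per-frame dropout).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dose_response import hill_function

__all__ = [
    "PlateSimConfig",
    "ExpressionSimConfig",
    "TrackSimConfig",
    "simulate_plate",
    "simulate_expression",
    "simulate_tracks",
    "simulate_gene_set",
]


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {fieldname}: {msg}")


# ---------------------------------------------------------------------------
# plates


def _default_lines() -> dict[str, tuple[float, float, float, float]]:
    # (min %, max %, IC50 µM, H) per line; IC50s spread over ~6x as is
    # typical for a five-line panel, viability at dose 0 pinned at 100%.
    return {
        "LINE1": (8.0, 100.0, 5.0, 1.5),
        "LINE2": (10.0, 100.0, 9.0, 1.2),
        "LINE3": (6.0, 100.0, 14.0, 1.8),
        "LINE4": (12.0, 100.0, 22.0, 1.0),
        "LINE5": (9.0, 100.0, 30.0, 1.4),
    }


def _default_doses() -> list[float]:
    # 0 (untreated) plus eight 2-fold steps bracketing the default IC50s
    return [0.0] + [100.0 / 2**i for i in range(7, -1, -1)]


@dataclass
class PlateSimConfig:
    """Ground truth and acquisition settings for a simulated viability plate."""

    cell_lines: list[str] = field(default_factory=lambda: list(_default_lines()))
    true_hill_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_lines
    )
    dose_ladder: list[float] = field(default_factory=_default_doses)
    n_replicates: int = 6
    noise_sd: float = 0.0
    background_level: float = 500.0
    reference_intensity: float = 10000.0
    multiplicative_noise: bool = False
    compound: str = "DRUG"
    timepoint_h: float = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.cell_lines) >= 1, "cell_lines", "need at least one")
        for line in self.cell_lines:
            _require(
                line in self.true_hill_params,
                "true_hill_params",
                f"missing parameters for cell line {line!r}",
            )
            mn, mx, ic50, h = self.true_hill_params[line]
            _require(ic50 > 0, "true_hill_params", f"IC50 must be > 0 ({line})")
            _require(h > 0, "true_hill_params", f"H must be > 0 ({line})")
            _require(
                0 <= mn < mx, "true_hill_params", f"need 0 <= min < max ({line})"
            )
        doses = np.asarray(self.dose_ladder, dtype=float)
        _require(np.all(doses >= 0), "dose_ladder", "doses must be non-negative")
        _require(
            np.all(np.diff(doses) > 0),
            "dose_ladder",
            "doses must be strictly increasing",
        )
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.background_level >= 0, "background_level", "must be >= 0")
        _require(self.reference_intensity > 0, "reference_intensity", "must be > 0")


def simulate_plate(config: PlateSimConfig) -> pd.DataFrame:
    """Simulate raw plate-reader intensities from ground-truth Hill curves.

    Each sample well reads ``background + reference * anI(dose)/100``
    plus Gaussian noise (additive by default; multiplicative scales the
    noise sd with the mean signal). Dose-0 entries of the ladder become
    untreated reference wells; blank wells carry background only.
    """
    rng = np.random.default_rng(config.seed)
    rows = []

    def noisy(mean: float) -> float:
        if config.noise_sd == 0:
            return mean
        sd = config.noise_sd
        if config.multiplicative_noise:
            sd = sd * mean / config.reference_intensity
        return mean + rng.normal(0.0, sd)

    for line in config.cell_lines:
        mn, mx, ic50, h = config.true_hill_params[line]
        for rep in range(1, config.n_replicates + 1):
            for dose in config.dose_ladder:
                viability = hill_function(dose, mn, mx, ic50, h)
                mean = (
                    config.background_level
                    + config.reference_intensity * viability / 100.0
                )
                rows.append(
                    {
                        "cell_line": line,
                        "compound": config.compound,
                        "timepoint_h": config.timepoint_h,
                        "dose_uM": dose,
                        "replicate": rep,
                        "well_type": "untreated" if dose == 0 else "sample",
                        "intensity": noisy(mean),
                    }
                )
            rows.append(
                {
                    "cell_line": line,
                    "compound": config.compound,
                    "timepoint_h": config.timepoint_h,
                    "dose_uM": 0.0,
                    "replicate": rep,
                    "well_type": "blank",
                    "intensity": noisy(config.background_level),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression matrix with planted signal


@dataclass
class ExpressionSimConfig:
    """Planted-signal expression matrix settings.

    ``planted_signature`` is the per-line susceptibility pattern the
    planted transcripts follow (positives rank-concordant, negatives
    rank-anticoncordant). Null transcripts are drawn exchangeably over
    the patterns whose |Spearman rho| with the signature stays below
    ``null_max_abs_rho``, so that the planted sets are exactly
    identifiable by an exact-p screen at the matching significance
    level — the property the generator exists to provide.
    """

    n_transcripts: int = 22277
    n_cell_lines: int = 5
    planted_signature: list[float] | None = None
    n_planted_positive: int = 144
    n_planted_negative: int = 281
    pattern_noise_sd: float = 0.0
    frac_absent_calls: float = 0.0
    null_max_abs_rho: float = 0.9
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_transcripts >= 1, "n_transcripts", "must be >= 1")
        _require(self.n_cell_lines >= 3, "n_cell_lines", "must be >= 3")
        _require(
            self.n_planted_positive >= 0 and self.n_planted_negative >= 0,
            "n_planted_positive",
            "planted counts must be >= 0",
        )
        _require(
            self.n_planted_positive + self.n_planted_negative
            <= self.n_transcripts,
            "n_planted_positive",
            "planted counts exceed n_transcripts",
        )
        _require(
            0 <= self.frac_absent_calls < 1,
            "frac_absent_calls",
            "must be in [0, 1)",
        )
        _require(self.pattern_noise_sd >= 0, "pattern_noise_sd", "must be >= 0")
        _require(
            0 < self.null_max_abs_rho <= 1, "null_max_abs_rho", "must be in (0, 1]"
        )
        if self.planted_signature is not None:
            _require(
                len(self.planted_signature) == self.n_cell_lines,
                "planted_signature",
                "length must equal n_cell_lines",
            )
            _require(
                len(set(self.planted_signature)) == self.n_cell_lines,
                "planted_signature",
                "signature values must be distinct",
            )

    def signature(self) -> np.ndarray:
        if self.planted_signature is not None:
            return np.asarray(self.planted_signature, dtype=float)
        return np.linspace(0.0, 1.0, self.n_cell_lines)


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple["pd.DataFrame", "pd.DataFrame", pd.DataFrame]:
    """Generate (values, calls, truth) for a planted expression matrix.

    Returns the value and call DataFrames (transcript x line, ready to
    wrap in :class:`~ic50screen.screen.ExpressionMatrix`) and a truth
    table with one row per planted transcript (columns transcript_id,
    direction = +1/-1).
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_cell_lines
    n = config.n_transcripts
    sig = config.signature()
    z = (sig - sig.mean()) / sig.std()

    lines = [f"CL{i+1}" for i in range(m)]
    ids = np.array([f"T{i:06d}" for i in range(1, n + 1)])
    positions = rng.permutation(n)
    n_pos, n_neg = config.n_planted_positive, config.n_planted_negative
    pos_idx = positions[:n_pos]
    neg_idx = positions[n_pos : n_pos + n_neg]
    null_idx = positions[n_pos + n_neg :]

    values = np.empty((n, m))
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    noise = (
        rng.normal(0.0, config.pattern_noise_sd, size=(n, m))
        if config.pattern_noise_sd > 0
        else np.zeros((n, m))
    )
    values[pos_idx] = baseline[pos_idx, None] + z[None, :] + noise[pos_idx]
    values[neg_idx] = baseline[neg_idx, None] - z[None, :] + noise[neg_idx]

    # Null patterns: exchangeable over the sub-critical orderings only,
    # redrawn while they (anti)correlate with the signature at or above
    # null_max_abs_rho. This keeps the planted sets exactly separable.
    n_null = null_idx.size
    zr = rankdata(sig).astype(float)
    zr = (zr - zr.mean()) / zr.std()

    def _row_rhos(block: np.ndarray) -> np.ndarray:
        ranks = block.argsort(axis=1).argsort(axis=1) + 1.0
        zp = (ranks - ranks.mean(axis=1, keepdims=True)) / ranks.std(
            axis=1, keepdims=True
        )
        return zp @ zr / m

    pat = rng.normal(0.0, 1.0, size=(n_null, m))
    for _ in range(1000):
        bad = np.abs(_row_rhos(pat)) >= config.null_max_abs_rho - 1e-12
        if not bad.any():
            break
        pat[bad] = rng.normal(0.0, 1.0, size=(int(bad.sum()), m))
    else:  # pragma: no cover - requires pathological config
        raise RuntimeError(
            "could not draw sub-critical null patterns; raise null_max_abs_rho"
        )
    values[null_idx] = baseline[null_idx, None] + pat

    fa = config.frac_absent_calls
    u = rng.random(size=(n, m))
    calls = np.where(u < fa, "A", np.where(u < fa + (1 - fa) / 2, "M", "P"))

    values_df = pd.DataFrame(values, index=pd.Index(ids, name="gene_id"), columns=lines)
    calls_df = pd.DataFrame(calls, index=pd.Index(ids, name="gene_id"), columns=lines)
    truth = pd.DataFrame(
        {
            "transcript_id": np.concatenate([ids[pos_idx], ids[neg_idx]]),
            "direction": [1] * n_pos + [-1] * n_neg,
        }
    )
    return values_df, calls_df, truth


def simulate_gene_set(
    universe: list[str],
    include: list[str],
    n_total: int,
    n_from_include: int,
    seed: int = 0,
) -> list[str]:
    """A gene set of ``n_total`` labels with a planted overlap.

    Draws ``n_from_include`` labels from ``include`` and fills the rest
    from the remainder of the universe, emulating a reference set that
    shares a known number of members with a screen hit set.
    """
    rng = np.random.default_rng(seed)
    include = [g for g in include if g in set(universe)]
    if n_from_include > len(include):
        raise ValueError("n_from_include exceeds available include labels")
    if n_total < n_from_include:
        raise ValueError("n_total must be >= n_from_include")
    rest = sorted(set(universe) - set(include))
    if n_total - n_from_include > len(rest):
        raise ValueError("n_total exceeds universe")
    chosen = list(rng.choice(include, size=n_from_include, replace=False))
    chosen += list(rng.choice(rest, size=n_total - n_from_include, replace=False))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# cell tracks


@dataclass
class TrackSimConfig:
    """Persistent-random-walk settings for simulated cell trajectories."""

    n_cells: int = 100
    frame_interval: float = 20.0   # minutes
    total_time: float = 2880.0     # minutes (48 h acquisition)
    speed_mean: float = 0.5        # µm/min
    speed_sd: float = 0.0          # between-cell speed spread, µm/min
    turning_persistence: float = 0.7
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells", "must be >= 1")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(
            self.total_time > 0
            and abs(self.total_time / self.frame_interval
                    - round(self.total_time / self.frame_interval)) < 1e-9,
            "total_time",
            "must be a positive multiple of frame_interval",
        )
        _require(
            0 <= self.turning_persistence < 1,
            "turning_persistence",
            "must be in [0, 1)",
        )
        _require(0 <= self.dropout_prob <= 1, "dropout_prob", "must be in [0, 1]")
        _require(self.speed_mean >= 0, "speed_mean", "must be >= 0")
        _require(self.speed_sd >= 0, "speed_sd", "must be >= 0")


def simulate_tracks(config: TrackSimConfig) -> pd.DataFrame:
    """Simulate persistent random walks with per-frame dropout.

    Each step direction is a unit vector blending the previous direction
    (weight = turning_persistence) with a fresh random direction; step
    length is the cell's speed times the frame interval. Tracks always
    retain at least two observations so speed stays defined.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.total_time / config.frame_interval))
    p = config.turning_persistence
    rows = []
    for cell in range(1, config.n_cells + 1):
        tid = f"cell{cell:04d}"
        speed = config.speed_mean
        if config.speed_sd > 0:
            speed = abs(rng.normal(config.speed_mean, config.speed_sd))
        step = speed * config.frame_interval
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        pos = rng.uniform(0, 1000.0, size=2)
        rows.append((tid, 0, 0.0, pos[0], pos[1]))
        for frame in range(1, n_frames + 1):
            theta = rng.uniform(0, 2 * np.pi)
            fresh = np.array([np.cos(theta), np.sin(theta)])
            blend = p * direction + (1 - p) * fresh
            norm = np.hypot(blend[0], blend[1])
            direction = blend / norm if norm > 0 else fresh
            pos = pos + step * direction
            rows.append(
                (tid, frame, frame * config.frame_interval, pos[0], pos[1])
            )
            if frame >= 1 and frame < n_frames and config.dropout_prob > 0:
                if rng.random() < config.dropout_prob:
                    break
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"]
    )
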