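"""Plate-based viability normalization and Hill-sigmoid IC50 estimation.

The processing chain mirrors the standard CellTiter-Blue workflow:

1. subtract the blank-well background from every raw fluorescence reading;
2. normalize each reading to the untreated reference intensity ``I0``
   (``nI = 100 * I / I0``, percent of untreated);
3. average replicates into the mean dose-response pattern ``anI``;
4. fit the decreasing Hill sigmoid

   ``anI(D) = min + (max - min) / (1 + (D / IC50)**H)``

   by nonlinear least squares to obtain the half-maximal inhibitory
   concentration IC50 and the Hill coefficient H;
5. collect per-cell-line IC50 values into a profile with min-max
   normalized values ``nV`` in [0, 1] and average ranks.

The normalized profile (the "IC50 signature") is what downstream
expression screening correlates against.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseSeries",
    "NormalizedResponse",
    "HillFit",
    "IC50Profile",
    "HillCurveFitter",
    "subtract_background",
    "normalize_viability",
    "hill_function",
    "fit_hill",
    "build_profile",
    "aggregate_timepoints",
    "series_from_plate",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DoseResponseSeries:
    """Raw dose series for one (cell line, compound, timepoint).

    ``raw_intensities`` is a replicate x dose matrix of fluorescence
    readings (background NOT yet subtracted); ``background`` is the
    blank-well intensity and ``reference_intensity`` the
    background-subtracted untreated intensity I0.
    """

    cell_line: str
    compound: str
    timepoint: float
    doses: np.ndarray
    raw_intensities: np.ndarray
    background: float
    reference_intensity: float

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.raw_intensities = np.atleast_2d(
            np.asarray(self.raw_intensities, dtype=float)
        )
        if self.doses.ndim != 1:
            raise ValueError("doses must be a 1-D vector")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        if self.raw_intensities.shape[1] != self.doses.size:
            raise ValueError(
                "raw_intensities must have one column per dose "
                f"(got {self.raw_intensities.shape[1]} columns, "
                f"{self.doses.size} doses)"
            )
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.reference_intensity <= 0:
            raise ValueError(
                "reference signal below background: reference_intensity must "
                "be positive after background subtraction"
            )


@dataclass
class NormalizedResponse:
    """Viability as percent of untreated, per replicate and averaged."""

    doses: np.ndarray
    nI: np.ndarray           # replicate x dose, percent of untreated
    anI: np.ndarray          # mean over replicates, percent
    n_replicates: int


@dataclass
class HillFit:
    """Fitted Hill-sigmoid parameters with diagnostics."""

    min: float
    max: float
    ic50: float
    hill_coefficient: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return hill_function(
            doses, self.min, self.max, self.ic50, self.hill_coefficient
        )


@dataclass
class IC50Profile:
    """Per-cell-line IC50 values with min-max normalization and ranks.

    ``normalized`` is ``(V - Vmin) / (Vmax - Vmin)`` so the most
    sensitive line sits at 0 and the most resistant at 1; ``ranks`` are
    ascending average ranks (rank 1 = lowest IC50 = most sensitive).
    """

    cell_lines: list[str]
    values: np.ndarray
    normalized: np.ndarray = field(init=False)
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.cell_lines) != self.values.size:
            raise ValueError("cell_lines and values length mismatch")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("cell_lines must be unique")
        vmin, vmax = self.values.min(), self.values.max()
        if vmax > vmin:
            self.normalized = (self.values - vmin) / (vmax - vmin)
        else:
            warnings.warn(
                "all IC50 values are equal; normalized profile is degenerate "
                "(set to all zeros)",
                stacklevel=2,
            )
            self.normalized = np.zeros_like(self.values)
        self.ranks = rankdata(self.values, method="average")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line": self.cell_lines,
                "V_uM": self.values,
                "nV": self.normalized,
                "rank": self.ranks,
            }
        )


# ---------------------------------------------------------------------------
# normalization (background subtraction and percent-of-untreated)


def subtract_background(
    raw: np.ndarray, background: float, floor: float = 1e-6
) -> np.ndarray:
    """Subtract the blank-well background from raw intensities.

    Values falling at or below zero are clipped to ``floor`` (a small
    positive epsilon) so the subsequent ratio normalization stays
    defined; clipping is logged since it signals readings at or below
    the blank level.
    """
    if background < 0:
        raise ValueError("background must be non-negative")
    raw = np.asarray(raw, dtype=float)
    if raw.size and background >= raw.max():
        raise ValueError(
            "reference signal below background: all intensities are <= the "
            "blank-well background"
        )
    out = raw - background
    n_clip = int(np.count_nonzero(out < floor))
    if n_clip:
        logger.warning(
            "clipped %d background-subtracted intensities below floor=%g",
            n_clip,
            floor,
        )
        out = np.maximum(out, floor)
    return out


def normalize_viability(
    series: DoseResponseSeries, floor: float = 1e-6
) -> NormalizedResponse:
    """Convert raw intensities to percent-of-untreated viability.

    Per replicate and dose, ``nI = 100 * (I - background) / I0`` where
    I0 is the series' background-subtracted untreated reference; the
    averaged pattern ``anI`` is the arithmetic mean over replicates.
    """
    if series.reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    corrected = subtract_background(
        series.raw_intensities, series.background, floor=floor
    )
    nI = 100.0 * corrected / series.reference_intensity
    anI = nI.mean(axis=0)
    return NormalizedResponse(
        doses=series.doses, nI=nI, anI=anI, n_replicates=nI.shape[0]
    )


# ---------------------------------------------------------------------------
# Hill sigmoid


def hill_function(
    dose: np.ndarray | float,
    min_: float,
    max_: float,
    ic50: float,
    hill: float,
) -> np.ndarray | float:
    """Decreasing Hill sigmoid: min + (max - min) / (1 + (D/IC50)**H).

    At dose 0 the value is ``max``; at dose == IC50 it is the midpoint
    (min + max) / 2; for H > 0 it decreases monotonically to ``min``.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if hill <= 0:
        raise ValueError("hill coefficient must be positive")
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    val = min_ + (max_ - min_) / (1.0 + (dose / ic50) ** hill)
    return float(val) if val.ndim == 0 else val


class HillCurveFitter(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the decreasing Hill sigmoid.

    A scikit-learn style regressor: ``fit(doses, viability)`` estimates
    (min, max, IC50, H); ``predict(doses)`` evaluates the fitted curve.

    Parameters
    ----------
    min_points : int
        Minimum number of distinct non-zero doses required.
    max_restarts : int
        Random restarts jittering the IC50 start value by a factor in
        [0.1, 10] before declaring non-convergence.
    ic50_window_factor : float
        The fit is flagged non-converged when the fitted IC50 lies
        outside the observed dose range by more than this factor.
    hill_max, viability_max : float
        Upper bounds for H and for the max/min plateaus; the lower
        bounds (0) keep the decreasing branch of the sigmoid.
    random_state : int
        Seed for the restart jitter.

    Attributes
    ----------
    min_, max_, ic50_, hill_ : float
        Fitted plateaus (percent of untreated), IC50 (dose units) and
        Hill coefficient.
    rss_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
    n_points_ : int
    """

    def __init__(
        self,
        min_points: int = 4,
        max_restarts: int = 10,
        ic50_window_factor: float = 100.0,
        hill_max: float = 20.0,
        viability_max: float = 200.0,
        random_state: int = 0,
    ) -> None:
        self.min_points = min_points
        self.max_restarts = max_restarts
        self.ic50_window_factor = ic50_window_factor
        self.hill_max = hill_max
        self.viability_max = viability_max
        self.random_state = random_state

    def _validate(self, doses: np.ndarray, y: np.ndarray):
        doses = np.asarray(doses, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if doses.size != y.size:
            raise ValueError("doses and viability must have equal length")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(doses)):
            raise ValueError("doses and viability must be finite")
        if np.unique(doses[doses > 0]).size < self.min_points:
            raise ValueError(
                f"at least {self.min_points} distinct non-zero doses are "
                "required for Hill fitting"
            )
        if np.ptp(y) == 0:
            raise ValueError("no dose dependence: all viability values equal")
        return doses, y

    def fit(self, X, y):
        """Fit the sigmoid to (dose, mean viability) pairs.

        ``X`` is the dose vector (1-D, or a single-column 2-D array for
        sklearn pipeline compatibility); ``y`` the averaged normalized
        viability in percent.
        """
        doses = np.asarray(X, dtype=float)
        if doses.ndim == 2:
            if doses.shape[1] != 1:
                raise ValueError("X must be a dose vector or a single column")
            doses = doses[:, 0]
        doses, y = self._validate(doses, y)
        # sort so the fit is independent of row order
        order = np.argsort(doses, kind="stable")
        d, v = doses[order], y[order]

        lo, hi = float(v.min()), float(v.max())
        mid = 0.5 * (lo + hi)
        pos = d[d > 0]
        ic50_0 = float(pos[np.argmin(np.abs(v[d > 0] - mid))])
        p0 = [lo, hi, ic50_0, 1.0]
        bounds = (
            [0.0, 0.0, 1e-12, 1e-6],
            [self.viability_max, self.viability_max, np.inf, self.hill_max],
        )

        def model(D, mn, mx, ic50, h):
            return mn + (mx - mn) / (1.0 + (D / ic50) ** h)

        rng = np.random.default_rng(self.random_state)
        best = None
        start = list(p0)
        for attempt in range(self.max_restarts + 1):
            try:
                popt, _ = curve_fit(
                    model, d, v, p0=start, bounds=bounds, maxfev=20000
                )
                rss = float(np.sum((model(d, *popt) - v) ** 2))
                if best is None or rss < best[1]:
                    best = (popt, rss)
                if rss <= 1e-10 * max(1.0, float(np.sum(v**2))):
                    break
            except RuntimeError:
                pass
            start = list(p0)
            start[2] = ic50_0 * float(10.0 ** rng.uniform(-1, 1))

        if best is None:
            logger.warning("Hill fit failed to converge after restarts")
            self.min_, self.max_ = lo, hi
            self.ic50_, self.hill_ = ic50_0, 1.0
            self.rss_ = float(np.sum((model(d, lo, hi, ic50_0, 1.0) - v) ** 2))
            self.converged_ = False
        else:
            popt, rss = best
            self.min_, self.max_, self.ic50_, self.hill_ = map(float, popt)
            if self.max_ < self.min_:  # flat fits can land here
                self.min_, self.max_ = self.max_, self.min_
            self.rss_ = rss
            in_window = (
                d.max() * self.ic50_window_factor >= self.ic50_
                and self.ic50_ * self.ic50_window_factor >= pos.min()
            )
            self.converged_ = bool(in_window)
            if not in_window:
                logger.warning(
                    "fitted IC50 %.3g outside dose range [%.3g, %.3g] by more "
                    "than factor %g; flagged non-converged",
                    self.ic50_,
                    pos.min(),
                    d.max(),
                    self.ic50_window_factor,
                )
        self.n_points_ = int(d.size)
        return self

    def predict(self, X):
        doses = np.asarray(X, dtype=float)
        if doses.ndim == 2:
            doses = doses[:, 0]
        return hill_function(doses, self.min_, self.max_, self.ic50_, self.hill_)

    def to_hill_fit(self) -> HillFit:
        return HillFit(
            min=self.min_,
            max=self.max_,
            ic50=self.ic50_,
            hill_coefficient=self.hill_,
            rss=self.rss_,
            converged=self.converged_,
            n_points=self.n_points_,
        )


def fit_hill(response: NormalizedResponse, **kwargs) -> HillFit:
    """Fit the Hill sigmoid to the replicate-averaged pattern ``anI``."""
    est = HillCurveFitter(**kwargs)
    est.fit(response.doses, response.anI)
    return est.to_hill_fit()


# ---------------------------------------------------------------------------
# profiles across cell lines


def build_profile(fits: dict[str, HillFit]) -> IC50Profile:
    """Assemble per-cell-line IC50s into a normalized, ranked profile.

    Non-converged fits are excluded with a warning; at least two
    converged lines are required.
    """
    kept_lines: list[str] = []
    values: list[float] = []
    for line, f in fits.items():
        if not f.converged:
            warnings.warn(
                f"excluding cell line {line!r}: Hill fit did not converge",
                stacklevel=2,
            )
            continue
        kept_lines.append(line)
        values.append(f.ic50)
    if len(kept_lines) < 2:
        raise ValueError("at least 2 converged cell lines are required")
    return IC50Profile(cell_lines=kept_lines, values=np.asarray(values))


def aggregate_timepoints(profiles: list[IC50Profile]) -> IC50Profile:
    """Average normalized IC50 patterns over timepoints, then re-normalize.

    All profiles must cover the same cell lines; averaging is done on the
    normalized values (the per-timepoint µM scales differ), so the
    aggregated profile's ``values`` are unitless mean normalized IC50s.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0].cell_lines
    for p in profiles[1:]:
        if set(p.cell_lines) != set(ref):
            missing = set(ref) ^ set(p.cell_lines)
            raise ValueError(f"cell-line sets differ across timepoints: {sorted(missing)}")
    stacked = np.vstack(
        [
            p.normalized[[p.cell_lines.index(line) for line in ref]]
            for p in profiles
        ]
    )
    mean_nv = stacked.mean(axis=0)
    return IC50Profile(cell_lines=list(ref), values=mean_nv)


# ---------------------------------------------------------------------------
# plate-table adapter


def series_from_plate(
    plate: pd.DataFrame,
    cell_line: str,
    compound: str,
    timepoint: float,
) -> DoseResponseSeries:
    """Extract one dose series from a long-format plate table.

    Expects columns cell_line, compound, timepoint_h, dose_uM,
    replicate, well_type (sample/untreated/blank) and intensity, the
    dialect written by the plate simulator. The background is the mean
    blank intensity; I0 is the mean untreated intensity minus
    background. Untreated wells enter the series as the dose-0 column.
    """
    required = {
        "cell_line",
        "compound",
        "timepoint_h",
        "dose_uM",
        "replicate",
        "well_type",
        "intensity",
    }
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    sub = plate[
        (plate["cell_line"] == cell_line)
        & (plate["compound"] == compound)
        & (plate["timepoint_h"] == timepoint)
    ]
    if sub.empty:
        raise ValueError(
            f"no rows for ({cell_line!r}, {compound!r}, {timepoint} h)"
        )
    blanks = sub[sub["well_type"] == "blank"]["intensity"]
    background = float(blanks.mean()) if len(blanks) else 0.0
    untreated = sub[sub["well_type"] == "untreated"]
    if untreated.empty:
        raise ValueError("plate table has no untreated reference wells")
    reference = float(untreated["intensity"].mean()) - background

    wells = pd.concat([untreated.assign(dose_uM=0.0), sub[sub["well_type"] == "sample"]])
    pivot = wells.pivot_table(
        index="replicate", columns="dose_uM", values="intensity", aggfunc="mean"
    ).sort_index(axis=1)
    doses = pivot.columns.to_numpy(dtype=float)
    return DoseResponseSeries(
        cell_line=cell_line,
        compound=compound,
        timepoint=float(timepoint),
        doses=doses,
        raw_intensities=pivot.to_numpy(dtype=float),
        background=background,
        reference_intensity=reference,
    )
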