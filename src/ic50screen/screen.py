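"""Genome-wide correlation screen of expression patterns against an IC50 profile.

With only a handful of cell lines (five in the motivating design), the
null distribution of the Spearman rank correlation is coarse and the
usual large-sample p-values are unreliable. The screen therefore uses
the *exact* permutation null: all n! orderings of the profile's ranks
are enumerated and the p-value is the fraction of permutations whose
correlation is at least as extreme as the observed one. At n = 5 the
one-sided p-value floor is 1/120 and rho >= 0.9 is the smallest
correlation significant at alpha = 0.05.

Transcripts are first filtered on microarray detection calls (Present /
Marginal / Absent): only transcripts called P or M in every cell line
are screened, the standard guard against correlating noise-level
signals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .dose_response import IC50Profile

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneCorrelation",
    "ScreenResult",
    "CorrelationScreen",
    "filter_by_detection",
    "spearman_exact",
    "exact_null_distribution",
    "genome_screen",
    "signature_correlation",
    "rank_lines_by_gene",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_set",
]

VALID_CALLS = frozenset({"P", "M", "A"})


@dataclass
class ExpressionMatrix:
    """Transcript x cell-line expression values with P/M/A detection calls.

    ``values`` and ``calls`` are DataFrames indexed by transcript id
    with one column per cell line, identical shapes.
    """

    values: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.calls.shape:
            raise ValueError("values and calls must have identical shape")
        if list(self.values.columns) != list(self.calls.columns):
            raise ValueError("values and calls must share cell-line columns")
        if not self.values.index.equals(self.calls.index):
            raise ValueError("values and calls must share the transcript index")
        if self.values.columns.duplicated().any():
            raise ValueError("cell_lines must be unique")
        bad = set(np.unique(self.calls.to_numpy())) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneCorrelation:
    """Correlation of one transcript's pattern with the IC50 profile."""

    transcript_id: str
    rho: float
    p_one_sided_pos: float
    p_one_sided_neg: float
    p_two_sided: float
    n: int
    degenerate: bool = False


@dataclass
class ScreenResult:
    """Selected positive/negative transcript sets at a significance level."""

    n_input: int
    n_filtered: int
    positive_set: list[str]
    negative_set: list[str]
    alpha: float
    sidedness: str
    table: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# detection-call filter


def filter_by_detection(
    matrix: ExpressionMatrix, accepted: set[str] = frozenset({"P", "M"})
) -> ExpressionMatrix:
    """Keep transcripts whose call is in ``accepted`` in ALL cell lines."""
    accepted = set(accepted)
    if not accepted <= VALID_CALLS:
        raise ValueError(f"accepted calls must be a subset of {sorted(VALID_CALLS)}")
    keep = matrix.calls.isin(accepted).all(axis=1)
    if not keep.any():
        raise ValueError(
            "detection filter removed every transcript; relax the accepted "
            "call set"
        )
    return ExpressionMatrix(
        values=matrix.values.loc[keep], calls=matrix.calls.loc[keep]
    )


# ---------------------------------------------------------------------------
# exact small-n rank correlation


def _standardize_ranks(x: np.ndarray) -> np.ndarray | None:
    """Average ranks, centered and scaled to unit population variance.

    Returns None for a constant vector (correlation undefined).
    """
    r = rankdata(x, method="average")
    sd = r.std()
    if sd == 0:
        return None
    return (r - r.mean()) / sd


def _perm_matrix(y_ranks: np.ndarray) -> np.ndarray:
    """All n! permutations of the (possibly tied) rank multiset, standardized.

    Rows are centered/unit-variance permuted rank vectors; correlating a
    standardized x against each row and dividing by n yields the exact
    permutation null of Spearman's rho.
    """
    n = y_ranks.size
    perms = np.array(list(itertools.permutations(y_ranks)), dtype=float)
    perms = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(
        axis=1, keepdims=True
    )
    return perms


def exact_null_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null of Spearman's rho for n untied observations.

    Returns (support, probabilities): the distinct achievable rho values
    and their probabilities under uniform permutation, summing to 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    base = _standardize_ranks(np.arange(1, n + 1))
    perms = _perm_matrix(np.arange(1, n + 1, dtype=float))
    rhos = perms @ base / n
    rhos = np.round(rhos, 12)
    support, counts = np.unique(rhos, return_counts=True)
    return support, counts / counts.sum()


def spearman_exact(
    x: np.ndarray,
    y: np.ndarray,
    exact_cap: int = 8,
    transcript_id: str = "",
) -> GeneCorrelation:
    """Spearman rho with exact permutation p-values for small n.

    rho is the product-moment correlation of average ranks. For
    n <= ``exact_cap`` the p-values enumerate all n! permutations of
    y's rank multiset (ties permute the observed tied ranks); beyond the
    cap the t-approximation is used with a logged notice. A constant
    input yields rho = 0, p = 1 and the degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")

    zx = _standardize_ranks(x)
    zy = _standardize_ranks(y)
    if zx is None or zy is None:
        return GeneCorrelation(
            transcript_id=transcript_id,
            rho=0.0,
            p_one_sided_pos=1.0,
            p_one_sided_neg=1.0,
            p_two_sided=1.0,
            n=n,
            degenerate=True,
        )
    rho = float(zx @ zy / n)

    if n <= exact_cap:
        perms = _perm_matrix(rankdata(y, method="average"))
        null = perms @ zx / n
        eps = 1e-9
        p_pos = float(np.mean(null >= rho - eps))
        p_neg = float(np.mean(null <= rho + eps))
        p_two = float(np.mean(np.abs(null) >= abs(rho) - eps))
    else:
        logger.info(
            "n=%d above exact enumeration cap %d; using t-approximation",
            n,
            exact_cap,
        )
        r = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p_pos = float(stats.t.sf(t, n - 2))
        p_neg = float(stats.t.cdf(t, n - 2))
        p_two = float(2 * stats.t.sf(abs(t), n - 2))
    return GeneCorrelation(
        transcript_id=transcript_id,
        rho=rho,
        p_one_sided_pos=p_pos,
        p_one_sided_neg=p_neg,
        p_two_sided=min(p_two, 1.0),
        n=n,
    )


# ---------------------------------------------------------------------------
# the screen as an estimator


class CorrelationScreen(BaseEstimator):
    """Univariate rank-correlation feature screen against a response profile.

    A scikit-learn style selector: ``fit(X, y)`` with X of shape
    (n_cell_lines, n_transcripts) and y the normalized IC50 profile;
    transcripts whose pattern correlates (anti-correlates) with y at the
    exact one-sided significance level ``alpha`` populate the positive
    (negative) support.

    Parameters
    ----------
    alpha : float
        Nominal significance level (no multiple-testing correction by
        default, matching a discovery screen; set ``correct='bh'`` for
        Benjamini-Hochberg).
    sidedness : {'one_sided', 'two_sided'}
    method : {'spearman', 'pearson'}
        'spearman' permutes ranks; 'pearson' permutes the raw response
        values in the same exact scheme.
    exact_cap : int
        Largest n for full permutation enumeration.
    correct : {None, 'bh'}

    Attributes
    ----------
    rho_, p_pos_, p_neg_, p_two_ : ndarray of shape (n_transcripts,)
    degenerate_ : boolean ndarray
    positive_support_, negative_support_ : boolean ndarrays
    """

    def __init__(
        self,
        alpha: float = 0.05,
        sidedness: str = "one_sided",
        method: str = "spearman",
        exact_cap: int = 8,
        correct: str | None = None,
    ) -> None:
        self.alpha = alpha
        self.sidedness = sidedness
        self.method = method
        self.exact_cap = exact_cap
        self.correct = correct

    def fit(self, X, y):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in {"one_sided", "two_sided"}:
            raise ValueError("sidedness must be 'one_sided' or 'two_sided'")
        if self.method not in {"spearman", "pearson"}:
            raise ValueError("method must be 'spearman' or 'pearson'")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError(
                "X must be (n_cell_lines, n_transcripts) with rows matching y"
            )
        n, m = X.shape
        if n < 3:
            raise ValueError("need at least 3 cell lines")
        if np.isnan(y).any():
            raise ValueError("profile contains missing values")

        if self.method == "spearman":
            feat = np.apply_along_axis(
                lambda c: rankdata(c, method="average"), 0, X
            )
            resp = rankdata(y, method="average")
        else:
            feat, resp = X, y.copy()

        sd = feat.std(axis=0)
        degenerate = sd == 0
        zresp = resp.std()
        if zresp == 0:
            degenerate = np.ones(m, dtype=bool)
        Z = np.zeros_like(feat)
        ok = ~degenerate
        if zresp > 0 and ok.any():
            Z[:, ok] = (feat[:, ok] - feat[:, ok].mean(axis=0)) / sd[ok]
            zr = (resp - resp.mean()) / zresp
            rho = Z[:, ok].T @ zr / n
        else:
            rho = np.zeros(int(ok.sum()))

        p_pos = np.ones(m)
        p_neg = np.ones(m)
        p_two = np.ones(m)
        rho_full = np.zeros(m)
        if zresp > 0 and ok.any():
            rho_full[ok] = rho
            if n <= self.exact_cap:
                perms = _perm_matrix(resp)  # (n!, n) standardized
                null = Z[:, ok].T @ perms.T / n  # (m_ok, n!)
                eps = 1e-9
                p_pos[ok] = (null >= rho[:, None] - eps).mean(axis=1)
                p_neg[ok] = (null <= rho[:, None] + eps).mean(axis=1)
                p_two[ok] = (np.abs(null) >= np.abs(rho)[:, None] - eps).mean(
                    axis=1
                )
            else:
                logger.info(
                    "n=%d above exact cap %d; t-approximation in screen",
                    n,
                    self.exact_cap,
                )
                r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
                t = r * np.sqrt((n - 2) / (1 - r**2))
                p_pos[ok] = stats.t.sf(t, n - 2)
                p_neg[ok] = stats.t.cdf(t, n - 2)
                p_two[ok] = np.minimum(2 * stats.t.sf(np.abs(t), n - 2), 1.0)

        if self.correct == "bh":
            from statsmodels.stats.multitest import multipletests

            for arr in (p_pos, p_neg, p_two):
                arr[ok] = multipletests(arr[ok], method="fdr_bh")[1]

        self.n_lines_ = n
        self.rho_ = rho_full
        self.p_pos_ = p_pos
        self.p_neg_ = p_neg
        self.p_two_ = p_two
        self.degenerate_ = degenerate
        if self.sidedness == "one_sided":
            self.positive_support_ = (
                ~degenerate & (rho_full > 0) & (p_pos <= self.alpha)
            )
            self.negative_support_ = (
                ~degenerate & (rho_full < 0) & (p_neg <= self.alpha)
            )
        else:
            sig = ~degenerate & (p_two <= self.alpha)
            self.positive_support_ = sig & (rho_full > 0)
            self.negative_support_ = sig & (rho_full < 0)
        return self

    def get_support(self, direction: str = "positive") -> np.ndarray:
        if direction == "positive":
            return self.positive_support_
        if direction == "negative":
            return self.negative_support_
        raise ValueError("direction must be 'positive' or 'negative'")


def _align(matrix: ExpressionMatrix, profile: IC50Profile) -> pd.DataFrame:
    """Reorder matrix columns to the profile's cell lines (case-folded match)."""
    fold = {c.casefold(): c for c in matrix.cell_lines}
    wanted = []
    unmatched = []
    for line in profile.cell_lines:
        key = line.casefold()
        if key in fold:
            wanted.append(fold[key])
        else:
            unmatched.append(line)
    extra = set(matrix.cell_lines) - set(wanted)
    if unmatched or extra:
        raise ValueError(
            "cell-line labels do not align between expression matrix and "
            f"profile; unmatched profile lines: {sorted(unmatched)}, "
            f"extra matrix lines: {sorted(extra)}"
        )
    return matrix.values[wanted]


def genome_screen(
    matrix: ExpressionMatrix,
    profile: IC50Profile,
    alpha: float = 0.05,
    sidedness: str = "one_sided",
    method: str = "spearman",
    exact_cap: int = 8,
    correct: str | None = None,
) -> ScreenResult:
    """Correlate every transcript's cross-line pattern with the IC50 profile.

    The matrix should already be detection-filtered; transcripts with
    missing values among the aligned lines are dropped with a logged
    count. Returns the selected positive/negative sets and the full
    per-transcript correlation table.
    """
    n_input = len(matrix.transcript_ids)
    values = _align(matrix, profile)
    has_na = values.isna().any(axis=1)
    if has_na.any():
        logger.warning(
            "dropping %d transcripts with missing values", int(has_na.sum())
        )
        values = values.loc[~has_na]

    est = CorrelationScreen(
        alpha=alpha,
        sidedness=sidedness,
        method=method,
        exact_cap=exact_cap,
        correct=correct,
    )
    est.fit(values.to_numpy().T, profile.normalized)

    ids = np.asarray(values.index)
    table = pd.DataFrame(
        {
            "transcript_id": ids,
            "rho": est.rho_,
            "p_one_sided_pos": est.p_pos_,
            "p_one_sided_neg": est.p_neg_,
            "p_two_sided": est.p_two_,
            "degenerate": est.degenerate_,
        }
    )
    return ScreenResult(
        n_input=n_input,
        n_filtered=int(len(ids)),
        positive_set=list(ids[est.positive_support_]),
        negative_set=list(ids[est.negative_support_]),
        alpha=alpha,
        sidedness=sidedness,
        table=table,
    )


def signature_correlation(
    signature: list[str],
    matrix: ExpressionMatrix,
    profiles: dict[str, IC50Profile],
    alpha: float = 0.05,
    sidedness: str = "one_sided",
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a predefined gene signature against one or more IC50 profiles.

    Restricts the screen to the signature genes present in the matrix
    and reports, per profile, the fraction of signature genes whose
    correlation is significant — the per-compound comparison used to
    contrast, e.g., an EMT signature's association with two drugs'
    susceptibility profiles.
    """
    found = [g for g in signature if g in matrix.values.index]
    if not found:
        raise ValueError(
            f"no signature gene found in matrix; missing: {sorted(signature)}"
        )
    sub = ExpressionMatrix(
        values=matrix.values.loc[found], calls=matrix.calls.loc[found]
    )
    tables = []
    summary_rows = []
    for name, profile in profiles.items():
        res = genome_screen(
            sub, profile, alpha=alpha, sidedness=sidedness, **kwargs
        )
        t = res.table.assign(profile=name)
        tables.append(t)
        n_sig = len(res.positive_set) + len(res.negative_set)
        summary_rows.append(
            {
                "profile": name,
                "n_signature_found": len(found),
                "n_significant": n_sig,
                "n_significant_positive": len(res.positive_set),
                "n_significant_negative": len(res.negative_set),
                "fraction_significant": n_sig / len(found),
            }
        )
    return pd.concat(tables, ignore_index=True), pd.DataFrame(summary_rows)


def rank_lines_by_gene(matrix: ExpressionMatrix, gene: str) -> list[str]:
    """Cell lines ordered by one gene's expression, descending.

    With a marker such as CDH1 this orders lines from most epithelial to
    most mesenchymal. Ties keep the input column order (stable sort).
    """
    if gene not in matrix.values.index:
        raise ValueError(f"gene {gene!r} not present in the expression matrix")
    vals = matrix.values.loc[gene]
    order = np.argsort(-vals.to_numpy(), kind="stable")
    return [matrix.cell_lines[i] for i in order]


# ---------------------------------------------------------------------------
# file I/O (TSV dialect: gene_id, <line>_value, <line>_call per line)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = pd.DataFrame({"gene_id": matrix.transcript_ids})
    for line in matrix.cell_lines:
        out[f"{line}_value"] = matrix.values[line].to_numpy()
        out[f"{line}_call"] = matrix.calls[line].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression TSV must contain a gene_id column")
    lines = [c[: -len("_value")] for c in df.columns if c.endswith("_value")]
    if not lines:
        raise ValueError("expression TSV has no <line>_value columns")
    values = pd.DataFrame(
        {ln: df[f"{ln}_value"].to_numpy(dtype=float) for ln in lines},
        index=df["gene_id"],
    )
    calls = pd.DataFrame(
        {ln: df[f"{ln}_call"].astype(str).to_numpy() for ln in lines},
        index=df["gene_id"],
    )
    values.index.name = "gene_id"
    calls.index.name = "gene_id"
    return ExpressionMatrix(values=values, calls=calls)


def read_gene_set(path) -> list[str]:
    """One gene symbol per line; '#' starts a comment; order preserved."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name:
                genes.append(name)
    return genes
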