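"""Self-contained edgeR-style differential-expression engine for two-group count data.

The pipeline implemented here is the classic exact-test workflow for unpaired
tumor/normal comparisons of raw RNA-seq read counts:

1. low-count filtering (CPM threshold derived from the median library size),
2. TMM (trimmed mean of M-values) scaling-factor normalization,
3. negative-binomial dispersion estimation by conditional maximum likelihood,
   with empirical-Bayes moderation of per-gene estimates toward the common value,
4. an exact conditional test on group totals of library-size-equalized
   pseudo-counts,
5. Benjamini-Hochberg FDR adjustment, and
6. DEG calling at |log2FC| >= 1 and FDR < 0.05 (both configurable).

Counts are handled as a pandas DataFrame (genes x samples, nonnegative
integers); sample annotation is a Series mapping sample id to a group label in
{"tumor", "normal"}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "TUMOR",
    "NORMAL",
    "DataError",
    "NormalizationResult",
    "DEResult",
    "validate_counts",
    "validate_annotation",
    "tmm_factors",
    "cpm",
    "filter_low_counts",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersions",
    "exact_test",
    "bh_adjust",
    "run_de",
]

TUMOR = "tumor"
NORMAL = "normal"

#: search window for NB dispersion phi
DISPERSION_MIN = 1e-6
DISPERSION_MAX = 10.0


class DataError(ValueError):
    """Raised when an input matrix or annotation violates its contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationResult:
    """Per-sample library sizes and TMM scaling factors.

    ``effective_size = library_size * tmm_factor``; factors are renormalized so
    their geometric mean is 1, so effective sizes stay on the raw-depth scale.
    """

    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor

    @property
    def sample_ids(self) -> pd.Index:
        return self.library_size.index


@dataclass
class DEResult:
    """Result of one two-group differential-expression analysis.

    ``table`` is indexed by the kept genes and has columns ``log2FC``
    (tumor over normal), ``logCPM``, ``PValue``, ``FDR`` and ``is_DEG``.
    ``kept`` is a boolean Series over the full input gene list.  The
    normalization result and per-gene dispersions are retained so that
    downstream forensics (outlier-exclusion re-testing) can reuse them.
    """

    table: pd.DataFrame
    kept: pd.Series
    norm: NormalizationResult
    dispersions: pd.Series
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    @property
    def deg_set(self) -> set[str]:
        """Gene ids flagged as differentially expressed."""
        return set(self.table.index[self.table["is_DEG"]])

    @property
    def kept_genes(self) -> pd.Index:
        return self.table.index


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples count matrix: unique ids, nonnegative entries."""
    if counts.index.has_duplicates:
        raise DataError("duplicate gene identifiers in count matrix")
    if counts.columns.has_duplicates:
        raise DataError("duplicate sample identifiers in count matrix")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise DataError("count matrix must be numeric")
    if (arr < 0).any():
        raise DataError("count matrix contains negative entries")
    return counts


def validate_annotation(ann: pd.Series, sample_ids: Iterable[str]) -> pd.Series:
    """Check that every analyzed sample carries a tumor/normal label."""
    sample_ids = pd.Index(sample_ids)
    missing = sample_ids.difference(ann.index)
    if len(missing):
        raise DataError(f"samples without group label: {', '.join(map(str, missing))}")
    sub = ann.loc[sample_ids]
    bad = set(sub.unique()) - {TUMOR, NORMAL}
    if bad:
        raise DataError(f"unknown group labels: {sorted(bad)} (expected 'tumor'/'normal')")
    for grp in (TUMOR, NORMAL):
        if (sub == grp).sum() == 0:
            raise DataError(f"group '{grp}' has no samples")
    return sub


def _group_masks(ann: pd.Series, sample_ids: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    sub = validate_annotation(ann, sample_ids)
    return (sub.to_numpy() == TUMOR), (sub.to_numpy() == NORMAL)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.  For every other
    sample, genes expressed in both it and the reference contribute a log2
    abundance ratio M and an average log2 abundance A; after discarding the
    top/bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A, the
    factor is 2 to the precision-weighted mean of the surviving M values.
    Factors are renormalized to geometric mean 1.
    """
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise DataError(f"sample(s) with all-zero counts: {', '.join(map(str, zero.index))}")

    arr = counts.to_numpy(dtype=float)
    frac = arr / lib.to_numpy()
    q75 = np.percentile(frac, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))

    y_r = arr[:, ref_idx]
    n_r = lib.iloc[ref_idx]
    log_factors = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_idx:
            continue
        y_j = arr[:, j]
        n_j = lib.iloc[j]
        use = (y_j > 0) & (y_r > 0)
        if use.sum() == 0:
            continue
        pj, pr = y_j[use] / n_j, y_r[use] / n_r
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        # asymptotic (binomial) variance of M; inverse is the precision weight
        var = (n_j - y_j[use]) / (n_j * y_j[use]) + (n_r - y_r[use]) / (n_r * y_r[use])

        n = use.sum()
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (
            (rank_m >= n * trim_m + 1)
            & (rank_m <= n * (1 - trim_m))
            & (rank_a >= n * trim_a + 1)
            & (rank_a <= n * (1 - trim_a))
        )
        if keep.sum() == 0:
            continue
        w = 1.0 / np.maximum(var[keep], 1e-12)
        log_factors[j] = np.sum(w * m[keep]) / np.sum(w)

    log_factors -= log_factors.mean()  # geometric mean 1
    factors = pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")
    return NormalizationResult(library_size=lib.rename("library_size"), tmm_factor=factors)


def cpm(
    counts: pd.DataFrame,
    norm: NormalizationResult | None = None,
    log_scale: bool = False,
    prior_count: float = 0.0,
) -> pd.DataFrame:
    """Counts per million against effective (TMM-scaled) library sizes.

    With ``log_scale`` the prior count is added before scaling, i.e. the
    result is ``log2((count + prior_count) / effective_size * 1e6)``.
    """
    if norm is None:
        norm = tmm_factors(counts)
    eff = norm.effective_size.loc[counts.columns].to_numpy()
    arr = counts.to_numpy(dtype=float)
    if log_scale:
        vals = np.log2((arr + prior_count) / eff * 1e6)
    else:
        vals = arr / eff * 1e6
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# low-count filtering
# ---------------------------------------------------------------------------

def filter_low_counts(
    counts: pd.DataFrame,
    ann: pd.Series,
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> pd.Series:
    """Keep genes expressed at a usable level in at least the smaller group.

    A gene is kept iff the number of samples with CPM >= c is at least the
    smaller group size, where ``c = min_count / median library size * 1e6``,
    and its total count across all samples is at least ``min_total``.
    CPM here uses raw library sizes (filtering precedes normalization).
    """
    tumor, normal = _group_masks(ann, counts.columns)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    c = min_count / np.median(lib) * 1e6
    cpm_raw = counts.to_numpy(dtype=float) / lib * 1e6
    n_min = min(tumor.sum(), normal.sum())
    keep = ((cpm_raw >= c).sum(axis=1) >= n_min) & (
        counts.sum(axis=1).to_numpy() >= min_total
    )
    return pd.Series(keep, index=counts.index, name="kept")


# ---------------------------------------------------------------------------
# NB dispersion by conditional maximum likelihood
# ---------------------------------------------------------------------------

def _pseudo_counts(counts: pd.DataFrame, norm: NormalizationResult) -> tuple[np.ndarray, float]:
    """Rescale counts to the geometric-mean effective library size."""
    eff = norm.effective_size.loc[counts.columns].to_numpy()
    common_size = float(np.exp(np.mean(np.log(eff))))
    pseudo = counts.to_numpy(dtype=float) * (common_size / eff)
    return pseudo, common_size


def _group_cml(y: np.ndarray, log_phi: np.ndarray | float) -> np.ndarray:
    """Conditional NB log-likelihood of within-group counts given the group total.

    ``y`` is genes x samples for one group; ``log_phi`` is a scalar or a
    per-gene vector of log dispersions.  Terms constant in phi are dropped.
    """
    r = np.exp(-np.asarray(log_phi, dtype=float))  # 1/phi
    n = y.shape[1]
    z = y.sum(axis=1)
    r_col = r[:, None] if np.ndim(r) else r
    ll = (
        gammaln(y + r_col).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return ll


def _cml_per_gene(
    pseudo: np.ndarray, tumor: np.ndarray, normal: np.ndarray, log_phi: np.ndarray | float
) -> np.ndarray:
    return _group_cml(pseudo[:, tumor], log_phi) + _group_cml(pseudo[:, normal], log_phi)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    ann: pd.Series,
    norm: NormalizationResult,
) -> float:
    """Common NB dispersion maximizing the summed conditional log-likelihood.

    Counts are first equalized to the geometric-mean effective library size.
    The likelihood is profiled on a log-dispersion grid over
    [1e-6, 10] and refined by golden-section search; deterministic.
    """
    tumor, normal = _group_masks(ann, counts.columns)
    if tumor.sum() < 2 or normal.sum() < 2:
        raise DataError("dispersion estimation needs >= 2 samples per group")
    if counts.to_numpy().sum() == 0:
        raise DataError("all counts are zero; cannot estimate dispersion")
    pseudo, _ = _pseudo_counts(counts, norm)

    def neg_total(log_phi: float) -> float:
        return -float(_cml_per_gene(pseudo, tumor, normal, log_phi).sum())

    lo, hi = math.log(DISPERSION_MIN), math.log(DISPERSION_MAX)
    grid = np.linspace(lo, hi, 61)
    vals = np.array([neg_total(x) for x in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_total, bounds=(a, b), method="bounded", options={"xatol": 1e-10}
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    return float(np.clip(math.exp(best), DISPERSION_MIN, DISPERSION_MAX))


def estimate_tagwise_dispersions(
    counts: pd.DataFrame,
    ann: pd.Series,
    norm: NormalizationResult,
    common: float,
    prior_df: float = 10.0,
) -> pd.Series:
    """Per-gene dispersions moderated toward the common estimate.

    Each gene maximizes its conditional log-likelihood plus a ``prior_df``-
    weighted log-likelihood anchor at the common dispersion (Gaussian on the
    log-dispersion scale, one unit of curvature per prior degree of freedom):

        l_g(phi) - prior_df/2 * (log phi - log common)^2

    ``prior_df = 0`` gives unshrunk per-gene CML estimates; as
    ``prior_df -> inf`` every estimate collapses onto the common value.
    """
    if common <= 0:
        raise DataError("common dispersion must be positive")
    tumor, normal = _group_masks(ann, counts.columns)
    pseudo, _ = _pseudo_counts(counts, norm)
    log_common = math.log(common)

    def objective(log_phi: np.ndarray) -> np.ndarray:
        pen = -0.5 * prior_df * (log_phi - log_common) ** 2
        return _cml_per_gene(pseudo, tumor, normal, log_phi) + pen

    g = pseudo.shape[0]
    lo = np.full(g, math.log(DISPERSION_MIN))
    hi = np.full(g, math.log(DISPERSION_MAX))
    best = _golden_max(objective, lo, hi)
    phi = np.clip(np.exp(best), DISPERSION_MIN, DISPERSION_MAX)
    return pd.Series(phi, index=counts.index, name="dispersion")


def _golden_max(f, lo: np.ndarray, hi: np.ndarray, iters: int = 90) -> np.ndarray:
    """Vectorized golden-section maximization on [lo, hi] per component."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.astype(float).copy(), hi.astype(float).copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc > fd
        a = np.where(left, a, c)
        b = np.where(left, d, b)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    return (a + b) / 2.0


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def _exact_test_single(
    s_tumor: float, s_normal: float, n_tumor: int, n_normal: int, phi: float
) -> float:
    """Two-sided exact conditional p-value for one gene.

    Given equal per-sample means within a gene (after library equalization),
    the tumor total conditional on the grand total t follows the NB
    convolution conditional, which is BetaBinomial(t, n_tumor/phi,
    n_normal/phi).  p doubles the smaller tail including the observed outcome,
    capped at 1.  Tail sums are accumulated from the log pmf to avoid
    cancellation in the far tail.
    """
    if not np.isfinite(phi):
        raise DataError("non-finite dispersion")
    # round group totals separately so swapping the labels is an exact symmetry
    s = max(int(round(s_tumor)), 0)
    t = s + max(int(round(s_normal)), 0)
    if t == 0:
        return 1.0
    r = 1.0 / max(phi, DISPERSION_MIN)
    a, b = n_tumor * r, n_normal * r
    k = np.arange(t + 1)
    logpmf = (
        gammaln(k + a)
        - gammaln(k + 1)
        - gammaln(a)
        + gammaln(t - k + b)
        - gammaln(t - k + 1)
        - gammaln(b)
    )
    logpmf -= np.logaddexp.reduce(logpmf)  # normalize in log space
    pmf = np.exp(logpmf)
    lower = pmf[: s + 1].sum()
    upper = pmf[s:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_test(
    counts: pd.DataFrame,
    ann: pd.Series,
    norm: NormalizationResult,
    dispersions: pd.Series,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Exact NB conditional test per gene; returns PValue, log2FC, logCPM.

    Counts are rescaled to a common effective library size (pseudo-counts);
    each gene's tumor total is tested against its conditional distribution
    given the grand total.  log2FC is tumor over normal on moderated group
    mean pseudo-counts (``prior_count`` added to each group mean).
    """
    tumor, normal = _group_masks(ann, counts.columns)
    disp = dispersions.loc[counts.index].to_numpy(dtype=float)
    if not np.all(np.isfinite(disp)):
        raise DataError("non-finite dispersion")
    if np.any(disp <= 0):
        raise DataError("dispersions must be positive")
    pseudo, common_size = _pseudo_counts(counts, norm)
    n_t, n_n = int(tumor.sum()), int(normal.sum())
    s_t = pseudo[:, tumor].sum(axis=1)
    s_n = pseudo[:, normal].sum(axis=1)

    pvals = np.array(
        [
            _exact_test_single(s_t[i], s_n[i], n_t, n_n, disp[i])
            for i in range(pseudo.shape[0])
        ]
    )
    mean_t = s_t / n_t
    mean_n = s_n / n_n
    log2fc = np.log2((mean_t + prior_count) / (mean_n + prior_count))
    overall = (s_t + s_n) / (n_t + n_n)
    log_cpm = np.log2((overall + 2 * prior_count) / common_size * 1e6)
    return pd.DataFrame(
        {"PValue": pvals, "log2FC": log2fc, "logCPM": log_cpm}, index=counts.index
    )


# ---------------------------------------------------------------------------
# multiple testing and DEG calling
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def run_de(
    counts: pd.DataFrame,
    ann: pd.Series,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    min_group_size: int = 3,
    prior_df: float = 10.0,
    prior_count: float = 0.125,
    min_count: float = 10.0,
    min_total: float = 15.0,
    allow_small_groups: bool = False,
) -> DEResult:
    """Full two-group DE analysis: filter, TMM, dispersions, exact test, BH, calling.

    A gene is flagged as a DEG iff |log2FC| >= ``lfc_threshold`` and
    FDR < ``fdr_threshold``.  Groups smaller than ``min_group_size`` (default
    3, the minimum at which biological variability is estimable) are refused
    unless ``allow_small_groups`` is set.
    """
    validate_counts(counts)
    tumor, normal = _group_masks(ann, counts.columns)
    if not allow_small_groups and min(tumor.sum(), normal.sum()) < min_group_size:
        raise DataError(
            f"each group needs >= {min_group_size} samples "
            f"(got tumor={tumor.sum()}, normal={normal.sum()}); "
            "pass allow_small_groups=True to override"
        )
    kept = filter_low_counts(counts, ann, min_count=min_count, min_total=min_total)
    sub = counts.loc[kept]
    if sub.shape[0] == 0:
        raise DataError("no genes pass the low-count filter")
    norm = tmm_factors(sub)
    common = estimate_common_dispersion(sub, ann, norm)
    tagwise = estimate_tagwise_dispersions(sub, ann, norm, common, prior_df=prior_df)
    stats = exact_test(sub, ann, norm, tagwise, prior_count=prior_count)
    fdr = bh_adjust(stats["PValue"].to_numpy())
    table = pd.DataFrame(
        {
            "log2FC": stats["log2FC"],
            "logCPM": stats["logCPM"],
            "PValue": stats["PValue"],
            "FDR": fdr,
        },
        index=sub.index,
    )
    table["is_DEG"] = (table["log2FC"].abs() >= lfc_threshold) & (
        table["FDR"] < fdr_threshold
    )
    return DEResult(
        table=table,
        kept=kept,
        norm=norm,
        dispersions=tagwise,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
    )
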