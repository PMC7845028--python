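"""Forensics of non-common DEGs: count dispersion, outliers, and re-testing.

Non-common DEGs are genes called differentially expressed in one experimental
repeat but not in another.  This module quantifies why: the percent
coefficient of variation (%CV = 100 * SD / mean) of TMM-normalized counts per
group, Tukey-fence classification of mild (beyond 1.5 IQR from the box) and
extreme (beyond 3 IQR) outlier counts, detection of opposite regulating
trends (log2FC of strictly opposite sign in two repeats), and a per-gene
outlier-exclusion re-test that removes a gene's outlier samples and re-runs
the exact conditional test with the original normalization factors and
dispersion.

Quartiles use linear interpolation; fence membership for edge values may
differ from Tukey-hinge conventions by at most the hinge/interpolation
discrepancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decore import (
    NORMAL,
    TUMOR,
    DataError,
    DEResult,
    _exact_test_single,
    cpm,
    validate_annotation,
)

__all__ = [
    "RetestOutcome",
    "non_common_degs",
    "discordantly_filtered",
    "percent_cv",
    "tukey_outliers",
    "opposite_regulation",
    "exclude_outliers_and_retest",
    "build_noncommon_report",
]

logger = logging.getLogger(__name__)

MILD = "mild"
EXTREME = "extreme"


def non_common_degs(result_a: DEResult, result_b: DEResult) -> set[str]:
    """Genes called DEG in exactly one of two repeats, among genes kept in both.

    Genes filtered out of one analysis are a separate category (see
    :func:`discordantly_filtered`), not non-common DEGs.
    """
    kept_both = set(result_a.kept_genes) & set(result_b.kept_genes)
    return (result_a.deg_set ^ result_b.deg_set) & kept_both


def discordantly_filtered(result_a: DEResult, result_b: DEResult) -> set[str]:
    """Genes called DEG in one repeat but removed by the other's low-count filter."""
    kept_both = set(result_a.kept_genes) & set(result_b.kept_genes)
    return (result_a.deg_set | result_b.deg_set) - kept_both


def percent_cv(values) -> float:
    """100 * sample SD / mean; NaN when the mean is nonpositive."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("percent_cv needs at least two values")
    m = v.mean()
    if m <= 0:
        logger.warning("percent_cv undefined for nonpositive mean")
        return float("nan")
    return 100.0 * v.std(ddof=1) / m


def tukey_outliers(values: pd.Series) -> pd.DataFrame:
    """Classify mild and extreme outliers by Tukey's fences.

    Q1/Q3 by linear interpolation; with IQR = Q3 - Q1, a value is a mild
    outlier if it lies in (Q3 + 1.5 IQR, Q3 + 3 IQR] or [Q1 - 3 IQR,
    Q1 - 1.5 IQR), and extreme if it lies beyond Q3 + 3 IQR or below
    Q1 - 3 IQR.  Returns a table with columns sample_id, value, class.
    """
    if len(values) < 4:
        raise DataError("tukey_outliers needs at least four values")
    v = values.to_numpy(dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    hi_mild, hi_ext = q3 + 1.5 * iqr, q3 + 3.0 * iqr
    lo_mild, lo_ext = q1 - 1.5 * iqr, q1 - 3.0 * iqr
    rows = []
    for sid, x in values.items():
        if x > hi_ext or x < lo_ext:
            rows.append((sid, x, EXTREME))
        elif x > hi_mild or x < lo_mild:
            rows.append((sid, x, MILD))
    return pd.DataFrame(rows, columns=["sample_id", "value", "class"])


def opposite_regulation(
    common_genes, result_a: DEResult, result_b: DEResult
) -> pd.DataFrame:
    """Genes among ``common_genes`` with strictly opposite log2FC signs.

    A zero log2FC in either repeat excludes the gene.  Returns a table
    indexed by gene with both log2FC values.
    """
    genes = [g for g in common_genes
             if g in result_a.table.index and g in result_b.table.index]
    fa = result_a.table.loc[genes, "log2FC"]
    fb = result_b.table.loc[genes, "log2FC"]
    opposite = np.sign(fa) * np.sign(fb) < 0
    return pd.DataFrame({"log2FC_a": fa[opposite], "log2FC_b": fb[opposite]})


@dataclass(frozen=True)
class RetestOutcome:
    """Before/after DEG status of one gene under outlier exclusion."""

    gene: str
    pre_deg: bool
    post_deg: bool | None      # None when untestable
    status: str                # "tested" or "untestable"
    removed_samples: tuple
    p_value: float
    log2fc: float


def exclude_outliers_and_retest(
    gene: str,
    counts: pd.DataFrame,
    ann: pd.Series,
    result: DEResult,
    prior_count: float = 0.125,
) -> RetestOutcome:
    """Remove a gene's Tukey-outlier samples and re-run its exact test.

    Outliers (mild and extreme) are identified per group on the gene's
    TMM-normalized counts; only this gene loses those samples.  The re-test
    reuses the original normalization factors and the gene's original
    dispersion; significance compares the new p-value against the analysis's
    original FDR threshold, together with the original |log2FC| threshold.
    Groups reduced below two samples make the gene untestable.
    """
    if gene not in result.table.index:
        raise DataError(f"gene {gene} was not kept in this analysis")
    samples = result.norm.sample_ids
    sub_ann = validate_annotation(ann, samples)
    norm_counts = cpm(counts.loc[[gene], samples], result.norm).loc[gene]
    pre_deg = bool(result.table.loc[gene, "is_DEG"])

    removed: list = []
    for grp in (TUMOR, NORMAL):
        grp_vals = norm_counts[sub_ann[sub_ann == grp].index]
        if len(grp_vals) >= 4:
            out = tukey_outliers(grp_vals)
            removed.extend(out["sample_id"].tolist())
    keep = [s for s in samples if s not in set(removed)]
    keep_ann = sub_ann.loc[keep]
    n_t = int((keep_ann == TUMOR).sum())
    n_n = int((keep_ann == NORMAL).sum())
    if min(n_t, n_n) < 2:
        logger.warning("gene %s untestable after exclusion (%dv%d)", gene, n_t, n_n)
        return RetestOutcome(
            gene=gene, pre_deg=pre_deg, post_deg=None, status="untestable",
            removed_samples=tuple(removed), p_value=float("nan"),
            log2fc=float("nan"),
        )

    eff = result.norm.effective_size
    common_size = float(np.exp(np.mean(np.log(eff.to_numpy()))))
    pseudo = counts.loc[gene, keep].to_numpy(dtype=float) * (
        common_size / eff.loc[keep].to_numpy()
    )
    s_t = float(pseudo[(keep_ann == TUMOR).to_numpy()].sum())
    s_n = float(pseudo[(keep_ann == NORMAL).to_numpy()].sum())
    phi = float(result.dispersions.loc[gene])
    p_new = _exact_test_single(s_t, s_n, n_t, n_n, phi)
    lfc_new = float(
        np.log2((s_t / n_t + prior_count) / (s_n / n_n + prior_count))
    )
    post_deg = (abs(lfc_new) >= result.lfc_threshold) and (
        p_new < result.fdr_threshold
    )
    return RetestOutcome(
        gene=gene, pre_deg=pre_deg, post_deg=post_deg, status="tested",
        removed_samples=tuple(removed), p_value=p_new, log2fc=lfc_new,
    )


def build_noncommon_report(
    result_a: DEResult,
    result_b: DEResult,
    counts: pd.DataFrame,
    ann: pd.Series,
    top_k: int = 10,
    labels: tuple[str, str] = ("II", "III"),
) -> pd.DataFrame:
    """Characterize the top non-common DEGs between two repeats.

    Selects the ``top_k`` non-common DEGs ranked by FDR in the repeat where
    each is significant, then reports per gene and per repeat the DEG status,
    log2FC, FDR and %CV of normalized counts per group, plus the
    opposite-trend flag and the outlier-exclusion re-test outcome.  A gene is
    "rescued" when exclusion makes its status concordant across the two
    repeats.
    """
    ncd = non_common_degs(result_a, result_b)
    la, lb = labels
    cols = ["gene"]
    for lab in labels:
        cols += [f"deg_{lab}", f"log2FC_{lab}", f"FDR_{lab}",
                 f"cv_normal_{lab}", f"cv_tumor_{lab}", f"post_deg_{lab}"]
    cols += ["opposite_trend", "rescued", "n_removed"]
    if not ncd:
        logger.info("no non-common DEGs between repeats %s and %s", la, lb)
        return pd.DataFrame(columns=cols).set_index("gene")
    if top_k > len(ncd):
        logger.warning(
            "top_k=%d exceeds the %d non-common DEGs; clamping", top_k, len(ncd)
        )
        top_k = len(ncd)

    def sig_fdr(g: str) -> float:
        if g in result_a.deg_set:
            return float(result_a.table.loc[g, "FDR"])
        return float(result_b.table.loc[g, "FDR"])

    selected = sorted(ncd, key=lambda g: (sig_fdr(g), g))[:top_k]

    rows = []
    for g in selected:
        row: dict = {"gene": g}
        outcomes = {}
        for lab, res in ((la, result_a), (lb, result_b)):
            sub_ann = validate_annotation(ann, res.norm.sample_ids)
            norm_counts = cpm(counts.loc[[g], res.norm.sample_ids], res.norm).loc[g]
            row[f"deg_{lab}"] = bool(res.table.loc[g, "is_DEG"])
            row[f"log2FC_{lab}"] = float(res.table.loc[g, "log2FC"])
            row[f"FDR_{lab}"] = float(res.table.loc[g, "FDR"])
            for grp, tag in ((NORMAL, "normal"), (TUMOR, "tumor")):
                row[f"cv_{tag}_{lab}"] = percent_cv(
                    norm_counts[sub_ann[sub_ann == grp].index]
                )
            outcomes[lab] = exclude_outliers_and_retest(g, counts, ann, res)
            row[f"post_deg_{lab}"] = outcomes[lab].post_deg
        fa, fb = row[f"log2FC_{la}"], row[f"log2FC_{lb}"]
        row["opposite_trend"] = bool(np.sign(fa) * np.sign(fb) < 0)
        oa, ob = outcomes[la], outcomes[lb]
        row["rescued"] = bool(
            oa.status == "tested"
            and ob.status == "tested"
            and oa.post_deg == ob.post_deg
        )
        row["n_removed"] = len(oa.removed_samples) + len(ob.removed_samples)
        rows.append(row)
    return pd.DataFrame(rows, columns=cols).set_index("gene")
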