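"""Reproducibility and detection-power statistics over repeated DEG lists.

The central quantity is the overlap rate of k DEG lists: the number of common
DEGs (genes in every compared list) divided by the total number of distinct
DEGs across those lists, i.e. |intersection| / |union|.  For four repeats at a
given replicate number n this is averaged over all C(4, k) combinations for
k = 2, 3, 4.  Detection power at n is the fraction of a reference DEG set —
the intersection (or union) of the four repeats at the maximum n — recovered
by the corresponding set at n; DEGs at n absent from the reference are
"specific".  The union/intersection ratio (>= 1) summarizes how many detected
DEGs are sample-specific rather than shared.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .resampling import REPEAT_LABELS, GridResult

__all__ = [
    "overlap_rate",
    "k_of_4_stats",
    "deg_count_stats",
    "power",
    "union_intersection_ratio",
    "build_reports",
]

logger = logging.getLogger(__name__)


def overlap_rate(deg_sets) -> float:
    """|intersection| / |union| of two or more DEG sets (0 if the union is empty)."""
    deg_sets = [set(s) for s in deg_sets]
    if len(deg_sets) < 2:
        raise ValueError("overlap_rate needs at least two sets")
    union = set.union(*deg_sets)
    if not union:
        logger.warning("overlap_rate: empty union, returning 0")
        return 0.0
    inter = set.intersection(*deg_sets)
    return len(inter) / len(union)


def k_of_4_stats(deg_sets, k: int) -> tuple[float, float]:
    """Mean common-DEG count and mean overlap rate over all C(4, k) combinations."""
    deg_sets = [set(s) for s in deg_sets]
    if len(deg_sets) != 4:
        raise ValueError("k_of_4_stats needs exactly four sets")
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    commons, rates = [], []
    for combo in combinations(deg_sets, k):
        commons.append(len(set.intersection(*combo)))
        rates.append(overlap_rate(combo))
    return float(np.mean(commons)), float(np.mean(rates))


def deg_count_stats(deg_sets) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of the four DEG-list sizes."""
    sizes = [len(s) for s in deg_sets]
    if len(sizes) != 4:
        raise ValueError("deg_count_stats needs exactly four sets")
    return float(np.mean(sizes)), float(np.std(sizes, ddof=1))


def power(target_set, reference_set) -> tuple[int, int, float]:
    """(matched, specific, power) of a DEG set against a reference DEG set.

    ``matched`` counts target DEGs present in the reference, ``specific``
    those absent from it; power = matched / |reference|.
    """
    target, reference = set(target_set), set(reference_set)
    if not reference:
        raise ValueError("reference set is empty")
    matched = len(target & reference)
    specific = len(target - reference)
    return matched, specific, matched / len(reference)


def union_intersection_ratio(deg_sets) -> float:
    """|union| / |intersection| of four DEG sets; NaN when the intersection is empty."""
    deg_sets = [set(s) for s in deg_sets]
    inter = set.intersection(*deg_sets)
    union = set.union(*deg_sets)
    if not inter:
        logger.warning("union/intersection undefined: empty intersection")
        return float("nan")
    return len(union) / len(inter)


def build_reports(grid: GridResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-n reproducibility and power tables from a subsampling grid.

    The power references are the intersection and union of the four DEG sets
    at the grid's maximum n, so power at n_max is 1 by construction.  The
    reproducibility table also carries the mean non-common fraction over
    repeat pairs (1 - mean pairwise overlap rate).
    """
    n_max = grid.max_n
    ref_sets = grid.deg_sets(n_max)
    ref_inter = set.intersection(*ref_sets)
    ref_union = set.union(*ref_sets)
    if not ref_inter:
        logger.warning("reference intersection at n_max=%d is empty", n_max)

    repro_rows, power_rows = [], []
    for n in grid.n_values:
        sets = grid.deg_sets(n)
        mean_count, sd_count = deg_count_stats(sets)
        row = {"n": n, "deg_count_mean": mean_count, "deg_count_sd": sd_count}
        for k in (2, 3, 4):
            common, rate = k_of_4_stats(sets, k)
            row[f"common_count_k{k}"] = common
            row[f"overlap_rate_k{k}"] = rate
        inter = set.intersection(*sets)
        union = set.union(*sets)
        row["intersection_size"] = len(inter)
        row["union_size"] = len(union)
        row["union_over_intersection"] = union_intersection_ratio(sets)
        row["noncommon_fraction_k2"] = 1.0 - row["overlap_rate_k2"]
        repro_rows.append(row)

        prow = {
            "n": n,
            "reference_intersection_size": len(ref_inter),
            "reference_union_size": len(ref_union),
        }
        if ref_inter:
            m, s, p = power(inter, ref_inter)
            prow.update(
                matched_intersection=m, specific_intersection=s, power_intersection=p
            )
        else:
            prow.update(
                matched_intersection=np.nan,
                specific_intersection=np.nan,
                power_intersection=np.nan,
            )
        if ref_union:
            m, s, p = power(union, ref_union)
            prow.update(matched_union=m, specific_union=s, power_union=p)
        else:
            prow.update(
                matched_union=np.nan, specific_union=np.nan, power_union=np.nan
            )
        power_rows.append(prow)

    repro = pd.DataFrame(repro_rows).set_index("n")
    pwr = pd.DataFrame(power_rows).set_index("n")
    return repro, pwr
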