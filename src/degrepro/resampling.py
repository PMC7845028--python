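"""Disjoint repeated-subsampling experimental design over a grid of replicate numbers.

For each replicate number n, four "experimental repeats" (labeled I-IV) are
formed by partitioning a uniform random permutation of each group's sample
pool into four blocks of n, so the repeats are mutually disjoint by
construction and every repeat analyzes entirely different subjects.  The DE
engine then runs once per repeat, independently — including its own low-count
filter — mirroring how four separate labs would each analyze only their own
samples.  The feasible maximum n is floor(pool/4) of the smaller group (e.g.
a 99-sample normal pool supports n up to 24).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decore import NORMAL, TUMOR, DataError, DEResult, run_de, validate_annotation

__all__ = ["REPEAT_LABELS", "RepeatDesign", "GridResult", "max_replicates",
           "draw_repeats", "run_grid", "child_seed"]

logger = logging.getLogger(__name__)

REPEAT_LABELS = ("I", "II", "III", "IV")

MIN_REPLICATES = 3  # below this, biological variability is not estimable


def max_replicates(tumor_pool: int, normal_pool: int) -> int:
    """Largest n supported by four mutually disjoint repeats per group."""
    if min(tumor_pool, normal_pool) < 12:
        raise DataError(
            f"pools ({tumor_pool}, {normal_pool}) cannot support n = 3 with "
            "four disjoint repeats (need >= 12 samples per group)"
        )
    return min(tumor_pool, normal_pool) // 4


def child_seed(master_seed: int, n: int) -> int:
    """Deterministic per-n seed; adding an n to the grid never perturbs others."""
    ss = np.random.SeedSequence((int(master_seed), int(n)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class RepeatDesign:
    """Four mutually disjoint tumor and normal subsets of size n each."""

    n: int
    repeats: dict  # label -> {"tumor": [ids], "normal": [ids]}
    seed: int

    def __post_init__(self) -> None:
        for label in REPEAT_LABELS:
            if label not in self.repeats:
                raise DataError(f"missing repeat label {label}")
            for grp in (TUMOR, NORMAL):
                if len(self.repeats[label][grp]) != self.n:
                    raise DataError(f"repeat {label} {grp} subset is not of size n")
        for grp in (TUMOR, NORMAL):
            all_ids = [s for lab in REPEAT_LABELS for s in self.repeats[lab][grp]]
            if len(all_ids) != len(set(all_ids)):
                raise DataError(f"{grp} subsets are not pairwise disjoint")

    def samples(self, label: str) -> list:
        rep = self.repeats[label]
        return list(rep[TUMOR]) + list(rep[NORMAL])


def draw_repeats(tumor_ids, normal_ids, n: int, seed: int) -> RepeatDesign:
    """Partition random permutations of both pools into four blocks of n.

    Sampling is without replacement; disjointness across repeats holds by
    construction.  Samples beyond 4n are unused for this n.  Deterministic
    for a fixed seed.
    """
    tumor_ids = list(tumor_ids)
    normal_ids = list(normal_ids)
    for name, pool in (("tumor", tumor_ids), ("normal", normal_ids)):
        if 4 * n > len(pool):
            raise DataError(
                f"4n = {4 * n} exceeds the {name} pool size {len(pool)}"
            )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed),))))
    perm_t = [tumor_ids[i] for i in rng.permutation(len(tumor_ids))]
    perm_n = [normal_ids[i] for i in rng.permutation(len(normal_ids))]
    repeats = {
        label: {
            TUMOR: perm_t[k * n : (k + 1) * n],
            NORMAL: perm_n[k * n : (k + 1) * n],
        }
        for k, label in enumerate(REPEAT_LABELS)
    }
    return RepeatDesign(n=n, repeats=repeats, seed=seed)


@dataclass
class GridResult:
    """DE results for every (n, repeat) cell of the subsampling grid."""

    results: dict  # (n, label) -> DEResult
    designs: dict  # n -> RepeatDesign
    n_values: list
    seed: int
    child_seeds: dict = field(default_factory=dict)  # n -> seed used

    def deg_sets(self, n: int) -> list[set]:
        """The four DEG sets at replicate number n, in repeat-label order."""
        return [self.results[(n, label)].deg_set for label in REPEAT_LABELS]

    def result(self, n: int, label: str) -> DEResult:
        return self.results[(n, label)]

    @property
    def max_n(self) -> int:
        return max(self.n_values)


def run_grid(
    counts: pd.DataFrame,
    ann: pd.Series,
    n_values=None,
    seed: int = 0,
    **de_kwargs,
) -> GridResult:
    """Run the full design: per n, draw four disjoint repeats and DE-test each.

    ``n_values`` defaults to 3..max_replicates.  Each n uses a fresh,
    independently drawn design under its own child seed; each repeat's
    analysis sees only its own 2n samples (filtering included).
    """
    sub_ann = validate_annotation(ann, counts.columns)
    tumor_ids = list(sub_ann.index[sub_ann == TUMOR])
    normal_ids = list(sub_ann.index[sub_ann == NORMAL])
    n_max = max_replicates(len(tumor_ids), len(normal_ids))
    if n_values is None:
        n_values = list(range(MIN_REPLICATES, n_max + 1))
    n_values = sorted(int(n) for n in n_values)
    for n in n_values:
        if not MIN_REPLICATES <= n <= n_max:
            raise DataError(
                f"replicate number n = {n} outside the feasible range "
                f"[{MIN_REPLICATES}, {n_max}] for pools "
                f"({len(tumor_ids)}, {len(normal_ids)})"
            )

    results: dict = {}
    designs: dict = {}
    seeds: dict = {}
    for n in n_values:
        cs = child_seed(seed, n)
        seeds[n] = cs
        design = draw_repeats(tumor_ids, normal_ids, n, seed=cs)
        designs[n] = design
        for label in REPEAT_LABELS:
            cols = design.samples(label)
            logger.info("n=%d repeat %s: samples %s", n, label, ",".join(map(str, cols)))
            try:
                results[(n, label)] = run_de(counts[cols], ann, **de_kwargs)
            except Exception as exc:
                raise DataError(f"DE analysis failed at (n={n}, repeat {label}): {exc}") from exc
    return GridResult(
        results=results, designs=designs, n_values=n_values, seed=seed, child_seeds=seeds
    )
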