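"""Synthetic two-condition RNA-seq count generator with known truth.

Emulates the statistical structure of heterogeneous tumor/normal cohorts:
negative-binomial counts with gamma-distributed gene-wise dispersions, a
minority of truly differentially expressed genes at |log2FC| >= 1, lognormal
per-sample library-size variation, lognormal per-cell biological heterogeneity
that is stronger in the tumor group than in the normal group, and rare large
outlier counts scattered independently across gene-sample cells.

Counts for gene g in sample j are drawn as

    y_gj ~ NB(mean = L_j * q_gj / sum_g q_gj,  dispersion = phi_g)

with relative expression q_gj = baseline_g * 2^(lfc_g * [j is tumor]) * h_gj,
where h_gj is unit-mean lognormal heterogeneity with group-specific spread.
Injected outliers multiply selected cells post hoc so their positions are
exactly known.

Everything is deterministic given the single config seed; each sub-stage
(baselines, dispersions, fold changes, library sizes, heterogeneity, counts,
outliers) draws from its own child stream keyed by a fixed offset, so the
output of one stage never depends on how often another is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .decore import NORMAL, TUMOR

__all__ = ["ConfigError", "SimConfig", "SimTruth", "simulate_dataset", "inject_outliers"]


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its contract."""


# child-stream keys: one per sub-stage, fixed so call order is irrelevant
_STREAM_BASELINE = 0
_STREAM_DISPERSION = 1
_STREAM_LFC = 2
_STREAM_LIBSIZE = 3
_STREAM_HETERO = 4
_STREAM_COUNTS = 5
_STREAM_OUTLIERS = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, stream))))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the heterogeneous two-condition count simulation.

    Defaults define the desk-scale study profile: 2,000 genes and pools of
    60 tumor / 60 normal samples, enough for replicate numbers up to 15 with
    four mutually disjoint repeats per group.  Heterogeneity defaults place
    the median per-gene %CV in the 50-150 range typical of tumor cohorts,
    with tumor variability above normal.
    """

    n_genes: int = 2000
    n_tumor_pool: int = 60
    n_normal_pool: int = 60
    frac_de: float = 0.1
    lfc_magnitude: float = 1.0      # lower bound of true |log2FC|
    lfc_spread: float = 1.0         # scale of the exponential excess above the bound
    baseline_log_mean: float = 4.0  # natural log of per-gene relative expression
    baseline_log_sd: float = 1.5
    dispersion_shape: float = 2.0   # gamma shape of gene-wise NB dispersions
    dispersion_mean: float = 0.15   # gamma mean of gene-wise NB dispersions
    hetero_sd_tumor: float = 0.5    # lognormal sigma of per-cell heterogeneity
    hetero_sd_normal: float = 0.25
    libsize_log_mean: float = 11.7  # exp(11.7) ~ 1.2e5 reads
    libsize_log_sd: float = 0.3
    outlier_rate: float = 0.002     # per gene-sample cell
    outlier_factor_min: float = 10.0
    outlier_factor_max: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> ConfigError:
            return ConfigError(f"invalid SimConfig.{name}: {why}")

        for name in ("n_genes", "n_tumor_pool", "n_normal_pool"):
            if int(getattr(self, name)) <= 0:
                raise bad(name, "must be a positive integer")
        for name in ("n_tumor_pool", "n_normal_pool"):
            if getattr(self, name) < 12:
                raise bad(name, "pool must be >= 12 (n = 3 with four disjoint repeats)")
        for name in ("frac_de", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise bad(name, "must lie in [0, 1]")
        for name in ("lfc_magnitude", "dispersion_shape", "dispersion_mean"):
            if getattr(self, name) <= 0:
                raise bad(name, "must be positive")
        for name in ("lfc_spread", "hetero_sd_tumor", "hetero_sd_normal",
                     "baseline_log_sd", "libsize_log_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "must be nonnegative")
        if self.outlier_factor_min <= 1:
            raise bad("outlier_factor_min", "must exceed 1")
        if self.outlier_factor_max < self.outlier_factor_min:
            raise bad("outlier_factor_max", "must be >= outlier_factor_min")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig key(s): {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class SimTruth:
    """Latent truth behind one simulated dataset."""

    is_true_de: pd.Series                 # per gene, bool
    true_log2fc: pd.Series                # per gene, 0 for non-DE genes
    gene_dispersions: pd.Series           # per gene NB dispersion phi_g
    outlier_cells: pd.DataFrame = field(  # columns: gene, sample, factor
        default_factory=lambda: pd.DataFrame(columns=["gene", "sample", "factor"])
    )

    @property
    def outlier_positions(self) -> set[tuple[str, str]]:
        return set(zip(self.outlier_cells["gene"], self.outlier_cells["sample"]))


def inject_outliers(
    counts: pd.DataFrame,
    rate: float,
    factor_range: tuple[float, float],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiply independently selected gene-sample cells by a random factor.

    Each cell is selected with probability ``rate`` independently of every
    other cell, so injected outliers scatter across samples rather than
    concentrating in one.  Selected cells are multiplied by a factor drawn
    uniformly from ``factor_range`` and rounded.  Returns the modified matrix
    and a table of (gene, sample, factor) positions.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("invalid outlier rate: must lie in [0, 1]")
    lo, hi = factor_range
    if lo <= 1:
        raise ConfigError("invalid outlier_factor_min: must exceed 1")
    if hi < lo:
        raise ConfigError("invalid outlier factor range: max < min")
    rng = _rng(seed, _STREAM_OUTLIERS)
    out = counts.copy()
    if rate == 0.0:
        return out, pd.DataFrame(columns=["gene", "sample", "factor"])
    mask = rng.random(counts.shape) < rate
    gi, sj = np.nonzero(mask)
    factors = rng.uniform(lo, hi, size=gi.size)
    arr = out.to_numpy().astype(np.int64)
    arr[gi, sj] = np.rint(arr[gi, sj] * factors).astype(np.int64)
    out = pd.DataFrame(arr, index=counts.index, columns=counts.columns)
    positions = pd.DataFrame(
        {
            "gene": counts.index.to_numpy()[gi],
            "sample": counts.columns.to_numpy()[sj],
            "factor": factors,
        }
    )
    return out, positions


def simulate_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Draw one heterogeneous two-condition count matrix with known truth.

    Returns the genes x samples count DataFrame, the sample annotation
    (tumor/normal), and the :class:`SimTruth` recording every latent value.
    Bit-identical for identical configs.
    """
    g = int(config.n_genes)
    n_t, n_n = int(config.n_tumor_pool), int(config.n_normal_pool)
    genes = pd.Index([f"gene{i + 1:05d}" for i in range(g)], name="gene")
    samples = pd.Index(
        [f"T{j + 1:03d}" for j in range(n_t)] + [f"N{j + 1:03d}" for j in range(n_n)],
        name="sample",
    )
    ann = pd.Series([TUMOR] * n_t + [NORMAL] * n_n, index=samples, name="group")

    baseline = np.exp(
        _rng(config.seed, _STREAM_BASELINE).normal(
            config.baseline_log_mean, config.baseline_log_sd, size=g
        )
    )
    phi = _rng(config.seed, _STREAM_DISPERSION).gamma(
        shape=config.dispersion_shape,
        scale=config.dispersion_mean / config.dispersion_shape,
        size=g,
    )
    phi = np.maximum(phi, 1e-8)

    rng_lfc = _rng(config.seed, _STREAM_LFC)
    n_de = int(round(config.frac_de * g))
    de_idx = rng_lfc.choice(g, size=n_de, replace=False)
    signs = rng_lfc.choice([-1.0, 1.0], size=n_de)
    excess = (
        rng_lfc.exponential(config.lfc_spread, size=n_de)
        if config.lfc_spread > 0
        else np.zeros(n_de)
    )
    lfc = np.zeros(g)
    lfc[de_idx] = signs * (config.lfc_magnitude + excess)
    is_de = np.zeros(g, dtype=bool)
    is_de[de_idx] = True

    lib = np.exp(
        _rng(config.seed, _STREAM_LIBSIZE).normal(
            config.libsize_log_mean, config.libsize_log_sd, size=n_t + n_n
        )
    )

    rng_h = _rng(config.seed, _STREAM_HETERO)
    sd = np.where(ann.to_numpy() == TUMOR, config.hetero_sd_tumor, config.hetero_sd_normal)
    # unit-mean lognormal: meanlog = -sigma^2/2
    h = np.exp(rng_h.normal(0.0, 1.0, size=(g, n_t + n_n)) * sd - 0.5 * sd**2)

    is_tumor = (ann.to_numpy() == TUMOR).astype(float)
    q = baseline[:, None] * np.power(2.0, lfc[:, None] * is_tumor[None, :]) * h
    mean = lib[None, :] * q / q.sum(axis=0, keepdims=True)

    rng_counts = _rng(config.seed, _STREAM_COUNTS)
    r = 1.0 / phi
    p = r[:, None] / (r[:, None] + mean)
    counts = rng_counts.negative_binomial(r[:, None], p).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)

    if config.outlier_rate > 0:
        counts_df, positions = inject_outliers(
            counts_df,
            config.outlier_rate,
            (config.outlier_factor_min, config.outlier_factor_max),
            seed=config.seed,
        )
    else:
        positions = pd.DataFrame(columns=["gene", "sample", "factor"])

    truth = SimTruth(
        is_true_de=pd.Series(is_de, index=genes, name="is_true_de"),
        true_log2fc=pd.Series(lfc, index=genes, name="true_log2fc"),
        gene_dispersions=pd.Series(phi, index=genes, name="dispersion"),
        outlier_cells=positions,
    )
    return counts_df, ann, truth
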