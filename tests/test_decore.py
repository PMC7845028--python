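"""DE-engine contracts, each checked against an independent oracle where one exists:

- TMM factors vs a step-by-step reimplementation of the trimming arithmetic,
- low-count filter vs a direct two-clause evaluation,
- BH vs a brute-force O(m^2) step-up,
- the exact conditional test vs enumeration of NB-product conditionals,
- dispersion estimators vs parameter-recovery simulations with known truth.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from degrepro import (
    DataError,
    SimConfig,
    bh_adjust,
    cpm,
    estimate_common_dispersion,
    estimate_tagwise_dispersions,
    exact_test,
    filter_low_counts,
    run_de,
    simulate_dataset,
    tmm_factors,
)
from degrepro.decore import _exact_test_single

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> pd.Series:
    """Step-by-step TMM arithmetic, written independently of the implementation."""
    lib = counts.sum(axis=0).astype(float)
    frac = counts.divide(lib, axis=1)
    q75 = frac.quantile(0.75)
    ref = (q75 - q75.mean()).abs().idxmin()
    logf = {}
    for sample in counts.columns:
        if sample == ref:
            logf[sample] = 0.0
            continue
        y, yr = counts[sample].astype(float), counts[ref].astype(float)
        ok = (y > 0) & (yr > 0)
        y, yr = y[ok], yr[ok]
        m = np.log2((y / lib[sample]) / (yr / lib[ref]))
        a = 0.5 * np.log2((y / lib[sample]) * (yr / lib[ref]))
        w = (lib[sample] - y) / (lib[sample] * y) + (lib[ref] - yr) / (lib[ref] * yr)
        n = len(m)
        rm, ra = m.rank(), a.rank()
        keep = (
            (rm >= n * trim_m + 1)
            & (rm <= n * (1 - trim_m))
            & (ra >= n * trim_a + 1)
            & (ra <= n * (1 - trim_a))
        )
        logf[sample] = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    s = pd.Series(logf)[counts.columns]
    s -= s.mean()
    return 2.0**s


def exact_p_oracle(s_obs, t, n_a, n_b, phi):
    """Two-sided conditional p by enumerating NB pmf products over all splits."""
    r_a, r_b = n_a / phi, n_b / phi
    k = np.arange(t + 1)
    w = stats.nbinom.pmf(k, r_a, 0.5) * stats.nbinom.pmf(t - k, r_b, 0.5)
    w = w / w.sum()
    lower = w[: s_obs + 1].sum()
    upper = w[s_obs:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def bh_oracle(p):
    """Brute-force BH step-up, O(m^2)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        # ties share the largest rank: rank(p_j) = #{k: p_k <= p_j}
        candidates = [
            p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80, 33])
        counts = pd.DataFrame(
            {f"s{j}": col for j in range(4)}, index=[f"g{i}" for i in range(6)]
        )
        norm = tmm_factors(counts)
        assert np.allclose(norm.tmm_factor, 1.0)

    def test_pure_depth_doubling_absorbed_by_library_size(self):
        a = np.array([12, 40, 7, 300, 95, 18])
        counts = pd.DataFrame({"A": a, "B": 2 * a}, index=[f"g{i}" for i in range(6)])
        norm = tmm_factors(counts)
        assert np.allclose(norm.tmm_factor, 1.0, atol=1e-10)
        assert norm.library_size["B"] == 2 * norm.library_size["A"]

    def test_toy_matrix_matches_stepwise_oracle(self, toy_counts):
        norm = tmm_factors(toy_counts)
        oracle = tmm_oracle(toy_counts)
        assert np.allclose(norm.tmm_factor[toy_counts.columns], oracle, rtol=1e-10)

    def test_geometric_mean_one(self, hetero_sim):
        counts, _, _ = hetero_sim
        norm = tmm_factors(counts)
        assert abs(np.exp(np.mean(np.log(norm.tmm_factor))) - 1.0) < 1e-8
        assert (norm.tmm_factor > 0).all()

    def test_all_zero_sample_rejected_by_name(self, toy_counts):
        bad = toy_counts.copy()
        bad["N2"] = 0
        with pytest.raises(DataError, match="N2"):
            tmm_factors(bad)

    def test_column_scaling_leaves_cpm_invariant(self, toy_counts):
        norm = tmm_factors(toy_counts)
        base = cpm(toy_counts, norm)
        scaled = toy_counts.copy()
        scaled["T1"] = scaled["T1"] * 5
        norm2 = tmm_factors(scaled)
        other = cpm(scaled, norm2)
        assert np.allclose(base.to_numpy(), other.to_numpy(), rtol=1e-8)


class TestCPM:
    def test_unit_library(self):
        counts = pd.DataFrame({"s": [5, 0]}, index=["g1", "g2"])
        norm = tmm_factors(counts)
        vals = cpm(counts, norm)
        # effective size is the library (5), so 5 reads -> 1e6 CPM exactly
        assert vals.loc["g1", "s"] == pytest.approx(5 / 5 * 1e6)
        assert vals.loc["g2", "s"] == 0.0

    def test_columns_sum_to_million_times_size_ratio(self, toy_counts):
        norm = tmm_factors(toy_counts)
        vals = cpm(toy_counts, norm)
        expect = 1e6 * norm.library_size / norm.effective_size
        assert np.allclose(vals.sum(axis=0), expect)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


class TestFilter:
    def _toy(self):
        counts = pd.DataFrame(
            {
                "T1": [0, 900, 3, 20, 6],
                "T2": [0, 800, 2, 25, 7],
                "T3": [0, 700, 1, 30, 5],
                "N1": [0, 600, 2, 0, 6],
                "N2": [0, 500, 3, 0, 8],
                "N3": [0, 400, 1, 0, 7],
            },
            index=[f"g{i}" for i in range(5)],
        )
        ann = pd.Series(
            {s: ("tumor" if s.startswith("T") else "normal") for s in counts.columns}
        )
        return counts, ann

    def test_all_zero_gene_removed_and_strong_gene_kept(self):
        counts, ann = self._toy()
        keep = filter_low_counts(counts, ann)
        assert not keep["g0"]
        assert keep["g1"]

    def test_mask_matches_rule_by_rule_oracle(self):
        counts, ann = self._toy()
        keep = filter_low_counts(counts, ann, min_count=10, min_total=15)
        lib = counts.sum(axis=0)
        c = 10 / np.median(lib) * 1e6
        cpm_raw = counts.divide(lib, axis=1) * 1e6
        n_min = 3
        expected = ((cpm_raw >= c).sum(axis=1) >= n_min) & (counts.sum(axis=1) >= 15)
        pd.testing.assert_series_equal(keep, expected.rename("kept"))


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


class TestDispersion:
    def test_poisson_data_yields_near_zero(self):
        cfg = SimConfig(
            n_genes=400, n_tumor_pool=50, n_normal_pool=50, frac_de=0.0,
            dispersion_mean=1e-6, dispersion_shape=1e6,
            hetero_sd_tumor=0.0, hetero_sd_normal=0.0, outlier_rate=0.0, seed=21,
        )
        counts, ann, _ = simulate_dataset(cfg)
        norm = tmm_factors(counts)
        assert estimate_common_dispersion(counts, ann, norm) <= 0.01

    def test_recovers_known_dispersion(self):
        cfg = SimConfig(
            n_genes=2000, n_tumor_pool=30, n_normal_pool=30, frac_de=0.0,
            dispersion_mean=0.2, dispersion_shape=1e6,
            hetero_sd_tumor=0.0, hetero_sd_normal=0.0, outlier_rate=0.0, seed=11,
        )
        counts, ann, _ = simulate_dataset(cfg)
        norm = tmm_factors(counts)
        est = estimate_common_dispersion(counts, ann, norm)
        assert 0.15 <= est <= 0.25

    def test_zero_within_group_variability_hits_lower_bound(self):
        counts = pd.DataFrame(
            {"T1": [40, 7, 100], "T2": [40, 7, 100], "N1": [10, 30, 90],
             "N2": [10, 30, 90]},
            index=["g0", "g1", "g2"],
        )
        ann = pd.Series(
            {"T1": "tumor", "T2": "tumor", "N1": "normal", "N2": "normal"}
        )
        norm = tmm_factors(counts)
        assert estimate_common_dispersion(counts, ann, norm) < 1e-4

    def test_infinite_shrinkage_collapses_to_common(self, tiny_sim):
        counts, ann, _ = tiny_sim
        sub = counts.iloc[:80]
        norm = tmm_factors(sub)
        common = estimate_common_dispersion(sub, ann, norm)
        tag = estimate_tagwise_dispersions(sub, ann, norm, common, prior_df=1e9)
        assert np.allclose(tag, common, atol=1e-6)

    def test_unshrunk_overdispersed_gene_exceeds_common(self, tiny_sim):
        counts, ann, _ = tiny_sim
        sub = counts.iloc[:80].copy()
        wild = sub.iloc[0].to_numpy().copy()
        wild[::2] = wild[::2] * 40 + 500  # extreme within-group variability
        sub.iloc[0] = wild
        norm = tmm_factors(sub)
        common = estimate_common_dispersion(sub, ann, norm)
        tag = estimate_tagwise_dispersions(sub, ann, norm, common, prior_df=0.0)
        assert tag.iloc[0] > common

    def test_homogeneous_data_median_tagwise_near_truth(self):
        cfg = SimConfig(
            n_genes=600, n_tumor_pool=30, n_normal_pool=30, frac_de=0.0,
            dispersion_mean=0.2, dispersion_shape=1e6,
            hetero_sd_tumor=0.0, hetero_sd_normal=0.0, outlier_rate=0.0, seed=31,
        )
        counts, ann, _ = simulate_dataset(cfg)
        norm = tmm_factors(counts)
        common = estimate_common_dispersion(counts, ann, norm)
        tag = estimate_tagwise_dispersions(counts, ann, norm, common)
        assert abs(np.median(tag) - 0.2) / 0.2 < 0.25


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


class TestExactTest:
    def test_balanced_identical_groups_p_one_lfc_zero(self):
        counts = pd.DataFrame(
            {"T1": [30, 6], "T2": [12, 60], "N1": [30, 6], "N2": [12, 60]},
            index=["g0", "g1"],
        )
        ann = pd.Series(
            {"T1": "tumor", "T2": "tumor", "N1": "normal", "N2": "normal"}
        )
        norm = tmm_factors(counts)
        disp = pd.Series(0.1, index=counts.index)
        res = exact_test(counts, ann, norm, disp)
        assert np.allclose(res["PValue"], 1.0)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-12)

    def test_label_swap_symmetry(self, toy_counts, toy_annotation):
        norm = tmm_factors(toy_counts)
        disp = pd.Series(0.2, index=toy_counts.index)
        res = exact_test(toy_counts, toy_annotation, norm, disp)
        swapped = toy_annotation.map({"tumor": "normal", "normal": "tumor"})
        res2 = exact_test(toy_counts, swapped, norm, disp)
        assert np.allclose(res["PValue"], res2["PValue"], rtol=1e-10)
        assert np.allclose(res["log2FC"], -res2["log2FC"], atol=1e-10)

    @pytest.mark.parametrize("t,s,n_a,n_b,phi", [
        (6, 5, 1, 1, 0.5),
        (6, 3, 1, 1, 0.5),
        (20, 4, 3, 2, 0.2),
        (15, 15, 2, 2, 1.0),
        (11, 0, 4, 4, 0.05),
    ])
    def test_matches_enumeration_oracle(self, t, s, n_a, n_b, phi):
        p = _exact_test_single(s, t - s, n_a, n_b, phi)
        assert p == pytest.approx(exact_p_oracle(s, t, n_a, n_b, phi), rel=1e-8)

    def test_nonfinite_dispersion_rejected(self, toy_counts, toy_annotation):
        norm = tmm_factors(toy_counts)
        disp = pd.Series(np.nan, index=toy_counts.index)
        with pytest.raises(DataError):
            exact_test(toy_counts, toy_annotation, norm, disp)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_hand_stepped_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_range_and_sorted_monotonicity(self, p):
        q = bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


class TestRunDE:
    def test_group_size_refusal_and_override(self, toy_counts, toy_annotation):
        with pytest.raises(DataError, match="allow_small_groups"):
            run_de(toy_counts, toy_annotation)
        res = run_de(toy_counts, toy_annotation, allow_small_groups=True)
        assert len(res.table) > 0

    def test_recall_and_flag_biconditional(self):
        cfg = SimConfig(
            n_genes=800, n_tumor_pool=20, n_normal_pool=20, frac_de=0.1,
            lfc_magnitude=2.0, hetero_sd_tumor=0.2, hetero_sd_normal=0.1,
            outlier_rate=0.0, seed=13,
        )
        counts, ann, truth = simulate_dataset(cfg)
        res = run_de(counts, ann)
        table = res.table
        flag = (table["log2FC"].abs() >= 1.0) & (table["FDR"] < 0.05)
        assert (table["is_DEG"] == flag).all()
        true_de = set(truth.is_true_de.index[truth.is_true_de])
        recall = len(res.deg_set & true_de) / len(true_de)
        assert recall > 0.5

    def test_fdr_is_bh_of_pvalues(self, tiny_sim):
        counts, ann, _ = tiny_sim
        res = run_de(counts, ann)
        assert np.allclose(
            res.table["FDR"], bh_oracle(res.table["PValue"].to_numpy())
        )

    def test_filtered_gene_absent_from_result(self, tiny_sim):
        counts, ann, _ = tiny_sim
        counts = counts.copy()
        counts.loc["gene_dead"] = 0
        res = run_de(counts, ann)
        assert "gene_dead" not in res.table.index
        assert not res.kept["gene_dead"]
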