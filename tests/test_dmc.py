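"""Differential methylation/expression tests: model reductions, a dense-GLS
oracle, calibration, and the rank-overlap arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methfield.datamodel import BetaMatrix
from methfield.dmc import (
    consensus_correlation,
    de_mixed_test,
    log_cpm,
    meth_expr_correlation,
    mixed_group_test,
    rank_overlap,
)
from methfield.simulate import SimulationConfig, generate_cohort, generate_expression


def _one_sample_per_patient_cohort(n_probes=40, n_patients=12, seed=0):
    rng = np.random.default_rng(seed)
    pids = [f"P{i}" for i in range(n_patients)]
    samples = pd.DataFrame(
        {
            "sample_id": [f"{p}_s" for p in pids],
            "patient_id": pids,
            "tissue_class": "cancer",
            "cancer_area_pct": 50.0,
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "recurrence": [True] * (n_patients // 2) + [False] * (n_patients - n_patients // 2),
            "metastasis": False,
            "followup_years": 10.0,
        }
    )
    beta = BetaMatrix(
        pd.DataFrame(
            rng.uniform(0.2, 0.8, (n_probes, n_patients)),
            index=[f"cg{i}" for i in range(n_probes)],
            columns=samples["sample_id"],
        )
    )
    return beta, samples, patients


def test_reduces_to_ordinary_t_test_with_one_sample_per_patient():
    beta, samples, patients = _one_sample_per_patient_cohort()
    res = mixed_group_test(beta, samples, patients, outcome="recurrence")
    assert res.attrs["consensus_correlation"] == 0.0
    rec = patients.set_index("patient_id")["recurrence"]
    g = rec.loc[samples["patient_id"]].to_numpy()
    for i, pid in enumerate(beta.probe_ids[:10]):
        y = beta.values[i]
        t, p = sps.ttest_ind(y[g], y[~g], equal_var=True)
        assert res.loc[res["feature_id"] == pid, "p"].iloc[0] == pytest.approx(p, abs=1e-10)
        diff = y[g].mean() - y[~g].mean()
        assert res.loc[res["feature_id"] == pid, "effect"].iloc[0] == pytest.approx(diff, abs=1e-10)


def test_matches_dense_gls_oracle(small_cohort):
    """The whitened OLS must equal textbook GLS with the full block
    compound-symmetry covariance, built densely and solved independently."""
    beta, samples, patients = (small_cohort["beta"], small_cohort["samples"],
                               small_cohort["patients"])
    res = mixed_group_test(beta, samples, patients, outcome="recurrence")
    rho = res.attrs["consensus_correlation"]
    info = samples.set_index("sample_id").loc[beta.sample_ids]
    pat = info["patient_id"].to_numpy()
    rec = patients.set_index("patient_id")["recurrence"]
    g = rec.loc[pat].to_numpy().astype(float)
    n = len(pat)
    Sigma = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j and pat[i] == pat[j]:
                Sigma[i, j] = rho
    Si = np.linalg.inv(Sigma)
    X = np.column_stack([np.ones(n), g])
    XtSiX_inv = np.linalg.inv(X.T @ Si @ X)
    for i in [0, 5, 17]:
        y = beta.values[i]
        b = XtSiX_inv @ X.T @ Si @ y
        resid = y - X @ b
        s2 = (resid @ Si @ resid) / (n - 2)
        se = np.sqrt(s2 * XtSiX_inv[1, 1])
        t = b[1] / se
        p = 2 * sps.t.sf(abs(t), n - 2)
        row = res.iloc[i]
        assert row["effect"] == pytest.approx(b[1], abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-10)


def test_group_relabeling_and_sample_order_invariance(small_cohort):
    beta, samples, patients = (small_cohort["beta"], small_cohort["samples"],
                               small_cohort["patients"])
    res = mixed_group_test(beta, samples, patients, outcome="recurrence")
    flipped = patients.copy()
    flipped["recurrence"] = ~flipped["recurrence"].astype(bool)
    flipped.loc[~flipped["recurrence"], "recurrence_free_interval_months"] = np.nan
    flipped.loc[flipped["recurrence"], "recurrence_free_interval_months"] = 12.0
    flipped["metastasis"] = False
    res_flip = mixed_group_test(beta, samples, flipped, outcome="recurrence")
    np.testing.assert_allclose(res["p"], res_flip["p"], atol=1e-12)
    np.testing.assert_allclose(res["effect"], -res_flip["effect"], atol=1e-12)

    order = list(reversed(beta.sample_ids))
    res_perm = mixed_group_test(beta.subset_samples(order), samples, patients,
                                outcome="recurrence")
    np.testing.assert_allclose(res["p"], res_perm["p"], atol=1e-10)


def test_patient_level_permutation_p_values_are_calibrated():
    """Permuting outcome labels at the patient level yields uniform p."""
    cfg = SimulationConfig(n_probes=500, delta_beta=0.0, n_filter_fail=0, seed=21)
    beta, samples, patients, _, _ = generate_cohort(cfg)
    rng = np.random.default_rng(9)
    perm = patients.copy()
    labels = perm["recurrence"].to_numpy().copy()
    rng.shuffle(labels)
    perm["recurrence"] = labels
    perm["metastasis"] = perm["metastasis"] & perm["recurrence"]
    perm["recurrence_free_interval_months"] = np.where(perm["recurrence"], 12.0, np.nan)
    res = mixed_group_test(beta, samples, perm, outcome="recurrence")
    ks = sps.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.01


def test_too_few_patients_per_group_rejected(tiny_beta):
    beta, samples = tiny_beta
    patients = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "recurrence": [True, False, False],
            "metastasis": False,
            "followup_years": 10.0,
            "recurrence_free_interval_months": [12.0, np.nan, np.nan],
        }
    )
    with pytest.raises(ValueError, match="2 patients"):
        mixed_group_test(beta, samples, patients)


class TestRankOverlap:
    def _mk(self, ids):
        n = len(ids)
        return pd.DataFrame({"feature_id": ids, "effect": 0.0, "p": np.linspace(0.01, 0.9, n),
                             "q": 0.5, "rank": np.arange(1, n + 1)})

    def test_identical_lists_fraction_one(self):
        a = self._mk(list("abcdefghij"))
        count, frac = rank_overlap(a, a, 0.3)
        assert (count, frac) == (3, 1.0)

    def test_constructed_partial_overlap(self):
        a = self._mk(list("abcdefghij"))
        b = self._mk(["d", "e", "x1", "x2", "x3", "a", "b", "c", "f", "g"])
        # universes must match: rebuild b over the same ids, top-5 = d,e,a,b,c? no:
        b = self._mk(["d", "e", "h", "i", "j", "a", "b", "c", "f", "g"])
        count, frac = rank_overlap(a, b, 0.5)  # top5 a: a-e; top5 b: d,e,h,i,j
        assert (count, frac) == (2, 0.4)

    def test_full_fraction_is_one_regardless_of_order(self):
        a = self._mk(list("abcde"))
        b = self._mk(list("edcba"))
        _, frac = rank_overlap(a, b, 1.0)
        assert frac == 1.0

    def test_invalid_fraction_rejected(self):
        a = self._mk(list("abc"))
        with pytest.raises(ValueError):
            rank_overlap(a, a, 0.0)
        with pytest.raises(ValueError):
            rank_overlap(a, a, 1.5)


class TestDifferentialExpression:
    def test_duplicated_columns_across_groups_give_no_hits(self):
        # identical count blocks in both outcome groups: zero group effect
        rng = np.random.default_rng(3)
        beta, samples, patients = _one_sample_per_patient_cohort(n_patients=12, seed=3)
        block = rng.poisson(100, (500, 6))
        counts = pd.DataFrame(
            np.hstack([block, block]), columns=samples["sample_id"],
            index=[f"G{i}" for i in range(500)],
        )
        res = de_mixed_test(counts, samples, patients, grouping="outcome")
        assert (res["q"].dropna() < 0.05).sum() == 0
        assert np.allclose(res["effect"].abs(), 0.0, atol=1e-12)

    def test_tissue_spiked_genes_recovered_and_rank_first(self, small_cohort):
        counts, gene_truth = generate_expression(
            small_cohort["annotation"], small_cohort["samples"], small_cohort["truth"],
            tissue_log2fc=2.0, seed=8,
        )
        res = de_mixed_test(counts, small_cohort["samples"], small_cohort["patients"],
                            grouping="tissue")
        hits = set(res.loc[res["q"] < 0.05, "feature_id"])
        de = set(gene_truth.loc[gene_truth["tissue_de"], "gene"])
        assert len(hits & de) / len(de) > 0.9
        # spiked genes dominate the top of the ranking (CPM is compositional,
        # so unspiked genes shift in relative terms and may also reach q<0.05)
        top = set(res.nsmallest(len(de), "rank")["feature_id"])
        assert len(top & de) / len(de) > 0.8

    def test_zero_library_size_rejected(self):
        beta, samples, patients = _one_sample_per_patient_cohort(n_patients=6)
        counts = pd.DataFrame(0, index=["G1"], columns=samples["sample_id"])
        with pytest.raises(ValueError, match="library size"):
            de_mixed_test(counts, samples, patients)

    def test_constant_gene_flagged_undefined(self):
        beta, samples, patients = _one_sample_per_patient_cohort(n_patients=8)
        counts = pd.DataFrame(50, index=["G1"], columns=samples["sample_id"])
        res = de_mixed_test(counts, samples, patients)
        assert np.isnan(res["p"].iloc[0])


class TestMethExprCorrelation:
    def _setup(self, transform):
        rng = np.random.default_rng(4)
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "patient_id": [f"p{i}" for i in range(10)],
                "tissue_class": "cancer",
                "cancer_area_pct": 50.0,
            }
        )
        betas = rng.uniform(0.2, 0.8, 10)
        beta = BetaMatrix(pd.DataFrame([betas], index=["cg1"], columns=samples["sample_id"]))
        ann = pd.DataFrame({"probe_id": ["cg1"], "chrom": "chr1", "pos": 100,
                            "gene_symbols": "GENE1", "island_relation": "island"})
        expr = np.round(transform(betas) * 1e4).astype(int)
        # a large constant background gene pins the library size so that the
        # target gene's log-CPM tracks its own counts
        counts = pd.DataFrame(
            [expr, np.full(10, 10**8)], index=["GENE1", "BACKGROUND"],
            columns=samples["sample_id"],
        )
        return beta, counts, ann, samples

    def test_perfect_linear_correlation(self):
        beta, counts, ann, samples = self._setup(lambda b: 2.0 ** (10 * b) / 2000)
        res = meth_expr_correlation(beta, counts, ann, samples)
        assert res["r"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_perfect_anticorrelation(self):
        beta, counts, ann, samples = self._setup(lambda b: 2.0 ** (-10 * b))
        res = meth_expr_correlation(beta, counts, ann, samples)
        assert res["r"].iloc[0] == pytest.approx(-1.0, abs=1e-3)

    def test_independent_pairs_have_small_mean_r(self, small_cohort):
        counts, _ = generate_expression(
            small_cohort["annotation"], small_cohort["samples"], small_cohort["truth"],
            tissue_log2fc=0.0, frac_tissue_de=0.0, seed=10,
        )
        res = meth_expr_correlation(
            small_cohort["beta"], counts, small_cohort["annotation"], small_cohort["samples"]
        )
        assert len(res) > 50
        assert abs(res["r"].mean()) < 0.1


def test_consensus_correlation_recovers_block_structure():
    rng = np.random.default_rng(11)
    n_pat, k, n_feat = 20, 3, 300
    patient = np.repeat(np.arange(n_pat), k)
    rho_true = 0.6
    b = rng.normal(size=(n_feat, n_pat)) * np.sqrt(rho_true)
    e = rng.normal(size=(n_feat, n_pat * k)) * np.sqrt(1 - rho_true)
    Y = b[:, np.repeat(np.arange(n_pat), k)] + e
    X = np.ones((n_pat * k, 1))
    est = consensus_correlation(Y, X, patient)
    assert est == pytest.approx(rho_true, abs=0.07)


def test_log_cpm_prior_count():
    counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
    out = log_cpm(counts, prior_count=0.5)
    assert out.loc["g1", "s1"] == pytest.approx(np.log2(0.5 / 101 * 1e6))
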