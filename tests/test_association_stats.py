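"""Independence tests, tau-b concordance and perfect-band detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_band_matrix
from msapbf.association_stats import (
    build_2x2,
    conditional_independence_test,
    kendall_tau_b,
    pairwise_concordance,
    pearson_chi2,
    perfectly_associated_bands,
    phi_coefficient,
)
from msapbf.bandmatrix_io import AccessionMeta
from msapbf.epigenotyping import classify_matrix, dichotomize_bf


def tau_b_bruteforce(x, y):
    """Pair-enumeration oracle with explicit tie corrections."""
    n = len(x)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        conc += s > 0
        disc += s < 0
    n0 = n * (n - 1) // 2
    n1 = sum(c * (c - 1) // 2 for c in pd.Series(list(x)).value_counts())
    n2 = sum(c * (c - 1) // 2 for c in pd.Series(list(y)).value_counts())
    return (conc - disc) / np.sqrt((n0 - n1) * (n0 - n2))


class TestPhi:
    def test_published_counts(self):
        t = np.array([[6598, 5799], [5798, 6597]])
        assert round(phi_coefficient(t), 3) == 0.064

    def test_perfect_association(self):
        assert phi_coefficient([[10, 0], [0, 10]]) == 1.0

    def test_symmetric_example(self):
        assert phi_coefficient([[3, 1], [1, 3]]) == pytest.approx(0.5)

    def test_zero_margin_signalled(self):
        with pytest.raises(ZeroDivisionError):
            phi_coefficient([[0, 0], [3, 4]])

    def test_phi_squared_times_n_equals_chi2(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 200, size=(2, 2))
            res = pearson_chi2(t)
            assert res.chi2 == pytest.approx(res.n * phi_coefficient(t) ** 2, rel=1e-12)


class TestPearsonChi2:
    def test_no_departure_gives_zero(self):
        t = np.array([[10, 20], [10, 20]])
        res = pearson_chi2(t)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.residuals, 0.0)

    def test_small_table_closed_form(self):
        res = pearson_chi2([[3, 1], [1, 3]])
        assert res.chi2 == pytest.approx(2.0)
        assert res.df == 1

    def test_brute_force_sum(self):
        t = np.array([[6598, 5799], [5798, 6597]], float)
        e = np.outer(t.sum(1), t.sum(0)) / t.sum()
        chi2_brute = ((t - e) ** 2 / e).sum()
        res = pearson_chi2(t)
        assert res.chi2 == pytest.approx(chi2_brute, rel=1e-12)
        assert res.residuals.to_numpy() == pytest.approx((t - e) / np.sqrt(e))


class TestBuild2x2:
    def test_all_demethylated(self):
        m = make_band_matrix([[1, 1], [1, 1]], [[1, 1], [1, 1]], ["a1_", "a2_"])
        epi = classify_matrix(m)
        t = build_2x2(epi, {"a1_": "BF", "a2_": "NBF"})
        assert (t.loc["methylated"] == 0).all()

    def test_hand_tally(self, classified_toy):
        t = build_2x2(classified_toy, {"acc1": "BF", "acc2": "NBF"})
        # acc1: demeth, hemi, internal -> 2 methylated; acc2: full, demeth, hemi -> 2
        assert t.loc["methylated", "BF"] == 2
        assert t.loc["unmethylated", "BF"] == 1
        assert t.loc["methylated", "NBF"] == 2
        assert t.to_numpy().sum() == 6

    def test_conservation(self, small_synthetic, accession_meta):
        matrix, _ = small_synthetic
        epi = classify_matrix(matrix)
        t = build_2x2(epi, dichotomize_bf(accession_meta))
        assert t.to_numpy().sum() == len(epi.accessions) * len(epi.band_names)


class TestCMH:
    def test_odds_ratio_one_everywhere(self):
        strata = [np.array([[20, 40], [10, 20]])] * 3
        res = conditional_independence_test(strata)
        assert res.chi2 == pytest.approx(0.0, abs=0.3)  # continuity correction
        assert res.df == 1

    def test_single_stratum_matches_corrected_chi2(self):
        # CMH on one stratum = continuity-corrected chi2 up to the (N-1)/N factor
        t = np.array([[30, 10], [12, 28]])
        res = conditional_independence_test([t])
        chi2, _, _, _ = stats.chi2_contingency(t, correction=True)
        n = t.sum()
        assert res.chi2 == pytest.approx(chi2 * (n - 1) / n, rel=1e-8)

    def test_invariant_to_stratum_order(self):
        rng = np.random.default_rng(1)
        strata = [rng.integers(5, 50, (2, 2)) for _ in range(4)]
        a = conditional_independence_test(strata)
        b = conditional_independence_test(strata[::-1])
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_zero_margin_stratum_skipped(self):
        good = np.array([[30, 10], [12, 28]])
        bad = np.array([[0, 0], [5, 5]])
        with pytest.warns(UserWarning, match="skipped"):
            res = conditional_independence_test([good, bad])
        ref = conditional_independence_test([good])
        assert res.chi2 == pytest.approx(ref.chi2)

    def test_null_p_values_roughly_uniform(self):
        # conditional independence holds: uncorrected p over replicates ~ U(0,1)
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            strata = []
            for _k in range(3):
                row = rng.binomial(200, 0.5, size=2)
                strata.append(
                    np.array([[row[0], 200 - row[0]], [row[1], 200 - row[1]]])
                )
            pvals.append(
                conditional_independence_test(strata, correction=False).p_value
            )
        ks = stats.kstest(pvals, "uniform").pvalue
        assert ks > 0.01


class TestKendallTauB:
    def test_identity_and_reversal(self):
        assert kendall_tau_b([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert kendall_tau_b([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(-1.0)

    def test_tie_adjusted_example(self):
        assert kendall_tau_b([0, 1, 1, 0, 1], [0, 1, 0, 0, 1]) == pytest.approx(2 / 3)

    def test_constant_vector_signalled(self):
        with pytest.raises(ZeroDivisionError):
            kendall_tau_b([1, 1, 1], [0, 1, 0])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7, 8])
    def test_exhaustive_binary_vectors(self, n):
        """tau-b equals pair enumeration on every non-constant binary pair."""
        vecs = [v for v in itertools.product((0, 1), repeat=n) if 0 < sum(v) < n]
        # exhaustive for n <= 5; deterministic subsample above to bound runtime
        if n > 5:
            vecs = vecs[:: max(1, len(vecs) // 40)]
        for x in vecs:
            for y in vecs:
                assert kendall_tau_b(x, y) == pytest.approx(
                    tau_b_bruteforce(x, y), rel=1e-12
                )


class TestConcordance:
    def _meta(self, ids, genotypes):
        return [
            AccessionMeta(i, g, "No", 1, 1) for i, g in zip(ids, genotypes)
        ]

    def test_duplicate_accession_gives_tau_one(self):
        m = make_band_matrix(
            [[1, 0, 0], [1, 0, 0]], [[1, 1, 0], [1, 1, 0]], ["p", "q"]
        )
        epi = classify_matrix(m)
        c = pairwise_concordance(epi, self._meta(["p", "q"], ["G", "G"]))
        assert c.tau.loc["p", "q"] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        m = make_band_matrix(
            [[1, 1, 0, 0], [0, 0, 1, 1]], [[1, 1, 1, 1], [1, 1, 1, 1]], ["p", "q"]
        )
        epi = classify_matrix(m)
        c = pairwise_concordance(epi, self._meta(["p", "q"], ["G", "H"]))
        assert c.tau.loc["p", "q"] == pytest.approx(-1.0)

    def test_matrix_composes_pairwise_calls(self, small_synthetic, accession_meta):
        matrix, _ = small_synthetic
        epi = classify_matrix(matrix)
        sub = epi.accessions[:4]
        epi.states = epi.states.loc[sub]
        epi.__post_init__()
        c = pairwise_concordance(epi, accession_meta)
        for i, a in enumerate(sub):
            for b in sub[i + 1 :]:
                expect = kendall_tau_b(
                    epi.binary_methylated.loc[a], epi.binary_methylated.loc[b]
                )
                assert c.tau.loc[a, b] == pytest.approx(expect)
        assert np.allclose(c.tau.to_numpy(), c.tau.to_numpy().T, equal_nan=True)


class TestPerfectBands:
    def test_planted_band_recovered(self, small_synthetic, accession_meta):
        from msapbf.synthetic_data import plant_perfect_band

        matrix, truth = small_synthetic
        grouping = dichotomize_bf(accession_meta)
        planted, truth2 = plant_perfect_band(matrix, truth, grouping)
        epi = classify_matrix(planted)
        hits = perfectly_associated_bands(epi, grouping)
        names = [b.name for b, _ in hits]
        assert truth2.planted_bands[0] in names

    def test_no_perfect_band_empty(self):
        m = make_band_matrix(
            [[1, 1], [1, 1], [0, 1]], [[1, 1], [1, 1], [1, 1]], ["x", "y", "z"]
        )
        epi = classify_matrix(m)
        assert perfectly_associated_bands(epi, {"x": "BF", "y": "NBF", "z": "BF"}) == []

    def test_one_mismatch_excluded(self):
        # band methylated in both BF accessions and in one NBF accession
        m = make_band_matrix(
            [[0], [0], [0], [1]], [[1], [1], [1], [1]],
            ["b1", "b2", "n1", "n2"],
        )
        epi = classify_matrix(m)
        grouping = {"b1": "BF", "b2": "BF", "n1": "NBF", "n2": "NBF"}
        assert perfectly_associated_bands(epi, grouping) == []

    def test_complement_orientation_flagged(self):
        m = make_band_matrix(
            [[1], [0]], [[1], [1]], ["bf_acc", "nbf_acc"]
        )
        epi = classify_matrix(m)
        hits = perfectly_associated_bands(epi, {"bf_acc": "BF", "nbf_acc": "NBF"})
        assert hits and hits[0][1] == "methylated_in_NBF"

    def test_sweep_oracle_agreement(self, small_synthetic, accession_meta):
        matrix, _ = small_synthetic
        grouping = dichotomize_bf(accession_meta)
        epi = classify_matrix(matrix)
        hits = {b.name for b, _ in perfectly_associated_bands(epi, grouping)}
        bf = [a for a in epi.accessions if grouping[a] == "BF"]
        nbf = [a for a in epi.accessions if grouping[a] == "NBF"]
        for band in epi.band_names:
            col = epi.binary_methylated[band]
            sep = (col[bf].nunique() == 1 and col[nbf].nunique() == 1
                   and col[bf].iloc[0] != col[nbf].iloc[0])
            assert (band in hits) == sep
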