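"""Statistics: correlations, early ROC, expanded-core labels, bootstrap,
KL logos, amino-acid frequencies, ELISpot calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhc2deconv.evaluation import (
    aa_frequency_pcc,
    auc01,
    bootstrap_compare_scc,
    elispot_call,
    expanded_core_label,
    kl_logo,
    ppv_top_n,
    precision_recall_scan,
    profile_scc,
)


def brute_force_auc01(labels, scores, fmax=0.1):
    """Threshold-sweep ROC oracle, trapezoidal to FPR <= fmax, normalized."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos, neg = labels.sum(), (1 - labels).sum()
    points = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        points.append(((pred & (labels == 0)).sum() / neg, (pred & (labels == 1)).sum() / pos))
    points.append((1.0, 1.0))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    tpr_at = np.interp(fmax, fpr, tpr)
    keep = fpr < fmax
    return float(np.trapezoid(np.append(tpr[keep], tpr_at), np.append(fpr[keep], fmax))) / fmax


class TestProfileScc:
    def test_identical_profiles(self):
        x = np.array([0.1, 0.5, 0.9, 0.3])
        assert profile_scc(x, x) == pytest.approx(1.0)

    def test_reversed_ranking(self):
        assert profile_scc([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_toy_value(self):
        assert profile_scc([0, 1, 2, 3], [0, 2, 1, 3]) == pytest.approx(0.8)

    def test_constant_profile_nan(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(profile_scc([1, 1, 1], [1, 2, 3]))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(30), rng.random(30)
        assert profile_scc(a, b) == pytest.approx(profile_scc(b, a))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            profile_scc([1, 2], [1, 2, 3])


class TestAuc01:
    def test_perfect_separation(self):
        labels = [1] * 5 + [0] * 45
        scores = list(np.linspace(0.9, 1, 5)) + list(np.linspace(0, 0.5, 45))
        assert auc01(labels, scores) == pytest.approx(1.0)

    def test_anti_ranking(self):
        labels = [0] * 45 + [1] * 5
        scores = list(np.linspace(0.9, 1, 45)) + list(np.linspace(0, 0.5, 5))
        assert auc01(labels, scores) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc01([1, 1, 1], [0.1, 0.2, 0.3])

    def test_twenty_point_toy_equals_oracle(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        scores = rng.random(20)
        assert auc01(labels, scores) == pytest.approx(brute_force_auc01(labels, scores))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_equals_oracle_on_small_instances(self, seed):
        """Implementation agrees with the exhaustive threshold sweep on every
        random instance of up to 50 points (including ties)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
        assert auc01(labels, scores) == pytest.approx(
            brute_force_auc01(labels, scores), abs=1e-9
        )


class TestExpandedCore:
    def test_overlap_is_positive(self):
        labeling = expanded_core_label([(20, 28)], [(10, 24)])
        assert labeling.labels.tolist() == [1]
        assert labeling.provenance == ["core_overlap"]

    def test_disjoint_is_negative(self):
        labeling = expanded_core_label([(30, 38)], [(10, 24)])
        assert labeling.labels.tolist() == [0]

    def test_no_core_keeps_direct_label(self):
        labeling = expanded_core_label([None, None], [(1, 9)], direct_labels=[True, False])
        assert labeling.labels.tolist() == [1, 0]
        assert labeling.provenance[0] == "direct_mapps"

    def test_core_outside_protein_error(self):
        with pytest.raises(ValueError):
            expanded_core_label([(95, 103)], [(10, 24)], protein_length=100)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        cores = [(int(s), int(s) + 8) for s in rng.integers(1, 192, 100)]
        spans = [(int(s), int(s) + int(rng.integers(12, 22)) - 1) for s in rng.integers(1, 170, 15)]
        labeling = expanded_core_label(cores, spans, protein_length=250)
        for (cs, ce), label in zip(cores, labeling.labels):
            expected = any(
                len(set(range(cs, ce + 1)) & set(range(ms, me + 1))) > 0
                for ms, me in spans
            )
            assert bool(label) == expected


class TestPpv:
    def test_perfect_ranking(self):
        assert ppv_top_n([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_half_right(self):
        assert ppv_top_n([1, 0, 1, 0], [0.9, 0.8, 0.2, 0.1]) == 0.5

    def test_all_negative_error(self):
        with pytest.raises(ValueError):
            ppv_top_n([0, 0], [0.5, 0.6])

    def test_stable_under_score_permutation(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 30)
        labels[0] = 1
        scores = rng.random(30)
        order = np.argsort(-scores, kind="stable")
        n_pos = labels.sum()
        expected = labels[order[:n_pos]].sum() / n_pos
        assert ppv_top_n(labels, scores) == pytest.approx(expected)


class TestPrecisionRecallScan:
    ranks = np.array([0.5, 0.8, 2.0, 5.0, 60.0])
    labels = np.array([1, 0, 1, 0, 1])

    def test_three_threshold_toy(self):
        rows = precision_recall_scan(self.ranks, self.labels, [1.0, 5.0, 100.0])
        assert rows[0]["precision"] == pytest.approx(0.5)  # 1 of {0.5, 0.8}
        assert rows[0]["recall"] == pytest.approx(1 / 3)
        assert rows[1]["precision"] == pytest.approx(0.5)  # 2 of 4
        assert rows[2]["recall"] == pytest.approx(1.0)

    def test_threshold_below_all_flags_nan(self, caplog):
        with caplog.at_level("WARNING"):
            rows = precision_recall_scan(self.ranks, self.labels, [0.1])
        assert np.isnan(rows[0]["precision"])
        assert rows[0]["n_predicted"] == 0

    def test_empty_threshold_list(self):
        with pytest.raises(ValueError):
            precision_recall_scan(self.ranks, self.labels, [])


class TestBootstrap:
    ref = np.sin(np.linspace(0, 6, 60))

    def test_identical_methods_give_half(self):
        a = self.ref + 0.1
        assert bootstrap_compare_scc(a, a, self.ref, iters=200, seed=0) == pytest.approx(0.5)

    def test_anti_reference_loses(self):
        p = bootstrap_compare_scc(self.ref, -self.ref, self.ref, iters=300, seed=0)
        assert p < 0.01

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(60), rng.random(60)
        p1 = bootstrap_compare_scc(a, b, self.ref, iters=200, seed=3)
        p2 = bootstrap_compare_scc(a, b, self.ref, iters=200, seed=3)
        assert p1 == p2

    def test_complementarity(self):
        """p(A beats B) + p(B beats A) = 1 under the half-tie rule."""
        rng = np.random.default_rng(9)
        a = self.ref + rng.normal(0, 0.3, 60)
        b = self.ref + rng.normal(0, 0.3, 60)
        p_ab = bootstrap_compare_scc(a, b, self.ref, iters=500, seed=17)
        p_ba = bootstrap_compare_scc(b, a, self.ref, iters=500, seed=17)
        assert p_ab + p_ba == pytest.approx(1.0)


class TestKlLogo:
    def test_uniform_cores_zero_information(self):
        from mhc2deconv.datamodel import ALPHABET

        cores = [aa * 9 for aa in ALPHABET]  # every column flat
        logo = kl_logo(cores, pseudocount_beta=0.0)
        np.testing.assert_allclose(logo.information, 0.0, atol=1e-12)
        np.testing.assert_allclose(logo.heights, 0.0, atol=1e-12)

    def test_fixed_column_full_information(self):
        logo = kl_logo(["A" * 9] * 10, pseudocount_beta=0.0)
        assert logo.information[0] == pytest.approx(np.log2(20))

    def test_heights_sum_to_information(self):
        rng = np.random.default_rng(4)
        from mhc2deconv.datamodel import ALPHABET

        cores = ["".join(ALPHABET[i] for i in rng.integers(0, 20, 9)) for _ in range(30)]
        logo = kl_logo(cores)
        np.testing.assert_allclose(logo.heights.sum(axis=1), logo.information)

    def test_information_nonnegative(self):
        rng = np.random.default_rng(8)
        from mhc2deconv.datamodel import ALPHABET

        cores = ["".join(ALPHABET[i] for i in rng.integers(0, 5, 9)) for _ in range(20)]
        logo = kl_logo(cores)
        assert np.all(logo.information >= 0)

    def test_empty_core_set_error(self):
        with pytest.raises(ValueError):
            kl_logo([])

    def test_wrong_core_length_error(self):
        with pytest.raises(ValueError):
            kl_logo(["ACDEFGHI"])  # 8-mer


class TestAaFrequencyPcc:
    def test_identical_pools(self):
        pools = {"AL1": ["ACDEFGHIKLMNP"] * 5}
        assert aa_frequency_pcc(pools, pools, n_per_allele=5, seed=0) == pytest.approx(1.0)

    def test_disjoint_single_letter_pools_negative(self):
        a = {"AL1": ["A" * 13] * 10}
        c = {"AL1": ["C" * 13] * 10}
        assert aa_frequency_pcc(a, c, n_per_allele=10, seed=0) < 0

    def test_small_pool_warns_and_uses_all(self, caplog):
        a = {"AL1": ["ACDEFGHIKLMNP"] * 3}
        with caplog.at_level("WARNING"):
            aa_frequency_pcc(a, a, n_per_allele=500, seed=0)
        assert any("only 3" in m for m in caplog.messages)

    def test_seeded_sampling_reproducible(self):
        rng = np.random.default_rng(1)
        from mhc2deconv.datamodel import ALPHABET

        pool = {
            "AL1": ["".join(ALPHABET[i] for i in rng.integers(0, 20, 15)) for _ in range(50)]
        }
        other = {
            "AL1": ["".join(ALPHABET[i] for i in rng.integers(0, 20, 15)) for _ in range(50)]
        }
        r1 = aa_frequency_pcc(pool, other, n_per_allele=20, seed=5)
        r2 = aa_frequency_pcc(pool, other, n_per_allele=20, seed=5)
        assert r1 == r2


class TestElispot:
    def test_positive_call(self):
        # control mean 10, sd 5 -> threshold 30; both replicates exceed it
        delta, positive = elispot_call([45, 40], [5, 10, 15])
        assert delta == pytest.approx(32.5)
        assert positive

    def test_one_replicate_below_threshold(self):
        _, positive = elispot_call([45, 25], [5, 10, 15])
        assert not positive

    def test_replicates_at_control_mean(self):
        delta, positive = elispot_call([10, 10], [5, 10, 15])
        assert delta == 0.0
        assert not positive

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            elispot_call([45], [5, 10, 15])
        with pytest.raises(ValueError):
            elispot_call([45, 40], [10])
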