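"""Ground-truthed synthetic data generators."""

import numpy as np
import pytest

from mhc2deconv import simulate as sim


class TestGenerateMotif:
    def test_deterministic_under_seed(self):
        a = sim.generate_motif(5)
        b = sim.generate_motif(5)
        np.testing.assert_array_equal(a.pwm, b.pwm)

    def test_rows_are_distributions(self):
        motif = sim.generate_motif(1)
        np.testing.assert_allclose(motif.pwm.sum(axis=1), 1.0)

    def test_anchor_concentration(self):
        motif = sim.generate_motif(2)
        for p in (1, 4, 6, 9):
            assert motif.pwm[p - 1].max() >= 0.5

    def test_large_concentration_flattens_nonanchors(self):
        motif = sim.generate_motif(3, concentration=1e5)
        nonanchors = [p for p in range(9) if (p + 1) not in motif.anchors]
        for p in nonanchors:
            np.testing.assert_allclose(motif.pwm[p], 1 / 20, atol=0.01)

    def test_invalid_concentration(self):
        with pytest.raises(ValueError):
            sim.generate_motif(1, concentration=0)

    def test_invalid_anchor(self):
        with pytest.raises(ValueError):
            sim.generate_motif(1, anchors=(0, 4))

    def test_independent_seeds_give_uncorrelated_anchors(self):
        """Anchor columns from different seeds are essentially unrelated."""
        rows = []
        for pair in range(20):
            a = sim.generate_motif(100 + pair)
            b = sim.generate_motif(200 + pair)
            anchors = [p - 1 for p in a.anchors]
            rows.append(
                np.corrcoef(a.pwm[anchors].ravel(), b.pwm[anchors].ravel())[0, 1]
            )
        assert np.mean(rows) < 0.5

    def test_disjoint_motif_set(self):
        motifs = sim.generate_disjoint_motifs(3, ["A1", "A2", "A3", "A4"])
        for p in (1, 4, 6, 9):
            preferred = [m.pwm[p - 1].argmax() for m in motifs]
            assert len(set(preferred)) == 4
        for m in motifs:
            own = [int(m.pwm[p - 1].argmax()) for p in (1, 4, 6, 9)]
            assert len(set(own)) == 4


class TestGenerateMaDonor:
    def test_degenerate_weights(self, proteome):
        motifs = sim.generate_disjoint_motifs(1, ["AL1", "AL2"])
        donor, truth = sim.generate_ma_donor(
            motifs, np.array([1.0, 0.0]), 30, proteome, seed=2
        )
        assert set(truth.positive_alleles) == {"AL1"}

    def test_truth_covers_every_positive(self, proteome):
        motifs = sim.generate_disjoint_motifs(1, ["AL1", "AL2"])
        donor, truth = sim.generate_ma_donor(
            motifs, np.array([0.5, 0.5]), 40, proteome, seed=3
        )
        assert len(truth.positive_alleles) == len(donor.positives)
        assert len(truth.core_offsets) == len(donor.positives)
        for rec, offset in zip(donor.positives, truth.core_offsets):
            assert 0 <= offset <= len(rec.sequence) - 9

    def test_planted_cores_score_high_under_own_pssm(self, proteome):
        """Positives outscore random proteome peptides under the generating
        motif's log-odds (the independent oracle), AUC > 0.95."""
        from mhc2deconv.evaluation import auc01
        from mhc2deconv.profiles import sample_background_peptides

        motif = sim.generate_motif(9, allele="AL1")
        donor, truth = sim.generate_ma_donor(
            [motif], np.array([1.0]), 500, proteome, seed=4
        )
        background = sample_background_peptides(proteome, 500, seed=5)
        scores = [motif.best_log_odds(r.sequence)[0] for r in donor.positives] + [
            motif.best_log_odds(r.sequence)[0] for r in background
        ]
        labels = [1] * 500 + [0] * 500
        # full ROC area, not just the early part: global separability
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, scores) > 0.95

    def test_allele_counts_near_multinomial_expectation(self, proteome):
        motifs = sim.generate_disjoint_motifs(2, ["AL1", "AL2", "AL3"])
        w = np.array([0.6, 0.3, 0.1])
        n = 600
        _, truth = sim.generate_ma_donor(motifs, w, n, proteome, seed=6)
        counts = np.array(
            [truth.positive_alleles.count(m.allele) for m in motifs], dtype=float
        )
        sigma = np.sqrt(n * w * (1 - w))
        assert np.all(np.abs(counts - n * w) <= 3 * sigma)

    def test_default_weights_are_drb1_skewed(self):
        w = sim.default_allele_weights(["DRB1_A", "DRB1_B", "DRB3_C", "DRB5_D"])
        assert w[0] + w[1] == pytest.approx(0.9)
        assert w.sum() == pytest.approx(1.0)

    def test_negative_count_follows_augmentation_rule(self, proteome):
        motifs = sim.generate_disjoint_motifs(1, ["AL1"])
        donor, _ = sim.generate_ma_donor(motifs, np.array([1.0]), 100, proteome, seed=7)
        lengths, counts = np.unique(
            [len(r.sequence) for r in donor.positives], return_counts=True
        )
        assert len(donor.negatives) == 9 * 5 * counts.max()

    def test_minimum_positive_count(self, proteome):
        motifs = sim.generate_disjoint_motifs(1, ["AL1"])
        with pytest.raises(ValueError):
            sim.generate_ma_donor(motifs, np.array([1.0]), 5, proteome, seed=1)


class TestGenerateSaBa:
    def test_noise_free_targets_monotone_in_log_odds(self, motif, proteome):
        records = sim.generate_sa_ba(motif, 200, noise_sd=0.0, seed=1, proteome=proteome)
        lods = np.array([motif.best_log_odds(r.sequence)[0] for r in records])
        targets = np.array([r.target for r in records])
        order = np.argsort(lods)
        # strictly monotone transform up to clipping
        diffs = np.diff(targets[order])
        assert np.all(diffs >= -1e-12)

    def test_rank_correlation_with_motif_score(self, motif, proteome):
        from scipy import stats

        records = sim.generate_sa_ba(motif, 500, noise_sd=0.1, seed=2, proteome=proteome)
        lods = [motif.best_log_odds(r.sequence)[0] for r in records]
        targets = [r.target for r in records]
        rho, _ = stats.spearmanr(lods, targets)
        assert rho >= 0.9

    def test_records_are_ba_without_context(self, motif, proteome):
        records = sim.generate_sa_ba(motif, 20, seed=3, proteome=proteome)
        assert all(r.source_kind == "BA" for r in records)
        assert all(r.context is None for r in records)
        assert all(r.allele == motif.allele for r in records)

    def test_seeded_reproducibility(self, motif, proteome):
        a = sim.generate_sa_ba(motif, 50, seed=4, proteome=proteome)
        b = sim.generate_sa_ba(motif, 50, seed=4, proteome=proteome)
        assert [(r.sequence, r.target) for r in a] == [(r.sequence, r.target) for r in b]

    def test_negative_noise_rejected(self, motif, proteome):
        with pytest.raises(ValueError):
            sim.generate_sa_ba(motif, 10, noise_sd=-0.1, seed=1, proteome=proteome)


class TestGenerateDrugProtein:
    def test_no_regions_is_pure_random(self):
        protein, truth = sim.generate_drug_protein([], n_regions=0, length=100, seed=1)
        assert len(protein) == 100
        assert truth.regions == []

    def test_truth_intervals_inside_protein(self):
        motifs = sim.generate_disjoint_motifs(2, ["AL1", "AL2"])
        protein, truth = sim.generate_drug_protein(motifs, n_regions=4, length=150, seed=2)
        assert len(truth.regions) == 4
        for start, end in truth.regions:
            assert 1 <= start <= end <= 150
            assert end - start + 1 == 9

    def test_planted_regions_do_not_overlap(self):
        motifs = sim.generate_disjoint_motifs(3, ["AL1", "AL2"])
        _, truth = sim.generate_drug_protein(motifs, n_regions=5, length=200, seed=3)
        spans = sorted(truth.regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_length_guard(self):
        motifs = sim.generate_disjoint_motifs(1, ["AL1"])
        with pytest.raises(ValueError):
            sim.generate_drug_protein(motifs, n_regions=5, length=60, seed=1)

    def test_planted_cores_beat_background_under_pssm_oracle(self):
        """Log-odds of the planted windows exceed the protein's median
        window score for their generating motif."""
        motifs = sim.generate_disjoint_motifs(4, ["AL1", "AL2"])
        protein, truth = sim.generate_drug_protein(motifs, n_regions=4, length=200, seed=5)
        for i, (start, end) in enumerate(truth.regions):
            motif = motifs[i % len(motifs)]
            planted = motif.log_odds(protein.sequence[start - 1 : end])
            window_scores = [
                motif.log_odds(protein.sequence[j : j + 9])
                for j in range(len(protein) - 8)
            ]
            assert planted > np.median(window_scores)


class TestDeconvolutionAccuracy:
    def _donor(self, proteome, annotations=None):
        motifs = sim.generate_disjoint_motifs(1, ["AL1", "AL2"])
        donor, truth = sim.generate_ma_donor(
            motifs, np.array([0.5, 0.5]), 30, proteome, seed=8
        )
        donor.annotations_pos = annotations or list(truth.positive_alleles)
        donor.annotations_neg = ["AL1"] * len(donor.negatives)
        return donor, truth

    def test_all_correct(self, proteome):
        donor, truth = self._donor(proteome)
        assert sim.deconvolution_accuracy(truth, donor) == 1.0

    def test_missing_annotation_error(self, proteome):
        donor, truth = self._donor(proteome)
        donor.annotations_pos = None
        with pytest.raises(ValueError):
            sim.deconvolution_accuracy(truth, donor)

    def test_random_assignment_near_chance(self, proteome):
        motifs = sim.generate_disjoint_motifs(1, ["A1", "A2", "A3", "A4"])
        donor, truth = sim.generate_ma_donor(
            motifs, np.full(4, 0.25), 1000, proteome, seed=9
        )
        rng = np.random.default_rng(0)
        donor.annotations_pos = [
            donor.allele_names[i] for i in rng.integers(0, 4, len(donor.positives))
        ]
        donor.annotations_neg = []
        donor.annotations_neg = None
        acc = sim.deconvolution_accuracy(truth, donor)
        assert acc == pytest.approx(0.25, abs=0.05)

    def test_invariant_to_peptide_order(self, proteome):
        donor, truth = self._donor(proteome)
        acc = sim.deconvolution_accuracy(truth, donor)
        order = np.random.default_rng(1).permutation(len(donor.positives))
        donor.positives = [donor.positives[i] for i in order]
        donor.annotations_pos = [donor.annotations_pos[i] for i in order]
        truth.positive_alleles = [truth.positive_alleles[i] for i in order]
        truth.core_offsets = [truth.core_offsets[i] for i in order]
        assert sim.deconvolution_accuracy(truth, donor) == acc


def test_pseudo_sequences_distinct_and_stable():
    names = ["DRB1_A", "DRB1_B", "DRB3_C", "DRB5_D", "DRB4_E"]
    seqs = [sim.pseudo_sequence_for(n) for n in names]
    assert len(set(seqs)) == len(names)
    assert all(len(s) == 34 for s in seqs)
    assert seqs == [sim.pseudo_sequence_for(n) for n in names]


def test_length_distribution_peaks_at_15():
    dist = sim.triangular_length_distribution()
    assert max(dist, key=dist.get) in (15, 16, 17)
    assert dist[15] == pytest.approx(0.2, abs=0.05)
    assert sum(dist.values()) == pytest.approx(1.0)
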