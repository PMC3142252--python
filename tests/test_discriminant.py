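import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from xprio.discriminant import (
    CLASSES,
    CvResult,
    FeatureMatrix,
    build_feature_matrix,
    combined_report,
    count_occurrences,
    cross_predict,
    loocv,
    loocv_posteriors,
    sweep_tau,
    train_lda,
)
from xprio.genome import DISEASE, NON_DISEASE, Contig, GeneRecord, build_contigs


def gaussian_fm(rng, n_per_class=15, p=4, separation=6.0):
    """Two Gaussian clouds along the first axis; counts clipped at zero."""
    Xd = rng.normal(separation, 1.0, size=(n_per_class, p))
    Xn = rng.normal(0.0, 1.0, size=(n_per_class, p))
    X = np.clip(np.vstack([Xd, Xn]), 0, None)
    ids = [f"g{i}" for i in range(2 * n_per_class)]
    labels = [DISEASE] * n_per_class + [NON_DISEASE] * n_per_class
    return FeatureMatrix(ids, labels, [f"f{j}" for j in range(p)], X)


def poisson_fm(rng, n_disease, n_non, p=3, rate_d=4.0, rate_n=0.2):
    X = np.vstack(
        [
            rng.poisson(rate_d, size=(n_disease, p)),
            rng.poisson(rate_n, size=(n_non, p)),
        ]
    ).astype(float)
    ids = [f"g{i}" for i in range(n_disease + n_non)]
    labels = [DISEASE] * n_disease + [NON_DISEASE] * n_non
    return FeatureMatrix(ids, labels, [f"f{j}" for j in range(p)], X)


class TestCountOccurrences:
    def test_overlapping_occurrences(self):
        # AA occurs at 3 overlapping offsets; its revcomp TT is absent
        assert count_occurrences("AAAA", "AA") == 3

    def test_revcomp_counted(self):
        assert count_occurrences("ACGGT", "ACCGT") == 1  # matches via revcomp

    def test_palindrome_not_double_counted(self):
        assert count_occurrences("ACGT", "ACGT") == 1


class TestBuildFeatureMatrix:
    def test_planted_counts_from_ground_truth(self, small_dataset):
        seqs = small_dataset.sequences
        motif = small_dataset.config.planted_motifs[0][0]
        genes = [g for g in small_dataset.genes]
        contigs, _ = build_contigs(genes, 5, {"chrS": len(seqs["chrS"])})
        fm, excluded = build_feature_matrix(genes, contigs, [motif], seqs)
        plants = {}
        for m, gid, pos in small_dataset.ground_truth.motif_positions:
            plants[gid] = plants.get(gid, 0) + 1
        for gid, row in zip(fm.gene_ids, fm.counts):
            assert row[0] >= plants.get(gid, 0)

    def test_absent_oligomer_zero_column_retained(self, small_dataset):
        seqs = small_dataset.sequences
        genes = small_dataset.genes[:4]
        contigs, _ = build_contigs(genes, 2, {"chrS": len(seqs["chrS"])})
        fm, _ = build_feature_matrix(genes, contigs, ["ACGGTCACGTTA", "A" * 30], seqs)
        assert "A" * 30 in fm.features
        assert fm.counts[:, 1].sum() == 0

    def test_gene_without_contig_excluded(self):
        g1 = GeneRecord("a", "c", "+", 5_000, 4_000, DISEASE)
        g2 = GeneRecord("b", "c", "+", 9_000, 8_000, NON_DISEASE)
        contig = Contig("c", 2_000, 4_000, DISEASE, ["a"])
        fm, excluded = build_feature_matrix([g1, g2], [contig], ["ACGT"], {"c": "ACGT" * 4_000})
        assert fm.gene_ids == ["a"]
        assert excluded == [("b", "no surviving contig")]

    def test_merged_contig_counts_shared(self):
        g1 = GeneRecord("a", "c", "+", 5_000, 4_000, DISEASE)
        g2 = GeneRecord("b", "c", "+", 6_000, 5_500, DISEASE)
        contig = Contig("c", 0, 4_000, DISEASE, ["a", "b"])
        fm, _ = build_feature_matrix([g1, g2], [contig], ["ACGT"], {"c": "ACGT" * 2_000})
        assert fm.counts[0, 0] == fm.counts[1, 0] > 0

    def test_empty_oligomers_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_feature_matrix([], [], [], {})


class TestTrainLda:
    def test_separable_resubstitution_perfect(self):
        rng = np.random.default_rng(0)
        fm = gaussian_fm(rng)
        model = train_lda(fm, tau=0.5)
        assert model.predict(fm.counts) == fm.labels

    def test_posteriors_valid_and_complementary(self):
        rng = np.random.default_rng(1)
        fm = gaussian_fm(rng, separation=1.0)
        model = train_lda(fm, tau=0.5)
        post = model.posterior_disease(fm.counts)
        assert np.all((post >= 0) & (post <= 1))
        # softmax construction: P(disease) + P(non_disease) = 1 identically
        assert np.all(np.isfinite(post))

    def test_small_class_errors(self):
        fm = FeatureMatrix(
            ["a", "b", "c"], [DISEASE, NON_DISEASE, NON_DISEASE], ["f"],
            np.array([[1.0], [0.0], [2.0]]),
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            train_lda(fm)

    def test_zero_variance_errors(self):
        fm = FeatureMatrix(
            ["a", "b", "c", "d"], [DISEASE, DISEASE, NON_DISEASE, NON_DISEASE],
            ["f"], np.ones((4, 1)),
        )
        with pytest.raises(ValueError, match="zero-variance"):
            train_lda(fm)

    def test_duplicating_samples_preserves_class_means(self):
        rng = np.random.default_rng(2)
        fm = gaussian_fm(rng, n_per_class=8)
        doubled = FeatureMatrix(
            fm.gene_ids + [g + "_dup" for g in fm.gene_ids],
            fm.labels + fm.labels,
            fm.features,
            np.vstack([fm.counts, fm.counts]),
        )
        m1 = train_lda(fm, variance_kept=1.0)
        m2 = train_lda(doubled, variance_kept=1.0)
        # compare means in the original feature space (basis may differ in sign)
        for cls in CLASSES:
            back1 = m1.class_means[cls] @ m1.components + m1.center
            back2 = m2.class_means[cls] @ m2.components + m2.center
            assert np.allclose(back1, back2, atol=1e-8)

    def test_closed_form_boundary_at_one(self):
        # equal covariances, means (0,0) and (2,0), equal priors -> boundary x1 = 1
        offsets = np.array(
            [[0.5, 0.0], [-0.5, 0.0], [0.0, 0.5], [0.0, -0.5]] * 3
        )
        Xd = np.array([2.0, 0.0]) + offsets
        Xn = np.array([0.0, 0.0]) + offsets
        fm = FeatureMatrix(
            [f"g{i}" for i in range(24)],
            [DISEASE] * 12 + [NON_DISEASE] * 12,
            ["x1", "x2"],
            np.vstack([Xd, Xn]),
        )
        model = train_lda(fm, tau=0.5, variance_kept=1.0)
        probe = np.array([[1.0, 0.3], [1.0, -1.5], [1.0, 5.0]])
        assert np.allclose(model.posterior_disease(probe), 0.5, atol=1e-6)
        assert model.predict(np.array([[1.2, 0.0]])) == [DISEASE]
        assert model.predict(np.array([[0.8, 0.0]])) == [NON_DISEASE]

    def test_tau_out_of_range(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="tau"):
            train_lda(gaussian_fm(rng), tau=1.5)


class TestLoocv:
    def test_separable_perfect(self):
        rng = np.random.default_rng(4)
        cv = loocv(gaussian_fm(rng, separation=8.0), tau=0.5)
        assert cv.success_disease == 100.0
        assert cv.success_non_disease == 100.0

    def test_chance_level_on_permuted_labels(self):
        # no-signal data: balanced accuracy hovers around 50%
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.poisson(2.0, size=(30, 6)).astype(float)
            labels = [DISEASE] * 15 + [NON_DISEASE] * 15
            perm = rng.permutation(30)
            fm = FeatureMatrix(
                [f"g{i}" for i in range(30)], [labels[i] for i in perm],
                [f"f{j}" for j in range(6)], X,
            )
            accs.append(loocv(fm, tau=0.5).balanced_accuracy)
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_requires_three_genes(self):
        fm = FeatureMatrix(["a", "b"], [DISEASE, NON_DISEASE], ["f"], np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            loocv(fm)

    def test_invariant_to_gene_and_feature_order(self):
        rng = np.random.default_rng(6)
        fm = poisson_fm(rng, 8, 12)
        cv = loocv(fm, tau=0.5)
        gperm = rng.permutation(len(fm.gene_ids))
        fperm = rng.permutation(len(fm.features))
        fm2 = FeatureMatrix(
            [fm.gene_ids[i] for i in gperm],
            [fm.labels[i] for i in gperm],
            [fm.features[j] for j in fperm],
            fm.counts[np.ix_(gperm, fperm)],
        )
        cv2 = loocv(fm2, tau=0.5)
        assert cv.success_disease == pytest.approx(cv2.success_disease)
        assert cv.success_non_disease == pytest.approx(cv2.success_non_disease)

    def test_signal_recovery_monotone_in_effect_size(self):
        # LOOCV balanced accuracy tracks the planted effect size
        levels = [0.0, 0.5, 1.0, 2.0, 4.0]
        means = []
        for rate in levels:
            accs = []
            for seed in range(10):
                rng = np.random.default_rng(1_000 + seed)
                fm = poisson_fm(rng, 10, 14, rate_d=0.2 + rate, rate_n=0.2)
                accs.append(loocv(fm, tau=0.5).balanced_accuracy)
            means.append(np.mean(accs))
        rho, _ = spearmanr(levels, means)
        assert rho > 0.8


class TestSweepTau:
    def test_extreme_taus(self):
        rng = np.random.default_rng(7)
        fm = poisson_fm(rng, 10, 10, rate_d=1.0, rate_n=0.8)  # weak signal, moderate posteriors
        results, _ = sweep_tau(fm, [1e-9, 1 - 1e-9])
        low, high = results[0], results[-1]
        assert low.success_disease == 100.0
        assert high.success_non_disease == 100.0

    def test_disease_success_monotone_nonincreasing_in_tau(self):
        rng = np.random.default_rng(8)
        fm = poisson_fm(rng, 8, 20, rate_d=1.0, rate_n=0.5)
        results, _ = sweep_tau(fm, [0.1 * i for i in range(1, 10)])
        succ = [r.success_disease for r in results]
        assert all(a >= b - 1e-9 for a, b in zip(succ, succ[1:]))
        nsucc = [r.success_non_disease for r in results]
        assert all(a <= b + 1e-9 for a, b in zip(nsucc, nsucc[1:]))

    def test_optimum_tie_goes_to_larger_tau(self):
        rng = np.random.default_rng(9)
        fm = gaussian_fm(rng, separation=9.0)
        results, best = sweep_tau(fm, [0.2, 0.5, 0.8])
        perfect = [r.tau for r in results if r.balanced_accuracy == 100.0]
        assert best.tau == max(perfect)

    def test_empty_grid_errors(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="empty"):
            sweep_tau(gaussian_fm(rng), [])


class TestCrossPredict:
    def test_same_set_equals_resubstitution(self):
        rng = np.random.default_rng(11)
        fm = gaussian_fm(rng)
        model = train_lda(fm, tau=0.5)
        cv = cross_predict(model, fm)
        resub = model.predict(fm.counts)
        assert [cv.per_gene[g][1] for g in fm.gene_ids] == resub

    def test_feature_mismatch_errors(self):
        rng = np.random.default_rng(12)
        fm = gaussian_fm(rng)
        model = train_lda(fm)
        other = FeatureMatrix(fm.gene_ids, fm.labels, ["alien"] * len(fm.features), fm.counts)
        with pytest.raises(ValueError, match="re-featurize"):
            cross_predict(model, other)

    def test_zero_count_foreign_set_gets_majority_class(self):
        rng = np.random.default_rng(13)
        fm = poisson_fm(rng, 5, 20, rate_d=6.0, rate_n=0.1)  # non-disease majority near zero
        model = train_lda(fm, tau=0.5)
        foreign = FeatureMatrix(
            ["x1", "x2", "x3"], [DISEASE, NON_DISEASE, NON_DISEASE],
            fm.features, np.zeros((3, len(fm.features))),
        )
        cv = cross_predict(model, foreign)
        assert {cv.per_gene[g][1] for g in foreign.gene_ids} == {NON_DISEASE}

    def test_disjoint_strata_degrade_cross_prediction(self):
        rng = np.random.default_rng(14)
        # stratum A's features carry signal only in stratum A
        fm_a = poisson_fm(rng, 12, 18, rate_d=5.0, rate_n=0.1)
        within = loocv(fm_a, tau=0.5).balanced_accuracy
        # stratum B genes have no counts on A's oligomers (disjoint planted motifs)
        nb = 24
        fm_b = FeatureMatrix(
            [f"b{i}" for i in range(nb)],
            [DISEASE] * 8 + [NON_DISEASE] * 16,
            fm_a.features,
            rng.poisson(0.1, size=(nb, len(fm_a.features))).astype(float),
        )
        model = train_lda(fm_a, tau=0.5)
        cross = cross_predict(model, fm_b).balanced_accuracy
        assert within - cross >= 20.0


class TestCombinedReport:
    def _ranking(self):
        return pd.DataFrame(
            {"gene_id": ["MAG", "KNOWN", "NOTSS", "LOW"], "score": [12, 15, 11, 3]}
        )

    def test_candidate_flag_two_distance_pattern(self):
        preds = {50: {"MAG": "NX", "KNOWN": "X"}, 100: {"MAG": "X", "KNOWN": "X"}}
        preds[10] = {"MAG": "X", "KNOWN": "X"}
        report = combined_report(
            self._ranking(), preds, {"MAG": 100_000, "KNOWN": 100_000},
            known={"KNOWN"}, min_score=10,
        )
        row = report[report.gene_id == "MAG"].iloc[0]
        assert row["candidate"]
        assert row["call_50kb"] == "NX" and row["call_100kb"] == "X"

    def test_no_tss_excluded_with_reason(self):
        preds = {50: {"MAG": "X"}, 100: {"MAG": "X"}}
        report = combined_report(self._ranking(), preds, {"MAG": 100_000}, known=set())
        row = report[report.gene_id == "NOTSS"].iloc[0]
        assert row["excluded"] == "no annotated TSS"

    def test_known_gene_predicted_x_correctly_classified(self):
        preds = {50: {"KNOWN": "X"}, 100: {"KNOWN": "X"}}
        report = combined_report(self._ranking(), preds, {"KNOWN": 100_000}, known={"KNOWN"})
        row = report[report.gene_id == "KNOWN"].iloc[0]
        assert row["correctly_classified"] is True or row["correctly_classified"] == True  # noqa: E712
        assert not row["candidate"]

    def test_low_scores_dropped(self):
        report = combined_report(self._ranking(), {50: {}}, {}, min_score=10)
        assert "LOW" not in set(report.gene_id)
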