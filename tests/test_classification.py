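"""UAF feature selection and SVM classification."""

import numpy as np
import pytest

from lamorph.classification import (
    per_time_classification,
    svm_evaluate,
    trajectory_attribute_classification,
    uaf_select,
)
from lamorph.core_geometry import ShapePCA
from lamorph.errors import InvalidDesignError
from lamorph.parallel_transport import DeformationPCA
from lamorph.trajectory_analysis import TrajectoryAttributes


def labels(n=20):
    return np.array(["Control"] * n + ["HCM"] * n)


def blobs(rng, n=20, sep=6.0, p=5):
    x0 = rng.standard_normal((n, p))
    x1 = rng.standard_normal((n, p)) + sep / np.sqrt(p)
    return np.vstack([x0, x1])


class TestUAF:
    def test_alpha_one_selects_everything(self, rng):
        X = rng.standard_normal((30, 8))
        sel = uaf_select(X, labels(15), alpha=1.0, n_perm=49)
        assert np.array_equal(sel, np.arange(8))

    def test_planted_feature_found_among_noise(self, rng):
        y = labels(20)
        X = rng.standard_normal((40, 50))
        X[:, 17] += (y == "HCM") * 5.0
        sel = uaf_select(X, y, alpha=0.05, n_perm=199, seed=0)
        assert 17 in sel
        # false selections near the 5% expectation for the 49 null features
        assert len(sel) - 1 <= 10

    def test_null_selection_rate_matches_alpha(self, rng):
        y = labels(15)
        rates = []
        for i in range(60):
            X = rng.standard_normal((30, 40))
            sel = uaf_select(X, y, alpha=0.05, n_perm=99, seed=i)
            rates.append(len(sel) / 40)
        assert 0.02 <= np.mean(rates) <= 0.09

    def test_empty_selection_warns(self, rng):
        X = rng.standard_normal((20, 4))
        with pytest.warns(RuntimeWarning):
            sel = uaf_select(X, labels(10), alpha=1e-6, n_perm=49)
        assert sel.size == 0


class TestSVM:
    def test_separable_blobs_perfect_in_sample(self, rng):
        X = blobs(rng)
        rep = svm_evaluate(X, labels(20), seed=0)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0
        assert rep.loocv_error <= 0.05

    def test_null_features_give_chance_loocv(self, rng):
        errs = []
        for i in range(20):
            X = rng.standard_normal((40, 5))
            errs.append(svm_evaluate(X, labels(20), seed=i).loocv_error)
        assert 0.35 <= np.mean(errs) <= 0.65

    def test_sensitivity_uses_disease_as_positive(self, rng):
        X = blobs(rng, n=15)
        y = labels(15)
        rep = svm_evaluate(X, y, seed=1)
        # flip one HCM subject far into the control blob: sensitivity drops,
        # specificity does not
        X2 = X.copy()
        X2[-1] = X[0]
        rep2 = svm_evaluate(X2, y, seed=1)
        assert rep2.sensitivity < rep.sensitivity or rep2.sensitivity < 1.0
        assert rep2.specificity == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidDesignError):
            svm_evaluate(rng.standard_normal((10, 3)), ["Control"] * 10)


def make_deformation(scores_by_subject, groups):
    """Assemble a minimal DeformationPCA from per-subject (12, p) scores."""
    n_sub = len(scores_by_subject)
    p = scores_by_subject[0].shape[1]
    all_scores = np.concatenate(scores_by_subject)
    eigenvalues = all_scores.var(axis=0, ddof=1)
    vf = eigenvalues / eigenvalues.sum()
    pca = ShapePCA(
        mean_vector=np.zeros(p), eigenvalues=eigenvalues,
        loadings=np.eye(p), scores=all_scores,
        variance_fraction=vf, cumulative_fraction=np.cumsum(vf),
    )
    sids = [f"s{i}" for i in range(n_sub)]
    row_index = {(sid, t): i * 12 + t for i, sid in enumerate(sids)
                 for t in range(12)}
    return DeformationPCA(pca=pca, grand_mean=np.zeros((p // 3 + 1, 3)),
                          subject_ids=sids, groups=list(groups),
                          row_index=row_index)


class TestPerTime:
    def test_accuracy_peaks_at_planted_times(self, rng):
        groups = labels(12)
        scores = []
        for i, g in enumerate(groups):
            s = rng.standard_normal((12, 6))
            if g == "HCM":
                s[2:5, 0] += 4.0  # group signal only at times 3-5 (1-based)
            scores.append(s)
        defo = make_deformation(scores, groups)
        reports = per_time_classification(defo, n_pcs=6, alpha=0.05, seed=0,
                                          uaf_n_perm=99)
        assert len(reports) == 12
        acc = np.array([r.accuracy for r in reports])
        assert np.argmax(acc) in (2, 3, 4)
        assert acc[2:5].mean() > np.delete(acc, [2, 3, 4]).mean()

    def test_identical_groups_hover_near_chance(self, rng):
        groups = labels(10)
        scores = [rng.standard_normal((12, 5)) for _ in groups]
        defo = make_deformation(scores, groups)
        reports = per_time_classification(defo, n_pcs=5, alpha=0.05, seed=1,
                                          uaf_n_perm=99)
        loocv = np.mean([r.loocv_error for r in reports])
        # LOOCV is pessimistically biased above 0.5 on balanced null data
        assert 0.3 <= loocv <= 0.8

    def test_truncation_warns_when_pcs_missing(self, rng):
        groups = labels(8)
        scores = [rng.standard_normal((12, 4)) for _ in groups]
        defo = make_deformation(scores, groups)
        with pytest.warns(RuntimeWarning):
            reports = per_time_classification(defo, n_pcs=50, seed=0,
                                              uaf_n_perm=49)
        assert len(reports) == 12


class TestTrajectoryAttributes:
    @staticmethod
    def attrs_from(pc1, sizes, groups):
        return [
            TrajectoryAttributes(
                shape_scores=np.array([p]), size=s, angle_12=0.0, angle_13=0.0,
                subject_id=f"s{i}", group=g,
            )
            for i, (p, s, g) in enumerate(zip(pc1, sizes, groups))
        ]

    def test_bend_only_difference_favors_shape(self, rng):
        g = labels(15)
        pc1 = rng.standard_normal(30) + (g == "HCM") * 3.0
        sizes = np.abs(rng.standard_normal(30)) + 5.0
        reports = trajectory_attribute_classification(
            self.attrs_from(pc1, sizes, g), seed=0)
        assert reports["shape_pc1"].auc > reports["size"].auc

    def test_amplitude_only_difference_favors_size(self, rng):
        g = labels(15)
        pc1 = rng.standard_normal(30)
        sizes = np.abs(rng.standard_normal(30)) + 5.0 + (g == "HCM") * 4.0
        reports = trajectory_attribute_classification(
            self.attrs_from(pc1, sizes, g), seed=0)
        assert reports["size"].auc > reports["shape_pc1"].auc

    def test_null_attributes_near_chance_auc(self, rng):
        g = labels(15)
        aucs = []
        for i in range(10):
            pc1 = rng.standard_normal(30)
            sizes = np.abs(rng.standard_normal(30)) + 5.0
            reports = trajectory_attribute_classification(
                self.attrs_from(pc1, sizes, g), seed=i)
            aucs += [reports["shape_pc1"].auc, reports["size"].auc]
        assert abs(np.mean(aucs) - 0.5) < 0.2
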