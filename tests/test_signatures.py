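"""Signature derivation, classifier panel, random forest training/prediction."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from sclc_subtyping.quantify import impute_missing
from sclc_subtyping.signatures import (
    classifier_features,
    predict_subtypes,
    subtype_signatures,
    train_classifier,
)

from conftest import make_abundance


def _labelled_matrix(seed=0, n_per=(12, 12, 12), n_prot=60, fc=(4.0, 4.0, 12.0)):
    """Block-structured matrix: first 10 proteins mark each subtype."""
    rng = np.random.default_rng(seed)
    n = sum(n_per)
    labels = np.repeat(np.arange(3), n_per)
    base = rng.lognormal(-8, 0.3, size=(n_prot, n))
    for s in range(3):
        base[s * 10 : (s + 1) * 10, labels == s] *= fc[s]
    return make_abundance(base), labels


class TestSubtypeSignatures:
    def test_constant_protein_excluded(self):
        m, labels = _labelled_matrix()
        m.fot.iloc[30] = 1e-8  # constant across all samples -> FC = 1
        sigs = subtype_signatures(m, labels)
        for s in sigs.values():
            assert "p30" not in s.entries.index

    def test_planted_marker_retained_for_its_subtype(self):
        m, labels = _labelled_matrix(fc=(4.0, 4.0, 12.0))
        sigs = subtype_signatures(m, labels, {0: 3.0, 1: 3.0, 2: 10.0})
        planted_s2 = {f"p{i}" for i in range(20, 30)}
        # sampling noise can push an observed FC just under the strict
        # threshold, so require most planted markers, and no foreign ones
        assert len(planted_s2 & set(sigs[2].entries.index)) >= 8
        assert {f"p{i}" for i in range(10)} <= set(sigs[0].entries.index)
        assert not planted_s2 & set(sigs[0].entries.index)

    def test_fc_exactly_at_threshold_excluded(self):
        # two groups of 3; protein 0 has exact mean ratio 2 between groups
        vals = np.ones((5, 6)) * 1e-6
        vals[0, :3] = 2e-6  # mean in = 2e-6, mean out = 1e-6 -> FC exactly 2
        vals[1, :3] = 9e-6
        m = make_abundance(vals)
        labels = np.array([0, 0, 0, 1, 1, 1])
        sigs = subtype_signatures(m, labels, {0: 2.0, 1: 2.0}, alpha=0.2)
        assert "p0" not in sigs[0].entries.index
        assert "p1" in sigs[0].entries.index

    def test_small_subtype_rejected(self):
        m, labels = _labelled_matrix()
        labels = labels.copy()
        labels[labels == 2] = 1
        labels[0] = 2  # singleton subtype
        with pytest.raises(ValueError, match="2"):
            subtype_signatures(m, labels)

    def test_signature_sets_disjoint(self):
        m, labels = _labelled_matrix(seed=5)
        sigs = subtype_signatures(m, labels, {0: 3.0, 1: 3.0, 2: 3.0})
        ids = [set(s.entries.index) for s in sigs.values()]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_statistics_match_direct_computation(self):
        m, labels = _labelled_matrix(seed=2)
        sigs = subtype_signatures(m, labels)
        fot = m.fot.to_numpy()
        mask = labels == 0
        entries = sigs[0].entries
        for pid in list(entries.index)[:5]:
            i = m.fot.index.get_loc(pid)
            fc = fot[i, mask].mean() / fot[i, ~mask].mean()
            p = sps.mannwhitneyu(fot[i, mask], fot[i, ~mask],
                                 alternative="two-sided").pvalue
            assert entries.loc[pid, "fold_change"] == pytest.approx(fc, rel=1e-12)
            assert entries.loc[pid, "p_value"] == pytest.approx(p, rel=1e-9)


class TestClassifierFeatures:
    def test_single_informative_protein_found(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(-8, 0.05, size=(20, 30))
        labels = np.repeat([0, 1, 2], 10)
        vals[7, labels == 1] *= 5.0  # only informative protein
        m = make_abundance(vals)
        got = classifier_features(m, labels, {f"p{i}" for i in range(20)})
        assert got == ["p7"]

    def test_alpha_zero_empty(self):
        m, labels = _labelled_matrix()
        got = classifier_features(m, labels, set(m.protein_ids), alpha=0.0)
        assert got == []

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_deterministic_ordering(self):
        m, labels = _labelled_matrix(seed=3)
        a = classifier_features(m, labels, set(m.protein_ids))
        b = classifier_features(m, labels, set(m.protein_ids))
        assert a == b and len(a) > 0


@pytest.fixture(scope="module")
def trained():
    m, labels = _labelled_matrix(seed=4, n_per=(14, 14, 14))
    panel = classifier_features(m, labels, set(m.protein_ids))
    model = train_classifier(m, labels, panel, seed=7)
    return m, labels, panel, model


class TestTrainPredict:

    def test_separable_cohort_high_cv_accuracy(self, trained):
        _, _, _, model = trained
        assert model.cv_accuracy >= 0.95

    def test_folds_balanced_and_cover_all(self, trained):
        _, labels, _, model = trained
        counts = np.bincount(model.fold_assignments)
        assert counts.sum() == len(labels)
        assert counts.max() - counts.min() <= 1

    def test_same_seed_reproducible(self, trained):
        m, labels, panel, model = trained
        again = train_classifier(m, labels, panel, seed=7)
        assert again.cv_accuracy == model.cv_accuracy
        np.testing.assert_array_equal(again.fold_assignments, model.fold_assignments)

    def test_permuted_labels_near_chance(self):
        m, labels = _labelled_matrix(seed=4, n_per=(14, 14, 14))
        panel = classifier_features(m, labels, set(m.protein_ids))
        rng = np.random.default_rng(0)
        perm = rng.permutation(labels)
        model = train_classifier(m, perm, panel, seed=7)
        assert abs(model.cv_accuracy - 1 / 3) <= 0.15

    def test_resubstitution_at_least_cv(self, trained):
        m, labels, _, model = trained
        preds = predict_subtypes(model, m)
        resub = (preds["predicted"].to_numpy() == labels).mean()
        assert resub >= model.cv_accuracy - 1e-12

    def test_probabilities_sum_to_one(self, trained):
        m, _, _, model = trained
        preds = predict_subtypes(model, m)
        probs = preds.drop(columns="predicted").to_numpy(float)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_feature_filled_by_imputation(self, trained):
        m, labels, panel, model = trained
        m2 = make_abundance(m.fot.drop(index=panel[0]).to_numpy(),
                            protein_ids=[p for p in m.protein_ids if p != panel[0]])
        preds = predict_subtypes(model, m2)
        assert len(preds) == m.fot.shape[1]

    def test_mostly_absent_panel_rejected(self, trained):
        m, labels, panel, model = trained
        keep = [p for p in m.protein_ids if p not in panel[: int(0.8 * len(panel))]]
        m2 = make_abundance(m.fot.loc[keep].to_numpy(), protein_ids=keep)
        with pytest.raises(ValueError, match="not transferable"):
            predict_subtypes(model, m2)

    def test_missing_feature_at_training_rejected(self, trained):
        m, labels, panel, _ = trained
        with pytest.raises(ValueError, match="missing"):
            train_classifier(m, labels, panel + ["nonexistent"], seed=0)
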