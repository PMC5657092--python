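import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepskip.dataset import LabeledDataset, generate_synthetic_benchmark
from pepskip.evaluation import (
    ConfusionCounts,
    compute_metrics,
    cross_validate_matrix,
    jackknife,
    kfold,
    roc_auc,
    tree_sweep,
)
from pepskip.features import featurize_dataset
from pepskip.sequence_io import Peptide

from ._oracles import pairwise_auc

counts_strategy = st.builds(
    ConfusionCounts,
    tp=st.integers(0, 50), tn=st.integers(0, 50),
    fp=st.integers(0, 50), fn=st.integers(0, 50),
)


def tiny_separable_dataset(n_pairs=15):
    """Duplicated, perfectly separable R-rich vs G-rich peptides."""
    peptides, labels = [], []
    for i in range(n_pairs):
        peptides.append(Peptide(f"pos{i}", "RRKKRRKKRR"))
        labels.append(1)
        peptides.append(Peptide(f"neg{i}", "GGSSAAGGSS"))
        labels.append(0)
    return LabeledDataset(peptides=peptides, labels=labels)


class TestComputeMetrics:
    def test_symmetric_counts_give_chance(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=5, fn=5))
        assert m.acc == pytest.approx(50.0)
        assert m.mcc == pytest.approx(0.0)

    def test_hand_derived_values(self):
        m = compute_metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert m.se == pytest.approx(90.0)
        assert m.sp == pytest.approx(80.0)
        assert m.acc == pytest.approx(85.0)
        assert m.mcc == pytest.approx(70 / math.sqrt(9900))

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
        assert m.se == m.sp == m.acc == pytest.approx(100.0)
        assert m.mcc == pytest.approx(1.0)

    def test_degenerate_denominator_flagged(self):
        m = compute_metrics(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert m.mcc == 0.0 and m.mcc_degenerate

    def test_absent_class_reported_not_applicable(self):
        m = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=8, fp=2))
        assert m.se is None
        assert m.sp == pytest.approx(80.0)

    @given(counts_strategy)
    def test_mcc_symmetric_under_class_swap(self, c):
        if c.total == 0:
            return
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        assert compute_metrics(c).mcc == pytest.approx(
            compute_metrics(swapped).mcc)

    @given(counts_strategy)
    def test_mcc_flips_sign_when_predictions_inverted(self, c):
        if c.total == 0:
            return
        inverted = ConfusionCounts(tp=c.fn, fn=c.tp, tn=c.fp, fp=c.tn)
        assert compute_metrics(inverted).mcc == pytest.approx(
            -compute_metrics(c).mcc, abs=1e-12)

    @given(counts_strategy)
    def test_acc_invariant_under_label_renaming(self, c):
        if c.total == 0:
            return
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        assert compute_metrics(c).acc == pytest.approx(
            compute_metrics(swapped).acc)

    def test_bounds(self):
        m = compute_metrics(ConfusionCounts(tp=3, fn=2, tn=4, fp=1))
        assert 0 <= m.se <= 100 and 0 <= m.sp <= 100 and 0 <= m.acc <= 100
        assert -1 <= m.mcc <= 1


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)

    def test_three_quarters(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle(self, rng):
        for n in (5, 12, 27, 50):
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties
            scores = np.round(rng.random(n), 1)
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(pairwise_auc(scores, labels))


class TestCrossValidation:
    def test_jackknife_predicts_every_sample_once(self):
        ds = tiny_separable_dataset(8)
        res = jackknife(ds, t=10, seed=0)
        assert len(res.predictions) == len(ds)
        assert sorted(res.predictions["id"]) == sorted(
            p.id for p in ds.peptides)

    def test_separable_dataset_perfect_jackknife(self):
        ds = tiny_separable_dataset(8)
        res = jackknife(ds, t=10, seed=0)
        assert res.metrics.acc == pytest.approx(100.0)
        assert res.metrics.mcc == pytest.approx(1.0)

    def test_jackknife_equals_full_kfold_bitwise(self):
        ds = generate_synthetic_benchmark(15, 0.5, seed=2)
        jk = jackknife(ds, t=12, seed=5)
        kf = kfold(ds, t=12, folds=len(ds), seed=5)
        assert jk.predictions.equals(kf.predictions)
        assert jk.metrics.counts == kf.metrics.counts
        assert jk.metrics.auc == kf.metrics.auc

    def test_every_sample_held_out_once_in_kfold(self):
        ds = generate_synthetic_benchmark(20, 0.5, seed=3)
        res = kfold(ds, t=10, folds=5, seed=1)
        assert len(res.predictions) == 40
        assert res.predictions["fold"].value_counts().between(7, 9).all()

    def test_stratification_within_one_sample(self):
        ds = generate_synthetic_benchmark(25, 0.5, seed=4)
        res = kfold(ds, t=10, folds=5, seed=2)
        table = res.predictions.groupby("fold")["truth"].agg(["sum", "count"])
        global_ratio = 0.5
        for _, row in table.iterrows():
            expected = row["count"] * global_ratio
            assert abs(row["sum"] - expected) <= 1

    def test_folds_exceeding_samples_rejected(self):
        ds = tiny_separable_dataset(3)
        with pytest.raises(ValueError, match="exceeds"):
            kfold(ds, t=10, folds=7, seed=0)

    def test_seed_determinism(self):
        ds = generate_synthetic_benchmark(12, 0.5, seed=6)
        a = kfold(ds, t=15, folds=4, seed=3)
        b = kfold(ds, t=15, folds=4, seed=3)
        assert a.predictions.equals(b.predictions)


class TestTreeSweep:
    def test_two_value_sweep_shape(self):
        ds = tiny_separable_dataset(6)
        table, best = tree_sweep(ds, t_values=[10, 150], seed=0,
                                 folds=4)
        assert len(table) == 2
        assert set(table.columns) == {"t", "SE", "SP", "ACC", "MCC", "AUC"}

    def test_recommends_smallest_t_on_ties(self):
        ds = tiny_separable_dataset(6)
        table, best = tree_sweep(ds, t_values=[10, 50, 150], seed=0, folds=4)
        # separable data scores 100% ACC at every t; tie-break -> smallest
        assert table["ACC"].nunique() == 1
        assert best == 10

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            tree_sweep(tiny_separable_dataset(4), t_values=[], seed=0)


class TestStability:
    def test_accuracy_stable_across_seeds(self):
        """Repeated evaluation across seeds varies by < 3 ACC points."""
        ds = generate_synthetic_benchmark(40, 0.5, seed=11)
        feats = featurize_dataset(ds.peptides)
        accs = [
            cross_validate_matrix(feats, ds.labels, t=60, folds=5,
                                  seed=s).metrics.acc
            for s in range(5)
        ]
        assert np.std(accs) < 3.0
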