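"""Outlier and cell-count classifiers: contracts, metrics, learning sanity."""

import numpy as np
import pytest

from dropscreen.config import RenderConfig, TrainingConfig
from dropscreen.datasets import make_crop_dataset
from dropscreen.models import (
    HEADS,
    CellCountModel,
    accuracy_report,
    relative_count_error,
    stack_crops,
    train_cellcount_model,
    train_outlier_model,
)

OUTLIER_MIX = {"bubble": 0.08, "edge_cutoff": 0.06, "double_layer_blur": 0.06}


class TestRelativeCountError:
    @pytest.mark.parametrize(
        "true, pred, expected",
        [(1, 2, 100.0), (1, 0, 100.0), (4, 5, 25.0), (4, 3, 25.0), (3, 3, 0.0)],
    )
    def test_worked_examples(self, true, pred, expected):
        assert relative_count_error(true, pred) == pytest.approx(expected)

    def test_true_zero_is_undefined(self):
        assert np.isnan(relative_count_error(0, 2))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            relative_count_error(-1, 0)
        with pytest.raises(ValueError):
            relative_count_error(1, -2)


class TestAccuracyReport:
    def test_perfect_predictions(self):
        pred = np.array([[0, 1, 2, 0], [3, 0, 1, 1]])
        overall, strat = accuracy_report(pred, pred)
        assert all(v == 1.0 for v in overall.values())
        assert (strat.accuracy == 1.0).all()

    def test_nine_of_ten(self):
        true = np.zeros((10, 4), dtype=int)
        pred = true.copy()
        pred[0, 0] = 1  # one miss on the first head
        overall, _ = accuracy_report(pred, true)
        assert overall[HEADS[0]] == pytest.approx(0.9)
        assert overall[HEADS[1]] == 1.0

    def test_stratified_recombines_to_overall(self):
        rng = np.random.default_rng(60)
        true = rng.integers(0, 4, size=(200, 4))
        pred = np.where(rng.uniform(size=(200, 4)) < 0.8, true, (true + 1) % 4)
        overall, strat = accuracy_report(pred, true)
        for k, head in enumerate(HEADS):
            sub = strat[strat["head"] == head]
            recombined = (sub.n * sub.accuracy).sum() / sub.n.sum()
            assert recombined == pytest.approx(overall[head])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            accuracy_report(np.empty((0, 4)), np.empty((0, 4)))


class TestCountModel:
    def test_heldout_accuracy_is_informative(self, trained_count_setup):
        """The reduced-scale model is well above chance on every head."""
        for head, acc in trained_count_setup.overall.items():
            assert acc > 0.6, head

    def test_empty_droplet_predicts_zero(self, trained_count_setup):
        ds = trained_count_setup.dataset
        empties = [i for i, c in enumerate(ds.counts) if c.sum() == 0][:20]
        assert empties
        pred = trained_count_setup.model.predict_counts_array(
            [ds.crops[i] for i in empties]
        )
        assert (pred.sum(axis=1) == 0).mean() >= 0.9

    def test_easy_droplets_predicted_exactly(self, trained_count_setup):
        """Held-out 1-live-effector + 2-live-target crops are read back as
        (2, 0, 1, 0); each head is right most of the time even at the
        fixture's reduced training scale."""
        ds = trained_count_setup.dataset
        want = np.array([2, 0, 1, 0])  # HEADS order
        idx = [
            i for i, c in enumerate(ds.counts) if i >= 2500 and np.array_equal(c, want)
        ]
        assert len(idx) >= 10
        pred = trained_count_setup.model.predict_counts_array([ds.crops[i] for i in idx])
        per_head = (pred == want).mean(axis=0)
        assert (per_head >= 0.75).all()
        assert (pred == want).all(axis=1).mean() >= 0.5

    def test_missing_channel_is_an_error(self, trained_count_setup):
        crop = dict(trained_count_setup.dataset.crops[0].channels)
        del crop["effector_stain"]
        with pytest.raises(ValueError):
            trained_count_setup.model.predict(crop)

    def test_single_class_head_rejected(self):
        ds = make_crop_dataset(30, seed=61)
        counts = ds.counts.copy()
        counts[:, 3] = 0  # dead effectors all zero
        with pytest.raises(ValueError):
            train_cellcount_model(ds.crops, counts, TrainingConfig(epochs=1))

    def test_training_deterministic_under_seed(self):
        ds = make_crop_dataset(120, seed=62)
        cfg = TrainingConfig(epochs=2, seed=5)
        m1 = train_cellcount_model(ds.crops[:100], ds.counts[:100], cfg)
        m2 = train_cellcount_model(ds.crops[:100], ds.counts[:100], cfg)
        p1 = m1.predict_counts_array(ds.crops[100:])
        p2 = m2.predict_counts_array(ds.crops[100:])
        assert np.array_equal(p1, p2)
        assert m1.training_log == m2.training_log

    def test_checkpoint_round_trip(self, trained_count_setup, tmp_path):
        path = tmp_path / "counts.npz"
        trained_count_setup.model.save(path)
        loaded = CellCountModel.load(path)
        ds = trained_count_setup.dataset
        a = trained_count_setup.model.predict_counts_array(ds.crops[:10])
        b = loaded.predict_counts_array(ds.crops[:10])
        assert np.array_equal(a, b)

    def test_accuracy_degrades_with_cell_overlap(self, trained_count_setup):
        """More permissive cell overlap → clusters → counting gets no easier.

        The fixture model (trained at the default 30% cap) is evaluated on
        populations rendered at increasing overlap caps, 3 seeds each; the
        pooled exact-match accuracy must be non-increasing (small slack for
        sampling error at n=1200 per cap).
        """
        accs = []
        for cap in (0.0, 0.4, 0.8):
            hits = total = 0
            for seed in (70, 71, 72):
                ds = make_crop_dataset(
                    400, seed=seed, render_config=RenderConfig(max_overlap=cap)
                )
                pred = trained_count_setup.model.predict_counts_array(ds.crops)
                labels = np.clip(ds.counts, 0, trained_count_setup.config.c_max)
                hits += (pred == labels).all(axis=1).sum()
                total += len(ds)
            accs.append(hits / total)
        assert accs[0] >= accs[1] - 0.02
        assert accs[1] >= accs[2] - 0.02
        assert accs[0] > accs[2]

    def test_label_permutation_control(self):
        """Training on shuffled labels collapses to the majority-class rate —
        guards against information leaking through the crop generator."""
        ds = make_crop_dataset(900, seed=63)
        rng = np.random.default_rng(64)
        shuffled = ds.counts[rng.permutation(len(ds.counts))]
        cfg = TrainingConfig(epochs=4, seed=8)
        model = train_cellcount_model(ds.crops[:600], shuffled[:600], cfg)
        pred = model.predict_counts_array(ds.crops[600:])
        true = np.clip(ds.counts[600:], 0, cfg.c_max)
        for k, head in enumerate(HEADS):
            counts = np.bincount(np.clip(shuffled[:600, k], 0, cfg.c_max))
            majority = counts.max() / counts.sum()
            acc = (pred[:, k] == true[:, k]).mean()
            se = np.sqrt(majority * (1 - majority) / len(true))
            assert acc <= majority + 3 * se + 0.02, head


@pytest.fixture(scope="module")
def outlier_setup():
    ds = make_crop_dataset(
        2000, seed=65, outlier_rates={"bubble": 0.07, "edge_cutoff": 0.07,
                                      "double_layer_blur": 0.06}
    )
    cfg = TrainingConfig(epochs=10, seed=9)
    model = train_outlier_model(ds.crops[:1600], ds.outlier_labels[:1600], cfg)
    return model, ds


class TestOutlierModel:

    def test_heldout_balanced_accuracy(self, outlier_setup):
        """Held-out balanced accuracy of the outlier CNN reaches ≥ 0.95."""
        model, ds = outlier_setup
        scores = model.predict_scores(ds.crops[1600:])
        pred = scores > 0.5
        true = ds.outlier_labels[1600:]
        sens = pred[true].mean()
        spec = (~pred[~true]).mean()
        assert (sens + spec) / 2 >= 0.95

    def test_predict_interface(self, outlier_setup):
        model, ds = outlier_setup
        clean_idx = int(np.flatnonzero(~ds.outlier_labels)[0])
        is_out, score = model.predict(ds.crops[clean_idx])
        assert isinstance(is_out, bool)
        assert 0.0 <= score <= 1.0

    def test_bubble_crops_flagged(self, outlier_setup):
        model, ds = outlier_setup
        bubbles = [i for i, t in enumerate(ds.truths) if t.outlier_class == "bubble"]
        scores = model.predict_scores([ds.crops[i] for i in bubbles])
        assert (scores > 0.5).mean() >= 0.9

    def test_single_class_labels_rejected(self):
        ds = make_crop_dataset(20, seed=66)
        with pytest.raises(ValueError):
            train_outlier_model(ds.crops, np.ones(20, dtype=bool), TrainingConfig(epochs=1))


def test_stack_crops_selects_channels_by_name():
    rng = np.random.default_rng(67)
    crop = {f"ch{i}": rng.integers(0, 100, size=(8, 8)) for i in range(3)}
    x = stack_crops([crop], ("ch2", "ch0"))
    assert x.shape == (1, 2, 8, 8)
    assert np.array_equal(x[0, 0], crop["ch2"])
    with pytest.raises(ValueError):
        stack_crops([crop], ("ch2", "missing"))
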