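"""Area/contour features, polygon gates and the AND/exclusive-trigger logic."""

import time

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dropscreen.config import EFFECTOR_STAIN, TARGET_STAIN, RenderConfig
from dropscreen.gating import (
    GateConfigError,
    GateFeatures,
    GatingStrategy,
    PolygonGate,
    binarize,
    calibrate_gates,
    evaluate_strategy,
    gate_features,
    in_gate,
)
from dropscreen.killing import CellRecord, DropletGroundTruth
from dropscreen.render import render_droplet


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _winding_number_contains(vertices, px, py):
    """Independent winding-number point-in-polygon oracle."""
    wn = 0
    n = len(vertices)
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        if ay <= py:
            if by > py and (bx - ax) * (py - ay) - (by - ay) * (px - ax) > 0:
                wn += 1
        elif by <= py and (bx - ax) * (py - ay) - (by - ay) * (px - ax) < 0:
            wn -= 1
    return wn != 0


class TestBinarize:
    def test_threshold_extremes(self):
        img = np.arange(16, dtype=np.uint16).reshape(4, 4)
        assert not binarize(img, 15).any()  # threshold at max: strict > empties it
        assert binarize(img, -1).all()

    def test_rendered_two_cell_droplet_has_two_components(self):
        from skimage.measure import label

        cfg = RenderConfig(max_overlap=0.0)
        truth = DropletGroundTruth(0, [CellRecord("target"), CellRecord("target")])
        two = 0
        for seed in range(10):
            stack = render_droplet(truth, 0.0, cfg, rng=200 + seed)
            thr = 0.5 * (cfg.background_level[TARGET_STAIN] + cfg.signal_level[TARGET_STAIN])
            two += label(binarize(stack.channels[TARGET_STAIN], thr)).max() == 2
        assert two >= 9


class TestGateFeatures:
    def test_filled_square(self):
        """A filled 5×5 block: area 25, contour 25 − 9 interior = 16."""
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        f = gate_features(mask)
        assert (f.area, f.contour) == (25, 16)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert gate_features(mask) == GateFeatures(1, 1)

    def test_empty_mask(self):
        assert gate_features(np.zeros((4, 4), dtype=bool)) == GateFeatures(0, 0)

    def test_mask_edge_counts_as_boundary(self):
        mask = np.ones((4, 4), dtype=bool)
        f = gate_features(mask)
        assert f.area == 16
        assert f.contour == 12  # all but the 4 interior pixels

    def test_roi_disk_restriction(self):
        mask = np.ones((50, 50), dtype=bool)
        f = gate_features(mask, (25.0, 25.0, 10.0))
        assert f.area == _disk_mask((50, 50), (25, 25), 10).sum()

    def test_two_disks_versus_one_contour_ratio(self):
        """Equal area, twice the cells: contour ratio ≈ √2 (within 10%).

        This is the discriminative property the gating exploits — several
        small cells expose more boundary than one large cell of equal area.
        """
        for r in (10, 14, 18):
            one = _disk_mask((200, 200), (100, 100), r * np.sqrt(2))
            two = _disk_mask((200, 200), (60, 60), r) | _disk_mask(
                (200, 200), (140, 140), r
            )
            ratio = gate_features(two).contour / gate_features(one).contour
            assert ratio == pytest.approx(np.sqrt(2), rel=0.10)

    def test_invariant_contour_not_exceeding_area(self):
        rng = np.random.default_rng(50)
        for _ in range(20):
            mask = rng.uniform(size=(30, 30)) > 0.6
            f = gate_features(mask)
            assert 0 <= f.contour <= f.area


class TestInGate:
    UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]

    def test_inside_and_outside(self):
        gate = PolygonGate("ch", self.UNIT_SQUARE)
        assert in_gate(GateFeatures(1, 1), PolygonGate("ch", [(0, 0), (2, 0), (2, 2), (0, 2)]))
        assert not in_gate(GateFeatures(2, 2), gate)

    def test_boundary_inclusivity(self):
        on_edge = GateFeatures(1, 0)
        incl = PolygonGate("ch", [(0, 0), (2, 0), (2, 2), (0, 2)], boundary_inclusive=True)
        excl = PolygonGate("ch", [(0, 0), (2, 0), (2, 2), (0, 2)], boundary_inclusive=False)
        assert in_gate(on_edge, incl)
        assert not in_gate(on_edge, excl)

    def test_matches_winding_number_oracle(self):
        """Ray casting agrees with an independent winding-number oracle on
        1,000 random points against a non-convex polygon."""
        poly = [(0, 0), (10, 0), (10, 4), (5, 4), (5, 8), (10, 8), (10, 12), (0, 12)]
        gate = PolygonGate("ch", poly)
        rng = np.random.default_rng(51)
        pts = rng.uniform(-2, 14, size=(1000, 2))
        for px, py in pts:
            f = GateFeatures.__new__(GateFeatures)
            object.__setattr__(f, "area", px)
            object.__setattr__(f, "contour", py)
            assert in_gate(f, gate) == _winding_number_contains(poly, px, py)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GateConfigError):
            PolygonGate("ch", [(0, 0), (1, 1)])
        with pytest.raises(GateConfigError):
            PolygonGate("ch", [(0, 0), (1, 1), (2, 2)])  # zero area
        with pytest.raises(GateConfigError):
            PolygonGate("ch", [(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting

    def test_winding_direction_normalised(self):
        cw = PolygonGate("ch", [(0, 0), (0, 2), (2, 2), (2, 0)])
        from dropscreen.gating import _polygon_area

        assert _polygon_area(cw.vertices) > 0


class TestEvaluateStrategy:
    def _strategy(self):
        g1 = PolygonGate(EFFECTOR_STAIN, [(0, 0), (10, 0), (10, 10), (0, 10)])
        g2 = PolygonGate(TARGET_STAIN, [(5, 5), (20, 5), (20, 20), (5, 20)])
        return GatingStrategy(
            thresholds={EFFECTOR_STAIN: 100.0, TARGET_STAIN: 100.0}, gates=[g1, g2]
        )

    def test_all_gates_pass_high_e1(self):
        s = self._strategy()
        d = evaluate_strategy(
            {EFFECTOR_STAIN: GateFeatures(5, 5), TARGET_STAIN: GateFeatures(10, 10)}, s
        )
        assert d.positive and d.trigger == "HIGH" and d.electrode_state == (True, False)

    def test_any_gate_fails_low_e2(self):
        s = self._strategy()
        d = evaluate_strategy(
            {EFFECTOR_STAIN: GateFeatures(5, 5), TARGET_STAIN: GateFeatures(30, 30)}, s
        )
        assert not d.positive and d.trigger == "LOW" and d.electrode_state == (False, True)

    def test_missing_channel_raises(self):
        with pytest.raises(GateConfigError):
            evaluate_strategy({EFFECTOR_STAIN: GateFeatures(5, 5)}, self._strategy())

    def test_empty_strategy_rejected_at_construction(self):
        with pytest.raises(GateConfigError):
            GatingStrategy(thresholds={}, gates=[])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=30),
                st.integers(min_value=0, max_value=30),
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_equals_brute_force_conjunction(self, points):
        """The strategy decision is exactly the AND of individual gate tests."""
        channels = [f"ch{i}" for i in range(len(points))]
        gates = [
            PolygonGate(ch, [(2, 2), (18, 2), (18, 18), (2, 18)]) for ch in channels
        ]
        strategy = GatingStrategy(
            thresholds={ch: 1.0 for ch in channels}, gates=gates
        )
        feats = {
            ch: GateFeatures(a, min(c, a)) for ch, (a, c) in zip(channels, points)
        }
        expected = all(in_gate(feats[g.channel_name], g) for g in strategy.gates)
        assert evaluate_strategy(feats, strategy).positive == expected

    def test_json_round_trip(self, tmp_path):
        s = self._strategy()
        path = tmp_path / "strategy.json"
        s.save(path)
        loaded = GatingStrategy.load(path)
        assert loaded.to_dict() == s.to_dict()


class TestCalibration:
    @staticmethod
    def _clusters(rng, centers, n=60, sd=3.0):
        feats, counts = [], []
        for cnt, (cx, cy) in centers.items():
            pts = rng.normal((cx, cy), sd, size=(n, 2))
            feats.append(pts)
            counts.extend([cnt] * n)
        return np.vstack(feats), np.asarray(counts)

    def test_separated_clusters_reproduce_predicate(self):
        """Gates from well-separated clusters recover the true count predicate."""
        rng = np.random.default_rng(52)
        centers = {0: (0, 0), 1: (100, 40), 2: (200, 80), 3: (300, 120)}
        feats, counts = self._clusters(rng, centers)
        strategy = calibrate_gates(
            {"ch": feats}, {"ch": counts}, {"ch": {1}}, {"ch": 10.0}, margin=5.0
        )
        test_f, test_c = self._clusters(rng, centers)
        pred = np.array([_eval(strategy.gates[0], a, c) for a, c in test_f])
        agreement = np.mean(pred == (test_c == 1))
        assert agreement >= 0.9

    def test_margin_zero_excludes_points_outside_hull(self):
        rng = np.random.default_rng(53)
        feats, counts = self._clusters(rng, {1: (50, 20)}, n=40)
        strategy = calibrate_gates(
            {"ch": feats}, {"ch": counts}, {"ch": {1}}, {"ch": 10.0}, margin=0.0, trim_z=0.0
        )
        # a point far outside the hull must not pass
        assert not _eval(strategy.gates[0], 500.0, 200.0)

    def test_overlapping_clusters_log_warning(self, caplog):
        rng = np.random.default_rng(54)
        feats, counts = self._clusters(rng, {1: (50, 20), 2: (55, 22)}, n=60, sd=6.0)
        import logging

        with caplog.at_level(logging.WARNING, logger="dropscreen.gating"):
            calibrate_gates(
                {"ch": feats}, {"ch": counts}, {"ch": {1}}, {"ch": 10.0}, margin=5.0
            )
        assert any("overlapping" in rec.message for rec in caplog.records)

    def test_absent_class_raises(self):
        rng = np.random.default_rng(55)
        feats, counts = self._clusters(rng, {1: (50, 20)})
        with pytest.raises(ValueError):
            calibrate_gates({"ch": feats}, {"ch": counts}, {"ch": {4}}, {"ch": 10.0})

    def test_contour_scales_linearly_and_clusters_separate(self):
        """Contour and area grow ≈ linearly in cell number (R² ≥ 0.95) and the
        per-count clusters are separated by > 2× their within-cluster spread."""
        cfg = RenderConfig(max_overlap=0.0)
        thr = 0.5 * (cfg.background_level[TARGET_STAIN] + cfg.signal_level[TARGET_STAIN])
        centroids, spreads, mean_feats = [], [], {}
        for n in (1, 2, 3, 4):
            feats = []
            for k in range(50):
                truth = DropletGroundTruth(0, [CellRecord("target")] * n)
                stack = render_droplet(truth, 0.0, cfg, rng=3000 + 100 * n + k)
                mask = binarize(stack.channels[TARGET_STAIN], thr)
                f = gate_features(mask, (47.5, 47.5, cfg.droplet_radius_px))
                feats.append((f.area, f.contour))
            feats = np.asarray(feats, dtype=float)
            centroids.append(feats.mean(axis=0))
            spreads.append(feats.std(axis=0).mean())
            mean_feats[n] = feats.mean(axis=0)
        ns = np.array([1, 2, 3, 4], dtype=float)
        for dim in (0, 1):
            y = np.array([mean_feats[n][dim] for n in (1, 2, 3, 4)])
            slope, intercept = np.polyfit(ns, y, 1)
            resid = y - (slope * ns + intercept)
            r2 = 1 - resid.var() / y.var()
            assert r2 >= 0.95
        for a, b, sa, sb in zip(centroids, centroids[1:], spreads, spreads[1:]):
            gap = np.linalg.norm(np.asarray(b) - np.asarray(a))
            assert gap > 2.0 * max(sa, sb)

    def test_per_droplet_pipeline_latency(self):
        """binarize → features → gates stays below 1 ms/droplet on 96² crops."""
        rng = np.random.default_rng(56)
        img = (rng.uniform(0, 65535, size=(96, 96))).astype(np.uint16)
        gate = PolygonGate("ch", [(0, 0), (4000, 0), (4000, 2000), (0, 2000)])
        strategy = GatingStrategy(thresholds={"ch": 30000.0}, gates=[gate])
        t0 = time.perf_counter()
        n = 300
        for _ in range(n):
            mask = binarize(img, 30000.0)
            f = gate_features(mask, (47.5, 47.5, 40.0))
            evaluate_strategy({"ch": f}, strategy)
        assert (time.perf_counter() - t0) / n < 1e-3


def _eval(gate, a, c):
    f = GateFeatures.__new__(GateFeatures)
    object.__setattr__(f, "area", float(a))
    object.__setattr__(f, "contour", float(c))
    return in_gate(f, gate)
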