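"""In-silico droplet sorting: stream, gate, route, and score purity/enrichment.

``run_sort`` pushes a ground-truth droplet population through the imaging and
gating chain exactly as the physical sorter would see it — one rendered frame
per droplet at the sort time, thresholded per channel, area/contour features
inside the droplet disk, AND-combined polygon gates — and then applies a
timing-error model (misrouting and dropped frames) before routing each
droplet to the positive or negative outlet.  Purity is always scored against
ground truth, the simulator's analogue of re-inspecting the sorted emulsion
under a microscope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from ._seeds import child_rng
from .config import (
    APOPTOSIS_STAIN,
    EFFECTOR_STAIN,
    TARGET_STAIN,
    ExperimentConfig,
    SortErrorModel,
    RenderConfig,
)
from .datasets import make_population
from .gating import (
    GateFeatures,
    GatingStrategy,
    PolygonGate,
    SortDecision,
    binarize,
    calibrate_gates,
    evaluate_strategy,
    gate_features,
)
from .killing import DropletGroundTruth
from .render import ImageStack, render_droplet

__all__ = [
    "SortRecord",
    "run_sort",
    "purity",
    "enrichment",
    "droplet_features",
    "midpoint_thresholds",
    "open_count_gate",
    "stoichiometry_sort_experiment",
    "killer_sort_experiment",
]

log = logging.getLogger(__name__)


@dataclass
class SortRecord:
    """One droplet's passage through the sorter, with its ground truth."""

    truth: DropletGroundTruth
    decision: SortDecision
    routed: str  # "positive" | "negative"
    misrouted: bool = False
    frame_dropped: bool = False

    @property
    def droplet_id(self) -> int:
        return self.truth.droplet_id


def midpoint_thresholds(config: RenderConfig) -> dict[str, float]:
    """Default manual thresholds: midpoint of background and signal levels."""
    return {
        ch: 0.5 * (config.background_level[ch] + config.signal_level[ch])
        for ch in config.fluorescence_channels
    }


def droplet_features(
    stack: ImageStack,
    strategy: GatingStrategy,
    radius: float,
    center: tuple[float, float] | None = None,
) -> dict[str, GateFeatures]:
    """Per-channel (area, contour) features of one droplet frame."""
    h, w = stack.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    out = {}
    for ch in strategy.channels:
        mask = binarize(stack.channels[ch], strategy.thresholds[ch])
        out[ch] = gate_features(mask, (center[0], center[1], radius))
    return out


def run_sort(
    population: Iterable[DropletGroundTruth],
    sort_time: float,
    strategy: GatingStrategy,
    render_config: RenderConfig,
    error_model: SortErrorModel,
    seed: int,
    oracle: Callable[[DropletGroundTruth], bool] | None = None,
) -> list[SortRecord]:
    """Sort a droplet stream; fully reproducible under ``seed``.

    ``oracle`` replaces the imaging/gating chain by a ground-truth predicate
    (used to isolate routing error from gating error in diagnostics).
    """
    population = list(population)
    if not population:
        raise ValueError("cannot sort an empty population")
    render_rng = child_rng(seed, "sort-render")
    err_rng = child_rng(seed, "sort-errors")
    radius = render_config.droplet_radius_px
    records = []
    prev_trigger = False  # electrode state before the first droplet arrives
    for truth in population:
        if oracle is not None:
            decision = SortDecision(truth.droplet_id, bool(oracle(truth)))
        else:
            stack = render_droplet(truth, sort_time, render_config, render_rng)
            feats = droplet_features(stack, strategy, radius)
            decision = evaluate_strategy(feats, strategy, truth.droplet_id)
        dropped = bool(err_rng.uniform() < error_model.frame_drop_probability)
        shifted = bool(err_rng.uniform() < error_model.misroute_probability)
        if dropped:
            # undetected droplet: default electrode state routes it negative
            decision = SortDecision(truth.droplet_id, False)
            routed_positive = False
            misrouted = False
        elif shifted:
            # trigger window mis-synchronised by one droplet period: the
            # electrode pattern of the previous droplet acts on this one
            routed_positive = prev_trigger
            misrouted = routed_positive != decision.positive
        else:
            routed_positive = decision.positive
            misrouted = False
        records.append(
            SortRecord(
                truth=truth,
                decision=decision,
                routed="positive" if routed_positive else "negative",
                misrouted=misrouted,
                frame_dropped=dropped,
            )
        )
        prev_trigger = decision.positive
    return records


def purity(
    records: Iterable[SortRecord],
    predicate: Callable[[DropletGroundTruth], bool],
) -> float:
    """Fraction of positively routed droplets whose ground truth satisfies
    ``predicate``; ``nan`` (with a warning) when nothing was routed positive."""
    positives = [r for r in records if r.routed == "positive"]
    if not positives:
        warnings.warn("no droplets were routed positive; purity is undefined")
        return float("nan")
    return float(np.mean([bool(predicate(r.truth)) for r in positives]))


def enrichment(sorted_fraction: float, parent_fraction: float) -> float:
    """Fold enrichment of a predicate, reported to 2 significant figures."""
    if parent_fraction <= 0:
        raise ValueError("parent fraction must be positive")
    return float(f"{sorted_fraction / parent_fraction:.2g}")


def open_count_gate(
    features: np.ndarray,
    counts: np.ndarray,
    min_count: int,
    channel: str,
    margin: float = 6.0,
    percentile: float = 2.0,
    min_droplets: int = 20,
) -> PolygonGate:
    """Box gate selecting "``min_count`` or more" cells on one channel.

    Area and contour both grow with cell number, so an open-ended count
    criterion is a lower-left corner in feature space.  The lower bound sits
    per dimension at the midpoint between the (``min_count``−1)-cell
    cluster's 95th percentile and the pooled ≥``min_count`` cloud's
    ``percentile``-th percentile — the separating boundary of the two
    clusters; when no (``min_count``−1) droplets are available it falls back
    to the pooled cloud's low percentile minus ``margin``.  The box extends
    far beyond the largest observed feature.
    """
    feats = np.asarray(features, dtype=float)
    counts = np.asarray(counts)
    cloud = feats[counts >= min_count]
    if len(cloud) < min_droplets:
        raise ValueError(
            f"channel {channel!r}: only {len(cloud)} calibration droplets with "
            f">= {min_count} cells"
        )
    below = feats[counts == min_count - 1]
    if len(below) >= min_droplets:
        lo = 0.5 * (
            np.percentile(below, 95, axis=0) + np.percentile(cloud, percentile, axis=0)
        )
    else:
        lo = np.percentile(cloud, percentile, axis=0) - margin
    hi = feats.max(axis=0) * 10.0 + 1000.0
    return PolygonGate(
        channel_name=channel,
        vertices=[(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])],
    )


def _calibration_features(
    truths: list[DropletGroundTruth],
    time: float,
    config: RenderConfig,
    thresholds: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Render labelled droplets and collect per-channel features and counts."""
    radius = config.droplet_radius_px
    feats: dict[str, list] = {ch: [] for ch in thresholds}
    labels: dict[str, list] = {ch: [] for ch in thresholds}
    for truth in truths:
        stack = render_droplet(truth, time, config, rng)
        el, ed, tl, td = truth.counts_at(time)
        per_channel_counts = {
            EFFECTOR_STAIN: truth.n_effectors,
            TARGET_STAIN: truth.n_targets,
            APOPTOSIS_STAIN: ed + td,
        }
        center = ((stack.shape[0] - 1) / 2.0, (stack.shape[1] - 1) / 2.0)
        for ch in thresholds:
            mask = binarize(stack.channels[ch], thresholds[ch])
            f = gate_features(mask, (center[0], center[1], radius))
            feats[ch].append((f.area, f.contour))
            labels[ch].append(per_channel_counts[ch])
    return (
        {ch: np.asarray(v, dtype=float) for ch, v in feats.items()},
        {ch: np.asarray(v) for ch, v in labels.items()},
    )


def _report(records, predicate, parent_fraction, label, seed) -> dict:
    n_pos = sum(r.routed == "positive" for r in records)
    pur = purity(records, predicate)
    return dict(
        label=label,
        seed=seed,
        n_droplets=len(records),
        n_sorted=int(n_pos),
        parent_fraction=float(parent_fraction),
        purity=pur,
        enrichment=enrichment(pur, parent_fraction) if parent_fraction > 0 else float("nan"),
    )


def stoichiometry_sort_experiment(config: ExperimentConfig, seed: int) -> dict:
    """End-to-end stoichiometry sort: select droplets with 1 effector and 2-4 targets.

    Samples a Poisson-loaded droplet stream at the configured concentrations,
    calibrates effector/target polygon gates on a disjoint labelled split,
    sorts the main stream at encapsulation time, and reports parent fraction,
    purity and fold enrichment against ground truth.
    """
    rc, km = config.render, config.killing
    n_total = config.n_droplets + config.calibration_droplets
    truths = make_population(
        n_total, child_rng(seed, "population").integers(2**31 - 1),
        config.conc_effector, config.conc_target, rc, km,
    )
    cal, stream = truths[: config.calibration_droplets], truths[config.calibration_droplets :]
    thresholds = midpoint_thresholds(rc)
    feats, labels = _calibration_features(
        cal, 0.0, rc, thresholds, child_rng(seed, "calibration")
    )
    strategy = calibrate_gates(
        {ch: feats[ch] for ch in (EFFECTOR_STAIN, TARGET_STAIN)},
        {ch: labels[ch] for ch in (EFFECTOR_STAIN, TARGET_STAIN)},
        {EFFECTOR_STAIN: {1}, TARGET_STAIN: {2, 3, 4}},
        thresholds,
        label="1 effector AND 2-4 targets",
        margin=config.gate_margin,
    )
    records = run_sort(stream, 0.0, strategy, rc, config.sort_errors, seed)
    predicate = lambda t: t.n_effectors == 1 and 2 <= t.n_targets <= 4
    parent = float(np.mean([predicate(t) for t in stream]))
    return _report(records, predicate, parent, strategy.label, seed)


def killer_sort_experiment(
    config: ExperimentConfig, mode: str, seed: int
) -> dict:
    """Sort killing phenotypes after incubation (default 6 h).

    ``mode="serial"`` gates droplets with exactly one effector and two or
    more apoptotic cells; the ground-truth predicate is an effector that
    killed at least two targets.  ``mode="non_cytotoxic"`` gates droplets
    with two or more targets and not a single apoptotic cell; the predicate
    is that no killing occurred in the droplet over the whole assay window.
    """
    if mode not in ("serial", "non_cytotoxic"):
        raise ValueError(f"unknown mode {mode!r}")
    rc, km = config.render, config.killing
    n_total = config.n_droplets + config.calibration_droplets
    truths = make_population(
        n_total, child_rng(seed, "population").integers(2**31 - 1),
        config.conc_effector, config.conc_target, rc, km,
    )
    cal, stream = truths[: config.calibration_droplets], truths[config.calibration_droplets :]
    thresholds = midpoint_thresholds(rc)
    t_sort = config.sort_time
    feats, labels = _calibration_features(
        cal, t_sort, rc, thresholds, child_rng(seed, "calibration")
    )
    if mode == "serial":
        base = calibrate_gates(
            {EFFECTOR_STAIN: feats[EFFECTOR_STAIN]},
            {EFFECTOR_STAIN: labels[EFFECTOR_STAIN]},
            {EFFECTOR_STAIN: {1}},
            thresholds,
            margin=config.gate_margin,
        )
        apo_gate = open_count_gate(
            feats[APOPTOSIS_STAIN], labels[APOPTOSIS_STAIN], 2,
            APOPTOSIS_STAIN, margin=config.gate_margin,
        )
        strategy = GatingStrategy(
            thresholds=thresholds,
            gates=base.gates + [apo_gate],
            label="1 effector AND >=2 dead cells",
        )
        predicate = lambda t: t.n_effectors == 1 and max(
            t.kills_by_effector(), default=0
        ) >= 2
        phenotype = lambda t: max(t.kills_by_effector(), default=0) >= 2
    else:
        tgt_gate = open_count_gate(
            feats[TARGET_STAIN], labels[TARGET_STAIN], 2,
            TARGET_STAIN, margin=config.gate_margin,
        )
        apo_zero = calibrate_gates(
            {APOPTOSIS_STAIN: feats[APOPTOSIS_STAIN]},
            {APOPTOSIS_STAIN: labels[APOPTOSIS_STAIN]},
            {APOPTOSIS_STAIN: {0}},
            thresholds,
            margin=config.gate_margin,
        )
        strategy = GatingStrategy(
            thresholds=thresholds,
            gates=[tgt_gate] + apo_zero.gates,
            label=">=2 targets AND 0 dead cells",
        )
        predicate = lambda t: t.total_kills == 0
        phenotype = lambda t: max(t.kills_by_effector(), default=0) == 0
    records = run_sort(stream, t_sort, strategy, rc, config.sort_errors, seed)
    # parent fraction mirrors the microscopy analysis: the phenotype's share
    # among single-effector droplets co-encapsulated with multiple targets
    classifiable = [t for t in stream if t.n_effectors == 1 and t.n_targets >= 2]
    parent = float(np.mean([phenotype(t) for t in classifiable]))
    return _report(records, predicate, parent, strategy.label, seed)
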