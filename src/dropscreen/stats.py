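"""Screening statistics from per-droplet count time series.

These are the population-level readouts of the droplet cytotoxicity assay:
the effector:target co-encapsulation histogram, the time course of the
dead-target fraction in matched droplets (single effector with 2–4 targets),
baseline viability from singly encapsulated cells, the distribution of
killing events per NK cell, and the per-droplet phenotype call.  All
statistics accept either ground-truth counts or model predictions in the
same ``(live targets, dead targets, live effectors, dead effectors)`` layout
(:data:`dropscreen.models.HEADS`), and skip outlier-flagged droplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .killing import DropletGroundTruth

__all__ = [
    "NOT_CLASSIFIABLE",
    "DropletTimeSeries",
    "timeseries_from_truths",
    "stoichiometry_histogram",
    "dead_target_fraction",
    "baseline_viability",
    "killing_distribution",
    "classify_phenotype",
]

#: sentinel for droplets the single-NK phenotype rule cannot classify
NOT_CLASSIFIABLE = "not_classifiable"


@dataclass
class DropletTimeSeries:
    """Counts of one droplet across the imaging timepoints.

    ``counts`` has one row per timepoint with columns
    (live_targets, dead_targets, live_effectors, dead_effectors).
    """

    droplet_id: int
    times: np.ndarray
    counts: np.ndarray
    outlier_flag: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.counts.shape != (len(self.times), 4):
            raise ValueError("counts must have shape (n_timepoints, 4)")

    # column helpers, HEADS order
    @property
    def live_targets(self):
        return self.counts[:, 0]

    @property
    def dead_targets(self):
        return self.counts[:, 1]

    @property
    def live_effectors(self):
        return self.counts[:, 2]

    @property
    def dead_effectors(self):
        return self.counts[:, 3]

    @property
    def n_targets(self) -> int:
        return int(self.counts[0, 0] + self.counts[0, 1])

    @property
    def n_effectors(self) -> int:
        return int(self.counts[0, 2] + self.counts[0, 3])


def timeseries_from_truths(
    truths: list[DropletGroundTruth], times
) -> list[DropletTimeSeries]:
    """Build exact count time series from ground truth on a time grid."""
    times = np.asarray(times, dtype=float)
    out = []
    for t in truths:
        rows = []
        for tp in times:
            el, ed, tl, td = t.counts_at(float(tp))
            rows.append((tl, td, el, ed))
        out.append(
            DropletTimeSeries(
                droplet_id=t.droplet_id,
                times=times,
                counts=np.array(rows, dtype=int),
                outlier_flag=t.outlier_class != "none",
            )
        )
    return out


def _usable(series: list[DropletTimeSeries]) -> list[DropletTimeSeries]:
    return [s for s in series if not s.outlier_flag]


def stoichiometry_histogram(series: list[DropletTimeSeries]):
    """Joint effector:target co-encapsulation distribution at t = 0.

    Returns ``(joint, eff_marginal, tgt_marginal)``: a DataFrame of fractions
    indexed by effector count (rows) × target count (columns), plus the two
    marginal Series.  Fractions sum to 1.
    """
    series = _usable(series)
    if not series:
        raise ValueError("no usable droplets")
    eff = np.array([s.n_effectors for s in series])
    tgt = np.array([s.n_targets for s in series])
    joint = np.zeros((eff.max() + 1, tgt.max() + 1))
    for e, t in zip(eff, tgt):
        joint[e, t] += 1
    joint /= joint.sum()
    df = pd.DataFrame(
        joint,
        index=pd.RangeIndex(joint.shape[0], name="n_effectors"),
        columns=pd.RangeIndex(joint.shape[1], name="n_targets"),
    )
    return df, df.sum(axis=1), df.sum(axis=0)


def baseline_viability(series: list[DropletTimeSeries], cell_type: str) -> pd.Series:
    """Viability over time of singly encapsulated cells of one type.

    Uses droplets that contained exactly one cell of ``cell_type``
    (``"effector"`` or ``"target"``) and nothing else — the spontaneous-death
    control population.
    """
    series = _usable(series)
    if cell_type == "effector":
        singles = [s for s in series if s.n_effectors == 1 and s.n_targets == 0]
        live = lambda s: s.live_effectors
    elif cell_type == "target":
        singles = [s for s in series if s.n_targets == 1 and s.n_effectors == 0]
        live = lambda s: s.live_targets
    else:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if not singles:
        raise ValueError(f"no single-{cell_type} droplets available")
    times = singles[0].times
    alive = np.mean([live(s) > 0 for s in singles], axis=0)
    return pd.Series(alive, index=pd.Index(times, name="time_h"), name="viability")


def dead_target_fraction(
    series: list[DropletTimeSeries],
    min_targets: int = 2,
    max_targets: int = 4,
    baseline_correct: bool = False,
) -> pd.DataFrame:
    """Fraction of dead target cells over time in matched droplets.

    Restricted to droplets with exactly one effector and ``min_targets`` to
    ``max_targets`` targets at encapsulation.  The baseline column is the
    spontaneous dead fraction from target-only single-cell droplets; with
    ``baseline_correct`` it is subtracted (floored at 0).
    """
    series = _usable(series)
    sel = [
        s
        for s in series
        if s.n_effectors == 1 and min_targets <= s.n_targets <= max_targets
    ]
    if not sel:
        raise ValueError("no droplets match the single-effector/multi-target filter")
    times = sel[0].times
    dead = np.sum([s.dead_targets for s in sel], axis=0)
    total = np.sum([s.n_targets for s in sel])
    frac = dead / total
    try:
        baseline = 1.0 - baseline_viability(series, "target").to_numpy()
    except ValueError:
        baseline = np.zeros_like(frac)
    out = frac - baseline if baseline_correct else frac
    return pd.DataFrame(
        {
            "dead_target_fraction": np.clip(out, 0.0, 1.0),
            "baseline_dead_fraction": baseline,
        },
        index=pd.Index(times, name="time_h"),
    )


def killing_distribution(
    series: list[DropletTimeSeries],
    min_targets: int = 1,
    k_max: int = 3,
    baseline_correct: bool = False,
) -> pd.Series:
    """Distribution of killing events per NK cell at the assay endpoint.

    Droplets with exactly one effector and at least ``min_targets`` targets
    contribute their endpoint dead-target count as the kill count of their
    NK cell (the apoptosis reporter cannot attribute cause, so spontaneous
    target deaths count as kills unless ``baseline_correct`` subtracts the
    expected baseline).  Counts are bucketed at ``k_max`` ("k_max or more");
    the returned fractions sum to 1.
    """
    series = _usable(series)
    sel = [s for s in series if s.n_effectors == 1 and s.n_targets >= min_targets]
    if not sel:
        raise ValueError("no droplets match the killing-distribution filter")
    kills = np.array([s.dead_targets[-1] for s in sel], dtype=float)
    if baseline_correct:
        viab = baseline_viability(series, "target")
        expected_spontaneous = (1.0 - viab.iloc[-1]) * np.array(
            [s.n_targets for s in sel]
        )
        kills = np.maximum(kills - expected_spontaneous, 0.0)
    kills = np.minimum(np.round(kills).astype(int), k_max)
    frac = np.bincount(kills, minlength=k_max + 1) / len(kills)
    labels = [str(k) for k in range(k_max)] + [f"{k_max}+"]
    return pd.Series(frac, index=pd.Index(labels, name="kills"), name="fraction")


def classify_phenotype(
    n_effectors: int, dead_targets: int
) -> str:
    """Phenotype call from endpoint counts of a single-NK droplet.

    Exactly one effector is required (multi-NK droplets are excluded from
    phenotyping); 0 dead targets → ``non_cytotoxic``, 1 → ``single_killer``,
    ≥2 → ``serial_killer``.  Returns :data:`NOT_CLASSIFIABLE` otherwise.
    """
    if n_effectors != 1:
        return NOT_CLASSIFIABLE
    if dead_targets == 0:
        return "non_cytotoxic"
    if dead_targets == 1:
        return "single_killer"
    return "serial_killer"
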