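"""Ground-truth droplet content and stochastic killing kinetics.

Each droplet is simulated as a small continuous-time system: every effector
receives a cytotoxic phenotype (non-killer / single killer / serial killer),
killer effectors eliminate live targets with independent exponential waiting
times until their capacity is spent or no live target remains, and all cells
are exposed to baseline exponential death.  A dead effector kills no further.
The resulting :class:`DropletGroundTruth` records are the oracle against
which every downstream classifier and statistic is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import KillingModel, ConfigError

__all__ = ["CellRecord", "DropletGroundTruth", "simulate_killing", "assign_outlier_classes"]

EFFECTOR = "effector"
TARGET = "target"


@dataclass
class CellRecord:
    """One encapsulated cell and its fate within the assay window."""

    cell_type: str  # "effector" | "target"
    phenotype: str | None = None  # effectors only
    death_time: float | None = None  # hours; None = alive through the window
    killed_by: int | None = None  # index of the killer effector, targets only

    @property
    def is_effector(self) -> bool:
        return self.cell_type == EFFECTOR

    def alive_at(self, t: float) -> bool:
        return self.death_time is None or self.death_time > t


@dataclass
class DropletGroundTruth:
    """True content of one droplet: cells, fates and image-artifact class."""

    droplet_id: int
    cells: list[CellRecord] = field(default_factory=list)
    outlier_class: str = "none"

    @property
    def effectors(self) -> list[CellRecord]:
        return [c for c in self.cells if c.is_effector]

    @property
    def targets(self) -> list[CellRecord]:
        return [c for c in self.cells if not c.is_effector]

    @property
    def n_effectors(self) -> int:
        return len(self.effectors)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def counts_at(self, t: float) -> tuple[int, int, int, int]:
        """(live effectors, dead effectors, live targets, dead targets) at time ``t``."""
        el = sum(c.alive_at(t) for c in self.effectors)
        tl = sum(c.alive_at(t) for c in self.targets)
        return el, self.n_effectors - el, tl, self.n_targets - tl

    def kills_by_effector(self) -> list[int]:
        """Kills attributed to each effector, in encapsulation order."""
        kills = [0] * self.n_effectors
        for c in self.targets:
            if c.killed_by is not None:
                kills[c.killed_by] += 1
        return kills

    @property
    def total_kills(self) -> int:
        return sum(1 for c in self.targets if c.killed_by is not None)


def simulate_killing(
    stoichiometries: np.ndarray,
    model: KillingModel,
    rng: np.random.Generator | int,
) -> list[DropletGroundTruth]:
    """Simulate killing kinetics for a population of droplets.

    Parameters
    ----------
    stoichiometries : array of shape (n, 2)
        Per-droplet encapsulated ``(n_effectors, n_targets)`` counts.
    model : KillingModel
        Rates, phenotype mix and assay duration.
    rng : Generator or int
        Random stream; an int is used as a seed.

    Returns
    -------
    list of DropletGroundTruth, one per input row, in order.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    fr = np.asarray(model.phenotype_fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
        raise ConfigError("phenotype fractions must be a probability vector")
    duration = model.duration
    truths: list[DropletGroundTruth] = []

    def _baseline(rate: float) -> float:
        return float(rng.exponential(1.0 / rate)) if rate > 0 else np.inf

    for droplet_id, (n_eff, n_tgt) in enumerate(np.asarray(stoichiometries, dtype=int)):
        effectors = [
            CellRecord(EFFECTOR, phenotype=model.PHENOTYPES[rng.choice(3, p=fr)])
            for _ in range(n_eff)
        ]
        targets = [CellRecord(TARGET) for _ in range(n_tgt)]
        eff_death = [_baseline(model.baseline_effector_death_rate) for _ in effectors]
        tgt_death = [_baseline(model.baseline_target_death_rate) for _ in targets]
        tgt_killed_at = [np.inf] * n_tgt

        # pending kill-attempt times per killer: cumulative exponential waits
        events: list[tuple[float, int]] = []  # (time, effector index)
        if model.kill_rate > 0:
            for i, eff in enumerate(effectors):
                cap = model.capacity(eff.phenotype)
                if cap:
                    times = np.cumsum(rng.exponential(1.0 / model.kill_rate, size=cap))
                    events.extend((float(t), i) for t in times if t <= duration)
        events.sort()

        for t, i in events:
            if eff_death[i] <= t:  # the killer itself died first
                continue
            live = [
                j
                for j in range(n_tgt)
                if tgt_killed_at[j] > t and tgt_death[j] > t
            ]
            if not live:
                break
            victim = live[int(rng.integers(len(live)))]
            tgt_killed_at[victim] = t
            targets[victim].killed_by = i

        for c, bl in zip(effectors, eff_death):
            if bl <= duration:
                c.death_time = bl
        for j, c in enumerate(targets):
            d = min(tgt_death[j], tgt_killed_at[j])
            if d <= duration:
                c.death_time = d
                if tgt_killed_at[j] > tgt_death[j]:
                    c.killed_by = None  # baseline death won the race
        truths.append(DropletGroundTruth(int(droplet_id), effectors + targets))
    return truths


def assign_outlier_classes(
    truths: list[DropletGroundTruth],
    outlier_rates: dict[str, float],
    rng: np.random.Generator | int,
) -> None:
    """Draw an image-artifact class per droplet in place.

    ``outlier_rates`` maps artifact class → probability; the remainder of the
    probability mass is the clean ``"none"`` class.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    classes = list(outlier_rates.keys())
    probs = np.array([outlier_rates[c] for c in classes], dtype=float)
    if np.any(probs < 0) or probs.sum() > 1.0 + 1e-12:
        raise ConfigError("outlier rates must be non-negative and sum to at most 1")
    full = np.concatenate([[1.0 - probs.sum()], probs])
    draws = rng.choice(len(full), size=len(truths), p=full)
    for truth, d in zip(truths, draws):
        truth.outlier_class = "none" if d == 0 else classes[d - 1]
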