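"""Turn the generator into labelled crop datasets for model training.

These builders wire stoichiometry sampling, killing simulation and rendering
together and return crops with their ground-truth labels, drawing all
randomness from named child streams of one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import child_rng
from .config import ExperimentConfig, KillingModel, RenderConfig
from .encapsulation import sample_stoichiometry
from .killing import DropletGroundTruth, assign_outlier_classes, simulate_killing
from .models import HEADS
from .render import ImageStack, render_droplet

__all__ = ["CropDataset", "make_crop_dataset", "make_population"]


@dataclass
class CropDataset:
    """Rendered crops plus every label downstream stages may need."""

    crops: list[ImageStack]
    counts: np.ndarray  # (N, 4) in models.HEADS order at the rendered time
    outlier_labels: np.ndarray  # bool, True = artifact droplet
    truths: list[DropletGroundTruth]
    times: np.ndarray  # hours, per crop

    def __len__(self) -> int:
        return len(self.crops)


def make_population(
    n_droplets: int,
    seed: int,
    conc_effector: float = 3.0e6,
    conc_target: float = 6.0e6,
    render_config: RenderConfig | None = None,
    killing_model: KillingModel | None = None,
    outlier_rates: dict[str, float] | None = None,
) -> list[DropletGroundTruth]:
    """Sample a droplet population and simulate its killing kinetics."""
    render_config = render_config or RenderConfig()
    killing_model = killing_model or KillingModel()
    stoich = sample_stoichiometry(
        conc_effector,
        conc_target,
        render_config.droplet_diameter,
        n_droplets,
        child_rng(seed, "stoichiometry"),
    )
    truths = simulate_killing(stoich, killing_model, child_rng(seed, "phenotypes"))
    rates = outlier_rates if outlier_rates is not None else render_config.outlier_rates
    if any(v > 0 for v in rates.values()):
        assign_outlier_classes(truths, rates, child_rng(seed, "outliers"))
    return truths


def make_crop_dataset(
    n_droplets: int,
    seed: int,
    render_config: RenderConfig | None = None,
    killing_model: KillingModel | None = None,
    conc_effector: float = 3.0e6,
    conc_target: float = 6.0e6,
    outlier_rates: dict[str, float] | None = None,
    times: str | float = "random",
) -> CropDataset:
    """Generate ``n_droplets`` labelled single-droplet crops.

    ``times`` is either a fixed acquisition time in hours or ``"random"``,
    which draws each crop's time uniformly from the killing model's time grid
    so training data covers the whole assay window.
    """
    render_config = render_config or RenderConfig()
    killing_model = killing_model or KillingModel()
    truths = make_population(
        n_droplets,
        seed,
        conc_effector,
        conc_target,
        render_config,
        killing_model,
        outlier_rates,
    )
    time_rng = child_rng(seed, "times")
    grid = killing_model.time_grid
    if times == "random":
        t_arr = grid[time_rng.integers(len(grid), size=n_droplets)]
    else:
        t_arr = np.full(n_droplets, float(times))
    render_rng = child_rng(seed, "render")
    crops, counts = [], []
    for truth, t in zip(truths, t_arr):
        crops.append(render_droplet(truth, float(t), render_config, render_rng))
        el, ed, tl, td = truth.counts_at(float(t))
        counts.append({"live_targets": tl, "dead_targets": td,
                       "live_effectors": el, "dead_effectors": ed})
    counts_arr = np.array([[c[h] for h in HEADS] for c in counts], dtype=int)
    outliers = np.array([t.outlier_class != "none" for t in truths])
    return CropDataset(
        crops=crops, counts=counts_arr, outlier_labels=outliers, truths=truths, times=t_arr
    )
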