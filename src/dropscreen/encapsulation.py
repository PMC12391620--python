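"""Droplet volume arithmetic and Poisson co-encapsulation statistics.

A droplet of diameter *d* holds a sphere volume π·d³/6; at the µm scale one
µm³ is 10⁻³ pL, so an 80 µm droplet holds ≈270 pL and a single cell inside it
corresponds to an effective bulk concentration of ≈3.7×10⁶ cells mL⁻¹.
Random co-encapsulation of a cell suspension at concentration *c* loads each
droplet with a Poisson(λ = c·V) number of cells, independently per cell type.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "droplet_volume",
    "equivalent_bulk_concentration",
    "poisson_lambda",
    "sample_stoichiometry",
]

_UM3_PER_PL = 1.0e3  # 1 pL = 10^3 µm^3
_PL_PER_ML = 1.0e9  # 1 mL = 10^9 pL


def droplet_volume(diameter_um: float) -> float:
    """Volume of a spherical droplet, in picolitres.

    Parameters
    ----------
    diameter_um : float
        Droplet diameter in micrometres.  Must be non-negative.
    """
    if diameter_um < 0:
        raise ValueError("droplet diameter must be non-negative")
    return float(np.pi * diameter_um**3 / 6.0 / _UM3_PER_PL)


def equivalent_bulk_concentration(cells_per_droplet: float, volume_pl: float) -> float:
    """Bulk concentration (cells·mL⁻¹) equivalent to *n* cells in one droplet."""
    if volume_pl <= 0:
        raise ValueError("droplet volume must be positive")
    if cells_per_droplet < 0:
        raise ValueError("cell count must be non-negative")
    return cells_per_droplet / volume_pl * _PL_PER_ML


def poisson_lambda(concentration_per_ml: float, diameter_um: float) -> float:
    """Mean cells per droplet for a suspension at the given concentration."""
    if concentration_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_per_ml * droplet_volume(diameter_um) / _PL_PER_ML


def sample_stoichiometry(
    conc_effector: float,
    conc_target: float,
    diameter_um: float,
    n_droplets: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw per-droplet (effector, target) cell counts under Poisson loading.

    Counts per cell type are independent Poisson with mean λ = c·V.  Returns
    an integer array of shape ``(n_droplets, 2)`` with columns
    ``(n_effectors, n_targets)``.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be at least 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    lam_e = poisson_lambda(conc_effector, diameter_um)
    lam_t = poisson_lambda(conc_target, diameter_um)
    eff = rng.poisson(lam_e, size=n_droplets)
    tgt = rng.poisson(lam_t, size=n_droplets)
    return np.stack([eff, tgt], axis=1)
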