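"""Deterministic fan-out of one master seed into named child streams.

Every stochastic stage of the pipeline (stoichiometry sampling, phenotype
assignment, waiting times, cell placement, pixel noise, sort errors, model
initialisation) draws from its own named stream so that stages are
independently reproducible: changing how many numbers one stage consumes
never perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from ``master_seed`` and a stream name."""
    tag = zlib.crc32(name.encode("utf-8"))
    mixed = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(mixed.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from the named child stream."""
    return np.random.default_rng(child_seed(master_seed, name))
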