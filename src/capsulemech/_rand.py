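"""Deterministic seed derivation for cohort generation.

A cohort is driven by a single root seed; every sample-level random stream is
derived by stable hashing of (root seed, group, animal, replicate, purpose).
Adding a new purpose tag therefore never perturbs existing streams, and the
same (config, root seed) pair always regenerates bit-identical cohorts.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for", "lognormal_with_moments"]


def derive_seed(root_seed: int, *tags) -> int:
    """Hash (root_seed, *tags) into a stable 31-bit integer seed."""
    key = "|".join([str(int(root_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_for(root_seed: int, *tags) -> np.random.Generator:
    """A dedicated numpy Generator for one (root seed, tag...) stream."""
    return np.random.default_rng(derive_seed(root_seed, *tags))


def lognormal_with_moments(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a lognormal parameterized by its arithmetic mean and SD.

    Biological quantities here (moduli, ratios, thicknesses, area fractions)
    are strictly positive, so between-animal variation is modelled lognormal;
    moment matching keeps the configured mean/SD exact.
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if sd == 0:
        return float(mean)
    s2 = np.log1p((sd / mean) ** 2)
    return float(rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2)))
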