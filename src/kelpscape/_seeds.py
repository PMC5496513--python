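"""Deterministic per-stage seed derivation.

A single master seed spawns independent streams for every named stage (and
optional sub-keys such as site id or repeat index) through a counter-based
``SeedSequence`` derivation, so adding a stage or reordering execution never
perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_hash(key) -> int:
    return zlib.crc32(str(key).encode("utf8"))


def seed_sequence(master_seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence for a stage identified by a hashable key path."""
    entropy = [int(master_seed)] + [_key_hash(k) for k in keys]
    return np.random.SeedSequence(entropy)


def rng_for(master_seed: int, *keys) -> np.random.Generator:
    """Independent Generator for ``(master_seed, *keys)``."""
    return np.random.default_rng(seed_sequence(master_seed, *keys))


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stage_seed_int(master_seed: int, *keys) -> int:
    """A plain 31-bit integer seed for libraries that want one (manifests,
    sklearn ``random_state``)."""
    return int(seed_sequence(master_seed, *keys).generate_state(1)[0] % (2**31))
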