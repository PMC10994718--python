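"""Deterministic seed derivation.

Every stochastic stage draws its generator from the master seed plus a path of
string/int tags, so adding a stage never perturbs the randomness of earlier
stages and identical (seed, path) pairs always reproduce byte-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _spawn_key(tags: tuple) -> tuple[int, ...]:
    key = []
    for tag in tags:
        if isinstance(tag, (int, np.integer)):
            key.append(int(tag) & 0xFFFFFFFF)
        else:
            key.append(zlib.crc32(str(tag).encode("utf-8")))
    return tuple(key)


def derive_seed(master_seed: int, *tags) -> int:
    """A 31-bit child seed derived deterministically from master_seed and tags."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_spawn_key(tags))
    return int(ss.generate_state(1)[0]) % (2**31)


def derive_rng(master_seed: int, *tags) -> np.random.Generator:
    """A Generator whose stream depends only on (master_seed, tags)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_spawn_key(tags))
    return np.random.default_rng(ss)
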