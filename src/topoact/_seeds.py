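"""Named seed substreams.

All randomness in a run flows from one top-level integer seed. Each
pipeline stage draws from a named substream so that adding or reordering
stages never perturbs the random numbers of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.SeedSequence:
    """Return a SeedSequence for stage ``name`` derived from ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def substream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream(seed, name))


def child_seed_ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    """Draw ``n`` independent 31-bit integer seeds from a SeedSequence."""
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)]
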