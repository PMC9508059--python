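"""Deterministic seed fan-out.

One master seed is expanded into independent substreams keyed on
``(stage, subject, run, ...)``.  Because the key — not the number of
consumers — identifies a stream, adding subjects to a cohort never
perturbs the streams of existing subjects.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def _key_part(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def seed_sequence(master_seed: int, *key) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``key``."""
    return np.random.SeedSequence(
        int(master_seed), spawn_key=tuple(_key_part(p) for p in key)
    )


def substream(master_seed: int, *key) -> np.random.Generator:
    """Independent Generator for the substream identified by ``key``."""
    return np.random.default_rng(seed_sequence(master_seed, *key))


def child_seed(master_seed: int, *key) -> int:
    """A plain integer seed (< 2**31) derived from the keyed substream."""
    state = seed_sequence(master_seed, *key).generate_state(1, np.uint32)
    return int(state[0]) % MAX_SEED
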