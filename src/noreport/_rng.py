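"""Seed fan-out helpers.

Every stochastic stage derives its generator from a single top-level seed via
named substreams, so toggling one stage never perturbs another stage's draws.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _keys(names: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(n).encode("utf8")) for n in names)


def substream(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same (seed, names) pair always yields an identical stream; distinct
    name paths yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=_keys(names))
    return np.random.default_rng(ss)


def spawn_seed(seed: int, *names) -> int:
    """Derive a deterministic 31-bit child seed (for libraries taking ints)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_keys(names))
    return int(ss.generate_state(1)[0] % (2**31))
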