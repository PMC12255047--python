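"""Named random substreams.

Every simulation stage (global ancestry, local ancestry, alleles, traits,
mating, ...) draws from its own `numpy.random.Generator` derived from a single
run seed, so a stage can be re-run independently without disturbing the
others.  Substreams are keyed by name, not by spawn order, so adding a stage
never reshuffles existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key(name: str) -> int:
    # stable 32-bit key; Python's hash() is salted per process
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for stage `name` of run `seed`."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),))
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for stage `name` of run `seed`."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
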