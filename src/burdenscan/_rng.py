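"""Named random substreams derived from one master seed.

Every stochastic component (simulation, MCMC, GA, permutations) draws from
its own substream so runs are reproducible component-by-component: the
same master seed always yields the same simulation regardless of how many
searches preceded it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _tag_entropy(tag: str | int) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    return zlib.crc32(str(tag).encode())


def derive_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """A Generator keyed by (seed, tags); stable across runs and platforms."""
    entropy = [int(seed)] + [_tag_entropy(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *tags: str | int) -> int:
    """A 31-bit integer seed keyed by (seed, tags)."""
    entropy = [int(seed)] + [_tag_entropy(t) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
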