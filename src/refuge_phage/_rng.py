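"""Deterministic random-stream derivation.

One root seed per run; every module/replicate derives an independent child
stream from it so that reruns with the same config are bit-identical while
replicates stay statistically independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *keys)``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def child_seed(seed: int, *keys: int) -> int:
    """Derive a 31-bit integer seed (for RNGs that take a plain int)."""
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
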