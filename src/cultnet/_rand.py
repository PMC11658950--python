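"""Seed handling: one integer seed drives counter-based (Philox) generators."""

from __future__ import annotations

import numpy as np


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    """A Philox-backed Generator; passing a Generator returns it unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(key=int(seed)))


def child_seed(seed: int, stream: int) -> int:
    """Derive a per-stage seed from a master seed, stable across runs."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream),))
    return int(ss.generate_state(1)[0] % (2**31 - 1))
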