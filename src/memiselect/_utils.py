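"""Seed bookkeeping shared by every stochastic stage.

Every module derives its random state from a master seed plus a string
path naming the stage (e.g. ``("tlearner", "post", "arm1", "fold", 3)``),
so that stages are decoupled: changing how many draws one stage consumes
never perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master: int, *keys) -> int:
    """Derive a stable 31-bit seed from a master seed and a key path."""
    tag = zlib.crc32("::".join(str(k) for k in keys).encode("utf-8"))
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master: int, *keys) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded from the derived seed."""
    return np.random.default_rng(derive_seed(master, *keys))
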