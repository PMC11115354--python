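"""Deterministic seed substreams.

All randomness in the package flows from a single master seed through named
substreams, so that any stage (corpus synthesis, weight init, epoch sampling,
MCMC, manifold sampling) can be re-run in isolation and still reproduce the
values it produced inside the full pipeline.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    digest = hashlib.blake2s(str(tag).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def seed_sequence(master_seed: int, *tags) -> np.random.SeedSequence:
    """SeedSequence for the substream named by ``tags`` under ``master_seed``."""
    return np.random.SeedSequence([int(master_seed)] + [_tag_to_int(t) for t in tags])


def substream(master_seed: int, *tags) -> np.random.Generator:
    """Independent PCG64 generator for the named substream."""
    return np.random.Generator(np.random.PCG64(seed_sequence(master_seed, *tags)))


def child_seed(master_seed: int, *tags) -> int:
    """A plain integer seed (< 2**31) derived from the named substream."""
    return int(seed_sequence(master_seed, *tags).generate_state(1)[0] % (2**31))
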