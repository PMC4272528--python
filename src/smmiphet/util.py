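"""Small shared helpers: named random substreams."""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, *names) -> np.random.Generator:
    """Return a Generator on a named substream of a master seed.

    Every stage of the simulator and pipeline draws from its own substream so
    that, e.g., changing the error model does not perturb which molecules are
    sampled.  The stream key is derived by hashing the stage names, so streams
    are independent of call order.
    """
    key = tuple(
        int.from_bytes(hashlib.blake2b(str(n).encode(), digest_size=4).digest(), "big")
        for n in names
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def stable_int_hash(text: str) -> int:
    """Deterministic 63-bit hash of a string (stable across runs/platforms)."""
    digest = hashlib.blake2b(text.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") >> 1
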