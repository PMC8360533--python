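"""Deterministic child-seed derivation.

Every stochastic operation in the package is a pure function of its inputs
and an integer seed.  Sub-computations (CV repetitions, inner tuning loops,
bootstrap draws) get their own streams derived by hashing
(master seed, purpose tag, index), so adding repetitions or reordering
execution never perturbs earlier streams.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_from"]

_MOD = 2**31  # derived seeds stay valid for any consumer expecting < 2^31


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) % _MOD
    digest = hashlib.blake2b(str(tag).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def child_seed(master: int, *tags: object) -> int:
    """Derive a reproducible child seed from a master seed and purpose tags."""
    entropy = [int(master) % _MOD] + [_tag_to_int(t) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0]) % _MOD


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
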