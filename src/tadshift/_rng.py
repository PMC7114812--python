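"""Deterministic seed derivation.

All randomness in the package flows from a single top-level integer seed;
every stage derives its own sub-seed from that seed plus a stage key, so
stages can be re-run in isolation with identical results.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, *keys: int | str) -> int:
    """Derive a stage sub-seed (< 2**31) from a top-level seed and keys."""
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))
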