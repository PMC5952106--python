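"""Deterministic seed splitting.

A single root seed drives every stochastic component; child streams are
derived with :class:`numpy.random.SeedSequence` keyed on small integers
and stable string hashes, so per-dataset / per-imputation streams are
independent and bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(k) -> int:
    if isinstance(k, (int, np.integer)):
        return int(k) & 0xFFFFFFFF
    return zlib.crc32(str(k).encode())


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Generator for the stream identified by ``(seed, *keys)``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [_key(k) for k in keys]))


def child_int_seed(seed: int, *keys) -> int:
    """A 31-bit integer seed derived from ``(seed, *keys)`` (for sklearn)."""
    ss = np.random.SeedSequence([int(seed)] + [_key(k) for k in keys])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
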