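"""Counter-based uniform random streams.

All stochastic stages (schedule shuffles, choice sampling, cohort
generation) draw uniforms from a splitmix64-style hash of
``(seed, index...)`` tuples.  Unlike a stateful generator, a
counter-based stream is vectorizable and partition-invariant: results
are bit-identical no matter how a grid is chunked across workers, and
any single subject can be replayed from its recorded seed alone.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / float(1 << 53)


def _mix(h: np.ndarray) -> np.ndarray:
    h = (h + _GOLDEN) & np.uint64(0xFFFFFFFFFFFFFFFF)
    h ^= h >> np.uint64(30)
    h *= _M1
    h ^= h >> np.uint64(27)
    h *= _M2
    h ^= h >> np.uint64(31)
    return h


def hash_u64(seed: int, *keys) -> np.ndarray:
    """Combine ``seed`` and integer key arrays into mixed 64-bit hashes.

    Keys broadcast against each other; the result has the broadcast shape.
    """
    with np.errstate(over="ignore"):
        h = _mix(np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
        for k in keys:
            k = np.asarray(k, dtype=np.uint64)
            h = _mix(h ^ (k * _GOLDEN))
    return h


def u01(seed: int, *keys) -> np.ndarray:
    """Uniform(0, 1) doubles keyed by ``(seed, keys...)``; 53-bit mantissa."""
    return (hash_u64(seed, *keys) >> np.uint64(11)) * _INV53


def derive_seed(seed: int, *keys) -> int:
    """A stable 31-bit child seed for nested components."""
    return int(hash_u64(seed, *keys) & np.uint64(0x7FFFFFFF))
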