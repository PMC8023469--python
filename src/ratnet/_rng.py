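"""Counter-based per-run seed derivation for reproducible simulation.

Each Monte-Carlo replicate of each problem gets its own 31-bit seed,
derived with a splitmix64 chain from (master seed, problem key, run
index).  Replicates are therefore independent of execution order and of
how runs are batched, which is what makes common-random-number coupling
across step budgets and bit-identical re-runs possible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["problem_key", "derive_run_seeds", "spawn_seed"]

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)


def _splitmix64(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # uint64 wraparound is the point
        z = (z + _C1).astype(np.uint64)
        z = ((z ^ (z >> np.uint64(30))) * _C2).astype(np.uint64)
        z = ((z ^ (z >> np.uint64(27))) * _C3).astype(np.uint64)
        return (z ^ (z >> np.uint64(31))).astype(np.uint64)


def problem_key(problem_id: str) -> int:
    """Stable 32-bit key for a problem id (CRC-32 of its UTF-8 bytes)."""
    return zlib.crc32(str(problem_id).encode("utf-8"))


def derive_run_seeds(
    master_seed: int, key: int, n_runs: int, *, start: int = 0
) -> np.ndarray:
    """Seeds (int64, each < 2**31) for runs ``start .. start + n_runs - 1``."""
    z0 = _splitmix64(np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF))
    z1 = _splitmix64(z0 ^ np.uint64(key & 0xFFFFFFFFFFFFFFFF))
    runs = np.arange(start, start + n_runs, dtype=np.uint64)
    s = _splitmix64(z1 ^ (runs * _C1).astype(np.uint64))
    return (s & np.uint64(0x7FFFFFFF)).astype(np.int64)


def spawn_seed(master_seed: int, tag: str) -> int:
    """An independent 31-bit stream seed derived from a master seed and a label."""
    z = _splitmix64(np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF))
    z = _splitmix64(z ^ np.uint64(zlib.crc32(tag.encode("utf-8"))))
    return int(z & np.uint64(0x7FFFFFFF))
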