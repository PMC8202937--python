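"""Seed plumbing and stage logging helpers.

All randomness flows from one top-level seed.  Stages derive independent
substreams with :func:`substream`, which hashes the seed together with a
stage name and optional integer indices via ``numpy.random.SeedSequence`` —
reordering or skipping stages therefore never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from typing import Iterator

import numpy as np

logger = logging.getLogger("hipponet")


def _stage_key(name: str) -> int:
    """Stable 32-bit key for a stage name."""
    digest = hashlib.sha256(name.encode()).digest()
    return int.from_bytes(digest[:4], "little")


def substream(seed: int, stage: str, *indices: int) -> np.random.Generator:
    """Independent generator for (seed, stage, indices...)."""
    ss = np.random.SeedSequence([int(seed), _stage_key(stage), *map(int, indices)])
    return np.random.default_rng(ss)


def child_seeds(seed: int, stage: str, n: int) -> np.ndarray:
    """n deterministic 31-bit child seeds for a stage."""
    rng = substream(seed, stage)
    return rng.integers(0, 2**31 - 1, size=n)


def array_hash(arr: np.ndarray) -> str:
    """Short content hash of an array, for stage-log provenance."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


@contextmanager
def stage_log(stage: str, **params: object) -> Iterator[None]:
    """One log line per stage: input hash, parameters, runtime."""
    t0 = time.perf_counter()
    yield
    dt = time.perf_counter() - t0
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s %s runtime_s=%.2f", stage, kv, dt)
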