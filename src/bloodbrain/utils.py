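"""Seeding and logging helpers.

Every stochastic stage (fold assignment, permutations, simulation, inner
CV) draws from its own substream derived deterministically from the run's
root seed, so individual stages are reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from typing import Iterator

import numpy as np

__all__ = ["substream", "subseed", "stage_timer"]

logger = logging.getLogger("bloodbrain")


def _tag_to_int(tag: str) -> int:
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, *tags: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``tags``.

    The same ``(seed, tags)`` pair always yields the same stream, and
    distinct tags yield statistically independent streams.
    """
    entropy = [int(seed)] + [
        t if isinstance(t, int) else _tag_to_int(t) for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subseed(seed: int, *tags: str | int) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain ints."""
    entropy = [int(seed)] + [
        t if isinstance(t, int) else _tag_to_int(t) for t in tags
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@contextmanager
def stage_timer(stage: str) -> Iterator[None]:
    t0 = time.perf_counter()
    logger.info("%s: started", stage)
    try:
        yield
    finally:
        logger.info("%s: finished in %.2fs", stage, time.perf_counter() - t0)
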