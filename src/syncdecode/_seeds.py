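"""Deterministic stream splitting.

Every stochastic routine in the package receives an integer seed and derives
independent substreams from it by hashing a tag path into a
``numpy.random.SeedSequence``.  The scheme is documented so that any stage of
a run can be reproduced in isolation: ``child_rng(master, "cohort", "s3",
"c1")`` always yields the same generator for the same master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng", "derive_seed"]


def _tag_words(tags: tuple) -> list[int]:
    words = []
    for t in tags:
        words.append(zlib.crc32(str(t).encode("utf8")) & 0xFFFFFFFF)
    return words


def child_seed_sequence(master_seed: int, *tags) -> np.random.SeedSequence:
    """SeedSequence for the stream named by ``tags`` under ``master_seed``."""
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_tag_words(tags)])


def child_rng(master_seed: int, *tags) -> np.random.Generator:
    """Generator for the stream named by ``tags`` under ``master_seed``."""
    return np.random.default_rng(child_seed_sequence(master_seed, *tags))


def derive_seed(master_seed: int, *tags) -> int:
    """A plain integer seed (< 2**31) for APIs that want one."""
    return int(child_seed_sequence(master_seed, *tags).generate_state(1)[0] & 0x7FFFFFFF)
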