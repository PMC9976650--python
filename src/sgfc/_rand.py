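"""Seed-derivation scheme.

All randomness in the package flows from a single integer seed.  Each
stochastic stage derives an independent generator from (seed, stage-tag)
via :class:`numpy.random.SeedSequence`, so stages can be re-run in
isolation and adding a stage never perturbs the streams of the others.
No global random state is ever touched.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key(seed: int, tags: tuple) -> list[int]:
    out = [int(seed) & 0xFFFFFFFF]
    for t in tags:
        if isinstance(t, str):
            out.append(zlib.crc32(t.encode("utf-8")))
        else:
            out.append(int(t) & 0xFFFFFFFF)
    return out


def derive_rng(seed: int, *tags) -> np.random.Generator:
    """Generator for stage `tags`, deterministic in (seed, tags)."""
    return np.random.default_rng(np.random.SeedSequence(_key(seed, tags)))


def derive_seed(seed: int, *tags) -> int:
    """A 31-bit integer sub-seed for stage `tags`."""
    return int(np.random.SeedSequence(_key(seed, tags)).generate_state(1)[0] >> 1)
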