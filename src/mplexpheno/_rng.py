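"""Deterministic random-stream management.

A single global seed fans out to per-stage substreams with fixed string
labels, so that changing one stage's draws never perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_key(label: str) -> int:
    # CRC32 is stable across platforms and Python versions.
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stage `label` derived from the global `seed`.

    The same (seed, label) pair always yields an identical stream;
    distinct labels yield statistically independent streams.
    """
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(_label_key(label),))
    return np.random.default_rng(ss)
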