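"""Seed plumbing: named substreams derived from one master seed.

Every stage of the pipeline (schedule, ratings, choices, neural, bootstrap)
draws from its own generator so that any stage can be re-run in isolation
and still reproduce byte-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit seed for a named pipeline stage."""
    return (int(master_seed) ^ zlib.crc32(stage.encode("utf-8"))) & 0x7FFFFFFF


def substream(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for stage ``stage`` (optionally one per subject via ``index``)."""
    return np.random.default_rng([stage_seed(master_seed, stage), int(index)])
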