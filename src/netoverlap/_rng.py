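"""Seed derivation.

Every stochastic stage gets its own generator, forked from the run seed by a
fixed string label, so adding or reordering stages never perturbs the draws
of another stage.
"""
from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a sequence of stage labels."""
    entropy = [int(seed)] + [zlib.crc32(label.encode("utf-8")) for label in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
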