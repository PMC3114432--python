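"""Deterministic substream derivation from a single master seed.

Every stochastic component derives its generator from the master seed plus a
stable string label, so adding entities (genes, operons, restarts) never
reshuffles the streams of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(master_seed: int, *labels: object) -> int:
    """A stable 63-bit integer seed derived from ``master_seed`` and labels."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for lab in labels:
        h.update(b"\x1f")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:8], "big") >> 1


def substream(master_seed: int, *labels: object) -> np.random.Generator:
    """Independent ``numpy`` generator for the (master seed, labels) pair."""
    return np.random.default_rng(subseed(master_seed, *labels))
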