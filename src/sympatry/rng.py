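"""Deterministic random-stream management.

A single master seed fans out to named substreams so that every layer of
the synthetic study system (demography, climate, landscape, movement, ...)
draws from its own independent stream.  Adding a new layer never perturbs
the draws of existing layers.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a layer name.

    Uses SHA-256 of ``"{master_seed}/{name}"`` so the mapping is stable
    across processes and Python versions (unlike ``hash``).
    """
    digest = hashlib.sha256(f"{int(master_seed)}/{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a ``numpy`` Generator for the named substream."""
    return np.random.default_rng(child_seed(master_seed, name))
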