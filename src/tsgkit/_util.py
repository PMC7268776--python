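"""Small shared helpers."""
from __future__ import annotations

import hashlib
import math
from pathlib import Path

import numpy as np


def nearest_rank_quantile(values, q: float) -> float:
    """Empirical quantile by the nearest-rank method.

    Returns the element at rank ``ceil(q * n)`` (1-based) of the sorted
    sample; ``q = 0`` maps to the minimum.  No interpolation, so the result
    is always an observed value — thresholds derived from it keep the
    "ties included" semantics well defined.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"quantile must be in [0, 1], got {q}")
    rank = max(1, math.ceil(q * arr.size))
    return float(arr[rank - 1])


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def fmt_float(x: float) -> str:
    """Format a number with 12 significant digits (round-trip stable)."""
    return f"{x:.12g}"
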