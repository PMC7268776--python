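"""Hypergeometric over-representation analysis (ORA).

The upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n) is the
enrichment p-value of observing k query genes inside a K-gene annotated set
when n query genes are drawn from an N-gene background.  Point masses are
summed in log space so deeply significant overlaps do not underflow.
Multiple testing is corrected with Benjamini-Hochberg step-up adjustment.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom as _hg

from tsgkit.formats import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the number of annotated genes in the
    background, n the query size, k the observed overlap.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if k > min(K, n):
        raise ValueError("k must not exceed min(K, n)")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = _hg.logpmf(support, N, K, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Idempotent and order-invariant; adjusted values are monotone in the raw
    p-values and never below them.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(monotone, 1.0)
    return adj


def _prepare(query: Iterable[str], background: Iterable[str]):
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    q = set(query) & bg
    if not q:
        raise ValueError("query is empty after intersecting with the background")
    return q, bg


def ora(
    collection: GeneSetCollection,
    query: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Over-representation test of a query gene set against a collection.

    Genes outside the background are dropped from both the query and the
    sets before counting.  One row per set with >= 1 background member;
    ``significant`` flags adjusted p < alpha when ``use_adjusted`` (the GO
    convention) or raw p < alpha otherwise (the GSEA/TF convention).
    """
    q, bg = _prepare(query, background)
    rows = []
    for gs in collection:
        members = set(gs.genes) & bg
        if not members:
            continue
        k = len(members & q)
        rows.append(
            (
                gs.set_id,
                gs.description,
                k,
                len(members),
                len(q),
                len(bg),
                hypergeom_upper_tail(k, len(members), len(q), len(bg)),
            )
        )
    if not rows:
        raise ValueError("no gene set has members inside the background")
    df = pd.DataFrame(
        rows, columns=["set_id", "description", "k", "K", "n", "N", "p_value"]
    )
    df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    crit = df["adjusted_p"] if use_adjusted else df["p_value"]
    df["significant"] = crit < alpha
    return df.sort_values(["p_value", "set_id"], kind="mergesort", ignore_index=True)


def tf_enrichment(
    tf_targets: Mapping[str, Iterable[str]],
    query: Iterable[str],
    background: Iterable[str],
    contrast: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-transcription-factor target-set over-representation.

    A TF is ``associated`` with the query at raw p < alpha.  When a
    ``contrast`` gene set is given (e.g. the non-specific genes), the
    ``selective`` column flags TFs associated with the query and not with
    the contrast.  TFs with empty target sets are skipped with a warning.
    """
    q, bg = _prepare(query, background)
    c = None
    if contrast is not None:
        c = set(contrast) & bg
        if not c:
            raise ValueError("contrast set is empty after background intersection")
    rows = []
    for tf in sorted(tf_targets):
        targets = set(tf_targets[tf]) & bg
        if not targets:
            logger.warning("TF %s has no targets inside the background; skipped", tf)
            continue
        k = len(targets & q)
        p = hypergeom_upper_tail(k, len(targets), len(q), len(bg))
        row = {
            "motif_id": tf,
            "k": k,
            "K": len(targets),
            "n": len(q),
            "N": len(bg),
            "p_value": p,
            "associated": p < alpha,
        }
        if c is not None:
            pc = hypergeom_upper_tail(len(targets & c), len(targets), len(c), len(bg))
            row["p_contrast"] = pc
            row["selective"] = (p < alpha) and (pc >= alpha)
        rows.append(row)
    if not rows:
        raise ValueError("no TF has targets inside the background")
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "motif_id"], kind="mergesort", ignore_index=True)
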