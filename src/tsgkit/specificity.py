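"""Tissue-specificity index (tau) and tissue-specific gene calling.

The tissue-specificity index for a gene with replicate-averaged abundances
x_1..x_N over N organs is

    tau = sum_i [ 1 - log2(x_i + 1) / log2(x_max + 1) ] / (N - 1)

with x_max = max_i x_i.  tau is 0 for a perfectly uniform positive profile
and 1 when expression is confined to a single organ.  Genes are called
specific to a tissue when three filters hold simultaneously: tau in the top
fraction of the retained-gene distribution (default top 20%, nearest-rank
threshold with ties included), abundance >= 1 FPKM in the tissue, and the
tissue ranking in the top ``rank_k`` (default 3) by abundance, where rank is
the strictly-greater count so ties never disqualify a tissue.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tsgkit._util import nearest_rank_quantile
from tsgkit.formats import ExpressionTable
from tsgkit.stats import chi2_2x2

logger = logging.getLogger(__name__)


def average_replicates(
    table: ExpressionTable,
    species: str | None = None,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse replicate samples to a gene x tissue matrix by arithmetic mean.

    Parameters
    ----------
    table:
        Expression table with sample metadata.
    species:
        Restrict to samples of this species (required when the table mixes
        species).
    tissues:
        When given, assert that each requested tissue has at least one
        sample; a tissue with zero samples raises ``ValueError`` naming it.
    """
    meta = table.samples
    if species is not None:
        meta = meta[meta["species"] == species]
        if meta.empty:
            raise ValueError(f"no samples for species {species!r}")
    present = set(meta["tissue"])
    if tissues is not None:
        missing = [t for t in tissues if t not in present]
        if missing:
            raise ValueError(f"tissue(s) without samples: {missing}")
    sub = table.values[list(meta.index)]
    out = sub.T.groupby(meta["tissue"]).mean().T
    out.index.name = "gene_id"
    out.columns.name = "tissue"
    return out


def compute_tau(profile) -> float:
    """Tissue-specificity index of a single replicate-averaged profile.

    The profile must span at least two tissues and must not be all-zero
    (non-expressed genes are discarded before scoring).
    """
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("profile must be a 1-D vector over >= 2 tissues")
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise ValueError("abundances must be finite and >= 0")
    x_max = arr.max()
    if x_max <= 0:
        raise ValueError("all-zero profile; filter non-expressed genes first")
    terms = 1.0 - np.log2(arr + 1.0) / np.log2(x_max + 1.0)
    return float(terms.sum() / (arr.size - 1))


def tau_table(matrix: pd.DataFrame) -> pd.Series:
    """Vectorized tau over a gene x tissue matrix (no all-zero rows)."""
    arr = matrix.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need at least two tissues")
    x_max = arr.max(axis=1)
    if (x_max <= 0).any():
        raise ValueError("matrix contains all-zero gene rows; filter first")
    terms = 1.0 - np.log2(arr + 1.0) / np.log2(x_max + 1.0)[:, None]
    return pd.Series(terms.sum(axis=1) / (arr.shape[1] - 1), index=matrix.index, name="tau")


@dataclass
class SpecificityResult:
    """Per-gene tau plus tissue-specific calls.

    ``per_gene`` is indexed by gene id with columns ``tau``, ``x_max`` and
    ``argmax_tissue``; ``calls`` holds one row per (gene, tissue) call with
    the gene's tau, the abundance in the tissue, and the 1-based rank
    (strictly-greater count + 1).  ``tau_threshold`` is the realized
    top-fraction cutoff; genes exactly at the threshold are included.
    """

    per_gene: pd.DataFrame
    calls: pd.DataFrame
    tau_threshold: float
    n_dropped_all_zero: int
    params: dict = field(default_factory=dict)

    def genes_for(self, tissue: str) -> list[str]:
        sub = self.calls[self.calls["tissue"] == tissue]
        return sorted(sub["gene_id"])

    def assigned(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, tissue in zip(self.calls["gene_id"], self.calls["tissue"]):
            out.setdefault(gene, []).append(tissue)
        return out


def call_tissue_specific(
    matrix: pd.DataFrame,
    top_frac: float = 0.20,
    min_fpkm: float = 1.0,
    rank_k: int = 3,
) -> SpecificityResult:
    """Call tissue-specific genes from a replicate-averaged matrix.

    A gene is specific to tissue ``t`` iff (a) its tau is at or above the
    nearest-rank ``(1 - top_frac)`` quantile of tau over retained genes,
    (b) its abundance in ``t`` is >= ``min_fpkm``, and (c) fewer than
    ``rank_k`` tissues have strictly greater abundance.  A gene may be
    specific to several tissues (up to ``rank_k``).
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    if rank_k < 1:
        raise ValueError("rank_k must be >= 1")
    arr = matrix.to_numpy(dtype=float)
    nonzero = arr.max(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero genes before tau", n_dropped)
    matrix = matrix.loc[nonzero]
    arr = arr[nonzero]
    if arr.shape[0] == 0:
        raise ValueError("no genes retained after removing all-zero rows")

    taus = tau_table(matrix)
    threshold = nearest_rank_quantile(taus.to_numpy(), 1.0 - top_frac)
    candidate = taus.to_numpy() >= threshold

    # strictly-greater counts per (gene, tissue)
    greater = (arr[:, :, None] < arr[:, None, :]).sum(axis=2)  # genes x tissues
    call_mask = candidate[:, None] & (arr >= min_fpkm) & (greater < rank_k)

    argmax = arr.argmax(axis=1)
    per_gene = pd.DataFrame(
        {
            "tau": taus,
            "x_max": arr.max(axis=1),
            "argmax_tissue": [matrix.columns[j] for j in argmax],
        },
        index=matrix.index,
    )
    per_gene.index.name = "gene_id"

    gi, tj = np.nonzero(call_mask)
    calls = pd.DataFrame(
        {
            "gene_id": matrix.index[gi],
            "tissue": matrix.columns[tj],
            "tau": taus.to_numpy()[gi],
            "abundance": arr[gi, tj],
            "rank": greater[gi, tj] + 1,
        }
    ).sort_values(["gene_id", "tissue"], kind="mergesort", ignore_index=True)
    return SpecificityResult(
        per_gene,
        calls,
        float(threshold),
        n_dropped,
        {"top_frac": top_frac, "min_fpkm": min_fpkm, "rank_k": rank_k},
    )


def transcription_breadth(
    matrix: pd.DataFrame,
    focal_tissue: str,
    threshold: float = 0.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Count transcribed genes per tissue and chi-square-test each against a
    focal tissue.

    A gene counts as transcribed in a tissue iff its abundance is strictly
    greater than ``threshold`` (default 0).  For every non-focal tissue a
    2x2 table (transcribed / not, focal vs other) is tested with the Pearson
    chi-square statistic without continuity correction (1 df).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if focal_tissue not in matrix.columns:
        raise ValueError(f"focal tissue {focal_tissue!r} absent from matrix")
    counts = (matrix > threshold).sum(axis=0)
    counts.name = "n_transcribed"
    n = matrix.shape[0]
    a = int(counts[focal_tissue])
    rows = []
    for tissue in matrix.columns:
        if tissue == focal_tissue:
            continue
        b = int(counts[tissue])
        res = chi2_2x2(np.array([[a, n - a], [b, n - b]]))
        rows.append((tissue, b, res.statistic, res.p_value))
    tests = pd.DataFrame(rows, columns=["tissue", "n_transcribed", "chi2", "p_value"])
    return counts, tests
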