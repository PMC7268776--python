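"""Alternative-splicing presence summaries and isoform contribution rates.

An event is present in a tissue iff its PSI lies in [5, 95] (inclusive;
missing PSI means absent).  Per-gene splicing counts deduplicate events:
a gene counts for a (tissue, event type) cell iff at least one of its
events of that type is present in that tissue.  The contribution rate of a
gene's dominant isoform in a tissue is FPKM_top_isoform / (FPKM_gene + 1);
only genes with >= 2 isoforms are scored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tsgkit.formats import EVENT_TYPES, IsoformTable, PsiTable
from tsgkit.specificity import SpecificityResult, call_tissue_specific

logger = logging.getLogger(__name__)


def event_presence(psi: PsiTable, lo: float = 5.0, hi: float = 95.0) -> pd.DataFrame:
    """Flag per-row presence: ``lo <= psi <= hi`` inclusive; missing -> absent."""
    df = psi.df.copy()
    vals = df["psi"]
    df["present"] = vals.notna() & (vals >= lo) & (vals <= hi)
    return df


@dataclass
class SplicingSummary:
    """Gene-level splicing counts.

    ``per_tissue``: number of genes with >= 1 present event per tissue.
    ``per_tissue_type``: tissue x event-type gene counts.
    ``type_proportions``: fraction of spliced genes affected by each event
    type, over genes with >= 1 present event anywhere (the denominator is
    recorded in ``n_spliced_genes``).
    """

    per_tissue: pd.Series
    per_tissue_type: pd.DataFrame
    type_proportions: pd.Series
    n_spliced_genes: int
    n_events_present: int


def count_spliced_genes(psi: PsiTable, lo: float = 5.0, hi: float = 95.0) -> SplicingSummary:
    df = event_presence(psi, lo, hi)
    present = df[df["present"]]
    per_tissue = (
        present.groupby("tissue")["gene_id"].nunique().astype(int).sort_index()
    )
    per_tissue.name = "n_genes"
    cell = (
        present.groupby(["tissue", "event_type"])["gene_id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=list(EVENT_TYPES), fill_value=0)
        .sort_index()
    )
    spliced_genes = present["gene_id"].unique()
    denom = len(spliced_genes)
    by_type = present.groupby("event_type")["gene_id"].nunique()
    props = pd.Series(
        {t: (by_type.get(t, 0) / denom if denom else np.nan) for t in EVENT_TYPES},
        name="proportion",
    )
    return SplicingSummary(
        per_tissue=per_tissue,
        per_tissue_type=cell,
        type_proportions=props,
        n_spliced_genes=denom,
        n_events_present=int(present["event_id"].nunique()),
    )


def contribution_rates(
    isoforms: IsoformTable,
    gene_matrix: pd.DataFrame,
    gene_set=None,
    rel_tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.Series]:
    """Dominant-isoform contribution rates for multi-isoform genes.

    For each gene in ``gene_set`` (default: all genes in the isoform table)
    with >= 2 isoforms, the most highly expressed isoform is selected per
    tissue (ties broken by lexicographic isoform id) and the rate
    FPKM_top / (FPKM_gene + 1) computed.  Gene abundance is taken from
    ``gene_matrix`` when it matches the isoform sum within ``rel_tol``
    (relative); otherwise the isoform sum wins and a warning is logged,
    which keeps the rate's upper bound F/(F+1) < 1 true by construction.

    Returns the per-record table and the per-tissue median rate.
    """
    df = isoforms.df
    if gene_set is not None:
        wanted = set(gene_set)
        missing = sorted(wanted - set(df["gene_id"]))
        if missing:
            logger.warning(
                "%d requested genes have no isoform rows; skipped (e.g. %s)",
                len(missing),
                missing[:3],
            )
        df = df[df["gene_id"].isin(wanted)]
    n_iso = df.groupby("gene_id")["isoform_id"].nunique()
    multi = set(n_iso[n_iso >= 2].index)
    df = df[df["gene_id"].isin(multi)]

    records = []
    n_mismatch = 0
    # deterministic top-isoform choice: highest fpkm, then lexicographic id
    df = df.sort_values(["gene_id", "tissue", "fpkm", "isoform_id"],
                        ascending=[True, True, False, True], kind="mergesort")
    for (gene, tissue), grp in df.groupby(["gene_id", "tissue"], sort=True):
        iso_sum = float(grp["fpkm"].sum())
        top = float(grp["fpkm"].iloc[0])
        gene_val = iso_sum
        if gene in gene_matrix.index and tissue in gene_matrix.columns:
            supplied = float(gene_matrix.at[gene, tissue])
            if abs(supplied - iso_sum) <= rel_tol * max(1.0, abs(iso_sum)):
                gene_val = supplied
            else:
                n_mismatch += 1
        rate = top / (gene_val + 1.0)
        records.append((gene, tissue, gene_val, top, int(n_iso[gene]), rate))
    if n_mismatch:
        logger.warning(
            "%d gene/tissue abundances mismatched the isoform sum; recomputed",
            n_mismatch,
        )
    rec = pd.DataFrame(
        records,
        columns=["gene_id", "tissue", "fpkm_gene", "fpkm_top", "n_isoforms", "rate"],
    )
    medians = rec.groupby("tissue")["rate"].median().sort_index()
    medians.name = "median_rate"
    return rec, medians


def transcript_specific(
    isoforms: IsoformTable,
    top_frac: float = 0.20,
    min_fpkm: float = 1.0,
    rank_k: int = 3,
) -> SpecificityResult:
    """Tissue-specificity calling at the transcript level.

    The isoform table is pivoted into a transcript x tissue matrix
    (missing combinations treated as 0) and scored with the same tau
    top-fraction, minimum-abundance and rank filters used for genes.
    """
    matrix = isoforms.df.pivot_table(
        index="isoform_id", columns="tissue", values="fpkm", fill_value=0.0
    )
    matrix.index.name = "gene_id"  # SpecificityResult is id-agnostic
    return call_tissue_specific(matrix, top_frac=top_frac, min_fpkm=min_fpkm, rank_k=rank_k)
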