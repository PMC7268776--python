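"""Promoter windows and motif-hit to TF-target mapping.

Promoters are +/- ``flank`` bp around the transcription start site; the TSS
is strand-aware (annotated gene start on '+', gene end on '-').  Motif hits
scanned on extracted promoter sequences (``window_relative`` mode, FIMO run
per promoter, sequence ids are gene ids) or on the genome (``genomic``
mode, coordinates intersected with windows, inclusive overlap) are turned
into deduplicated TF -> target-gene sets.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tsgkit.formats import GeneAnnotation, MotifHitTable

logger = logging.getLogger(__name__)


def promoter_windows(
    annotation: GeneAnnotation,
    flank: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build one promoter window per gene.

    Windows are [TSS - flank, TSS + flank], 1-based inclusive, clipped at
    position 1; when chromosome lengths are supplied the right edge is
    clipped too, otherwise it is unbounded.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    g = annotation.genes
    tss = np.where(g["strand"] == "+", g["start"], g["end"]).astype(int)
    start = np.maximum(1, tss - flank)
    end = tss + flank
    out = pd.DataFrame(
        {
            "chrom": g["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "strand": g["strand"].to_numpy(),
            "tss": tss,
        },
        index=g.index,
    )
    if chrom_lengths:
        lengths = out["chrom"].map(chrom_lengths)
        known = lengths.notna()
        out.loc[known, "end"] = np.minimum(
            out.loc[known, "end"], lengths[known].astype(int)
        )
    out.index.name = "gene_id"
    return out


def map_hits_to_targets(
    hits: MotifHitTable,
    windows: pd.DataFrame,
    mode: str = "window_relative",
    max_p: float | None = None,
) -> tuple[dict[str, set[str]], int]:
    """Convert motif hits into motif_id -> target gene sets.

    A gene is a target of a motif iff at least one hit of that motif lies
    within the gene's promoter window; interval overlap is inclusive at
    both ends.  Hits referencing unknown genes/chromosomes are skipped and
    counted.  Returns ``(targets, n_skipped)``.
    """
    if mode not in ("window_relative", "genomic"):
        raise ValueError(f"unknown coordinate mode {mode!r}")
    df = hits.df
    if max_p is not None:
        df = df[df["p_value"].notna() & (df["p_value"] <= max_p)]
    targets: dict[str, set[str]] = {}
    n_skipped = 0

    if mode == "window_relative":
        known = df["sequence_name"].isin(windows.index)
        n_skipped = int((~known).sum())
        for motif, genes in df[known].groupby("motif_id")["sequence_name"]:
            targets[str(motif)] = set(genes)
    else:
        by_chrom = {
            chrom: sub[["start", "end"]].assign(gene_id=sub.index)
            for chrom, sub in windows.groupby("chrom")
        }
        for chrom, sub in df.groupby("sequence_name"):
            wins = by_chrom.get(str(chrom))
            if wins is None:
                n_skipped += len(sub)
                continue
            hs = sub["start"].to_numpy()[:, None]
            he = sub["stop"].to_numpy()[:, None]
            ws = wins["start"].to_numpy()[None, :]
            we = wins["end"].to_numpy()[None, :]
            overlap = (hs <= we) & (he >= ws)  # inclusive at both ends
            motifs = sub["motif_id"].to_numpy()
            genes = wins["gene_id"].to_numpy()
            for i, j in zip(*np.nonzero(overlap)):
                targets.setdefault(str(motifs[i]), set()).add(str(genes[j]))
    if n_skipped:
        logger.warning("%d motif hits referenced unknown sequences; skipped", n_skipped)
    return targets, n_skipped
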