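"""Readers and writers for every external format the pipeline touches.

All inputs are plain-text tabular dialects: TSV expression matrices with a
sample-metadata sidecar, OrthoMCL ``groups.txt`` orthogroup files, GMT
gene-set collections, GTF gene annotation, FIMO-style motif-hit tables,
two/three-column interaction edge lists, PSI (percent-spliced-in) event
tables and per-isoform abundance tables.  Each reader validates the domain
invariants and hands back a light container built on pandas; downstream
modules never re-parse files.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven alternative-splicing event codes (SUPPA-style).
EVENT_TYPES = ("SE", "RI", "A5", "A3", "MX", "AF", "AL")


class FormatError(ValueError):
    """Raised when a file does not follow its declared dialect."""


class ValidationError(ValueError):
    """Raised when a well-formed file violates a domain invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """A gene x sample abundance matrix (FPKM) with sample metadata.

    ``values`` is indexed by gene identifier with one column per sample;
    ``samples`` is indexed by sample identifier with columns ``species``,
    ``tissue`` and ``replicate``.  Every matrix column must have exactly one
    metadata row; abundances are finite and non-negative; gene identifiers
    are unique.  Gene identifiers are assumed unique within a species;
    tables may hold one species or several (the metadata disambiguates).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        meta = self.samples
        for col in ("species", "tissue", "replicate"):
            if col not in meta.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        orphans = [s for s in v.columns if s not in meta.index]
        if orphans:
            raise ValidationError(f"samples without metadata: {orphans}")
        for col in ("species", "tissue"):
            bad = meta[col].isna() | (meta[col].astype(str).str.strip() == "")
            if bad.any():
                raise ValidationError(
                    f"empty {col} label for samples {meta.index[bad].tolist()}"
                )
        extra = [s for s in meta.index if s not in set(v.columns)]
        if extra:
            logger.warning("dropping %d metadata rows without matrix columns", len(extra))
        # align metadata to matrix column order
        self.samples = meta.loc[list(v.columns)]

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def species(self) -> list[str]:
        return sorted(self.samples["species"].unique())

    def tissues(self, species: str | None = None) -> list[str]:
        meta = self.samples
        if species is not None:
            meta = meta[meta["species"] == species]
        return sorted(meta["tissue"].unique())

    def subset(self, species: str) -> "ExpressionTable":
        meta = self.samples[self.samples["species"] == species]
        if meta.empty:
            raise ValidationError(f"no samples for species {species!r}")
        return ExpressionTable(self.values[list(meta.index)], meta.copy())


def read_expression(matrix_path, metadata_path) -> ExpressionTable:
    """Load a TSV expression matrix plus its sample-metadata TSV.

    The matrix has a header row of sample ids and a first column of gene
    ids.  Malformed numeric cells raise :class:`FormatError` naming the
    offending gene and sample; referential problems raise
    :class:`ValidationError`.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[int(np.argmax(bad.to_numpy()))]
            cell = raw.loc[gene, col]
            raise FormatError(
                f"non-numeric abundance {cell!r} at gene {gene!r}, sample {col!r}"
            )
        cols[col] = converted.astype(float)
    values = pd.DataFrame(cols, index=raw.index)
    values.index.name = "gene_id"

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "species", "tissue", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"sample metadata lacks columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id rows in metadata")
    meta = meta.set_index("sample_id")
    return ExpressionTable(values, meta)


# ---------------------------------------------------------------------------
# Orthogroups (OrthoMCL groups.txt dialect)
# ---------------------------------------------------------------------------

@dataclass
class OrthoGroups:
    """family_id -> species -> member gene ids; no gene in two families."""

    families: dict[str, dict[str, list[str]]]

    @property
    def species(self) -> list[str]:
        out: set[str] = set()
        for members in self.families.values():
            out.update(members)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.families)

    def genes(self, species: str) -> list[str]:
        out = []
        for members in self.families.values():
            out.extend(members.get(species, ()))
        return out


def read_orthogroups(path) -> OrthoGroups:
    """Parse an OrthoMCL ``groups.txt`` file.

    One family per line: ``FAM_ID: species|gene species|gene ...``.
    """
    families: dict[str, dict[str, list[str]]] = {}
    seen: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"line {lineno}: missing ':' family separator")
            fam, _, rest = line.partition(":")
            fam = fam.strip()
            tokens = rest.split()
            if not fam or not tokens:
                raise FormatError(f"line {lineno}: empty family id or member list")
            if fam in families:
                raise ValidationError(f"family {fam!r} appears twice")
            members: dict[str, list[str]] = {}
            for tok in tokens:
                if "|" not in tok:
                    raise FormatError(
                        f"line {lineno}: member token {tok!r} lacks 'species|gene'"
                    )
                sp, _, gene = tok.partition("|")
                if not sp or not gene:
                    raise FormatError(f"line {lineno}: malformed member {tok!r}")
                key = (sp, gene)
                if key in seen:
                    raise ValidationError(
                        f"gene {sp}|{gene} in families {seen[key]!r} and {fam!r}"
                    )
                seen[key] = fam
                members.setdefault(sp, []).append(gene)
            families[fam] = members
    return OrthoGroups(families)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __iter__(self):
        return iter(self.sets.values())


def read_gmt(path) -> GeneSetCollection:
    """Load a tab-separated GMT file: set_id, description, members...

    Duplicate members within one line are deduplicated with a logged
    warning — over-representation counts must be over unique genes.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 tab-separated fields")
            set_id, desc = fields[0], fields[1]
            if set_id in sets:
                raise ValidationError(f"duplicate gene set id {set_id!r}")
            members: list[str] = []
            dupes = 0
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dupes += 1
                    continue
                seen.add(g)
                members.append(g)
            if dupes:
                logger.warning(
                    "gene set %s: %d duplicate members deduplicated", set_id, dupes
                )
            if not members:
                raise ValidationError(f"gene set {set_id!r} has no members")
            sets[set_id] = GeneSet(set_id, desc, tuple(members))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# FIMO-style motif hits
# ---------------------------------------------------------------------------

@dataclass
class MotifHitTable:
    """Rows of (motif_id, sequence_name, start, stop, strand, score, p_value)."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


def read_motif_hits(path) -> MotifHitTable:
    """Read a FIMO TSV hit table; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [re.sub(r"[-\s]", "_", str(c)).lower() for c in df.columns]
    required = ["motif_id", "sequence_name", "start", "stop", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"motif hit table lacks columns {missing}")
    for col in ("score", "p_value"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[required + ["score", "p_value"]].copy()
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(int)
    df["stop"] = pd.to_numeric(df["stop"], errors="raise").astype(int)
    if (df["start"] > df["stop"]).any():
        raise ValidationError("motif hit with start > stop")
    pv = df["p_value"].dropna()
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("motif hit p-value outside [0, 1]")
    return MotifHitTable(df)


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Rows of (gene_a, gene_b, optional score)."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


_EDGE_HEADER = re.compile(r"^(gene|protein|node|source|target|interactor)", re.I)


def read_edges(path) -> EdgeList:
    """Read a 2- or 3-column TSV edge list (STRING/BioGRID-like)."""
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _EDGE_HEADER.match(fields[0]):
                continue  # header row
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: fewer than 2 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValidationError(f"line {lineno}: empty gene identifier")
            score = np.nan
            if len(fields) >= 3 and fields[2].strip():
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: bad score {fields[2]!r}") from exc
                if not np.isfinite(score):
                    raise ValidationError(f"line {lineno}: non-finite score")
            rows.append((a, b, score))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return EdgeList(df)


# ---------------------------------------------------------------------------
# GTF gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene chromosome/coordinates/strand plus a transcript->gene map.

    Coordinates are GTF-native: 1-based, inclusive at both ends.
    """

    genes: pd.DataFrame  # index gene_id; columns chrom, start, end, strand
    transcripts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        if (g["start"] > g["end"]).any():
            raise ValidationError("gene with start > end")
        bad = ~g["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError(
                f"genes with invalid strand: {g.index[bad].tolist()[:5]}"
            )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_annotation(path) -> GeneAnnotation:
    """Parse ``gene``/``transcript`` records from a GTF file.

    Genes without an explicit ``gene`` feature are reconstructed from the
    span of their transcripts.  A record with strand other than ``+``/``-``
    is rejected (promoter windows need an orientation).
    """
    genes: dict[str, tuple[str, int, int, str]] = {}
    spans: dict[str, list] = {}
    tx2gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature not in ("gene", "transcript"):
                continue
            if strand not in ("+", "-"):
                raise ValidationError(f"line {lineno}: record without strand")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if not gid:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            if feature == "gene":
                if gid in genes:
                    raise ValidationError(f"duplicate gene feature for {gid!r}")
                genes[gid] = (chrom, start_i, end_i, strand)
            else:
                tid = attr.get("transcript_id")
                if tid:
                    tx2gene[tid] = gid
                rec = spans.setdefault(gid, [chrom, start_i, end_i, strand])
                rec[1] = min(rec[1], start_i)
                rec[2] = max(rec[2], end_i)
    for gid, (chrom, s, e, strand) in spans.items():
        genes.setdefault(gid, (chrom, s, e, strand))
    if not genes:
        raise FormatError("no gene or transcript records found")
    df = pd.DataFrame.from_dict(
        genes, orient="index", columns=["chrom", "start", "end", "strand"]
    )
    df.index.name = "gene_id"
    return GeneAnnotation(df.sort_index(), tx2gene)


# ---------------------------------------------------------------------------
# PSI event tables
# ---------------------------------------------------------------------------

@dataclass
class PsiTable:
    """Rows of (event_id, gene_id, event_type, tissue, psi).

    PSI is stored on the 0-100 percent scale; missing values are NaN.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


def read_psi(path, scale: str = "auto") -> PsiTable:
    """Read a PSI event table.

    ``scale`` is one of ``auto`` (default), ``percent`` or ``fraction``.
    Inputs on the 0-1 scale are rescaled x100 at load; auto-detection fires
    when at least 20 finite values are all <= 1.
    """
    if scale not in ("auto", "percent", "fraction"):
        raise ValueError(f"unknown scale {scale!r}")
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene_id": str, "tissue": str})
    required = ["event_id", "gene_id", "event_type", "tissue", "psi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"PSI table lacks columns {missing}")
    bad_types = sorted(set(df["event_type"]) - set(EVENT_TYPES))
    if bad_types:
        raise ValidationError(f"unknown event_type codes: {bad_types}")
    psi = pd.to_numeric(df["psi"], errors="coerce")
    unparsed = psi.isna() & df["psi"].notna() & ~df["psi"].astype(str).str.upper().isin(
        ["NA", "NAN", ""]
    )
    if unparsed.any():
        raise FormatError(f"non-numeric PSI value {df['psi'][unparsed].iloc[0]!r}")
    finite = psi.dropna()
    if scale == "fraction" or (
        scale == "auto" and len(finite) >= 20 and finite.max() <= 1.0
    ):
        logger.warning("PSI values look like fractions; rescaling x100")
        psi = psi * 100.0
    if ((finite := psi.dropna()) < 0).any() or (finite > 100).any():
        raise ValidationError("PSI values outside [0, 100]")
    out = df[required[:-1]].copy()
    out["psi"] = psi
    return PsiTable(out)


# ---------------------------------------------------------------------------
# Isoform abundance tables
# ---------------------------------------------------------------------------

@dataclass
class IsoformTable:
    """Rows of (gene_id, isoform_id, tissue, fpkm); unique per triple."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


def read_isoforms(path) -> IsoformTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "isoform_id": str, "tissue": str})
    required = ["gene_id", "isoform_id", "tissue", "fpkm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"isoform table lacks columns {missing}")
    fpkm = pd.to_numeric(df["fpkm"], errors="coerce")
    if fpkm.isna().any():
        raise FormatError("non-numeric isoform abundance")
    if (~np.isfinite(fpkm)).any() or (fpkm < 0).any():
        raise ValidationError("isoform abundance must be finite and >= 0")
    keys = df[["gene_id", "isoform_id", "tissue"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate (gene, isoform, tissue) row: {dup}")
    out = df[required[:-1]].copy()
    out["fpkm"] = fpkm.astype(float)
    return IsoformTable(out)


# ---------------------------------------------------------------------------
# Generic deterministic TSV output
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    """Write a DataFrame as deterministic TSV.

    Rows are sorted lexicographically over all columns, floats are printed
    with 12 significant digits, and optional ``#``-prefixed comment lines
    precede the header.  Writing then re-reading reproduces the table
    (string-level for identifiers, 12 significant digits numerically).
    """
    out = df.reset_index() if df.index.name is not None else df.copy()
    if len(out):
        out = out.sort_values(by=list(out.columns), kind="mergesort")
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
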