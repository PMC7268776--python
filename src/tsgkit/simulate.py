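"""Synthetic multi-species study bundles with planted ground truth.

The generator emulates the processed layer of a multi-species, multi-tissue
bulk RNA-seq compendium: per-species FPKM matrices with replicates, 1:1
orthogroups wired to realize configured cross-species sharing patterns for
the planted focal-tissue-specific genes, isoform tables whose per-gene sums
equal gene abundances, PSI tables over the seven event types, FIMO-style
motif hits enriched on planted-gene promoters, a GTF annotation, a sparse
interaction network with planted high-degree genes, and a per-gene dN/dS
table with a location shift for the planted genes.

The effect model: background genes share one per-gene baseline across all
tissues (log-normal on the log2 scale) so their specificity index is
noise-only; planted specific genes are in an "off" state everywhere (a low
log-normal with dropout to exact zero) and receive a multiplicative
fold-change in their target tissue.  Everything is deterministic for a
fixed seed: one global seed drives independent named substreams, so adding
a generator never perturbs earlier streams.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from tsgkit._util import fmt_float
from tsgkit.formats import EVENT_TYPES

# substream names in fixed spawn order; append-only
_STREAMS = (
    "expression:pig",
    "expression:cattle",
    "expression:sheep",
    "expression:human",
    "expression:mouse",
    "isoforms",
    "annotation",
    "psi",
    "motifs",
    "genesets",
    "network",
    "dnds",
)

TIER_ORDER = ("HCTSG", "MCTSG", "LCTSG", "OTHER")


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Counts are per species unless noted.  Abundance parameters are on the
    log2(FPKM) scale.
    """

    seed: int
    species: tuple[str, ...] = ("pig", "cattle", "sheep", "human", "mouse")
    focal_species: str = "pig"
    tissues: tuple[str, ...] = ("testis", "brain", "heart", "liver", "kidney", "muscle")
    focal_tissue: str = "testis"
    replicates: int = 2
    n_genes: int = 2000
    n_specific: int = 100           # planted focal-tissue genes per species
    fold_change: float = 32.0       # focal-tissue uplift over the off state
    n_specific_other: int = 55      # planted genes per non-focal tissue
    other_fold_change: float = 8.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    off_log2_mean: float = -2.5     # off-state abundance of planted genes
    off_log2_sd: float = 0.5
    off_dropout: float = 0.4        # P(off-state value is exactly 0)
    replicate_log2_sd: float = 0.2
    zero_fraction: float = 0.1      # genes non-expressed in every tissue
    tier_mixture: dict = field(
        default_factory=lambda: {"HCTSG": 0.4, "MCTSG": 0.2, "LCTSG": 0.3, "OTHER": 0.1}
    )
    mc_partners: tuple[str, ...] = ("cattle", "sheep")
    other_pattern_species: tuple[str, ...] = ("human",)  # sharing for OTHER tier
    n_one_to_one: int = 1500
    n_mc_families: int = 25
    isoform_count_probs: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)  # 1..4 isoforms
    dominant_concentration: float = 12.0
    events_per_type: dict = field(
        default_factory=lambda: {
            "SE": 1200, "RI": 300, "A5": 300, "A3": 300, "MX": 120, "AF": 300, "AL": 120
        }
    )
    psi_presence_rate: float = 0.75
    psi_missing_rate: float = 0.05
    n_tfs: int = 50
    n_enriched_tfs: int = 5
    tf_background_rate: float = 0.06
    tf_enrichment_odds: float = 5.0
    n_gene_sets: int = 20
    gene_set_size: int = 50
    planted_set_n_specific: int = 60
    planted_set_n_background: int = 15
    pa_edges_per_node: int = 2
    n_hubs: int = 6
    hub_extra_degree: int = 45
    tsg_edges_per_gene: int = 2
    ds_shape: float = 2.0
    ds_scale: float = 0.10
    dnds_shape: float = 2.0
    dnds_scale: float = 0.08
    dnds_tsg_shift: float = 0.15

    # -- derived layout ----------------------------------------------------
    @property
    def n_zero(self) -> int:
        return round(self.zero_fraction * self.n_genes)

    @property
    def n_retained(self) -> int:
        return self.n_genes - self.n_zero

    def tier_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of planted genes over tiers."""
        props = [self.tier_mixture.get(t, 0.0) for t in TIER_ORDER]
        exact = [p * self.n_specific for p in props]
        counts = [math.floor(x) for x in exact]
        short = self.n_specific - sum(counts)
        order = sorted(range(len(TIER_ORDER)), key=lambda i: exact[i] - counts[i], reverse=True)
        for i in order[:short]:
            counts[i] += 1
        return dict(zip(TIER_ORDER, counts))

    def tier_pattern(self, tier: str) -> tuple[str, ...]:
        """Species in which a planted gene of this tier is focal-specific."""
        if tier == "HCTSG":
            return self.species
        if tier == "MCTSG":
            return (self.focal_species,) + tuple(self.mc_partners)
        if tier == "LCTSG":
            return (self.focal_species,)
        return (self.focal_species,) + tuple(self.other_pattern_species)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if len(self.species) < 2 or self.focal_species not in self.species:
            raise ValueError("need >= 2 species including the focal species")
        if len(self.tissues) < 2 or self.focal_tissue not in self.tissues:
            raise ValueError("need >= 2 tissues including the focal tissue")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        mix_sum = sum(self.tier_mixture.get(t, 0.0) for t in TIER_ORDER)
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"tier mixture proportions must sum to 1, got {mix_sum}")
        unknown = set(self.mc_partners + self.other_pattern_species) - set(self.species)
        if unknown:
            raise ValueError(f"tier pattern references unknown species: {sorted(unknown)}")
        if self.n_specific > self.n_retained:
            raise ValueError("n_specific exceeds the number of expressed genes")
        layout = _Layout(self)  # raises on infeasible index layout
        if layout.extra_end > self.n_one_to_one:
            raise ValueError("planted genes do not fit inside the 1:1 ortholog block")
        if self.n_one_to_one + 2 * self.n_mc_families > self.n_retained:
            raise ValueError("ortholog blocks exceed the number of expressed genes")
        if abs(sum(self.isoform_count_probs) - 1.0) > 1e-9:
            raise ValueError("isoform count probabilities must sum to 1")
        bad = [t for t in self.events_per_type if t not in EVENT_TYPES]
        if bad:
            raise ValueError(f"unknown event types in events_per_type: {bad}")
        if self.n_enriched_tfs > self.n_tfs:
            raise ValueError("n_enriched_tfs exceeds n_tfs")
        if self.n_hubs > self.n_specific:
            raise ValueError("n_hubs exceeds the number of planted genes")
        if self.hub_extra_degree >= self.n_specific:
            raise ValueError("hub_extra_degree must be below n_specific")


class _Layout:
    """Deterministic gene-index layout implied by a config."""

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        counts = cfg.tier_counts()
        self.tier_of: dict[int, str] = {}
        cur = 0
        for tier in TIER_ORDER:
            for i in range(cur, cur + counts[tier]):
                self.tier_of[i] = tier
            cur += counts[tier]
        self.focal_specific = list(range(cfg.n_specific))

        self.other_tissues = [t for t in cfg.tissues if t != cfg.focal_tissue]
        self.other_planted: dict[str, list[int]] = {}
        cur = cfg.n_specific
        for t in self.other_tissues:
            self.other_planted[t] = list(range(cur, cur + cfg.n_specific_other))
            cur += cfg.n_specific_other

        # extra focal-tissue genes per non-focal species so each species has
        # n_specific of them in total
        self.extra: dict[str, list[int]] = {}
        for sp in cfg.species:
            if sp == cfg.focal_species:
                self.extra[sp] = []
                continue
            shared = sum(1 for i in self.focal_specific if sp in cfg.tier_pattern(self.tier_of[i]))
            n_extra = cfg.n_specific - shared
            if n_extra < 0:
                raise ValueError(f"species {sp} shares more planted genes than n_specific")
            self.extra[sp] = list(range(cur, cur + n_extra))
            cur += n_extra
        self.extra_end = cur
        self.zero = list(range(cfg.n_genes - cfg.n_zero, cfg.n_genes))

    def focal_tissue_planted(self, sp: str) -> list[int]:
        """Indices planted as focal-tissue-specific in one species."""
        cfg = self.cfg
        shared = [
            i for i in self.focal_specific if sp in cfg.tier_pattern(self.tier_of[i])
        ]
        return shared + self.extra[sp]

    def planted(self, sp: str) -> list[tuple[int, str, float]]:
        """(gene index, target tissue, fold change) for one species, sorted."""
        cfg = self.cfg
        out = [
            (i, cfg.focal_tissue, cfg.fold_change)
            for i in self.focal_tissue_planted(sp)
        ]
        for t in self.other_tissues:
            out.extend((i, t, cfg.other_fold_change) for i in self.other_planted[t])
        return sorted(out)


@dataclass
class TruthBundle:
    """Planted ground truth plus the paths of every emitted input file."""

    config: SyntheticConfig
    outdir: Path
    files: dict[str, Path]
    tsg_true: dict[str, tuple[str, ...]]           # species -> focal-tissue genes
    tissue_assignments: dict[str, dict[str, str]]  # species -> gene -> tissue
    tiers: dict[str, str]                          # focal gene -> tier label
    tier_counts: dict[str, int]
    enriched_tfs: tuple[str, ...]
    hubs: tuple[str, ...]
    planted_set_id: str

    def to_json(self, path) -> None:
        # paths are stored relative to the bundle directory so that a bundle
        # is byte-identical wherever it is generated
        payload = {
            "config": asdict(self.config),
            "files": {k: Path(v).name for k, v in self.files.items()},
            "tsg_true": {k: list(v) for k, v in self.tsg_true.items()},
            "tissue_assignments": self.tissue_assignments,
            "tiers": self.tiers,
            "tier_counts": self.tier_counts,
            "enriched_tfs": list(self.enriched_tfs),
            "hubs": list(self.hubs),
            "planted_set_id": self.planted_set_id,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _gene_id(sp: str, i: int) -> str:
    return f"{sp}_g{i:04d}"


def _write(path: Path, lines) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        fh.write("\n")


def simulate_study(config: SyntheticConfig, outdir) -> TruthBundle:
    """Generate a complete study bundle under ``outdir``.

    Returns the :class:`TruthBundle`; also writes ``truth.json`` beside the
    input files.  Byte-identical across reruns with the same seed/config.
    """
    cfg = config
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = _Layout(cfg)

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(_STREAMS))
    streams = {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}
    for sp in cfg.species:  # species beyond the default five get fresh streams
        if f"expression:{sp}" not in streams:
            streams[f"expression:{sp}"] = np.random.default_rng(root.spawn(1)[0])

    files: dict[str, Path] = {}
    T = len(cfg.tissues)
    tissue_idx = {t: j for j, t in enumerate(cfg.tissues)}

    # ------------------------------------------------------------------ expression
    tissue_means: dict[str, np.ndarray] = {}
    for sp in cfg.species:
        rng = streams[f"expression:{sp}"]
        base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
        vals = np.tile(base[:, None], (1, T))
        for i, tissue, fold in layout.planted(sp):
            drop = rng.random(T) < cfg.off_dropout
            off = 2.0 ** rng.normal(cfg.off_log2_mean, cfg.off_log2_sd, T)
            target = fold * 2.0 ** rng.normal(cfg.off_log2_mean, cfg.off_log2_sd)
            row = np.where(drop, 0.0, off)
            row[tissue_idx[tissue]] = target
            vals[i] = row
        vals[layout.zero] = 0.0

        reps = np.empty((cfg.replicates, cfg.n_genes, T))
        for r in range(cfg.replicates):
            noise = 2.0 ** rng.normal(0.0, cfg.replicate_log2_sd, (cfg.n_genes, T))
            reps[r] = vals * noise
        tissue_means[sp] = reps.mean(axis=0)

        sample_ids = [
            f"{sp}_{t}_r{r + 1}" for t in cfg.tissues for r in range(cfg.replicates)
        ]
        lines = ["gene_id\t" + "\t".join(sample_ids)]
        for i in range(cfg.n_genes):
            cells = [
                fmt_float(reps[r, i, j])
                for j in range(T)
                for r in range(cfg.replicates)
            ]
            lines.append(_gene_id(sp, i) + "\t" + "\t".join(cells))
        mpath = outdir / f"expression_{sp}.tsv"
        _write(mpath, lines)
        files[f"expression_{sp}"] = mpath

        meta = ["sample_id\tspecies\ttissue\treplicate"]
        for t in cfg.tissues:
            for r in range(cfg.replicates):
                meta.append(f"{sp}_{t}_r{r + 1}\t{sp}\t{t}\t{r + 1}")
        spath = outdir / f"samples_{sp}.tsv"
        _write(spath, meta)
        files[f"samples_{sp}"] = spath

    focal = cfg.focal_species
    focal_mean = tissue_means[focal]
    retained = list(range(cfg.n_retained))

    # ------------------------------------------------------------------ isoforms
    rng = streams["isoforms"]
    probs = np.asarray(cfg.isoform_count_probs)
    multi_probs = probs[1:] / probs[1:].sum()
    iso_of: dict[int, list[str]] = {}
    iso_lines = ["gene_id\tisoform_id\ttissue\tfpkm"]
    planted_focal = set(layout.focal_specific)
    for i in retained:
        if i in planted_focal:
            k = int(rng.choice(np.arange(2, len(probs) + 1), p=multi_probs))
        else:
            k = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
        w = rng.dirichlet([cfg.dominant_concentration] + [1.0] * (k - 1))
        gid = _gene_id(focal, i)
        iso_of[i] = [f"{gid}.t{j + 1}" for j in range(k)]
        for j, tid in enumerate(iso_of[i]):
            for t in cfg.tissues:
                fpkm = w[j] * focal_mean[i, tissue_idx[t]]
                iso_lines.append(f"{gid}\t{tid}\t{t}\t{fmt_float(fpkm)}")
    ipath = outdir / "isoforms.tsv"
    _write(ipath, iso_lines)
    files["isoforms"] = ipath

    # ------------------------------------------------------------------ annotation
    rng = streams["annotation"]
    n_chrom = 18
    gtf = []
    for i in range(cfg.n_genes):
        gid = _gene_id(focal, i)
        chrom = f"chr{(i % n_chrom) + 1}"
        start = 10000 + (i // n_chrom) * 20000
        length = int(rng.integers(1000, 9001))
        strand = "+" if rng.integers(2) == 0 else "-"
        end = start + length
        attrs = f'gene_id "{gid}";'
        gtf.append(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
        for tid in iso_of.get(i, [f"{gid}.t1"]):
            tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            gtf.append(f"{chrom}\tsim\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{tattrs}")
    gpath = outdir / "annotation.gtf"
    _write(gpath, gtf)
    files["annotation"] = gpath

    # ------------------------------------------------------------------ PSI events
    rng = streams["psi"]
    psi_lines = ["event_id\tgene_id\tevent_type\ttissue\tpsi"]
    for etype in EVENT_TYPES:
        count = int(cfg.events_per_type.get(etype, 0))
        for e in range(count):
            gi = int(rng.integers(0, cfg.n_retained))
            gid = _gene_id(focal, gi)
            eid = f"{etype}.{e:05d}"
            for t in cfg.tissues:
                if rng.random() < cfg.psi_missing_rate:
                    psi_lines.append(f"{eid}\t{gid}\t{etype}\t{t}\tNA")
                    continue
                if rng.random() < cfg.psi_presence_rate:
                    psi = rng.uniform(5.0, 95.0)
                else:
                    psi = rng.uniform(0.0, 5.0) if rng.random() < 0.5 else rng.uniform(95.0, 100.0)
                psi_lines.append(f"{eid}\t{gid}\t{etype}\t{t}\t{fmt_float(psi)}")
    ppath = outdir / "psi_events.tsv"
    _write(ppath, psi_lines)
    files["psi"] = ppath

    # ------------------------------------------------------------------ motif hits
    rng = streams["motifs"]
    tf_ids = [f"TF{j + 1:03d}" for j in range(cfg.n_tfs)]
    enriched = tuple(tf_ids[: cfg.n_enriched_tfs])
    p_bg = cfg.tf_background_rate
    p_hi = min(0.95, cfg.tf_enrichment_odds * p_bg)
    hit_lines = [
        "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\tq-value\tmatched_sequence"
    ]
    for tf in tf_ids:
        u = rng.random(cfg.n_retained)
        for i in retained:
            p = p_hi if (tf in enriched and i in planted_focal) else p_bg
            if u[i] >= p:
                continue
            start = int(rng.integers(1, 990))
            length = int(rng.integers(8, 16))
            strand = "+" if rng.integers(2) == 0 else "-"
            score = rng.uniform(5.0, 20.0)
            pval = 10.0 ** rng.uniform(-8.0, -4.0)
            hit_lines.append(
                f"{tf}\t{tf}\t{_gene_id(focal, i)}\t{start}\t{start + length - 1}"
                f"\t{strand}\t{score:.4f}\t{pval:.3e}\t1.0e-02\t{'N' * length}"
            )
    hpath = outdir / "motif_hits.tsv"
    _write(hpath, hit_lines)
    files["motif_hits"] = hpath

    # ------------------------------------------------------------------ orthogroups
    og_lines = []
    for i in range(cfg.n_one_to_one):
        members = " ".join(f"{sp}|{_gene_id(sp, i)}" for sp in cfg.species)
        og_lines.append(f"F{i:04d}: {members}")
    for j in range(cfg.n_mc_families):
        a = cfg.n_one_to_one + 2 * j
        b = a + 1
        members = [f"{focal}|{_gene_id(focal, a)}", f"{focal}|{_gene_id(focal, b)}"]
        members += [f"{sp}|{_gene_id(sp, a)}" for sp in cfg.species if sp != focal]
        og_lines.append(f"M{j:03d}: " + " ".join(members))
    opath = outdir / "orthogroups.txt"
    _write(opath, og_lines)
    files["orthogroups"] = opath

    # ------------------------------------------------------------------ gene sets
    rng = streams["genesets"]
    pool = [i for i in range(layout.extra_end, cfg.n_one_to_one)]
    planted_set_id = "MALE_GAMETE_PROGRAM"
    chosen = sorted(
        int(x)
        for x in rng.choice(layout.focal_specific, cfg.planted_set_n_specific, replace=False)
    )
    bg_members = sorted(
        int(x) for x in rng.choice(pool, cfg.planted_set_n_background, replace=False)
    )
    gmt = [
        planted_set_id
        + "\tplanted set enriched in focal-tissue genes\t"
        + "\t".join(_gene_id(focal, i) for i in chosen + bg_members)
    ]
    for s in range(cfg.n_gene_sets - 1):
        members = sorted(int(x) for x in rng.choice(pool, cfg.gene_set_size, replace=False))
        gmt.append(
            f"RANDOM_SET_{s + 1:02d}\trandom background set\t"
            + "\t".join(_gene_id(focal, i) for i in members)
        )
    gmt_path = outdir / "gene_sets.gmt"
    _write(gmt_path, gmt)
    files["gene_sets"] = gmt_path

    # ------------------------------------------------------------------ network
    rng = streams["network"]
    ba_seed = int(rng.integers(2**31))
    ba = nx.barabasi_albert_graph(cfg.n_retained, cfg.pa_edges_per_node, seed=ba_seed)
    node_gene = rng.permutation(cfg.n_retained)  # BA node j -> gene index
    edge_set: dict[tuple[str, str], None] = {}

    def _add(ia: int, ib: int) -> None:
        a, b = _gene_id(focal, ia), _gene_id(focal, ib)
        key = (a, b) if a < b else (b, a)
        edge_set.setdefault(key, None)

    for u, v in ba.edges():
        _add(int(node_gene[u]), int(node_gene[v]))
    planted_arr = np.asarray(layout.focal_specific)
    for a in layout.focal_specific:
        others = planted_arr[planted_arr != a]
        for b in rng.choice(others, cfg.tsg_edges_per_gene, replace=False):
            _add(a, int(b))
    hub_idx = sorted(int(x) for x in rng.choice(planted_arr, cfg.n_hubs, replace=False))
    for h in hub_idx:
        others = planted_arr[planted_arr != h]
        for b in rng.choice(others, cfg.hub_extra_degree, replace=False):
            _add(h, int(b))

    rows = [list(key) for key in edge_set]
    # deliberate dirty rows exercising the cleaning step: reversed duplicates
    # and self-interactions
    rows.extend([b, a] for a, b in rows[:15])
    rows.extend([_gene_id(focal, i), _gene_id(focal, i)] for i in range(5))
    scores = rng.integers(150, 1000, len(rows))
    order = rng.permutation(len(rows))
    epath = outdir / "edges.tsv"
    _write(
        epath,
        [f"{rows[i][0]}\t{rows[i][1]}\t{scores[i]}" for i in order],
    )
    files["edges"] = epath

    # ------------------------------------------------------------------ dN/dS
    rng = streams["dnds"]
    n11 = cfg.n_one_to_one
    ds = rng.gamma(cfg.ds_shape, cfg.ds_scale, n11) + 1e-3
    ratio = rng.gamma(cfg.dnds_shape, cfg.dnds_scale, n11)
    ratio[layout.focal_specific] += cfg.dnds_tsg_shift
    dn = ratio * ds
    dlines = ["gene_id\tdn\tds\tdnds"]
    for i in range(n11):
        dlines.append(
            f"{_gene_id(focal, i)}\t{fmt_float(dn[i])}\t{fmt_float(ds[i])}\t{fmt_float(ratio[i])}"
        )
    dpath = outdir / "dnds.tsv"
    _write(dpath, dlines)
    files["dnds"] = dpath

    # ------------------------------------------------------------------ truth
    tsg_true = {
        sp: tuple(_gene_id(sp, i) for i in sorted(layout.focal_tissue_planted(sp)))
        for sp in cfg.species
    }
    assignments: dict[str, dict[str, str]] = {}
    for sp in cfg.species:
        assignments[sp] = {
            _gene_id(sp, i): t for i, t, _fold in layout.planted(sp)
        }
    tiers = {_gene_id(focal, i): layout.tier_of[i] for i in layout.focal_specific}
    bundle = TruthBundle(
        config=cfg,
        outdir=outdir,
        files=files,
        tsg_true=tsg_true,
        tissue_assignments=assignments,
        tiers=tiers,
        tier_counts=cfg.tier_counts(),
        enriched_tfs=enriched,
        hubs=tuple(_gene_id(focal, i) for i in hub_idx),
        planted_set_id=planted_set_id,
    )
    bundle.to_json(outdir / "truth.json")
    files["truth"] = outdir / "truth.json"
    return bundle
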