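"""End-to-end orchestration: specificity -> orthology -> enrichment ->
regulation -> splicing -> network -> evolutionary-rate comparisons.

Each stage is a pure function of its input files and parameters.  A stage
writes its tables under ``<outdir>/<stage>/`` together with a manifest
holding a digest of everything it depends on; a rerun with unchanged inputs
reuses the cached result, and mutating one input file recomputes only the
stages downstream of it.  The final report is deterministic JSON (no
timestamps), embedding the resolved configuration and input digests.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tsgkit
from tsgkit import enrichment as enr
from tsgkit import formats, network, orthology, regulation, specificity, splicing, stats
from tsgkit._util import sha256_file

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Paths plus the parameter block of a full study run."""

    expression: dict  # species -> {"matrix": path, "metadata": path}
    orthogroups: str
    gene_sets: str
    annotation: str
    motif_hits: str
    psi: str
    isoforms: str
    edges: str
    outdir: str
    dnds: str | None = None
    focal_species: str = "pig"
    focal_tissue: str = "testis"
    mc_partners: tuple[str, ...] = ("cattle", "sheep")
    top_frac: float = 0.20
    min_fpkm: float = 1.0
    rank_k: int = 3
    flank: int = 500
    motif_mode: str = "window_relative"
    psi_lo: float = 5.0
    psi_hi: float = 95.0
    hub_top_frac: float = 0.05
    alpha: float = 0.05
    correction: str = "bh"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "mc_partners" in raw:
            raw["mc_partners"] = tuple(raw["mc_partners"])
        return cls(**raw)

    @classmethod
    def from_bundle(cls, bundle, outdir) -> "PipelineConfig":
        """Point a config at the files of a synthetic TruthBundle."""
        cfg = bundle.config
        return cls(
            expression={
                sp: {
                    "matrix": str(bundle.files[f"expression_{sp}"]),
                    "metadata": str(bundle.files[f"samples_{sp}"]),
                }
                for sp in cfg.species
            },
            orthogroups=str(bundle.files["orthogroups"]),
            gene_sets=str(bundle.files["gene_sets"]),
            annotation=str(bundle.files["annotation"]),
            motif_hits=str(bundle.files["motif_hits"]),
            psi=str(bundle.files["psi"]),
            isoforms=str(bundle.files["isoforms"]),
            edges=str(bundle.files["edges"]),
            dnds=str(bundle.files["dnds"]),
            outdir=str(outdir),
            focal_species=cfg.focal_species,
            focal_tissue=cfg.focal_tissue,
            mc_partners=tuple(cfg.mc_partners),
        )

    def input_paths(self) -> dict[str, str]:
        out = {}
        for sp, d in self.expression.items():
            out[f"expression:{sp}"] = d["matrix"]
            out[f"metadata:{sp}"] = d["metadata"]
        for name in ("orthogroups", "gene_sets", "annotation", "motif_hits",
                     "psi", "isoforms", "edges"):
            out[name] = getattr(self, name)
        if self.dnds:
            out["dnds"] = self.dnds
        return out

    def validate(self) -> None:
        for name, p in self.input_paths().items():
            if not Path(p).exists():
                raise PipelineError(f"config validation: missing input {name} at {p}")
        if not 0 < self.top_frac <= 1:
            raise PipelineError("top_frac must be in (0, 1]")
        if self.correction not in ("bh", "none"):
            raise PipelineError(f"unknown correction mode {self.correction!r}")
        if self.focal_species not in self.expression:
            raise PipelineError(
                f"no expression input for focal species {self.focal_species!r}"
            )


@dataclass
class StudyReport:
    """In-memory result of a pipeline run.

    ``body`` is the deterministic JSON-serializable report (also written to
    ``report.json``); ``recomputed`` records which stages actually ran
    (cache bookkeeping, deliberately kept out of the report body so reruns
    are byte-identical).
    """

    body: dict
    path: Path
    recomputed: dict = field(default_factory=dict)


def _params_digest(params: dict, inputs: dict[str, str]) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    for name in sorted(inputs):
        h.update(name.encode())
        h.update(sha256_file(Path(inputs[name])).encode())
    return h.hexdigest()


class _StageRunner:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.recomputed: dict[str, bool] = {}

    def run(self, name: str, inputs: dict[str, str], params: dict, compute):
        stage_dir = self.outdir / name
        stage_dir.mkdir(parents=True, exist_ok=True)
        digest = _params_digest(params, inputs)
        manifest = stage_dir / "manifest.json"
        if manifest.exists():
            try:
                cached = json.loads(manifest.read_text())
            except json.JSONDecodeError:
                cached = None
            if cached and cached.get("digest") == digest:
                self.recomputed[name] = False
                return cached["result"]
        try:
            result = compute(stage_dir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest.write_text(
            json.dumps({"digest": digest, "result": result}, sort_keys=True, indent=1)
            + "\n"
        )
        self.recomputed[name] = True
        return result


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run all stages; deterministic outputs for identical inputs/config."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(outdir)
    species = sorted(config.expression)

    # ---------------------------------------------------------- specificity
    spec_params = {
        "top_frac": config.top_frac,
        "min_fpkm": config.min_fpkm,
        "rank_k": config.rank_k,
        "focal_tissue": config.focal_tissue,
    }
    spec_inputs = {
        k: v
        for k, v in config.input_paths().items()
        if k.startswith(("expression:", "metadata:"))
    }

    def _specificity(stage_dir: Path) -> dict:
        out: dict = {}
        for sp in species:
            table = formats.read_expression(
                config.expression[sp]["matrix"], config.expression[sp]["metadata"]
            )
            matrix = specificity.average_replicates(table, species=sp)
            res = specificity.call_tissue_specific(
                matrix,
                top_frac=config.top_frac,
                min_fpkm=config.min_fpkm,
                rank_k=config.rank_k,
            )
            formats.write_table(res.per_gene, stage_dir / f"tau_table_{sp}.tsv")
            formats.write_table(res.calls, stage_dir / f"tsg_calls_{sp}.tsv")
            entry = {
                "n_retained": int(res.per_gene.shape[0]),
                "n_dropped_all_zero": res.n_dropped_all_zero,
                "tau_threshold": res.tau_threshold,
                "tsg_counts": {
                    t: int(n) for t, n in res.calls["tissue"].value_counts().items()
                },
                "focal_tsgs": res.genes_for(config.focal_tissue),
            }
            if sp == config.focal_species:
                counts, tests = specificity.transcription_breadth(
                    matrix, config.focal_tissue
                )
                formats.write_table(
                    tests, stage_dir / f"breadth_chi2_{sp}.tsv"
                )
                entry["breadth"] = {t: int(c) for t, c in counts.items()}
                entry["breadth_max_p"] = float(tests["p_value"].max())
            out[sp] = entry
        return out

    spec_res = runner.run("specificity", spec_inputs, spec_params, _specificity)
    spec_dir = outdir / "specificity"
    spec_outputs = {
        f"tsg_calls:{sp}": str(spec_dir / f"tsg_calls_{sp}.tsv") for sp in species
    }
    focal_tsgs = sorted(spec_res[config.focal_species]["focal_tsgs"])
    focal_matrix_inputs = {
        "expression": config.expression[config.focal_species]["matrix"],
        "metadata": config.expression[config.focal_species]["metadata"],
    }

    def _focal_background() -> list[str]:
        table = formats.read_expression(
            config.expression[config.focal_species]["matrix"],
            config.expression[config.focal_species]["metadata"],
        )
        matrix = specificity.average_replicates(table, species=config.focal_species)
        keep = matrix.to_numpy().max(axis=1) > 0
        return sorted(matrix.index[keep])

    # ------------------------------------------------------------ orthology
    orth_params = {
        "focal": config.focal_species,
        "mc_partners": list(config.mc_partners),
        "species": species,
    }
    orth_inputs = {"orthogroups": config.orthogroups, **spec_outputs}

    def _orthology(stage_dir: Path) -> dict:
        groups = formats.read_orthogroups(config.orthogroups)
        omap = orthology.one_to_one(groups, species)
        tsg_sets = {
            sp: set(spec_res[sp]["focal_tsgs"]) for sp in species
        }
        tiers = orthology.conservation_tiers(
            tsg_sets, omap, focal=config.focal_species, mc_partners=config.mc_partners
        )
        df = pd.DataFrame(
            {
                "gene_id": sorted(tiers.labels),
                "tier": [tiers.labels[g] for g in sorted(tiers.labels)],
                "pattern": [tiers.patterns[g] for g in sorted(tiers.labels)],
            }
        )
        formats.write_table(df, stage_dir / "tiers.tsv")
        copy = orthology.copy_class(
            groups, config.focal_species, genes=tsg_sets[config.focal_species]
        )
        n_sc = sum(
            1 for g in tsg_sets[config.focal_species] if copy.get(g) == "SC"
        )
        return {
            "n_one_to_one": len(omap),
            "tier_counts": tiers.counts(),
            "n_focal_tsg_single_copy": n_sc,
            "pattern_note": "MCTSG requires sharing with "
            + "+".join(config.mc_partners)
            + " and excludes all-species sharing",
        }

    orth_res = runner.run("orthology", orth_inputs, orth_params, _orthology)

    # ----------------------------------------------------------- enrichment
    enr_params = {"alpha": config.alpha, "correction": config.correction}
    enr_inputs = {"gene_sets": config.gene_sets, **spec_outputs, **focal_matrix_inputs}

    def _enrichment(stage_dir: Path) -> dict:
        collection = formats.read_gmt(config.gene_sets)
        background = _focal_background()
        df = enr.ora(
            collection,
            focal_tsgs,
            background,
            alpha=config.alpha,
            use_adjusted=config.correction == "bh",
        )
        formats.write_table(df, stage_dir / "enrichment.tsv")
        return {
            "n_sets_tested": int(len(df)),
            "n_significant": int(df["significant"].sum()),
            "top_set": df.iloc[0]["set_id"] if len(df) else None,
            "top_set_p": float(df.iloc[0]["p_value"]) if len(df) else None,
        }

    enr_res = runner.run("enrichment", enr_inputs, enr_params, _enrichment)

    # ----------------------------------------------------------- regulation
    reg_params = {
        "flank": config.flank,
        "mode": config.motif_mode,
        "alpha": config.alpha,
    }
    reg_inputs = {
        "annotation": config.annotation,
        "motif_hits": config.motif_hits,
        **spec_outputs,
        **focal_matrix_inputs,
    }

    def _regulation(stage_dir: Path) -> dict:
        annotation = formats.read_gtf_annotation(config.annotation)
        windows = regulation.promoter_windows(annotation, flank=config.flank)
        hits = formats.read_motif_hits(config.motif_hits)
        targets, n_skipped = regulation.map_hits_to_targets(
            hits, windows, mode=config.motif_mode
        )
        pairs = pd.DataFrame(
            [(m, g) for m in sorted(targets) for g in sorted(targets[m])],
            columns=["motif_id", "gene_id"],
        )
        formats.write_table(pairs, stage_dir / "tf_targets.tsv")
        background = _focal_background()
        ntsg = sorted(set(background) - set(focal_tsgs))
        df = enr.tf_enrichment(
            targets, focal_tsgs, background, contrast=ntsg, alpha=config.alpha
        )
        formats.write_table(df, stage_dir / "tf_enrichment.tsv")
        return {
            "n_tfs_tested": int(len(df)),
            "n_associated": int(df["associated"].sum()),
            "n_selective": int(df["selective"].sum()),
            "associated_tfs": sorted(df.loc[df["associated"], "motif_id"]),
            "selective_tfs": sorted(df.loc[df["selective"], "motif_id"]),
            "n_hits_skipped": n_skipped,
        }

    reg_res = runner.run("regulation", reg_inputs, reg_params, _regulation)

    # ------------------------------------------------------------- splicing
    spl_params = {
        "psi_lo": config.psi_lo,
        "psi_hi": config.psi_hi,
        "top_frac": config.top_frac,
        "min_fpkm": config.min_fpkm,
        "rank_k": config.rank_k,
        "focal_tissue": config.focal_tissue,
    }
    spl_inputs = {
        "psi": config.psi,
        "isoforms": config.isoforms,
        **focal_matrix_inputs,
        **spec_outputs,
    }

    def _splicing(stage_dir: Path) -> dict:
        psi = formats.read_psi(config.psi)
        summary = splicing.count_spliced_genes(psi, config.psi_lo, config.psi_hi)
        formats.write_table(
            summary.per_tissue_type.reset_index(), stage_dir / "as_counts.tsv"
        )
        isoforms = formats.read_isoforms(config.isoforms)
        table = formats.read_expression(
            config.expression[config.focal_species]["matrix"],
            config.expression[config.focal_species]["metadata"],
        )
        matrix = specificity.average_replicates(table, species=config.focal_species)
        records, medians = splicing.contribution_rates(
            isoforms, matrix, gene_set=focal_tsgs
        )
        formats.write_table(records, stage_dir / "contribution.tsv")
        tx = splicing.transcript_specific(
            isoforms,
            top_frac=config.top_frac,
            min_fpkm=config.min_fpkm,
            rank_k=config.rank_k,
        )
        formats.write_table(tx.calls, stage_dir / "transcript_calls.tsv")
        return {
            "n_spliced_genes": summary.n_spliced_genes,
            "n_events_present": summary.n_events_present,
            "genes_per_tissue": {t: int(c) for t, c in summary.per_tissue.items()},
            "type_proportions": {
                t: float(p) for t, p in summary.type_proportions.items()
            },
            "median_contribution": {t: float(m) for t, m in medians.items()},
            "n_focal_specific_transcripts": len(tx.genes_for(config.focal_tissue)),
        }

    spl_res = runner.run("splicing", spl_inputs, spl_params, _splicing)

    # -------------------------------------------------------------- network
    net_params = {"hub_top_frac": config.hub_top_frac}
    net_inputs = {"edges": config.edges, **spec_outputs, **focal_matrix_inputs}

    def _network(stage_dir: Path) -> dict:
        edges = formats.read_edges(config.edges)
        graph = network.build_graph(edges)
        cent = network.centralities(graph)
        formats.write_table(cent, stage_dir / "centrality.tsv")
        hubs = network.hub_screen(graph, focal_tsgs, top_frac=config.hub_top_frac)
        formats.write_table(hubs.table, stage_dir / "tsg_subgraph_centrality.tsv")
        pd.DataFrame({"gene_id": hubs.hubs}).to_csv(
            stage_dir / "hubs.tsv", sep="\t", index=False
        )
        background = _focal_background()
        ntsg = sorted(set(background) - set(focal_tsgs))
        comparisons = {}
        for col in ("degree", "betweenness", "closeness"):
            values = cent[col].to_dict()
            try:
                cmp_res = stats.compare_gene_sets(
                    values, ntsg, focal_tsgs, alternative="a_greater"
                )
                comparisons[col] = {
                    "p_value": cmp_res.p_value,
                    "direction": "non_specific_greater",
                }
            except ValueError:
                comparisons[col] = {"p_value": None, "direction": None}
        return {
            "n_nodes": graph.n_nodes,
            "n_edges": graph.n_edges,
            "n_self_dropped": graph.n_self_dropped,
            "n_duplicate_dropped": graph.n_duplicate_dropped,
            "n_subgraph_nodes": int(len(hubs.table)),
            "hub_degree_threshold": hubs.degree_threshold,
            "hubs": hubs.hubs,
            "centrality_comparisons": comparisons,
        }

    net_res = runner.run("network", net_inputs, net_params, _network)

    # ------------------------------------------------------------ evolution
    evo_res = None
    if config.dnds:
        evo_inputs = {"dnds": config.dnds, **spec_outputs}

        def _evolution(stage_dir: Path) -> dict:
            df = pd.read_csv(config.dnds, sep="\t")
            out = {}
            tsg_set = set(focal_tsgs)
            genes = set(df["gene_id"])
            ntsg = sorted(genes - tsg_set)
            for col in ("dn", "ds", "dnds"):
                values = dict(zip(df["gene_id"], df[col]))
                cmp_res = stats.compare_gene_sets(
                    values, sorted(tsg_set & genes), ntsg, alternative="a_greater"
                )
                out[col] = {
                    "p_value": cmp_res.p_value,
                    "median_tsg": cmp_res.median_a,
                    "median_ntsg": cmp_res.median_b,
                    "direction": "specific_greater",
                }
            return out

        evo_res = runner.run("evolution", evo_inputs, {}, _evolution)

    # --------------------------------------------------------------- report
    body = {
        "version": tsgkit.__version__,
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            }
        },
        "input_digests": {
            name: sha256_file(Path(p)) for name, p in sorted(config.input_paths().items())
        },
        "specificity": {
            sp: {
                **{k: v for k, v in spec_res[sp].items() if k != "focal_tsgs"},
                "n_focal_tsgs": len(spec_res[sp]["focal_tsgs"]),
            }
            for sp in species
        },
        "focal_tsgs": focal_tsgs,
        "orthology": orth_res,
        "enrichment": enr_res,
        "regulation": reg_res,
        "splicing": spl_res,
        "network": net_res,
        "evolution": evo_res,
    }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")
    return StudyReport(body, report_path, runner.recomputed)
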