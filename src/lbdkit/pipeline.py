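"""Orchestration: run configured stages from a single YAML config.

Every output is re-derivable from the config and input files alone; the
run log records the package version, seeds and effective parameters.  Any
stage failure aborts the run naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from . import catalog as cat
from . import cispromoter as cis
from . import expression as expr
from . import lobscan, ortho, phylo
from .seqio import read_fasta

logger = logging.getLogger(__name__)

_KNOWN_BLOCKS = {
    "output_dir", "seed", "catalog", "scan", "phylo", "ortho",
    "promoters", "expression",
}
_KNOWN_KEYS = {
    "catalog": {"locus_table", "gff3", "max_gap", "min_size"},
    "scan": {"proteins"},
    "phylo": {"alignment", "reference", "reps", "collapse_below",
              "min_support", "min_coverage", "model"},
    "ortho": {"vitis", "species", "e_max", "identity_min"},
    "promoters": {"targets", "background", "motifs", "alpha"},
    "expression": {"matrix", "meta", "distance_threshold", "threshold_abs",
                   "heatmap"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    output_dir: Path
    seed: int = 0
    blocks: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Optional[Path] = None) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block, keys in _KNOWN_KEYS.items():
            extra = set(raw.get(block, {}) or {}) - keys
            if extra:
                raise ValueError(f"unknown keys in {block!r}: {sorted(extra)}")
        out_dir = Path(raw.get("output_dir", "lbdkit_out"))
        if base is not None and not out_dir.is_absolute():
            out_dir = base / out_dir
        blocks = {
            k: dict(raw[k] or {}) for k in _KNOWN_KEYS if k in raw
        }
        if base is not None:
            for block in blocks.values():
                for key, val in block.items():
                    if key in ("locus_table", "gff3", "proteins", "alignment",
                               "reference", "vitis", "targets", "background",
                               "motifs", "matrix", "meta"):
                        if isinstance(val, str) and val != "bundled":
                            block[key] = str((base / val).resolve()) if not Path(val).is_absolute() else val
                    if key == "species" and isinstance(val, dict):
                        block[key] = {
                            sp: str((base / p).resolve()) if not Path(p).is_absolute() else p
                            for sp, p in val.items()
                        }
        return cls(out_dir, int(raw.get("seed", 0)), blocks)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; return the machine-readable summary."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"version": __version__, "seed": config.seed,
                               "stages": {}}
    order = ["scan", "catalog", "phylo", "ortho", "promoters", "expression"]
    for stage in order:
        if stage not in config.blocks:
            continue
        block = config.blocks[stage]
        try:
            runner = globals()[f"_run_{stage}"]
            summary["stages"][stage] = runner(block, config, out)
            logger.info("stage %s done", stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        f"lbdkit {__version__}\nseed {config.seed}\n"
        + "".join(f"{k}: {json.dumps(v, sort_keys=True)}\n" for k, v in config.blocks.items())
    )
    return summary


def _run_catalog(block: dict, config: PipelineConfig, out: Path) -> dict:
    table = block.get("locus_table", "bundled")
    loci = (
        cat.load_reference_catalog()
        if table == "bundled"
        else cat.parse_locus_table(table)
    )
    census = cat.family_summary(loci)
    dist = cat.chromosome_distribution(loci)
    arrays = cat.detect_tandem_arrays(
        loci, int(block.get("max_gap", 100_000)), int(block.get("min_size", 2))
    )
    with open(out / "catalog_loci.tsv", "w") as fh:
        fh.write("locus_id\tshort_name\tchromosome\tstrand\tstart\tend\tlength\n")
        for l in loci:
            fh.write(
                f"{l.locus_id}\t{l.short_name}\t{l.chromosome}\t{l.strand}\t"
                f"{l.start}\t{l.end}\t{cat.locus_length(l)}\n"
            )
    with open(out / "catalog_arrays.tsv", "w") as fh:
        fh.write("chromosome\tsubclass\tsize\tspan\tmembers\n")
        for a in arrays:
            fh.write(
                f"{a.chromosome}\t{a.subclass}\t{a.size}\t{a.span}\t"
                + ",".join(a.member_loci) + "\n"
            )
    result = {
        "n_loci": census.total,
        "class_counts": census.class_counts,
        "subclass_counts": census.subclass_counts,
        "chromosome_distribution": dist,
        "n_tandem_arrays": len(arrays),
    }
    if block.get("gff3"):
        structures, hist = cat.exon_structure_summary(block["gff3"])
        with open(out / "catalog_structures.tsv", "w") as fh:
            fh.write("locus_id\tn_exons\tn_noncoding_exons\tn_nonsense_exons\n")
            for s in structures:
                fh.write(
                    f"{s.locus_id}\t{s.n_exons}\t{s.n_noncoding_exons}\t{s.n_nonsense_exons}\n"
                )
        result["exon_histogram"] = {str(k): v for k, v in sorted(hist.items())}
    return result


def _run_scan(block: dict, config: PipelineConfig, out: Path) -> dict:
    proteins = read_fasta(block["proteins"])
    counts = {"I": 0, "II": 0, "none": 0}
    with open(out / "scan_annotations.tsv", "w") as fh:
        fh.write(
            "sequence\tclass\tc_block\tgas\tzipper\tzipper_complete\n"
        )
        for name, seq in proteins.items():
            ann = lobscan.classify_protein(seq)
            counts[ann.class_call] += 1
            fmt = lambda span: f"{span[0]}-{span[1]}" if span else "."
            fh.write(
                f"{name}\t{ann.class_call}\t{fmt(ann.c_block_span)}\t"
                f"{fmt(ann.gas_span)}\t{fmt(ann.zipper_span)}\t"
                f"{'yes' if ann.zipper_complete else 'no'}\n"
            )
    return {"n_sequences": len(proteins), "class_counts": counts}


def _run_phylo(block: dict, config: PipelineConfig, out: Path) -> dict:
    msa = read_fasta(block["alignment"])
    msa = phylo.filter_columns(msa, float(block.get("min_coverage", 0.95)))
    tree = phylo.bootstrap_tree(
        msa,
        n_reps=int(block.get("reps", 100)),
        seed=config.seed,
        collapse_below=float(block.get("collapse_below", 30)),
        model=block.get("model", "poisson"),
    )
    (out / "phylo_tree.nwk").write_text(tree.to_newick() + "\n")
    result = {"n_taxa": len(tree.leaf_names)}
    if block.get("reference"):
        reference = {}
        for line in Path(block["reference"]).read_text().splitlines():
            if line.strip() and not line.startswith("#"):
                gene, subclass = line.split("\t")[:2]
                reference[gene] = subclass
        assignments = phylo.assign_subclasses(
            tree, reference, float(block.get("min_support", 70))
        )
        with open(out / "phylo_subclasses.tsv", "w") as fh:
            fh.write("gene\tstatus\tsubclass\tsupport\tevidence\n")
            for a in assignments:
                fh.write(
                    f"{a.gene}\t{a.status}\t{a.subclass or '.'}\t"
                    f"{a.support if a.support is not None else '.'}\t{a.evidence}\n"
                )
        result["n_assigned"] = sum(a.status == "assigned" for a in assignments)
    return result


def _run_ortho(block: dict, config: PipelineConfig, out: Path) -> dict:
    vitis = read_fasta(block["vitis"])
    species_sets = {sp: read_fasta(p) for sp, p in block["species"].items()}
    matrix, results = ortho.ortholog_presence_matrix(
        vitis, species_sets,
        e_max=float(block.get("e_max", 1e-20)),
        identity_min=float(block.get("identity_min", 0.40)),
    )
    matrix.to_csv(out / "ortho_matrix.tsv", sep="\t")
    counts = {"one_to_one": 0, "homolog_only": 0, "no_match": 0}
    for r in results:
        counts[r.category] += 1
    return {"n_genes": len(vitis), "n_species": len(species_sets),
            "category_counts": counts}


def _run_promoters(block: dict, config: PipelineConfig, out: Path) -> dict:
    targets = read_fasta(block["targets"])
    background = read_fasta(block["background"])
    window = max(
        max((len(s) for s in targets.values()), default=0),
        max((len(s) for s in background.values()), default=0),
    )
    tset = cis.PromoterSet(targets, window)
    bset = cis.PromoterSet(background, window)
    motifs = cis.load_motif_dictionary(
        None if block.get("motifs", "bundled") == "bundled" else block["motifs"]
    )
    rows = cis.motif_enrichment(tset, bset, motifs, float(block.get("alpha", 0.01)))
    with open(out / "promoter_enrichment.tsv", "w") as fh:
        fh.write("motif\tn_target_with\tn_target\tn_background_with\tn_background\tp_value\tenriched\n")
        for r in sorted(rows, key=lambda r: r.p_value):
            fh.write(
                f"{r.motif}\t{r.n_target_with}\t{r.n_target}\t{r.n_background_with}\t"
                f"{r.n_background}\t{r.p_value:.3g}\t{'yes' if r.enriched else 'no'}\n"
            )
    return {
        "n_motifs": len(motifs),
        "n_enriched": sum(r.enriched for r in rows),
    }


def _run_expression(block: dict, config: PipelineConfig, out: Path) -> dict:
    m = expr.read_expression_matrix(block["matrix"], block["meta"])
    calls = expr.assign_tissue_ontology(m, float(block.get("threshold_abs", 256)))
    with open(out / "expression_tissues.tsv", "w") as fh:
        fh.write("gene\ttissues\n")
        for c in calls:
            fh.write(f"{c.gene}\t{','.join(sorted(c.tissues)) or '.'}\n")
    clusters = expr.coexpression_clusters(
        m, float(block.get("distance_threshold", 0.2))
    )
    with open(out / "expression_clusters.tsv", "w") as fh:
        fh.write("cluster\tsize\tmax_internal_distance\tmembers\n")
        for i, c in enumerate(clusters, 1):
            fh.write(
                f"{i}\t{len(c.members)}\t{c.max_internal_distance:.4f}\t"
                + ",".join(c.members) + "\n"
            )
    if block.get("heatmap"):
        expr.plot_heatmap(m, out / "expression_heatmap.png")
    return {
        "n_genes": len(m.genes),
        "n_samples": len(m.samples),
        "n_clusters": len(clusters),
        "n_genes_with_tissue": sum(bool(c.tissues) for c in calls),
    }
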