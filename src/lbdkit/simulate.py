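"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of a :class:`SimConfig`: the same config
(including its seed) yields byte-identical output.  Ground truth is
returned alongside the data so downstream operations have planted-signal
recovery tests: domain classes for the scanner, tandem arrays for the
catalog, ortholog categories for the RBH search, motif plants for the
enrichment test and module membership / tissue labels for the expression
analyses.

The generators emulate the *statistical structure* the analyses assume,
not the biology in full: background residues are uniform over the 20 amino
acids / 4 nucleotides (the simplest null, conservative for pattern
scanning), ortholog families evolve by i.i.d. point substitutions with no
indels, and co-expression modules use a shared-latent-signal construction
whose variance ratio is solved from the target pairwise Pearson
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneLocus
from .expression import ExpressionMatrix
from .lobscan import (
    AMINO_ACIDS,
    DEFAULT_GRAMMAR,
    MotifGrammar,
    classify_protein,
    scan_c_block,
    scan_gas_block,
    scan_zipper,
)

__all__ = [
    "SimConfig",
    "SyntheticProteome",
    "SyntheticGeneModels",
    "SyntheticFamilies",
    "SyntheticPromoters",
    "SyntheticExpression",
    "generate_proteome",
    "generate_gene_models",
    "generate_ortholog_families",
    "generate_promoters",
    "generate_expression",
]

_NUCS = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters for all synthetic generators (see each generator's doc)."""

    seed: int = 0
    # proteome
    n_class1: int = 5
    n_class2: int = 3
    n_decoys: int = 10
    protein_len: tuple[int, int] = (180, 260)
    # gene models
    n_chromosomes: int = 19
    chromosome_len: int = 30_000_000
    genes_per_chromosome: int = 4
    tandem_array_spec: tuple[tuple[int, int, int], ...] = ()
    # ortholog families
    n_family_genes: int = 20
    n_species: int = 3
    mutation_rate: float = 0.05
    loss_prob: float = 0.0
    dup_prob: float = 0.0
    # promoters
    n_target_promoters: int = 20
    n_background_promoters: int = 20
    promoter_len: int = 500
    planted_motif: str = "ACGTGGC"
    motif_freq_target: float = 1.0
    motif_freq_background: float = 0.0
    # expression
    n_modules: int = 2
    module_size: int = 6
    module_pcc: float = 0.95
    n_tissue_specific: int = 5
    n_expr_background: int = 30
    n_tissues: int = 12
    n_replicates: int = 3
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("loss_prob", "dup_prob", "mutation_rate",
                     "motif_freq_target", "motif_freq_background", "module_pcc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_class1", "n_class2", "n_decoys", "n_chromosomes",
                     "n_family_genes", "n_species", "n_target_promoters",
                     "n_background_promoters", "n_modules", "module_size",
                     "n_tissue_specific", "n_expr_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.protein_len[0] < 80 or self.protein_len[0] > self.protein_len[1]:
            raise ValueError("protein_len must be an increasing range with min >= 80")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for chrom, n_genes, max_gap in self.tandem_array_spec:
            if chrom < 1 or chrom > self.n_chromosomes:
                raise ValueError(
                    f"tandem array on chromosome {chrom} outside 1..{self.n_chromosomes}"
                )
            if n_genes < 2 or max_gap <= 0:
                raise ValueError("tandem arrays need >= 2 genes and a positive gap")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so outputs do not entangle
    return np.random.default_rng([config.seed, stream])


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NUCS), size=n))


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticProteome:
    sequences: dict[str, str]        # insertion-ordered
    labels: dict[str, str]           # "I", "II" or "none"

    def to_fasta(self) -> str:
        return "".join(f">{name}\n{seq}\n" for name, seq in self.sequences.items())


def _build_domain_protein(
    rng: np.random.Generator,
    grammar: MotifGrammar,
    complete_zipper: bool,
    length: int,
) -> str:
    """One protein with C-block + GAS + (complete or broken) zipper."""
    non_anchor = [a for a in AMINO_ACIDS if a not in grammar.zipper_alphabet]
    while True:
        nterm = _random_aa(rng, int(rng.integers(10, 40)))
        c_block = "C" + "".join(
            _random_aa(rng, s) + "C" for s in grammar.c_spacings
        )
        linker1 = _random_aa(rng, int(rng.integers(5, 30)))
        gas = (
            "F" + _random_aa(rng, 2) + str(rng.choice(list("VA"))) + "H"
            + _random_aa(rng, int(rng.integers(8, 20)))
            + "DP" + str(rng.choice(list("VI"))) + "YG"
        )
        linker2 = _random_aa(rng, int(rng.integers(5, 25)))
        n_anchors = grammar.n_zipper_anchors
        if complete_zipper:
            anchor_ok = [True] * n_anchors
        else:
            # break 1..(n-2) anchors, keeping the first anchor and at least
            # min_partial_anchors intact so the frame reads as incomplete
            n_broken = int(rng.integers(1, n_anchors - grammar.min_partial_anchors + 1))
            broken = rng.choice(np.arange(1, n_anchors), size=n_broken, replace=False)
            anchor_ok = [i not in broken for i in range(n_anchors)]
        parts = []
        for i in range(n_anchors):
            aa = (
                str(rng.choice(list(grammar.zipper_alphabet)))
                if anchor_ok[i]
                else str(rng.choice(non_anchor))
            )
            parts.append(aa)
            if i < n_anchors - 1:
                parts.append(_random_aa(rng, grammar.zipper_spacings[i]))
        zipper = "".join(parts)
        core = nterm + c_block + linker1 + gas + linker2 + zipper
        cterm_len = max(0, length - len(core))
        seq = core + _random_aa(rng, cterm_len)
        want = "I" if complete_zipper else "II"
        if classify_protein(seq, grammar).class_call == want:
            return seq


def _build_decoy(rng: np.random.Generator, grammar: MotifGrammar, length: int) -> str:
    """Random protein rejected until it contains none of the three blocks."""
    while True:
        seq = _random_aa(rng, length)
        if scan_c_block(seq, grammar):
            continue
        span, complete = scan_zipper(seq, 0, grammar)
        if complete:
            continue
        gas_span, _ = scan_gas_block(seq, 0, None, grammar)
        if gas_span is not None:
            continue
        return seq


def generate_proteome(
    config: SimConfig, grammar: MotifGrammar = DEFAULT_GRAMMAR
) -> SyntheticProteome:
    """Labelled Class I / Class II / decoy proteins.

    Class I proteins contain, in order, a C-block, a GAS block and a
    complete zipper; Class II proteins the same with >= 1 zipper anchor
    replaced by a non-hydrophobic residue; decoys contain none of the
    three blocks (rejection-sampled against the scanners).
    """
    total = config.n_class1 + config.n_class2 + config.n_decoys
    if total == 0:
        raise ValueError("zero proteins requested")
    rng = _rng(config, 1)
    lo, hi = config.protein_len
    sequences: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i in range(config.n_class1):
        name = f"classI_{i + 1:03d}"
        sequences[name] = _build_domain_protein(
            rng, grammar, True, int(rng.integers(lo, hi + 1))
        )
        labels[name] = "I"
    for i in range(config.n_class2):
        name = f"classII_{i + 1:03d}"
        sequences[name] = _build_domain_protein(
            rng, grammar, False, int(rng.integers(lo, hi + 1))
        )
        labels[name] = "II"
    for i in range(config.n_decoys):
        name = f"decoy_{i + 1:03d}"
        sequences[name] = _build_decoy(rng, grammar, int(rng.integers(lo, hi + 1)))
        labels[name] = "none"
    return SyntheticProteome(sequences, labels)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGeneModels:
    catalog: list[GeneLocus]
    gff3: str
    arrays_truth: list[tuple[str, ...]]          # planted arrays as locus-id runs
    structures_truth: dict[str, tuple[int, int]]  # locus -> (n_exons, n_noncoding)


_SUBCLASS_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def generate_gene_models(config: SimConfig) -> SyntheticGeneModels:
    """Chromosomal gene catalog with planted tandem arrays + GFF3 models.

    Planted arrays are runs of same-subclass genes whose start-to-start
    gaps respect the per-array bound; background genes each get a unique
    subclass on their chromosome and are spaced far apart, so the planted
    arrays are exactly the detectable ones.  Every gene also receives a
    known exon/intron structure (1-3 exons, optionally a non-coding first
    exon) emitted as GFF3.
    """
    rng = _rng(config, 2)
    catalog: list[GeneLocus] = []
    arrays_truth: list[tuple[str, ...]] = []
    structures: dict[str, tuple[int, int]] = {}
    gff_lines = ["##gff-version 3"]
    gene_counter = 0
    subclass_index: dict[str, int] = {}

    arrays_by_chrom: dict[int, list[tuple[int, int]]] = {}
    for chrom, n_genes, max_gap in config.tandem_array_spec:
        arrays_by_chrom.setdefault(chrom, []).append((n_genes, max_gap))

    def next_name(subclass: str) -> str:
        subclass_index[subclass] = subclass_index.get(subclass, 0) + 1
        return f"LBDI{subclass}{subclass_index[subclass]}"

    def add_gene(chrom: int, start: int, end: int, subclass: str) -> GeneLocus:
        nonlocal gene_counter
        gene_counter += 1
        locus_id = f"Vitvi{chrom:02d}g{gene_counter:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        locus = GeneLocus(
            locus_id, next_name(subclass), (), strand, start, end
        )
        catalog.append(locus)
        _emit_gff(gff_lines, rng, locus, structures)
        return locus

    for chrom in range(1, config.n_chromosomes + 1):
        used_letters: list[str] = []
        pos = int(rng.integers(100_000, 200_000))
        # planted arrays first, at the chromosome head
        for n_genes, max_gap in arrays_by_chrom.get(chrom, []):
            letter = _SUBCLASS_LETTERS[len(used_letters) % 26]
            used_letters.append(letter)
            members = []
            for k in range(n_genes):
                gene_len = int(rng.integers(800, 2500))
                if pos + gene_len > config.chromosome_len:
                    raise ValueError(
                        f"infeasible packing on chromosome {chrom}: "
                        f"{n_genes}-gene array exceeds chromosome length"
                    )
                locus = add_gene(chrom, pos, pos + gene_len, letter)
                members.append(locus.locus_id)
                if k < n_genes - 1:
                    gap = int(rng.integers(gene_len + 500, max(gene_len + 501, max_gap)))
                    pos += min(gap, max_gap)
            arrays_truth.append(tuple(members))
            pos += 400_000  # clear margin after the array
        # background singletons, each with its own subclass letter
        for _ in range(config.genes_per_chromosome):
            if len(used_letters) >= 26:
                raise ValueError("too many genes per chromosome for unique subclasses")
            letter = _SUBCLASS_LETTERS[len(used_letters) % 26]
            used_letters.append(letter)
            gene_len = int(rng.integers(800, 2500))
            if pos + gene_len > config.chromosome_len:
                raise ValueError(
                    f"infeasible packing on chromosome {chrom}: "
                    "background genes exceed chromosome length"
                )
            add_gene(chrom, pos, pos + gene_len, letter)
            pos += int(rng.integers(300_000, 500_000))

    return SyntheticGeneModels(
        catalog, "\n".join(gff_lines) + "\n", arrays_truth, structures
    )


def _emit_gff(
    lines: list[str],
    rng: np.random.Generator,
    locus: GeneLocus,
    structures: dict[str, tuple[int, int]],
) -> None:
    chrom = f"chr{locus.chromosome}"
    n_exons = int(rng.integers(1, 4))
    noncoding_first = bool(n_exons >= 2 and rng.random() < 0.3)
    gid = locus.locus_id
    lines.append(
        f"{chrom}\tlbdkit\tgene\t{locus.start}\t{locus.end}\t.\t{locus.strand}\t.\tID={gid}"
    )
    lines.append(
        f"{chrom}\tlbdkit\tmRNA\t{locus.start}\t{locus.end}\t.\t{locus.strand}\t.\t"
        f"ID={gid}.1;Parent={gid}"
    )
    span = locus.end - locus.start
    bounds = sorted(
        {int(x) for x in rng.integers(40, max(41, span - 40), size=max(0, n_exons - 1) * 2)}
    )
    while len(bounds) < (n_exons - 1) * 2:
        bounds.append(bounds[-1] + 1 if bounds else 40)
    bounds = sorted(bounds)[: (n_exons - 1) * 2]
    cuts = [locus.start] + [locus.start + b for b in bounds] + [locus.end]
    exons = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_exons)]
    for i, (s, e) in enumerate(exons):
        lines.append(
            f"{chrom}\tlbdkit\texon\t{s}\t{e}\t.\t{locus.strand}\t.\t"
            f"ID={gid}.1.exon{i + 1};Parent={gid}.1"
        )
        if not (noncoding_first and i == 0):
            lines.append(
                f"{chrom}\tlbdkit\tCDS\t{s}\t{e}\t.\t{locus.strand}\t0\t"
                f"ID={gid}.1.cds{i + 1};Parent={gid}.1"
            )
    structures[gid] = (n_exons, 1 if noncoding_first else 0)


# ---------------------------------------------------------------------------
# ortholog families
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFamilies:
    vitis: dict[str, str]
    species: dict[str, dict[str, str]]
    truth: dict[tuple[str, str], str]  # (vitis gene, species) -> category


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alternatives = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = str(rng.choice(alternatives))
    return "".join(out)


def generate_ortholog_families(config: SimConfig) -> SyntheticFamilies:
    """Per-species protein sets derived from shared ancestral genes.

    Each ancestral (grapevine) gene is copied into every species with
    i.i.d. point substitutions at ``mutation_rate``.  With ``loss_prob``
    the species copy is dropped (true no-match); otherwise with
    ``dup_prob`` it is duplicated into two diverged copies (true
    homolog-only: a one-to-many relationship is not a one-to-one
    ortholog).  Loss takes precedence over duplication.
    """
    rng = _rng(config, 3)
    lo, hi = config.protein_len
    vitis = {
        f"Vv{g + 1:03d}": _random_aa(rng, int(rng.integers(lo, hi + 1)))
        for g in range(config.n_family_genes)
    }
    species: dict[str, dict[str, str]] = {}
    truth: dict[tuple[str, str], str] = {}
    for s in range(config.n_species):
        sp = f"sp{s + 1}"
        genes: dict[str, str] = {}
        for gname, gseq in vitis.items():
            u_loss, u_dup = rng.random(), rng.random()
            if u_loss < config.loss_prob:
                truth[(gname, sp)] = "no_match"
                continue
            base = _mutate(rng, gseq, config.mutation_rate)
            if u_dup < config.dup_prob:
                genes[f"{sp}_{gname}a"] = _mutate(rng, base, config.mutation_rate / 2)
                genes[f"{sp}_{gname}b"] = _mutate(rng, base, config.mutation_rate / 2)
                truth[(gname, sp)] = "homolog_only"
            else:
                genes[f"{sp}_{gname}"] = base
                truth[(gname, sp)] = "one_to_one"
        species[sp] = genes
    return SyntheticFamilies(vitis, species, truth)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPromoters:
    targets: dict[str, str]
    background: dict[str, str]
    plant_positions: dict[str, int]   # promoter id -> planted offset
    motif: str


def generate_promoters(config: SimConfig) -> SyntheticPromoters:
    """Target/background promoters with a motif planted at set frequencies.

    Each promoter is uniform random DNA; with the per-set probability the
    planted motif replaces a window at a uniform position.  Plant offsets
    are recorded (chance occurrences elsewhere are possible and are part
    of the background model).
    """
    rng = _rng(config, 4)
    motif = config.planted_motif.upper()
    if len(motif) > config.promoter_len:
        raise ValueError("planted motif longer than the promoter window")

    def build(n: int, prefix: str, freq: float) -> tuple[dict[str, str], dict[str, int]]:
        seqs: dict[str, str] = {}
        plants: dict[str, int] = {}
        for i in range(n):
            name = f"{prefix}{i + 1:03d}"
            seq = _random_dna(rng, config.promoter_len)
            if rng.random() < freq:
                pos = int(rng.integers(0, config.promoter_len - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
                plants[name] = pos
            seqs[name] = seq
        return seqs, plants

    targets, p1 = build(config.n_target_promoters, "tgt", config.motif_freq_target)
    background, p2 = build(
        config.n_background_promoters, "bg", config.motif_freq_background
    )
    return SyntheticPromoters(targets, background, {**p1, **p2}, motif)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpression:
    matrix: ExpressionMatrix
    modules_truth: list[tuple[str, ...]]
    tissue_truth: dict[str, str]  # tissue-specific gene -> designated tissue


def generate_expression(config: SimConfig) -> SyntheticExpression:
    """Expression matrix with planted co-expression modules and
    tissue-specific genes.

    Module genes follow ``x = baseline + a*(sqrt(r) z + sqrt(1-r) e)``
    with a shared per-sample latent ``z`` per module and independent noise
    ``e``, so the expected pairwise Pearson correlation is exactly the
    configured ``module_pcc``.  Tissue-specific genes exceed the linear-
    scale 256 threshold (log2 = 8) only in their designated tissue's
    samples.  Remaining background genes are independent noise.
    """
    rng = _rng(config, 5)
    tissues = [f"T{t + 1:02d}" for t in range(config.n_tissues)]
    samples, tissue_of = [], {}
    for t in tissues:
        for r in range(config.n_replicates):
            sid = f"{t}_r{r + 1}"
            samples.append(sid)
            tissue_of[sid] = t
    n_samples = len(samples)
    baseline, amplitude = 6.0, 1.2 * config.noise_sd / 0.5

    rows: dict[str, np.ndarray] = {}
    modules_truth: list[tuple[str, ...]] = []
    r = config.module_pcc
    for m in range(config.n_modules):
        latent = rng.normal(size=n_samples)
        members = []
        for g in range(config.module_size):
            gene = f"mod{m + 1}_g{g + 1}"
            noise = rng.normal(size=n_samples)
            rows[gene] = baseline + amplitude * (
                math.sqrt(r) * latent + math.sqrt(1.0 - r) * noise
            )
            members.append(gene)
        modules_truth.append(tuple(members))

    tissue_truth: dict[str, str] = {}
    for g in range(config.n_tissue_specific):
        gene = f"spec_g{g + 1}"
        tissue = tissues[g % len(tissues)]
        tissue_truth[gene] = tissue
        vals = rng.normal(5.0, 0.3, size=n_samples)
        mask = np.array([tissue_of[s] == tissue for s in samples])
        vals[mask] = rng.normal(9.5, 0.3, size=int(mask.sum()))
        rows[gene] = vals

    for g in range(config.n_expr_background):
        rows[f"bg_g{g + 1}"] = rng.normal(baseline, config.noise_sd, size=n_samples)

    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    meta = pd.DataFrame(
        {"tissue": [tissue_of[s] for s in samples], "condition": "atlas",
         "platform": "synthetic"},
        index=pd.Index(samples, name="sample"),
    )
    return SyntheticExpression(
        ExpressionMatrix(values, meta), modules_truth, tissue_truth
    )
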