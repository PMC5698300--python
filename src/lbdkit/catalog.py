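"""Gene-catalog parsing and locus statistics for the LBD family.

The catalog is the tab-delimited locus table (one row per gene: locus id,
family short name, legacy names, strand, coordinates).  A transcription of
the published 50-gene grapevine *VviLBD* catalog ships with the package
(:func:`load_reference_catalog`).

A deliberate convention used throughout: the *locus length* is ``end -
start``, not the usual 1-based-inclusive ``end - start + 1``.  The published
catalog quotes locus sizes under the former convention (e.g. LBDId4 at
1022072-1022675 is listed as a 603-nt locus), and we reproduce it exactly.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "FamilyName",
    "GeneLocus",
    "GeneStructure",
    "TandemArray",
    "FamilyCensus",
    "parse_family_name",
    "format_family_name",
    "parse_locus_table",
    "write_locus_table",
    "load_reference_catalog",
    "locus_length",
    "family_summary",
    "chromosome_distribution",
    "detect_tandem_arrays",
    "exon_structure_summary",
]

_NAME_RE = re.compile(r"^LBD(?P<cls>I{1,2})(?P<sub>[a-z])(?P<idx>[1-9][0-9]*)$")
_LOCUS_RE = re.compile(r"^[A-Za-z]+(?P<chrom>\d{2})g\d+$")

#: Label used for unplaced scaffolds (chromosome field "00").
UNPLACED_LABEL = "Unknown"


@dataclass(frozen=True)
class FamilyName:
    """Parsed family nomenclature: class (roman), subclass letter, index."""

    family: str
    class_label: str  # "I" or "II"
    subclass: str     # single lowercase letter
    index: int

    def __str__(self) -> str:
        return format_family_name(self)

    @property
    def class_subclass(self) -> str:
        """Combined key, e.g. ``"If"`` or ``"IIa"``."""
        return self.class_label + self.subclass


def parse_family_name(short_name: str) -> FamilyName:
    """Parse a family gene symbol such as ``"LBDIIa3"`` or ``"LBDIf10"``.

    The grammar is ``LBD`` + roman class numeral (I or II) + one subclass
    letter + a positive integer.
    """
    m = _NAME_RE.match(short_name)
    if m is None:
        raise ValueError(f"not a valid LBD family gene symbol: {short_name!r}")
    return FamilyName(
        family="LBD",
        class_label=m.group("cls"),
        subclass=m.group("sub"),
        index=int(m.group("idx")),
    )


def format_family_name(name: FamilyName) -> str:
    return f"{name.family}{name.class_label}{name.subclass}{name.index}"


@dataclass(frozen=True)
class GeneLocus:
    """One catalog row: identifiers and genomic placement of a family gene.

    ``start`` and ``end`` are 1-based positions with ``start <= end``
    regardless of strand.  The chromosome label is the two-digit field of
    the locus id ("00" marks unplaced scaffolds).
    """

    locus_id: str
    short_name: str
    legacy_names: tuple[str, ...]
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start {self.start} > end {self.end}")
        if _LOCUS_RE.match(self.locus_id) is None:
            raise ValueError(f"unparseable locus id: {self.locus_id!r}")
        # validate the short name eagerly so a bad row fails at parse time
        parse_family_name(self.short_name)

    @property
    def chromosome(self) -> str:
        """Two-digit chromosome label parsed from the locus id."""
        return _LOCUS_RE.match(self.locus_id).group("chrom")

    @property
    def family_name(self) -> FamilyName:
        return parse_family_name(self.short_name)


def locus_length(locus: GeneLocus) -> int:
    """Locus size in bp under the catalog's ``end - start`` convention."""
    return locus.end - locus.start


_COLUMNS = ("locus_id", "short_name", "legacy_names", "strand", "start", "end")


def parse_locus_table(path) -> list[GeneLocus]:
    """Read a tab-delimited locus table into a list of :class:`GeneLocus`.

    Expected columns: locus_id, short_name, legacy_names (comma separated,
    may be empty), strand, start, end.  Row order is preserved.  Malformed
    rows raise :class:`ValueError` naming the offending row.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    if tuple(header) != _COLUMNS:
        raise ValueError(f"unexpected locus table header: {header}")
    loci: list[GeneLocus] = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(_COLUMNS):
            raise ValueError(f"row {i}: expected {len(_COLUMNS)} columns, got {len(fields)}")
        locus_id, short_name, legacy, strand, start_s, end_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"row {i} ({locus_id}): non-numeric coordinates {start_s!r}/{end_s!r}") from None
        legacy_names = tuple(x for x in legacy.split(",") if x)
        try:
            loci.append(
                GeneLocus(locus_id, short_name, legacy_names, strand, start, end)
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return loci


def write_locus_table(loci: Iterable[GeneLocus], path) -> None:
    """Write loci back to the tab-delimited table format (lossless round-trip)."""
    out = io.StringIO()
    out.write("\t".join(_COLUMNS) + "\n")
    for loc in loci:
        out.write(
            "\t".join(
                [
                    loc.locus_id,
                    loc.short_name,
                    ",".join(loc.legacy_names),
                    loc.strand,
                    str(loc.start),
                    str(loc.end),
                ]
            )
            + "\n"
        )
    if hasattr(path, "write"):
        path.write(out.getvalue())
    else:
        Path(path).write_text(out.getvalue())


def load_reference_catalog() -> list[GeneLocus]:
    """The bundled 50-gene grapevine *VviLBD* locus table."""
    ref = resources.files("lbdkit.data").joinpath("table1_vvilbd.tsv")
    return parse_locus_table(io.StringIO(ref.read_text()))


@dataclass
class FamilyCensus:
    """Per-class and per-subclass gene counts."""

    total: int
    class_counts: dict[str, int]
    subclass_counts: dict[str, int]  # keyed by e.g. "If", "IIa"

    def subclasses_of(self, class_label: str) -> list[str]:
        """Distinct subclass letters observed for a class, sorted."""
        return sorted(
            key[len(class_label):]
            for key in self.subclass_counts
            if key.startswith(class_label) and not key.startswith(class_label + "I")
        )


def family_summary(catalog: Iterable[GeneLocus]) -> FamilyCensus:
    """Census of classes and subclasses from the gene symbols."""
    class_counts: Counter[str] = Counter()
    subclass_counts: Counter[str] = Counter()
    total = 0
    for locus in catalog:
        name = locus.family_name
        class_counts[name.class_label] += 1
        subclass_counts[name.class_subclass] += 1
        total += 1
    return FamilyCensus(total, dict(class_counts), dict(subclass_counts))


def chromosome_distribution(catalog: Iterable[GeneLocus]) -> dict[str, int]:
    """Gene counts per chromosome label; unplaced ("00") reported as "Unknown"."""
    counts: Counter[str] = Counter()
    for locus in catalog:
        chrom = locus.chromosome
        counts[UNPLACED_LABEL if chrom == "00" else chrom] += 1
    return dict(counts)


@dataclass(frozen=True)
class TandemArray:
    """A maximal run of same-subclass genes within a chromosome gap bound."""

    chromosome: str
    member_loci: tuple[str, ...]  # locus ids ordered by start
    subclass: str                 # combined key, e.g. "If"
    span: int                     # bp from first start to last end

    @property
    def size(self) -> int:
        return len(self.member_loci)


def detect_tandem_arrays(
    catalog: Iterable[GeneLocus],
    max_gap: int = 100_000,
    min_size: int = 2,
) -> list[TandemArray]:
    """Find tandem-duplication arrays: same-chromosome, same-subclass runs.

    Genes of one (class, subclass) on one chromosome, sorted by start, are
    split wherever the start-to-start gap between consecutive genes exceeds
    ``max_gap``; maximal runs of at least ``min_size`` genes are reported,
    ordered by (chromosome, start).
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    groups: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in catalog:
        key = (locus.chromosome, locus.family_name.class_subclass)
        groups.setdefault(key, []).append(locus)
    arrays: list[TandemArray] = []
    for (chrom, subclass), members in groups.items():
        members.sort(key=lambda l: (l.start, l.locus_id))
        run: list[GeneLocus] = []
        for locus in members:
            if run and locus.start - run[-1].start > max_gap:
                if len(run) >= min_size:
                    arrays.append(_make_array(chrom, subclass, run))
                run = []
            run.append(locus)
        if len(run) >= min_size:
            arrays.append(_make_array(chrom, subclass, run))
    arrays.sort(key=lambda a: (a.chromosome, a.subclass, a.member_loci))
    return arrays


def _make_array(chrom: str, subclass: str, run: list[GeneLocus]) -> TandemArray:
    return TandemArray(
        chromosome=chrom,
        member_loci=tuple(l.locus_id for l in run),
        subclass=subclass,
        span=run[-1].end - run[0].start,
    )


@dataclass(frozen=True)
class GeneStructure:
    """Exon composition of one gene model."""

    locus_id: str
    n_exons: int
    n_noncoding_exons: int
    n_nonsense_exons: int = 0

    def __post_init__(self) -> None:
        if self.n_noncoding_exons + self.n_nonsense_exons > self.n_exons:
            raise ValueError(
                f"{self.locus_id}: non-coding + nonsense exons exceed exon count"
            )


def exon_structure_summary(gff3) -> tuple[list[GeneStructure], dict[int, int]]:
    """Summarise exon structure per gene from GFF3 gene models.

    Exon counts come from the exon features of the first (primary) mRNA of
    each gene.  An exon with no CDS overlap on that mRNA is counted as
    non-coding.  "Nonsense" exons are not computable from coordinates; they
    are read from an ``nonsense=true`` attribute on the exon feature when an
    annotator has supplied one.  Genes without an mRNA child are skipped
    with a warning.

    Returns the per-gene structures and a histogram ``{n_exons: n_genes}``.
    """
    import gffutils

    if hasattr(gff3, "read"):
        data = gff3.read()
    else:
        text = str(gff3)
        data = text if "\n" in text else Path(text).read_text()
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    structures: list[GeneStructure] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            warnings.warn(f"gene {gene.id} has no mRNA child; skipped")
            continue
        mrna = mrnas[0]
        exons = list(db.children(mrna, featuretype="exon", order_by="start"))
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        n_noncoding = 0
        n_nonsense = 0
        for exon in exons:
            if exon.attributes.get("nonsense", ["false"])[0].lower() == "true":
                n_nonsense += 1
                continue
            if not any(c.start <= exon.end and exon.start <= c.end for c in cds):
                n_noncoding += 1
        structures.append(
            GeneStructure(gene.id, len(exons), n_noncoding, n_nonsense)
        )
    hist = Counter(s.n_exons for s in structures)
    return structures, dict(hist)
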