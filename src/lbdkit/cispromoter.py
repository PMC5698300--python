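"""Promoter extraction, IUPAC cis-element scanning and motif enrichment.

Promoters are the window upstream of the translation start on the coding
strand (reverse-complemented for minus-strand genes).  The ``noorf`` option
truncates the window at the nearest upstream annotated gene so neighbouring
coding sequence is not swept in.  Three window presets mirror the common
database analyses: ``plantcare`` (1.5 kb), ``plantpan`` (3 kb) and
``homer`` (2.5 kb).

Enrichment is per-promoter presence/absence against a background promoter
set, scored with the one-sided hypergeometric upper tail.  No multiple-
testing correction is applied by default (raw p < alpha, as such scans are
conventionally reported); Benjamini-Hochberg is available.  An enumerative
exhaustive k-mer scan stands in for de-novo motif discovery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .catalog import GeneLocus

__all__ = [
    "MotifDef",
    "PromoterSet",
    "EnrichmentRow",
    "WINDOW_PRESETS",
    "load_motif_dictionary",
    "extract_promoters",
    "scan_motif",
    "motif_enrichment",
    "kmer_discovery",
    "reverse_complement",
]

#: upstream window presets in bp, named after the analyses they mirror
WINDOW_PRESETS = {"plantcare": 1500, "plantpan": 3000, "homer": 2500}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """A named cis-regulatory element as an IUPAC DNA pattern."""

    name: str
    pattern: str
    category: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC codes {sorted(bad)}")

    def regex(self) -> re.Pattern:
        return re.compile(
            "".join(
                ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]"
                for ch in self.pattern.upper()
            )
        )


def load_motif_dictionary(path=None) -> list[MotifDef]:
    """Load a tab-delimited motif dictionary (name, pattern, category).

    Without a path the curated bundled dictionary is returned: a subset of
    elements reported for this family's promoters, with IUPAC patterns
    drawn from the public PLACE/PlantCARE literature.  The dictionary is
    data, not code — replace it freely.
    """
    if path is None:
        text = resources.files("lbdkit.data").joinpath(
            "motifs_plantcare.tsv"
        ).read_text()
    else:
        text = Path(path).read_text()
    motifs = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:  # skip header
        name, pattern, *rest = line.split("\t")
        motifs.append(MotifDef(name, pattern, rest[0] if rest else ""))
    return motifs


@dataclass
class PromoterSet:
    """Promoter sequences keyed by gene id, plus truncation bookkeeping."""

    sequences: dict[str, str]
    window: int
    truncated: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        too_long = [g for g, s in self.sequences.items() if len(s) > self.window]
        if too_long:
            raise ValueError(f"promoters longer than window: {too_long}")


def extract_promoters(
    genome: Mapping[str, str],
    catalog: Sequence[GeneLocus],
    window: int = 1500,
    noorf: bool = False,
) -> PromoterSet:
    """Extract upstream promoter windows on the coding strand.

    ``genome`` maps chromosome labels (matching ``GeneLocus.chromosome``)
    to sequences.  For a plus-strand gene the window ends at the base
    before the annotated start; minus-strand windows are the reverse
    complement of the downstream flank.  With ``noorf`` the window is
    truncated at the nearest upstream gene boundary; genes at a contig
    edge simply yield shorter sequences (flagged, not an error).
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in catalog:
        if locus.chromosome not in genome:
            raise KeyError(f"{locus.locus_id}: chromosome {locus.chromosome} not in genome")
        by_chrom.setdefault(locus.chromosome, []).append(locus)

    sequences: dict[str, str] = {}
    truncated: dict[str, bool] = {}
    for chrom, loci in by_chrom.items():
        seq = genome[chrom].upper()
        for locus in loci:
            if locus.strand == "+":
                end0 = locus.start - 1          # 0-based, exclusive
                start0 = max(0, end0 - window)
                if noorf:
                    for other in loci:
                        if other is locus:
                            continue
                        bound = other.end        # 0-based exclusive == 1-based end
                        if start0 < bound <= end0:
                            start0 = bound
                prom = seq[start0:end0]
            else:
                start0 = locus.end               # flank starts after the gene
                end0 = min(len(seq), start0 + window)
                if noorf:
                    for other in loci:
                        if other is locus:
                            continue
                        bound = other.start - 1  # 0-based start of the neighbour
                        if start0 <= bound < end0:
                            end0 = bound
                prom = reverse_complement(seq[start0:end0])
            sequences[locus.locus_id] = prom
            truncated[locus.locus_id] = len(prom) < window
    return PromoterSet(sequences, window, truncated)


def scan_motif(
    promoter: str,
    motif: MotifDef,
    both_strands: bool = True,
) -> list[tuple[int, str]]:
    """All motif hits as (0-based offset, strand), sorted by offset.

    Minus-strand hits are reported at the plus-strand coordinate of the
    matched window's left end.
    """
    seq = promoter.upper()
    regex = motif.regex()
    # lookahead wrapper so overlapping occurrences are all reported
    hits = [
        (m.start(), "+")
        for m in re.compile(f"(?=({regex.pattern}))").finditer(seq)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        k = len(motif.pattern)
        for m in re.compile(f"(?=({regex.pattern}))").finditer(rc):
            hits.append((len(seq) - m.start() - k, "-"))
    return sorted(hits)


@dataclass(frozen=True)
class EnrichmentRow:
    motif: str
    n_target_with: int
    n_target: int
    n_background_with: int
    n_background: int
    p_value: float
    enriched: bool
    p_adjusted: Optional[float] = None


def _presence(promoters: Mapping[str, str], motif: MotifDef) -> int:
    return sum(
        1 for seq in promoters.values() if scan_motif(seq, motif, both_strands=True)
    )


def motif_enrichment(
    targets: PromoterSet,
    background: PromoterSet,
    motifs: Sequence[MotifDef],
    alpha: float = 0.01,
    correction: Optional[str] = None,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of motif presence among targets.

    Presence/absence per promoter (not occurrence counts) keeps the test
    robust to promoter-length differences.  ``correction="bh"`` applies
    Benjamini-Hochberg to the p-values; by default raw p < alpha flags a
    motif as enriched.
    """
    if not background.sequences:
        raise ValueError("empty background promoter set")
    overlap = set(targets.sequences) & set(background.sequences)
    if overlap:
        raise ValueError(f"target/background sets overlap: {sorted(overlap)}")
    n_t = len(targets.sequences)
    n_b = len(background.sequences)
    rows = []
    for motif in motifs:
        k_t = _presence(targets.sequences, motif)
        k_b = _presence(background.sequences, motif)
        # P(X >= k_t) with X ~ Hypergeom(M = n_t+n_b, K = k_t+k_b, N = n_t)
        p = float(hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
        p = min(1.0, max(p, np.nextafter(0, 1)))
        rows.append(
            EnrichmentRow(motif.name, k_t, n_t, k_b, n_b, p, p < alpha)
        )
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        rejected, p_adj, _, _ = multipletests(
            [r.p_value for r in rows], alpha=alpha, method="fdr_bh"
        )
        rows = [
            EnrichmentRow(
                r.motif, r.n_target_with, r.n_target, r.n_background_with,
                r.n_background, r.p_value, bool(rej), float(pa),
            )
            for r, rej, pa in zip(rows, rejected, p_adj)
        ]
    return rows


def _canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def kmer_discovery(
    targets: PromoterSet,
    background: PromoterSet,
    k_range: Iterable[int] = range(6, 13),
    top_n: Optional[int] = 50,
) -> pd.DataFrame:
    """Exhaustive k-mer presence enrichment, ranked by hypergeometric p.

    Every k-mer observed in either promoter set is scored by per-promoter
    presence (either strand); reverse-complement pairs are merged under the
    lexicographically smaller representative.  Rows are sorted by
    ascending p-value (ties: more target promoters, then k-mer).
    """
    n_t = len(targets.sequences)
    n_b = len(background.sequences)

    def presence_sets(promoters: Mapping[str, str], k: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seq in promoters.values():
            seq = seq.upper()
            seen = set()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if set(kmer) - set("ACGT"):
                    continue
                seen.add(_canonical_kmer(kmer))
            for kmer in seen:
                counts[kmer] = counts.get(kmer, 0) + 1
        return counts

    records = []
    for k in k_range:
        if all(len(s) < k for s in list(targets.sequences.values()) + list(background.sequences.values())):
            continue
        tc = presence_sets(targets.sequences, k)
        bc = presence_sets(background.sequences, k)
        for kmer in set(tc) | set(bc):
            k_t, k_b = tc.get(kmer, 0), bc.get(kmer, 0)
            p = float(hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
            records.append((kmer, k, k_t, k_b, min(1.0, p)))
    df = pd.DataFrame(
        records, columns=["kmer", "k", "n_target_with", "n_background_with", "p_value"]
    )
    df = df.sort_values(
        by=["p_value", "n_target_with", "kmer"],
        ascending=[True, False, True],
    ).reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df
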