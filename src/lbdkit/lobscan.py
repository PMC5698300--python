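"""LOB-domain motif grammar: block scanners and Class I/II classification.

The LOB domain is modelled as three ordered blocks near the N terminus:

* **C-block** (zinc-finger-like): ``C X2 C X6 C X3 C`` — four invariant
  cysteines with fixed spacing, required for DNA binding.
* **GAS block**: opens with ``F X2 [VA] H`` and closes with ``D P [VI] Y G``,
  of which the proline and glycine are invariant across the family; the
  remaining positions may be relaxed.
* **Leucine-zipper-like motif**: ``[LVI] X6 [LVI] X3 [LVI] X6 [LVI]`` — four
  hydrophobic anchor positions.  Class I proteins carry a complete zipper;
  Class II proteins carry a broken one (or none), with an intact C-block.

The anchor alphabet for the zipper is ``LVI`` rather than leucine alone:
the hydrophobic anchor positions tolerate valine and isoleucine in known
family members, and a strict-leucine grammar would misclassify them.  A
strict mode is available via :class:`MotifGrammar`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "MotifGrammar",
    "LobDomainAnnotation",
    "ConservedBlock",
    "scan_c_block",
    "scan_zipper",
    "scan_gas_block",
    "classify_protein",
    "find_conserved_blocks",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifGrammar:
    """Tunable motif grammar for the three LOB-domain blocks.

    ``zipper_spacings`` gives the number of free residues between
    consecutive anchors; the default ``(6, 3, 6)`` yields the canonical
    four-anchor frame.  ``max_gap_cblock_to_gas`` / ``max_gap_gas_to_zipper``
    bound the residue gaps between blocks during classification; the family
    alignments comfortably fit within the defaults.
    """

    c_spacings: tuple[int, ...] = (2, 6, 3)
    zipper_spacings: tuple[int, ...] = (6, 3, 6)
    zipper_alphabet: str = "LVI"  # set to "L" for strict-leucine mode
    min_partial_anchors: int = 2  # >= this many anchors = incomplete zipper
    gas_strict: bool = True
    max_gap_cblock_to_gas: int = 120
    max_gap_gas_to_zipper: int = 80

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.c_spacings + self.zipper_spacings):
            raise ValueError("spacings must be non-negative")
        if not (1 <= self.min_partial_anchors <= len(self.zipper_spacings) + 1):
            raise ValueError("min_partial_anchors out of range")

    @property
    def n_zipper_anchors(self) -> int:
        return len(self.zipper_spacings) + 1

    @property
    def c_block_len(self) -> int:
        return len(self.c_spacings) + 1 + sum(self.c_spacings)

    @property
    def zipper_len(self) -> int:
        return self.n_zipper_anchors + sum(self.zipper_spacings)


DEFAULT_GRAMMAR = MotifGrammar()


@dataclass(frozen=True)
class LobDomainAnnotation:
    """Located block spans (0-based half-open) and the resulting class call."""

    c_block_span: Optional[tuple[int, int]]
    gas_span: Optional[tuple[int, int]]
    zipper_span: Optional[tuple[int, int]]
    zipper_complete: bool
    class_call: str  # "I", "II" or "none"
    gas_anchor_flags: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.class_call not in ("I", "II", "none"):
            raise ValueError(f"bad class call {self.class_call!r}")
        if self.class_call == "I" and not self.zipper_complete:
            raise ValueError("Class I requires a complete zipper")
        if self.class_call in ("I", "II") and self.c_block_span is None:
            raise ValueError("Class I/II require a C-block")


def _c_block_regex(grammar: MotifGrammar) -> re.Pattern:
    body = "C" + "".join(f".{{{s}}}C" for s in grammar.c_spacings)
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({body}))")


def scan_c_block(
    seq: str, grammar: MotifGrammar = DEFAULT_GRAMMAR
) -> list[tuple[int, int]]:
    """All (possibly overlapping) C-block matches, leftmost first.

    ``X`` is tolerated in the sequence but never matches a cysteine anchor.
    """
    n = grammar.c_block_len
    return [(m.start(), m.start() + n) for m in _c_block_regex(grammar).finditer(seq)]


def scan_zipper(
    seq: str,
    search_from: int = 0,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
    prefer_complete: bool = True,
    search_to: Optional[int] = None,
) -> tuple[Optional[tuple[int, int]], bool]:
    """Locate the zipper frame at or after ``search_from``.

    A frame is *complete* when every anchor position holds a residue from
    the hydrophobic anchor alphabet; a frame with at least
    ``grammar.min_partial_anchors`` (but not all) anchors is a *partial*
    (incomplete) zipper.  With ``prefer_complete`` (default) the first
    complete frame wins even if a partial frame precedes it; otherwise the
    first qualifying frame of either kind is returned.

    ``search_to`` bounds the allowed frame *start* (half-open).
    Returns ``(span, complete)``; ``(None, False)`` when no frame qualifies.
    """
    if search_from < 0 or search_from > len(seq):
        raise ValueError("search_from outside sequence")
    offsets = [0]
    for s in grammar.zipper_spacings:
        offsets.append(offsets[-1] + 1 + s)
    frame_len = grammar.zipper_len
    anchors = set(grammar.zipper_alphabet)
    last_start = len(seq) - frame_len
    if search_to is not None:
        last_start = min(last_start, search_to - 1)
    first_partial: Optional[tuple[int, int]] = None
    for pos in range(search_from, last_start + 1):
        n_hit = sum(seq[pos + o] in anchors for o in offsets)
        if n_hit == len(offsets):
            return (pos, pos + frame_len), True
        # anchor the partial frame on a hydrophobic first position so that
        # frames are not free-floating over arbitrary residues
        if (
            first_partial is None
            and n_hit >= grammar.min_partial_anchors
            and seq[pos] in anchors
        ):
            first_partial = (pos, pos + frame_len)
            if not prefer_complete:
                return first_partial, False
    return first_partial, False


def scan_gas_block(
    seq: str,
    start: int = 0,
    end: Optional[int] = None,
    grammar: MotifGrammar = DEFAULT_GRAMMAR,
) -> tuple[Optional[tuple[int, int]], dict]:
    """Locate the GAS block between ``start`` and ``end``.

    Anchor 1 is ``F X2 [VA] H``; anchor 2, downstream, is ``D P [VI] Y G``.
    In strict mode (``grammar.gas_strict``) both full patterns are required;
    in relaxed mode only the invariant F/H of anchor 1 and P/G of anchor 2.
    Returns ``(span, flags)`` where flags report per-anchor strictness
    ("strict", "relaxed" or None).
    """
    region_end = len(seq) if end is None else min(end, len(seq))
    window = seq[start:region_end]
    strict1 = re.compile(r"F.{2}[VA]H")
    strict2 = re.compile(r"DP[VI]YG")
    relaxed1 = re.compile(r"F.{3}H")
    relaxed2 = re.compile(r".P.{2}G")
    flags: dict = {"anchor1": None, "anchor2": None}

    m1 = strict1.search(window)
    if m1 is not None:
        flags["anchor1"] = "strict"
    elif not grammar.gas_strict:
        m1 = relaxed1.search(window)
        if m1 is not None:
            flags["anchor1"] = "relaxed"
    if m1 is None:
        return None, flags

    tail = window[m1.end():]
    m2 = strict2.search(tail)
    if m2 is not None:
        flags["anchor2"] = "strict"
    elif not grammar.gas_strict:
        m2 = relaxed2.search(tail)
        if m2 is not None:
            flags["anchor2"] = "relaxed"
    if m2 is None:
        return None, flags
    span = (start + m1.start(), start + m1.end() + m2.end())
    return span, flags


def classify_protein(
    seq: str, grammar: MotifGrammar = DEFAULT_GRAMMAR
) -> LobDomainAnnotation:
    """Classify a protein as Class I, Class II or non-family.

    Class I: a C-block followed (within the grammar's gap limits) by a
    complete zipper.  Class II: a C-block but no complete zipper downstream
    of it.  No C-block at all: "none".  The earliest C-block admitting a
    complete downstream grammar match is chosen; failing that, the earliest
    C-block anchors the Class II annotation.
    """
    c_blocks = scan_c_block(seq, grammar)
    if not c_blocks:
        return LobDomainAnnotation(None, None, None, False, "none")

    best_partial: Optional[LobDomainAnnotation] = None
    for c_span in c_blocks:
        c_end = c_span[1]
        gas_span, gas_flags = scan_gas_block(
            seq, c_end, c_end + grammar.max_gap_cblock_to_gas + 10, grammar
        )
        if gas_span is not None:
            z_from = gas_span[1]
            z_to = gas_span[1] + grammar.max_gap_gas_to_zipper
        else:
            z_from = c_end
            z_to = c_end + grammar.max_gap_cblock_to_gas + grammar.max_gap_gas_to_zipper
        zipper_span, complete = scan_zipper(
            seq, z_from, grammar, prefer_complete=True, search_to=z_to
        )
        if complete:
            return LobDomainAnnotation(
                c_span, gas_span, zipper_span, True, "I", gas_flags
            )
        if best_partial is None:
            best_partial = LobDomainAnnotation(
                c_span, gas_span, zipper_span, False, "II", gas_flags
            )
    assert best_partial is not None
    return best_partial


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of conserved alignment columns."""

    start: int  # column interval, 0-based half-open
    end: int
    mean_conservation: float

    @property
    def length(self) -> int:
        return self.end - self.start


def find_conserved_blocks(
    msa: Sequence[str] | dict[str, str],
    min_len: int = 10,
    min_conservation: float = 0.5,
) -> list[ConservedBlock]:
    """Maximal column intervals conserved across an alignment.

    A column qualifies when the majority (non-gap) residue accounts for at
    least ``min_conservation`` of *all* rows — gap rows count against the
    column.  Maximal runs of at least ``min_len`` qualifying columns are
    reported left to right.
    """
    rows = list(msa.values()) if isinstance(msa, dict) else list(msa)
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    n = len(rows)
    scores = []
    for j in range(width):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[j]
            if ch not in "-.":
                counts[ch] = counts.get(ch, 0) + 1
        scores.append(max(counts.values()) / n if counts else 0.0)
    blocks: list[ConservedBlock] = []
    run_start: Optional[int] = None
    for j in range(width + 1):
        ok = j < width and scores[j] >= min_conservation
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            if j - run_start >= min_len:
                mean = sum(scores[run_start:j]) / (j - run_start)
                blocks.append(ConservedBlock(run_start, j, mean))
            run_start = None
    return blocks
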