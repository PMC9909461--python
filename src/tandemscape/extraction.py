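"""Locate a gene in a contig via two flanking anchors and orient it 5'->3'.

The anchors are short unique sequences just outside/at the ends of the gene
(for SLC6A3: a printed 5'-UTR 30-mer and 3'-UTR 31-mer).  The extracted span
runs from the outermost anchor start to the outermost anchor end, anchors
included, and the returned sequence is oriented so that the 5' anchor reads
forward at the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import AlignParams, edit_align
from .seqio import GeneInterval, _validate_dna, reverse_complement

# SLC6A3 anchor sequences as printed (UTR flanks of the gene).  The 3'-UTR
# anchor is a 31-mer; both are used verbatim.
SLC6A3_ANCHOR_5P = "AGCCTCGGCCTCGGGCTCTTATCCAGTAGA"
SLC6A3_ANCHOR_3P = "CAGCGGAAACGAGACAAGGAGGCTGAGGCAG"


class GeneExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class AnchorPair:
    anchor_5p: str = SLC6A3_ANCHOR_5P
    anchor_3p: str = SLC6A3_ANCHOR_3P
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        _validate_dna(self.anchor_5p, "anchor_5p")
        _validate_dna(self.anchor_3p, "anchor_3p")
        if len(self.anchor_5p) < 20 or len(self.anchor_3p) < 20:
            raise ValueError("anchors must be at least 20 bp")
        if self.anchor_5p == self.anchor_3p:
            raise ValueError("anchors must differ")
        if self.anchor_5p == reverse_complement(self.anchor_3p):
            raise ValueError("anchors must not be reverse complements of each other")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class TechComparison:
    similarity_percent: float
    mismatches: int
    indels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity_percent <= 100.0):
            raise ValueError("similarity_percent out of range")
        if self.mismatches < 0 or self.indels < 0:
            raise ValueError("counts must be >= 0")


def _find_occurrences(contig: str, pattern: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        hits, start = [], 0
        while True:
            i = contig.find(pattern, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1
    # Small mismatch budget: sliding Hamming comparison.
    m = len(pattern)
    hits = []
    for i in range(len(contig) - m + 1):
        window = contig[i : i + m]
        mism = sum(1 for x, y in zip(window, pattern) if x != y)
        if mism <= max_mismatches:
            hits.append(i)
    return hits


def _locate_anchor(contig: str, anchor: str, name: str, max_mismatches: int) -> tuple[int, str]:
    """Return (position, orientation) of a uniquely occurring anchor."""
    fwd = _find_occurrences(contig, anchor, max_mismatches)
    rev = _find_occurrences(contig, reverse_complement(anchor), max_mismatches)
    total = len(fwd) + len(rev)
    if total == 0:
        raise GeneExtractionError(f"gene incomplete in contig: anchor {name} not found")
    if total > 1:
        where = [f"+{p}" for p in fwd] + [f"-{p}" for p in rev]
        raise GeneExtractionError(
            f"anchor {name} found {total} times (positions {', '.join(where)}); "
            "gene copy number ambiguous"
        )
    return (fwd[0], "+") if fwd else (rev[0], "-")


def locate_gene(
    contig: str,
    anchors: AnchorPair | None = None,
    contig_name: str = "contig",
) -> tuple[GeneInterval, str]:
    """Find the gene between the two anchors and orient it 5'->3'.

    Both anchors and their reverse complements are searched; each must occur
    exactly once.  The reported interval spans from the outermost anchor
    start to the outermost anchor end (anchors included), in contig
    coordinates; the returned sequence is reverse-complemented when the gene
    lies on the minus strand.
    """
    anchors = anchors or AnchorPair()
    _validate_dna(contig, contig_name)
    if len(contig) < len(anchors.anchor_5p) + len(anchors.anchor_3p):
        raise GeneExtractionError("contig shorter than the two anchors")
    p5, o5 = _locate_anchor(contig, anchors.anchor_5p, "anchor_5p", anchors.max_mismatches)
    p3, o3 = _locate_anchor(contig, anchors.anchor_3p, "anchor_3p", anchors.max_mismatches)
    if o5 != o3:
        raise GeneExtractionError(
            "anchors found on opposite strands; gene incomplete or rearranged in contig"
        )
    if o5 == "+":
        if not p5 < p3:
            raise GeneExtractionError("anchor order inconsistent with forward orientation")
        start, end = p5, p3 + len(anchors.anchor_3p)
        interval = GeneInterval(contig_name, start, end, "+")
        return interval, contig[start:end]
    # Minus strand: the reverse complement of anchor_3p precedes that of anchor_5p.
    if not p3 < p5:
        raise GeneExtractionError("anchor order inconsistent with reverse orientation")
    start, end = p3, p5 + len(anchors.anchor_5p)
    interval = GeneInterval(contig_name, start, end, "-")
    return interval, reverse_complement(contig[start:end])


def compare_technologies(seq_a: str, seq_b: str, params: AlignParams | None = None) -> TechComparison:
    """Globally align two sequencings of the same haplotype and summarize.

    similarity_percent counts matching columns over all alignment columns
    (gap columns included in the denominator); a k-base gap counts as one
    indel event.
    """
    aln = edit_align(seq_a, seq_b, params or AlignParams())
    return TechComparison(
        similarity_percent=aln.identity * 100.0,
        mismatches=aln.mismatches,
        indels=aln.gap_events,
    )
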