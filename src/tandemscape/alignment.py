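"""Global pairwise alignment with affine gaps (EMBOSS-needle default scoring).

Two engines sit behind one result type:

* :func:`global_align` — optimal affine-gap global alignment (match +5,
  mismatch -4, gap open 10, gap extend 0.5, end gaps free), delegated to
  ``Bio.Align.PairwiseAligner``.  Intended for unit-vs-consensus and other
  short comparisons; a configurable cell cap guards against accidental
  quadratic blowups.
* :func:`edit_align` — global edit-distance alignment via edlib, intended
  for long, near-identical pairs (whole-gene technology comparison, trio
  similarity, reference projection).  The returned score is recomputed
  under the affine model from the alignment columns so both engines report
  on the same scale.

A gap *event* is a maximal run of gap columns in one sequence; a k-base gap
counts as one event (the convention used for indel counts throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

from .seqio import _validate_dna


@dataclass(frozen=True)
class AlignParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("need gap_open >= gap_extend >= 0")


DEFAULT_PARAMS = AlignParams()


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    mismatches: int
    gap_columns: int
    gap_events: int

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


class AlignmentCapError(ValueError):
    """Raised when the DP matrix would exceed the configured cell cap."""


def _gap_runs(aligned: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as (start, length)."""
    runs = []
    i = 0
    n = len(aligned)
    while i < n:
        if aligned[i] == "-":
            j = i
            while j < n and aligned[j] == "-":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _score_alignment(aligned_a: str, aligned_b: str, params: AlignParams) -> float:
    """Affine-model score of a given alignment; terminal gap runs free if configured."""
    score = 0.0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            score += params.match if ca == cb else params.mismatch
    n = len(aligned_a)
    for aligned in (aligned_a, aligned_b):
        for start, length in _gap_runs(aligned):
            terminal = start == 0 or start + length == n
            if params.end_gaps_free and terminal:
                continue
            score -= params.gap_open + params.gap_extend * length
    return score


def _stats(aligned_a: str, aligned_b: str, score: float) -> Alignment:
    n = len(aligned_a)
    matches = sum(1 for ca, cb in zip(aligned_a, aligned_b) if ca == cb and ca != "-")
    gap_columns = sum(1 for ca, cb in zip(aligned_a, aligned_b) if ca == "-" or cb == "-")
    mismatches = n - matches - gap_columns
    gap_events = len(_gap_runs(aligned_a)) + len(_gap_runs(aligned_b))
    return Alignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity=matches / n if n else 0.0,
        mismatches=mismatches,
        gap_columns=gap_columns,
        gap_events=gap_events,
    )


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # EMBOSS convention: a gap of length k costs gap_open + gap_extend * k.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if params.end_gaps_free:
        new_names = (
            "open_end_insertion_score",
            "extend_end_insertion_score",
            "open_end_deletion_score",
            "extend_end_deletion_score",
        )
        old_names = (
            "target_end_open_gap_score",
            "target_end_extend_gap_score",
            "query_end_open_gap_score",
            "query_end_extend_gap_score",
        )
        names = new_names if hasattr(aligner, new_names[0]) else old_names
        for name in names:
            setattr(aligner, name, 0.0)
    return aligner


def global_align(
    a: str,
    b: str,
    params: AlignParams = DEFAULT_PARAMS,
    max_cells: float = 1e8,
) -> Alignment:
    """Optimal global alignment under the affine model.

    Raises :class:`AlignmentCapError` when ``len(a) * len(b)`` exceeds
    ``max_cells``; use :func:`edit_align` for long near-identical pairs.
    """
    _validate_dna(a, "a")
    _validate_dna(b, "b")
    if len(a) * len(b) > max_cells:
        raise AlignmentCapError(
            f"alignment of {len(a)} x {len(b)} exceeds the {max_cells:.0g}-cell cap; "
            "use edit_align (banded edit-distance mode) for long pairs"
        )
    aligner = _make_aligner(params)
    best = aligner.align(a, b)[0]
    aligned_a, aligned_b = best[0], best[1]
    return _stats(aligned_a, aligned_b, float(best.score))


def edit_align(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> Alignment:
    """Global alignment via edlib (unit edit costs), restated as an Alignment.

    Suited to long, highly similar sequences; the reported score is the
    affine-model score of the edlib path (end gaps free as configured).
    """
    _validate_dna(a, "a")
    _validate_dna(b, "b")
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    aligned_a, aligned_b = nice["query_aligned"], nice["target_aligned"]
    return _stats(aligned_a, aligned_b, _score_alignment(aligned_a, aligned_b, params))


def project_to_reference(
    ref: str,
    hap: str,
    params: AlignParams = DEFAULT_PARAMS,
    max_cells: float = 1e8,
) -> str:
    """Per-reference-position base calls for ``hap`` (keeplength semantics).

    The haplotype is globally aligned to the reference; columns where the
    haplotype has a gap emit '-', insertions relative to the reference are
    discarded, substitutions are carried through.  Output length == len(ref).
    """
    if len(ref) * len(hap) <= max_cells:
        aln = global_align(ref, hap, params, max_cells)
    else:
        aln = edit_align(ref, hap, params)
    out = []
    for cr, ch in zip(aln.aligned_a, aln.aligned_b):
        if cr == "-":
            continue  # insertion in hap: dropped
        out.append(ch)  # base call, or '-' where hap has a gap
    projection = "".join(out)
    assert len(projection) == len(ref)
    return projection


def format_pair(aln: Alignment, name_a: str = "a", name_b: str = "b", width: int = 60) -> str:
    """EMBOSS-pair-like text dump for debugging."""
    lines = []
    for i in range(0, aln.columns, width):
        sa = aln.aligned_a[i : i + width]
        sb = aln.aligned_b[i : i + width]
        marks = "".join("|" if x == y and x != "-" else " " for x, y in zip(sa, sb))
        lines += [f"{name_a:>10} {sa}", f"{'':>10} {marks}", f"{name_b:>10} {sb}", ""]
    return "\n".join(lines)
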