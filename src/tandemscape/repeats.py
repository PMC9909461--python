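"""De novo tandem-repeat detection, filtering, and unit decomposition.

The detector finds candidate arrays by exact k-mer recurrence at each
candidate period (a position votes for period p when the k-mer starting
there recurs p bases downstream), extends each candidate unit-by-unit
against the majority-vote consensus, refines the boundaries with an x-drop
character scan, and decomposes the span into units by wraparound dynamic
programming against the cyclic consensus.  Statistical significance is
assessed with a mononucleotide shuffle test; overlapping survivors are
resolved by (p-value, divergence) rank.

Copy number is the spanned length divided by the consensus length, rounded
half-up to one decimal (so 129 bases of a 38-mer report as 3.4 copies).
Divergence is the mean per-unit edit distance to the consensus, normalized
by consensus length, with a trailing partial unit excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from ._kernels import DIAG, LEFT, UP, encode, traceback_global, wrap_global
from .seqio import GeneInterval, _validate_dna, round_half_up

MATCH = 5.0
MISMATCH = -4.0
GAP = -7.0


@dataclass
class RepeatAnnotation:
    """A detected tandem array in gene-local coordinates."""

    interval: GeneInterval
    consensus: str
    units: list[str]
    copy_number: float
    divergence: float
    p_value: float | None = None
    partial_tail: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence):
            raise ValueError("divergence must be >= 0")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")

    @property
    def unit_length(self) -> int:
        return len(self.consensus)

    @property
    def has_partial_tail(self) -> bool:
        return self.partial_tail

    def spanned_sequence(self) -> str:
        return "".join(self.units)


def canonical_rotation(s: str) -> str:
    """Lexicographically smallest rotation (phase-independent motif key)."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _divergence(units: list[str], consensus: str, partial_tail: bool) -> float:
    full = units[:-1] if (partial_tail and len(units) > 1) else list(units)
    if partial_tail and len(units) == 1:
        full = []
    if not full:
        return 0.0
    p = len(consensus)
    return float(np.mean([_edit_distance(u, consensus) / p for u in full]))


def _majority_consensus(frames: list[str], p: int) -> str:
    """Per-column majority vote; ties broken by fixed base order A<C<G<T."""
    cols = []
    for j in range(p):
        counts = Counter(f[j] for f in frames if len(f) > j and f[j] != "N")
        if not counts:
            cols.append("N")
            continue
        best = max(sorted(counts), key=lambda b: counts[b])
        cols.append(best)
    return "".join(cols)


# ---------------------------------------------------------------------------
# Decomposition (wraparound global alignment against a cyclic motif)
# ---------------------------------------------------------------------------

def _decompose_span(span: str, motif: str) -> tuple[list[str], list[int]]:
    """Cut ``span`` into motif-period units.

    Returns (units, phases, end_phase) where phases[i] is the motif index
    consumed by span character i (-1 for characters inserted relative to the
    motif) and end_phase is the motif index the alignment stopped at (0 means
    the last unit completed a full cycle; nonzero means a partial tail).
    Unit boundaries sit where the motif phase wraps to 0; the concatenation
    of units equals ``span`` byte-for-byte.
    """
    codes = encode(span)
    motif_codes = encode(motif)
    _, end_phase, ptr = wrap_global(codes, motif_codes, MATCH, MISMATCH, GAP)
    steps, step_phases = traceback_global(ptr, end_phase)
    units: list[list[str]] = []
    phases: list[int] = []
    si = 0
    for t, ph in zip(steps, step_phases):
        if t in (DIAG, LEFT) and ph == 0:
            units.append([])
        if t == DIAG:
            if not units:
                units.append([])
            units[-1].append(span[si])
            phases.append(int(ph))
            si += 1
        elif t == UP:
            if not units:
                units.append([])
            units[-1].append(span[si])
            phases.append(-1)
            si += 1
    assert si == len(span)
    return ["".join(u) for u in units], phases, int(end_phase)


def decompose(seq: str, interval: GeneInterval, motif: str) -> RepeatAnnotation:
    """Decompose the spanned subsequence into tandem units of ``motif``."""
    _validate_dna(motif, "motif")
    if len(motif) < 7:
        raise ValueError("motif must be at least 7 bp")
    span = seq[interval.start : interval.end]
    if len(span) < len(motif):
        raise ValueError(
            f"spanned length {len(span)} is shorter than the motif ({len(motif)} bp)"
        )
    units, _, end_phase = _decompose_span(span, motif)
    assert "".join(units) == span
    p = len(motif)
    copy_number = round_half_up(len(span) / p, 1)
    partial = end_phase != 0
    divergence = _divergence(units, motif, partial)
    return RepeatAnnotation(
        interval=interval,
        consensus=motif,
        units=units,
        copy_number=copy_number,
        divergence=divergence,
        partial_tail=partial,
    )


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _raw_candidates(codes: np.ndarray, min_unit: int, max_unit: int, k: int):
    """k-mer recurrence votes -> (start, end, period) raw windows."""
    n = codes.shape[0]
    out = []
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        kp = min(k, p)
        eq = codes[p:] == codes[:-p]
        if eq.size < kp:
            continue
        csum = np.concatenate(([0], np.cumsum(eq)))
        full = csum[kp:] - csum[:-kp] == kp
        idx = np.flatnonzero(full)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > p + kp)
        for grp in np.split(idx, breaks + 1):
            a, b = int(grp[0]), int(grp[-1])
            end = b + kp + p
            # permissive here (refinement recovers full span; a final
            # >= 1.9-copy check applies after boundary polishing)
            if end - a >= int(np.ceil(1.5 * p)):
                out.append((a, end, p))
    return out


def _rotate(s: str, d: int) -> str:
    d %= len(s)
    return s[d:] + s[:d]


def _identity(a: str, b: str) -> float:
    denom = max(len(a), len(b))
    return 1.0 - _edit_distance(a, b) / denom if denom else 0.0


def _step_units(
    seq: str, s: int, e: int, consensus: str, min_identity: float = 0.8
) -> tuple[int, int]:
    """Extend a frame-aligned block [s, e) by whole units while each next
    window keeps ``min_identity`` to the consensus (edit-distance identity,
    so single indels only nudge, not break, the extension)."""
    p = len(consensus)
    while e + p <= len(seq) and _identity(seq[e : e + p], consensus) >= min_identity:
        e += p
    while s - p >= 0 and _identity(seq[s - p : s], consensus) >= min_identity:
        s -= p
    return s, e


def _phase_offset(window: str, consensus: str) -> int:
    """Rotation offset d such that window[j] best matches consensus[(d+j) % p]."""
    p = len(consensus)
    doubled = consensus + consensus
    best_d, best_m = 0, -1
    for d in range(p):
        m = sum(1 for j, ch in enumerate(window[:p]) if ch == doubled[d + j])
        if m > best_m:
            best_d, best_m = d, m
    return best_d


def _char_refine(
    seq: str, s: int, e: int, consensus: str
) -> tuple[int, int, str] | None:
    """Char-exact boundary refinement driven by the decomposition register.

    The stepped span is decomposed against the cyclic consensus (wraparound
    DP, so interior indels shift the register without corrupting it), each
    character scores +1 when it matches the consensus at its decomposed
    phase and -3 otherwise, and the kept block maximizes the score sum —
    ragged flank absorbed by the stepping is shed while isolated interior
    substitutions are retained.  The block is then extended outward
    base-by-base while the flank continues the cyclic consensus exactly.
    Returns (start, end, consensus rotated to phase 0 at start).
    """
    p = len(consensus)
    span = seq[s:e]
    if len(span) < p:
        return None
    rot = _rotate(consensus, _phase_offset(span[:p], consensus))
    _, phases, _ = _decompose_span(span, rot)

    # +1 per consensus match, -3 per mismatch or insertion; motif positions
    # the DP skipped (deletions) are charged to the following character,
    # otherwise the DP could delete its way into flank junk and make it
    # look repeat-consistent
    scores = []
    prev_ph = None
    for k, ph in enumerate(phases):
        sc = 1 if (ph >= 0 and span[k] == rot[ph]) else -3
        if ph >= 0:
            if prev_ph is not None:
                jump = (ph - prev_ph - 1) % p
                if jump:
                    sc -= 3 * min(jump, 3)
            prev_ph = ph
        scores.append(sc)
    prefix = [0]
    for sc in scores:
        prefix.append(prefix[-1] + sc)
    # best [a, b) with b - a >= p maximizing prefix[b] - prefix[a]
    best = None
    min_a, min_val = 0, prefix[0]
    for b in range(p, len(span) + 1):
        cand_a = b - p
        if prefix[cand_a] < min_val:
            min_val, min_a = prefix[cand_a], cand_a
        if best is None or prefix[b] - min_val > best[0]:
            best = (prefix[b] - min_val, min_a, b)
    _, a, b = best

    # snap inward to consensus-matching characters
    while a < b and scores[a] < 0:
        a += 1
    while b > a and scores[b - 1] < 0:
        b -= 1
    if b - a < p:
        return None

    # scored outward extension from the decomposed register at each edge:
    # +1 per consensus-continuing base, -3 per mismatch, boundary at the
    # strict running maximum — clustered terminal-unit substitutions are
    # crossed (the x-drop bounds only how far the scan looks, not where
    # the boundary lands), non-continuing flank is excluded
    xdrop = 14
    # edge registers are calibrated on the terminal windows themselves
    # (max-match rotation) rather than taken from the DP phases: near a
    # span edge the DP may realize a substitution as deletion+shift, which
    # would poison the continuation register
    d_start = _phase_offset(span[a : a + p], rot)
    new_start = s + a
    run, best_run, i = 0, 0, s + a - 1
    k = -1
    best_k = 0
    while i >= 0:
        run += 1 if seq[i] == rot[(d_start + k) % p] else -3
        if run > best_run:
            best_run, new_start, best_k = run, i, k
        if run < best_run - xdrop:
            break
        i -= 1
        k -= 1
    start_rot = _rotate(rot, (d_start + best_k) % p if best_k else d_start)

    d_end = _phase_offset(span[b - p : b], rot)
    new_end = s + b
    run, best_run, i, k = 0, 0, s + b, 0
    while i < len(seq):
        run += 1 if seq[i] == rot[(d_end + p + k) % p] else -3
        if run > best_run:
            best_run, new_end = run, i + 1
        if run < best_run - xdrop:
            break
        i += 1
        k += 1
    return new_start, new_end, start_rot


def _refine_candidate(
    seq: str, codes: np.ndarray, a: int, b: int, p: int, contig: str
) -> RepeatAnnotation | None:
    n = len(seq)
    b = min(b, n)
    n_frames = max(1, (b - a) // p)
    if a + p > n:
        return None
    frames = [seq[a + i * p : a + (i + 1) * p] for i in range(n_frames)]
    frames = [f for f in frames if len(f) == p]
    if not frames:
        return None
    consensus = _majority_consensus(frames, p)
    if "N" in consensus:
        return None
    s, e = a, a + p * len(frames)
    # two rounds: extend by units, re-estimate the consensus from the
    # decomposed full units (indel-aware), extend again
    for _ in range(2):
        s, e = _step_units(seq, s, e, consensus)
        units, _, _ = _decompose_span(seq[s:e], consensus)
        full = [u for u in units if len(u) == p]
        if not full:
            break
        refreshed = _majority_consensus(full, p)
        if "N" in refreshed or refreshed == consensus:
            break
        consensus = refreshed
    refined = _char_refine(seq, s, e, consensus)
    if refined is None:
        return None
    s, e, consensus = refined
    if e - s < max(p + 1, int(np.ceil(1.9 * p))):
        return None
    # Low-complexity motifs make the phase estimate ambiguous (an
    # off-by-one rotation of a C-rich unit matches almost as well), so
    # decompose under each near-best rotation and keep the lowest
    # divergence.
    head = seq[s : s + p]
    doubled = consensus + consensus
    head_matches = [
        sum(1 for j, ch in enumerate(head) if ch == doubled[d + j])
        for d in range(p)
    ]
    best_m = max(head_matches)
    candidates_d = [d for d, m in enumerate(head_matches) if m >= best_m - 3]
    best_ann = None
    for d in sorted(candidates_d, key=lambda d: (-head_matches[d], d)):
        ann = decompose(seq, GeneInterval(contig, s, e), _rotate(consensus, d))
        if best_ann is None or ann.divergence < best_ann.divergence:
            best_ann = ann
    if best_ann is None or best_ann.copy_number < 1.9:
        return None
    return best_ann


def _dedup(
    annotations: list[RepeatAnnotation], max_divergence: float = 0.05
) -> list[RepeatAnnotation]:
    """Drop duplicate, period-multiple, and nested refinements of an array.

    Two rules besides exact duplicates: (i) for near-coincident spans where
    one period is a multiple of the other, the shorter period wins
    (parsimony, the TRF convention); (ii) a short array essentially
    contained within a much longer credible array is a sub-repeat of the
    longer unit's internal structure and is dropped — internal
    near-periodicities of long units otherwise shed small pure fragments
    that outcompete the true annotation at overlap resolution.
    """
    annotations = sorted(
        annotations, key=lambda a: (a.interval.start, a.unit_length, a.interval.end)
    )
    n = len(annotations)
    drop = [False] * n
    for i in range(n):
        if drop[i]:
            continue
        for j in range(i + 1, n):
            if drop[j]:
                continue
            a, b = annotations[i], annotations[j]
            ov = min(a.interval.end, b.interval.end) - max(
                a.interval.start, b.interval.start
            )
            shorter = min(a.interval.length, b.interval.length)
            if ov < 0.8 * shorter:
                continue
            if a.unit_length == b.unit_length:
                # same-period refinements of one array: keep the longer span
                if a.interval.length >= b.interval.length:
                    drop[j] = True
                else:
                    drop[i] = True
                    break
                continue
            # (approximate) period multiples: indels shift a k-unit reading
            # by a base or two, so 115 is treated as a multiple of 38.  The
            # shorter period wins (parsimony, the TRF convention) when its
            # span covers the longer-period candidate's span — a shorter-
            # period *fragment* inside a longer-period array stays subject
            # to the containment pass instead.
            small, large = (a, b) if a.unit_length < b.unit_length else (b, a)
            k = round(large.unit_length / small.unit_length)
            if (
                k >= 2
                and abs(large.unit_length - k * small.unit_length) <= 2
                and ov >= 0.8 * large.interval.length
                and small.divergence <= large.divergence + 0.02
            ):
                if large is b:
                    drop[j] = True
                else:
                    drop[i] = True
                    break
    kept = [ann for ann, d in zip(annotations, drop) if not d]
    # containment pass (symmetric: list is start-sorted, container may follow)
    final: list[RepeatAnnotation] = []
    for ann in kept:
        nested = False
        for other in kept:
            if other is ann or other.divergence > max_divergence:
                continue
            ov = min(ann.interval.end, other.interval.end) - max(
                ann.interval.start, other.interval.start
            )
            if (
                ov >= 0.9 * ann.interval.length
                and other.interval.length >= 1.5 * ann.interval.length
            ):
                nested = True
                break
        if not nested:
            final.append(ann)
    return final


def detect_repeats(
    seq: str,
    min_unit: int = 7,
    max_unit: int = 200,
    k: int = 8,
    contig: str = "gene",
) -> list[RepeatAnnotation]:
    """Find candidate tandem arrays with unit length in [min_unit, max_unit].

    Candidates span at least 1.9 copies.  The returned annotations carry no
    p-value yet; run :func:`significance_test` and :func:`filter_and_resolve`.
    """
    _validate_dna(seq)
    if len(seq) < 2 * min_unit:
        return []
    codes = encode(seq)
    raw = _raw_candidates(codes, min_unit, max_unit, k)
    refined = []
    for a, b, p in raw:
        ann = _refine_candidate(seq, codes, a, b, p, contig)
        if ann is not None:
            refined.append(ann)
    refined = _merge_same_period(seq, refined, contig)
    return _dedup(refined)


def _merge_same_period(
    seq: str, annotations: list[RepeatAnnotation], contig: str
) -> list[RepeatAnnotation]:
    """Unify same-motif segments separated by a short gap.

    An interior indel can break the vote runs of one array into fragments
    that refine separately; fragments with the same unit length and
    canonical consensus lying within two units of each other are one
    array and are re-decomposed over their union.
    """
    annotations = sorted(
        annotations,
        key=lambda a: (a.unit_length, canonical_rotation(a.consensus), a.interval.start),
    )
    merged: list[RepeatAnnotation] = []
    for ann in annotations:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.unit_length == ann.unit_length
            and _identity(
                canonical_rotation(last.consensus), canonical_rotation(ann.consensus)
            )
            >= 0.9
            and ann.interval.start - last.interval.end <= 2 * last.unit_length
        ):
            union = GeneInterval(
                contig,
                min(last.interval.start, ann.interval.start),
                max(last.interval.end, ann.interval.end),
            )
            merged[-1] = decompose(seq, union, last.consensus)
        else:
            merged.append(ann)
    return merged


# ---------------------------------------------------------------------------
# Significance (mononucleotide shuffle test)
# ---------------------------------------------------------------------------

def _period_match_count(codes: np.ndarray, p: int) -> int:
    if codes.shape[0] <= p:
        return 0
    return int(np.sum(codes[p:] == codes[:-p]))


def significance_test(
    candidate: RepeatAnnotation,
    seq: str,
    n_shuffles: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical p-value of the array against mononucleotide-shuffled windows.

    The statistic is the number of positions matching their period-p
    successor within the spanned window; the null redistributes the window's
    own base composition, so GC-rich arrays are judged against an equally
    GC-rich background.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be at least 20")
    if rng is None:
        rng = np.random.default_rng(seed)
    window = seq[candidate.interval.start : candidate.interval.end]
    codes = encode(window)
    p = candidate.unit_length
    observed = _period_match_count(codes, p)
    tiled = np.tile(codes, (n_shuffles, 1))
    shuffled = rng.permuted(tiled, axis=1)
    null_counts = np.sum(shuffled[:, p:] == shuffled[:, :-p], axis=1)
    return float(np.mean(null_counts >= observed))


def filter_and_resolve(
    candidates: list[RepeatAnnotation],
    max_divergence: float = 0.05,
    alpha: float = 0.05,
) -> list[RepeatAnnotation]:
    """Apply significance/divergence filters and resolve overlaps.

    Candidates with p > alpha or divergence > max_divergence are dropped;
    among overlapping survivors the lowest (p_value, divergence) wins, with
    unit length and position as deterministic tie-breakers.  The result is
    pairwise non-overlapping and position-sorted.
    """
    survivors = [
        c
        for c in candidates
        if c.p_value is not None
        and c.p_value <= alpha
        and c.divergence <= max_divergence
    ]
    ranked = sorted(
        survivors,
        key=lambda c: (c.p_value, c.divergence, c.unit_length, c.interval.start),
    )
    kept: list[RepeatAnnotation] = []
    for cand in ranked:
        if any(cand.interval.overlaps(k.interval) for k in kept):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda c: c.interval.start)


def annotate_gene(
    seq: str,
    min_unit: int = 7,
    max_unit: int = 200,
    max_divergence: float = 0.05,
    alpha: float = 0.05,
    n_shuffles: int = 200,
    seed: int | None = 0,
    contig: str = "gene",
) -> list[RepeatAnnotation]:
    """detect -> significance -> filter/resolve, in one call."""
    rng = np.random.default_rng(seed)
    candidates = detect_repeats(seq, min_unit=min_unit, max_unit=max_unit, contig=contig)
    for cand in candidates:
        cand.p_value = significance_test(cand, seq, n_shuffles=n_shuffles, rng=rng)
    return filter_and_resolve(candidates, max_divergence=max_divergence, alpha=alpha)
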