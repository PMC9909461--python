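"""G-quadruplex propensity scoring (run-based, windowed) and PWM scanning.

The G4 score of a base is +min(run, 4) inside a run of consecutive G and
-min(run, 4) inside a run of consecutive C; A/T/N score 0 (N breaks runs).
A sliding window mean over 25 bases with |mean| >= 1.6 flags a candidate
quadruplex-forming region; overlapping same-sign windows merge into
maximal regions whose mean is recomputed over the merged span.  Positive
regions sit on the given strand, negative regions on its complement.

PWM scanning is generic log-odds against a uniform background on both
strands, reported as a relative score in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from .seqio import GeneInterval, _validate_dna, reverse_complement


@dataclass(frozen=True)
class G4Params:
    window: int = 25
    threshold: float = 1.6
    bin_size: int = 500

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")


@dataclass
class G4Hit:
    interval: GeneInterval
    mean_score: float
    strand_sign: str  # "+" for G-rich, "-" for C-rich

    def __post_init__(self) -> None:
        if self.strand_sign not in ("+", "-"):
            raise ValueError("strand_sign must be '+' or '-'")


def g4_base_scores(seq: str) -> np.ndarray:
    """Per-base run scores: +min(k,4) in G-runs of length k, -min(k,4) in C-runs."""
    _validate_dna(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    scores = np.zeros(len(seq), dtype=np.int8)
    for base, sign in ((b"G", 1), (b"C", -1)):
        is_base = arr == base
        if not is_base.any():
            continue
        # run-length encode
        padded = np.concatenate(([False], is_base, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            scores[s:e] = sign * min(e - s, 4)
    return scores


def g4_windows(scores: np.ndarray, params: G4Params | None = None) -> list[G4Hit]:
    """Sliding-mean windows with |mean| >= threshold, merged into regions."""
    params = params or G4Params()
    w = params.window
    n = len(scores)
    if n < w:
        warnings.warn(f"sequence shorter than window ({n} < {w}); no G4 scan")
        return []
    csum = np.concatenate(([0], np.cumsum(scores, dtype=np.int64)))
    means = (csum[w:] - csum[:-w]) / w  # window starting at i covers [i, i+w)
    hits = []
    for sign in (1, -1):
        keep = np.flatnonzero(sign * means >= params.threshold)
        if keep.size == 0:
            continue
        # merge overlapping/adjacent same-sign windows
        breaks = np.flatnonzero(np.diff(keep) > w)
        for grp in np.split(keep, breaks + 1):
            start, end = int(grp[0]), int(grp[-1]) + w
            mean = float((csum[end] - csum[start]) / (end - start))
            hits.append(
                G4Hit(
                    interval=GeneInterval("gene", start, end),
                    mean_score=mean,
                    strand_sign="+" if sign > 0 else "-",
                )
            )
    return sorted(hits, key=lambda h: h.interval.start)


def g4_profile(
    hits: list[G4Hit], gene_length: int, params: G4Params | None = None
):
    """Per-bin G4 coverage percent and hit count across the gene."""
    import pandas as pd

    params = params or G4Params()
    b = params.bin_size
    n_bins = max(1, int(np.ceil(gene_length / b)))
    rows = []
    for k in range(n_bins):
        lo, hi = k * b, min((k + 1) * b, gene_length)
        covered = 0
        count = 0
        for h in hits:
            ov = min(hi, h.interval.end) - max(lo, h.interval.start)
            if ov > 0:
                covered += ov
                count += 1
        rows.append(
            {
                "bin_start": lo,
                "bin_end": hi,
                "coverage_percent": 100.0 * covered / (hi - lo),
                "hit_count": count,
            }
        )
    return pd.DataFrame(rows)


def scan_g4(seq: str, params: G4Params | None = None) -> list[G4Hit]:
    """g4_base_scores + g4_windows in one call."""
    return g4_windows(g4_base_scores(seq), params)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # (4, length) counts or frequencies, rows A,C,G,T

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM needs 4 rows (A, C, G, T)")
        if self.matrix.shape[1] < 4:
            raise ValueError("PWM length must be >= 4")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValueError("PWM has a zero column sum")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, pseudocount: float = 0.01, background: float = 0.25) -> np.ndarray:
        freqs = self.matrix / self.matrix.sum(axis=0, keepdims=True)
        freqs = freqs + pseudocount
        freqs = freqs / freqs.sum(axis=0, keepdims=True)
        return np.log2(freqs / background)

    @classmethod
    def from_sites(cls, motif_id: str, sites: list[str]) -> "PWM":
        length = len(sites[0])
        mat = np.zeros((4, length))
        for s in sites:
            for j, b in enumerate(s):
                mat[_BASES.index(b), j] += 1
        return cls(motif_id, mat)


def read_jaspar(path) -> PWM:
    """Read a JASPAR-format position frequency matrix."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    mat = np.array([list(motif.counts[b]) for b in _BASES], dtype=float)
    return PWM(motif_id=motif.matrix_id or motif.name or "pwm", matrix=mat)


def scan_pwm(
    seq: str,
    pwm: PWM,
    rel_score_min: float = 0.8,
    pseudocount: float = 0.01,
) -> list[tuple[int, str, float]]:
    """Scan both strands; report (position, strand, relative score) hits.

    Relative score rescales the log-odds score between the minimum and
    maximum achievable for the matrix; overlapping hits are all reported.
    Positions refer to the forward strand (start of the matched window).
    """
    _validate_dna(seq)
    L = pwm.length
    if len(seq) < L:
        return []
    lods = pwm.log_odds(pseudocount=pseudocount)
    smin, smax = lods.min(axis=0).sum(), lods.max(axis=0).sum()
    span = smax - smin if smax > smin else 1.0

    hits = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        codes = np.full(len(s), 4, dtype=np.int64)
        for i, b in enumerate(_BASES):
            codes[np.frombuffer(s.encode(), dtype="S1") == b.encode()] = i
        # N (code 4) scores the column minimum
        lods_n = np.vstack([lods, lods.min(axis=0)])
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        scores = lods_n[windows, np.arange(L)].sum(axis=1)
        rel = (scores - smin) / span
        for off in np.flatnonzero(rel >= rel_score_min):
            pos = int(off) if strand == "+" else len(seq) - L - int(off)
            hits.append((pos, strand, float(rel[off])))
    return sorted(hits, key=lambda h: (h[0], h[1]))
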