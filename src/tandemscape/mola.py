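"""Mola charts: per-unit grids visualizing VNTR sequence purity.

Each row is one haplotype, each cell one repeat unit.  Two modes:

* multicolor — every distinct unit sequence gets its own color from a
  seeded palette, exposing sequence diversity (many colors = low purity);
* threecolor — every cell is colored by its global-alignment score against
  the locus consensus on a red (worst) / white (median) / blue (best)
  gradient, exposing the degree of divergence from the consensus.

Charts are emitted as deterministic SVG plus a TSV cell table so analyses
assert on data, not pixels.  Units containing N are excluded from the
unique-sequence catalog and drawn grey.  A trailing partial unit
participates in uniqueness (as its literal string) and is hatched.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignParams, global_align
from .harmonize import Locus


@dataclass
class MolaCell:
    unit_seq: str
    color: str  # "#rrggbb"
    score: float | None  # similarity score vs consensus (threecolor)
    is_partial: bool


@dataclass
class MolaChart:
    locus_id: str
    rows: list[str]  # haplotype labels, display order
    cells: dict[str, list[MolaCell]]
    mode: str  # {"multicolor", "threecolor"}
    sort_mode: str  # {"by_copy_number", "by_first_units"}

    def to_table(self) -> pd.DataFrame:
        recs = []
        for lab in self.rows:
            for i, cell in enumerate(self.cells[lab]):
                recs.append(
                    {
                        "haplotype": lab,
                        "unit_index": i,
                        "unit_seq": cell.unit_seq,
                        "color": cell.color,
                        "score": cell.score if cell.score is not None else "",
                        "is_partial": cell.is_partial,
                    }
                )
        return pd.DataFrame(recs)

    def to_svg(self, cell_w: int = 10, cell_h: int = 12, label_w: int = 120) -> str:
        max_units = max((len(c) for c in self.cells.values()), default=0)
        width = label_w + max_units * cell_w + 10
        height = (len(self.rows) + 1) * cell_h + 10
        out = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
            f'<text x="4" y="{cell_h - 2}" font-size="10" font-family="monospace">'
            f"{self.locus_id} ({self.mode})</text>",
        ]
        for r, lab in enumerate(self.rows):
            y = (r + 1) * cell_h + 5
            out.append(
                f'<text x="4" y="{y + cell_h - 3}" font-size="8" '
                f'font-family="monospace">{lab}</text>'
            )
            for c, cell in enumerate(self.cells[lab]):
                x = label_w + c * cell_w
                out.append(
                    f'<rect x="{x}" y="{y}" width="{cell_w}" height="{cell_h}" '
                    f'fill="{cell.color}" stroke="#444" stroke-width="0.3"/>'
                )
                if cell.is_partial:
                    out.append(
                        f'<line x1="{x}" y1="{y + cell_h}" x2="{x + cell_w}" '
                        f'y2="{y}" stroke="#000" stroke-width="0.6"/>'
                    )
        out.append("</svg>")
        return "\n".join(out)

    def write_svg(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_svg())


# ---------------------------------------------------------------------------
# Unit catalogs and homopolymer sensitivity
# ---------------------------------------------------------------------------

def catalog_units(locus: Locus) -> tuple[dict[str, int], dict[str, list[int]]]:
    """Unique unit sequences (exact string equality) and per-haplotype indexes.

    Returns (counts, index_lists): ``counts`` maps each distinct unit string
    to its cohort-wide count, ordered by count descending then lexicographic;
    ``index_lists`` maps each haplotype to the rank of each of its units in
    that order (-1 for N-containing units, which are excluded).
    """
    raw: dict[str, int] = {}
    for ann in locus.annotations.values():
        for unit in ann.units:
            if "N" in unit:
                continue
            raw[unit] = raw.get(unit, 0) + 1
    ordered = dict(sorted(raw.items(), key=lambda kv: (-kv[1], kv[0])))
    rank = {u: i for i, u in enumerate(ordered)}
    index_lists = {
        lab: [rank.get(u, -1) for u in ann.units]
        for lab, ann in locus.annotations.items()
    }
    return ordered, index_lists


def collapse_homopolymers(seq: str, min_run: int = 4) -> str:
    """Replace every single-base run of length >= min_run by one base."""
    if not seq:
        return seq
    out = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        out.append(seq[i] if run >= min_run else seq[i:j])
        i = j
    return "".join(out)


def homopolymer_sensitivity(locus: Locus, min_run: int = 4) -> tuple[int, int]:
    """Unique unit counts before/after homopolymer collapse.

    If collapsing barely reduces the unique count, the observed unit
    diversity is not an artifact of homopolymer-length sequencing error.
    """
    counts, _ = catalog_units(locus)
    collapsed = {collapse_homopolymers(u, min_run) for u in counts}
    return len(counts), len(collapsed)


# ---------------------------------------------------------------------------
# Chart construction
# ---------------------------------------------------------------------------

_GREY = "#bbbbbb"


def _palette(n: int, seed: int) -> list[str]:
    """n visually spread colors; deterministic for a given (n, seed)."""
    rng = np.random.default_rng(seed)
    hues = (np.arange(n) * 0.6180339887498949 + rng.random()) % 1.0
    colors = []
    for i, h in enumerate(hues):
        sat = 0.45 + 0.45 * float(rng.random())
        val = 0.65 + 0.3 * float(rng.random())
        r, g, b = colorsys.hsv_to_rgb(float(h), sat, val)
        colors.append(f"#{int(r*255):02x}{int(g*255):02x}{int(b*255):02x}")
    return colors


def _sorted_rows_by_copy_number(locus: Locus) -> list[str]:
    return sorted(
        locus.annotations,
        key=lambda lab: (-locus.annotations[lab].copy_number, lab),
    )


def build_multicolor(locus: Locus, seed: int = 0) -> MolaChart:
    """Multicolor chart: one color per distinct unit sequence.

    Rows are sorted by copy number, descending (largest alleles on top).
    """
    counts, index_lists = catalog_units(locus)
    palette = _palette(len(counts), seed)
    p = locus.unit_length
    cells = {}
    for lab, ann in locus.annotations.items():
        cells[lab] = [
            MolaCell(
                unit_seq=u,
                color=palette[idx] if idx >= 0 else _GREY,
                score=None,
                is_partial=(i == len(ann.units) - 1 and ann.has_partial_tail),
            )
            for i, (u, idx) in enumerate(zip(ann.units, index_lists[lab]))
        ]
    return MolaChart(
        locus_id=locus.tr_id,
        rows=_sorted_rows_by_copy_number(locus),
        cells=cells,
        mode="multicolor",
        sort_mode="by_copy_number",
    )


def _gradient_color(score: float, lo: float, mid: float, hi: float) -> str:
    """3-anchor linear gradient: lo -> red, mid -> white, hi -> blue."""
    red, white, blue = (222, 45, 38), (255, 255, 255), (49, 100, 200)
    if hi == lo:
        r, g, b = white
    elif score <= mid:
        t = 0.0 if mid == lo else (score - lo) / (mid - lo)
        r, g, b = (int(a + t * (w - a)) for a, w in zip(red, white))
    else:
        t = 0.0 if hi == mid else (score - mid) / (hi - mid)
        r, g, b = (int(w + t * (u - w)) for w, u in zip(white, blue))
    return f"#{r:02x}{g:02x}{b:02x}"


def build_threecolor(
    locus: Locus,
    params: AlignParams | None = None,
    sort_mode: str | None = None,
) -> MolaChart:
    """3-color chart: per-unit global alignment score against the consensus.

    Scores map onto a red/white/blue gradient anchored at the locus's
    minimum, median, and maximum unit scores.  Rows sort by similarity of
    the first units unless ``sort_mode="by_copy_number"`` is requested
    (the convention for complex hypervariable loci).
    """
    params = params or AlignParams()
    consensus = locus.consensus
    score_cache: dict[str, float] = {}

    def unit_score(u: str) -> float:
        if u not in score_cache:
            score_cache[u] = global_align(u, consensus, params).score
        return score_cache[u]

    all_scores = []
    per_hap_scores = {}
    for lab, ann in locus.annotations.items():
        s = [unit_score(u) for u in ann.units]
        per_hap_scores[lab] = s
        all_scores.extend(s)
    lo, mid, hi = (
        float(np.min(all_scores)),
        float(np.median(all_scores)),
        float(np.max(all_scores)),
    )
    cells = {}
    for lab, ann in locus.annotations.items():
        cells[lab] = [
            MolaCell(
                unit_seq=u,
                color=_gradient_color(s, lo, mid, hi),
                score=s,
                is_partial=(i == len(ann.units) - 1 and ann.has_partial_tail),
            )
            for i, (u, s) in enumerate(zip(ann.units, per_hap_scores[lab]))
        ]
    if sort_mode is None:
        sort_mode = "by_first_units"
    if sort_mode == "by_copy_number":
        rows = _sorted_rows_by_copy_number(locus)
    else:
        # descending similarity of the leading units, then label
        rows = sorted(
            locus.annotations,
            key=lambda lab: (
                [-s for s in per_hap_scores[lab][:8]],
                lab,
            ),
        )
    return MolaChart(
        locus_id=locus.tr_id,
        rows=rows,
        cells=cells,
        mode="threecolor",
        sort_mode=sort_mode,
    )


def max_divergence_from_consensus(locus: Locus, params: AlignParams | None = None) -> int:
    """Worst unit's gaps+mismatches against the consensus (purity headline)."""
    params = params or AlignParams()
    worst = 0
    seen: set[str] = set()
    for ann in locus.annotations.values():
        for u in ann.units:
            if u in seen:
                continue
            seen.add(u)
            aln = global_align(u, locus.consensus, params)
            worst = max(worst, aln.mismatches + aln.gap_columns)
    return worst
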