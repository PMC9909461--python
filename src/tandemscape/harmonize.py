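"""Cross-haplotype locus harmonization: stable TR IDs, presence rule, VNTR flags.

Annotations from different haplotypes are clustered into loci by
single-linkage: two annotations link when their canonical-rotation
consensuses reach 80% identity AND both 50 bp flanks reach 90% identity.
Flanks are the stable key — a hypervariable locus can have divergent
consensuses across haplotypes, but its genomic neighborhood is conserved.
Clusters present in more than half of the haplotypes (strictly) receive
IDs numbered 5'->3' by median gene-local position; loci with at least two
distinct copy-number alleles are flagged as VNTRs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .repeats import (
    RepeatAnnotation,
    _identity,
    canonical_rotation,
    decompose,
)
from .seqio import GeneInterval, gc_percent, round_half_up


class HarmonizationError(ValueError):
    pass


@dataclass
class Locus:
    tr_id: str
    consensus: str
    annotations: dict[str, RepeatAnnotation]  # haplotype label -> annotation
    is_vntr: bool
    allele_table: dict[float, int]  # copy number -> haplotype count

    @property
    def unit_length(self) -> int:
        return len(self.consensus)

    @property
    def n_haplotypes(self) -> int:
        return len(self.annotations)

    def copy_numbers(self) -> dict[str, float]:
        return {lab: ann.copy_number for lab, ann in self.annotations.items()}

    def median_position(self) -> float:
        return float(np.median([a.interval.start for a in self.annotations.values()]))


@dataclass
class LocusCatalog:
    loci: list[Locus]
    n_haplotypes: int

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    def get(self, tr_id: str) -> Locus:
        for locus in self.loci:
            if locus.tr_id == tr_id:
                return locus
        raise KeyError(tr_id)

    @property
    def vntrs(self) -> list[Locus]:
        return [l for l in self.loci if l.is_vntr]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def reduce_doubled_motif(consensus: str, identity_threshold: float = 0.8) -> str:
    """Collapse a consensus that is two near-identical halves into one half.

    Detectors sometimes report a doubled motif (e.g. a 78 bp unit that is
    two copies of a 38/40 bp repeat); if the best near-halving split aligns
    half-vs-half at >= identity_threshold, the half consensus (per-column
    majority of the two halves, first half winning ties) replaces the
    doubled one, recursively.
    """
    n = len(consensus)
    if n < 14:
        return consensus
    best_split, best_ident = None, -1.0
    for m in range((n - 2) // 2, n // 2 + 2):
        a, b = consensus[:m], consensus[m:]
        if len(a) < 7 or len(b) < 7 or abs(len(a) - len(b)) > 2:
            continue
        ident = _identity(a, b)
        if ident > best_ident:
            best_ident, best_split = ident, m
    if best_split is None or best_ident < identity_threshold:
        return consensus
    # consensus of the two halves with ties to the first half == the first half
    half = consensus[:best_split]
    return reduce_doubled_motif(half, identity_threshold)


def _flanks(seq: str, interval: GeneInterval, size: int) -> tuple[str, str]:
    left = seq[max(0, interval.start - size) : interval.start]
    right = seq[interval.end : interval.end + size]
    return left, right


def _link(
    node_a: tuple,
    node_b: tuple,
    consensus_min_identity: float,
    flank_min_identity: float,
) -> bool:
    _, cons_a, left_a, right_a = node_a
    _, cons_b, left_b, right_b = node_b
    la, lb = len(cons_a), len(cons_b)
    if min(la, lb) / max(la, lb) < consensus_min_identity:
        return False
    if cons_a != cons_b and _identity(cons_a, cons_b) < consensus_min_identity:
        return False
    if not left_a or not left_b or not right_a or not right_b:
        return False
    return (
        _identity(left_a, left_b) >= flank_min_identity
        and _identity(right_a, right_b) >= flank_min_identity
    )


def assign_ids(
    per_haplotype_annotations: dict[str, list[RepeatAnnotation]],
    sequences: dict[str, str],
    min_presence: float = 0.5,
    consensus_min_identity: float = 0.8,
    flank_min_identity: float = 0.9,
    flank_size: int = 50,
    reduce_doubled: bool = True,
) -> LocusCatalog:
    """Cluster per-haplotype annotations into a stable locus catalog.

    The result is invariant to the order haplotypes are supplied in: linkage
    is symmetric single-linkage over all cross-haplotype pairs, IDs follow
    median gene-local position, and representatives are chosen by sorted
    haplotype label.
    """
    n_haps = len(per_haplotype_annotations)
    labels = sorted(per_haplotype_annotations)
    nodes = []  # (hap_label, canonical consensus, left flank, right flank)
    anns = []
    for lab in labels:
        for ann in sorted(per_haplotype_annotations[lab], key=lambda a: a.interval.start):
            left, right = _flanks(sequences[lab], ann.interval, flank_size)
            nodes.append((lab, canonical_rotation(ann.consensus), left, right))
            anns.append(ann)

    uf = _UnionFind(len(nodes))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][0] == nodes[j][0]:
                continue  # same haplotype never links directly
            if uf.find(i) == uf.find(j):
                continue
            if _link(nodes[i], nodes[j], consensus_min_identity, flank_min_identity):
                uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        clusters.setdefault(uf.find(i), []).append(i)

    kept = []
    for members in clusters.values():
        member_haps = [nodes[i][0] for i in members]
        dup = [h for h, c in Counter(member_haps).items() if c > 1]
        if dup:
            raise HarmonizationError(
                f"cluster merged {len(members)} annotations including multiple from "
                f"haplotype(s) {dup}: thresholds are over-merging distinct loci"
            )
        if len(member_haps) > min_presence * n_haps:  # strictly more than half
            kept.append(members)

    kept.sort(key=lambda ms: float(np.median([anns[i].interval.start for i in ms])))
    loci = []
    for idx, members in enumerate(kept, start=1):
        by_hap = {nodes[i][0]: anns[i] for i in members}
        rep_hap = sorted(by_hap)[0]
        consensus = by_hap[rep_hap].consensus
        if reduce_doubled:
            reduced = reduce_doubled_motif(consensus)
            if len(reduced) < len(consensus):
                # re-decompose every member against the reduced motif
                by_hap = {
                    lab: decompose(
                        sequences[lab], ann.interval, _match_phase(reduced, ann)
                    )
                    for lab, ann in by_hap.items()
                }
                consensus = _match_phase(reduced, by_hap[rep_hap])
        allele_table = Counter(a.copy_number for a in by_hap.values())
        loci.append(
            Locus(
                tr_id=f"TR{idx:02d}",
                consensus=consensus,
                annotations=by_hap,
                is_vntr=len(allele_table) >= 2,
                allele_table=dict(sorted(allele_table.items())),
            )
        )
    return LocusCatalog(loci=loci, n_haplotypes=n_haps)


def _match_phase(motif: str, ann: RepeatAnnotation) -> str:
    """Rotate ``motif`` to the phase best matching the annotation's first unit."""
    head = ann.units[0][: len(motif)]
    doubled = motif + motif
    best, best_m = motif, -1
    for r in range(len(motif)):
        rot = doubled[r : r + len(motif)]
        m = sum(1 for x, y in zip(head, rot) if x == y)
        if m > best_m:
            best, best_m = rot, m
    return best


def summarize_catalog(
    catalog: LocusCatalog,
    heterozygosity_by_locus: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Published-style locus summary: one row per locus.

    Columns: TR id, consensus length, number of distinct copy-number
    alleles, copy number of the major allele, degree of heterozygosity
    (when genotypes are supplied), 1-based interval of a representative
    haplotype, consensus sequence and GC percent.
    """
    rows = []
    for locus in catalog:
        rep_hap = sorted(locus.annotations)[0]
        ann = locus.annotations[rep_hap]
        start1, end1 = ann.interval.to_1based()
        major = max(
            locus.allele_table, key=lambda cn: (locus.allele_table[cn], -cn)
        )
        het = (
            heterozygosity_by_locus.get(locus.tr_id)
            if heterozygosity_by_locus
            else None
        )
        rows.append(
            {
                "tr_id": locus.tr_id,
                "consensus_length": locus.unit_length,
                "n_alleles": len(locus.allele_table),
                "major_copy_number": major,
                "heterozygosity": round_half_up(het, 3) if het is not None else float("nan"),
                "is_vntr": locus.is_vntr,
                "n_haplotypes": locus.n_haplotypes,
                "start_1based": start1,
                "end_1based": end1,
                "consensus": locus.consensus,
                "gc_percent": gc_percent(locus.consensus),
            }
        )
    return pd.DataFrame(rows)


def annotations_from_table(
    table: pd.DataFrame, sequences: dict[str, str]
) -> dict[str, list[RepeatAnnotation]]:
    """Rebuild per-haplotype annotations from a repeats TSV.

    Expects the columns written by the annotate stage (haplotype, start,
    end, consensus, p_value); units and divergence are re-derived by
    decomposing the spanned sequence against the stored consensus.
    """
    per_hap: dict[str, list[RepeatAnnotation]] = {lab: [] for lab in sequences}
    for _, row in table.iterrows():
        lab = row["haplotype"]
        if lab not in sequences:
            raise HarmonizationError(f"no sequence for haplotype {lab}")
        ann = decompose(
            sequences[lab],
            GeneInterval(lab, int(row["start"]), int(row["end"])),
            str(row["consensus"]),
        )
        if "p_value" in row and pd.notna(row["p_value"]):
            ann.p_value = float(row["p_value"])
        per_hap[lab].append(ann)
    return per_hap
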