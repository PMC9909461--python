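"""SNP calling from reference projections, LD, heterozygosity, ANOVA, trios.

SNPs are the substitution-only variant columns of the reference-projected
haplotypes: a retained position has no gap in any haplotype, exactly two
observed alleles, lies outside every VNTR interval, and its minor-allele
frequency (over haplotypes) strictly exceeds the threshold.  LD between any
two variants is the squared Pearson correlation of their per-haplotype
vectors: SNPs enter as minor-allele indicators, VNTRs as real copy numbers.
Monomorphic vectors yield an undefined r^2, recorded as missing (never 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignParams, edit_align, global_align
from .harmonize import LocusCatalog
from .seqio import GeneInterval


class PopGenError(ValueError):
    pass


@dataclass
class VariantSet:
    positions: np.ndarray  # 0-based reference coordinates, ascending
    ref_alleles: list[str]
    alt_alleles: list[str]
    haplotype_labels: list[str]
    genotypes: np.ndarray  # (n_haplotypes, n_positions) minor-allele indicator
    maf: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def snp_ids(self) -> list[str]:
        return [f"snp{p + 1}" for p in self.positions]

    def to_vcf_table(self, contig: str = "gene") -> pd.DataFrame:
        rows = []
        for k, pos in enumerate(self.positions):
            rows.append(
                {
                    "CHROM": contig,
                    "POS": int(pos) + 1,
                    "ID": f"snp{int(pos) + 1}",
                    "REF": self.ref_alleles[k],
                    "ALT": self.alt_alleles[k],
                    "MAF": float(self.maf[k]),
                    **{
                        lab: int(self.genotypes[i, k])
                        for i, lab in enumerate(self.haplotype_labels)
                    },
                }
            )
        return pd.DataFrame(rows)


@dataclass
class LDMatrix:
    labels: list[str]
    r2: np.ndarray  # symmetric, unit diagonal, NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.labels, columns=self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.r2[i, j])


def call_snps(
    projections: dict[str, str],
    ref: str,
    maf_min: float = 0.05,
    excluded_regions: list[GeneInterval] | None = None,
) -> VariantSet:
    """Variant columns of the projected alignment (substitutions only).

    Columns where any haplotype projects a gap are excluded, as are
    non-biallelic columns, columns inside ``excluded_regions`` (VNTR
    intervals), and columns with minor-allele frequency <= maf_min
    (strict inequality retains).
    """
    labels = sorted(projections)
    lengths = {len(projections[lab]) for lab in labels}
    if lengths != {len(ref)}:
        raise PopGenError(
            f"projections must all have reference length {len(ref)}, got {sorted(lengths)}"
        )
    mat = np.frombuffer("".join(projections[lab] for lab in labels).encode(), dtype="S1")
    mat = mat.reshape(len(labels), len(ref))
    refarr = np.frombuffer(ref.encode(), dtype="S1")
    n_hap = len(labels)

    no_gap = ~np.any(mat == b"-", axis=0)
    any_diff = np.any(mat != refarr, axis=0)
    candidates = np.flatnonzero(no_gap & any_diff)

    excluded_regions = excluded_regions or []
    positions, refs, alts, genos, mafs = [], [], [], [], []
    for pos in candidates:
        if any(iv.contains(int(pos)) for iv in excluded_regions):
            continue
        col = mat[:, pos]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) != 2:
            continue
        minor_idx = int(np.argmin(counts))
        maf = counts[minor_idx] / n_hap
        if not maf > maf_min:
            continue
        minor = alleles[minor_idx].decode()
        major = alleles[1 - minor_idx].decode()
        ref_base = refarr[pos].decode()
        alt = minor if minor != ref_base else major
        positions.append(int(pos))
        refs.append(ref_base)
        alts.append(alt)
        genos.append((col == alleles[minor_idx]).astype(np.int8))
        mafs.append(float(maf))

    return VariantSet(
        positions=np.array(positions, dtype=int),
        ref_alleles=refs,
        alt_alleles=alts,
        haplotype_labels=labels,
        genotypes=(
            np.stack(genos, axis=1) if genos else np.zeros((n_hap, 0), dtype=np.int8)
        ),
        maf=np.array(mafs),
    )


def ld_matrix(
    variants: VariantSet | None,
    loci_copy_numbers: pd.DataFrame | None = None,
) -> LDMatrix:
    """Pairwise r^2 among SNPs and VNTR copy numbers over haplotypes.

    ``loci_copy_numbers``: DataFrame indexed by haplotype label with one
    column per VNTR locus (real copy numbers).  Vector order follows the
    variant set's haplotype labels; a locus table alone is accepted.
    """
    blocks, labels = [], []
    if variants is not None and len(variants):
        hap_order = variants.haplotype_labels
        blocks.append(variants.genotypes.astype(float))
        labels.extend(variants.snp_ids())
    elif loci_copy_numbers is not None:
        hap_order = sorted(loci_copy_numbers.index)
    else:
        raise PopGenError("nothing to correlate")
    if loci_copy_numbers is not None and not loci_copy_numbers.empty:
        cn = loci_copy_numbers.loc[list(hap_order)]
        blocks.append(cn.to_numpy(dtype=float))
        labels.extend(cn.columns)
    data = np.concatenate(blocks, axis=1)  # (n_hap, n_var)
    if variants is not None and len(variants) and data.shape[0] != len(variants.haplotype_labels):
        raise PopGenError("haplotype count mismatch between SNPs and copy numbers")
    sd = data.std(axis=0)
    centered = data - data.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ centered) / data.shape[0]
        denom = np.outer(sd, sd)
        r = corr / denom
    r2 = r**2
    r2[:, sd == 0] = np.nan
    r2[sd == 0, :] = np.nan
    np.fill_diagonal(r2, np.where(sd == 0, np.nan, 1.0))
    return LDMatrix(labels=labels, r2=r2)


# ---------------------------------------------------------------------------
# Genotype-level statistics
# ---------------------------------------------------------------------------

def genotype_table(
    catalog: LocusCatalog, vntrs_only: bool = True, on_missing: str = "error"
) -> pd.DataFrame:
    """Per-individual (copy_number_h1, copy_number_h2) rows per locus.

    Haplotype labels follow the ``<sample>_h<1|2>`` convention.  An
    individual missing one haplotype at a locus raises by default;
    ``on_missing="drop"`` skips that individual at that locus instead
    (useful when a locus evaded detection in a single haplotype).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    loci = catalog.vntrs if vntrs_only else list(catalog)
    rows = []
    for locus in loci:
        by_sample: dict[str, dict[int, float]] = {}
        for lab, ann in locus.annotations.items():
            sample, h = lab.rsplit("_h", 1)
            by_sample.setdefault(sample, {})[int(h)] = ann.copy_number
        for sample, cns in sorted(by_sample.items()):
            if set(cns) != {1, 2}:
                if on_missing == "drop":
                    continue
                raise PopGenError(
                    f"unpaired individual {sample} at {locus.tr_id}: haplotypes {sorted(cns)}"
                )
            rows.append(
                {
                    "individual": sample,
                    "locus": locus.tr_id,
                    "copy_number_h1": cns[1],
                    "copy_number_h2": cns[2],
                }
            )
    return pd.DataFrame(rows)


def heterozygosity(genotypes: pd.DataFrame, locus: str) -> float:
    """Fraction of individuals with two different copy-number alleles.

    Copy numbers are compared at 1-decimal resolution (the unit they are
    reported in).
    """
    sub = genotypes[genotypes["locus"] == locus]
    if sub.empty:
        raise PopGenError(f"no genotypes for locus {locus}")
    h1 = np.round(sub["copy_number_h1"].to_numpy(float), 1)
    h2 = np.round(sub["copy_number_h2"].to_numpy(float), 1)
    return float(np.mean(h1 != h2))


def anova_copy_number(
    copy_numbers,
    group_labels,
    min_group_n: int = 3,
) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of haplotype copy numbers on group labels.

    Groups smaller than ``min_group_n`` are dropped before testing (the
    convention for underpowered ancestry categories).  Returns
    (F, df_between, df_within, p).
    """
    copy_numbers = np.asarray(copy_numbers, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = []
    for g in np.unique(group_labels):
        vals = copy_numbers[group_labels == g]
        if len(vals) >= min_group_n:
            groups.append(vals)
    if len(groups) < 2:
        raise PopGenError("need at least two groups of sufficient size")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise PopGenError("all copy numbers identical: F undefined")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(f), df1, df2, float(p)


# ---------------------------------------------------------------------------
# Trio transmission
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTransmission:
    child_hap: str
    parent: str  # "mother" | "father"
    parent_hap: str
    similarity_percent: float
    per_locus: pd.DataFrame  # tr_id, copy_match, mismatches, indel_events, ...


class MendelianInconsistencyError(ValueError):
    pass


def _whole_gene_similarity(a: str, b: str) -> float:
    return edit_align(a, b).identity * 100.0


def trio_transmission(
    child: dict[str, str],
    mother: dict[str, str],
    father: dict[str, str],
    catalog: LocusCatalog,
    params: AlignParams | None = None,
) -> list[HaplotypeTransmission]:
    """Assign each child haplotype to its transmitting parental haplotype.

    Arguments are ``{haplotype_label: sequence}`` with two entries each;
    the catalog must contain annotations for all six haplotypes.  Each
    child haplotype goes to the parental haplotype with maximal whole-gene
    similarity, under the constraint of one maternal and one paternal
    transmission; if both child haplotypes unambiguously prefer the same
    parent, a Mendelian inconsistency is raised.  Per-VNTR statistics come
    from affine global alignment of the annotated locus spans.
    """
    params = params or AlignParams()
    child_labels = sorted(child)
    mother_labels = sorted(mother)
    father_labels = sorted(father)
    if not (len(child_labels) == len(mother_labels) == len(father_labels) == 2):
        raise PopGenError("each trio member needs exactly two haplotypes")

    sim = {
        (c, p): _whole_gene_similarity(child[c], seq)
        for c in child_labels
        for p, seq in {**mother, **father}.items()
    }
    # Mendelian check: both children preferring the same parent is an error
    best_parent = {}
    for c in child_labels:
        best = max(sim[(c, p)] for p in (*mother_labels, *father_labels))
        from_mother = any(sim[(c, m)] == best for m in mother_labels)
        from_father = any(sim[(c, f)] == best for f in father_labels)
        best_parent[c] = (from_mother, from_father)
    if all(bp == (True, False) for bp in best_parent.values()) or all(
        bp == (False, True) for bp in best_parent.values()
    ):
        raise MendelianInconsistencyError(
            "both child haplotypes align best to the same parent"
        )

    # constrained optimum over (which child hap is maternal) x (parent haps)
    best_assign, best_total = None, -1.0
    for maternal_child, paternal_child in (
        (child_labels[0], child_labels[1]),
        (child_labels[1], child_labels[0]),
    ):
        for m in mother_labels:
            for f in father_labels:
                total = sim[(maternal_child, m)] + sim[(paternal_child, f)]
                if total > best_total:
                    best_total = total
                    best_assign = ((maternal_child, "mother", m), (paternal_child, "father", f))

    results = []
    for child_hap, parent_name, parent_hap in best_assign:
        rows = []
        for locus in catalog.vntrs:
            if child_hap not in locus.annotations or parent_hap not in locus.annotations:
                continue
            ca = locus.annotations[child_hap]
            pa = locus.annotations[parent_hap]
            aln = global_align(ca.spanned_sequence(), pa.spanned_sequence(), params)
            rows.append(
                {
                    "tr_id": locus.tr_id,
                    "child_copy_number": ca.copy_number,
                    "parent_copy_number": pa.copy_number,
                    "copy_match": ca.copy_number == pa.copy_number,
                    "mismatches": aln.mismatches,
                    "indel_events": aln.gap_events,
                }
            )
        results.append(
            HaplotypeTransmission(
                child_hap=child_hap,
                parent=parent_name,
                parent_hap=parent_hap,
                similarity_percent=sim[(child_hap, parent_hap)],
                per_locus=pd.DataFrame(rows),
            )
        )
    return results
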