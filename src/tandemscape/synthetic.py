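"""Synthetic cohorts of haplotype gene sequences with full ground truth.

The generator emulates the study design the pipeline targets: a ~55 kb gene
bounded by the two UTR anchor sequences, ~30 embedded tandem-repeat loci of
unit length >= 7 bp, five of them copy-number variable — one hypervariable,
GC-rich, with alleles spanning 3.4-133.4 copies — flanking SNPs with
configurable frequency and configurable LD to a named VNTR, ancestry
labels, parent-child trios with faithful transmission plus optional de novo
indels, and technology noise with CLR-like homopolymer-biased indels.

Every planted quantity (locus intervals, unit strings, genotypes, SNP
carriers, trio edit scripts) is recorded so downstream stages can be
verified exactly.

Boundary convention: each planted array is flanked by two guard bases per
side that do not continue the cyclic consensus.  This makes the planted
interval the maximal repeat-consistent span, i.e. it makes the planted
copy number well defined — without the guards, flanking bases that happen
to continue the motif would belong to the repeat under any reasonable
definition and the "truth" itself would be ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .extraction import SLC6A3_ANCHOR_3P, SLC6A3_ANCHOR_5P
from .seqio import HaplotypeRecord, _validate_dna

_B = np.array(list("ACGT"))


class SyntheticSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class LocusSpec:
    name: str
    consensus: str
    allele_distribution: dict[float, float]  # copy number -> frequency
    per_unit_sub_rate: float = 0.0  # per-base substitution probability in full units
    het_target: int | None = None  # exact heterozygous-individual count, optional
    partial_tail_fraction: float = 0.0  # used when synthesizing random allele sets
    gc_target: float | None = None

    def __post_init__(self) -> None:
        _validate_dna(self.consensus, self.name)
        if len(self.consensus) < 7:
            raise SyntheticSpecError(f"{self.name}: consensus must be >= 7 bp")
        total = sum(self.allele_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise SyntheticSpecError(f"{self.name}: allele frequencies sum to {total}")
        if any(cn < 2 for cn in self.allele_distribution):
            raise SyntheticSpecError(f"{self.name}: copy numbers must be >= 2")
        if not (0.0 <= self.partial_tail_fraction < 1.0):
            raise SyntheticSpecError(f"{self.name}: partial_tail_fraction out of range")

    @property
    def is_variable(self) -> bool:
        return len(self.allele_distribution) > 1


@dataclass
class SnpSpec:
    name: str
    minor_freq: float
    position: int | None = None  # template coordinate; auto-placed when None
    target_r2: float | None = None
    ld_locus: str | None = None  # locus whose copy number the SNP correlates with
    inside_locus: str | None = None  # plant inside this locus's first unit

    def __post_init__(self) -> None:
        if not (0.0 < self.minor_freq < 0.5):
            raise SyntheticSpecError(f"{self.name}: minor_freq must be in (0, 0.5)")
        if self.target_r2 is not None and self.ld_locus is None:
            raise SyntheticSpecError(f"{self.name}: target_r2 needs ld_locus")


@dataclass
class TrioSpec:
    name: str
    de_novo_indels: dict[str, int] = field(default_factory=dict)  # locus -> count


@dataclass
class NoiseParams:
    indel_rate: float  # per base
    substitution_rate: float
    homopolymer_weight: float = 10.0  # extra weight inside runs >= 3
    c_run_a_weight: float = 2.0  # further bias for C-runs followed by A

    def __post_init__(self) -> None:
        if self.indel_rate < 0 or self.substitution_rate < 0:
            raise SyntheticSpecError("noise rates must be >= 0")


DEFAULT_NOISE = {
    # CLR indel error concentrates in homopolymers; CCS is ~10x cleaner
    "CLR": NoiseParams(indel_rate=3.0e-4, substitution_rate=2.0e-5),
    "CCS": NoiseParams(indel_rate=3.0e-5, substitution_rate=2.0e-6),
}

DEFAULT_ANCESTRY_COUNTS = {
    # individuals per group (haplotype counts double these)
    "African": 9,
    "South_Asian": 5,
    "East_Asian": 6,
    "European": 6,
    "African_admixed": 1,
    "Indigenous_admixed": 5,
}


@dataclass
class CohortSpec:
    n_individuals: int = 32
    gene_length: int = 55000
    loci: list[LocusSpec] = field(default_factory=list)
    snps: list[SnpSpec] = field(default_factory=list)
    trios: list[TrioSpec] = field(default_factory=list)
    ancestry_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ANCESTRY_COUNTS))
    noise: dict[str, NoiseParams] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    anchor_5p: str = SLC6A3_ANCHOR_5P
    anchor_3p: str = SLC6A3_ANCHOR_3P
    min_spacing: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise SyntheticSpecError("need at least one individual")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise SyntheticSpecError("duplicate locus names")
        if self.ancestry_counts and sum(self.ancestry_counts.values()) != self.n_individuals:
            raise SyntheticSpecError("ancestry counts must sum to n_individuals")

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_individuals


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class LocusTruth:
    name: str
    consensus: str
    template_interval: tuple[int, int]
    intervals: dict[str, tuple[int, int]]  # haplotype label -> (start, end)
    copy_numbers: dict[str, float]
    units: dict[str, list[str]]
    is_variable: bool


@dataclass
class TrioTruth:
    name: str
    mother: list[HaplotypeRecord]
    father: list[HaplotypeRecord]
    child: list[HaplotypeRecord]
    transmitted: dict[str, tuple[str, str]]  # child label -> (parent, parent label)
    de_novo: dict[tuple[str, str], pd.DataFrame]  # (child label, locus) -> edit script
    child_intervals: dict[tuple[str, str], tuple[int, int]]


@dataclass
class Cohort:
    spec: CohortSpec
    records: list[HaplotypeRecord]
    template: str  # reference gene sequence (major alleles, SNP reference bases)
    loci: dict[str, LocusTruth]
    snp_table: pd.DataFrame
    genotypes: pd.DataFrame  # individual, locus, cn_h1, cn_h2
    ancestry: dict[str, str]
    trios: list[TrioTruth]

    @property
    def reference_record(self) -> HaplotypeRecord:
        return HaplotypeRecord(
            sample_id="REF", haplotype_index=1, technology="synthetic",
            sequence=self.template, source_path="template",
        )

    @property
    def vntr_names(self) -> list[str]:
        return [n for n, t in self.loci.items() if t.is_variable]

    def sequences(self) -> dict[str, str]:
        return {r.label: r.sequence for r in self.records}


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_B, size=n, p=p))


def _tail_length(copy_number: float, unit: int) -> int:
    return int(round((copy_number - int(copy_number)) * unit))


def _array_length(copy_number: float, unit: int) -> int:
    return int(copy_number) * unit + _tail_length(copy_number, unit)


def _true_copy_number(length: int, unit: int) -> float:
    import math

    return math.floor(length / unit * 10 + 0.5) / 10


def _guard(motif: str, tail: int, side: str) -> str:
    """Two bases that do not continue the cyclic motif on the given side.

    Each guard base also differs from its inward neighbor (the adjacent
    array or guard character): a guard that extends a homopolymer run
    across the boundary would still admit a repeat-consistent reading of
    the flank (via an insertion), leaving the planted boundary ambiguous.
    """
    u = len(motif)
    if side == "left":
        # read outward from the array start: avoid the cyclic predecessors
        inner = motif[0]
        g1 = next(b for b in "ACGT" if b not in (motif[(u - 1) % u], inner))
        g2 = next(b for b in "ACGT" if b not in (motif[(u - 2) % u], g1))
        return g2 + g1
    edge = motif[tail - 1] if tail else motif[u - 1]
    g1 = next(b for b in "ACGT" if b not in (motif[tail % u], edge))
    g2 = next(b for b in "ACGT" if b not in (motif[(tail + 1) % u], g1))
    return g1 + g2


_BOUNDARY_CLEAN = 4  # outermost bases of the array kept consensus-exact


def _realize_array(
    rng: np.random.Generator, spec: LocusSpec, copy_number: float
) -> list[str]:
    """Unit strings for one allele: mutated full units + verbatim tail.

    The outermost bases of the array (first bases of the first unit; last
    bases of the last unit when there is no tail) are kept consensus-exact:
    a substitution at the extreme edge of an array is indistinguishable
    from a shorter array with mismatching flank, so planting one would make
    the ground-truth boundary ill defined (same rationale as the guard
    bases).
    """
    u = len(spec.consensus)
    n_full = int(copy_number)
    tail = _tail_length(copy_number, u)
    # the cohort emulates repeats *retained* by the 0.05-divergence filter,
    # so the realized per-allele load stays below it; terminal units carry
    # at most one substitution (a mutation cluster at the array terminus
    # makes the boundary itself ill defined, like an edge substitution)
    budget = int(np.floor(0.04 * n_full * u))
    units = []
    for k in range(n_full):
        unit = list(spec.consensus)
        if spec.per_unit_sub_rate > 0 and budget > 0:
            terminal = k == 0 or (k == n_full - 1 and tail == 0)
            cap = 1 if terminal else int(np.ceil(0.06 * u))
            allowed = np.arange(u)
            if k == 0:
                allowed = allowed[allowed >= _BOUNDARY_CLEAN]
            if k == n_full - 1 and tail == 0:
                allowed = allowed[allowed < u - _BOUNDARY_CLEAN]
            n_mut = min(
                rng.binomial(u, spec.per_unit_sub_rate), cap, budget, len(allowed)
            )
            for pos in rng.choice(allowed, size=n_mut, replace=False):
                unit[pos] = rng.choice([b for b in "ACGT" if b != unit[pos]])
            budget -= n_mut
        units.append("".join(unit))
    if tail:
        units.append(spec.consensus[:tail])
    return units


def _allele_counts(dist: dict[float, float], n: int) -> dict[float, int]:
    """Largest-remainder apportionment; every positive-frequency allele >= 1."""
    items = sorted(dist.items())
    raw = {cn: f * n for cn, f in items}
    counts = {cn: max(1, int(np.floor(v))) if dist[cn] > 0 else 0 for cn, v in raw.items()}
    while sum(counts.values()) > n:
        cn = max(counts, key=lambda c: (counts[c] - raw[c], counts[c]))
        if counts[cn] <= 1:
            raise SyntheticSpecError("cannot fit all alleles into the haplotype count")
        counts[cn] -= 1
    rema = sorted(raw, key=lambda c: (raw[c] - counts[c]), reverse=True)
    i = 0
    while sum(counts.values()) < n:
        counts[rema[i % len(rema)]] += 1
        i += 1
    return counts


def _pair_genotypes(
    rng: np.random.Generator,
    counts: dict[float, int],
    n_individuals: int,
    het_target: int | None,
) -> list[tuple[float, float]]:
    """Pair 2N allele copies into N individual genotypes.

    With ``het_target`` set, exactly that many individuals are heterozygous.
    """
    if het_target is None:
        pool = [cn for cn, c in counts.items() for _ in range(c)]
        pool = list(rng.permutation(pool))
        return [(pool[2 * i], pool[2 * i + 1]) for i in range(n_individuals)]
    if not (0 <= het_target <= n_individuals):
        raise SyntheticSpecError("het_target out of range")
    pool = dict(counts)
    pairs: list[tuple[float, float]] = []
    for _ in range(n_individuals - het_target):  # homozygotes first
        cn = max(pool, key=lambda c: (pool[c], -c))
        if pool[cn] < 2:
            raise SyntheticSpecError(
                f"cannot build {n_individuals - het_target} homozygotes from {counts}"
            )
        pool[cn] -= 2
        pairs.append((cn, cn))
    for _ in range(het_target):
        avail = sorted([c for c, k in pool.items() if k > 0])
        if len(avail) < 2:
            raise SyntheticSpecError(f"cannot build {het_target} heterozygotes from {counts}")
        a = max(avail, key=lambda c: (pool[c], -c))
        b = max([c for c in avail if c != a], key=lambda c: (pool[c], -c))
        pool[a] -= 1
        pool[b] -= 1
        pairs.append((a, b))
    order = rng.permutation(n_individuals)
    out = []
    for i in order:
        a, b = pairs[int(i)]
        if rng.random() < 0.5:
            a, b = b, a
        out.append((a, b))
    return out


def _ld_carrier_probs(
    copy_numbers: np.ndarray, q: float, target_r2: float, name: str
) -> np.ndarray:
    """P(minor | copy number) hitting |Pearson r| = sqrt(target_r2) in expectation.

    The conditional probability is linear in the copy number, which solves
    the covariance constraint exactly; r^2 fixes only the magnitude, so the
    sign is chosen to keep every probability inside [0, 1].
    """
    mu, sd = copy_numbers.mean(), copy_numbers.std()
    if sd == 0:
        raise SyntheticSpecError(f"{name}: LD target against a monomorphic locus")
    sx = np.sqrt(q * (1 - q))
    for r in (float(np.sqrt(target_r2)), -float(np.sqrt(target_r2))):
        p = q + r * sx * (copy_numbers - mu) / sd
        if p.min() >= 0 and p.max() <= 1:
            return p
    ext_hi = (copy_numbers.max() - mu) / sd
    ext_lo = (mu - copy_numbers.min()) / sd
    r_max = max(
        min((1 - q) / (sx * ext_hi), q / (sx * ext_lo)),
        min((1 - q) / (sx * ext_lo), q / (sx * ext_hi)),
    )
    raise SyntheticSpecError(
        f"{name}: target r^2 {target_r2:.3f} infeasible for minor_freq {q}; "
        f"max feasible r^2 under the linear model is {min(1.0, r_max**2):.3f}"
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Build the cohort deterministically from (spec, seed).

    The template ("reference") gene carries the modal allele at every locus
    and the reference base at every SNP; haplotypes differ from it by their
    planted alleles, unit substitutions, and SNP minor alleles.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_hap = spec.n_haplotypes

    # --- template layout -------------------------------------------------
    template_arrays = {}
    modal = {}
    for locus in spec.loci:
        cn = max(locus.allele_distribution, key=lambda c: (locus.allele_distribution[c], -c))
        modal[locus.name] = cn
        u = len(locus.consensus)
        arr = locus.consensus * int(cn) + locus.consensus[: _tail_length(cn, u)]
        template_arrays[locus.name] = arr

    fixed = (
        len(spec.anchor_5p)
        + len(spec.anchor_3p)
        + sum(len(a) + 4 for a in template_arrays.values())  # +4: guard bases
    )
    n_seg = len(spec.loci) + 1
    budget = spec.gene_length - fixed
    if budget < n_seg * spec.min_spacing:
        raise SyntheticSpecError("gene_length too small for the requested loci")
    weights = rng.random(n_seg) + 0.5
    extra = np.floor(weights / weights.sum() * (budget - n_seg * spec.min_spacing)).astype(int)
    seg_lengths = [spec.min_spacing + int(e) for e in extra]
    seg_lengths[-1] += budget - sum(seg_lengths)

    flanks = [_rand_seq(rng, n) for n in seg_lengths]
    # place guards at flank/array junctions
    parts = [spec.anchor_5p]
    template_intervals = {}
    pos = len(spec.anchor_5p)
    for i, locus in enumerate(spec.loci):
        u = len(locus.consensus)
        cn = modal[locus.name]
        tail = _tail_length(cn, u)
        left_guard = _guard(locus.consensus, tail, "left")
        right_guard = _guard(locus.consensus, tail, "right")
        flank = flanks[i]
        parts.append(flank)
        pos += len(flank)
        parts.append(left_guard)
        pos += 2
        arr = template_arrays[locus.name]
        template_intervals[locus.name] = (pos, pos + len(arr))
        parts.append(arr)
        pos += len(arr)
        parts.append(right_guard)
        pos += 2
    parts.append(flanks[-1])
    pos += len(flanks[-1])
    parts.append(spec.anchor_3p)
    template = "".join(parts)

    # --- SNP placement ----------------------------------------------------
    snp_rows = []
    auto = [s for s in spec.snps if s.position is None and s.inside_locus is None]
    flank_bounds = []
    cursor = len(spec.anchor_5p)
    for i, locus in enumerate(spec.loci):
        flank_bounds.append((cursor + 30, cursor + seg_lengths[i] - 30))
        cursor += seg_lengths[i] + 4 + len(template_arrays[locus.name])
    flank_bounds.append((cursor + 30, cursor + seg_lengths[-1] - 30))
    taken: set[int] = set()
    auto_positions = []
    for k, s in enumerate(auto):
        lo, hi = flank_bounds[k % len(flank_bounds)]
        while True:
            p = int(rng.integers(lo, hi))
            if all(abs(p - t) > 3 for t in taken):
                taken.add(p)
                auto_positions.append(p)
                break
    it = iter(auto_positions)
    for s in spec.snps:
        if s.inside_locus is not None:
            lo, hi = template_intervals[s.inside_locus]
            unit_len = len(next(l for l in spec.loci if l.name == s.inside_locus).consensus)
            p = lo + min(unit_len // 2, hi - lo - 1)
        elif s.position is not None:
            p = s.position
        else:
            p = next(it)
        ref_base = template[p]
        alt_base = next(b for b in "ACGT" if b != ref_base)
        snp_rows.append(
            {"name": s.name, "position": p, "ref": ref_base, "alt": alt_base,
             "minor_freq": s.minor_freq, "target_r2": s.target_r2,
             "ld_locus": s.ld_locus, "inside_locus": s.inside_locus}
        )
    snp_df = pd.DataFrame(snp_rows)

    # --- genotypes --------------------------------------------------------
    samples = [f"S{i + 1:02d}" for i in range(spec.n_individuals)]
    hap_labels = [f"{s}_h{h}" for s in samples for h in (1, 2)]
    genotype_pairs = {}
    for locus in spec.loci:
        counts = _allele_counts(locus.allele_distribution, n_hap)
        genotype_pairs[locus.name] = _pair_genotypes(
            rng, counts, spec.n_individuals, locus.het_target
        )
    geno_rows = []
    hap_alleles: dict[str, dict[str, float]] = {lab: {} for lab in hap_labels}
    for locus in spec.loci:
        for i, s in enumerate(samples):
            a, b = genotype_pairs[locus.name][i]
            hap_alleles[f"{s}_h1"][locus.name] = a
            hap_alleles[f"{s}_h2"][locus.name] = b
            geno_rows.append(
                {"individual": s, "locus": locus.name, "cn_h1": a, "cn_h2": b}
            )
    genotypes = pd.DataFrame(geno_rows)

    # --- SNP carriers -----------------------------------------------------
    carrier_sets: dict[str, np.ndarray] = {}
    for _, row in snp_df.iterrows():
        q = row["minor_freq"]
        if row["target_r2"] is not None and not pd.isna(row["target_r2"]):
            c = np.array([hap_alleles[lab][row["ld_locus"]] for lab in hap_labels])
            probs = _ld_carrier_probs(c, q, float(row["target_r2"]), row["name"])
            carriers = rng.random(n_hap) < probs
        else:
            k = max(1, int(round(q * n_hap)))
            idx = rng.choice(n_hap, size=k, replace=False)
            carriers = np.zeros(n_hap, dtype=bool)
            carriers[idx] = True
        carrier_sets[row["name"]] = carriers
    snp_df["carriers"] = [
        [hap_labels[i] for i in np.flatnonzero(carrier_sets[nm])] for nm in snp_df["name"]
    ] if len(snp_df) else []

    # --- haplotype assembly ----------------------------------------------
    records = []
    loci_truth = {
        locus.name: LocusTruth(
            name=locus.name,
            consensus=locus.consensus,
            template_interval=template_intervals[locus.name],
            intervals={},
            copy_numbers={},
            units={},
            is_variable=locus.is_variable,
        )
        for locus in spec.loci
    }
    ancestry_of = {}
    group_list = [g for g, k in spec.ancestry_counts.items() for _ in range(k)]
    for s, grp in zip(samples, group_list):
        ancestry_of[s] = grp

    for hi, lab in enumerate(hap_labels):
        sample = lab.rsplit("_h", 1)[0]
        seq, intervals, unit_lists = _assemble_haplotype(
            spec, rng, flanks, seg_lengths, hap_alleles[lab],
            {nm: carrier_sets[nm][hi] for nm in carrier_sets},
            snp_df, template_intervals,
        )
        for locus in spec.loci:
            truth = loci_truth[locus.name]
            truth.intervals[lab] = intervals[locus.name]
            length = intervals[locus.name][1] - intervals[locus.name][0]
            truth.copy_numbers[lab] = _true_copy_number(length, len(locus.consensus))
            truth.units[lab] = unit_lists[locus.name]
        records.append(
            HaplotypeRecord(
                sample_id=sample,
                haplotype_index=int(lab[-1]),
                technology="synthetic",
                ancestry=ancestry_of.get(sample),
                sequence=seq,
                source_path="synthetic",
            )
        )

    cohort = Cohort(
        spec=spec,
        records=records,
        template=template,
        loci=loci_truth,
        snp_table=snp_df,
        genotypes=genotypes,
        ancestry=ancestry_of,
        trios=[],
    )

    # --- trios ------------------------------------------------------------
    for t_idx, trio_spec in enumerate(spec.trios, start=1):
        cohort.trios.append(
            _generate_trio_family(spec, rng, flanks, seg_lengths, snp_df,
                                  template_intervals, trio_spec, t_idx)
        )
    return cohort


def _assemble_haplotype(
    spec, rng, flanks, seg_lengths, alleles, carrier_flags, snp_df, template_intervals
):
    """One haplotype: shared flanks + per-allele arrays + SNP substitutions."""
    flank_strs = [list(f) for f in flanks]
    # apply flank SNPs (carriers only); positions are template coordinates
    flank_starts = []
    cursor = len(spec.anchor_5p)
    for i, locus in enumerate(spec.loci):
        flank_starts.append(cursor)
        cursor += seg_lengths[i] + 4 + (
            template_intervals[locus.name][1] - template_intervals[locus.name][0]
        )
    flank_starts.append(cursor)

    unit_lists = {}
    arrays = {}
    for locus in spec.loci:
        units = _realize_array(rng, locus, alleles[locus.name])
        unit_lists[locus.name] = units
        arrays[locus.name] = "".join(units)

    for _, row in snp_df.iterrows():
        if not carrier_flags.get(row["name"], False):
            continue
        p = int(row["position"])
        if row["inside_locus"] is not None and not pd.isna(row["inside_locus"]):
            nm = row["inside_locus"]
            off = p - template_intervals[nm][0]
            arr = arrays[nm]
            if off < len(arr):
                arrays[nm] = arr[:off] + row["alt"] + arr[off + 1 :]
                # keep unit bookkeeping consistent
                us, acc = [], 0
                for u in unit_lists[nm]:
                    if acc <= off < acc + len(u):
                        k = off - acc
                        u = u[:k] + row["alt"] + u[k + 1 :]
                    us.append(u)
                    acc += len(u)
                unit_lists[nm] = us
            continue
        for i, fs in enumerate(flank_starts):
            if fs <= p < fs + seg_lengths[i]:
                flank_strs[i][p - fs] = row["alt"]
                break

    parts = [spec.anchor_5p]
    intervals = {}
    pos = len(spec.anchor_5p)
    for i, locus in enumerate(spec.loci):
        u = len(locus.consensus)
        cn = alleles[locus.name]
        tail = _tail_length(cn, u)
        parts.append("".join(flank_strs[i]))
        pos += seg_lengths[i]
        parts.append(_guard(locus.consensus, tail, "left"))
        pos += 2
        arr = arrays[locus.name]
        intervals[locus.name] = (pos, pos + len(arr))
        parts.append(arr)
        pos += len(arr)
        parts.append(_guard(locus.consensus, tail, "right"))
        pos += 2
    parts.append("".join(flank_strs[-1]))
    pos += seg_lengths[-1]
    parts.append(spec.anchor_3p)
    return "".join(parts), intervals, unit_lists


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------

def _sample_parent(spec, rng, flanks, seg_lengths, snp_df, template_intervals,
                   sample_id, min_copies: dict | None = None
                   ) -> tuple[list[HaplotypeRecord], dict, dict]:
    """Parent haplotypes sampled from the cohort allele distributions.

    ``min_copies`` restricts the allele pool at named loci (used for de novo
    instability loci: a planted indel in a very short array is not
    identifiable, since the period itself becomes ambiguous there).
    """
    min_copies = min_copies or {}
    recs, intervals_by_lab, units_by_lab = [], {}, {}
    for h in (1, 2):
        alleles = {}
        for locus in spec.loci:
            dist = locus.allele_distribution
            floor_cn = min_copies.get(locus.name)
            if floor_cn is not None:
                restricted = {c: f for c, f in dist.items() if c >= floor_cn}
                if restricted:
                    tot = sum(restricted.values())
                    dist = {c: f / tot for c, f in restricted.items()}
            alleles[locus.name] = float(
                rng.choice(list(dist), p=np.array(list(dist.values())))
            )
        carrier_flags = {
            row["name"]: bool(rng.random() < row["minor_freq"])
            for _, row in snp_df.iterrows()
        }
        seq, intervals, unit_lists = _assemble_haplotype(
            spec, rng, flanks, seg_lengths, alleles, carrier_flags, snp_df,
            template_intervals,
        )
        rec = HaplotypeRecord(
            sample_id=sample_id, haplotype_index=h, technology="synthetic",
            sequence=seq, source_path="synthetic",
        )
        recs.append(rec)
        intervals_by_lab[rec.label] = intervals
        units_by_lab[rec.label] = unit_lists
    return recs, intervals_by_lab, units_by_lab


def generate_trio(
    mother: list[HaplotypeRecord],
    father: list[HaplotypeRecord],
    de_novo: dict[str, int],
    locus_intervals: dict[str, dict[str, tuple[int, int]]],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    child_id: str = "CHILD",
) -> tuple[list[HaplotypeRecord], dict[str, tuple[str, str]], dict, dict]:
    """One haplotype from each parent, verbatim, plus optional de novo indels.

    ``locus_intervals`` maps parent haplotype label -> locus -> (start, end).
    De novo single-base indels are placed inside the named loci at
    homopolymer-preferring positions, at least 3 bp apart; the edit script
    and the child's shifted locus intervals are returned.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    picks = {1: ("mother", mother[int(rng.integers(2))]),
             2: ("father", father[int(rng.integers(2))])}
    child_records = []
    transmitted = {}
    edit_scripts: dict[tuple[str, str], pd.DataFrame] = {}
    child_intervals: dict[tuple[str, str], tuple[int, int]] = {}
    for h in (1, 2):
        parent_name, parent_rec = picks[h]
        seq = parent_rec.sequence
        intervals = dict(locus_intervals[parent_rec.label])
        shift_events: list[tuple[int, int]] = []  # (position, +1/-1)
        # process loci right-to-left so edits never shift pending positions
        for locus_name in sorted(
            (nm for nm in de_novo), key=lambda nm: -intervals[nm][0]
        ):
            count = de_novo[locus_name]
            if count == 0:
                continue
            lo, hi = intervals[locus_name]
            if count >= hi - lo:
                raise SyntheticSpecError(
                    f"{locus_name}: {count} de novo indels exceed locus length"
                )
            # interior placement: an indel near the array terminus entangles
            # boundary placement with the event itself, making the
            # intergenerational comparison ill defined, so events stay at
            # least ~2 units clear of each edge; >= 8 bp spacing keeps each
            # indel a separate event under affine alignment (a close
            # ins/del pair aligns as substitutions instead)
            margin = min(100, (hi - lo) // 3)
            ilo, ihi = lo + margin, hi - margin
            if ihi - ilo <= count * 8:
                ilo, ihi = lo + 4, hi - 4
            positions = _homopolymer_preferring_positions(seq, ilo, ihi, count, rng, min_gap=8)
            ops = []
            for p in sorted(positions, reverse=True):
                if rng.random() < 0.5:
                    seq = seq[:p] + seq[p] + seq[p:]  # single-base duplication
                    ops.append({"locus": locus_name, "op": "ins", "position": p})
                    shift_events.append((p, 1))
                else:
                    seq = seq[:p] + seq[p + 1 :]
                    ops.append({"locus": locus_name, "op": "del", "position": p})
                    shift_events.append((p, -1))
            edit_scripts[(f"{child_id}_h{h}", locus_name)] = pd.DataFrame(ops)
        # shift intervals downstream of each edit; grow/shrink the edited locus
        new_intervals = {}
        for nm, (lo, hi) in intervals.items():
            d_lo = sum(d for p, d in shift_events if p < lo)
            d_hi = sum(d for p, d in shift_events if p < hi)
            new_intervals[nm] = (lo + d_lo, hi + d_hi)
        rec = HaplotypeRecord(
            sample_id=child_id, haplotype_index=h, technology="synthetic",
            sequence=seq, source_path="synthetic",
        )
        child_records.append(rec)
        transmitted[rec.label] = (parent_name, parent_rec.label)
        for nm, iv in new_intervals.items():
            child_intervals[(rec.label, nm)] = iv
    return child_records, transmitted, edit_scripts, child_intervals


def _homopolymer_preferring_positions(seq, lo, hi, count, rng, min_gap: int = 8):
    window = seq[lo:hi]
    weights = np.ones(len(window))
    i = 0
    while i < len(window):
        j = i
        while j < len(window) and window[j] == window[i]:
            j += 1
        if j - i >= 3:
            weights[i:j] *= 10.0
            if window[i] == "C" and j < len(window) and window[j] == "A":
                weights[i:j] *= 2.0
        i = j
    chosen: list[int] = []
    for _ in range(count):
        w = weights.copy()
        for c in chosen:
            w[max(0, c - min_gap) : c + min_gap + 1] = 0
        if w.sum() == 0:
            raise SyntheticSpecError("cannot place de novo indels with spacing")
        p = int(rng.choice(len(window), p=w / w.sum()))
        chosen.append(p)
    return [lo + c for c in chosen]


def _generate_trio_family(spec, rng, flanks, seg_lengths, snp_df, template_intervals,
                          trio_spec, t_idx) -> TrioTruth:
    mid, fid, cid = f"T{t_idx}M", f"T{t_idx}F", f"T{t_idx}C"
    # longer arrays are the unstable ones (replication slippage scales with
    # array length); require enough copies that the planted events stay
    # individually resolvable
    min_copies = {
        nm: max(8.0, 4.0 * count)
        for nm, count in trio_spec.de_novo_indels.items()
    }
    mother, m_ivs, m_units = _sample_parent(
        spec, rng, flanks, seg_lengths, snp_df, template_intervals, mid, min_copies
    )
    father, f_ivs, f_units = _sample_parent(
        spec, rng, flanks, seg_lengths, snp_df, template_intervals, fid, min_copies
    )
    locus_intervals = {**m_ivs, **f_ivs}
    child, transmitted, edits, child_ivs = generate_trio(
        mother, father, trio_spec.de_novo_indels, locus_intervals, rng=rng,
        child_id=cid,
    )
    return TrioTruth(
        name=trio_spec.name,
        mother=mother,
        father=father,
        child=child,
        transmitted=transmitted,
        de_novo=edits,
        child_intervals=child_ivs,
    )


# ---------------------------------------------------------------------------
# Technology noise
# ---------------------------------------------------------------------------

def add_technology_noise(
    record: HaplotypeRecord,
    technology: str,
    rates: NoiseParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeRecord, pd.DataFrame]:
    """A noisy copy of the haplotype with a recorded edit script.

    Indel counts are Poisson in the sequence length; positions prefer
    homopolymer runs >= 3 (10x weight, doubled again for C-runs followed
    by A), matching the error profile of CLR reads; CCS uses ~10x lower
    rates.  An insertion duplicates the base at its position.
    """
    if technology not in ("CLR", "CCS"):
        raise SyntheticSpecError("technology must be CLR or CCS")
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = rates or DEFAULT_NOISE[technology]
    seq = record.sequence
    n = len(seq)
    ops = []

    n_sub = rng.poisson(rates.substitution_rate * n)
    sub_pos = sorted(rng.choice(n, size=min(n_sub, n), replace=False)) if n_sub else []
    seq_list = list(seq)
    for p in sub_pos:
        old = seq_list[p]
        seq_list[p] = rng.choice([b for b in "ACGT" if b != old])
        ops.append({"op": "sub", "position": int(p)})
    seq = "".join(seq_list)

    n_indel = rng.poisson(rates.indel_rate * n)
    if n_indel:
        weights = np.ones(n)
        i = 0
        while i < n:
            j = i
            while j < n and seq[j] == seq[i]:
                j += 1
            if j - i >= 3:
                weights[i:j] *= rates.homopolymer_weight
                if seq[i] == "C" and j < n and seq[j] == "A":
                    weights[i:j] *= rates.c_run_a_weight
            i = j
        weights /= weights.sum()
        positions = rng.choice(n, size=min(n_indel, n), replace=False, p=weights)
        kept = []
        for p in sorted(positions):
            if kept and p - kept[-1] < 2:
                continue
            kept.append(int(p))
        for p in sorted(kept, reverse=True):
            if rng.random() < 0.5:
                seq = seq[:p] + seq[p] + seq[p:]
                ops.append({"op": "ins", "position": p})
            else:
                seq = seq[:p] + seq[p + 1 :]
                ops.append({"op": "del", "position": p})

    noisy = replace(record, technology=technology, sequence=seq)
    script = pd.DataFrame(ops, columns=["op", "position"])
    return noisy, script


# ---------------------------------------------------------------------------
# Default cohort (study-shaped)
# ---------------------------------------------------------------------------

# Published VNTR consensus sequences (genomic orientation) used as the
# default variable-locus units.
VNTR_CONSENSUS = {
    "vntr_a": "TGGCCACCACCGTTCAAGGGAGCCATTTCCTCACCCAGGTGCCCAGGGAAGCATCCAGGAGGGGAC",  # 66 bp
    "vntr_b": "TGTGGGCAGCGGTGGGTACCCAGCACCGTGGGCAGCAC",  # 38 bp
    "hyvntr": "CCCCCACCCAGCGCCTTCCCCGCCCTGCCCCTCCAGGC",  # 38 bp, 82% GC
    "vntr_c": "TGTGTCTGAGTGTGTATGTTGCATGGTATG",  # 30 bp
    "vntr_d": "AGGAGCGTGTACTACCCCAGGACGCATGCAGGGCCCCCAC",  # 40 bp
}

HYVNTR_ALLELES = [
    3.4, 5.4, 8.4, 12.4, 17.4, 23.4, 30.4, 38.4, 47.4, 57.4, 75.4, 95.4, 115.4, 133.4,
]


def default_cohort_spec(
    n_individuals: int = 32,
    gene_length: int = 55000,
    n_invariant: int = 25,
    structure_seed: int = 20230208,
) -> CohortSpec:
    """The study-shaped default: 32 individuals, ~30 loci, 5 VNTRs, 3 trios.

    The hypervariable locus uses the GC-rich 38-mer unit with 14 alleles
    spanning 3.4-133.4 copies and a 30/32 heterozygosity target; the other
    four VNTRs use the published unit sequences with small allele sets.
    Invariant loci are planted pure (no unit substitutions) so their
    alleles are invariant by construction; unit-level heterogeneity is
    planted at the variable loci, where purity is actually analyzed.
    """
    srng = np.random.default_rng(structure_seed)

    n_hap = 2 * n_individuals
    alleles = list(HYVNTR_ALLELES)
    if n_hap < 2 * len(alleles):  # small cohorts carry a thinned allele set
        k = max(2, n_hap // 4)
        idx = np.linspace(0, len(alleles) - 1, k).round().astype(int)
        alleles = [alleles[int(i)] for i in sorted(set(idx))]
    hy_weights = np.r_[2.0, np.linspace(1.6, 0.6, len(alleles) - 1)]
    hy_freqs = hy_weights / hy_weights.sum()
    het_target = int(round(30 / 32 * n_individuals))
    loci = [
        LocusSpec("vntr_a", VNTR_CONSENSUS["vntr_a"], {7.0: 0.7, 8.0: 0.3},
                  per_unit_sub_rate=0.01),
        LocusSpec("vntr_b", VNTR_CONSENSUS["vntr_b"],
                  {21.0: 0.2, 26.0: 0.25, 28.0: 0.35, 32.4: 0.2},
                  per_unit_sub_rate=0.015),
        LocusSpec("hyvntr", VNTR_CONSENSUS["hyvntr"],
                  dict(zip(alleles, hy_freqs)),
                  per_unit_sub_rate=0.015, het_target=het_target),
        LocusSpec("vntr_c", VNTR_CONSENSUS["vntr_c"], {5.0: 0.35, 6.0: 0.65},
                  per_unit_sub_rate=0.01),
        LocusSpec("vntr_d", VNTR_CONSENSUS["vntr_d"], {9.0: 0.2, 10.0: 0.6, 11.0: 0.2},
                  per_unit_sub_rate=0.01),
    ]
    # invariant loci are planted pure: their measured alleles must be
    # invariant by construction, and unit heterogeneity is the object of
    # study only at the copy-number-variable loci
    for i in range(n_invariant):
        u = int(srng.integers(20, 70)) if i % 3 == 0 else int(srng.integers(7, 16))
        consensus = _rand_seq(srng, u, gc=0.45 + 0.1 * srng.random())
        cn = float(srng.integers(2, 12)) + (0.4 if srng.random() < 0.3 else 0.0)
        loci.append(LocusSpec(f"inv{i + 1:02d}", consensus, {cn: 1.0}))
    order = srng.permutation(len(loci))
    loci = [loci[int(i)] for i in order]

    snps = []
    freqs = [0.06, 0.09, 0.12, 0.16, 0.20, 0.25, 0.31, 0.38, 0.44]
    for i in range(20):
        snps.append(SnpSpec(f"snp{i + 1:02d}", minor_freq=freqs[i % len(freqs)]))
    snps += [
        # low LD against the heavy-tailed hypervariable locus (realistic for
        # such loci); the higher targets need a near-binary allele spectrum,
        # and r^2 = 0.9 additionally needs the SNP frequency to sit on the
        # locus's realized minor-allele frequency
        SnpSpec("ld_low", minor_freq=0.35, target_r2=0.1, ld_locus="hyvntr"),
        SnpSpec("ld_mid", minor_freq=0.40, target_r2=0.5, ld_locus="vntr_c"),
        SnpSpec("ld_high", minor_freq=max(1, round(0.35 * n_hap)) / n_hap,
                target_r2=0.9, ld_locus="vntr_c"),
        SnpSpec("rare1", minor_freq=0.03),
        SnpSpec("rare2", minor_freq=0.04),
        SnpSpec("in_vntr1", minor_freq=0.2, inside_locus="hyvntr"),
        SnpSpec("in_vntr2", minor_freq=0.2, inside_locus="vntr_c"),
    ]

    trios = [
        TrioSpec("trio1", {"hyvntr": 1}),
        TrioSpec("trio2", {"hyvntr": 3}),
        TrioSpec("trio3", {"hyvntr": 5}),
    ]
    # ancestry apportioned to the requested cohort size (largest remainder)
    base = DEFAULT_ANCESTRY_COUNTS
    total = sum(base.values())
    raw = {g: k * n_individuals / total for g, k in base.items()}
    counts = {g: int(v) for g, v in raw.items()}
    leftovers = sorted(raw, key=lambda g: raw[g] - counts[g], reverse=True)
    i = 0
    while sum(counts.values()) < n_individuals:
        counts[leftovers[i % len(leftovers)]] += 1
        i += 1
    counts = {g: k for g, k in counts.items() if k > 0}
    return CohortSpec(
        n_individuals=n_individuals,
        gene_length=gene_length,
        loci=loci,
        snps=snps,
        trios=trios,
        ancestry_counts=counts,
    )
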