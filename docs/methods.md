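# Methods

This note documents the models, algorithms and design choices behind
`tandemscape`: what each stage computes, which knobs matter, what the
synthetic cohort does and does not emulate, and where the genuinely open
decisions were made.

## Coordinates, records, conventions

All coordinates are 0-based half-open internally; table writers that mimic
published coordinate style convert to 1-based inclusive at the edge. The
DNA alphabet is {A, C, G, T, N}. N is accepted in input sequences, breaks
G4 runs with score 0, and excludes a repeat unit from unique-sequence
catalogs (such units are drawn grey in Mola charts). Values printed to a
fixed number of decimals round half away from zero, the convention of the
published tables this package's outputs imitate (31/38 G+C = 81.58% reports
as 82%; 129/38 copies reports as 3.4).

## Pairwise alignment

Two engines sit behind one `Alignment` type:

- `global_align` — optimal global alignment with affine gaps at the EMBOSS
  needle defaults: match +5, mismatch −4, a gap of length k costs
  10 + 0.5·k, end gaps free. Delegated to Biopython's `PairwiseAligner`
  (tie-breaking is the engine's, deterministic). A configurable cell cap
  (default 10⁸) rejects accidental quadratic blowups.
- `edit_align` — global edit-distance alignment via edlib for long,
  near-identical pairs (whole-gene technology comparison, trio whole-gene
  similarity, reference projection), with the affine-model score recomputed
  from the returned path so both engines report on one scale.

One consequence of free end gaps worth knowing: for two single mismatching
bases the staggered alignment (`A-`/`-G`, two free terminal gaps, score 0)
beats the mismatch column (−4). The brute-force oracle in the test suite
agrees; `end_gaps_free=False` recovers the classical −4.

An *indel event* is a maximal run of gap columns in one sequence: a k-base
gap is one event. *Similarity percent* counts matching columns over all
alignment columns, gap columns included in the denominator.

`project_to_reference` maps a haplotype onto reference coordinates with
"keeplength" semantics: deletions emit `-`, insertions relative to the
reference are discarded, substitutions are carried through; the projection
always has exactly the reference length. This per-haplotype pairwise
projection defines the same variant columns as a keeplength multiple
alignment would, without an external aligner.

## Repeat detection

Detection proceeds in four steps.

1. **Vote scan.** For each candidate period p in [7, 200], position i votes
   for p when the k-mer at i recurs exactly p bases downstream
   (k = min(8, p)). Runs of votes (gaps ≤ p + k bridge substitution-induced
   holes) yield raw windows; windows shorter than 1.5 p are discarded
   (a final ≥ 1.9-copy check comes later).
2. **Consensus and unit-stepping.** A provisional consensus is the
   per-column majority over period-length frames of the raw window. The
   window is extended outward one unit at a time while the next window
   keeps ≥ 0.8 edit-distance identity to the consensus — edit distance, so
   a single interior indel nudges rather than breaks the extension. The
   consensus is then re-estimated from the *decomposed* full units
   (indel-aware; frame-chopping would smear the consensus as the register
   drifts past an indel) and the stepping repeated once.
3. **Boundary refinement.** The stepped span is decomposed against the
   cyclic consensus (step 4's wraparound DP, so interior indels shift the
   register without corrupting it) and every character scores +1 when it
   matches the consensus at its decomposed phase and −3 otherwise, with
   motif positions the DP skipped charged to the following character —
   otherwise the DP could delete its way into flank junk and make it look
   repeat-consistent. The kept block maximizes the score sum (so ragged
   flank absorbed by the stepping is shed while isolated interior
   substitutions are retained), then each edge extends outward scoring +1
   per consensus-continuing base and −3 per mismatch, boundary at the
   strict running maximum (x-drop 14 bounds how far the scan looks, not
   where the boundary lands). The register for each extension is
   calibrated on the terminal window itself rather than taken from the DP
   phases, because near a span edge the DP may realize a substitution as
   deletion-plus-shift and poison the continuation register. Same-period
   overlapping fragments with near-identical canonical consensus (one
   array split by an interior indel) are merged and re-decomposed over
   their union.
4. **Decomposition.** The refined span is decomposed against the cyclic
   consensus by wraparound dynamic programming (numba kernels): state
   (sequence position, motif phase), transitions for
   match/mismatch/insertion/deletion, deletions relax each row in two
   passes to handle the phase wraparound. The path starts at phase 0 and
   may end mid-motif (trailing partial unit); unit boundaries sit at phase
   wraps, and the unit concatenation reproduces the span byte-for-byte.

Copy number = span length / consensus length, rounded half-up to one
decimal. Divergence = mean per-unit edit distance to the consensus over
full units, normalized by consensus length.

**Redundancy removal.** Same-period refinements of one array keep the
longest span; when one period is an (approximate) multiple of the other —
an interior indel shifts a k-unit reading by a base or two, so 115 counts
as a multiple of 38 — the shorter period wins provided its span covers the
longer-period candidate's span and its divergence is not worse by > 0.02
(parsimony, the TRF convention); and a short array essentially contained
(≥ 90% of its span) in a ≥ 1.5×-longer credible array is dropped as a
sub-repeat of the longer unit's internal structure — without this rule,
internal near-periodicities of long GC-rich units shed small pure
fragments that would outrank the true annotation at overlap resolution.

**Significance.** Each candidate's statistic is the number of positions in
its span matching their period-p successor; the null redistributes the
span's own base composition (mononucleotide shuffle, default 200 draws), so
GC-rich arrays are judged against an equally GC-rich background. The
p-value is the fraction of shuffles reaching the observed statistic.
Candidates with p > 0.05 or divergence > 0.05 are discarded; among
overlapping survivors the lowest (p-value, divergence) is kept, with unit
length and position as deterministic tie-breakers.

## Harmonization

Annotations link across haplotypes when canonical-rotation consensus
identity ≥ 0.8 *and* both 50 bp flank identities ≥ 0.9 (identity
= 1 − edit distance / max length). Flanks are the load-bearing key: a
hypervariable locus can present divergent consensuses, but its genomic
neighborhood is conserved. Clustering is single-linkage via union-find, so
the catalog is invariant to haplotype input order; a cluster containing two
annotations from one haplotype raises (it signals over-merging). Clusters
present in strictly more than half of the haplotypes get IDs numbered
5′→3′ by median position. A consensus that is two near-identical halves
(best near-halving split with ≥ 0.8 half-vs-half identity) is reduced to
its first half, recursively, and members re-decomposed — the doubled-motif
case where a 76/78 bp reading is really two ~38 bp units. A locus is a
VNTR when its allele table holds ≥ 2 distinct 1-decimal copy numbers.

The 0.8/0.9 thresholds are this package's declared choices; the manual
criterion they automate was never stated numerically.

## Mola charts

Multicolor mode assigns each distinct unit string (exact equality, partial
trailing units included as their literal string) a color from a seeded
palette keyed by frequency rank; rows sort by copy number descending.
3-color mode scores every unit against the locus consensus with the affine
aligner and maps scores onto red (minimum) / white (median) / blue
(maximum); if all scores coincide the chart is uniformly white. Rows sort
by similarity of the leading units, or by copy number for complex loci.
Charts are emitted as deterministic SVG plus a TSV cell table so analyses
assert on data rather than pixels; partial units are hatched.

Homopolymer sensitivity: collapsing every single-base run ≥ 4 to one base
and re-counting unique units tests whether apparent unit diversity is
homopolymer-length sequencing error. Collapse is idempotent and can only
reduce the unique count.

## Population genetics

SNPs are the substitution-only variant columns of the projected
haplotypes: no gap in any haplotype, exactly two observed alleles, outside
every VNTR interval, minor-allele frequency strictly above 5% of
haplotypes. LD is the squared Pearson correlation over haplotype vectors —
minor-allele indicators for SNPs, real copy numbers for VNTRs; monomorphic
vectors give an undefined r² stored as missing, never 0. Heterozygosity is
the fraction of individuals whose two haplotypes differ at 1-decimal
copy-number resolution. The ancestry ANOVA is one-way fixed-effects on
haplotype copy numbers with groups under 3 haplotypes dropped
(df = (k−1, N−k), p from the F distribution, via scipy).

Trio analysis assigns each child haplotype to the parental haplotype with
maximal whole-gene similarity under the one-maternal + one-paternal
constraint (both children preferring the same parent raises a Mendelian
inconsistency), then aligns the annotated VNTR spans child-vs-parent with
the affine aligner to count mismatches and indel events and to compare
copy numbers.

## G4 and PWM scanning

Each base in a run of k consecutive G scores +min(k, 4); C runs score the
negative; A/T/N score 0 and break runs. Sliding 25-base windows with
|mean| ≥ 1.6 are hits; overlapping or adjacent same-sign windows merge into
maximal regions whose mean is recomputed over the merged span (the merged
score rule is this package's choice — the underlying windowed-score method
leaves it open). Profiles tile the gene into 500 bp bins (configurable; a
"section" width is not standardized) and report coverage percent and hit
count per bin. Positive regions lie on the scanned strand, negative on its
complement.

PWM scanning is log-odds against a uniform 0.25 background with +0.01
pseudocount after column normalization, both strands, every offset;
relative score rescales between the matrix's minimum and maximum achievable
scores, and hits at ≥ 0.8 (configurable) are reported with overlaps
allowed. JASPAR count matrices are read via Biopython. Binding-site counts
from external motif-track versions depend on those external thresholds and
are out of scope.

## Synthetic cohorts: what is emulated, what is not

The default cohort mirrors the study shape: 32 individuals / 64
haplotypes, a ~55 kb gene bounded by the two UTR anchors, 30 loci of which
5 are copy-number variable, ancestry groups of 9/5/6/6/1/5 individuals,
and three trios. The five variable loci use the published unit sequences
(66/38/38/30/40 bp); the hypervariable locus carries 14 alleles spanning
3.4–133.4 copies of the 82%-GC 38-mer with a 30-of-32 heterozygosity
target, realized by exact allele apportionment (largest remainder) and
explicit genotype pairing. Unit substitution rates at the variable loci
are 0.01–0.015 per base — comfortably under the 0.05 divergence retention
filter, because the emulated repeats are the *retained* ones; invariant
loci are planted pure so that their alleles are invariant by construction.
SNPs are planted in inter-locus flanks (plus deliberate below-MAF and
inside-VNTR controls); LD to a named VNTR is planted by a linear
conditional-probability model p(minor | copy) that solves the covariance
constraint exactly in expectation, with the sign of r chosen for
feasibility and an error (reporting the feasible bound) when the target is
unreachable — high r² against a heavy-tailed copy-number spectrum is
mathematically infeasible for a binary SNP, so the 0.5/0.9 targets attach
to a two-allele locus.

Ground-truth identifiability drives three deliberate conventions:

- **Guard bases.** Two bases on each side of every planted array neither
  continue the cyclic consensus nor repeat their inward neighbor (a guard
  extending a homopolymer run across the boundary would readmit a
  repeat-consistent reading of the flank via an insertion). This makes the
  planted interval the maximal repeat-consistent span; without it, flank
  bases that happen to continue the motif belong to the repeat under any
  definition and the "true" copy number is ambiguous.
- **Clean array edges.** The outermost 4 bases of an array are kept
  consensus-exact (substitutions are planted elsewhere in the terminal
  units): an edge substitution is indistinguishable from a shorter array
  with mismatching flank.
- **Identifiable de novo events.** Trio de novo indels are single-base,
  homopolymer-preferring, placed ≥ 8 bp apart in the array interior
  (excluding terminal units), and the transmitting parents carry
  ≥ max(8, 4·count) copies at the instability locus. Closer ins/del pairs
  align as substitutions, edge indels move the boundary itself, and an
  indel in a ~3-copy array makes even the period ambiguous — in each case
  the planted count would stop being the uniquely correct answer.

Technology noise plants Poisson indels preferring homopolymer runs ≥ 3
(10× weight, doubled for C-runs followed by A) at 3×10⁻⁴ per base for
CLR-like copies and 10× lower for CCS-like ones, with substitutions at
2×10⁻⁵ / 2×10⁻⁶ — rates chosen so a ~55 kb gene shows on the order of 17
CLR indels and ~99.96% cross-technology similarity.

Not emulated: read-level errors and assembly (haplotypes are sequences,
not reads), recombination within the gene, population structure beyond
group labels, reference bias, and homopolymer-length *polymorphism*
(as opposed to noise). Passing tests therefore demonstrate correctness of
the measurement pipeline under a faithful, boundary-identifiable model of
the data, not robustness to assembly artifacts.

## Numerical and degenerate-case choices

- Majority-vote consensus ties break by fixed base order (A<C<G<T);
  canonical rotation is the lexicographically smallest, used only for
  comparison — reported consensuses keep the phase found at the array
  start.
- The detection DP uses match +5 / mismatch −4 / gap −7 (linear), the
  boundary scan +1/−3 with x-drop 8; all are module constants.
- Shuffle p-values are plain fractions (a perfect array reports 0);
  n_shuffles < 20 is rejected.
- An all-identical copy-number vector makes F undefined (error), a
  monomorphic variant makes r² missing, an all-equal score distribution
  makes a 3-color chart white; none of these crash a pipeline run.
- Sequences shorter than the G4 window warn and return no hits.
- `genotype_table(on_missing="drop")` skips an individual at a locus where
  one haplotype evaded detection; the default is a hard error.

## Problem sizes

The default cohort analysis (64 haplotypes × ~55 kb, 30 loci) annotates in
roughly 10–15 s and the full pipeline in under a minute on one CPU; the
acceptance script uses exactly these sizes, 200 replicates for LD recovery,
and 8 haplotype pairs for the technology comparison.

## Known limitations

- Boundary placement at a planted array is exact only because the truth is
  constructed to be identifiable; on real data, arrays whose flanks continue
  the motif have genuinely ambiguous copy numbers at the ±1-base level.
- The shuffle test conditions on base composition only; it will pass
  dispersed repeats whose structure survives shuffling no better than
  chance, and 2-copy pure micro-arrays in random sequence are genuinely
  significant under it (the cross-haplotype presence rule is what removes
  them from the catalog).
- Harmonization assumes conserved flanks; a structural rearrangement
  adjacent to a locus would orphan its annotations.
- The LD planting model is linear in copy number; correlation targets
  beyond the linear-feasible bound require a different joint distribution.
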