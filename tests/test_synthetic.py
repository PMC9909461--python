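import numpy as np
import pandas as pd
import pytest

from tandemscape.extraction import compare_technologies
from tandemscape.synthetic import (
    CohortSpec,
    LocusSpec,
    SnpSpec,
    SyntheticSpecError,
    TrioSpec,
    _allele_counts,
    _pair_genotypes,
    add_technology_noise,
    default_cohort_spec,
    generate_cohort,
    generate_trio,
)


class TestSpecs:
    def test_locus_spec_validation(self):
        with pytest.raises(SyntheticSpecError):
            LocusSpec("x", "ACGTACG", {5.0: 0.5})  # freqs don't sum to 1
        with pytest.raises(SyntheticSpecError):
            LocusSpec("x", "ACGTACG", {1.0: 1.0})  # copies < 2
        with pytest.raises(ValueError):
            LocusSpec("x", "ACG", {5.0: 1.0})  # unit < 7

    def test_snp_spec_validation(self):
        with pytest.raises(SyntheticSpecError):
            SnpSpec("s", minor_freq=0.6)
        with pytest.raises(SyntheticSpecError):
            SnpSpec("s", minor_freq=0.1, target_r2=0.5)  # needs ld_locus

    def test_default_spec_shape(self):
        spec = default_cohort_spec()
        assert spec.n_individuals == 32
        assert len(spec.loci) == 30
        variable = [l for l in spec.loci if l.is_variable]
        assert len(variable) == 5
        hy = next(l for l in spec.loci if l.name == "hyvntr")
        assert min(hy.allele_distribution) == 3.4
        assert max(hy.allele_distribution) == 133.4
        assert len(hy.consensus) == 38


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_cohort):
        spec = default_cohort_spec(n_individuals=6, n_invariant=6)
        again = generate_cohort(spec, seed=5)
        assert [r.sequence for r in small_cohort.records] == [
            r.sequence for r in again.records
        ]
        assert small_cohort.template == again.template

    def test_different_seed_differs(self):
        spec = default_cohort_spec(n_individuals=4, n_invariant=4)
        a = generate_cohort(spec, seed=1)
        b = generate_cohort(spec, seed=2)
        assert [r.sequence for r in a.records] != [r.sequence for r in b.records]


class TestTruthBookkeeping:
    def test_units_match_intervals(self, small_cohort):
        for rec in small_cohort.records:
            for name, truth in small_cohort.loci.items():
                lo, hi = truth.intervals[rec.label]
                assert "".join(truth.units[rec.label]) == rec.sequence[lo:hi]

    def test_boundary_guards(self, small_cohort):
        """The planted interval is the maximal repeat-consistent span."""
        for rec in small_cohort.records[:4]:
            for name, truth in small_cohort.loci.items():
                lo, hi = truth.intervals[rec.label]
                cons = truth.consensus
                u = len(cons)
                tail = (hi - lo) % u if (hi - lo) % u else 0
                assert rec.sequence[lo - 1] != cons[u - 1]
                assert rec.sequence[hi] != cons[(hi - lo) % u]

    def test_monomorphic_locus(self):
        spec = CohortSpec(
            n_individuals=4,
            gene_length=8000,
            loci=[LocusSpec("only", "ACGGTTCAGTACG", {5.0: 1.0})],
            ancestry_counts={},
        )
        cohort = generate_cohort(spec, seed=3)
        truth = cohort.loci["only"]
        assert set(truth.copy_numbers.values()) == {5.0}
        units = truth.units[cohort.records[0].label]
        assert all(u == "ACGGTTCAGTACG" for u in units)

    def test_allele_counts_apportionment(self):
        counts = _allele_counts({3.4: 0.06, 5.0: 0.5, 7.0: 0.44}, 64)
        assert sum(counts.values()) == 64
        assert all(v >= 1 for v in counts.values())
        assert counts[5.0] >= counts[7.0] >= counts[3.4]

    def test_het_target_exact(self):
        rng = np.random.default_rng(0)
        counts = {3.4: 10, 5.4: 30, 8.4: 24}
        pairs = _pair_genotypes(rng, counts, 32, het_target=30)
        het = sum(a != b for a, b in pairs)
        assert het == 30
        realized = {}
        for a, b in pairs:
            realized[a] = realized.get(a, 0) + 1
            realized[b] = realized.get(b, 0) + 1
        assert realized == counts


class TestLDPlanting:
    def test_infeasible_target_reports_bound(self):
        spec = CohortSpec(
            n_individuals=8,
            gene_length=9000,
            loci=[LocusSpec("v", "ACGGTTCAGTACG", {2.0: 0.9, 20.0: 0.1})],
            snps=[SnpSpec("s", minor_freq=0.1, target_r2=0.95, ld_locus="v")],
            ancestry_counts={},
        )
        with pytest.raises(SyntheticSpecError, match="feasible"):
            generate_cohort(spec, seed=1)

    def test_mean_recovery_over_replicates(self):
        """Planted r^2 targets are recovered in the mean over replicates."""
        from tandemscape.synthetic import _ld_carrier_probs

        rng = np.random.default_rng(1)
        cn = np.array([5.0] * 22 + [6.0] * 42)
        for target in (0.1, 0.5, 0.9):
            est = []
            for _ in range(100):
                probs = _ld_carrier_probs(cn, 0.35, target, "s")
                x = (rng.random(64) < probs).astype(float)
                if x.std() == 0:
                    continue
                est.append(np.corrcoef(x, cn)[0, 1] ** 2)
            assert np.mean(est) == pytest.approx(target, abs=0.06)


class TestTrios:
    def test_zero_de_novo_verbatim(self, small_cohort):
        trio = small_cohort.trios[0]
        rng = np.random.default_rng(3)
        intervals = {}
        for rec in trio.mother + trio.father:
            intervals[rec.label] = {
                nm: (0, 10) for nm in small_cohort.loci
            }
        # actual intervals irrelevant when nothing is edited
        child, transmitted, edits, _ = generate_trio(
            trio.mother, trio.father, {}, intervals, rng=rng, child_id="Z"
        )
        assert not edits
        parent_seqs = {r.label: r.sequence for r in trio.mother + trio.father}
        for rec in child:
            _, src = transmitted[rec.label]
            assert rec.sequence == parent_seqs[src]

    def test_de_novo_edit_script(self, small_cohort):
        trio = small_cohort.trios[1]  # planted 3 indels per child haplotype
        for (child_lab, locus), script in trio.de_novo.items():
            assert len(script) == 3
            assert set(script.op) <= {"ins", "del"}
        # edits lie inside the child's locus interval
        for rec in trio.child:
            lo, hi = trio.child_intervals[(rec.label, "hyvntr")]
            for (child_lab, locus), script in trio.de_novo.items():
                if child_lab != rec.label:
                    continue
                assert ((script.position >= lo - 5) & (script.position <= hi + 5)).all()

    def test_transmitted_labels(self, small_cohort):
        for trio in small_cohort.trios:
            sources = [src for (_, src) in trio.transmitted.values()]
            assert any(s.startswith(trio.mother[0].sample_id) for s in sources)
            assert any(s.startswith(trio.father[0].sample_id) for s in sources)


class TestTechnologyNoise:
    def test_zero_rates_identical(self, small_cohort):
        from tandemscape.synthetic import NoiseParams

        rec = small_cohort.records[0]
        noisy, script = add_technology_noise(
            rec, "CLR", NoiseParams(0.0, 0.0), seed=1
        )
        assert noisy.sequence == rec.sequence
        assert script.empty
        assert noisy.technology == "CLR"

    def test_clr_ccs_rate_ratio(self, small_cohort):
        rec = small_cohort.records[0]
        counts = {"CLR": [], "CCS": []}
        for tech in counts:
            for rep in range(40):
                _, script = add_technology_noise(rec, tech, seed=1000 + rep)
                counts[tech].append((script.op != "sub").sum())
        ratio = np.mean(counts["CLR"]) / max(np.mean(counts["CCS"]), 1e-9)
        assert 5 <= ratio <= 20  # configured 10x, Poisson noise around it

    def test_edit_script_recovered_by_alignment(self, small_cohort):
        rec = small_cohort.records[1]
        noisy, script = add_technology_noise(rec, "CLR", seed=7)
        tc = compare_technologies(rec.sequence, noisy.sequence)
        assert tc.mismatches == (script.op == "sub").sum()
        assert tc.indels == (script.op != "sub").sum()

    def test_homopolymer_preference(self, small_cohort):
        rec = small_cohort.records[2]
        in_run = total = 0
        for rep in range(30):
            _, script = add_technology_noise(rec, "CLR", seed=rep)
            for _, row in script[script.op != "sub"].iterrows():
                p = int(row.position)
                window = rec.sequence[max(0, p - 3) : p + 4]
                total += 1
                in_run += any(b * 3 in window for b in "ACGT")
        # ~2% of positions sit in runs >= 3; with 10x weighting the edited
        # positions should be heavily enriched
        assert total > 0
        assert in_run / total > 0.3


class TestCohortStatistics:
    def test_heterozygosity_planted(self, default_cohort):
        g = default_cohort.genotypes
        sub = g[g.locus == "hyvntr"]
        assert float((sub.cn_h1 != sub.cn_h2).mean()) == pytest.approx(30 / 32)

    def test_ancestry_counts(self, default_cohort):
        counts = pd.Series(default_cohort.ancestry).value_counts()
        assert counts.sum() == 32
        assert counts["African"] == 9

    def test_snp_frequencies(self, default_cohort):
        snp = default_cohort.snp_table
        rare = snp[snp.name.str.startswith("rare")]
        for _, row in rare.iterrows():
            assert len(row.carriers) / 64 <= 0.05
        common = snp[snp.name.str.startswith("snp")]
        for _, row in common.iterrows():
            assert len(row.carriers) > 0
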