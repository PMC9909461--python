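import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tandemscape.popgen import (
    MendelianInconsistencyError,
    PopGenError,
    anova_copy_number,
    call_snps,
    heterozygosity,
    ld_matrix,
)
from tandemscape.seqio import GeneInterval


def _projections(ref, edits):
    """edits: {label: {pos: base}} applied to copies of ref."""
    out = {}
    for lab, muts in edits.items():
        s = list(ref)
        for pos, base in muts.items():
            s[pos] = base
        out[lab] = "".join(s)
    return out


class TestCallSnps:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ref = "".join(rng.choice(list("ACGT"), 500))

    def test_no_variation(self):
        projections = {f"s{i}_h1": self.ref for i in range(4)}
        assert len(call_snps(projections, self.ref)) == 0

    def test_maf_threshold_arithmetic(self):
        # 64 haplotypes: minor count 4 (6.25%) retained, 3 (4.7%) dropped
        labels = [f"s{i:02d}_h{h}" for i in range(32) for h in (1, 2)]
        alt1 = "A" if self.ref[100] != "A" else "C"
        alt2 = "A" if self.ref[200] != "A" else "C"
        edits = {lab: {} for lab in labels}
        for lab in labels[:4]:
            edits[lab][100] = alt1
        for lab in labels[4:7]:
            edits[lab][200] = alt2
        vs = call_snps(_projections(self.ref, edits), self.ref)
        assert vs.positions.tolist() == [100]
        assert vs.maf[0] == pytest.approx(4 / 64)

    def test_excluded_regions(self):
        labels = [f"s{i}_h1" for i in range(10)]
        alt = "A" if self.ref[50] != "A" else "C"
        edits = {lab: ({50: alt} if i < 5 else {}) for i, lab in enumerate(labels)}
        vs = call_snps(_projections(self.ref, edits), self.ref,
                       excluded_regions=[GeneInterval("g", 40, 60)])
        assert len(vs) == 0

    def test_gap_columns_excluded(self):
        labels = [f"s{i}_h1" for i in range(10)]
        edits = {lab: {} for lab in labels}
        projections = _projections(self.ref, edits)
        alt = "A" if self.ref[10] != "A" else "C"
        projections["s0_h1"] = (
            projections["s0_h1"][:10] + alt + projections["s0_h1"][11:]
        )
        for lab in list(projections)[:6]:
            projections[lab] = projections[lab][:10] + alt + projections[lab][11:]
        projections["s9_h1"] = projections["s9_h1"][:10] + "-" + projections["s9_h1"][11:]
        vs = call_snps(projections, self.ref)
        assert 10 not in vs.positions

    def test_order_invariance(self):
        labels = [f"s{i}_h1" for i in range(8)]
        alt = "A" if self.ref[33] != "A" else "C"
        edits = {lab: ({33: alt} if i % 2 else {}) for i, lab in enumerate(labels)}
        p = _projections(self.ref, edits)
        v1 = call_snps(p, self.ref)
        v2 = call_snps(dict(reversed(list(p.items()))), self.ref)
        assert v1.positions.tolist() == v2.positions.tolist()
        assert (v1.genotypes == v2.genotypes).all()

    def test_length_mismatch(self):
        with pytest.raises(PopGenError):
            call_snps({"a_h1": "ACGT"}, "ACGTA")


class TestLDMatrix:
    def _variants(self, genos, labels=None):
        from tandemscape.popgen import VariantSet

        genos = np.asarray(genos, dtype=np.int8)
        n_hap, n_pos = genos.shape
        labels = labels or [f"s{i}_h1" for i in range(n_hap)]
        return VariantSet(
            positions=np.arange(n_pos),
            ref_alleles=["A"] * n_pos,
            alt_alleles=["C"] * n_pos,
            haplotype_labels=labels,
            genotypes=genos,
            maf=genos.mean(axis=0),
        )

    def test_identical_vectors(self):
        v = self._variants([[1, 1], [0, 0], [1, 1], [0, 0]])
        ld = ld_matrix(v)
        assert ld.r2[0, 1] == pytest.approx(1.0)

    def test_complement_vectors(self):
        v = self._variants([[1, 0], [0, 1], [1, 0], [0, 1]])
        ld = ld_matrix(v)
        assert ld.r2[0, 1] == pytest.approx(1.0)  # r = -1 squared

    def test_exact_planted_correlation(self):
        """A 64-haplotype 0/1 vector built to correlate r = 0.7 with copy
        number yields r^2 = 0.49."""
        n = 64
        cn = np.array([5.0] * 32 + [6.0] * 32)
        # brute-force adjustment: flip entries until sample r hits 0.7
        x = (cn == 6.0).astype(float)
        rng = np.random.default_rng(2)
        target = 0.7
        for _ in range(10000):
            r = np.corrcoef(x, cn)[0, 1]
            if abs(r - target) < 5e-3:
                break
            i = rng.integers(n)
            x2 = x.copy()
            x2[i] = 1 - x2[i]
            if abs(np.corrcoef(x2, cn)[0, 1] - target) < abs(r - target):
                x = x2
        labels = [f"s{i:02d}_h1" for i in range(n)]
        v = self._variants(x[:, None].astype(int), labels)
        cn_frame = pd.DataFrame({"TR": cn}, index=labels)
        ld = ld_matrix(v, cn_frame)
        assert ld.value("snp1", "TR") == pytest.approx(
            np.corrcoef(x, cn)[0, 1] ** 2, abs=1e-12
        )
        assert ld.value("snp1", "TR") == pytest.approx(0.49, abs=0.01)

    def test_constant_vector_missing_not_zero(self):
        v = self._variants([[1, 0], [1, 1], [1, 0], [1, 1]])
        ld = ld_matrix(v)
        assert np.isnan(ld.r2[0, 1])
        assert np.isnan(ld.r2[0, 0])

    def test_matrix_properties(self):
        rng = np.random.default_rng(5)
        v = self._variants(rng.integers(0, 2, size=(20, 6)))
        ld = ld_matrix(v)
        finite = np.isfinite(ld.r2)
        assert np.allclose(ld.r2[finite], ld.r2.T[finite])
        assert ((ld.r2[finite] >= 0) & (ld.r2[finite] <= 1.0 + 1e-12)).all()


class TestHeterozygosity:
    def _table(self, pairs, locus="TR21"):
        return pd.DataFrame(
            [
                {"individual": f"s{i}", "locus": locus,
                 "copy_number_h1": a, "copy_number_h2": b}
                for i, (a, b) in enumerate(pairs)
            ]
        )

    def test_all_homozygous(self):
        assert heterozygosity(self._table([(3.4, 3.4)] * 10), "TR21") == 0.0

    def test_30_of_32(self):
        pairs = [(3.4, 5.4)] * 30 + [(3.4, 3.4), (7.4, 7.4)]
        assert heterozygosity(self._table(pairs), "TR21") == pytest.approx(0.9375)

    def test_one_decimal_resolution(self):
        pairs = [(3.41, 3.44)]  # identical at 1-decimal resolution
        assert heterozygosity(self._table(pairs), "TR21") == 0.0

    def test_missing_locus(self):
        with pytest.raises(PopGenError):
            heterozygosity(self._table([(1, 2)]), "TR99")


class TestAnova:
    def test_identical_means(self):
        f, df1, df2, p = anova_copy_number([1, 2, 3, 1, 2, 3],
                                           ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0)

    def test_two_groups_hand_computed(self):
        # SSB = 13.5 (df 1), SSW = 4 (df 4) -> F = 13.5
        f, df1, df2, p = anova_copy_number([1, 2, 3, 4, 5, 6],
                                           ["a"] * 3 + ["b"] * 3)
        assert (df1, df2) == (1, 4)
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_small_groups_dropped(self):
        values = [1, 2, 3, 4, 5, 6, 99]
        labels = ["a"] * 3 + ["b"] * 3 + ["tiny"]
        f, df1, df2, _ = anova_copy_number(values, labels, min_group_n=3)
        assert (df1, df2) == (1, 4)
        assert f == pytest.approx(13.5)

    def test_label_permutation_within_groups(self):
        rng = np.random.default_rng(0)
        values = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        f0, *_ = anova_copy_number(values, labels)
        perm = np.r_[rng.permutation(3), 3 + rng.permutation(3)]
        f1, *_ = anova_copy_number(values[perm], labels)
        assert f0 == pytest.approx(f1)

    def test_degenerate_errors(self):
        with pytest.raises(PopGenError):
            anova_copy_number([2, 2, 2, 2, 2, 2], ["a"] * 3 + ["b"] * 3)
        with pytest.raises(PopGenError):
            anova_copy_number([1, 2], ["a", "b"], min_group_n=3)


class TestTrioTransmission:
    def _setup(self, small_cohort):
        from tandemscape.harmonize import assign_ids
        from tandemscape.repeats import annotate_gene

        trio = small_cohort.trios[0]
        seqs = {r.label: r.sequence for r in trio.mother + trio.father + trio.child}
        per_hap = {
            lab: annotate_gene(s, seed=2, contig=lab) for lab, s in sorted(seqs.items())
        }
        catalog = assign_ids(per_hap, seqs)
        return trio, catalog

    def test_verbatim_transmission(self, small_cohort):
        from tandemscape.popgen import trio_transmission

        trio, catalog = self._setup(small_cohort)
        res = trio_transmission(
            {r.label: r.sequence for r in trio.child},
            {r.label: r.sequence for r in trio.mother},
            {r.label: r.sequence for r in trio.father},
            catalog,
        )
        assert len(res) == 2
        parents = {r.parent for r in res}
        assert parents == {"mother", "father"}
        for r in res:
            assert trio.transmitted[r.child_hap] == (r.parent, r.parent_hap)
            assert r.similarity_percent > 99.9

    def test_swapped_parents_mirror(self, small_cohort):
        from tandemscape.popgen import trio_transmission

        trio, catalog = self._setup(small_cohort)
        child = {r.label: r.sequence for r in trio.child}
        mother = {r.label: r.sequence for r in trio.mother}
        father = {r.label: r.sequence for r in trio.father}
        res = trio_transmission(child, mother, father, catalog)
        swapped = trio_transmission(child, father, mother, catalog)
        by_hap = {r.child_hap: r for r in res}
        for r in swapped:
            assert r.parent_hap == by_hap[r.child_hap].parent_hap
            assert r.parent != by_hap[r.child_hap].parent  # labels swap

    def test_same_parent_twice_is_inconsistent(self, small_cohort):
        from tandemscape.popgen import trio_transmission

        trio, catalog = self._setup(small_cohort)
        child = {r.label: r.sequence for r in trio.child}
        mother = {r.label: r.sequence for r in trio.mother}
        rng = np.random.default_rng(8)
        fake_father = {
            f"FAKE_h{h}": "".join(rng.choice(list("ACGT"), 3000)) for h in (1, 2)
        }
        with pytest.raises((MendelianInconsistencyError, PopGenError)):
            trio_transmission(child, mother, fake_father, catalog)
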