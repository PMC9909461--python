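import numpy as np
import pytest

from tandemscape.repeats import (
    RepeatAnnotation,
    annotate_gene,
    canonical_rotation,
    decompose,
    detect_repeats,
    filter_and_resolve,
    significance_test,
)
from tandemscape.seqio import GeneInterval, reverse_complement

TR22_CONSENSUS = "TGTGTCTGAGTGTGTATGTTGCATGGTATG"  # 30 bp intronic unit
TR21_CONSENSUS = "CCCCCACCCAGCGCCTTCCCCGCCCTGCCCCTCCAGGC"  # 38 bp GC-rich unit


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _plant(rng, motif, copies, flank=500, sub_rate=0.0):
    """Planted array with 2-base boundary guards; returns (seq, start, end)."""
    u = len(motif)
    n_full = int(copies)
    tail = round((copies - n_full) * u)
    units = []
    for k in range(n_full):
        unit = list(motif)
        n_mut = rng.binomial(u, sub_rate)
        allowed = [i for i in range(u) if not (k == 0 and i < 4)]
        for pos in rng.choice(allowed, size=min(n_mut, len(allowed)), replace=False):
            unit[pos] = rng.choice([b for b in "ACGT" if b != unit[pos]])
        units.append("".join(unit))
    arr = "".join(units) + motif[:tail]
    lg = "".join(next(b for b in "ACGT" if b != motif[(u - 2 + i) % u]) for i in (0, 1))
    rg = "".join(next(b for b in "ACGT" if b != motif[(tail + i) % u]) for i in (0, 1))
    left, right = _rand(rng, flank), _rand(rng, flank)
    seq = left + lg + arr + rg + right
    return seq, len(left) + 2, len(left) + 2 + len(arr)


class TestDecompose:
    def test_fractional_copy(self):
        s = TR21_CONSENSUS * 3 + TR21_CONSENSUS[:15]
        ann = decompose(s, GeneInterval("g", 0, len(s)), TR21_CONSENSUS)
        assert ann.copy_number == 3.4  # 129/38 rounds half-up to 3.4
        assert [len(u) for u in ann.units] == [38, 38, 38, 15]
        assert ann.has_partial_tail

    def test_exact_copies(self):
        s = TR21_CONSENSUS * 5
        ann = decompose(s, GeneInterval("g", 0, len(s)), TR21_CONSENSUS)
        assert ann.copy_number == 5.0
        assert ann.divergence == 0.0
        assert not ann.has_partial_tail

    def test_substituted_unit_divergence(self):
        rng = np.random.default_rng(0)
        unit = list(TR21_CONSENSUS)
        for pos in (10, 25):
            unit[pos] = next(b for b in "ACGT" if b != unit[pos])
        s = TR21_CONSENSUS * 2 + "".join(unit) + TR21_CONSENSUS
        ann = decompose(s, GeneInterval("g", 0, len(s)), TR21_CONSENSUS)
        assert ann.divergence == pytest.approx(2 / (4 * 38))
        assert ann.units[2] == "".join(unit)

    def test_lossless(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            motif = _rand(rng, int(rng.integers(7, 40)))
            s, a, b = _plant(rng, motif, float(rng.integers(2, 9)) + 0.4, flank=50,
                             sub_rate=0.02)
            ann = decompose(s, GeneInterval("g", a, b), motif)
            assert "".join(ann.units) == s[a:b]

    def test_short_span_errors(self):
        with pytest.raises(ValueError):
            decompose("ACGTACG", GeneInterval("g", 0, 7), TR21_CONSENSUS)


class TestDetect:
    def test_planted_pure_array(self):
        rng = np.random.default_rng(1)
        seq, a, b = _plant(rng, TR22_CONSENSUS, 6.0, flank=2000)
        cands = detect_repeats(seq)
        assert len(cands) == 1
        ann = cands[0]
        assert (ann.interval.start, ann.interval.end) == (a, b)
        assert ann.unit_length == 30
        assert ann.copy_number == 6.0
        assert ann.divergence == 0.0
        assert canonical_rotation(ann.consensus) == canonical_rotation(TR22_CONSENSUS)

    def test_short_period_excluded(self):
        assert detect_repeats("ACGTACGTACGT") == []  # period 4 < min_unit 7

    def test_recovery_experiment(self):
        """Planted loci across unit lengths 7-80 and copies 2-40 are found
        with the correct period and 1-decimal copy number (>= 95%)."""
        rng = np.random.default_rng(7)
        ok = total = 0
        for _ in range(100):
            u = int(rng.integers(7, 81))
            motif = _rand(rng, u)
            copies = float(rng.integers(2, 41)) + rng.choice([0.0, 0.4])
            sub = 0.0 if u < 20 else 0.02
            seq, a, b = _plant(rng, motif, copies, flank=300, sub_rate=sub)
            truth = np.floor((b - a) / u * 10 + 0.5) / 10
            total += 1
            ok += any(
                abs(c.interval.start - a) <= 5
                and c.unit_length == u
                and abs(c.copy_number - truth) < 0.051
                for c in detect_repeats(seq)
            )
        assert ok / total >= 0.95

    def test_reverse_complement_consistency(self):
        rng = np.random.default_rng(9)
        seq, a, b = _plant(rng, TR22_CONSENSUS, 5.0, flank=400)
        fwd = detect_repeats(seq)
        rev = detect_repeats(reverse_complement(seq))
        assert len(fwd) == len(rev) == 1
        n = len(seq)
        assert (rev[0].interval.start, rev[0].interval.end) == (n - b, n - a)
        assert canonical_rotation(rev[0].consensus) == canonical_rotation(
            reverse_complement(fwd[0].consensus)
        )


class TestSignificance:
    def test_pure_array_is_significant(self):
        rng = np.random.default_rng(2)
        seq, a, b = _plant(rng, TR21_CONSENSUS, 10.0, flank=200)
        ann = decompose(seq, GeneInterval("g", a, b), TR21_CONSENSUS)
        assert significance_test(ann, seq, seed=0) <= 0.005

    def test_random_sequence_not_significant(self):
        """Random 500-mers rarely yield a significant candidate."""
        passing = 0
        for s in range(30):
            rng = np.random.default_rng(400 + s)
            seq = _rand(rng, 500)
            cands = detect_repeats(seq)
            if not cands:
                passing += 1
                continue
            ps = [significance_test(c, seq, seed=s) for c in cands]
            passing += min(ps) > 0.05
        assert passing >= 0.95 * 30

    def test_p_monotone_in_copy_number(self):
        rng = np.random.default_rng(3)
        motif = _rand(rng, 20)
        ps = []
        for copies in (2.0, 4.0, 8.0, 16.0):
            seq, a, b = _plant(rng, motif, copies, flank=100)
            ann = decompose(seq, GeneInterval("g", a, b), motif)
            ps.append(significance_test(ann, seq, seed=1))
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_too_few_shuffles(self):
        rng = np.random.default_rng(4)
        seq, a, b = _plant(rng, TR22_CONSENSUS, 4.0, flank=50)
        ann = decompose(seq, GeneInterval("g", a, b), TR22_CONSENSUS)
        with pytest.raises(ValueError):
            significance_test(ann, seq, n_shuffles=10)


def _cand(start, end, p, div, unit=10):
    units = ["A" * unit] * ((end - start) // unit)
    return RepeatAnnotation(
        interval=GeneInterval("g", start, end),
        consensus="A" * unit,
        units=units,
        copy_number=round((end - start) / unit, 1),
        divergence=div,
        p_value=p,
    )


class TestFilterAndResolve:
    def test_identical_span_keeps_lower_divergence(self):
        a = _cand(0, 100, 0.0, 0.01)
        b = _cand(0, 100, 0.0, 0.04)
        assert filter_and_resolve([b, a]) == [a]

    def test_divergence_threshold(self):
        assert filter_and_resolve([_cand(0, 100, 0.0, 0.06)]) == []
        assert filter_and_resolve([_cand(0, 100, 0.2, 0.01)]) == []

    def test_output_sorted_nonoverlapping(self):
        cands = [_cand(50, 150, 0.0, 0.02), _cand(0, 60, 0.0, 0.01),
                 _cand(200, 260, 0.0, 0.03)]
        kept = filter_and_resolve(cands)
        starts = [c.interval.start for c in kept]
        assert starts == sorted(starts)
        for x, y in zip(kept, kept[1:]):
            assert x.interval.end <= y.interval.start

    def test_against_exhaustive_oracle(self):
        from ._oracles import best_nonoverlapping_subset

        rng = np.random.default_rng(13)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            cands = []
            for _ in range(n):
                s = int(rng.integers(0, 200))
                e = s + int(rng.integers(20, 120))
                cands.append(_cand(s, e, float(rng.choice([0.0, 0.01])),
                                   float(rng.integers(0, 5)) / 100))
            kept = filter_and_resolve(cands)
            oracle_idx = best_nonoverlapping_subset(
                [(c.interval.start, c.interval.end, c.p_value, c.divergence)
                 for c in cands]
            )
            assert [(c.interval.start, c.interval.end) for c in kept] == [
                (cands[i].interval.start, cands[i].interval.end) for i in oracle_idx
            ]


class TestAnnotateGene:
    def test_end_to_end_single_locus(self):
        rng = np.random.default_rng(21)
        seq, a, b = _plant(rng, TR21_CONSENSUS, 10.0, flank=800)
        anns = annotate_gene(seq, seed=3)
        assert len(anns) == 1
        assert (anns[0].interval.start, anns[0].interval.end) == (a, b)
        assert anns[0].copy_number == 10.0
        assert anns[0].p_value <= 0.05
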