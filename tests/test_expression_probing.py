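import numpy as np
import pytest

from crstool.expression_probing import (
    CountMatrix,
    call_islands,
    coexpression,
    cpm_rle_normalize,
    empirical_pvalue,
    exosome_sensitivity,
    expression_calls,
    probing_concordance,
    probing_lfc,
)
from crstool.io_formats import Interval, IntervalSet
from crstool.pscore import parse_structure
from crstool.synth_fixtures import simulate_probing_counts


class TestEmpiricalPvalue:
    def test_top_of_999(self):
        bg = list(range(999))
        assert empirical_pvalue(10_000, bg) == pytest.approx(1 / 1000)

    def test_observed_zero(self):
        bg = [1, 2, 3]
        assert empirical_pvalue(0, bg) == 1.0

    def test_median(self):
        bg = list(range(1, 1002))
        p = empirical_pvalue(501, bg)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_empty_background(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1, [])

    def test_monotone(self):
        rng = np.random.default_rng(0)
        bg = rng.poisson(20, 500)
        ps = [empirical_pvalue(x, bg) for x in range(60)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))


class TestRLE:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 3))
        m = cpm_rle_normalize(CountMatrix(counts))
        assert np.allclose(m.size_factors, 1.0)

    def test_doubling_doubles_factor(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(200, 1))
        counts = np.hstack([base, base * 2, base])
        m = cpm_rle_normalize(CountMatrix(counts))
        assert m.size_factors[1] / m.size_factors[0] == pytest.approx(2.0, rel=1e-6)

    def test_factor_recovery_nb(self):
        rng = np.random.default_rng(42)
        true = np.array([1.0, 2.0, 0.5, 1.0])
        size = 1 / 0.3
        mu = rng.lognormal(3.5, 1.0, size=500)
        mean = mu[:, None] * true[None, :]
        counts = rng.negative_binomial(size, size / (size + mean))
        m = cpm_rle_normalize(CountMatrix(counts))
        est = m.size_factors / np.exp(np.mean(np.log(m.size_factors)))
        ref = true / np.exp(np.mean(np.log(true)))
        assert np.allclose(est, ref, rtol=0.10)

    def test_requires_allpositive_feature(self):
        counts = np.array([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            cpm_rle_normalize(CountMatrix(counts))


class TestExpressionCalls:
    def test_threshold(self):
        bg = list(range(1000))
        calls = expression_calls([5000, 0], bg)
        assert calls[0].expressed and not calls[1].expressed


class TestCoexpression:
    def test_identical(self):
        assert coexpression([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)

    def test_negated(self):
        assert coexpression([1, 2, 3], [-1, -2, -3])[0] == pytest.approx(-1.0)

    def test_textbook_formula(self):
        a, b = np.array([1, 2, 3.0]), np.array([1, 2, 4.0])
        expect = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert coexpression(a, b)[0] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_nan(self):
        r, strong = coexpression([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and not strong


def stranded(*quads):
    return IntervalSet([Interval(c, s, e, ".", 0, st) for c, s, e, st in quads])


class TestIslands:
    def test_two_overlapping_plus_reads(self):
        reads = stranded(("c", 100, 150, "+"), ("c", 180, 230, "+"))
        islands = call_islands(reads)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.interval.start, isl.interval.end) == (100, 330)
        assert isl.read_count == 2

    def test_distant_reads_two_islands(self):
        reads = stranded(("c", 100, 150, "+"), ("c", 500, 550, "+"))
        islands = call_islands(reads)
        assert [i.read_count for i in islands] == [1, 1]

    def test_minus_strand_extension(self):
        reads = stranded(("c", 400, 450, "-"),)
        isl = call_islands(reads)[0]
        assert (isl.interval.start, isl.interval.end) == (300, 450)

    def test_repeat_removal_at_half_overlap(self):
        reads = stranded(("c", 100, 200, "+"),)  # 100 nt read
        repeats = IntervalSet([Interval("c", 150, 300)])  # overlap 50 = 50%
        assert call_islands(reads, repeats=repeats) == []

    def test_repeat_below_half_kept(self):
        reads = stranded(("c", 100, 200, "+"),)
        repeats = IntervalSet([Interval("c", 151, 300)])  # overlap 49 < 50%
        assert len(call_islands(reads, repeats=repeats)) == 1

    def test_strands_do_not_merge(self):
        reads = stranded(("c", 100, 150, "+"), ("c", 120, 170, "-"))
        assert len(call_islands(reads)) == 2

    def test_order_invariance_and_count_sum(self):
        rng = np.random.default_rng(3)
        quads = [("c", int(s), int(s) + 50, "+-"[rng.integers(2)]) for s in rng.integers(0, 5000, 60)]
        a = call_islands(stranded(*quads))
        b = call_islands(stranded(*quads[::-1]))
        key = lambda i: (i.interval.chrom, i.interval.start, i.strand)
        assert sorted(key(i) for i in a) == sorted(key(i) for i in b)
        assert sum(i.read_count for i in a) == 60

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            call_islands(IntervalSet([Interval("c", 0, 50)]))

    def test_on_target_and_pvalue(self):
        reads = stranded(*[("c", 1000 * k, 1000 * k + 50, "+") for k in range(20)])
        # cluster 5 extra reads on the first island -> strong on-target signal
        extra = stranded(*[("c", 10, 60, "+") for _ in range(5)])
        allreads = IntervalSet(reads.records + extra.records)
        probes = IntervalSet([Interval("c", 0, 400)])
        islands = call_islands(allreads, probes=probes)
        on = [i for i in islands if i.on_target]
        assert len(on) == 1
        assert on[0].expressed


class TestStability:
    def test_unstable_boundary(self):
        call = exosome_sensitivity(8, 2)
        assert call.s == pytest.approx(0.75)
        assert call.klass == "unstable"

    def test_clipped_to_zero(self):
        call = exosome_sensitivity(5, 9)
        assert call.s == 0.0
        assert call.klass == "stable"

    def test_stable_boundary(self):
        call = exosome_sensitivity(8, 6)
        assert call.s == pytest.approx(0.25)
        assert call.klass == "stable"

    def test_scale_invariance(self):
        s1 = exosome_sensitivity(8, 3).s
        s2 = exosome_sensitivity(80, 30).s
        assert s1 == pytest.approx(s2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            exosome_sensitivity(0, 1)


class TestProbing:
    def test_boundary_not_paired(self):
        prof = probing_lfc([11], [27])
        assert prof.lfc[0] == pytest.approx(1.0)
        assert not prof.paired_call[0]

    def test_strong_signal(self):
        prof = probing_lfc([0], [59])
        assert prof.lfc[0] == pytest.approx(6 - np.log2(5), abs=1e-9)
        assert prof.paired_call[0]

    def test_equal_counts_no_calls(self):
        prof = probing_lfc([3, 10, 0], [3, 10, 0])
        assert np.all(prof.lfc == 0)
        assert not prof.paired_call.any()

    def test_depth_normalization(self):
        p1 = probing_lfc([10], [40], depth_native=1, depth_denatured=1)
        p2 = probing_lfc([20], [80], depth_native=2, depth_denatured=2)
        assert p1.lfc[0] == pytest.approx(p2.lfc[0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            probing_lfc([1, 2], [1])


class TestConcordance:
    def test_perfect_profile(self):
        struct = parse_structure("(((....)))")
        native, den = simulate_probing_counts(struct, 10, probing_noise=0.0, seed=1)
        prof = probing_lfc(native, den)
        assert probing_concordance(struct, prof) == 1.0

    def test_flat_profile_zero(self):
        struct = parse_structure("(((....)))")
        prof = probing_lfc([5] * 10, [5] * 10)
        assert probing_concordance(struct, prof) == 0.0

    def test_noise_calibration(self):
        struct = parse_structure("((((((((((..........))))))))))")
        vals = []
        for seed in range(100):
            native, den = simulate_probing_counts(struct, 30, probing_noise=0.2, seed=seed)
            vals.append(probing_concordance(struct, probing_lfc(native, den)))
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_no_pairs_error(self):
        struct = parse_structure(".....")
        with pytest.raises(ValueError):
            probing_concordance(struct, probing_lfc([1] * 5, [1] * 5))
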