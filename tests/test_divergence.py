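import math

import numpy as np
import pytest

from mitocompare.align import AlignParams, Alignment, global_align
from mitocompare.divergence import (classify_sites, cross_pairs, distance_matrix,
                                    p_distance, positional_alignment,
                                    skew_profile, sliding_divergence, tamura3p)
from mitocompare.io import AnnotatedGenome, CircularSequence, Feature
from mitocompare.simulate import mutate_sequence, random_rna

NT = AlignParams()

# frozen from an independent double-precision evaluation of the closed form:
# -0.5*ln(0.75) - 0.25*ln(0.9) for theta=0.5, P=0.1, Q=0.05
T92_SPOT = 0.17018116514034703


def aln(a, b, params=NT):
    return Alignment(gapped_a=a, gapped_b=b, params=params, score=0.0)


class TestPDistance:
    def test_identical_rows_give_zero(self):
        r = p_distance(aln("ACGTACGT", "ACGTACGT"))
        assert r.p == 0 and r.compared_sites == 8

    def test_single_transversion_counted(self):
        r = p_distance(aln("ACGT", "ACGA"))
        assert (r.p, r.P, r.Q) == (0.25, 0.0, 0.25)

    def test_transition_classified(self):
        r = p_distance(aln("AAAA", "GAAA"))
        assert (r.P, r.Q) == (0.25, 0.0)

    def test_pairwise_deletion_skips_gap_columns(self):
        r = p_distance(aln("AC-T", "ACGT"))
        assert (r.compared_sites, r.p) == (3, 0.0)

    def test_n_columns_excluded(self):
        r = p_distance(aln("ACNT", "ACGT"))
        assert r.compared_sites == 3

    def test_zero_compared_sites_flagged(self):
        r = p_distance(aln("A--", "-CG"))
        assert not r.defined and r.compared_sites == 0

    def test_sum_rule_p_equals_P_plus_Q(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 60))
            r = p_distance(positional_alignment(a, b))
            assert r.p == pytest.approx(r.P + r.Q, abs=1e-12)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), 40))
        b = "".join(rng.choice(list("ACGT"), 40))
        assert p_distance(aln(a, b)).p == p_distance(aln(b, a)).p


class TestTamura3P:
    def test_zero_divergence_gives_zero(self):
        r = tamura3p(aln("ACGT", "ACGT"))
        assert r.d_t92 == 0.0 and r.t92_defined

    def test_closed_form_spot_value(self):
        # 40 sites: 17 GG + 17 AA identical, 4 A/G transitions, 2 A/C
        # transversions -> theta=0.5, P=0.1, Q=0.05
        a = "G" * 17 + "A" * 17 + "A" * 4 + "A" * 2
        b = "G" * 17 + "A" * 17 + "G" * 4 + "C" * 2
        r = tamura3p(aln(a, b))
        assert (r.theta, r.P, r.Q) == (0.5, 0.1, 0.05)
        assert r.d_t92 == pytest.approx(T92_SPOT, rel=1e-9)

    def test_saturation_flagged_not_raised(self):
        # P=0.5, Q=0.3 drive the first log argument negative
        a = "A" * 10
        b = "G" * 5 + "C" * 3 + "A" * 2
        r = tamura3p(aln(a, b))
        assert r.saturated and not r.t92_defined and math.isnan(r.d_t92)

    def test_correction_dominates_p_when_defined(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 200))
            b = mutate_sequence(a, float(rng.uniform(0.01, 0.4)), rng)
            r = tamura3p(positional_alignment(a, b))
            if r.t92_defined:
                assert r.d_t92 >= r.p - 1e-12

    def test_converges_to_p_at_low_divergence(self, rng):
        a = random_rna(30000, rng)
        b = mutate_sequence(a, 0.005, rng)
        r = tamura3p(positional_alignment(a, b))
        assert r.p <= 0.01
        assert r.d_t92 == pytest.approx(r.p, rel=0.05)

    def test_requires_nucleotide_level(self):
        with pytest.raises(ValueError):
            tamura3p(aln("MK", "MK", AlignParams(level="aa")))


class TestSlidingDivergence:
    def test_window_equal_to_length_reproduces_global_p(self, rng):
        a = "".join(rng.choice(list("ACGT"), 120))
        b = mutate_sequence(a, 0.2, rng)
        pair = positional_alignment(a, b)
        prof = sliding_divergence(pair, window=120, step=25)
        assert prof.values == [p_distance(pair).p]

    def test_uniform_divergence_stays_in_binomial_band(self, rng):
        from scipy.stats import binom
        a = random_rna(5000, rng)
        b = mutate_sequence(a, 0.2, rng)
        prof = sliding_divergence(positional_alignment(a, b), 100, 25)
        lo = binom.ppf(0.005, 100, 0.2) / 100
        hi = binom.ppf(0.995, 100, 0.2) / 100
        inside = [lo <= v <= hi for v in prof.values]
        assert np.mean(inside) >= 0.95

    def test_step_profile_localizes_breakpoint(self, rng):
        half = 2500
        a = random_rna(2 * half, rng)
        b = a[:half] + random_rna(half, rng)
        prof = sliding_divergence(positional_alignment(a, b), 100, 25)
        crossed = [c for c, v in zip(prof.centers, prof.values) if v > 0.3]
        assert crossed, "no divergent windows found"
        onset = min(crossed)
        assert abs(onset - half) <= 100 // 2 + 25

    def test_window_larger_than_alignment_rejected(self):
        with pytest.raises(ValueError):
            sliding_divergence(aln("ACGT", "ACGT"), window=10)


class TestSkew:
    def _genome(self, residues, features=()):
        return AnnotatedGenome(
            sequence=CircularSequence("g", residues), features=list(features))

    def test_balanced_sequence_has_zero_at_skew(self):
        prof = skew_profile(self._genome("AATT" * 100), "at_skew", 40, 20)
        assert all(v == 0 for v in prof.values)

    def test_at_skew_value(self):
        prof = skew_profile(self._genome("AAAT" * 100), "at_skew", 4, 4)
        assert all(v == pytest.approx(0.5) for v in prof.values)

    def test_reverse_complement_negates_and_reverses_skews(self, rng):
        from mitocompare.io import reverse_complement
        n, w, s = 400, 40, 20
        seq = "".join(rng.choice(list("ACGT"), n))
        g = self._genome(seq)
        g_rc = self._genome(reverse_complement(seq))
        for metric in ("at_skew", "gc_skew"):
            v = skew_profile(g, metric, w, s).values
            v_rc = skew_profile(g_rc, metric, w, s).values
            starts = list(range(0, n, s))
            for i, start in enumerate(starts):
                j = starts.index((n - start - w) % n)
                assert v_rc[i] == pytest.approx(-v[j], abs=1e-12)

    def test_gc_content_rel_is_centered(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        prof = skew_profile(self._genome(seq), "gc_content_rel", 200, 25)
        assert abs(np.mean(prof.values)) < 0.05

    def test_site_mask_restricts_to_codon_positions(self, rng):
        gene = "ATG" + "GGA" * 32 + "TAA"  # codon2 everywhere G except start/stop
        seq = gene + "TTAA" * 25
        g = self._genome(seq, [Feature("cds", "CDS", "+", [(0, len(gene))])])
        classes = classify_sites(g)
        assert classes[:3] == ["codon1", "codon2", "codon3"]
        assert classes[len(gene)] == "noncoding"
        prof = skew_profile(g, "gc_skew", len(seq), len(seq),
                            site_mask={"codon2"})
        assert prof.values[0] == pytest.approx(1.0)  # only G at codon2 inside

    def test_zero_denominator_yields_nan(self):
        prof = skew_profile(self._genome("GGCC" * 30), "at_skew", 12, 12)
        assert all(math.isnan(v) for v in prof.values)


class TestDistanceMatrix:
    def test_identical_genomes_all_zero(self, sim_pair):
        f, _, _ = sim_pair
        genomes = {"a": f, "b": f}
        pairs = cross_pairs("a", ["cox1", "cytb"], "b", ["cox1", "cytb"])
        df = distance_matrix(genomes, pairs, NT)
        same = df[df.feature_a == df.feature_b]
        assert (same.p == 0).all()

    def test_missing_feature_flagged_not_fatal(self, sim_pair):
        f, _, _ = sim_pair
        df = distance_matrix({"a": f}, [("a", "cox1", "a", "ghost")], NT)
        assert df.flag.str.contains("error").iloc[0]
        assert math.isnan(df.p.iloc[0])

    def test_planted_divergence_recovered_within_binomial_bounds(self, sim_pair):
        f, m, truth = sim_pair
        genomes = {"F": f, "M": m}
        df = distance_matrix(
            genomes, [("F", g, "M", g) for g in ("atp6", "cox3", "cytb")], NT)
        for _, row in df.iterrows():
            planted = truth.gene_p[row.feature_a]
            # realignment may shave a little off the positional divergence
            assert planted - 0.06 <= row.p <= planted + 0.02
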