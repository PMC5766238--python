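import itertools
import math

import numpy as np
import pandas as pd
import pytest

from seqexpr.features import (
    DINUCLEOTIDES,
    FeatureConfig,
    NUCLEOTIDES,
    PWM,
    build_feature_matrix,
    collapse_double_strand,
    double_strand_groups,
    kmer_label,
    kmer_percentage,
    nt_percentage,
    pwm_from_counts,
    pwm_score_at,
    pwm_score_max,
    pwm_score_sum,
    shape_means,
)
from seqexpr.regions import reverse_complement
from seqexpr.synthetic import generate_pwms


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestNtPercentage:
    def test_uniform(self):
        assert nt_percentage("ACGT") == {"A": 25, "C": 25, "G": 25, "T": 25}

    def test_single_base(self):
        vals = nt_percentage("AAAA")
        assert vals["A"] == 100 and vals["C"] == vals["G"] == vals["T"] == 0

    def test_ambiguous_bases_excluded_from_denominator(self):
        vals = nt_percentage("ACGN")
        assert vals["A"] == pytest.approx(100 / 3)
        assert vals["T"] == 0

    def test_all_ambiguous_is_missing(self):
        assert nt_percentage("NNN") is None

    def test_sums_to_100(self, rng):
        for _ in range(20):
            vals = nt_percentage(random_seq(rng, 50, "ACGTN"))
            assert sum(vals.values()) == pytest.approx(100, abs=1e-9)


class TestKmerPercentage:
    def test_homopolymer_dinucleotides(self):
        vals = kmer_percentage("AAA", 2)
        assert vals["ApA"] == 100
        assert sum(vals.values()) == 100

    def test_cg_alternating(self):
        vals = kmer_percentage("CGCG", 2)
        assert vals["CpG"] == pytest.approx(200 / 3)
        assert vals["GpC"] == pytest.approx(100 / 3)

    def test_trinucleotides(self):
        vals = kmer_percentage("ACGT", 3)
        assert vals["ACG"] == 50 and vals["CGT"] == 50

    def test_too_short_is_missing(self):
        assert kmer_percentage("A", 2) is None

    def test_ambiguous_windows_excluded_both_sides(self):
        # windows: AN, NC excluded; only AC..: "ANCA" -> valid windows CA only
        vals = kmer_percentage("ANCA", 2)
        assert vals["CpA"] == 100

    def test_window_counting_oracle(self, rng):
        for _ in range(30):
            seq = random_seq(rng, rng.integers(5, 40), "ACGTN")
            for k in (2, 3):
                got = kmer_percentage(seq, k)
                windows = [
                    seq[i : i + k]
                    for i in range(len(seq) - k + 1)
                    if "N" not in seq[i : i + k]
                ]
                if not windows:
                    assert got is None
                    continue
                for kmer in map("".join, itertools.product("ACGT", repeat=k)):
                    expected = 100 * windows.count(kmer) / len(windows)
                    assert got[kmer_label(kmer)] == pytest.approx(expected, abs=1e-9)

    def test_reversal_maps_npm_to_mpn(self, rng):
        seq = random_seq(rng, 60)
        fwd = kmer_percentage(seq, 2)
        rev = kmer_percentage(seq[::-1], 2)
        for d in DINUCLEOTIDES:
            assert fwd[kmer_label(d)] == pytest.approx(rev[kmer_label(d[::-1])])


class TestCollapseDoubleStrand:
    def _frame(self, values):
        return pd.DataFrame([values], index=["g1"])

    def test_complementary_nucleotides_sum(self):
        df = pd.DataFrame(
            {f"{n}_CORE": [v] for n, v in zip("ACGT", [30.0, 25.0, 25.0, 20.0])},
            index=["g1"],
        )
        out = collapse_double_strand(df)
        assert out.loc["g1", "A|T_CORE"] == 50
        assert out.loc["g1", "C|G_CORE"] == 50

    def test_self_reverse_complementary_pass_through(self):
        groups = double_strand_groups(2)
        assert groups["CpG"] == ("CG",)
        assert groups["ApT"] == ("AT",)
        # duplex steps: 6 pairs + 4 palindromic = 10 groups
        assert len(groups) == 10

    def test_partition_conserves_total(self, rng):
        seq = random_seq(rng, 200)
        vals = kmer_percentage(seq, 2)
        df = pd.DataFrame([{f"{k}_INTR": v for k, v in vals.items()}], index=["g"])
        out = collapse_double_strand(df)
        assert out.loc["g"].sum() == pytest.approx(100, abs=1e-9)

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 80)
            frames = []
            for s in (seq, reverse_complement(seq)):
                vals = {f"{n}_CDS": v for n, v in nt_percentage(s).items()}
                vals.update({f"{k}_CDS": v for k, v in kmer_percentage(s, 2).items()})
                frames.append(collapse_double_strand(pd.DataFrame([vals], index=["g"])))
            pd.testing.assert_frame_equal(
                frames[0].sort_index(axis=1), frames[1].sort_index(axis=1)
            )


class TestPwmScores:
    def test_background_motif_scores_zero_everywhere(self):
        pwm = PWM("bg", np.full((4, 3), 0.25))
        for i in range(5):
            assert pwm_score_at(pwm, "ACGTACG", i) == pytest.approx(0.0)

    def test_hand_computed_log_odds(self):
        # P(A|w0)=1, P(C|w1)=1 before pseudocount; window "AC" at i=1 of TACG
        pwm = pwm_from_counts("m", np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=float),
                              pseudocount=0.0 + 1e-12)
        score = pwm_score_at(pwm, "TACG", 1)
        assert score == pytest.approx(2 * math.log(4), rel=1e-6)

    def test_pseudocount_keeps_probabilities_positive(self):
        pwm = pwm_from_counts("m", np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=float))
        assert (pwm.probs > 0).all()

    def test_max_and_sum_match_exhaustive_oracle(self, rng):
        for _ in range(25):
            seq = random_seq(rng, 60)
            counts = rng.integers(0, 20, size=(4, 8)).astype(float)
            pwm = pwm_from_counts("m", counts)
            scores = [pwm_score_at(pwm, seq, i) for i in range(len(seq) - 8 + 1)]
            assert pwm_score_max(pwm, seq) == pytest.approx(max(scores), abs=1e-9)
            assert pwm_score_sum(pwm, seq) == pytest.approx(sum(scores), abs=1e-9)

    def test_ambiguous_windows_skipped(self):
        pwm = PWM("bg", np.array([[0.7, 0.1], [0.1, 0.7], [0.1, 0.1], [0.1, 0.1]]))
        # only the "AC" window at position 3 is N-free
        seq = "NANAC"
        expected = pwm_score_at(pwm, seq[3:], 0)
        assert pwm_score_max(pwm, seq) == pytest.approx(expected)
        assert pwm_score_sum(pwm, seq) == pytest.approx(expected)

    def test_all_windows_ambiguous_is_missing(self):
        pwm = PWM("bg", np.full((4, 2), 0.25))
        assert math.isnan(pwm_score_max(pwm, "ANNA"))

    def test_single_window_max_equals_sum(self):
        pwm = PWM("bg", np.array([[0.7], [0.1], [0.1], [0.1]]))
        assert pwm_score_max(pwm, "A") == pwm_score_sum(pwm, "A")


class TestShapeMeans:
    def test_constant_table(self):
        table = {p: (1.0, 2.0, 3.0, 4.0) for p in map("".join, itertools.product("ACGT", repeat=5))}
        means = shape_means("ACGTACGTA", table)
        assert means == {"MGW": 1.0, "HelT": 2.0, "ProT": 3.0, "Roll": 4.0}

    def test_single_window(self):
        table = {"ACGTA": (5.0, 30.0, -7.0, 1.0)}
        assert shape_means("ACGTA", table)["MGW"] == 5.0

    def test_mean_of_three_windows(self):
        table = {"AAAAA": (1.0, 0, 0, 0), "AAAAC": (2.0, 0, 0, 0), "AAACA": (6.0, 0, 0, 0)}
        means = shape_means("AAAAACA", table)
        assert means["MGW"] == pytest.approx(3.0)

    def test_reverse_complement_fallback(self):
        # TACGT's reverse complement is ACGTA
        table = {"ACGTA": (2.5, 0, 0, 0)}
        assert shape_means("TACGT", table)["MGW"] == 2.5

    def test_missing_pentamer_raises(self):
        with pytest.raises(ValueError, match="missing from shape table"):
            shape_means("ACGTA", {"AAAAA": (0, 0, 0, 0)})

    def test_too_short_is_missing(self):
        assert shape_means("ACGT", {}) is None


class TestBuildFeatureMatrix:
    def test_full_composition_model_has_160_columns(self, small_sim):
        assert small_sim["X"].shape == (80, 160)

    def test_promoter_only_model_has_60_columns(self, small_sim):
        X = build_feature_matrix(
            small_sim["catalog"], FeatureConfig(regions=("DU", "CORE", "DD"))
        )
        assert X.shape[1] == 60

    def test_promoter_percentages_plus_471_core_motifs_gives_531(self, small_sim):
        catalog = small_sim["catalog"]
        tiny = type(catalog)(entries=dict(list(catalog.entries.items())[:3]))
        pwms = [
            pwm_from_counts(mid, counts)
            for mid, counts in generate_pwms(471, (6, 10), seed=5).items()
        ]
        X = build_feature_matrix(
            tiny,
            FeatureConfig(regions=("DU", "CORE", "DD"), motif_regions=("CORE",)),
            pwms=pwms,
        )
        assert X.shape[1] == 531

    def test_shape_columns_are_12(self, small_sim):
        catalog = small_sim["catalog"]
        tiny = type(catalog)(entries=dict(list(catalog.entries.items())[:3]))
        table = {
            p: (1.0, 2.0, 3.0, 4.0)
            for p in map("".join, itertools.product("ACGT", repeat=5))
        }
        X = build_feature_matrix(
            tiny,
            FeatureConfig(
                regions=(), nucleotides=False, dinucleotides=False,
                shape_regions=("DU", "CORE", "DD"),
            ),
            shape_table=table,
        )
        assert X.shape[1] == 12

    def test_percentage_rows_sum_to_100_per_family(self, small_sim):
        X = small_sim["X"]
        nt_cols = [f"{n}_CORE" for n in NUCLEOTIDES]
        dint_cols = [f"{kmer_label(d)}_CORE" for d in DINUCLEOTIDES]
        assert np.allclose(X[nt_cols].sum(axis=1), 100, atol=1e-9)
        assert np.allclose(X[dint_cols].sum(axis=1), 100, atol=1e-9)

    def test_empty_sequence_missing_coded(self):
        from seqexpr.regions import GeneModel, build_catalog

        genome = {"chr1": "ACGT" * 3000}
        gene = GeneModel(
            "g1", "chr1", "+", 4000, 5000, tss_list=[4000],
            utr5=[], cds=[], utr3=[],
        )
        catalog = build_catalog([gene], genome)
        X = build_feature_matrix(catalog, FeatureConfig(regions=("UTR5", "INTR")))
        assert X.loc["g1", "A_UTR5"] != X.loc["g1", "A_UTR5"]  # NaN, not 0
        assert not np.isnan(X.loc["g1", "A_INTR"])

    def test_motif_family_without_pwms_is_config_error(self, small_sim):
        with pytest.raises(ValueError, match="no PWMs"):
            build_feature_matrix(
                small_sim["catalog"], FeatureConfig(motif_regions=("CORE",))
            )
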