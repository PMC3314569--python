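"""Shuffle null models and the SNR / specificity statistics."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mircos.seqio import ESTRecord, MatureMiRNA
from mircos.shufflestats import (
    StatsParams,
    compute_stats,
    dinuc_shuffle,
    estimate_fp,
    mononuc_shuffle,
    specificity_from_snr,
    truncated_percent,
)

from _oracles import oracle_dinuc_permutations


def _dinuc_counts(s: str) -> Counter:
    return Counter(a + b for a, b in zip(s, s[1:]))


class TestDinucShuffle:
    def test_homopolymer_fixed_point(self, rng):
        assert dinuc_shuffle("AAAA", rng) == "AAAA"

    def test_counts_and_terminals_preserved(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            seq = "".join(rng.choice(list("ACGU"), size=21))
            out = dinuc_shuffle(seq, rng)
            assert len(out) == len(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]
            assert _dinuc_counts(out) == _dinuc_counts(seq)

    def test_outputs_lie_in_enumerated_permutation_set(self):
        # "AUGCUA" admits exactly one valid walk; a longer word several
        for word in ("AUGCUA", "AUGCAUGGCA"):
            valid = oracle_dinuc_permutations(word)
            rng = np.random.default_rng(5)
            seen = set()
            for _ in range(200):
                out = dinuc_shuffle(word, rng)
                assert out in valid
                seen.add(out)
            assert seen == valid  # every valid permutation is reachable

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            dinuc_shuffle("A", rng)

    @given(
        seq=st.text(alphabet="ACGU", min_size=2, max_size=40),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_contract_holds_for_arbitrary_sequences(self, seq, seed):
        out = dinuc_shuffle(seq, np.random.default_rng(seed))
        assert len(out) == len(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert _dinuc_counts(out) == _dinuc_counts(seq)


class TestMononucShuffle:
    def test_composition_preserved(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            seq = "".join(rng.choice(list("ACGT"), size=30))
            out = mononuc_shuffle(seq, rng)
            assert Counter(out) == Counter(seq)

    def test_permutation_of_distinct_letters(self, rng):
        assert sorted(mononuc_shuffle("ACGT", rng)) == ["A", "C", "G", "T"]

    def test_position_uniformity_chi_square(self):
        """Position of 'A' in shuffles of ACGG is uniform (alpha 0.001)."""
        rng = np.random.default_rng(42)
        counts = [0, 0, 0, 0]
        for _ in range(10_000):
            counts[mononuc_shuffle("ACGG", rng).index("A")] += 1
        chi2 = sum((c - 2500) ** 2 / 2500 for c in counts)
        assert chi2 < sps.chi2.ppf(0.999, df=3)


class TestEstimateFp:
    def _mir(self, seq):
        return MatureMiRNA("syn-miRt", "miRt", "syn", seq)

    def test_impossible_hits_give_zero(self):
        # poly-A can only bind poly-T, absent from a poly-A EST's forward
        # strand (its reverse complement would bind, so forward mode here)
        from mircos.duplexscan import ScanParams

        m = self._mir("A" * 21)
        ests = [ESTRecord(f"e{i}", "s", "A" * 300) for i in range(5)]
        fp, s1, s2 = estimate_fp(
            m, ests, StatsParams(rng_seed=1),
            scan_params=ScanParams(strand_mode="forward"),
        )
        assert fp == s1 == s2 == 0.0

    def test_deterministic_given_seed(self, default_synth):
        m = default_synth.panel[0]
        ests = default_synth.ests_a[:10]
        p = StatsParams(rng_seed=123)
        assert estimate_fp(m, ests, p) == estimate_fp(m, ests, p)

    def test_fp_tracks_background_hit_rate(self, default_synth):
        """On unplanted background the shuffle estimate approximates the
        real hit rate measured on a disjoint background sample."""
        from mircos.duplexscan import scan_dataset
        from mircos.synthetic_data import SynthConfig, generate

        null = generate(
            SynthConfig(n_ests=60, n_planted_precursors=0,
                        n_conserved_targets=0, n_nonconserved_targets=0,
                        seed=901)
        )
        m = null.panel[0]
        half_a, half_b = null.ests_a[:30], null.ests_a[30:]
        fp, _s1, _s2 = estimate_fp(m, half_a, StatsParams(rng_seed=3))
        reference = len(scan_dataset([m], half_b))
        # crude Poisson scale for the comparison
        se = math.sqrt(max(reference, fp, 1.0))
        assert abs(fp - reference) <= 3 * se


class TestComputeStats:
    def test_snr26_gives_specificity_096(self):
        s = compute_stats("m", observed=26, fp=1.0)
        assert s.snr == pytest.approx(26.0)
        assert round(s.specificity, 2) == 0.96

    def test_direct_formula_case_fails_threshold(self):
        s = compute_stats("m", observed=30, fp=10.0)
        assert s.snr == pytest.approx(3.0)
        assert s.specificity == pytest.approx(2 / 3, abs=1e-9)
        assert not s.passes  # 0.667 < 0.85

    def test_zero_fp_limit_passes(self):
        s = compute_stats("m", observed=5, fp=0.0)
        assert math.isinf(s.snr)
        assert s.specificity == 1.0
        assert s.passes

    def test_degenerate_not_evaluable(self):
        s = compute_stats("m", observed=0, fp=0.0)
        assert not s.evaluable and not s.passes

    def test_zero_observed_with_noise_fails(self):
        s = compute_stats("m", observed=0, fp=2.0)
        assert s.evaluable and not s.passes
        assert s.specificity == 0.0

    def test_identity_with_snr_holds(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            observed = int(rng.integers(1, 500))
            fp = float(rng.uniform(0.01, observed))  # clamp-free region
            s = compute_stats("m", observed, fp)
            assert abs(s.specificity - (1 - 1 / s.snr)) < 1e-12

    def test_specificity_monotonicity(self):
        s1 = compute_stats("m", 20, 5.0).specificity
        s2 = compute_stats("m", 40, 5.0).specificity
        s3 = compute_stats("m", 20, 8.0).specificity
        assert s2 > s1 > s3

    def test_threshold_boundary_is_strict_for_snr(self):
        at = compute_stats("m", observed=20, fp=10.0)  # snr exactly 2
        assert not at.passes
        above = compute_stats("m", observed=40, fp=6.0)  # snr 6.67, S 0.85
        assert above.specificity == pytest.approx(0.85)
        assert above.passes


class TestRatesHelpers:
    def test_specificity_from_snr(self):
        assert round(specificity_from_snr(26), 2) == 0.96
        with pytest.raises(ValueError):
            specificity_from_snr(0)

    def test_truncated_percent_truncates_not_rounds(self):
        assert truncated_percent(17, 78334) == 0.021
        assert truncated_percent(196, 1_065_779) == 0.018
        assert truncated_percent(196, 221, decimals=0) == 88.0
        with pytest.raises(ZeroDivisionError):
            truncated_percent(1, 0)
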