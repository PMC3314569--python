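"""Precursor candidate assembly, window extraction and fold validation."""

import dataclasses

import numpy as np
import pytest

from mircos.duplexscan import EnergyModel
from mircos.irfinder import InvertedRepeat, find_inverted_repeats
from mircos.precursor import (
    PrecursorParams,
    extract_window,
    fold_and_validate,
    fold_nussinov,
    match_mature_and_star,
)
from mircos.seqio import ESTRecord, MatureMiRNA, PrecursorReference, revcomp, to_dna
from mircos.shufflestats import mononuc_shuffle

from _oracles import oracle_fold_min_energy

MIR = MatureMiRNA("syn-miR1", "miR1", "syn", "UGACAGAAGAGAGUGAGCACA")


def _hairpin_est(rng, loop=40, star_subs=0, flank=60):
    """EST with mature + loop + revcomp(mature) planted after a flank."""
    mdna = to_dna(MIR.seq)
    star = list(revcomp(mdna))
    for p in rng.choice(len(star), size=star_subs, replace=False):
        star[p] = rng.choice([c for c in "ACGT" if c != star[p]])
    loop_seq = "".join(rng.choice(list("ACGT"), size=loop))
    f = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    construct = mdna + loop_seq + "".join(star)
    seq = f(flank) + construct + f(flank)
    ref = PrecursorReference("miR1", "syn", len(construct))
    return ESTRecord("h", "s", seq), ref, (flank, flank + len(construct))


class TestMatchMatureAndStar:
    def test_perfect_construct_yields_candidate(self, rng):
        est, ref, (start, end) = _hairpin_est(rng)
        irs = find_inverted_repeats(est)
        assert irs
        cands = match_mature_and_star(irs[0], est, [MIR], [ref])
        assert cands
        c = cands[0]
        assert c.mature_mismatches == 0 and c.star_mismatches == 0
        assert c.inter_match_distance == ref.precursor_length

    def test_wrong_spacing_is_rejected(self, rng):
        est, ref, _ = _hairpin_est(rng)
        off = PrecursorReference("miR1", "syn", 2 * ref.precursor_length)
        irs = find_inverted_repeats(est)
        assert match_mature_and_star(irs[0], est, [MIR], [off]) == []

    def test_unrelated_family_reference_is_rejected(self, rng):
        est, ref, _ = _hairpin_est(rng)
        other = PrecursorReference("miR99", "syn", ref.precursor_length)
        irs = find_inverted_repeats(est)
        assert match_mature_and_star(irs[0], est, [MIR], [other]) == []

    def test_ir_est_mismatch_raises(self, rng):
        est, ref, _ = _hairpin_est(rng)
        ir = InvertedRepeat("other", (0, 10), (20, 30), 10, 60, 1.0)
        with pytest.raises(ValueError):
            match_mature_and_star(ir, est, [MIR], [ref])

    @pytest.mark.parametrize("n_mut", range(5))
    def test_mature_mismatch_tolerance_boundary(self, n_mut):
        """Matures mutated at 0-4 positions are matched iff <= 2 mismatches.

        The inverted repeat is supplied directly so the Hamming contract of
        the matcher is tested in isolation from the IR score threshold.
        """
        detected = 0
        trials = 12
        for seed in range(trials):
            rng = np.random.default_rng(3000 + 97 * seed + n_mut)
            mdna = list(to_dna(MIR.seq))
            for p in rng.choice(len(mdna), size=n_mut, replace=False):
                mdna[p] = rng.choice([c for c in "ACGT" if c != mdna[p]])
            mdna = "".join(mdna)
            loop = "".join(rng.choice(list("ACGT"), size=40))
            construct = mdna + loop + revcomp(mdna)
            f = "".join(rng.choice(list("ACGT"), size=30))
            est = ESTRecord("h", "s", f + construct + f)
            ir = InvertedRepeat(
                "h", (30, 51), (30 + 61, 30 + 82), 40, 63, 1.0
            )
            ref = PrecursorReference("miR1", "syn", len(construct))
            cands = match_mature_and_star(ir, est, [MIR], [ref])
            detected += bool(cands)
        if n_mut <= 2:
            assert detected == trials
        else:
            assert detected == 0

    def test_no_overlapping_mature_and_star(self, rng, default_synth):
        data = default_synth
        for est in data.ests_a[:40]:
            for ir in find_inverted_repeats(est):
                for c in match_mature_and_star(ir, est, data.panel, data.refs):
                    m, s = sorted([c.mature_site, c.star_site])
                    assert m[1] <= s[0]


class TestExtractWindow:
    def _candidate(self, mature, star):
        est = ESTRecord("e", "s", "A" * 600)
        from mircos.precursor import HairpinCandidate

        c = HairpinCandidate(
            est_id="e", mirna="m", family="f", mature_site=mature,
            star_site=star, mature_mismatches=0, star_mismatches=0,
            inter_match_distance=star[1] - mature[0],
            matched_reference=PrecursorReference("f", "s", star[1] - mature[0]),
        )
        return est, c

    def test_centered_window(self):
        est, c = self._candidate((120, 141), (160, 181))  # midpoint 150
        out = extract_window(est, c, 200)
        assert out.window == (50, 250)
        assert len(out.window_seq) == 200

    def test_left_truncation(self):
        est, c = self._candidate((5, 26), (15, 36))  # midpoint 20
        out = extract_window(est, c, 200)
        assert out.window == (0, 120)

    def test_right_truncation(self):
        est, c = self._candidate((575, 596), (584, 600))  # midpoint near end
        out = extract_window(est, c, 200)
        assert out.window[1] == 600
        assert out.window[0] == max(0, out.window[1] - len(out.window_seq))
        assert len(out.window_seq) == 600 - out.window[0]


class TestFold:
    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 31))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        _dot, energy, pairs = fold_nussinov(seq)
        assert energy == oracle_fold_min_energy(seq)
        # reported pairs are consistent with the reported energy
        e = {"GC": -3.0, "CG": -3.0, "AT": -2.0, "TA": -2.0, "GT": -1.0,
             "TG": -1.0}
        assert energy == sum(e[seq[i] + seq[j]] for i, j in pairs)
        for i, j in pairs:
            assert j - i > 3

    def test_planted_hairpin_window_validates(self, rng):
        est, ref, _ = _hairpin_est(rng)
        irs = find_inverted_repeats(est)
        c = match_mature_and_star(irs[0], est, [MIR], [ref])[0]
        c = extract_window(est, c, 200)
        out = fold_and_validate(c)
        assert out.status == "validated"
        assert out.fold.count("(") == out.fold.count(")") > 0

    def test_shuffled_windows_are_dropped(self, rng):
        est, ref, _ = _hairpin_est(rng)
        irs = find_inverted_repeats(est)
        c = match_mature_and_star(irs[0], est, [MIR], [ref])[0]
        c = extract_window(est, c, 200)
        shuffle_rng = np.random.default_rng(11)
        dropped = sum(
            fold_and_validate(
                dataclasses.replace(
                    c, window_seq=mononuc_shuffle(c.window_seq, shuffle_rng)
                )
            ).status
            == "dropped"
            for _ in range(20)
        )
        assert dropped >= 18

    def test_missing_window_raises(self, rng):
        est, ref, _ = _hairpin_est(rng)
        irs = find_inverted_repeats(est)
        c = match_mature_and_star(irs[0], est, [MIR], [ref])[0]
        with pytest.raises(ValueError, match="window"):
            fold_and_validate(c)

    def test_tightening_thresholds_never_grows_validated_set(self, rng):
        est, ref, _ = _hairpin_est(rng)
        irs = find_inverted_repeats(est)
        c = extract_window(
            est, match_mature_and_star(irs[0], est, [MIR], [ref])[0], 200
        )
        loose = PrecursorParams()
        tighter = [
            dataclasses.replace(loose, min_paired_fraction_in_mature=0.95),
            dataclasses.replace(loose, min_stem_run_fraction=0.99),
            dataclasses.replace(loose, energy_density_cutoff=-5.0),
        ]
        base_ok = fold_and_validate(c, params=loose).status == "validated"
        for t in tighter:
            ok = fold_and_validate(c, params=t).status == "validated"
            assert (not ok) or base_ok
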