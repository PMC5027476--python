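"""Clone bisulfite analysis: alignment, calling, QC, patterns, comparison."""

import itertools
import math

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

import methrecover as mr
from methrecover.bisulfite import (
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    read_fasta,
)
from methrecover.exceptions import ValidationError


def brute_force_best_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Enumerate every global alignment recursively and return the best score."""

    best = -10**9
    stack = [(0, 0, 0)]
    while stack:
        i, j, score = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            stack.append((i + 1, j + 1, score + s))
        if i < len(a):
            stack.append((i + 1, j, score + gap))
        if j < len(b):
            stack.append((i, j + 1, score + gap))
    return best


class TestAlignGlobal:
    def test_identical_sequences_score_length_no_gaps(self):
        aln = mr.align_global("ACGTACGTAC", "ACGTACGTAC")
        assert aln.score == 10
        assert "-" not in aln.query_aligned + aln.ref_aligned

    def test_single_deletion_hand_checked(self):
        # reference ACGTAC vs clone ACTAC: 5 matches - one gap = 3
        aln = mr.align_global("ACTAC", "ACGTAC")
        assert aln.score == 3
        assert aln.ref_aligned.replace("-", "") == "ACGTAC"
        assert aln.query_aligned.count("-") == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            mr.align_global("", "ACGT")

    def test_exhaustive_enumeration_all_short_pairs(self):
        """DP score equals brute-force enumeration for every pair up to length 3."""
        seqs = ["".join(p) for n in (1, 2, 3)
                for p in itertools.product("ACGT", repeat=n)]
        for a in seqs:
            for b in seqs:
                assert mr.align_global(a, b).score == brute_force_best_score(a, b)

    @pytest.mark.parametrize("seed", range(60))
    def test_exhaustive_enumeration_sampled_longer_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
        assert mr.align_global(a, b).score == brute_force_best_score(a, b)

    @pytest.mark.parametrize("seed", range(20))
    def test_score_matches_biopython_aligner(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list("ACGT"), 30))
        b = "".join(rng.choice(list("ACGT"), rng.integers(20, 35)))
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        assert mr.align_global(a, b).score == aligner.score(a, b)

    @settings(derandomize=True, max_examples=100)
    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=25))
    def test_self_alignment_scores_length_property(self, seq):
        aln = mr.align_global(seq, seq)
        assert aln.score == len(seq)
        assert aln.query_aligned == aln.ref_aligned == seq

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=12),
        b=st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_score_symmetric_in_arguments_property(self, a, b):
        assert mr.align_global(a, b).score == mr.align_global(b, a).score

    def test_traceback_deterministic(self):
        a1 = mr.align_global("ACGT", "AGT")
        a2 = mr.align_global("ACGT", "AGT")
        assert (a1.query_aligned, a1.ref_aligned) == (a2.query_aligned, a2.ref_aligned)


class TestAmplicon:
    def test_cpg_autodetection(self):
        amp = mr.Amplicon.from_sequence("a", "ACGTTACGAA")
        assert amp.cpg_positions == (1, 6)

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValidationError):
            mr.Amplicon("a", "ACGT", cpg_positions=(0,))


class TestCallMethylation:
    def test_single_site_methylated_with_converted_noncpg(self):
        amp = mr.Amplicon.from_sequence("a", "ACCGT")  # CpG C at index 2
        call = mr.call_methylation(mr.align_global("ATCGT", amp.reference_sequence), amp)
        assert call.states == (METHYLATED,)
        assert call.conversion_rate == pytest.approx(1.0)

    def test_single_site_unmethylated(self):
        amp = mr.Amplicon.from_sequence("a", "ACCGT")
        call = mr.call_methylation(mr.align_global("ATTGT", amp.reference_sequence), amp)
        assert call.states == (UNMETHYLATED,)
        assert call.conversion_rate == pytest.approx(1.0)

    def test_partial_conversion_rate(self):
        # non-CpG Cs at 0, 2, 4; CpG C at 5; two of three non-CpG Cs read T
        amp = mr.Amplicon.from_sequence("a", "CACACCGA")
        clone = "TATACCGA"  # C0->T, C2->T, C4 stays C, CpG C stays C
        call = mr.call_methylation(mr.align_global(clone, amp.reference_sequence), amp)
        assert call.conversion_rate == pytest.approx(2 / 3)
        assert call.states == (METHYLATED,)

    def test_gap_at_cpg_is_missing(self):
        amp = mr.Amplicon.from_sequence("a", "AACGTTAA")
        clone = "AATTAA"  # CpG deleted
        call = mr.call_methylation(mr.align_global(clone, amp.reference_sequence), amp)
        assert call.states == (MISSING,)

    def test_bisulfite_changes_not_counted_as_mismatches(self):
        amp = mr.Amplicon.from_sequence("a", "ACCGTACTA")
        clone = "ATCGTACTA"  # only C1->T, a bisulfite-expected change
        call = mr.call_methylation(mr.align_global(clone, amp.reference_sequence), amp)
        assert call.identity == pytest.approx(1.0)

    def test_wrong_reference_rejected(self):
        amp = mr.Amplicon.from_sequence("a", "ACGTACGT")
        aln = mr.align_global("ACGT", "ACGT")
        with pytest.raises(ValidationError, match="reference"):
            mr.call_methylation(aln, amp)


def _call(clone_id, states, conv=1.0, ident=1.0):
    return mr.CloneCall(clone_id=clone_id, states=tuple(states),
                        conversion_rate=conv, identity=ident)


class TestBuildPattern:
    def test_fully_methylated_clones_give_100_percent(self):
        amp = mr.Amplicon.from_sequence("a", "AACGACGAA")
        calls = [_call(f"c{i}", [METHYLATED, METHYLATED]) for i in range(4)]
        pattern = mr.build_pattern(amp, calls)
        assert pattern.overall_percent == 100.0

    def test_hand_counted_mixed_pattern(self):
        amp = mr.Amplicon.from_sequence("a", "AACGACGAA")
        calls = [
            _call("c1", [METHYLATED, METHYLATED]),
            _call("c2", [METHYLATED, UNMETHYLATED]),
            _call("c3", [UNMETHYLATED, METHYLATED]),
        ]
        pattern = mr.build_pattern(amp, calls)
        assert pattern.overall_percent == pytest.approx(100 * 4 / 6)
        assert pattern.per_cpg_percent == pytest.approx([100 * 2 / 3, 100 * 2 / 3])

    def test_low_conversion_clone_excluded_with_reason(self):
        amp = mr.Amplicon.from_sequence("a", "AACGAA")
        calls = [_call("good", [METHYLATED]), _call("bad", [METHYLATED], conv=0.5)]
        pattern = mr.build_pattern(amp, calls)
        assert [c.clone_id for c in pattern.calls] == ["good"]
        assert ("bad", "conversion") in pattern.excluded

    def test_all_excluded_names_dominant_reason(self):
        amp = mr.Amplicon.from_sequence("a", "AACGAA")
        calls = [_call("b1", [METHYLATED], conv=0.5),
                 _call("b2", [METHYLATED], conv=0.6),
                 _call("b3", [METHYLATED], ident=0.1)]
        with pytest.raises(ValidationError, match="conversion"):
            mr.build_pattern(amp, calls)

    def test_overall_is_weighted_mean_of_per_cpg(self):
        amp = mr.Amplicon.from_sequence("a", "AACGACGAA")
        calls = [
            _call("c1", [METHYLATED, MISSING]),
            _call("c2", [UNMETHYLATED, METHYLATED]),
            _call("c3", [METHYLATED, METHYLATED]),
        ]
        pattern = mr.build_pattern(amp, calls)
        weights = [3, 2]  # non-missing calls per CpG
        weighted = sum(
            w * p for w, p in zip(weights, pattern.per_cpg_percent)
        ) / sum(weights)
        assert pattern.overall_percent == pytest.approx(weighted)


class TestComparePatterns:
    def _pattern(self, amp, n, frac):
        n_meth = round(n * frac)
        calls = [_call(f"m{i}", [METHYLATED]) for i in range(n_meth)]
        calls += [_call(f"u{i}", [UNMETHYLATED]) for i in range(n - n_meth)]
        return mr.build_pattern(amp, calls)

    def test_identical_patterns_zero_difference(self):
        amp = mr.Amplicon.from_sequence("a", "AACGAA")
        p = self._pattern(amp, 10, 0.5)
        out = mr.compare_patterns(p, p, n_bootstrap=200, seed=1)
        assert out.difference == 0.0

    def test_extreme_difference_is_100_points(self):
        amp = mr.Amplicon.from_sequence("a", "AACGAA")
        out = mr.compare_patterns(
            self._pattern(amp, 10, 0.0), self._pattern(amp, 10, 1.0),
            n_bootstrap=100, seed=2,
        )
        assert out.difference == pytest.approx(100.0)

    def test_amplicon_mismatch_rejected(self):
        a = mr.Amplicon.from_sequence("a", "AACGAA")
        b = mr.Amplicon.from_sequence("b", "TTCGTT")
        with pytest.raises(ValidationError):
            mr.compare_patterns(self._pattern(a, 5, 0.4), self._pattern(b, 5, 0.4))

    def test_bootstrap_interval_covers_simulated_truth(self):
        """Clone-resampling CI covers the true difference in >= 90% of runs."""
        amp = mr.simulate_amplicon("iap_like", length=200, n_cpgs=6, seed=0)
        p_low, p_high = 0.3, 0.7  # true difference: 40 points
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            clones_a, _ = mr.simulate_bisulfite_clones(
                amp, [p_low] * 6, n_clones=20, seed=10_000 + rep)
            clones_b, _ = mr.simulate_bisulfite_clones(
                amp, [p_high] * 6, n_clones=20, seed=20_000 + rep)
            pa = mr.analyze_clones(amp, clones_a)
            pb = mr.analyze_clones(amp, clones_b)
            out = mr.compare_patterns(pa, pb, n_bootstrap=300, seed=rep)
            if out.ci_low <= 40.0 <= out.ci_high:
                covered += 1
        assert covered / n_rep >= 0.90


class TestLollipopAndFasta:
    def test_direct_mapping(self):
        amp = mr.Amplicon.from_sequence("a", "AACGACGAA")
        pattern = mr.build_pattern(amp, [_call("c", [METHYLATED, UNMETHYLATED])])
        assert mr.render_lollipop_text(pattern) == "●○"

    def test_rendering_stable_and_no_empty_rows(self):
        amp = mr.simulate_amplicon("x", length=150, n_cpgs=5, seed=3)
        clones, _ = mr.simulate_bisulfite_clones(amp, [0.5] * 5, 12, seed=4)
        pattern = mr.analyze_clones(amp, clones)
        text = mr.render_lollipop_text(pattern)
        assert text == mr.render_lollipop_text(pattern)
        assert all(row for row in text.splitlines())
        assert len(text.splitlines()) == len(pattern.calls)

    def test_fasta_round_trip(self, tmp_path):
        p = tmp_path / "clones.fasta"
        p.write_text(">c1\nACGT\n>c2\nTTAAC\n")
        assert read_fasta(p) == [("c1", "ACGT"), ("c2", "TTAAC")]


class TestEstimatorRecovery:
    def test_per_cpg_frequencies_within_binomial_ci(self):
        """Noise-free chemistry: observed per-CpG frequencies fall inside the
        exact binomial 99% interval around the simulated probabilities."""
        from scipy.stats import binom

        amp = mr.simulate_amplicon("amp", length=300, n_cpgs=8, seed=5)
        probs = [0.1, 0.25, 0.4, 0.5, 0.6, 0.75, 0.9, 1.0]
        n = 50
        clones, truth = mr.simulate_bisulfite_clones(
            amp, probs, n_clones=n, conversion_failure=0.0, seq_error=0.0, seed=6)
        pattern = mr.analyze_clones(amp, clones)
        assert len(pattern.calls) == n
        for k, p in enumerate(probs):
            observed = round(pattern.per_cpg_percent[k] / 100 * n)
            lo, hi = binom.interval(0.99, n, p)
            assert lo <= observed <= hi
            # calls agree with the simulator's own truth exactly
            assert observed == truth[:, k].sum()

    def test_conversion_failure_detected_by_qc_metric(self):
        amp = mr.simulate_amplicon("amp", length=400, n_cpgs=6, seed=7)
        clones, _ = mr.simulate_bisulfite_clones(
            amp, [0.8] * 6, n_clones=50, conversion_failure=0.02, seed=8)
        pattern = mr.analyze_clones(amp, clones, min_conversion=0.90)
        rates = [c.conversion_rate for c in pattern.calls]
        assert np.mean(rates) == pytest.approx(0.98, abs=0.01)

    def test_incomplete_conversion_clone_filtered(self):
        amp = mr.simulate_amplicon("amp", length=400, n_cpgs=6, seed=9)
        clones, _ = mr.simulate_bisulfite_clones(
            amp, [0.8] * 6, n_clones=30, conversion_failure=0.5, seed=10)
        with pytest.raises(ValidationError, match="conversion"):
            mr.analyze_clones(amp, clones, min_conversion=0.95)
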