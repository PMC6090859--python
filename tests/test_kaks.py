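"""Unit tests for NG86 counting, Ka/Ks distances and region calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from camrewire import kaks, simulate
from camrewire.kaks import (
    SENSE_CODONS,
    CodonAlignment,
    KaKsEstimate,
    KaKsProfile,
    call_regions,
    classify_comparisons,
    kaks_global,
    ng86_diffs,
    ng86_sites,
    sliding_profile,
    strip_gaps,
)

from oracles import oracle_diffs, oracle_sites


def _aln(seq_a, seq_b, gene="g"):
    return CodonAlignment(gene, "spA", "spB", seq_a, seq_b)


class TestNG86Sites:
    @pytest.mark.parametrize(
        "codon,expected",
        [("TTT", (1 / 3, 8 / 3)), ("TGG", (0.0, 3.0)), ("ATG", (0.0, 3.0))],
    )
    def test_worked_examples(self, codon, expected):
        assert ng86_sites(codon) == pytest.approx(expected)

    def test_all_sense_codons_match_enumeration_oracle_and_sum_to_three(self):
        for codon in SENSE_CODONS:
            syn, non = ng86_sites(codon)
            osyn, onon = oracle_sites(codon)
            assert syn == pytest.approx(float(osyn), abs=1e-12)
            assert non == pytest.approx(float(onon), abs=1e-12)
            assert syn + non == pytest.approx(3.0, abs=1e-12)

    def test_rejects_stop_and_ambiguous(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")
        with pytest.raises(ValueError):
            ng86_sites("NNT")


class TestNG86Diffs:
    def test_identity_and_single_synonymous_change(self):
        assert ng86_diffs("TTT", "TTT") == (0.0, 0.0)
        assert ng86_diffs("TTT", "TTC") == (1.0, 0.0)

    def test_two_step_pathway_average(self):
        # TTT->GTT->GTA (1 nonsyn + 1 syn) and TTT->TTA->GTA (2 nonsyn)
        sd, nd = ng86_diffs("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)
        assert (sd, nd) == pytest.approx((0.5, 1.5))

    def test_symmetry_and_hamming_sum_against_oracle_all_pairs(self):
        for ca in SENSE_CODONS:
            for cb in SENSE_CODONS:
                sd, nd = ng86_diffs(ca, cb)
                assert (sd, nd) == ng86_diffs(cb, ca)
                ham = sum(x != y for x, y in zip(ca, cb))
                assert sd + nd == pytest.approx(ham, abs=1e-12)
                osd, ond = oracle_diffs(ca, cb)
                assert sd == pytest.approx(float(osd), abs=1e-12)
                assert nd == pytest.approx(float(ond), abs=1e-12)


class TestStripGaps:
    def test_gapped_codon_column_removed_whole(self):
        aln = strip_gaps("g", "a", "b", "ATG---AAA", "ATGCCCAAA")
        assert aln.seq_a == "ATGAAA"
        assert aln.seq_b == "ATGAAA"

    def test_no_gaps_is_identity(self):
        aln = strip_gaps("g", "a", "b", "ATGAAA", "ATGCCC")
        assert (aln.seq_a, aln.seq_b) == ("ATGAAA", "ATGCCC")

    def test_frame_breaking_gap_rejected(self):
        with pytest.raises(ValueError, match="frame-breaking"):
            strip_gaps("g", "a", "b", "AT-AAA", "ATGAAA")

    def test_stop_after_stripping_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            strip_gaps("g", "a", "b", "ATGTAA", "ATGTAA")


class TestKaKsGlobal:
    def test_identical_sequences_zero_distances_ratio_undefined(self):
        est = kaks_global(_aln("ATGAAACCC", "ATGAAACCC"))
        assert est.ka == est.ks == 0.0
        assert est.ratio is None

    def test_synonymous_only_differences_give_ratio_zero(self):
        # one synonymous change (CCC->CCT) in an otherwise identical gene
        est = kaks_global(_aln("TTT" * 7 + "CCC", "TTT" * 7 + "CCT"))
        assert est.ka == 0.0
        assert est.ks > 0
        assert est.ratio == 0.0

    def test_swap_invariance(self):
        a, _ = simulate.simulate_codon_pair(
            60, simulate.OmegaMap.uniform(60, 1.0), 0.4, seed=3
        )
        fwd = kaks_global(a)
        rev = kaks_global(_aln(a.seq_b, a.seq_a))
        assert fwd.ka == pytest.approx(rev.ka)
        assert fwd.ks == pytest.approx(rev.ks)

    @pytest.mark.parametrize("kappa", [1.0, 2.0])
    def test_neutral_simulation_mean_ratio_near_one(self, kappa):
        ratios = []
        for s in range(100):
            aln, _ = simulate.simulate_codon_pair(
                200, simulate.OmegaMap.uniform(200, 1.0), 0.3, kappa=kappa, seed=s
            )
            r = kaks_global(aln).ratio
            if r is not None:
                ratios.append(r)
        assert 0.8 <= np.mean(ratios) <= 1.2

    def test_site_counts_sum_to_three_per_codon(self):
        aln = _aln("ATGAAACCCTTT", "ATGAAGCCATTC")
        est = kaks_global(aln)
        assert est.syn_sites + est.nonsyn_sites == pytest.approx(3 * aln.n_codons)


class TestSlidingProfile:
    def test_single_window_equals_global(self):
        aln, _ = simulate.simulate_codon_pair(
            50, simulate.OmegaMap.uniform(50, 1.0), 0.4, seed=9
        )
        prof = sliding_profile(aln, window=50)
        assert len(prof.windows) == 1
        est, glob = prof.windows[0][1], kaks_global(aln)
        assert est.syn_diffs == pytest.approx(glob.syn_diffs)
        assert est.ka == pytest.approx(glob.ka)
        assert est.ks == pytest.approx(glob.ks)

    def test_window_count_arithmetic(self):
        aln, _ = simulate.simulate_codon_pair(
            52, simulate.OmegaMap.uniform(52, 1.0), 0.2, seed=2
        )
        prof = sliding_profile(aln, window=50, step=1)
        assert [s for s, _ in prof.windows] == [0, 1, 2]

    def test_too_short_gene_rejected(self):
        aln, _ = simulate.simulate_codon_pair(
            30, simulate.OmegaMap.uniform(30, 1.0), 0.2, seed=2
        )
        with pytest.raises(ValueError, match="too short"):
            sliding_profile(aln, window=50)

    def test_planted_omega_raises_windowed_ratio_monotonically(self):
        """Mean in-segment windowed ratio increases with the planted omega."""
        means = []
        for omega in (0.5, 1.0, 2.0, 4.0):
            om = simulate.OmegaMap.planted(300, 100, 150, omega, 0.2)
            vals = []
            for s in range(50):
                aln, _ = simulate.simulate_codon_pair(300, om, 0.3, seed=600 + s)
                prof = sliding_profile(aln)
                inside = [
                    e.ratio
                    for st, e in prof.windows
                    if 100 <= st and st + 50 <= 150 and e.ratio is not None
                ]
                vals.extend(inside)
            means.append(np.mean(vals))
        assert means == sorted(means)


def _fake_profile(ratios, window=50):
    """Profile with prescribed per-window ratios via synthetic counts."""
    windows = []
    for i, r in enumerate(ratios):
        if r is None:
            est = KaKsEstimate(100.0, 200.0, 0.0, 10.0, 0.0, 0.05)
        else:
            ks = 0.05
            est = KaKsEstimate(100.0, 200.0, 5.0, 10.0, ks, r * ks)
        windows.append((i, est))
    return KaKsProfile("g", window, 1, window + len(ratios) - 1, windows)


class TestCallRegions:
    def test_no_windows_above_one_gives_empty(self):
        assert call_regions(_fake_profile([0.5] * 40), min_run=3) == []

    def test_all_windows_above_one_gives_single_spanning_region(self):
        ratios = list(np.linspace(1.5, 2.5, 30))
        regions = call_regions(_fake_profile(ratios), min_run=3)
        assert len(regions) == 1
        assert regions[0].start_codon == 0
        assert regions[0].end_codon == 29 + 50
        assert regions[0].n_windows == 30

    def test_undefined_ratio_breaks_runs(self):
        ratios = [2.0, 2.1, 2.2, None, 2.0, 2.1]
        regions = call_regions(_fake_profile(ratios), min_run=3)
        assert len(regions) == 1
        assert regions[0].n_windows == 3

    def test_short_runs_below_min_run_dropped(self):
        ratios = [2.0, 2.0, 0.5, 2.0, 2.0]
        assert call_regions(_fake_profile(ratios), min_run=3) == []

    def test_degenerate_positive_variance_flagged_significant(self):
        regions = call_regions(_fake_profile([2.0] * 5), min_run=3)
        assert len(regions) == 1
        assert regions[0].degenerate_variance
        assert regions[0].p_value == 0.0
        assert regions[0].significant


class TestClassifyComparisons:
    def _regions(self, significant=True):
        return [
            kaks.PositiveRegion("g", "c", 0, 50, 10, 2.0, 0.001, significant)
        ]

    def test_hits_in_all_comparisons_is_set_1a(self):
        by_comp = {"At": self._regions(), "Os": self._regions(), "Zm": self._regions()}
        lab = classify_comparisons("g", by_comp, ["At", "Os"], ["Zm"])
        assert lab.label == "set_1a"

    def test_c3_only_hits_is_set_1b(self):
        by_comp = {"At": self._regions(), "Os": self._regions(), "Zm": []}
        lab = classify_comparisons("g", by_comp, ["At", "Os"], ["Zm"])
        assert lab.label == "set_1b"

    def test_single_comparison_hit_is_none(self):
        by_comp = {"At": self._regions(), "Os": [], "Zm": []}
        lab = classify_comparisons("g", by_comp, ["At", "Os"], ["Zm"])
        assert lab.label == "none"

    def test_missing_comparison_unclassifiable(self):
        lab = classify_comparisons("g", {"At": self._regions()}, ["At", "Os"], ["Zm"])
        assert lab.label == "none"

    def test_nonsignificant_regions_count_when_relaxed(self):
        by_comp = {
            "At": self._regions(significant=False),
            "Os": self._regions(significant=False),
            "Zm": [],
        }
        assert (
            classify_comparisons("g", by_comp, ["At", "Os"], ["Zm"]).label == "none"
        )
        assert (
            classify_comparisons(
                "g", by_comp, ["At", "Os"], ["Zm"], require_significant=False
            ).label
            == "set_1b"
        )


@given(st.integers(0, 2**31 - 1))
def test_alignment_invariants_hold_for_any_seed(seed):
    """Simulated alignments always satisfy the codon-alignment contract."""
    aln, _ = simulate.simulate_codon_pair(
        12, simulate.OmegaMap.uniform(12, 1.5), 0.5, seed=seed
    )
    est = kaks_global(aln)
    assert est.syn_sites + est.nonsyn_sites == pytest.approx(36.0)
    ham = sum(a != b for a, b in zip(aln.seq_a, aln.seq_b))
    assert est.syn_diffs + est.nonsyn_diffs == pytest.approx(ham)
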