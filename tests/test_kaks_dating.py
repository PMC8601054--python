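"""Nei-Gojobori counting, Jukes-Cantor correction, clock dating, binning."""

import math
from itertools import permutations

import numpy as np
import pytest

from ringscan.io_formats import AlignedRecord, CdsRecord
from ringscan.kaks_dating import (
    ClockParams, CodonAlignmentPair, KaKsResult, backtranslate_align,
    bin_duplications, count_codon_differences, divergence_time, ng86,
    synonymous_sites, translate_codon,
)
from ringscan.synthetic_data import _NON_STOP_CODONS, evolve_codon_pair

STOPS = {"TAA", "TAG", "TGA"}


def oracle_pathways(codon_a: str, codon_b: str):
    """Independent pathway enumeration: explicit step lists per ordering."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0

    def steps_for(order):
        current, steps = codon_a, []
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            steps.append((current, nxt))
            current = nxt
        return steps

    all_paths = [steps_for(order) for order in permutations(diffs)]
    valid = [
        p for p in all_paths
        if not any(b in STOPS for _a, b in p[:-1])
    ]
    if not valid:
        valid = all_paths
    syn = nonsyn = 0.0
    for path in valid:
        for a, b in path:
            aa_a = "*" if a in STOPS else translate_codon(a)
            aa_b = "*" if b in STOPS else translate_codon(b)
            if aa_a == aa_b:
                syn += 1
            else:
                nonsyn += 1
    return syn / len(valid), nonsyn / len(valid)


def pair_from_cds(a: CdsRecord, b: CdsRecord) -> CodonAlignmentPair:
    split = lambda s: tuple(s[i:i + 3] for i in range(0, len(s), 3))
    return CodonAlignmentPair(a.id, b.id, split(a.sequence), split(b.sequence))


class TestSitesAndDifferences:
    def test_fourfold_codon_has_one_synonymous_site(self):
        assert synonymous_sites("GGG") == pytest.approx(1.0)  # Gly, 4-fold

    def test_phe_codon_has_a_third_of_a_site(self):
        assert synonymous_sites("TTT") == pytest.approx(1 / 3)

    def test_single_synonymous_difference(self):
        assert count_codon_differences("TTT", "TTC") == (1.0, 0.0)

    def test_single_nonsynonymous_difference(self):
        assert count_codon_differences("TTT", "TTA") == (0.0, 1.0)  # Phe->Leu

    @pytest.mark.parametrize("seed", range(10))
    def test_multi_position_codons_match_pathway_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            ca, cb = (
                _NON_STOP_CODONS[i]
                for i in rng.integers(0, len(_NON_STOP_CODONS), size=2)
            )
            assert count_codon_differences(ca, cb) == \
                pytest.approx(oracle_pathways(ca, cb))

    def test_random_twenty_codon_pairs_match_oracle_exactly(self):
        rng = np.random.default_rng(314)
        for _ in range(60):
            a = [_NON_STOP_CODONS[i]
                 for i in rng.integers(0, len(_NON_STOP_CODONS), size=20)]
            b = list(a)
            for idx in rng.choice(20, size=3, replace=False):
                b[idx] = _NON_STOP_CODONS[rng.integers(0, len(_NON_STOP_CODONS))]
            pair = pair_from_cds(CdsRecord("a", "".join(a)),
                                 CdsRecord("b", "".join(b)))
            result = ng86(pair)
            syn = nonsyn = 0.0
            for ca, cb in zip(pair.codons_a, pair.codons_b):
                s, n = oracle_pathways(ca, cb)
                syn += s
                nonsyn += n
            assert result.s_diffs == pytest.approx(syn)
            assert result.n_diffs == pytest.approx(nonsyn)


class TestNg86:
    def test_identical_pair_is_zero_everywhere(self):
        cds = CdsRecord("a", "ATGGCTGGT")
        result = ng86(pair_from_cds(cds, CdsRecord("b", cds.sequence)))
        assert result.ka == 0.0 and result.ks == 0.0
        assert result.ratio is None
        assert result.t_mya == 0.0

    def test_lone_synonymous_change_gives_zero_ka_positive_ks(self):
        a = CdsRecord("a", "ATGGCTGGTCTTTTT")
        b = CdsRecord("b", "ATGGCTGGTCTTTTC")  # TTT->TTC, Phe->Phe
        result = ng86(pair_from_cds(a, b))
        assert result.n_diffs == 0.0 and result.s_diffs == 1.0
        assert result.ka == 0.0
        assert result.ks > 0.0

    def test_site_conservation(self):
        a, b = evolve_codon_pair(120, 0.1, 0.05, seed=6)
        result = ng86(pair_from_cds(a, b))
        assert result.n_sites + result.s_sites == pytest.approx(3 * 120, abs=1e-9)

    def test_symmetry_in_the_two_sequences(self):
        a, b = evolve_codon_pair(80, 0.15, 0.03, seed=9)
        fwd = ng86(pair_from_cds(a, b))
        rev = ng86(pair_from_cds(b, a))
        assert fwd.ka == pytest.approx(rev.ka)
        assert fwd.ks == pytest.approx(rev.ks)
        assert fwd.s_sites == pytest.approx(rev.s_sites)

    def test_gapped_and_n_columns_dropped_pairwise(self):
        pair = CodonAlignmentPair(
            "a", "b",
            ("ATG", "---", "GGT", "TTN"),
            ("ATG", "GCT", "GGT", "TTT"),
        )
        result = ng86(pair)
        assert result.n_sites + result.s_sites == pytest.approx(6.0)

    def test_saturation_flagged_when_correction_leaves_domain(self):
        # single codon, one synonymous diff: pS = 3 >= 3/4
        result = ng86(pair_from_cds(CdsRecord("a", "TTT"), CdsRecord("b", "TTC")))
        assert result.saturated
        assert result.ks is None

    def test_parameter_recovery_within_three_standard_errors(self):
        target_ps, target_pn, n = 0.2, 0.02, 500
        a, b = evolve_codon_pair(n, target_ps, target_pn, seed=77)
        result = ng86(pair_from_cds(a, b))
        ks_target = -0.75 * math.log(1 - 4 / 3 * target_ps)
        ka_target = -0.75 * math.log(1 - 4 / 3 * target_pn)
        se_s = math.sqrt(target_ps * (1 - target_ps) / result.s_sites)
        se_n = math.sqrt(target_pn * (1 - target_pn) / result.n_sites)
        assert abs(result.ks - ks_target) <= 3 * se_s / (1 - 4 / 3 * target_ps)
        assert abs(result.ka - ka_target) <= 3 * se_n / (1 - 4 / 3 * target_pn)
        assert result.ratio < 1


class TestBacktranslate:
    def test_gap_expands_to_codon_gap(self):
        pair = backtranslate_align(
            AlignedRecord("g1", "MK-R"),
            AlignedRecord("g2", "MKQR"),
            CdsRecord("g1", "ATGAAACGT"),
            CdsRecord("g2", "ATGAAACAACGT"),
        )
        assert pair.codons_a == ("ATG", "AAA", "---", "CGT")
        assert pair.codons_b == ("ATG", "AAA", "CAA", "CGT")

    def test_terminal_stop_is_trimmed(self):
        pair = backtranslate_align(
            AlignedRecord("g1", "MK"),
            AlignedRecord("g2", "MK"),
            CdsRecord("g1", "ATGAAATAA"),
            CdsRecord("g2", "ATGAAG"),
        )
        assert pair.codons_a == ("ATG", "AAA")

    def test_length_mismatch_names_the_gene(self):
        with pytest.raises(ValueError, match="g1"):
            backtranslate_align(
                AlignedRecord("g1", "MKR"),
                AlignedRecord("g2", "MKR"),
                CdsRecord("g1", "ATGAAA"),
                CdsRecord("g2", "ATGAAACGT"),
            )

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            backtranslate_align(
                AlignedRecord("g1", "MWR"),
                AlignedRecord("g2", "MKR"),
                CdsRecord("g1", "ATGAAACGT"),  # AAA is Lys, protein says Trp
                CdsRecord("g2", "ATGAAACGT"),
            )

    def test_degapping_codon_rows_recovers_the_cds(self):
        cds_a = CdsRecord("g1", "ATGAAACGT")
        pair = backtranslate_align(
            AlignedRecord("g1", "MK-R"), AlignedRecord("g2", "MKQR"),
            cds_a, CdsRecord("g2", "ATGAAACAACGT"),
        )
        rebuilt = "".join(c for c in pair.codons_a if c != "---")
        assert rebuilt == cds_a.sequence


class TestClockAndBinning:
    def test_stated_formula_values(self):
        assert divergence_time(0.03) == pytest.approx(1.0)
        assert divergence_time(0.0) == 0.0
        assert divergence_time(0.27) == pytest.approx(9.0)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    def test_t_strictly_increasing_in_ks(self):
        clock = ClockParams()
        times = [divergence_time(ks, clock) for ks in (0.01, 0.1, 0.5, 2.0)]
        assert times == sorted(times) and len(set(times)) == 4

    def _result(self, ks, saturated=False):
        t = None if ks is None else divergence_time(ks)
        return KaKsResult("a", "b", 0.01, ks, 100, 50, 1, 1, saturated, t)

    def test_direct_binning_and_means(self):
        results = [self._result(ks) for ks in (0.03, 0.06, 0.9)]  # T = 1, 2, 30
        bins = bin_duplications(results, boundary_mya=15)
        assert bins.counts == (2, 1, 0)
        assert bins.recent_mean_t == pytest.approx(1.5)
        assert bins.ancient_mean_t == pytest.approx(30.0)

    def test_saturated_pairs_are_excluded(self):
        results = [self._result(2.5, saturated=True),
                   self._result(None),
                   self._result(4.0)]  # above the Ks cutoff
        bins = bin_duplications(results)
        assert bins.counts == (0, 0, 3)

    def test_partition_of_pairs_is_complete(self):
        results = [self._result(ks) for ks in (0.01, 0.2, 0.8, 1.5, 3.5, None)]
        bins = bin_duplications(results)
        assert sum(bins.counts) == len(results)
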