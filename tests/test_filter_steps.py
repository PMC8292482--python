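"""Unit behaviour of each cascade step, with brute-force oracles."""

import numpy as np
import pytest

from isofilter.filter_pipeline import (
    best_call_per_strain,
    flag_within_strain_concordance,
    step_allele_balance,
    step_cross_platform_dispute,
    step_depth,
    step_equal_best,
    step_homopolymer_deletions,
    step_low_quality_discordant,
    step_quality_tier,
    step_require_difference,
    step_uncertain,
)
from isofilter.vcf_model import FilterConfig, Platform, PlatformCall, SampleKey, Strain

from conftest import PLATFORMS, make_variant

CFG = FilterConfig()


def removed(step, variant, *extra):
    kept, gone = step([variant], *extra, CFG)
    assert len(kept) + len(gone) == 1
    return len(gone) == 1


HOMREF3 = [((0, 0), 40, 20, (20, 0))] * 3
HOMALT3 = [((1, 1), 40, 20, (0, 20))] * 3


class TestDepth:
    @pytest.mark.parametrize(
        "dps, expect_removed",
        [
            ((1, 2, 1, 2, 1, 2), True),  # total 9 < 10
            ((2, 2, 2, 2, 1, 1), False),  # total 10, boundary kept
            ((20, 20, 20, 20, 20, 301), True),  # single-sample excess
            ((20, 20, 20, 20, 20, 300), False),  # boundary: 300 allowed
        ],
    )
    def test_boundaries(self, dps, expect_removed):
        v = make_variant(
            wli=[((1, 1), 40, dps[i], None) for i in range(3)],
            wmi=[((0, 0), 40, dps[3 + i], None) for i in range(3)],
        )
        assert removed(step_depth, v) is expect_removed

    def test_absent_depth_counts_zero(self):
        v = make_variant(wli=[((1, 1), 40)] * 3, wmi=[((0, 0), 40)] * 3)
        assert removed(step_depth, v) is True


class TestBestCall:
    def test_max_gq_selected_and_missing_breaks_concordance(self):
        v = make_variant(
            wli=[((1, 1), 40, 20, None), ((1, 1), 12, 20, None), (None,)],
            wmi=HOMREF3,
        )
        s = best_call_per_strain(v, CFG)[Strain.WLI]
        assert s.best_call == (1, 1)
        assert s.best_gq == 40
        assert s.concordant is False
        assert s.n_missing == 1

    def test_all_identical_is_concordant(self):
        v = make_variant(wli=HOMALT3, wmi=[((0, 0), 50, 20, None)] * 3)
        s = best_call_per_strain(v, CFG)[Strain.WMI]
        assert s.concordant is True
        assert s.disputed_q30 is False

    def test_all_missing_strain(self):
        v = make_variant(wli=[(None,)] * 3, wmi=HOMREF3)
        s = best_call_per_strain(v, CFG)[Strain.WLI]
        assert s.best_call is None and s.best_gq is None and s.n_missing == 3

    def test_matches_brute_force_on_random_tables(self):
        """Max-GQ selection with platform-priority ties on >=600 tables."""
        rng = np.random.default_rng(99)
        genotypes = [None, (0, 0), (0, 1), (1, 1)]
        priority = {Platform.ILLUMINA: 0, Platform.LINKEDREAD: 1, Platform.IONTORRENT: 2}
        for _ in range(600):
            triples = []
            for _p in range(6):
                g = genotypes[int(rng.integers(4))]
                gq = None if g is None else int(rng.integers(0, 4))  # narrow: force ties
                triples.append((g, gq, 20, None))
            v = make_variant(wli=triples[:3], wmi=triples[3:])
            for strain, subset in ((Strain.WLI, triples[:3]), (Strain.WMI, triples[3:])):
                # independent enumeration of the max/tie rule
                calls = {
                    p: (g, gq)
                    for p, (g, gq, _d, _a) in zip(PLATFORMS, subset)
                    if g is not None
                }
                summary = best_call_per_strain(v, CFG)[strain]
                if not calls:
                    assert summary.best_call is None
                    continue
                best_gq = max(gq for _g, gq in calls.values())
                tied = [p for p, (_g, gq) in calls.items() if gq == best_gq]
                winner = min(tied, key=lambda p: priority[p])
                assert summary.best_call == calls[winner][0]
                assert summary.best_gq == best_gq
                assert summary.best_platform == winner


class TestEqualBest:
    def test_identical_best_calls_removed(self):
        v = make_variant(wli=HOMALT3, wmi=HOMALT3)
        assert removed(step_equal_best, v) is True

    def test_differing_best_calls_kept(self):
        v = make_variant(wli=HOMALT3, wmi=HOMREF3)
        assert removed(step_equal_best, v) is False

    def test_different_alt_alleles_are_different_calls(self):
        v = make_variant(
            wli=[((1, 1), 40, 20, None)] * 3,
            wmi=[((2, 2), 40, 20, None)] * 3,
            alts=("G", "T"),
        )
        assert removed(step_equal_best, v) is False

    def test_missing_best_never_equal(self):
        v = make_variant(wli=[(None,)] * 3, wmi=[(None,)] * 3)
        assert removed(step_equal_best, v) is False


class TestConcordanceFlag:
    def test_flags_match_brute_force_triples(self):
        rng = np.random.default_rng(5)
        genotypes = [None, (0, 0), (0, 1), (1, 1)]
        for _ in range(300):
            triples = [
                (genotypes[int(rng.integers(4))], 30, 20, None) for _ in range(6)
            ]
            v = make_variant(wli=triples[:3], wmi=triples[3:])
            flags = flag_within_strain_concordance([v])[v.key()]
            for strain, subset in ((Strain.WLI, triples[:3]), (Strain.WMI, triples[3:])):
                gts = [g for g, *_ in subset]
                expect = None not in gts and gts[0] == gts[1] == gts[2]
                assert (strain in flags) is expect

    def test_two_calls_plus_missing_not_concordant(self):
        v = make_variant(
            wli=[((1, 1), 40, 20, None), ((1, 1), 40, 20, None), (None,)],
            wmi=HOMREF3,
        )
        assert Strain.WLI not in flag_within_strain_concordance([v])[v.key()]


class TestUncertain:
    @pytest.mark.parametrize(
        "n_missing, expect_removed", [(5, True), (4, False), (6, True)]
    )
    def test_missing_thresholds(self, n_missing, expect_removed):
        triples = [(None,)] * n_missing + [((1, 1), 40, 30, None)] * (6 - n_missing)
        v = make_variant(wli=triples[:3], wmi=triples[3:])
        assert removed(step_uncertain, v) is expect_removed


class TestLowQualityDiscordant:
    def _five_one(self, dissent_gq):
        return make_variant(
            wli=[((0, 0), 40, 20, None)] * 3,
            wmi=[((0, 0), 40, 20, None), ((0, 0), 40, 20, None), ((1, 1), dissent_gq, 20, None)],
        )

    def test_weak_dissent_removed(self):
        assert removed(step_low_quality_discordant, self._five_one(7)) is True

    def test_boundary_gq10_kept(self):
        assert removed(step_low_quality_discordant, self._five_one(10)) is False

    def test_no_five_way_majority_kept(self):
        v = make_variant(
            wli=[((0, 0), 40, 20, None)] * 3,
            wmi=[((0, 0), 40, 20, None), ((0, 1), 25, 20, None), ((1, 1), 3, 20, None)],
        )
        assert removed(step_low_quality_discordant, v) is False

    def test_missing_call_disables_rule(self):
        v = make_variant(
            wli=[((0, 0), 40, 20, None)] * 3,
            wmi=[((0, 0), 40, 20, None), (None,), ((1, 1), 3, 20, None)],
        )
        assert removed(step_low_quality_discordant, v) is False


class TestAlleleBalance:
    def _with_ads(self, wli_ads, wmi_ads):
        return make_variant(
            wli=[((0, 1), 30, sum(ad), ad) for ad in wli_ads],
            wmi=[((0, 1), 30, sum(ad), ad) for ad in wmi_ads],
        )

    def test_majority_shared_removed(self):
        # alt 95 of 100 pooled; strains split 50/50
        v = self._with_ads([(1, 15), (1, 15), (1, 17)], [(1, 16), (1, 16), (0, 16)])
        assert removed(step_allele_balance, v) is True

    def test_unbalanced_strain_share_kept(self):
        # alt 95 of 100, but one strain holds only 20% of reads
        v = self._with_ads([(2, 26), (1, 26), (1, 24)], [(1, 9), (0, 5), (0, 5)])
        assert removed(step_allele_balance, v) is False

    def test_no_majority_kept(self):
        # alt 85 of 100, split 50/50
        v = self._with_ads([(5, 14), (5, 14), (5, 7)], [(0, 17), (0, 17), (0, 16)])
        assert removed(step_allele_balance, v) is False

    def test_zero_total_reads_not_removed(self):
        v = make_variant(wli=[((0, 1), 30, 10, None)] * 3, wmi=[((0, 1), 30, 10, None)] * 3)
        assert removed(step_allele_balance, v) is False


class TestCrossPlatformDispute:
    def _dispute(self, opposing_gq):
        return make_variant(
            wli=HOMREF3,
            wmi=[((1, 1), 50, 20, None), ((0, 0), opposing_gq, 20, None), ((1, 1), 45, 20, None)],
        )

    def test_q30_dispute_removed(self):
        assert removed(step_cross_platform_dispute, self._dispute(35)) is True

    def test_q29_dispute_kept(self):
        assert removed(step_cross_platform_dispute, self._dispute(29)) is False

    def test_matches_brute_force_scan(self):
        """Pairwise dispute scan oracle on >=500 random tables."""
        rng = np.random.default_rng(17)
        genotypes = [None, (0, 0), (0, 1), (1, 1)]
        for _ in range(500):
            triples = [
                (
                    genotypes[int(rng.integers(4))],
                    int(rng.integers(0, 60)),
                    20,
                    None,
                )
                for _ in range(6)
            ]
            triples = [(g, None if g is None else gq, d, a) for g, gq, d, a in triples]
            v = make_variant(wli=triples[:3], wmi=triples[3:])
            summaries = best_call_per_strain(v, CFG)
            expect = False
            for strain, subset in ((Strain.WLI, triples[:3]), (Strain.WMI, triples[3:])):
                best = summaries[strain].best_call
                if best is None:
                    continue
                for g, gq, _d, _a in subset:
                    if g is not None and g != best and (gq or 0) >= 30:
                        expect = True
            kept, gone = step_cross_platform_dispute([v], CFG)
            assert (len(gone) == 1) is expect


class TestRequireDifference:
    def test_hom_ref_vs_hom_alt_kept(self):
        v = make_variant(wli=HOMREF3, wmi=HOMALT3)
        kept, _ = step_require_difference([v], CFG)
        assert len(kept) == 1

    def test_het_vs_hom_alt_removed(self):
        v = make_variant(wli=[((0, 1), 40, 20, None)] * 3, wmi=HOMALT3)
        assert removed(step_require_difference, v) is True

    def test_hom_ref_vs_het_kept(self):
        v = make_variant(wli=HOMREF3, wmi=[((0, 1), 40, 20, None)] * 3)
        kept, _ = step_require_difference([v], CFG)
        assert len(kept) == 1


class TestQualityTier:
    def test_q31_unopposed_kept(self):
        v = make_variant(wli=[((1, 1), 31, 20, None), (None,), (None,)], wmi=HOMREF3)
        assert removed(step_quality_tier, v) is False

    def test_no_q30_support_removed(self):
        v = make_variant(wli=[((1, 1), 29, 20, None), (None,), (None,)], wmi=HOMREF3)
        assert removed(step_quality_tier, v) is True

    def test_within_strain_opposition_at_q12_removed(self):
        v = make_variant(
            wli=[((1, 1), 45, 20, None), ((0, 1), 12, 20, None), (None,)],
            wmi=HOMREF3,
        )
        assert removed(step_quality_tier, v) is True

    def test_opposite_strain_hom_ref_is_not_opposition(self):
        v = make_variant(wli=[((1, 1), 45, 20, None)] * 3, wmi=[((0, 0), 59, 20, None)] * 3)
        assert removed(step_quality_tier, v) is False

    def test_opposite_strain_alt_call_is_opposition(self):
        v = make_variant(
            wli=[((1, 1), 45, 20, None)] * 3,
            wmi=[((0, 0), 40, 20, None), ((0, 0), 40, 20, None), ((0, 1), 11, 20, None)],
        )
        # WMI best is hom-ref, but its linked-read het call opposes at Q>=10
        assert removed(step_quality_tier, v) is True


class TestHomopolymerStep:
    def _deletion_variant(self, seq, n_callers, gqs=(40, 22)):
        # anchor before the first >=3 run in seq
        i = next(i for i in range(1, len(seq) - 3) if seq[i] == seq[i + 1] == seq[i + 2])
        pos = i
        ref, alt = seq[pos - 1] + seq[pos], seq[pos - 1]
        callers = [((1, 1), gqs[k] if k < len(gqs) else 20, 20, None) for k in range(n_callers)]
        wli = callers + [(None,)] * (3 - n_callers)
        return make_variant(wli=wli, wmi=HOMREF3, ref=ref, alts=(alt,), pos=pos)

    def test_single_platform_run_deletion_removed(self, ref_fasta):
        seq, fasta = ref_fasta
        v = self._deletion_variant(seq, 1)
        kept, gone = step_homopolymer_deletions([v], fasta, CFG)
        assert len(gone) == 1

    def test_two_platform_support_kept(self, ref_fasta):
        seq, fasta = ref_fasta
        v = self._deletion_variant(seq, 2)
        kept, gone = step_homopolymer_deletions([v], fasta, CFG)
        assert len(kept) == 1

    def test_non_homopolymer_deletion_kept(self, ref_fasta):
        seq, fasta = ref_fasta
        i = next(
            i for i in range(2, len(seq) - 2) if seq[i] != seq[i - 1] and seq[i] != seq[i + 1]
        )
        pos = i
        v = make_variant(
            wli=[((1, 1), 40, 20, None), (None,), (None,)],
            wmi=HOMREF3,
            ref=seq[pos - 1] + seq[pos],
            alts=(seq[pos - 1],),
            pos=pos,
        )
        kept, gone = step_homopolymer_deletions([v], fasta, CFG)
        assert len(kept) == 1

    def test_snp_never_removed_here(self, ref_fasta):
        _, fasta = ref_fasta
        v = make_variant(wli=[((1, 1), 40, 20, None)] * 3, wmi=HOMREF3, pos=500)
        kept, gone = step_homopolymer_deletions([v], fasta, CFG)
        assert len(kept) == 1
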