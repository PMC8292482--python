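"""ANN parsing, effect tabulation, impact extraction and gene-set arithmetic."""

import numpy as np
import pytest

from isofilter.annotation import (
    GeneSetSummary,
    effect_display,
    extract_high_moderate,
    gene_set_summary,
    overlap_with_gene_list,
    parse_ann,
    tabulate_effects,
)
from isofilter.synthetic import (
    EFFECT_VOCABULARY,
    generate_annotated_fixture,
    make_stub_variants,
    set_annotation,
)
from isofilter.vcf_model import Strain


class TestParseAnn:
    def test_missense_entry(self):
        ann = "T|missense_variant|MODERATE|Gnat2|ENSRNOG00000019296|transcript|x.1|protein_coding|1/8|c.1A>G||||||"
        (rec,) = parse_ann(ann)
        assert rec.effect == "missense variant"
        assert rec.impact == "MODERATE"
        assert rec.gene_symbol == "Gnat2"
        assert rec.gene_id == "ENSRNOG00000019296"
        assert rec.alt_allele == "T"

    def test_compound_effect_first_listed_primary(self):
        ann = "A|splice_donor_variant&intron_variant|HIGH|G1|ID1|"
        (rec,) = parse_ann(ann)
        assert rec.effect == "splice donor variant"
        assert rec.modification == "Splice donor variant & intron variant"

    def test_multiple_entries_split_on_comma(self):
        ann = "A|intron_variant|MODIFIER|G1|ID1|,A|upstream_gene_variant|MODIFIER|G2|ID2|"
        recs = parse_ann(ann)
        assert [r.effect for r in recs] == ["intron variant", "upstream gene variant"]

    def test_malformed_entry_warns_and_skips(self):
        with pytest.warns(UserWarning, match="malformed"):
            recs = parse_ann("A|missense_variant")
        assert recs == []
        with pytest.warns(UserWarning, match="unknown impact"):
            recs = parse_ann("A|missense_variant|SEVERE|G|ID|")
        assert recs == []

    def test_empty_input(self):
        assert parse_ann(None) == []
        assert parse_ann("") == []

    def test_fixture_round_trip_field_exact(self):
        """Planted categories/impacts/genes parse back exactly."""
        variants = {Strain.WLI: make_stub_variants(6)}
        plan = {
            Strain.WLI: [
                ("missense_variant", None),
                ("frameshift_variant", None),
                ("intron_variant", None),
                ("intergenic_region", None),
                ("stop_lost", "HIGH"),
                ("synonymous_variant", None),
            ]
        }
        generate_annotated_fixture(variants, seed=4, plan_by_strain=plan)
        for v, (category, planted_impact) in zip(variants[Strain.WLI], plan[Strain.WLI]):
            (rec,) = parse_ann(v.ann)
            assert rec.effect == category.replace("_", " ")
            assert rec.impact == (planted_impact or EFFECT_VOCABULARY[category])
            assert rec.gene_symbol
            assert rec.gene_id


class TestTabulateEffects:
    def test_single_intron_variant(self):
        v = set_annotation(make_stub_variants(1)[0], "intron_variant", "G1")
        table = tabulate_effects({Strain.WLI: [v], Strain.WMI: []})
        assert table.loc["intron variant", "WLI"] == 1
        assert table.loc["total", "WLI"] == 1
        assert table.loc["total", "WMI"] == 0

    def test_planted_counts_reproduced(self):
        plan = {
            Strain.WLI: [("intron_variant", None)] * 7 + [("missense_variant", None)] * 3,
            Strain.WMI: [("intergenic_region", None)] * 5,
        }
        variants = {s: make_stub_variants(len(plan[s])) for s in plan}
        generate_annotated_fixture(variants, seed=1, plan_by_strain=plan)
        table = tabulate_effects(variants)
        assert table.loc["intron variant", "WLI"] == 7
        assert table.loc["missense variant", "WLI"] == 3
        assert table.loc["intergenic region", "WMI"] == 5
        assert table.loc["total", "WLI"] == 10
        assert table.loc["total", "WMI"] == 5

    def test_multi_category_variant_counts_in_each(self):
        """More assignments than variants: totals exceed the variant count."""
        variants = {Strain.WLI: make_stub_variants(2)}
        plan = {
            Strain.WLI: [
                ("intron_variant", None),
                ("intron_variant", None),
                ("upstream_gene_variant", None),
            ]
        }
        generate_annotated_fixture(variants, seed=2, plan_by_strain=plan)
        table = tabulate_effects(variants)
        assert table.loc["total", "WLI"] == 3
        assert table.loc["intron variant", "WLI"] == 2

    def test_duplicate_category_on_same_variant_counts_once(self):
        v = make_stub_variants(1)[0]
        set_annotation(v, ["intron_variant", "intron_variant"], "G1")
        table = tabulate_effects({Strain.WLI: [v], Strain.WMI: []})
        assert table.loc["intron variant", "WLI"] == 1


class TestExtractHighModerate:
    def test_planted_impact_structure(self):
        wli = make_stub_variants(30)
        wmi = make_stub_variants(25)
        plan = {
            Strain.WLI: [("missense_variant", "MODERATE")] * 8
            + [("frameshift_variant", "HIGH")] * 3
            + [("intron_variant", None)] * 19,
            Strain.WMI: [("missense_variant", "MODERATE")] * 5
            + [("stop_lost", "HIGH")] * 4
            + [("intergenic_region", None)] * 16,
        }
        generate_annotated_fixture({Strain.WLI: wli, Strain.WMI: wmi}, seed=3, plan_by_strain=plan)
        rows = extract_high_moderate({Strain.WLI: wli, Strain.WMI: wmi})
        assert (rows.strain == "WLI").sum() == 11
        assert (rows.strain == "WMI").sum() == 9
        assert set(rows.impact) == {"HIGH", "MODERATE"}

    def test_modifier_only_excluded(self):
        v = set_annotation(make_stub_variants(1)[0], "intron_variant", "G1")
        rows = extract_high_moderate({Strain.WLI: [v], Strain.WMI: []})
        assert rows.empty

    def test_highest_impact_wins_and_compound_preserved(self):
        v = make_stub_variants(1)[0]
        v.ann = (
            "G|intron_variant|MODIFIER|G1|ID1|,"
            "G|splice_donor_variant&splice_region_variant&intron_variant|HIGH|G1|ID1|,"
            "G|missense_variant|MODERATE|G1|ID1|"
        )
        rows = extract_high_moderate({Strain.WLI: [v], Strain.WMI: []})
        assert len(rows) == 1
        assert rows.loc[0, "impact"] == "HIGH"
        assert (
            rows.loc[0, "modification"]
            == "Splice donor variant & splice region variant & intron variant"
        )

    def test_output_subset_of_finals(self):
        variants = {Strain.WLI: make_stub_variants(10), Strain.WMI: []}
        generate_annotated_fixture(variants, seed=9)
        rows = extract_high_moderate(variants)
        positions = {v.pos for v in variants[Strain.WLI]}
        assert set(rows.pos).issubset(positions)


class TestGeneSets:
    def test_disjoint_sets(self):
        s = GeneSetSummary(
            {
                Strain.WLI: frozenset("abc"),
                Strain.WMI: frozenset("defg"),
            }
        )
        assert s.union_size == 7 and s.shared == 0

    def test_inclusion_exclusion_on_random_sets(self):
        rng = np.random.default_rng(14)
        for _ in range(300):
            universe = [f"g{i}" for i in range(int(rng.integers(1, 100)))]
            a = frozenset(g for g in universe if rng.random() < 0.4)
            b = frozenset(g for g in universe if rng.random() < 0.4)
            s = GeneSetSummary({Strain.WLI: a, Strain.WMI: b})
            assert s.union_size == s.size(Strain.WLI) + s.size(Strain.WMI) - s.shared
            assert s.union_size == len(set(a) | set(b))

    def test_from_annotated_finals(self):
        wli = [
            set_annotation(v, "intron_variant", g)
            for v, g in zip(make_stub_variants(3), ["A", "B", "A"])
        ]
        wmi = [
            set_annotation(v, "intron_variant", g)
            for v, g in zip(make_stub_variants(3), ["B", "C", "D"])
        ]
        s = gene_set_summary({Strain.WLI: wli, Strain.WMI: wmi})
        assert s.size(Strain.WLI) == 2
        assert s.size(Strain.WMI) == 3
        assert s.shared == 1
        assert s.union_size == 4


class TestGeneListOverlap:
    def _finals(self):
        wli = [
            set_annotation(v, cat, gene)
            for v, (cat, gene) in zip(
                make_stub_variants(4),
                [
                    ("intergenic_region", "De1"),
                    ("intron_variant", "De2"),
                    ("upstream_gene_variant", "Other1"),
                    ("intron_variant", "De1"),
                ],
            )
        ]
        return {Strain.WLI: wli, Strain.WMI: []}

    def test_planted_membership_counts(self):
        counts = overlap_with_gene_list(self._finals(), ["De1", "De2"])
        assert counts["total"] == 3
        assert counts["intergenic region"] == 1
        assert counts["intron variant"] == 2

    def test_empty_list_zero(self):
        assert overlap_with_gene_list(self._finals(), [])["total"] == 0

    def test_no_matching_genes(self):
        assert overlap_with_gene_list(self._finals(), ["Nope"])["total"] == 0


def test_effect_display_formatting():
    assert effect_display("3_prime_UTR_variant") == "3 prime UTR variant"
    assert effect_display("missense_variant&splice_region_variant") == (
        "Missense variant & splice region variant"
    )
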