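"""Parse functional-annotation (ANN) fields and reproduce summary tables.

The upstream annotator (SnpEff-style) writes one comma-separated ``ANN``
INFO entry per (allele, feature) with pipe-delimited sub-fields::

    Allele | Annotation | Impact | Gene_Name | Gene_ID | Feature_Type | ...

This module parses those entries, tabulates effect categories per strain
(counting one assignment per distinct variant x primary category, which is
why category totals can exceed the number of variants), extracts the
high/moderate-impact rows, computes nearest-gene set arithmetic, and
intersects finalists with an externally supplied gene list (e.g. genes
differentially expressed between the strains).

Compound effects joined by ``&`` keep their full compound string for the
high-impact report but contribute their first-listed category to the
effect tabulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .vcf_model import Strain

__all__ = [
    "IMPACT_LEVELS",
    "AnnotationRecord",
    "GeneSetSummary",
    "parse_ann",
    "annotations_for",
    "tabulate_effects",
    "extract_high_moderate",
    "gene_set_summary",
    "overlap_with_gene_list",
    "effect_display",
]

IMPACT_LEVELS: tuple[str, ...] = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {lvl: i for i, lvl in enumerate(IMPACT_LEVELS)}


def effect_display(raw: str) -> str:
    """Human-readable effect: ``splice_donor_variant&intron_variant`` ->
    ``Splice donor variant & intron variant``."""
    parts = [p.strip().replace("_", " ") for p in raw.split("&")]
    text = " & ".join(parts)
    return text[:1].upper() + text[1:] if text else text


@dataclass
class AnnotationRecord:
    """One parsed annotation entry.

    ``effect`` is the primary (first-listed) category in lower-case
    space-separated form, e.g. ``"missense variant"``; ``raw_effect`` keeps
    the full ``&``-joined token string.  ``impact`` is one of HIGH /
    MODERATE / LOW / MODIFIER.
    """

    alt_allele: str
    effect: str
    raw_effect: str
    impact: str
    gene_symbol: str
    gene_id: str

    @property
    def modification(self) -> str:
        """Display form of the full (possibly compound) effect."""
        return effect_display(self.raw_effect)

    @property
    def impact_rank(self) -> int:
        return _IMPACT_RANK[self.impact]


def parse_ann(ann: Optional[str]) -> list[AnnotationRecord]:
    """Parse a raw ANN INFO string into annotation records.

    Malformed entries (too few sub-fields, unknown impact level) emit a
    warning and are skipped, never silently dropped.  ``None``/empty input
    yields an empty list.
    """
    if not ann:
        return []
    records: list[AnnotationRecord] = []
    for entry in str(ann).split(","):
        entry = entry.strip()
        if not entry:
            continue
        fields = entry.split("|")
        if len(fields) < 5:
            warnings.warn(f"skipping malformed ANN entry (need >=5 fields): {entry!r}")
            continue
        allele, raw_effect, impact, gene_symbol, gene_id = (f.strip() for f in fields[:5])
        impact = impact.upper()
        if not raw_effect:
            warnings.warn(f"skipping ANN entry with empty effect: {entry!r}")
            continue
        if impact not in _IMPACT_RANK:
            warnings.warn(f"skipping ANN entry with unknown impact {impact!r}: {entry!r}")
            continue
        primary = raw_effect.split("&")[0].strip().replace("_", " ").lower()
        records.append(
            AnnotationRecord(
                alt_allele=allele,
                effect=primary,
                raw_effect=raw_effect,
                impact=impact,
                gene_symbol=gene_symbol,
                gene_id=gene_id,
            )
        )
    return records


def annotations_for(final: object) -> list[AnnotationRecord]:
    """Annotations of a ``FinalVariant`` or ``JointVariant``."""
    variant = getattr(final, "variant", final)
    return parse_ann(getattr(variant, "ann", None))


def _finals_items(
    finals_per_strain: Mapping[Strain, Sequence[object]],
) -> Iterable[tuple[Strain, object, list[AnnotationRecord]]]:
    for strain, finals in finals_per_strain.items():
        for f in finals:
            yield Strain(strain), f, annotations_for(f)


def tabulate_effects(
    finals_per_strain: Mapping[Strain, Sequence[object]],
) -> pd.DataFrame:
    """Count annotation assignments per effect category and strain.

    One assignment is one distinct (variant, primary category) pairing, so
    a variant annotated against several features of the same category
    counts once for it, while a variant with annotations in two categories
    counts in both — column totals therefore exceed the variant count.
    Unknown categories keep their literal name (the table has an open
    vocabulary).  A ``total`` row holds the column sums.
    """
    counts: dict[str, dict[str, int]] = {s.value: {} for s in Strain}
    for strain, f, anns in _finals_items(finals_per_strain):
        for category in sorted({a.effect for a in anns}):
            col = counts[strain.value]
            col[category] = col.get(category, 0) + 1
    categories = sorted(set().union(*(c.keys() for c in counts.values())))
    frame = pd.DataFrame(
        {s: [counts[s].get(cat, 0) for cat in categories] for s in counts},
        index=categories,
        dtype=int,
    )
    frame.loc["total"] = frame.sum()
    return frame


def extract_high_moderate(
    finals_per_strain: Mapping[Strain, Sequence[object]],
) -> pd.DataFrame:
    """Rows for variants whose strongest annotation is HIGH or MODERATE.

    One row per qualifying variant, carrying its highest-impact annotation
    (HIGH before MODERATE; ties broken by entry order).  Columns: strain,
    chrom, pos, alt, gene, gene_id, impact, modification.  Sorted by
    strain, then chromosome and position.
    """
    rows = []
    for strain, f, anns in _finals_items(finals_per_strain):
        qualifying = [a for a in anns if a.impact in ("HIGH", "MODERATE")]
        if not qualifying:
            continue
        best = min(qualifying, key=lambda a: a.impact_rank)
        variant = getattr(f, "variant", f)
        alt = getattr(f, "called_alt", None) or best.alt_allele or variant.alts[0]
        rows.append(
            {
                "strain": strain.value,
                "chrom": variant.chrom,
                "pos": variant.pos,
                "alt": alt,
                "gene": best.gene_symbol,
                "gene_id": best.gene_id,
                "impact": best.impact,
                "modification": best.modification,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["strain", "chrom", "pos", "alt", "gene", "gene_id", "impact", "modification"],
    )
    return frame.sort_values(["strain", "chrom", "pos"]).reset_index(drop=True)


@dataclass
class GeneSetSummary:
    """Nearest-gene sets per strain with intersection/union arithmetic."""

    genes_per_strain: dict[Strain, frozenset[str]]

    @property
    def shared(self) -> int:
        return len(self.genes_per_strain[Strain.WLI] & self.genes_per_strain[Strain.WMI])

    @property
    def union_size(self) -> int:
        return len(self.genes_per_strain[Strain.WLI] | self.genes_per_strain[Strain.WMI])

    def size(self, strain: Strain) -> int:
        return len(self.genes_per_strain[strain])


def gene_set_summary(
    finals_per_strain: Mapping[Strain, Sequence[object]],
) -> GeneSetSummary:
    """Unique nearest genes per strain (primary annotation's gene)."""
    sets: dict[Strain, set[str]] = {s: set() for s in Strain}
    for strain, f, anns in _finals_items(finals_per_strain):
        if anns:
            gene = anns[0].gene_id or anns[0].gene_symbol
            if gene:
                sets[strain].add(gene)
    return GeneSetSummary({s: frozenset(g) for s, g in sets.items()})


def overlap_with_gene_list(
    finals_per_strain: Mapping[Strain, Sequence[object]],
    gene_list: Iterable[str],
) -> dict[str, int]:
    """Finalists annotated to genes on an external list, by effect category.

    ``gene_list`` holds symbols and/or stable identifiers (matched against
    both, case-insensitively for symbols).  Each matching variant counts
    once, under the primary category of its first matching annotation.
    Returns category -> count plus a ``"total"`` entry.
    """
    wanted = {g.strip() for g in gene_list if g.strip()}
    wanted |= {g.lower() for g in wanted}
    counts: dict[str, int] = {}
    total = 0
    for _, f, anns in _finals_items(finals_per_strain):
        match = next(
            (
                a
                for a in anns
                if a.gene_id in wanted or a.gene_symbol in wanted or a.gene_symbol.lower() in wanted
            ),
            None,
        )
        if match is None:
            continue
        counts[match.effect] = counts.get(match.effect, 0) + 1
        total += 1
    counts["total"] = total
    return counts


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list, ignoring blanks and ``#`` comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
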