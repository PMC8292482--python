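"""The ten-step filtering cascade that distills strain differences.

Starting from a jointly genotyped six-sample call set (two strains x three
platforms), the cascade removes sites that cannot be confident, strain-
distinguishing variants:

1.  **depth** — < 10 reads summed over all samples, or > 300 reads on any
    single sample (collapsed repeats, mapping pathology).
2.  **equal_best** — the two strains' highest-quality calls are identical:
    a shared difference to the reference, not a strain difference.
3.  *(flag only)* within-strain concordance across all three platforms is
    recorded, never used for removal.
4.  **uncertain** — >= 5 of 6 calls are missing (``./.``).
5.  **equal_best (re-applied)** — the equal-best comparison is run a second
    time at this point in the cascade; with per-sample calls immutable it
    is idempotent and in practice removes nothing.
6.  **low_q_discordant** — exactly five non-missing calls agree and the
    single dissenter has genotype quality < 10: the dissent is noise.
7.  **allele_balance** — one allele carries > 90% of all pooled reads while
    both strains contribute >= 25% of reads: both strains carry the same
    allele and the minor counts are noise.
8.  **cross_platform_dispute** — within a strain, a platform contradicts
    that strain's best call at genotype quality >= 30.
9.  **require_difference** then **quality_tier** — keep only sites where
    the strains' best calls differ, exactly one strain is homozygous
    reference, the carrier strain has a supporting call at Q >= 30, and no
    sample opposes the call at Q >= 10 (the opposite strain's hom-ref
    calls being required evidence, not opposition).
10. **homopolymer_deletion** — deletions inside reference homopolymer runs
    must be supported by >= 2 platforms within the carrier strain;
    single-platform homopolymer deletions are the classic Ion Torrent
    base-calling artifact.

Every input record ends up in exactly one removal bucket or one final set,
so the per-step counts form a conservation identity (a flowchart of the
run).  Each step's decision depends only on the record itself, which makes
the pipeline invariant to input order.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pysam

from .vcf_model import (
    FilterConfig,
    JointVariant,
    PLATFORM_PRIORITY,
    Platform,
    PlatformCall,
    SampleKey,
    Strain,
    homopolymer_context,
)

__all__ = [
    "Step",
    "STEP_ORDER",
    "StrainCallSummary",
    "FilterTrace",
    "FinalVariant",
    "PipelineResult",
    "best_call_per_strain",
    "flag_within_strain_concordance",
    "step_depth",
    "step_equal_best",
    "step_uncertain",
    "step_low_quality_discordant",
    "step_allele_balance",
    "step_cross_platform_dispute",
    "step_require_difference",
    "step_quality_tier",
    "step_homopolymer_deletions",
    "run_pipeline",
]


class Step(str, enum.Enum):
    """Identifiers of the cascade's removal buckets, in application order."""

    DEPTH = "depth"
    EQUAL_BEST = "equal_best"
    UNCERTAIN = "uncertain"
    EQUAL_BEST_REAPPLIED = "equal_best_reapplied"
    LOW_Q_DISCORDANT = "low_q_discordant"
    ALLELE_BALANCE = "allele_balance"
    CROSS_PLATFORM_DISPUTE = "cross_platform_dispute"
    REQUIRE_DIFFERENCE = "require_difference"
    QUALITY_TIER = "quality_tier"
    HOMOPOLYMER_DELETION = "homopolymer_deletion"
    SURVIVED = "survived"


STEP_ORDER: tuple[Step, ...] = (
    Step.DEPTH,
    Step.EQUAL_BEST,
    Step.UNCERTAIN,
    Step.EQUAL_BEST_REAPPLIED,
    Step.LOW_Q_DISCORDANT,
    Step.ALLELE_BALANCE,
    Step.CROSS_PLATFORM_DISPUTE,
    Step.REQUIRE_DIFFERENCE,
    Step.QUALITY_TIER,
    Step.HOMOPOLYMER_DELETION,
)


@dataclass
class StrainCallSummary:
    """Best-of-three-platform call for one strain at one site.

    ``best_call`` is the genotype of the maximum-GQ non-missing call among
    the strain's platforms (ties broken by fixed platform priority:
    Illumina > linked read > Ion Torrent); ``None`` when all three calls
    are missing.  ``concordant`` is true only when all three platforms make
    the identical non-missing call.  ``disputed_q30`` is true when another
    platform contradicts the best call at genotype quality >= ``q_high``.
    """

    strain: Strain
    best_call: Optional[tuple[int, ...]]
    best_gq: Optional[int]
    best_platform: Optional[Platform]
    concordant: bool
    n_missing: int
    disputed_q30: bool


@dataclass
class FilterTrace:
    """Which step eliminated a record (or ``SURVIVED``), and its order."""

    step_id: Step
    step_order: int
    concordant_stored: bool = False


@dataclass
class FinalVariant:
    """A surviving strain-distinguishing variant.

    ``carrier_strain`` is the strain whose best call is non-reference;
    the opposite strain's best call is homozygous reference.  ``zygosity``
    is ``"hom"`` or ``"het"`` from the carrier's best call.
    """

    variant: JointVariant
    carrier_strain: Strain
    zygosity: str
    carrier_summary: StrainCallSummary

    @property
    def called_alt_index(self) -> int:
        """ALT index carried by the carrier strain (max index if several)."""
        assert self.carrier_summary.best_call is not None
        return max(a for a in self.carrier_summary.best_call if a != 0)

    @property
    def called_alt(self) -> str:
        return self.variant.allele(self.called_alt_index)


def best_call_per_strain(
    variant: JointVariant, cfg: FilterConfig
) -> dict[Strain, StrainCallSummary]:
    """Summarize each strain's three platform calls into its best call."""
    out: dict[Strain, StrainCallSummary] = {}
    for strain in Strain:
        calls = variant.strain_calls(strain)
        present = {p: c for p, c in calls.items() if not c.is_missing}
        n_missing = 3 - len(present)
        if not present:
            out[strain] = StrainCallSummary(
                strain=strain,
                best_call=None,
                best_gq=None,
                best_platform=None,
                concordant=False,
                n_missing=n_missing,
                disputed_q30=False,
            )
            continue
        best_platform = min(
            present, key=lambda p: (-present[p].quality(), PLATFORM_PRIORITY[p])
        )
        best = present[best_platform]
        concordant = n_missing == 0 and len({c.genotype for c in present.values()}) == 1
        disputed = any(
            c.genotype != best.genotype and c.quality() >= cfg.q_high
            for c in present.values()
        )
        out[strain] = StrainCallSummary(
            strain=strain,
            best_call=best.genotype,
            best_gq=best.quality(),
            best_platform=best_platform,
            concordant=concordant,
            n_missing=n_missing,
            disputed_q30=disputed,
        )
    return out


# ---------------------------------------------------------------------------
# per-record predicates (True = remove)


def _fails_depth(v: JointVariant, cfg: FilterConfig) -> bool:
    if v.total_depth() < cfg.min_total_depth:
        return True
    return any(c.depth() > cfg.max_single_depth for c in v.calls.values())


def _fails_equal_best(v: JointVariant, cfg: FilterConfig) -> bool:
    s = best_call_per_strain(v, cfg)
    a, b = s[Strain.WLI].best_call, s[Strain.WMI].best_call
    return a is not None and b is not None and a == b


def _fails_uncertain(v: JointVariant, cfg: FilterConfig) -> bool:
    return sum(c.is_missing for c in v.calls.values()) >= cfg.max_uncertain


def _fails_low_q_discordant(v: JointVariant, cfg: FilterConfig) -> bool:
    present = [c for c in v.calls.values() if not c.is_missing]
    if len(present) != 6:
        return False
    counts = Counter(c.genotype for c in present)
    genotype, n = counts.most_common(1)[0]
    if n != 5:
        return False
    dissenter = next(c for c in present if c.genotype != genotype)
    return dissenter.quality() < cfg.q_low


def _fails_allele_balance(v: JointVariant, cfg: FilterConfig) -> bool:
    n_alleles = len(v.alts) + 1
    pooled = [0] * n_alleles
    strain_total = {s: 0 for s in Strain}
    for key, call in v.calls.items():
        if call.ad is None:
            continue
        for i, count in enumerate(call.ad[:n_alleles]):
            pooled[i] += count
            strain_total[key.strain] += count
    total = sum(pooled)
    if total == 0:
        return False  # insufficient evidence is the depth step's concern
    majority = max(pooled) > cfg.allele_majority * total
    shared = all(strain_total[s] >= cfg.strain_share * total for s in Strain)
    return majority and shared


def _fails_cross_platform_dispute(v: JointVariant, cfg: FilterConfig) -> bool:
    s = best_call_per_strain(v, cfg)
    return any(s[strain].disputed_q30 for strain in Strain)


def _final_assignment(
    v: JointVariant, cfg: FilterConfig
) -> Optional[tuple[Strain, str, StrainCallSummary]]:
    """Carrier strain and zygosity if the strains' best calls qualify."""
    s = best_call_per_strain(v, cfg)
    a, b = s[Strain.WLI], s[Strain.WMI]
    if a.best_call is None or b.best_call is None or a.best_call == b.best_call:
        return None
    hom_ref = [x for x in (a, b) if x.best_call == (0,) * len(x.best_call)]
    if len(hom_ref) != 1:
        return None
    carrier = a if hom_ref[0] is b else b
    zygosity = "het" if len(set(carrier.best_call)) > 1 else "hom"
    return carrier.strain, zygosity, carrier


def _fails_require_difference(v: JointVariant, cfg: FilterConfig) -> bool:
    return _final_assignment(v, cfg) is None


def _fails_quality_tier(v: JointVariant, cfg: FilterConfig) -> bool:
    assignment = _final_assignment(v, cfg)
    if assignment is None:
        return True
    carrier, _, summary = assignment
    best = summary.best_call
    supported = any(
        c.genotype == best and c.quality() >= cfg.q_high
        for c in v.strain_calls(carrier).values()
    )
    if not supported:
        return True
    # Opposition = any non-missing call at Q >= q_low that is neither the
    # carrier's call (in the carrier strain) nor hom-ref in the opposite
    # strain; the opposite strain's hom-ref calls are required evidence.
    for key, call in v.calls.items():
        if call.is_missing or call.quality() < cfg.q_low:
            continue
        if key.strain == carrier:
            if call.genotype != best:
                return True
        else:
            if not call.is_hom_ref:
                return True
    return False


def _fails_homopolymer(
    v: JointVariant, cfg: FilterConfig, ref_fasta: pysam.FastaFile
) -> bool:
    assignment = _final_assignment(v, cfg)
    if assignment is None:
        return False
    carrier, _, summary = assignment
    assert summary.best_call is not None
    deletion_alts = [
        k
        for k in set(summary.best_call)
        if k != 0
        and len(v.allele(k)) < len(v.ref)
        and v.ref.startswith(v.allele(k))
    ]
    if not deletion_alts:
        return False
    for k in deletion_alts:
        if not homopolymer_context(
            ref_fasta, v.chrom, v.pos, v.ref, v.allele(k), cfg.homopolymer_min_run
        ):
            continue
        supporting = sum(
            1
            for c in v.strain_calls(carrier).values()
            if not c.is_missing and k in c.alt_alleles and c.quality() >= cfg.q_low
        )
        if supporting < cfg.min_supporting_platforms:
            return True
    return False


# ---------------------------------------------------------------------------
# list-level step API: (kept, removed) partitions


def _partition(
    variants: Sequence[JointVariant],
    predicate: Callable[[JointVariant], bool],
) -> tuple[list[JointVariant], list[JointVariant]]:
    kept: list[JointVariant] = []
    removed: list[JointVariant] = []
    for v in variants:
        (removed if predicate(v) else kept).append(v)
    return kept, removed


def step_depth(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Remove low-total-depth and single-sample-excess-depth sites."""
    return _partition(variants, lambda v: _fails_depth(v, cfg))


def step_equal_best(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Remove sites where both strains' best calls are identical (non-missing)."""
    return _partition(variants, lambda v: _fails_equal_best(v, cfg))


def step_uncertain(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Remove sites with >= max_uncertain missing calls."""
    return _partition(variants, lambda v: _fails_uncertain(v, cfg))


def step_low_quality_discordant(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Remove 5-vs-1 sites where the lone dissenter has GQ < q_low."""
    return _partition(variants, lambda v: _fails_low_q_discordant(v, cfg))


def step_allele_balance(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Remove pooled-majority-allele sites shared by both strains."""
    return _partition(variants, lambda v: _fails_allele_balance(v, cfg))


def step_cross_platform_dispute(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Remove sites where a platform contradicts its strain's best call at Q >= q_high."""
    return _partition(variants, lambda v: _fails_cross_platform_dispute(v, cfg))


def step_require_difference(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Keep only sites where best calls differ and exactly one strain is 0/0."""
    return _partition(variants, lambda v: _fails_require_difference(v, cfg))


def step_quality_tier(variants: Sequence[JointVariant], cfg: FilterConfig):
    """Keep only Q>=q_high-supported carrier calls unopposed at Q>=q_low."""
    return _partition(variants, lambda v: _fails_quality_tier(v, cfg))


def step_homopolymer_deletions(
    variants: Sequence[JointVariant], ref_fasta: pysam.FastaFile, cfg: FilterConfig
):
    """Remove under-supported carrier deletions in homopolymer context."""
    return _partition(variants, lambda v: _fails_homopolymer(v, cfg, ref_fasta))


def flag_within_strain_concordance(
    variants: Sequence[JointVariant], cfg: Optional[FilterConfig] = None
) -> dict[tuple, frozenset[Strain]]:
    """Non-destructive flag: strains whose three platforms agree exactly.

    Returns a map from variant key to the set of concordant strains; sites
    concordant in at least one strain are the "stored for further analysis"
    set.  Nothing is ever removed on this flag.
    """
    cfg = cfg or FilterConfig()
    out: dict[tuple, frozenset[Strain]] = {}
    for v in variants:
        s = best_call_per_strain(v, cfg)
        out[v.key()] = frozenset(strain for strain in Strain if s[strain].concordant)
    return out


@dataclass
class PipelineResult:
    """Everything a cascade run produces.

    ``finals_hom`` / ``finals_het`` hold surviving variants per carrier
    strain.  ``step_counts`` is the flowchart: removals per step plus
    survivors, summing to the input size.  ``cross_tech_side_set`` is the
    separate report of homozygous candidates supported at Q >= q_low by all
    three platforms of the carrier strain yet lacking any Q >= q_high call —
    cross-technology-verified but excluded from the finals.  ``concordant_stored``
    counts input sites concordant within at least one strain.
    """

    finals_hom: dict[Strain, list[FinalVariant]]
    finals_het: dict[Strain, list[FinalVariant]]
    step_counts: dict[str, int]
    n_input: int
    cross_tech_side_set: list[FinalVariant]
    concordant_stored: int
    traces: dict[tuple, FilterTrace]

    def finals(self) -> list[FinalVariant]:
        out: list[FinalVariant] = []
        for d in (self.finals_hom, self.finals_het):
            for lst in d.values():
                out.extend(lst)
        out.sort(key=lambda f: (f.variant.chrom, f.variant.pos))
        return out

    def conservation_holds(self) -> bool:
        return sum(self.step_counts.values()) == self.n_input


def _classify_fate(
    v: JointVariant, cfg: FilterConfig, ref_fasta: Optional[pysam.FastaFile]
) -> Step:
    """Run the cascade on one record and return its elimination step."""
    if _fails_depth(v, cfg):
        return Step.DEPTH
    if _fails_equal_best(v, cfg):
        return Step.EQUAL_BEST
    if _fails_uncertain(v, cfg):
        return Step.UNCERTAIN
    if _fails_equal_best(v, cfg):  # re-applied per the published workflow
        return Step.EQUAL_BEST_REAPPLIED
    if _fails_low_q_discordant(v, cfg):
        return Step.LOW_Q_DISCORDANT
    if _fails_allele_balance(v, cfg):
        return Step.ALLELE_BALANCE
    if _fails_cross_platform_dispute(v, cfg):
        return Step.CROSS_PLATFORM_DISPUTE
    if _fails_require_difference(v, cfg):
        return Step.REQUIRE_DIFFERENCE
    if _fails_quality_tier(v, cfg):
        return Step.QUALITY_TIER
    if ref_fasta is not None and _fails_homopolymer(v, cfg, ref_fasta):
        return Step.HOMOPOLYMER_DELETION
    return Step.SURVIVED


def _is_cross_tech_side(v: JointVariant, cfg: FilterConfig) -> Optional[FinalVariant]:
    """Q>=q_low on all three carrier platforms, agreeing, but no Q>=q_high call."""
    assignment = _final_assignment(v, cfg)
    if assignment is None:
        return None
    carrier, zygosity, summary = assignment
    if zygosity != "hom":
        return None
    calls = list(v.strain_calls(carrier).values())
    if any(c.is_missing for c in calls):
        return None
    if len({c.genotype for c in calls}) != 1:
        return None
    if not all(c.quality() >= cfg.q_low for c in calls):
        return None
    if any(c.quality() >= cfg.q_high for c in calls):
        return None
    return FinalVariant(v, carrier, zygosity, summary)


def run_pipeline(
    variants: Sequence[JointVariant],
    ref_fasta: Optional[pysam.FastaFile | str] = None,
    cfg: Optional[FilterConfig] = None,
) -> PipelineResult:
    """Apply the full cascade and return finals, flowchart counts and traces.

    ``ref_fasta`` (path or open :class:`pysam.FastaFile`) enables the
    homopolymer-deletion step; without it that step is skipped and a
    configuration error is raised only if deletions reach it.  Results are
    independent of the input record order.
    """
    cfg = cfg or FilterConfig()
    opened_here = False
    if isinstance(ref_fasta, (str,)):
        ref_fasta = pysam.FastaFile(ref_fasta)
        opened_here = True
    try:
        step_counts: dict[str, int] = {s.value: 0 for s in STEP_ORDER}
        step_counts[Step.SURVIVED.value] = 0
        finals_hom: dict[Strain, list[FinalVariant]] = {s: [] for s in Strain}
        finals_het: dict[Strain, list[FinalVariant]] = {s: [] for s in Strain}
        side_set: list[FinalVariant] = []
        traces: dict[tuple, FilterTrace] = {}
        concordance = flag_within_strain_concordance(variants, cfg)
        step_order = {s: i + 1 for i, s in enumerate(STEP_ORDER)}
        step_order[Step.SURVIVED] = len(STEP_ORDER) + 1

        has_deletion_finalist = False
        for v in variants:
            fate = _classify_fate(v, cfg, ref_fasta if not isinstance(ref_fasta, str) else None)
            stored = bool(concordance.get(v.key()))
            trace = FilterTrace(fate, step_order[fate], concordant_stored=stored)
            v.trace = trace
            traces[v.key()] = trace
            step_counts[fate.value] += 1
            if fate is Step.QUALITY_TIER:
                side = _is_cross_tech_side(v, cfg)
                if side is not None:
                    side_set.append(side)
            if fate is Step.SURVIVED:
                carrier, zygosity, summary = _final_assignment(v, cfg)  # type: ignore[misc]
                final = FinalVariant(v, carrier, zygosity, summary)
                if ref_fasta is None and any(
                    k != 0
                    and len(v.allele(k)) < len(v.ref)
                    and v.ref.startswith(v.allele(k))
                    for k in set(summary.best_call or ())
                ):
                    has_deletion_finalist = True
                (finals_hom if zygosity == "hom" else finals_het)[carrier].append(final)
        if ref_fasta is None and has_deletion_finalist:
            raise ValueError(
                "reference FASTA required: deletions reached the homopolymer step"
            )
        for d in (finals_hom, finals_het):
            for lst in d.values():
                lst.sort(key=lambda f: (f.variant.chrom, f.variant.pos))
        side_set.sort(key=lambda f: (f.variant.chrom, f.variant.pos))
        return PipelineResult(
            finals_hom=finals_hom,
            finals_het=finals_het,
            step_counts=step_counts,
            n_input=len(variants),
            cross_tech_side_set=side_set,
            concordant_stored=sum(1 for s in concordance.values() if s),
            traces=traces,
        )
    finally:
        if opened_here and ref_fasta is not None:
            ref_fasta.close()  # type: ignore[union-attr]
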