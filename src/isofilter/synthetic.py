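"""Seeded generators for every pipeline input, each with a truth table.

No joint call set for the two substrains is publicly deposited, so this
module emulates one: a reference sequence with a controllable density of
homopolymer runs, a six-sample joint VCF in which every record belongs to
a *planted class* with a construction-derivable pipeline fate, annotated
fixtures with syntactically valid ANN strings, and targeted-resequencing
genotype matrices.

The planted classes encode the failure modes the real data exhibits:

* ``TRUE_DIFF_HOM`` / ``TRUE_DIFF_HET`` — genuine strain differences:
  the carrier strain calls the variant on all three platforms with at
  least one call at Q >= 30, the opposite strain is homozygous reference
  at Q >= 10.  These must survive.
* ``SHARED_VARIANT`` — both strains call the same non-reference allele
  (a difference to the reference, not between strains).
* ``HOMOPOLYMER_ARTIFACT`` — a single platform (Ion Torrent by default)
  calls a deletion inside a reference homopolymer run; the other two
  platforms of the strain have no call.
* ``COLLAPSED_PSEUDO_HET`` — heterozygous calls in all six samples at
  roughly double depth: a duplicated segment collapsed in the reference.
* ``LOW_DEPTH`` / ``HIGH_DEPTH`` — total depth below 10 / one sample
  above 300.
* ``UNCERTAIN_CALLS`` — five of six calls missing.
* ``LOW_Q_DISCORDANT`` — five identical calls plus one dissenter whose
  genotype quality is below 10.

Every class's defining constraints are enforced after the random draws
(clamped, not merely expected), so the expected fate is a theorem of the
construction, not a statistical tendency.  All generators are driven by a
single ``numpy`` Generator seeded per call; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .filter_pipeline import PipelineResult, Step
from .validation import Rat, Target, TargetStatus, ValidationMatrix
from .vcf_model import (
    JointVariant,
    Platform,
    PlatformCall,
    SampleKey,
    Strain,
    write_joint_vcf,
)

__all__ = [
    "PlantedClass",
    "SyntheticTruth",
    "NoiseModel",
    "DEFAULT_CLASS_COUNTS",
    "generate_reference",
    "write_reference",
    "plant_variants",
    "simulate_dataset",
    "generate_annotated_fixture",
    "make_stub_variants",
    "generate_validation_matrix",
    "validation_matrix_from_counts",
    "truth_table_frame",
    "check_fates",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


class PlantedClass(str, enum.Enum):
    TRUE_DIFF_HOM = "true_diff_hom"
    TRUE_DIFF_HET = "true_diff_het"
    SHARED_VARIANT = "shared_variant"
    HOMOPOLYMER_ARTIFACT = "homopolymer_artifact"
    COLLAPSED_PSEUDO_HET = "collapsed_pseudo_het"
    LOW_DEPTH = "low_depth"
    HIGH_DEPTH = "high_depth"
    UNCERTAIN_CALLS = "uncertain_calls"
    LOW_Q_DISCORDANT = "low_q_discordant"


#: pipeline fate implied by each class's construction
EXPECTED_FATE: Mapping[PlantedClass, str] = {
    PlantedClass.TRUE_DIFF_HOM: "survive_hom",
    PlantedClass.TRUE_DIFF_HET: "survive_het",
    PlantedClass.SHARED_VARIANT: Step.EQUAL_BEST.value,
    PlantedClass.HOMOPOLYMER_ARTIFACT: Step.HOMOPOLYMER_DELETION.value,
    PlantedClass.COLLAPSED_PSEUDO_HET: Step.EQUAL_BEST.value,
    PlantedClass.LOW_DEPTH: Step.DEPTH.value,
    PlantedClass.HIGH_DEPTH: Step.DEPTH.value,
    PlantedClass.UNCERTAIN_CALLS: Step.UNCERTAIN.value,
    PlantedClass.LOW_Q_DISCORDANT: Step.LOW_Q_DISCORDANT.value,
}

#: a realistic mixture exercising every class (>=1000 records)
DEFAULT_CLASS_COUNTS: Mapping[PlantedClass, int] = {
    PlantedClass.TRUE_DIFF_HOM: 200,
    PlantedClass.TRUE_DIFF_HET: 60,
    PlantedClass.SHARED_VARIANT: 400,
    PlantedClass.HOMOPOLYMER_ARTIFACT: 150,
    PlantedClass.COLLAPSED_PSEUDO_HET: 80,
    PlantedClass.LOW_DEPTH: 40,
    PlantedClass.HIGH_DEPTH: 20,
    PlantedClass.UNCERTAIN_CALLS: 30,
    PlantedClass.LOW_Q_DISCORDANT: 40,
}


@dataclass
class SyntheticTruth:
    """Identity, class and expected pipeline fate of one planted variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    planted_class: PlantedClass
    carrier_strain: Optional[Strain]
    expected_fate: str  # a Step value, or "survive_hom"/"survive_het"


@dataclass
class NoiseModel:
    """Stylized per-platform noise for the generated joint calls.

    Depth means follow the observed platform coverages (Ion Torrent ~41,
    linked reads ~27, Illumina ~43); genotype qualities are drawn uniformly
    from role-specific ranges (strong supporting call, ordinary call, weak
    dissent) and clamped to the class-defining constraints afterwards.
    ``pseudo_het_depth_multiplier`` models collapsed duplications at about
    twice the ordinary coverage; homopolymer deletion errors concentrate on
    ``homopolymer_platform``.
    """

    depth_mean: Mapping[Platform, float] = field(
        default_factory=lambda: {
            Platform.ILLUMINA: 43.0,
            Platform.IONTORRENT: 41.0,
            Platform.LINKEDREAD: 27.0,
        }
    )
    depth_cv: float = 0.15
    gq_strong: tuple[int, int] = (31, 60)
    gq_support: tuple[int, int] = (12, 60)
    gq_weak: tuple[int, int] = (1, 9)
    pseudo_het_depth_multiplier: float = 2.0
    homopolymer_platform: Platform = Platform.IONTORRENT

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.depth_mean.values()):
            raise ValueError("depth means must be positive")
        if not 0 <= self.depth_cv <= 1:
            raise ValueError("depth_cv must be in [0, 1]")
        if self.pseudo_het_depth_multiplier <= 0:
            raise ValueError("pseudo_het_depth_multiplier must be positive")

    def draw_depth(self, rng: np.random.Generator, platform: Platform, scale: float = 1.0) -> int:
        mean = self.depth_mean[platform] * scale
        d = int(round(rng.normal(mean, self.depth_cv * mean)))
        return int(np.clip(d, 10, 290))

    def draw_gq(self, rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
        lo, hi = lo_hi
        return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    length_bp: int,
    homopolymer_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Random reference sequence with a target homopolymer-run density.

    Returns the sequence and a run index of every maximal run of >= 2
    identical bases as ``(start, end, base)`` with 1-based inclusive
    coordinates.  ``homopolymer_fraction`` is the desired fraction of
    positions lying inside such runs; the achieved fraction is within a
    few percent for sequences of >= 10 kb.  Deterministic per seed.
    """
    if length_bp < 1000:
        raise ValueError("reference length must be >= 1000 bp")
    if not 0 <= homopolymer_fraction <= 1:
        raise ValueError("homopolymer_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mu = 3.5  # mean planted-run length (uniform 2..5)
    f = homopolymer_fraction
    p_run = 1.0 if f == 1 else f / (mu * (1 - f) + f)
    pieces: list[str] = []
    total = 0
    prev = ""
    while total < length_bp:
        choices = [b for b in _BASES if b != prev]
        base = choices[int(rng.integers(len(choices)))]
        if rng.random() < p_run:
            run_len = int(rng.integers(2, 6))
            pieces.append(base * run_len)
            total += run_len
        else:
            pieces.append(base)
            total += 1
        prev = base
    seq = "".join(pieces)[:length_bp]
    return seq, _run_index(seq)


def _run_index(seq: str) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[i - 1]:
            if i - start >= 2:
                runs.append((start + 1, i, seq[start]))
            start = i
    return runs


def write_reference(seq: str, path: str | Path, chrom: str = "1", width: int = 60) -> Path:
    """Write a FASTA (with .fai index) holding one chromosome."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))
    return path


# ---------------------------------------------------------------------------
# joint-VCF planting


def _ad_for(genotype: Optional[tuple[int, int]], dp: int, rng: np.random.Generator) -> Optional[tuple[int, int]]:
    if genotype is None:
        return None
    if genotype == (0, 0):
        err = int(rng.integers(0, min(2, dp) + 1))
        return (dp - err, err)
    if genotype == (1, 1):
        err = int(rng.integers(0, min(2, dp) + 1))
        return (err, dp - err)
    alt = dp // 2 + int(rng.integers(-2, 3))
    alt = int(np.clip(alt, 1, dp - 1)) if dp >= 2 else dp
    return (dp - alt, alt)


def _call(
    rng: np.random.Generator,
    noise: NoiseModel,
    platform: Platform,
    genotype: Optional[tuple[int, int]],
    gq_range: Optional[tuple[int, int]],
    dp: Optional[int] = None,
    depth_scale: float = 1.0,
) -> PlatformCall:
    if dp is None:
        dp = noise.draw_depth(rng, platform, depth_scale)
    gq = None if gq_range is None else noise.draw_gq(rng, gq_range)
    return PlatformCall(
        genotype=genotype,
        gq=gq,
        dp=dp,
        ad=_ad_for(genotype, dp, rng),
    )


def _pick_alleles(
    seq: str, pos: int, kind: str, rng: np.random.Generator
) -> tuple[str, str]:
    """SNP / insertion / deletion alleles anchored at 1-based ``pos``."""
    ref_base = seq[pos - 1]
    if kind == "snp":
        if rng.random() < 0.57:  # transition-biased, like real final sets
            return ref_base, _TRANSITION[ref_base]
        options = _TRANSVERSIONS[ref_base]
        return ref_base, options[int(rng.integers(2))]
    if kind == "ins":
        length = int(rng.integers(1, 4))
        inserted = "".join(_BASES[int(rng.integers(4))] for _ in range(length))
        return ref_base, ref_base + inserted
    if kind == "del":
        length = int(rng.integers(1, 3))
        return seq[pos - 1 : pos + length], ref_base
    raise ValueError(kind)


class _PositionPool:
    """Non-overlapping plant positions with enforced spacing."""

    def __init__(self, length: int, spacing: int = 10) -> None:
        self.length = length
        self.spacing = spacing
        self.blocked: set[int] = set()

    def try_claim(self, start: int, end: int) -> bool:
        lo, hi = start - self.spacing, end + self.spacing
        span = range(max(1, lo), min(self.length, hi) + 1)
        if any(p in self.blocked for p in span):
            return False
        self.blocked.update(span)
        return True


def plant_variants(
    ref_seq: str,
    counts: Optional[Mapping[PlantedClass, int]] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    chrom: str = "1",
    max_retries: int = 200,
) -> tuple[list[JointVariant], list[SyntheticTruth]]:
    """Plant class-labelled variants into a six-sample joint call set.

    ``counts`` maps each planted class to the number of records; the
    default mixture exercises all classes.  Positions never overlap and
    keep >= 10 bp spacing so one plant's homopolymer context cannot
    perturb another.  Raises ``ValueError`` when the reference cannot host
    the requested counts (after a bounded number of placement retries).

    Returns the records (sorted by position) and the truth table.
    """
    counts = dict(counts if counts is not None else DEFAULT_CLASS_COUNTS)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    pool = _PositionPool(len(ref_seq))
    eligible_runs = [r for r in _run_index(ref_seq) if r[0] >= 3]
    runs = [eligible_runs[i] for i in rng.permutation(len(eligible_runs))]
    run_cursor = 0

    variants: list[JointVariant] = []
    truths: list[SyntheticTruth] = []

    for cls in PlantedClass:  # fixed class order for determinism
        for _ in range(int(counts.get(cls, 0))):
            placed = False
            for _attempt in range(max_retries):
                if cls is PlantedClass.HOMOPOLYMER_ARTIFACT:
                    if run_cursor >= len(runs):
                        break
                    run_start, _run_end, _base = runs[run_cursor]
                    run_cursor += 1
                    pos = run_start - 1  # anchor base just before the run
                    ref = ref_seq[pos - 1] + ref_seq[run_start - 1]
                    alt = ref_seq[pos - 1]
                    if not pool.try_claim(pos, pos + len(ref) - 1):
                        continue
                else:
                    pos = int(rng.integers(10, len(ref_seq) - 10))
                    kind = _kind_for_class(cls, rng)
                    ref, alt = _pick_alleles(ref_seq, pos, kind, rng)
                    if not pool.try_claim(pos, pos + len(ref) - 1):
                        continue
                carrier = Strain.WLI if rng.random() < 0.5 else Strain.WMI
                calls = _build_calls(cls, carrier, noise, rng)
                variants.append(
                    JointVariant(chrom=chrom, pos=pos, ref=ref, alts=(alt,), calls=calls)
                )
                truths.append(
                    SyntheticTruth(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        planted_class=cls,
                        carrier_strain=_truth_carrier(cls, carrier),
                        expected_fate=EXPECTED_FATE[cls],
                    )
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place all {cls.value} variants: reference too "
                    f"short or homopolymer runs exhausted"
                )
    order = np.argsort([v.pos for v in variants], kind="stable")
    return [variants[i] for i in order], [truths[i] for i in order]


def _kind_for_class(cls: PlantedClass, rng: np.random.Generator) -> str:
    if cls is PlantedClass.TRUE_DIFF_HOM:
        # published final-set composition: ~45% ins, ~37% SNP, ~18% del
        r = rng.random()
        return "ins" if r < 0.453 else ("snp" if r < 0.822 else "del")
    return "snp"


def _truth_carrier(cls: PlantedClass, carrier: Strain) -> Optional[Strain]:
    if cls in (PlantedClass.SHARED_VARIANT, PlantedClass.COLLAPSED_PSEUDO_HET):
        return None
    return carrier


def _build_calls(
    cls: PlantedClass,
    carrier: Strain,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> dict[SampleKey, PlatformCall]:
    """Realize one class's defining six-call configuration."""
    opp = carrier.opposite()
    calls: dict[SampleKey, PlatformCall] = {}
    platforms = list(Platform)

    def strong_then_support() -> dict[Platform, tuple[int, int]]:
        ranges = {p: noise.gq_support for p in platforms}
        ranges[platforms[int(rng.integers(3))]] = noise.gq_strong
        return ranges

    if cls in (PlantedClass.TRUE_DIFF_HOM, PlantedClass.HIGH_DEPTH):
        ranges = strong_then_support()
        for p in platforms:
            calls[SampleKey(carrier, p)] = _call(rng, noise, p, (1, 1), ranges[p])
            calls[SampleKey(opp, p)] = _call(rng, noise, p, (0, 0), noise.gq_support)
        if cls is PlantedClass.HIGH_DEPTH:
            victim = list(calls)[int(rng.integers(6))]
            dp = int(rng.integers(301, 600))
            calls[victim].dp = dp
            if calls[victim].ad is not None:
                g = calls[victim].genotype
                calls[victim].ad = _ad_for(g, dp, rng)
    elif cls is PlantedClass.TRUE_DIFF_HET:
        ranges = strong_then_support()
        for p in platforms:
            calls[SampleKey(carrier, p)] = _call(rng, noise, p, (0, 1), ranges[p])
            calls[SampleKey(opp, p)] = _call(rng, noise, p, (0, 0), noise.gq_support)
    elif cls is PlantedClass.SHARED_VARIANT:
        for s in Strain:
            for p in platforms:
                calls[SampleKey(s, p)] = _call(rng, noise, p, (1, 1), noise.gq_support)
    elif cls is PlantedClass.HOMOPOLYMER_ARTIFACT:
        artifact = noise.homopolymer_platform
        for p in platforms:
            if p is artifact:
                calls[SampleKey(carrier, p)] = _call(rng, noise, p, (0, 1), noise.gq_strong)
            else:
                calls[SampleKey(carrier, p)] = PlatformCall(
                    genotype=None, gq=None, dp=int(rng.integers(3, 9)), ad=None
                )
            calls[SampleKey(opp, p)] = _call(rng, noise, p, (0, 0), noise.gq_support)
    elif cls is PlantedClass.COLLAPSED_PSEUDO_HET:
        scale = noise.pseudo_het_depth_multiplier
        for s in Strain:
            for p in platforms:
                calls[SampleKey(s, p)] = _call(
                    rng, noise, p, (0, 1), noise.gq_support, depth_scale=scale
                )
    elif cls is PlantedClass.LOW_DEPTH:
        total = int(rng.integers(3, 10))  # strictly below the 10-read floor
        parts = rng.multinomial(total, [1 / 6] * 6)
        keys = [SampleKey(s, p) for s in (carrier, opp) for p in platforms]
        for key, dp in zip(keys, parts):
            dp = int(dp)
            genotype = ((1, 1) if key.strain == carrier else (0, 0)) if dp > 0 else None
            gq = int(rng.integers(1, 15)) if genotype is not None else None
            ad = _ad_for(genotype, dp, rng)
            calls[key] = PlatformCall(genotype=genotype, gq=gq, dp=dp, ad=ad)
    elif cls is PlantedClass.UNCERTAIN_CALLS:
        caller = platforms[int(rng.integers(3))]
        for p in platforms:
            if p is caller:
                calls[SampleKey(carrier, p)] = _call(rng, noise, p, (1, 1), noise.gq_support)
            else:
                calls[SampleKey(carrier, p)] = PlatformCall(
                    genotype=None, gq=None, dp=int(rng.integers(2, 6)), ad=None
                )
            calls[SampleKey(opp, p)] = PlatformCall(
                genotype=None, gq=None, dp=int(rng.integers(2, 6)), ad=None
            )
    elif cls is PlantedClass.LOW_Q_DISCORDANT:
        dissent_gq = int(rng.integers(4, 10))  # < 10, yet its strain's maximum
        dissenter = platforms[int(rng.integers(3))]
        for p in platforms:
            if p is dissenter:
                calls[SampleKey(carrier, p)] = _call(
                    rng, noise, p, (1, 1), (dissent_gq, dissent_gq)
                )
            else:
                calls[SampleKey(carrier, p)] = _call(
                    rng, noise, p, (0, 0), (1, dissent_gq - 1)
                )
            calls[SampleKey(opp, p)] = _call(rng, noise, p, (0, 0), noise.gq_support)
    else:  # pragma: no cover
        raise ValueError(cls)
    return calls


def read_truth_table(path: str | Path) -> list[SyntheticTruth]:
    """Read back a truth table written by :func:`simulate_dataset`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    return [
        SyntheticTruth(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            planted_class=PlantedClass(r.planted_class),
            carrier_strain=Strain(r.carrier_strain) if r.carrier_strain else None,
            expected_fate=r.expected_fate,
        )
        for r in df.itertuples(index=False)
    ]


def truth_table_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "pos": t.pos,
                "ref": t.ref,
                "alt": t.alt,
                "planted_class": t.planted_class.value,
                "carrier_strain": t.carrier_strain.value if t.carrier_strain else "",
                "expected_fate": t.expected_fate,
            }
            for t in truths
        ]
    )


def simulate_dataset(
    out_dir: str | Path,
    length_bp: int = 200_000,
    counts: Optional[Mapping[PlantedClass, int]] = None,
    homopolymer_fraction: float = 0.3,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    chrom: str = "1",
) -> dict[str, Path]:
    """Generate reference + joint VCF + truth table under ``out_dir``.

    Returns paths keyed ``reference`` / ``vcf`` / ``truth``.  Sub-seeds for
    the reference and the planting are derived from ``seed`` so the two
    streams are independent but jointly reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq, _runs = generate_reference(length_bp, homopolymer_fraction, seed=seed)
    ref_path = write_reference(seq, out_dir / "ref.fa", chrom=chrom)
    variants, truths = plant_variants(
        seq, counts=counts, noise=noise, seed=seed + 1, chrom=chrom
    )
    vcf_path = out_dir / "joint.vcf"
    write_joint_vcf(variants, vcf_path, contig_lengths={chrom: length_bp})
    truth_path = out_dir / "truth.tsv"
    truth_table_frame(truths).to_csv(truth_path, sep="\t", index=False)
    return {"reference": ref_path, "vcf": vcf_path, "truth": truth_path}


def check_fates(
    result: PipelineResult, truths: Sequence[SyntheticTruth]
) -> tuple[int, int, list[SyntheticTruth]]:
    """Compare pipeline outcomes with the truth table.

    Returns ``(n_agree, n_total, mismatches)``.  A survivor agrees when it
    sits in the expected strain x zygosity final set; a removed record
    agrees when its trace names the expected step.
    """
    finals_at: dict[tuple[str, int], tuple[str, Strain]] = {}
    for zygosity, by_strain in (("hom", result.finals_hom), ("het", result.finals_het)):
        for strain, finals in by_strain.items():
            for f in finals:
                finals_at[(f.variant.chrom, f.variant.pos)] = (zygosity, strain)
    trace_at = {(c, p): tr for (c, p, _r, _a), tr in result.traces.items()}
    mismatches = []
    for t in truths:
        key = (t.chrom, t.pos)
        if t.expected_fate in ("survive_hom", "survive_het"):
            expected = (t.expected_fate.removeprefix("survive_"), t.carrier_strain)
            ok = finals_at.get(key) == expected
        else:
            trace = trace_at.get(key)
            ok = trace is not None and trace.step_id.value == t.expected_fate
        if not ok:
            mismatches.append(t)
    n = len(truths)
    return n - len(mismatches), n, mismatches


# ---------------------------------------------------------------------------
# annotated fixtures


#: effect vocabulary with each category's conventional impact level
EFFECT_VOCABULARY: Mapping[str, str] = {
    "3_prime_UTR_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "frameshift_variant": "HIGH",
    "intergenic_region": "MODIFIER",
    "intragenic_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "missense_variant": "MODERATE",
    "non_coding_transcript_exon_variant": "MODIFIER",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "splice_region_variant": "LOW",
    "stop_lost": "HIGH",
    "synonymous_variant": "LOW",
    "upstream_gene_variant": "MODIFIER",
}

DEFAULT_GENE_POOL: tuple[str, ...] = tuple(
    f"Gene{i:04d}" for i in range(1, 2001)
)


def _ann_entry(alt: str, raw_effect: str, impact: str, gene: str, gene_idx: int) -> str:
    gene_id = f"SYNGENE{gene_idx:08d}"
    return (
        f"{alt}|{raw_effect}|{impact}|{gene}|{gene_id}|transcript|"
        f"{gene_id}.1|protein_coding|1/1|c.1A>G||||||"
    )


def set_annotation(
    variant: JointVariant,
    categories: Sequence[str] | str,
    gene_symbol: str,
    impact: Optional[str] = None,
    gene_id: Optional[str] = None,
) -> JointVariant:
    """Deterministically attach one ANN entry per category to a variant.

    ``categories`` are raw tokens (``"missense_variant"``); ``impact``
    defaults to each category's conventional level.  Convenience for
    fixtures that need exact gene/category control.
    """
    if isinstance(categories, str):
        categories = [categories]
    gid = gene_id or f"ID_{gene_symbol}"
    entries = []
    for category in categories:
        level = impact or EFFECT_VOCABULARY.get(category.split("&")[0], "MODIFIER")
        entries.append(
            f"{variant.alts[0]}|{category}|{level}|{gene_symbol}|{gid}|transcript|"
            f"{gid}.1|protein_coding|1/1|c.1A>G||||||"
        )
    variant.ann = ",".join(entries)
    return variant


def make_stub_variants(
    n: int, chrom: str = "1", start: int = 1000, spacing: int = 50
) -> list[JointVariant]:
    """Minimal biallelic SNP records for annotation fixtures."""
    return [
        JointVariant(chrom=chrom, pos=start + i * spacing, ref="A", alts=("G",), calls={})
        for i in range(n)
    ]


def generate_annotated_fixture(
    variants_by_strain: Mapping[Strain, Sequence[JointVariant]],
    gene_pool: Sequence[str] = DEFAULT_GENE_POOL,
    seed: int = 0,
    plan_by_strain: Optional[Mapping[Strain, Sequence[tuple[str, Optional[str]]]]] = None,
) -> Mapping[Strain, Sequence[JointVariant]]:
    """Attach syntactically valid ANN strings to variants, in place.

    ``plan_by_strain`` lists ``(category, impact-or-None)`` assignments per
    strain (category in raw token form, e.g. ``"missense_variant"``;
    ``None`` impact uses the category's conventional level).  The first
    ``len(variants)`` entries seed one annotation per variant (cycling);
    surplus entries are appended to variants not yet carrying that
    category, so planted (variant, category) pair counts are exact.
    Without a plan, every variant receives one random category.  Genes are
    drawn from ``gene_pool``.  Returns the same mapping for convenience.
    """
    rng = np.random.default_rng(seed)
    vocab = list(EFFECT_VOCABULARY)
    for strain, variants in variants_by_strain.items():
        variants = list(variants)
        if not variants:
            continue
        if plan_by_strain is None:
            plan: list[tuple[str, Optional[str]]] = [
                (vocab[int(rng.integers(len(vocab)))], None) for _ in variants
            ]
        else:
            plan = list(plan_by_strain[Strain(strain)])
        assigned: list[list[tuple[str, str]]] = [[] for _ in variants]
        for i, (category, impact) in enumerate(plan):
            impact = impact or EFFECT_VOCABULARY.get(category, "MODIFIER")
            for offset in range(len(variants)):
                j = (i + offset) % len(variants)
                if category not in {c for c, _ in assigned[j]}:
                    assigned[j].append((category, impact))
                    break
            else:
                raise ValueError(
                    f"cannot place category {category!r}: every variant already has it"
                )
        for v, anns in zip(variants, assigned):
            entries = []
            for category, impact in anns:
                gene_idx = int(rng.integers(len(gene_pool)))
                entries.append(
                    _ann_entry(v.alts[0], category, impact, gene_pool[gene_idx], gene_idx)
                )
            v.ann = ",".join(entries) if entries else None
    return variants_by_strain


# ---------------------------------------------------------------------------
# validation matrices


def _design_rats() -> list[Rat]:
    return [
        Rat(f"{s.value}_{sex}{i}", s, sex)
        for s in Strain
        for sex in ("M", "F")
        for i in (1, 2)
    ]


def _confirmed_genotypes(
    rng: np.random.Generator, rats: Sequence[Rat], carrier: Strain
) -> dict[str, str]:
    out = {}
    carriers = [r for r in rats if r.strain == carrier]
    n_hom = 4 if rng.random() < 0.7 else 3
    holdout = int(rng.integers(4))
    for i, r in enumerate(carriers):
        if n_hom == 3 and i == holdout:
            out[r.rat_id] = "missing" if rng.random() < 0.5 else "het"
        else:
            out[r.rat_id] = "hom-alt"
    for r in rats:
        if r.strain != carrier:
            out[r.rat_id] = "hom-ref"
    return out


def _failed_genotypes(
    rng: np.random.Generator, rats: Sequence[Rat], carrier: Strain
) -> dict[str, str]:
    out = {}
    mode = "opposite_hom_alt" if rng.random() < 0.5 else "few_carriers"
    carriers = [r for r in rats if r.strain == carrier]
    others = [r for r in rats if r.strain != carrier]
    if mode == "opposite_hom_alt":
        for r in carriers:
            out[r.rat_id] = "hom-alt"
        culprit = int(rng.integers(4))
        for i, r in enumerate(others):
            out[r.rat_id] = "hom-alt" if i == culprit else "hom-ref"
    else:
        n_hom = int(rng.integers(0, 3))  # at most 2 carriers: criterion 1 fails
        for i, r in enumerate(carriers):
            out[r.rat_id] = "hom-alt" if i < n_hom else ("het" if rng.random() < 0.5 else "hom-ref")
        for r in others:
            out[r.rat_id] = "hom-ref"
    return out


def generate_validation_matrix(
    n_targets_per_strain: int = 112,
    true_positive_rate: float = 0.858,
    amplified_rate: float = 1.0,
    seed: int = 0,
) -> tuple[ValidationMatrix, dict[str, TargetStatus]]:
    """Random validation matrix with a controllable confirmation rate.

    Each amplified target is constructed confirmed with probability
    ``true_positive_rate`` and failed otherwise; the intended status per
    target is returned alongside.  The design is the published one: four
    rats per strain, equal sexes.
    """
    if not 0 <= true_positive_rate <= 1:
        raise ValueError("true_positive_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rats = _design_rats()
    targets: list[Target] = []
    genotypes: dict[tuple[str, str], str] = {}
    amplified: dict[str, bool] = {}
    truth: dict[str, TargetStatus] = {}
    for strain in Strain:
        for i in range(n_targets_per_strain):
            tid = f"{strain.value}_t{i + 1:04d}"
            targets.append(Target(tid, strain))
            if rng.random() >= amplified_rate:
                amplified[tid] = False
                truth[tid] = TargetStatus.NOT_AMPLIFIED
                for r in rats:
                    genotypes[(tid, r.rat_id)] = "missing"
                continue
            amplified[tid] = True
            if rng.random() < true_positive_rate:
                genos = _confirmed_genotypes(rng, rats, strain)
                truth[tid] = TargetStatus.CONFIRMED
            else:
                genos = _failed_genotypes(rng, rats, strain)
                truth[tid] = TargetStatus.FAILED
            for rat_id, g in genos.items():
                genotypes[(tid, rat_id)] = g
    matrix = ValidationMatrix(
        targets=targets, rats=rats, genotypes=genotypes, amplified=amplified
    )
    return matrix, truth


def validation_matrix_from_counts(
    confirmed: Mapping[Strain, int],
    amplified: Mapping[Strain, int],
    designed: Optional[Mapping[Strain, int]] = None,
    seed: int = 0,
) -> ValidationMatrix:
    """Deterministic matrix realizing exact per-strain outcome counts.

    ``confirmed[s] <= amplified[s] <= designed[s]`` targets predicted for
    strain ``s``; the confirmed ones get 4/4 carrier hom-alt calls with a
    clean opposite strain, the failed ones a single opposite-strain
    hom-alt call, the rest no PCR product.
    """
    rng = np.random.default_rng(seed)
    rats = _design_rats()
    targets: list[Target] = []
    genotypes: dict[tuple[str, str], str] = {}
    amplified_flags: dict[str, bool] = {}
    for strain in Strain:
        n_total = (designed or amplified)[strain]
        n_amp = amplified[strain]
        n_conf = confirmed[strain]
        if not n_conf <= n_amp <= n_total:
            raise ValueError("need confirmed <= amplified <= designed")
        for i in range(n_total):
            tid = f"{strain.value}_t{i + 1:04d}"
            targets.append(Target(tid, strain))
            if i >= n_amp:
                amplified_flags[tid] = False
                for r in rats:
                    genotypes[(tid, r.rat_id)] = "missing"
                continue
            amplified_flags[tid] = True
            genos = (
                _confirmed_genotypes(rng, rats, strain)
                if i < n_conf
                else _failed_genotypes(rng, rats, strain)
            )
            for rat_id, g in genos.items():
                genotypes[(tid, rat_id)] = g
    return ValidationMatrix(
        targets=targets, rats=rats, genotypes=genotypes, amplified=amplified_flags
    )
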