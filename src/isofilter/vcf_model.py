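"""Data model and I/O for a jointly genotyped two-strain, three-platform VCF.

The experimental design behind this package sequences two nearly-isogenic
rat strains (WLI and WMI) on three platforms (Illumina short reads, Ion
Torrent, and 10X Chromium linked reads), calls variants per sample, and
joint-genotypes all six samples into one multi-sample VCF.  This module
provides:

* :class:`SampleKey` — the (strain, platform) identity of a VCF sample
  column, with a total, injective mapping from column names;
* :class:`PlatformCall` — one sample's genotype call with its Phred-scaled
  genotype quality (FORMAT/GQ), read depth (FORMAT/DP) and per-allele read
  support (FORMAT/AD);
* :class:`JointVariant` — one VCF site with all six calls attached;
* :class:`FilterConfig` — every numeric threshold of the downstream
  filtering cascade, defaulting to the published values;
* readers/writers built on :mod:`pysam`, and reference-genome homopolymer
  context lookup used by the deletion-artifact filter.

Coordinate conventions: VCF positions are 1-based throughout the public
API; internal window/bin arithmetic is half-open.  Chromosome names are
normalized on ingest by stripping an optional ``chr`` prefix so that
``chr1`` and ``1`` refer to the same sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

__all__ = [
    "Strain",
    "Platform",
    "SampleKey",
    "PlatformCall",
    "JointVariant",
    "FilterConfig",
    "ALL_SAMPLE_KEYS",
    "PLATFORM_PRIORITY",
    "default_sample_map",
    "sample_map_from_config",
    "read_joint_vcf",
    "write_joint_vcf",
    "write_vcf",
    "homopolymer_context",
    "normalize_chrom",
    "VcfParseError",
    "SampleMapError",
]


class Strain(str, enum.Enum):
    """The two selectively bred substrains."""

    WLI = "WLI"
    WMI = "WMI"

    def opposite(self) -> "Strain":
        return Strain.WMI if self is Strain.WLI else Strain.WLI


class Platform(str, enum.Enum):
    """Sequencing technology that produced a sample."""

    ILLUMINA = "ILLUMINA"
    IONTORRENT = "IONTORRENT"
    LINKEDREAD = "LINKEDREAD"


# Fixed tie-break order for equal genotype qualities: short-read Illumina
# first, then linked reads, then Ion Torrent (most homopolymer-error prone).
PLATFORM_PRIORITY: Mapping[Platform, int] = {
    Platform.ILLUMINA: 0,
    Platform.LINKEDREAD: 1,
    Platform.IONTORRENT: 2,
}


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one VCF sample column: which strain on which platform."""

    strain: Strain
    platform: Platform

    def __str__(self) -> str:  # canonical column name
        return f"{self.strain.value}_{self.platform.value}"


ALL_SAMPLE_KEYS: tuple[SampleKey, ...] = tuple(
    SampleKey(s, p) for s in Strain for p in Platform
)

#: Genotype = sorted tuple of allele indices (0 = REF), or None if missing.
Genotype = Optional[tuple[int, ...]]

HOM_REF: tuple[int, int] = (0, 0)


@dataclass
class PlatformCall:
    """One sample's call at one site.

    ``genotype`` is a sorted tuple of allele indices (0 = reference,
    k >= 1 the k-th ALT) or ``None`` for a missing call (``./.``).  A
    missing call is distinct from a confident homozygous-reference call.
    ``gq`` is the per-sample Phred-scaled genotype quality; ``dp`` the read
    depth; ``ad`` per-allele read counts (reference first).
    """

    genotype: Genotype = None
    gq: Optional[int] = None
    dp: Optional[int] = None
    ad: Optional[tuple[int, ...]] = None

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype is not None and all(a == 0 for a in self.genotype)

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and len(set(self.genotype)) > 1

    @property
    def is_hom_alt(self) -> bool:
        g = self.genotype
        return g is not None and len(set(g)) == 1 and g[0] != 0

    @property
    def alt_alleles(self) -> frozenset[int]:
        """Indices of non-reference alleles present in the genotype."""
        if self.genotype is None:
            return frozenset()
        return frozenset(a for a in self.genotype if a != 0)

    def depth(self) -> int:
        """Effective depth: DP, falling back to sum(AD), then 0."""
        if self.dp is not None:
            return self.dp
        if self.ad is not None:
            return sum(self.ad)
        return 0

    def quality(self) -> int:
        """GQ with absent values treated as 0 (no confidence)."""
        return self.gq if self.gq is not None else 0


@dataclass
class JointVariant:
    """One jointly genotyped site with all six per-sample calls.

    ``calls`` is keyed by the full strain x platform cross-product; a sample
    with no call carries a missing-genotype :class:`PlatformCall`.  ``ann``
    holds the raw functional-annotation INFO string when present.  ``trace``
    is filled in by the filter pipeline with the step that eliminated the
    record (or a survived marker).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: dict[SampleKey, PlatformCall] = field(default_factory=dict)
    ann: Optional[str] = None
    trace: Optional[object] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise ValueError("ref and alts must be non-empty")
        for k in ALL_SAMPLE_KEYS:
            self.calls.setdefault(k, PlatformCall())

    def allele(self, index: int) -> str:
        """Allele string for index (0 = REF, k >= 1 the k-th ALT)."""
        return self.ref if index == 0 else self.alts[index - 1]

    def total_depth(self) -> int:
        return sum(c.depth() for c in self.calls.values())

    def strain_calls(self, strain: Strain) -> dict[Platform, PlatformCall]:
        return {p: self.calls[SampleKey(strain, p)] for p in Platform}

    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)


@dataclass
class FilterConfig:
    """All numeric thresholds of the filtering cascade.

    Defaults are the published operating point of the workflow:

    * ``min_total_depth`` / ``max_single_depth`` — sites with fewer than 10
      reads summed over all six samples, or more than 300 reads on any
      single sample, are discarded (too little evidence, or collapsed
      repeats / mapping pathology).
    * ``q_low`` / ``q_mid`` / ``q_high`` — the Phred genotype-quality tiers
      (10 / 20 / 30).  A finalist needs a Q>=30 supporting call, unopposed
      by any conflicting call at Q>=10.
    * ``allele_majority`` / ``strain_share`` — a site where one allele
      carries >90% of pooled reads while both strains contribute >=25% of
      reads is a shared variant (relative to the reference), not a strain
      difference, and is removed.
    * ``max_uncertain`` — sites with >=5 of 6 missing (``./.``) calls.
    * ``homopolymer_min_run`` / ``min_supporting_platforms`` — deletions
      whose deleted bases sit in a run of >=2 identical reference bases
      must be called by >=2 platforms within the carrier strain.
    * ``cluster_window_bp`` / ``upstream_window_bp`` — reporting windows
      for variant clusters (1 kb) and upstream-of-gene proximity (5 kb).
    """

    min_total_depth: int = 10
    max_single_depth: int = 300
    q_low: int = 10
    q_mid: int = 20
    q_high: int = 30
    allele_majority: float = 0.90
    strain_share: float = 0.25
    max_uncertain: int = 5
    cluster_window_bp: int = 1000
    upstream_window_bp: int = 5000
    homopolymer_min_run: int = 2
    min_supporting_platforms: int = 2

    def __post_init__(self) -> None:
        for name in (
            "min_total_depth",
            "max_single_depth",
            "q_low",
            "q_mid",
            "q_high",
            "max_uncertain",
            "cluster_window_bp",
            "upstream_window_bp",
            "homopolymer_min_run",
            "min_supporting_platforms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.q_low < self.q_mid < self.q_high:
            raise ValueError("quality tiers must satisfy q_low < q_mid < q_high")
        if not 0 < self.allele_majority < 1:
            raise ValueError("allele_majority must be in (0, 1)")
        if not 0 < self.strain_share <= 0.5:
            raise ValueError("strain_share must be in (0, 0.5]")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "FilterConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**known)  # type: ignore[arg-type]


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


class SampleMapError(ValueError):
    """The sample column -> (strain, platform) mapping is not total/injective."""


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix so dialects compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


def default_sample_map() -> dict[str, SampleKey]:
    """Canonical column names ``WLI_ILLUMINA`` ... -> :class:`SampleKey`."""
    return {str(k): k for k in ALL_SAMPLE_KEYS}


def sample_map_from_config(entries: Mapping[str, str]) -> dict[str, SampleKey]:
    """Build a sample map from config entries ``column = "STRAIN:PLATFORM"``."""
    out: dict[str, SampleKey] = {}
    for column, spec in entries.items():
        try:
            strain_s, platform_s = spec.split(":")
            key = SampleKey(Strain(strain_s.strip().upper()), Platform(platform_s.strip().upper()))
        except (ValueError, KeyError) as exc:
            raise SampleMapError(f"bad sample map entry {column!r} = {spec!r}") from exc
        out[column] = key
    _validate_sample_map(out, out.keys())
    return out


def _validate_sample_map(sample_map: Mapping[str, SampleKey], columns: Iterable[str]) -> None:
    cols = list(columns)
    missing = [c for c in cols if c not in sample_map]
    if missing:
        raise SampleMapError(f"sample columns without a strain/platform mapping: {missing}")
    keys = [sample_map[c] for c in cols]
    if len(set(keys)) != len(keys):
        raise SampleMapError("sample map is not injective: two columns share a (strain, platform)")
    if set(keys) != set(ALL_SAMPLE_KEYS):
        missing_keys = sorted(str(k) for k in set(ALL_SAMPLE_KEYS) - set(keys))
        raise SampleMapError(f"sample map does not cover the full design: missing {missing_keys}")


def _call_from_record_sample(sample: "pysam.libcbcf.VariantRecordSample") -> PlatformCall:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        genotype: Genotype = None
    else:
        genotype = tuple(sorted(int(a) for a in gt))
    gq = sample.get("GQ")
    dp = sample.get("DP")
    ad = sample.get("AD")
    if ad is not None:
        ad = tuple(0 if a is None else int(a) for a in ad)
    return PlatformCall(
        genotype=genotype,
        gq=None if gq is None else int(gq),
        dp=None if dp is None else int(dp),
        ad=ad,
    )


def read_joint_vcf(
    path: str | Path,
    sample_map: Optional[Mapping[str, SampleKey]] = None,
) -> list[JointVariant]:
    """Read a joint multi-sample VCF into :class:`JointVariant` records.

    ``sample_map`` maps VCF sample column names to sample keys; it must
    cover every column in the file and hit all six (strain, platform)
    combinations exactly once.  By default the canonical
    ``STRAIN_PLATFORM`` column names are assumed.

    Missing genotypes (``./.`` or any partially missing call) are recorded
    as missing; absent GQ/DP/AD stay absent.  Records are returned in file
    order.
    """
    sample_map = dict(sample_map) if sample_map is not None else default_sample_map()
    out: list[JointVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        _validate_sample_map(sample_map, list(vcf.header.samples))
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf):
            try:
                calls = {
                    sample_map[name]: _call_from_record_sample(rec.samples[name])
                    for name in vcf.header.samples
                }
                ann = rec.info.get("ANN")
                if isinstance(ann, tuple):
                    ann = ",".join(str(a) for a in ann)
                out.append(
                    JointVariant(
                        chrom=normalize_chrom(rec.chrom),
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=tuple(rec.alts or ()),
                        calls=calls,
                        ann=ann,
                    )
                )
            except (ValueError, TypeError, KeyError) as exc:
                raise VcfParseError(f"malformed VCF record #{i + 1} at {rec.chrom}:{rec.pos}: {exc}") from exc
    return out


def _build_header(
    variants: Sequence[JointVariant],
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=isofilter")
    lengths: dict[str, int] = dict(contig_lengths or {})
    for v in variants:
        need = v.pos + len(v.ref)
        if lengths.get(v.chrom, 0) < need:
            lengths[v.chrom] = need
    for contig in sorted(lengths, key=_chrom_sort_key):
        header.contigs.add(contig, length=lengths[contig])
    header.info.add("ANN", ".", "String", "Functional annotations")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Per-allele read depth")
    for key in ALL_SAMPLE_KEYS:
        header.add_sample(str(key))
    return header


def _chrom_sort_key(name: str) -> tuple[int, int | str]:
    n = normalize_chrom(name)
    return (0, int(n)) if n.isdigit() else (1, n)


def write_joint_vcf(
    variants: Sequence[JointVariant],
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> int:
    """Write records as a VCF 4.2 with canonical sample columns.

    Records are sorted by (chromosome, position); unsorted input is never
    an error.  Returns the number of records written.
    """
    header = _build_header(variants, contig_lengths)
    ordered = sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, *v.alts),
            )
            if v.ann is not None:
                rec.info["ANN"] = v.ann
            for key in ALL_SAMPLE_KEYS:
                call = v.calls[key]
                sample = rec.samples[str(key)]
                n = len(v.alts) + 1
                sample["GT"] = call.genotype if call.genotype is not None else (None, None)
                if call.gq is not None:
                    sample["GQ"] = call.gq
                if call.dp is not None:
                    sample["DP"] = call.dp
                if call.ad is not None:
                    ad = tuple(call.ad) + (0,) * (n - len(call.ad))
                    sample["AD"] = ad[:n]
            out.write(rec)
    return len(ordered)


def write_vcf(
    finals: Sequence[object],
    path: str | Path,
    subset: Optional[tuple[Strain, str]] = None,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> int:
    """Export finalist variants, optionally restricted to one strain x zygosity.

    ``finals`` are :class:`~isofilter.filter_pipeline.FinalVariant` records
    (anything with ``carrier_strain``, ``zygosity`` and ``variant``
    attributes).  ``subset`` is ``(strain, "hom"|"het")`` or ``None`` for
    everything.  An empty selection yields a header-only VCF.
    """
    selected = []
    for f in finals:
        if subset is not None:
            strain, zygosity = subset
            if f.carrier_strain != strain or f.zygosity != zygosity:
                continue
        selected.append(f.variant)
    return write_joint_vcf(selected, path, contig_lengths)


def homopolymer_context(
    ref_fasta: pysam.FastaFile,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    min_run: int = 2,
) -> bool:
    """True iff a deletion's removed bases all sit in homopolymer runs.

    ``ref``/``alt`` must describe a deletion in VCF convention: ``alt`` is a
    proper prefix of ``ref`` and the bases ``ref[len(alt):]`` are deleted
    from the reference starting at 1-based position ``pos + len(alt)``.

    The run structure is evaluated on the reference sequence spanning the
    deleted interval plus one flanking base on each side; every deleted
    base must lie inside a maximal run of at least ``min_run`` identical
    nucleotides within that window.  Ion-Torrent-style indel errors
    concentrate precisely on such runs, which is why single-platform
    deletions there are treated as suspect.
    """
    if len(ref) <= len(alt) or not ref.startswith(alt):
        raise ValueError(f"not a VCF-style deletion: ref={ref!r} alt={alt!r}")
    names = {normalize_chrom(n): n for n in ref_fasta.references}
    fasta_chrom = names.get(normalize_chrom(chrom))
    if fasta_chrom is None:
        raise ValueError(f"chromosome {chrom!r} not in reference")
    chrom_len = ref_fasta.get_reference_length(fasta_chrom)
    del_start = pos + len(alt)          # 1-based first deleted base
    del_end = pos + len(ref) - 1        # 1-based last deleted base
    if del_start < 1 or del_end > chrom_len:
        raise ValueError(
            f"deleted interval {chrom}:{del_start}-{del_end} outside reference (length {chrom_len})"
        )
    win_start = max(1, del_start - 1)
    win_end = min(chrom_len, del_end + 1)
    seq = ref_fasta.fetch(fasta_chrom, win_start - 1, win_end).upper()

    # run length at each window offset
    runs = [1] * len(seq)
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[i - 1]:
            for j in range(start, i):
                runs[j] = i - start
            start = i
    for p in range(del_start, del_end + 1):
        if runs[p - win_start] < min_run:
            return False
    return True
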