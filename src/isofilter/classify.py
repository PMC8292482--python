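"""Variant classification, per-strain summary tables, density tracks, clusters.

Classification follows the usual small-variant vocabulary: a SNP is a
single-base substitution, split into transitions (purine<->purine,
pyrimidine<->pyrimidine: A<->G and C<->T) and transversions (everything
else); length-changing alleles are insertions or deletions.  Equal-length
multi-base substitutions fall outside that vocabulary and are reported as
OTHER rather than silently dropped.

Summary fractions are computed over both strains pooled and rounded
half-up to one decimal, so they are directly comparable with published
percentage tables.  Density tracks use half-open fixed-width bins; cluster
detection slides a fixed window (1 kb by default) across sorted positions
and merges overlapping hits.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .vcf_model import Strain

__all__ = [
    "VariantClass",
    "SummaryTable",
    "DensityTrack",
    "ClusterRegion",
    "classify_variant",
    "summarize",
    "summarize_counts",
    "bin_density",
    "find_clusters",
    "round_half_up",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class VariantClass(str, enum.Enum):
    TRANSITION_SNP = "transition_snp"
    TRANSVERSION_SNP = "transversion_snp"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "other"


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a ref/alt allele pair.

    Raises ``ValueError`` on empty alleles or ``ref == alt`` (no variant).
    """
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}): not a variant")
    if len(ref) == 1 and len(alt) == 1:
        pair = {ref, alt}
        if pair <= _PURINES or pair <= _PYRIMIDINES:
            return VariantClass.TRANSITION_SNP
        return VariantClass.TRANSVERSION_SNP
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    if len(alt) < len(ref):
        return VariantClass.DELETION
    return VariantClass.OTHER


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Per-strain variant-class counts with pooled percentage fractions.

    ``counts[strain][cls]`` are the per-strain class counts; totals and the
    pooled fractions (percent of all variants that are insertions / SNPs /
    deletions, and percent of SNPs that are transitions) are derived.
    Fractions are ``None`` on an empty table.
    """

    counts: dict[Strain, dict[VariantClass, int]]

    def __post_init__(self) -> None:
        for strain in Strain:
            per = self.counts.setdefault(strain, {})
            for cls in VariantClass:
                per.setdefault(cls, 0)

    def strain_total(self, strain: Strain) -> int:
        return sum(self.counts[strain].values())

    @property
    def grand_total(self) -> int:
        return sum(self.strain_total(s) for s in Strain)

    def pooled(self, cls: VariantClass) -> int:
        return sum(self.counts[s][cls] for s in Strain)

    @property
    def snp_count(self) -> int:
        return self.pooled(VariantClass.TRANSITION_SNP) + self.pooled(
            VariantClass.TRANSVERSION_SNP
        )

    def _pct(self, n: int, total: int) -> Optional[float]:
        if total == 0:
            return None
        return round_half_up(100.0 * n / total, 1)

    @property
    def insertion_pct(self) -> Optional[float]:
        return self._pct(self.pooled(VariantClass.INSERTION), self.grand_total)

    @property
    def snp_pct(self) -> Optional[float]:
        return self._pct(self.snp_count, self.grand_total)

    @property
    def deletion_pct(self) -> Optional[float]:
        return self._pct(self.pooled(VariantClass.DELETION), self.grand_total)

    @property
    def transition_pct(self) -> Optional[float]:
        """Transitions as a percentage of SNPs (both strains pooled)."""
        return self._pct(self.pooled(VariantClass.TRANSITION_SNP), self.snp_count)

    def to_frame(self):
        """Render as a pandas DataFrame, classes x strains."""
        import pandas as pd

        data = {
            strain.value: {cls.value: self.counts[strain][cls] for cls in VariantClass}
            for strain in Strain
        }
        frame = pd.DataFrame(data)
        frame.loc["total"] = [self.strain_total(s) for s in Strain]
        return frame


def summarize_counts(
    counts: Mapping[Strain, Mapping[VariantClass, int]],
) -> SummaryTable:
    """Build a summary table directly from per-strain class counts."""
    return SummaryTable(
        {Strain(s): {VariantClass(c): int(n) for c, n in per.items()} for s, per in counts.items()}
    )


def summarize(finals_per_strain: Mapping[Strain, Sequence[object]]) -> SummaryTable:
    """Classify and tally finalist variants per carrier strain.

    ``finals_per_strain`` maps strain to ``FinalVariant``-like records; for
    multiallelic sites only the carrier strain's called allele is
    classified, so each finalist contributes exactly one class.
    """
    counts: dict[Strain, dict[VariantClass, int]] = {}
    for strain, finals in finals_per_strain.items():
        tally: Counter = Counter()
        for f in finals:
            tally[classify_variant(f.variant.ref, f.called_alt)] += 1
        counts[Strain(strain)] = dict(tally)
    return summarize_counts(counts)


@dataclass
class DensityTrack:
    """Per-chromosome variant counts in half-open fixed-width bins.

    Bin ``k`` covers 1-based positions ``[k*bin_size, (k+1)*bin_size)``
    (position 0 does not exist, so bin 0 is one position short); a variant
    exactly on a boundary belongs to the higher bin.  ``label`` carries the
    strain/zygosity the track describes.
    """

    bin_size: int
    counts: dict[str, np.ndarray]
    label: str = ""

    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def smoothed(self, window: int = 5) -> dict[str, np.ndarray]:
        """Centered moving average per chromosome (window must be odd)."""
        if window < 1 or window % 2 == 0:
            raise ValueError("smoothing window must be a positive odd integer")
        kernel = np.ones(window) / window
        return {
            chrom: np.convolve(arr.astype(float), kernel, mode="same")
            for chrom, arr in self.counts.items()
        }

    def to_bedgraph(self, path, smoothed: bool = False, window: int = 5) -> None:
        """Write the track as bedGraph (0-based half-open intervals)."""
        source = self.smoothed(window) if smoothed else self.counts
        with open(path, "w") as fh:
            name = self.label or "density"
            fh.write(f'track type=bedGraph name="{name}"\n')
            for chrom in sorted(source):
                arr = source[chrom]
                for k, value in enumerate(arr):
                    if value == 0:
                        continue
                    start = k * self.bin_size
                    fh.write(f"{chrom}\t{start}\t{start + self.bin_size}\t{value:g}\n")


def _positions(variants: Iterable[object]) -> Iterable[tuple[str, int]]:
    for v in variants:
        if isinstance(v, tuple):
            yield v[0], int(v[1])
        elif hasattr(v, "variant"):  # FinalVariant
            yield v.variant.chrom, v.variant.pos
        else:  # JointVariant or anything with chrom/pos
            yield v.chrom, v.pos


def bin_density(
    variants: Iterable[object],
    bin_size: int,
    exclude: Iterable[str] = (),
    label: str = "",
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> DensityTrack:
    """Count variants per fixed-width bin, per chromosome.

    ``variants`` may be ``(chrom, pos)`` tuples, ``JointVariant`` or
    ``FinalVariant`` records.  Chromosomes in ``exclude`` (e.g. Y, which the
    published density plot omits) are skipped.  Bin arrays extend to the
    chromosome length when known, else to the furthest observed position.
    Counts are conserved: the track total equals the number of included
    variants.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    excluded = set(exclude)
    per_chrom: dict[str, list[int]] = {}
    for chrom, pos in _positions(variants):
        if chrom in excluded:
            continue
        per_chrom.setdefault(chrom, []).append(pos // bin_size)
    counts: dict[str, np.ndarray] = {}
    for chrom, bins in per_chrom.items():
        if chrom_lengths and chrom in chrom_lengths:
            n_bins = chrom_lengths[chrom] // bin_size + 1
        else:
            n_bins = max(bins) + 1
        counts[chrom] = np.bincount(bins, minlength=n_bins).astype(np.int64)
    return DensityTrack(bin_size=bin_size, counts=counts, label=label)


@dataclass
class ClusterRegion:
    """A merged run of overlapping windows each holding >= min_count variants."""

    chrom: str
    start: int  # 1-based position of the first window's anchor variant
    end: int  # 1-based end of the last qualifying window (inclusive)
    count: int  # maximum variants in any single qualifying window

    def to_bed_fields(self) -> tuple[str, int, int, str]:
        """BED (0-based half-open) representation."""
        return (self.chrom, self.start - 1, self.end, f"n={self.count}")


def find_clusters(
    variants: Iterable[object],
    window_bp: int = 1000,
    min_count: int = 5,
) -> list[ClusterRegion]:
    """Find windows of ``window_bp`` holding at least ``min_count`` variants.

    A window anchored at a variant position ``p`` spans ``[p, p + window_bp)``.
    Qualifying windows that overlap are merged into one region reporting the
    maximum single-window count.  Regions are returned sorted by
    (chromosome, start).
    """
    if window_bp <= 0 or min_count <= 0:
        raise ValueError("window_bp and min_count must be positive")
    per_chrom: dict[str, list[int]] = {}
    for chrom, pos in _positions(variants):
        per_chrom.setdefault(chrom, []).append(pos)
    regions: list[ClusterRegion] = []
    for chrom in sorted(per_chrom):
        pos = sorted(per_chrom[chrom])
        hits: list[tuple[int, int, int]] = []  # (win_start, win_end_inclusive, count)
        j = 0
        for i in range(len(pos)):
            if j < i:
                j = i
            while j + 1 < len(pos) and pos[j + 1] < pos[i] + window_bp:
                j += 1
            count = j - i + 1
            if count >= min_count:
                hits.append((pos[i], pos[i] + window_bp - 1, count))
        # merge overlapping qualifying windows
        for start, end, count in hits:
            if regions and regions[-1].chrom == chrom and start <= regions[-1].end:
                regions[-1].end = max(regions[-1].end, end)
                regions[-1].count = max(regions[-1].count, count)
            else:
                regions.append(ClusterRegion(chrom, start, end, count))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions
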