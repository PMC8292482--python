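"""Score targeted re-sequencing genotypes against predicted strain variants.

The validation design genotypes individual animals — four rats per strain,
equal sexes — at amplicon targets centered on predicted strain-specific
variants.  A target whose PCR product was obtained is *confirmed* when

1. at least three rats of the predicted carrier strain are homozygous for
   the alternate allele, and
2. no rat of the opposite strain is homozygous alternate;

otherwise it *failed*.  Targets without a PCR product are excluded from
the rate denominator.  The positive rate is ``100 * confirmed / amplified``.

Missing genotypes count toward neither criterion: they are not
homozygous-alternate calls, so they neither support criterion 1 nor
violate criterion 2.  Heterozygous calls in carrier-strain rats likewise
do not support criterion 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import round_half_up
from .vcf_model import Strain

__all__ = [
    "GENOTYPE_STATES",
    "TargetStatus",
    "Rat",
    "Target",
    "ValidationMatrix",
    "ValidationResult",
    "confirm_target",
    "positive_rate",
]

GENOTYPE_STATES: tuple[str, ...] = ("hom-ref", "het", "hom-alt", "missing")


class TargetStatus(str, enum.Enum):
    CONFIRMED = "confirmed"
    FAILED = "failed"
    NOT_AMPLIFIED = "not_amplified"


@dataclass(frozen=True)
class Rat:
    rat_id: str
    strain: Strain
    sex: str = ""


@dataclass(frozen=True)
class Target:
    target_id: str
    predicted_strain: Strain


@dataclass
class ValidationMatrix:
    """Target x rat genotype matrix with per-target amplification flags."""

    targets: list[Target]
    rats: list[Rat]
    genotypes: dict[tuple[str, str], str] = field(default_factory=dict)
    amplified: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.target_id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids")
        rat_ids = [r.rat_id for r in self.rats]
        if len(set(rat_ids)) != len(rat_ids):
            raise ValueError("duplicate rat ids")
        for (tid, rid), g in self.genotypes.items():
            if g not in GENOTYPE_STATES:
                raise ValueError(f"unknown genotype state {g!r} at ({tid}, {rid})")
        for t in self.targets:
            self.amplified.setdefault(t.target_id, True)

    def genotype(self, target_id: str, rat_id: str) -> str:
        return self.genotypes.get((target_id, rat_id), "missing")

    def rats_of(self, strain: Strain) -> list[Rat]:
        return [r for r in self.rats if r.strain == strain]

    def target(self, target_id: str) -> Target:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(target_id)

    # ---- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.targets:
            row = {
                "target_id": t.target_id,
                "predicted_strain": t.predicted_strain.value,
                "amplified": int(self.amplified[t.target_id]),
            }
            for r in self.rats:
                row[r.rat_id] = self.genotype(t.target_id, r.rat_id)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, matrix_path, design_path) -> None:
        """Write the genotype matrix and a rat-design sidecar as TSV."""
        self.to_frame().to_csv(matrix_path, sep="\t", index=False)
        pd.DataFrame(
            [{"rat_id": r.rat_id, "strain": r.strain.value, "sex": r.sex} for r in self.rats]
        ).to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, design_path) -> "ValidationMatrix":
        design = pd.read_csv(design_path, sep="\t", dtype=str).fillna("")
        rats = [Rat(row.rat_id, Strain(row.strain), row.sex) for row in design.itertuples()]
        matrix = pd.read_csv(matrix_path, sep="\t", dtype=str)
        targets = []
        genotypes: dict[tuple[str, str], str] = {}
        amplified: dict[str, bool] = {}
        for row in matrix.itertuples(index=False):
            row_d = row._asdict()
            tid = row_d["target_id"]
            targets.append(Target(tid, Strain(row_d["predicted_strain"])))
            amplified[tid] = bool(int(row_d.get("amplified", 1)))
            for r in rats:
                genotypes[(tid, r.rat_id)] = row_d[r.rat_id]
        return cls(targets=targets, rats=rats, genotypes=genotypes, amplified=amplified)


@dataclass
class ValidationResult:
    """Per-target confirmation statuses and the overall positive rate."""

    status: dict[str, TargetStatus]
    confirmed_by_strain: dict[Strain, int]
    amplified_by_strain: dict[Strain, int]

    @property
    def n_confirmed(self) -> int:
        return sum(self.confirmed_by_strain.values())

    @property
    def n_amplified(self) -> int:
        return sum(self.amplified_by_strain.values())

    @property
    def n_failed(self) -> int:
        return self.n_amplified - self.n_confirmed

    @property
    def positive_rate(self) -> Optional[float]:
        """Percent of amplified targets confirmed, one decimal; None if none."""
        if self.n_amplified == 0:
            return None
        return round_half_up(100.0 * self.n_confirmed / self.n_amplified, 1)


def confirm_target(
    target: Target | str,
    matrix: ValidationMatrix,
    min_carriers: int = 3,
) -> TargetStatus:
    """Apply the two confirmation criteria to one target."""
    if isinstance(target, str):
        target = matrix.target(target)
    if not matrix.amplified.get(target.target_id, False):
        return TargetStatus.NOT_AMPLIFIED
    carrier = target.predicted_strain
    n_carrier_hom_alt = sum(
        matrix.genotype(target.target_id, r.rat_id) == "hom-alt"
        for r in matrix.rats_of(carrier)
    )
    n_opposite_hom_alt = sum(
        matrix.genotype(target.target_id, r.rat_id) == "hom-alt"
        for r in matrix.rats_of(carrier.opposite())
    )
    if n_carrier_hom_alt >= min_carriers and n_opposite_hom_alt == 0:
        return TargetStatus.CONFIRMED
    return TargetStatus.FAILED


def positive_rate(matrix: ValidationMatrix, min_carriers: int = 3) -> ValidationResult:
    """Score every target and compute the overall positive rate."""
    status: dict[str, TargetStatus] = {}
    confirmed = {s: 0 for s in Strain}
    amplified = {s: 0 for s in Strain}
    for t in matrix.targets:
        st = confirm_target(t, matrix, min_carriers=min_carriers)
        status[t.target_id] = st
        if st is not TargetStatus.NOT_AMPLIFIED:
            amplified[t.predicted_strain] += 1
        if st is TargetStatus.CONFIRMED:
            confirmed[t.predicted_strain] += 1
    return ValidationResult(
        status=status,
        confirmed_by_strain=confirmed,
        amplified_by_strain=amplified,
    )
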