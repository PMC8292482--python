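"""Shared fixtures: small seeded synthetic datasets and call-table builders."""

from __future__ import annotations

import pysam
import pytest

from isofilter.synthetic import (
    generate_reference,
    plant_variants,
    simulate_dataset,
    write_reference,
)
from isofilter.vcf_model import (
    JointVariant,
    Platform,
    PlatformCall,
    SampleKey,
    Strain,
    read_joint_vcf,
)

# platform order used by the call-table shorthand
PLATFORMS = (Platform.ILLUMINA, Platform.IONTORRENT, Platform.LINKEDREAD)


def make_variant(
    wli,
    wmi,
    ref: str = "A",
    alts=("G",),
    pos: int = 100,
    chrom: str = "1",
) -> JointVariant:
    """Build a six-call record from per-strain call triples.

    ``wli``/``wmi`` are sequences of three ``(genotype, gq, dp, ad)`` tuples
    in (Illumina, IonTorrent, LinkedRead) order; genotype ``None`` means a
    missing call.  ``gq``/``dp``/``ad`` may be omitted by passing shorter
    tuples.
    """
    calls = {}
    for strain, triple in ((Strain.WLI, wli), (Strain.WMI, wmi)):
        for platform, spec in zip(PLATFORMS, triple):
            spec = tuple(spec) + (None,) * (4 - len(spec))
            genotype, gq, dp, ad = spec
            calls[SampleKey(strain, platform)] = PlatformCall(
                genotype=genotype,
                gq=gq,
                dp=dp,
                ad=tuple(ad) if ad is not None else None,
            )
    return JointVariant(chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), calls=calls)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A seeded 1020-variant synthetic dataset with its truth table."""
    out = tmp_path_factory.mktemp("sim")
    paths = simulate_dataset(out, seed=7)
    seq, runs = generate_reference(200_000, 0.3, seed=7)
    variants, truths = plant_variants(seq, seed=8)
    return {
        "paths": paths,
        "sequence": seq,
        "runs": runs,
        "variants": read_joint_vcf(paths["vcf"]),
        "truths": truths,
    }


@pytest.fixture(scope="session")
def ref_fasta(tmp_path_factory):
    """A 20 kb reference FASTA with plentiful homopolymer runs."""
    seq, _ = generate_reference(20_000, 0.35, seed=11)
    path = write_reference(seq, tmp_path_factory.mktemp("ref") / "ref.fa")
    fasta = pysam.FastaFile(str(path))
    yield seq, fasta
    fasta.close()
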