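# isofilter

Cross-platform variant filtering and summarization for nearly-isogenic
strain pairs.

## The problem

Two inbred rat substrains, WLI and WMI, were bred from a common Wistar
Kyoto founder stock by bi-directional selection on forced-swim-test
immobility and then sib-mated for dozens of generations.  They are almost
coisogenic: only a few thousand genomic positions distinguish them, which
is what makes them attractive for reduced-complexity crosses — but it also
means that any platform-specific sequencing artifact is large relative to
the real signal.  Whole-genome sequencing of each strain on three
platforms (Illumina short reads, Ion Torrent, 10X Chromium linked reads),
per-sample variant calling and joint genotyping yield a six-sample VCF
with millions of raw candidate sites, almost all of which are either
shared differences to the reference genome or technology artifacts.

`isofilter` implements the downstream analysis as a tested, reusable
library and CLI: a ten-step hard-filter cascade that reduces the joint
call set to high-confidence strain-distinguishing variants, plus variant
classification (Ti/Tv, indels), density/cluster reporting, SnpEff
annotation summaries, and concordance scoring of targeted-resequencing
validation data.  Because no joint call set for these strains is publicly
deposited, the package also ships a seeded synthetic-data generator that
plants variants of known class — true strain differences, shared variants,
homopolymer deletion artifacts, collapsed-duplication pseudo-hets,
low/high-depth and uncertain sites — so that every pipeline decision is
testable against a machine-readable truth table.

## The filtering cascade

For each site, each strain's three platform calls are summarized by the
call with the highest genotype quality (FORMAT/GQ; ties broken Illumina >
linked read > Ion Torrent).  Writing `GQ_s` for the best call of strain
`s`, the cascade removes a site when:

 1. **depth** — `sum(DP) < 10` over all six samples, or `DP > 300` on any
    single sample;
 2. **equal best** — both strains' best calls are identical (a shared
    difference to the reference);
 3. *(flag)* within-strain concordance of all three platforms is recorded,
    never removed on;
 4. **uncertain** — at least 5 of 6 calls are `./.`;
 5. **equal best, re-applied**;
 6. **low-quality dissent** — five calls agree and the lone dissenter has
    `GQ < 10`;
 7. **allele balance** — one allele holds > 90 % of pooled AD reads while
    each strain contributes >= 25 % of reads;
 8. **cross-platform dispute** — a platform contradicts its strain's best
    call at `GQ >= 30`;
 9. **strain difference + quality tier** — keep only sites where exactly
    one strain is `0/0`, the carrier strain supports its call at
    `GQ >= 30`, and no sample opposes it at `GQ >= 10` (opposite-strain
    `0/0` calls are required evidence, not opposition);
10. **homopolymer deletions** — a carrier-strain deletion whose deleted
    bases lie in a reference run of >= 2 identical nucleotides must be
    called by >= 2 platforms of that strain (single-platform homopolymer
    deletions are the classic Ion Torrent base-calling error).

Survivors are exported per strain and zygosity; every input record carries
a trace naming the step that removed it, so the per-step counts form a
conservation identity (a flowchart of the run).

## Worked example

The checked-in `examples/config.toml` simulates a 200 kb reference and a
1,020-record joint VCF containing all nine planted classes, then runs the
cascade:

```sh
isofilter run-all --config examples/config.toml --out-dir out/
```

which logs the flowchart and prints the manifest summary:

```
INFO isofilter: removed at depth                        60
INFO isofilter: removed at equal_best                  480
INFO isofilter: removed at uncertain                    30
INFO isofilter: removed at equal_best_reapplied          0
INFO isofilter: removed at low_q_discordant             40
INFO isofilter: removed at allele_balance                0
INFO isofilter: removed at cross_platform_dispute        0
INFO isofilter: removed at require_difference            0
INFO isofilter: removed at quality_tier                  0
INFO isofilter: removed at homopolymer_deletion        150
INFO isofilter: survived    260 of 1020 input records
{
  "n_input": 1020,
  "final_counts": {
    "WLI_hom": 85,
    "WMI_hom": 115,
    "WLI_het": 28,
    "WMI_het": 32
  }
}
```

Reading the run: the 60 low/high-depth plants die at the depth step, the
400 shared variants and 80 collapsed pseudo-hets at the equal-best step
(both strains make the same call), the 30 five-missing sites at the
uncertain step, the 40 weak dissenters at the low-quality step, and all
150 single-platform homopolymer deletions at the final step.  Exactly the
260 planted true strain differences survive (200 homozygous + 60
heterozygous, split between carrier strains by the generator), and the
removal counts plus survivors sum to the 1,020 inputs.  `out/filter/`
holds the per-strain x zygosity VCFs, the per-site trace and the
flowchart TSV; `out/manifest.json` records inputs, checksums and counts.

Library use mirrors the CLI:

```python
from isofilter import read_joint_vcf, run_pipeline, summarize, Strain

variants = read_joint_vcf("out/sim/joint.vcf")
result = run_pipeline(variants, ref_fasta="out/sim/ref.fa")
finals = {s: result.finals_hom[s] + result.finals_het[s] for s in Strain}
print(result.step_counts, summarize(finals).to_frame())
```

## Layout

- `src/isofilter/vcf_model.py` — data model, VCF/FASTA I/O, homopolymer context
- `src/isofilter/filter_pipeline.py` — the ten-step cascade and traces
- `src/isofilter/classify.py` — Ti/Tv and indel classes, summary tables, density tracks, 1 kb clusters
- `src/isofilter/annotation.py` — ANN parsing, effect tables, gene-set arithmetic
- `src/isofilter/validation.py` — targeted-resequencing concordance
- `src/isofilter/synthetic.py` — seeded generators with truth tables
- `src/isofilter/cli.py` — `isofilter` subcommands and run manifests
- `docs/methods.md` — models, parameters, design choices and limitations
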