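# Example isofilter configuration.
#
# Every filtering threshold appears once, defaulted to the published
# operating point; delete a key to keep its default, change it to rerun
# the cascade at a different stringency.

# Jointly genotyped six-sample VCF (plain or bgzipped) and the reference
# FASTA.  Uncomment to analyse real data; when absent, the [simulate]
# section below generates both and they are picked up automatically.
#[inputs]
#vcf = "sim/joint.vcf"
#reference = "sim/ref.fa"

# Optional: map VCF sample columns to strain/platform when the file does
# not use the canonical STRAIN_PLATFORM column names.
#[samples]
#sample_01 = "WLI:ILLUMINA"
#sample_02 = "WLI:IONTORRENT"
#sample_03 = "WLI:LINKEDREAD"
#sample_04 = "WMI:ILLUMINA"
#sample_05 = "WMI:IONTORRENT"
#sample_06 = "WMI:LINKEDREAD"

[filter]
min_total_depth = 10      # min reads summed over all six samples
max_single_depth = 300    # max reads on any single sample
q_low = 10                # Phred GQ: dissent below this is noise
q_mid = 20                # middle reporting tier
q_high = 30               # a finalist needs a supporting call at or above this
allele_majority = 0.90    # pooled-read majority marking a shared allele
strain_share = 0.25       # both strains hold at least this read share
max_uncertain = 5         # missing (./.) calls that disqualify a site
cluster_window_bp = 1000  # window for variant-cluster reporting
upstream_window_bp = 5000 # upstream-of-gene proximity window
homopolymer_min_run = 2   # identical-base run length defining a homopolymer
min_supporting_platforms = 2  # platforms needed to keep a homopolymer deletion

# Optional: generate inputs instead of supplying [inputs] paths.
[simulate]
length = 200000             # reference length, bp
homopolymer_fraction = 0.3  # fraction of positions inside runs of >= 2
seed = 42

# Planted records per class; omit the table for the default mixture.
[simulate.classes]
true_diff_hom = 200
true_diff_het = 60
shared_variant = 400
homopolymer_artifact = 150
collapsed_pseudo_het = 80
low_depth = 40
high_depth = 20
uncertain_calls = 30
low_q_discordant = 40
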