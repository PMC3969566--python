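# Example configuration for `hetsel run-all`.
# Paths are resolved relative to the working directory.

# Aligned, indel-free allele sequences (FASTA, ACGT only).
fasta: alleles.fasta

# Exon/intron intervals on the alignment coordinate system,
# 1-based inclusive; concatenated exons must be divisible by 3.
annotation: annotation.yaml
# annotation.yaml contents look like:
#   exons: [[1, 150], [211, 420], [486, 767]]
#   introns: [[151, 210], [421, 485]]

# Optional: allele x tester binary incompatibility matrix (TSV, 0/1,
# header row of tester names, first column allele names).
matrix: incompatibility.tsv

# Optional (requires matrix): isolate counts per allele (TSV with
# columns "allele" and "count").
counts: counts.tsv

# Optional (requires counts): per-isolate plasmid presence (TSV with
# columns "allele" and "plasmid" in {0,1}).
# plasmid: plasmid.tsv

# Site-class models to fit; subset of [M0, M1, M2, M3k3, M7, M8].
models: [M0, M1, M2, M7, M8]

# Nucleotide distance model for the NJ tree: p | jc69 | k2p.
distance_model: k2p

# Bootstrap replicates for branch supports.
bootstrap_replicates: 1000

# Equilibrium codon frequency model: f3x4 | f1x4 | f61.
freqs: f3x4

# Global seed: bootstrap resampling, optimizer restarts, exact tests.
seed: 1

output_dir: hetsel_out
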