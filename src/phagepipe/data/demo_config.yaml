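# Demo pipeline configuration: a 3-cluster synthetic family of twelve
# 2.5-kbp genomes plus cos3/DTR packaging round trips.  Identical to the
# built-in defaults; edit and pass via `phagepipe run --config`.
seed: 1
n_clusters: 3
genomes_per_cluster: 4
genome_length_bp: 2500
genes_per_genome: 4
gc: 0.42
within_subcluster_divergence: 0.02
within_cluster_divergence: 0.25
between_cluster_divergence: 0.5
cos3_motif: CGACTGCCC
cos_spacing: 50
dtr_repeat_len: 377
read_coverage: 50.0
read_length: 150
max_motif_mismatch: 1
dtr_ratio_threshold: 1.6
dtr_sharpness_window: 20
alpha_cutoff: 8
min_orf_len: 75
cluster_ani_threshold: 60.0
subcluster_ani_threshold: 90.0
pham_identity_threshold: 32.5
pham_coverage_threshold: 0.5
evidence_quality: strong
log_level: INFO
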