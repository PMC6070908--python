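"""End-to-end orchestration of the comparative-genomics pipeline.

``run_pipeline`` drives: simulate a genome family -> stamp packaging signals
-> detect genome ends and reorient -> annotate genes -> ANI matrix ->
cluster/subcluster assignment -> pham partitioning -> gene-content distances
and NJ tree -> per-genome statistics.  Every stage writes its outputs under
a run directory, and a manifest records seeds, the configuration hash and a
checksum per output so runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotate as ann
from . import clustering as clu
from . import similarity as sim
from . import simulate as simdata
from . import stats as st
from . import termini as ter
from .records import PackagingCall, write_fasta, write_fastq

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Human-editable configuration; every threshold used anywhere in the
    pipeline is surfaced here."""

    seed: int = 1
    # synthetic family layout: n_clusters x members, per-level divergences
    n_clusters: int = 3
    genomes_per_cluster: int = 4
    genome_length_bp: int = 2500
    genes_per_genome: int = 4
    gc: float = 0.42
    within_subcluster_divergence: float = 0.02
    within_cluster_divergence: float = 0.25
    between_cluster_divergence: float = 0.5
    # packaging
    cos3_motif: str = simdata.DEFAULT_COS3_MOTIF
    cos_spacing: int = 50
    dtr_repeat_len: int = 377
    read_coverage: float = 50.0
    read_length: int = 150
    # detection / annotation / clustering thresholds
    max_motif_mismatch: int = 1
    dtr_ratio_threshold: float = 1.6
    dtr_sharpness_window: int = 20
    alpha_cutoff: int = ann.DEFAULT_ALPHA_CUTOFF
    min_orf_len: int = ann.DEFAULT_MIN_ORF_LEN
    cluster_ani_threshold: float = clu.CLUSTER_ANI_THRESHOLD
    subcluster_ani_threshold: float = clu.SUBCLUSTER_ANI_THRESHOLD
    pham_identity_threshold: float = clu.PHAM_IDENTITY_THRESHOLD
    pham_coverage_threshold: float = clu.PHAM_COVERAGE_THRESHOLD
    evidence_quality: str = "strong"
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_family(cfg: PipelineConfig):
    """Synthetic genome family with cluster/subcluster ground truth.

    Cluster seeds diverge from one common ancestor at the between-cluster
    fraction; each cluster holds two subclusters (the seed plus a
    within-subcluster twin, and a within-cluster divergent pair)."""
    rng = np.random.default_rng(cfg.seed)
    ancestor, truth = simdata.make_genome(
        simdata.GenomeSpec(
            length_bp=cfg.genome_length_bp, n_genes=cfg.genes_per_genome,
            gc=cfg.gc, seed=cfg.seed,
        )
    )
    genomes, truth_clusters = [], {}
    for ci in range(cfg.n_clusters):
        if ci == 0:
            seed_genome = ancestor
        else:
            seed_genome = simdata.mutate_family(
                ancestor, [cfg.between_cluster_divergence], seed=int(rng.integers(2**31))
            )[0]
        seed_genome.id = f"c{ci + 1}a1"
        members = [seed_genome]
        twin = simdata.mutate_family(
            seed_genome, [cfg.within_subcluster_divergence], seed=int(rng.integers(2**31))
        )[0]
        twin.id = f"c{ci + 1}a2"
        members.append(twin)
        far = simdata.mutate_family(
            seed_genome, [cfg.within_cluster_divergence], seed=int(rng.integers(2**31))
        )[0]
        far.id = f"c{ci + 1}b1"
        members.append(far)
        if cfg.genomes_per_cluster >= 4:
            far_twin = simdata.mutate_family(
                far, [cfg.within_subcluster_divergence], seed=int(rng.integers(2**31))
            )[0]
            far_twin.id = f"c{ci + 1}b2"
            members.append(far_twin)
        genomes.extend(members[: cfg.genomes_per_cluster])
        truth_clusters[f"cluster_{ci + 1}"] = [g.id for g in members[: cfg.genomes_per_cluster]]
    return ancestor, truth, genomes, truth_clusters


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg), "config_hash": cfg.digest(), "outputs": {}}

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)
        logger.info("wrote %s", path)
        return path

    # stage 1: simulate
    ancestor, anc_truth, genomes, truth_clusters = build_family(cfg)
    emit("genomes.fasta", lambda p: write_fasta(genomes, p))
    emit(
        "truth_clusters.json",
        lambda p: p.write_text(json.dumps(truth_clusters, indent=2)),
    )

    # stage 2: packaging demo on the ancestor (cos3 + DTR round trips)
    asm, truth_cos = simdata.apply_packaging(
        ancestor, anc_truth, "cos3", motif=cfg.cos3_motif,
        rotation=int(np.random.default_rng(cfg.seed + 1).integers(len(ancestor))),
        spacing=cfg.cos_spacing,
    )
    call, oriented = ter.classify_packaging(
        asm, motifs_cos3=(cfg.cos3_motif,),
        max_mismatch=cfg.max_motif_mismatch,
        terminase_anchor=truth_cos.gene_intervals[truth_cos.small_terminase_index][0],
    )
    emit("ancestor_oriented.fasta", lambda p: write_fasta([oriented], p))
    emit("packaging_call.json", lambda p: call.to_json(p))

    dtr_src, dtr_truth = simdata.make_genome(
        simdata.GenomeSpec(
            length_bp=max(10 * cfg.dtr_repeat_len, cfg.genome_length_bp),
            n_genes=max(3, cfg.genes_per_genome), gc=cfg.gc, seed=cfg.seed + 7,
        )
    )
    dtr_asm, dtr_truth = simdata.apply_packaging(
        dtr_src, dtr_truth, "dtr", repeat_len=cfg.dtr_repeat_len, rotation=cfg.seed * 13
    )
    reads = simdata.simulate_reads(
        dtr_asm.notes["physical_molecule"], "linear", cfg.read_coverage,
        cfg.read_length, seed=cfg.seed + 2,
    )
    emit("dtr_reads.fastq", lambda p: write_fastq(reads, p))
    profile = ter.coverage_pileup(reads, dtr_asm)
    emit("dtr_depth.tsv", lambda p: ter.write_depth_tsv(profile, p))
    dtr_call = ter.detect_dtr(
        profile, dtr_asm, cfg.dtr_ratio_threshold, cfg.dtr_sharpness_window
    )
    emit(
        "dtr_call.json",
        lambda p: p.write_text(json.dumps({k: v for k, v in dtr_call.to_dict().items() if k != "notes"}, indent=2)),
    )

    # stage 3: annotate every genome
    proteomes, all_proteins, gene_calls = {}, [], {}
    for genome in genomes:
        truth_ev = _truth_for(genome, anc_truth)
        evidence = ann.EvidenceBundle.from_table(
            simdata.make_evidence(truth_ev, cfg.evidence_quality, seed=cfg.seed + 11)
        )
        genes, report = ann.annotate_genome(
            genome, evidence, cutoff=cfg.alpha_cutoff, min_len=cfg.min_orf_len
        )
        gene_calls[genome.id] = (genes, report)
        proteomes[genome.id] = _translate_genes(genome, genes)
        for gi, prot in enumerate(proteomes[genome.id]):
            all_proteins.append((genome.id, f"gp{gi + 1}", prot))
    emit(
        "annotation.gff3",
        lambda p: _write_all_gff3(gene_calls, genomes, p),
    )

    # stage 4: similarity + clustering
    matrix = sim.ani_matrix(genomes)
    emit("ani_matrix.tsv", lambda p: matrix.to_tsv(p))
    assignment = clu.pick_representatives(
        clu.assign_clusters(
            matrix, cfg.cluster_ani_threshold, cfg.subcluster_ani_threshold
        ),
        matrix,
    )
    emit(
        "clusters.json",
        lambda p: p.write_text(json.dumps(assignment.to_dict(), indent=2)),
    )

    # stage 5: phams + gene-content tree
    phams = clu.group_phams(
        all_proteins, cfg.pham_identity_threshold, cfg.pham_coverage_threshold
    )
    emit("phams.tsv", lambda p: _write_phams(phams, p))
    labels, dmat = clu.gene_content_distance(phams, [g.id for g in genomes])
    emit("gene_content.nex", lambda p: clu.write_nexus_distances(labels, dmat, p))
    emit("gene_content_nj.nwk", lambda p: Path(p).write_text(clu.nj_tree(labels, dmat) + "\n"))

    # stage 6: statistics
    rows = []
    for genome in genomes:
        genes, report = gene_calls[genome.id]
        cl = assignment.cluster_of(genome.id)
        sc = assignment.subcluster_of(genome.id)
        gs = st.genome_summary(
            genome, genes, PackagingCall(), report["coding_fraction"], cl.name, sc.name
        )
        rows.append(gs)
    emit("genome_stats.tsv", lambda p: _write_stats(rows, p))
    lengths = {r.length_bp for r in rows}
    if len(rows) >= 3 and len(lengths) > 1:
        fit = st.fit_genes_vs_length([(r.length_bp / 1000.0, r.n_genes) for r in rows])
        emit(
            "genes_vs_length.json",
            lambda p: p.write_text(json.dumps(dataclasses.asdict(fit), indent=2)),
        )
    else:
        logger.info("genes-vs-length regression skipped: no length variance in family")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", outdir)
    return outdir


def _truth_for(genome, anc_truth):
    # family members share the ancestor's gene grid (substitutions only)
    return simdata.SyntheticTruth(
        gene_intervals=anc_truth.gene_intervals,
        small_terminase_index=anc_truth.small_terminase_index,
    )


def _translate_genes(genome, genes):
    from Bio.Seq import Seq

    prots = []
    for g in genes:
        lo, hi = g.interval
        text = genome.slice_circular(lo, (hi - lo) % len(genome) + 1)
        if g.strand == "-":
            from .records import revcomp

            text = revcomp(text)
        prots.append(str(Seq(text[: len(text) // 3 * 3]).translate()).rstrip("*"))
    return prots


def _write_all_gff3(gene_calls, genomes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for genome in genomes:
            genes, _ = gene_calls[genome.id]
            for i, g in enumerate(genes, start=1):
                lo, hi = g.interval
                fh.write(
                    f"{genome.id}\tphagepipe\tgene\t{lo}\t{hi}\t{g.alpha.total}\t"
                    f"{g.strand}\t0\tID={genome.id}_gene_{i};product={g.product};"
                    f"alpha={g.alpha.total};category={g.category}\n"
                )


def _write_phams(phams, path) -> None:
    with open(path, "w") as fh:
        fh.write("pham_id\tgenome_id\tgene_id\torpham\n")
        for ph in phams:
            for gid, gene in ph.members:
                fh.write(f"{ph.id}\t{gid}\t{gene}\t{int(ph.is_orpham)}\n")


def _write_stats(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tlength_bp\tgc_percent\tstrategy\tn_genes\t"
            "genes_per_kbp\tcoding_fraction_pct\tcluster\tsubcluster\n"
        )
        for r in rows:
            fh.write(
                f"{r.genome_id}\t{r.length_bp}\t{r.gc_percent:.1f}\t{r.strategy}\t"
                f"{r.n_genes}\t{r.density_2dp:.2f}\t{r.coding_fraction_pct:.1f}\t"
                f"{r.cluster}\t{r.subcluster}\n"
            )
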