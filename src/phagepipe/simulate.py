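"""Synthetic phage-genome generator with known ground truth.

Emulates the salient features of *Paenibacillus larvae* phage genomes so the
whole pipeline can be exercised without downloading real assemblies:

* gene-dense genomes (~90-95% coding) laid out as operons with small
  start/stop overlaps, genes on both strands with a forward bias;
* a fixed non-uniform codon-usage table, so a self-trained coding-potential
  model has a real statistical signal to learn;
* AGGAGG ribosome-binding sites planted upstream of gene starts where the
  intergenic gap leaves room;
* cos-type junction motifs written at a fixed spacing upstream of the small
  terminase gene, and direct terminal repeats yielding linear "physical
  molecules" that carry the repeat at both ends;
* error-free reads emulating a PCR-free library (fragment ends coincide with
  molecule termini, which is what makes terminal-repeat coverage doubling
  sharply delimited);
* genome families with controlled pairwise divergence, and evidence tables
  emulating gene-caller votes and homology hits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import GenomeRecord, PackagingCall, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")
_START_WEIGHTS = (0.80, 0.15, 0.05)

SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)

# Fixed codon-usage multipliers: a reproducible stand-in for organismal codon
# bias (lognormal spread around neutrality, frozen at module import).
_usage_rng = np.random.default_rng(987201)
CODON_USAGE = dict(zip(SENSE_CODONS, np.exp(_usage_rng.normal(0.0, 0.8, len(SENSE_CODONS)))))

MIN_GENE_LEN = 150  # bp incl. start and stop codon
LEADING_GAP = 50  # bp before gene 1 (the canonical cos spacing)
TAIL_GAP_MIN = 30  # bp reserved after the last gene (room for a cos motif)
OPERON_OVERLAP = 4  # bp shared by operonic start/stop junctions (ATGA / TCAT)
RBS = "AGGAGG"
RBS_SPACER = 7  # bases between RBS and the start codon

DEFAULT_COS3_MOTIF = "CGACTGCCC"

# Product strings cycled over truth genes when emitting evidence tables.  The
# order mirrors a typical phage genome layout (packaging/structural genes at
# the front, lysis cassette, then replication and regulatory genes); two
# "hypothetical protein" genes sit between the major tail protein and the
# tape measure protein so the tail-assembly synteny rule has its substrate.
PRODUCT_CYCLE = (
    "small terminase",
    "large terminase",
    "portal protein",
    "Clp protease ClpP",
    "major capsid protein",
    "head-tail adaptor",
    "major tail protein",
    "hypothetical protein",
    "hypothetical protein",
    "tail tape measure protein",
    "minor tail protein",
    "N-acetylmuramoyl-l-alanine amidase",
    "holin",
    "DNA polymerase",
    "DNA helicase",
    "DNA primase",
    "HNH endonuclease",
    "XRE family transcriptional regulator",
    "antirepressor",
    "integrase",
    "DNA methyltransferase",
    "HicA toxin",
    "ABC transporter",
    "metallo-hydrolase",
)


@dataclass
class GenomeSpec:
    """Target parameters for one synthetic genome."""

    length_bp: int
    n_genes: int
    gc: float = 0.42
    operon_fraction: float = 0.3
    mean_intergenic_gap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 1000:
            raise ValueError("length_bp must be >= 1000")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.operon_fraction <= 1.0:
            raise ValueError("operon_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic genome."""

    gene_intervals: list  # [(start, stop, strand)] 1-based inclusive; start > stop => wraps
    small_terminase_index: int = 0
    packaging: PackagingCall = field(default_factory=PackagingCall)
    family_divergences: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))

    def __post_init__(self) -> None:
        self.family_divergences = np.asarray(self.family_divergences, dtype=float)
        m = self.family_divergences
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("family_divergences must be square")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("family_divergences must be symmetric with zero diagonal")
        if not 0 <= self.small_terminase_index < len(self.gene_intervals):
            raise ValueError("small_terminase_index out of range")

    def to_dict(self) -> dict:
        return {
            "gene_intervals": [list(g) for g in self.gene_intervals],
            "small_terminase_index": self.small_terminase_index,
            "packaging": self.packaging.to_dict(),
            "family_divergences": self.family_divergences.tolist(),
        }


def _codon_weights(gc: float) -> np.ndarray:
    pbase = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    w = np.array(
        [pbase[c[0]] * pbase[c[1]] * pbase[c[2]] * CODON_USAGE[c] for c in SENSE_CODONS]
    )
    return w / w.sum()


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _sample_codons(rng, weights, n, first_base=None, last_base=None):
    """n sense codons; optionally constrain the first codon's first base or
    the last codon's last base (operon junction bookkeeping)."""
    idx = rng.choice(len(SENSE_CODONS), size=n, p=weights)
    codons = [SENSE_CODONS[i] for i in idx]
    if first_base is not None and n:
        codons[0] = _constrained_codon(rng, weights, 0, first_base)
    if last_base is not None and n:
        codons[-1] = _constrained_codon(rng, weights, 2, last_base)
    return codons

def _constrained_codon(rng, weights, pos, base):
    mask = np.array([c[pos] == base for c in SENSE_CODONS])
    w = weights * mask
    w = w / w.sum()
    return SENSE_CODONS[rng.choice(len(SENSE_CODONS), p=w)]


def make_genome(spec: GenomeSpec) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate one gene-dense genome plus its ground truth.

    Gene 1 (the small terminase by convention) starts at base 51, leaving the
    50-bp canonical spacer in front of it; the final intergenic gap is kept
    >= 30 bp so a cos motif can later be written over the genome tail.
    Raises ``ValueError`` for infeasible specs and ``RuntimeError`` if the
    realized coding fraction falls outside [0.85, 0.97].
    """
    rng = np.random.default_rng(spec.seed)
    L, n = spec.length_bp, spec.n_genes

    if n * MIN_GENE_LEN + LEADING_GAP + TAIL_GAP_MIN > L:
        raise ValueError(
            f"infeasible spec: {n} genes x {MIN_GENE_LEN} bp minimum plus "
            f"{LEADING_GAP + TAIL_GAP_MIN} bp of fixed gaps exceeds {L} bp"
        )

    # Strands: forward-biased 70/30, in runs so operons can form.
    strands = ["+" if rng.random() < 0.7 else "-" for _ in range(n)]
    operonic = [
        strands[i] == strands[i + 1] and rng.random() < spec.operon_fraction
        for i in range(n - 1)
    ]

    inner_gaps = [
        0 if operonic[i] else max(4, int(rng.poisson(spec.mean_intergenic_gap)))
        for i in range(n - 1)
    ]
    n_operons = sum(operonic)

    def coding_budget(gaps):
        return L - LEADING_GAP - TAIL_GAP_MIN - sum(gaps) + OPERON_OVERLAP * n_operons

    budget = coding_budget(inner_gaps)
    if budget < n * MIN_GENE_LEN:  # shrink gaps to fit
        scale = max(0.0, (budget + sum(inner_gaps) - n * MIN_GENE_LEN) / max(1, sum(inner_gaps)))
        inner_gaps = [0 if operonic[i] else max(4, int(g * scale)) for i, g in enumerate(inner_gaps)]
        budget = coding_budget(inner_gaps)
        if budget < n * MIN_GENE_LEN:
            raise ValueError("infeasible spec: cannot fit genes after shrinking gaps")

    # Gene lengths: lognormal weights, snapped to codons, summing to <= budget.
    w = rng.lognormal(0.0, 0.5, n)
    lens = np.maximum(MIN_GENE_LEN, (w / w.sum() * budget).astype(int))
    lens = (lens // 3) * 3
    while lens.sum() > budget:
        i = int(np.argmax(lens))
        lens[i] -= 3
    lens = lens.tolist()

    # Lay out intervals left to right.
    intervals = []
    s = LEADING_GAP + 1
    for i in range(n):
        e = s + lens[i] - 1
        intervals.append((s, e, strands[i]))
        if i < n - 1:
            s = e - (OPERON_OVERLAP - 1) if operonic[i] else e + 1 + inner_gaps[i]
    if intervals[-1][1] > L - TAIL_GAP_MIN:
        raise RuntimeError("layout overran the genome tail")

    cells: list[str | None] = [None] * L
    weights = _codon_weights(spec.gc)

    def put(pos0: int, s_: str) -> None:
        for k, ch in enumerate(s_):
            cells[pos0 + k] = ch

    for i, (gs, ge, strand) in enumerate(intervals):
        ov_prev = i > 0 and operonic[i - 1]
        ov_next = i < n - 1 and operonic[i]
        n_inner = (ge - gs + 1) // 3 - 2
        if strand == "+":
            # layout: start codon | inner codons | stop codon
            start = "ATG" if ov_prev else rng.choice(START_CODONS, p=_START_WEIGHTS)
            stop = "TGA" if ov_next else rng.choice(STOP_CODONS)
            inner = _sample_codons(
                rng, weights, n_inner,
                first_base="A" if ov_prev else None,   # base shared with upstream stop
                last_base="A" if ov_next else None,    # base shared with downstream start
            )
            body = start + "".join(inner) + stop
            if ov_prev:
                body = body[OPERON_OVERLAP:]  # ATGA junction already written
                put(gs - 1 + OPERON_OVERLAP, body)
            else:
                put(gs - 1, body)
            if ov_next:
                put(ge - OPERON_OVERLAP, "ATGA")
        else:
            # reverse-strand gene: forward cells hold the reverse complement
            start = "ATG" if ov_next else rng.choice(START_CODONS, p=_START_WEIGHTS)
            stop = "TGA" if ov_prev else rng.choice(STOP_CODONS)
            inner = _sample_codons(
                rng, weights, n_inner,
                first_base="A" if ov_next else None,
                last_base="A" if ov_prev else None,
            )
            body = revcomp(start + "".join(inner) + stop)  # forward-coordinate text
            if ov_prev:
                body = body[OPERON_OVERLAP:]  # TCAT junction written by prev gene
                put(gs - 1 + OPERON_OVERLAP, body)
            else:
                put(gs - 1, body)
            if ov_next:
                put(ge - OPERON_OVERLAP, "TCAT")

    # Ribosome-binding sites in free intergenic space.
    for gs, ge, strand in intervals:
        if strand == "+":
            lo = gs - 1 - RBS_SPACER - len(RBS)
            if lo >= 0 and all(cells[lo + k] is None for k in range(len(RBS))):
                put(lo, RBS)
        else:
            lo = ge + RBS_SPACER
            if lo + len(RBS) <= L and all(cells[lo + k] is None for k in range(len(RBS))):
                put(lo, revcomp(RBS))

    free = [i for i, c in enumerate(cells) if c is None]
    fill = _random_bases(rng, len(free), spec.gc)
    for i, ch in zip(free, fill):
        cells[i] = ch
    seq = "".join(cells)

    covered = np.zeros(L, dtype=bool)
    for gs, ge, _ in intervals:
        covered[gs - 1 : ge] = True
    cf = covered.mean()
    if not 0.85 <= cf <= 0.97:
        raise RuntimeError(f"coding fraction {cf:.3f} outside [0.85, 0.97]")

    genome = GenomeRecord(
        id=f"synth_{spec.seed}",
        seq=seq,
        topology="circular_permuted",
        notes={"coding_fraction": round(float(cf), 4), "spec_seed": spec.seed},
    )
    truth = SyntheticTruth(gene_intervals=intervals, small_terminase_index=0)
    return genome, truth


def _rotate_interval(iv, r, L):
    s, e, strand = iv
    s2 = (s - 1 - r) % L + 1
    e2 = (e - 1 - r) % L + 1
    return (s2, e2, strand)


def apply_packaging(
    genome: GenomeRecord,
    truth: SyntheticTruth,
    strategy: str,
    motif: str | None = None,
    repeat_len: int | None = None,
    rotation: int = 0,
    spacing: int = LEADING_GAP,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Stamp a packaging signal onto a canonical genome and rotate it.

    cos: the motif is written so its final base lies ``spacing`` bp upstream
    of the small-terminase start; the canonical origin (base 1) is the base
    after the motif.  dtr: the repeat is the first ``repeat_len`` bases of
    the canonical genome; the packaged linear molecule (stored under
    ``notes["physical_molecule"]``) carries it at both ends while the
    collapsed assembly carries it once.
    """
    L = len(genome)
    seq = genome.seq
    term_start = truth.gene_intervals[truth.small_terminase_index][0]

    if strategy in ("cos3", "cos5"):
        if motif is None or len(motif) < 5:
            raise ValueError("cos packaging requires a motif of length >= 5")
        if set(motif) - set("ACGT"):
            raise ValueError("motif must be over ACGT")
        m = len(motif)
        # motif occupies [term_start - spacing - m, term_start - spacing - 1] (circular)
        first0 = (term_start - spacing - m - 1) % L  # 0-based
        motif_cells = [(first0 + k) % L for k in range(m)]
        for gs, ge, _ in truth.gene_intervals:
            gene_cells = set(range(gs - 1, ge))
            if gene_cells & set(motif_cells):
                raise ValueError("cos motif placement collides with a truth gene")
        arr = list(seq)
        for k, pos in enumerate(motif_cells):
            arr[pos] = motif[k]
        stamped = "".join(arr)
        origin0 = (first0 + m) % L  # base 1 of the canonical orientation
        canonical = stamped[origin0:] + stamped[:origin0]
        r = rotation % L
        assembly = canonical[r:] + canonical[:r]
        junction = (0 - r) % L + 1  # canonical base 1 within the assembly
        call = PackagingCall(
            strategy=strategy, overhang_seq=motif, overhang_len=m,
            junction=junction, mismatches=0,
        )
        shift = (origin0 + r) % L  # total rotation applied to input coordinates
        intervals = [_rotate_interval(iv, shift, L) for iv in truth.gene_intervals]
        rec = GenomeRecord(
            id=genome.id, seq=assembly, topology="circular_permuted",
            notes={**genome.notes, "packaging": strategy},
        )
        new_truth = SyntheticTruth(
            gene_intervals=intervals,
            small_terminase_index=truth.small_terminase_index,
            packaging=call,
            family_divergences=truth.family_divergences,
        )
        return rec, new_truth

    if strategy == "dtr":
        if repeat_len is None or repeat_len < 50:
            raise ValueError("dtr packaging requires repeat_len >= 50")
        canonical = seq
        physical = canonical + canonical[:repeat_len]
        r = rotation % L
        assembly = canonical[r:] + canonical[:r]
        junction = (0 - r) % L + 1
        call = PackagingCall(strategy="dtr", dtr_len=repeat_len, junction=junction)
        intervals = [_rotate_interval(iv, r, L) for iv in truth.gene_intervals]
        rec = GenomeRecord(
            id=genome.id, seq=assembly, topology="circular_permuted",
            notes={**genome.notes, "packaging": "dtr", "physical_molecule": physical},
        )
        new_truth = SyntheticTruth(
            gene_intervals=intervals,
            small_terminase_index=truth.small_terminase_index,
            packaging=call,
            family_divergences=truth.family_divergences,
        )
        return rec, new_truth

    raise ValueError(f"unknown packaging strategy {strategy!r}")


def simulate_reads(
    molecule: str,
    topology: str,
    coverage: float,
    read_len: int = 150,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[tuple[str, str]]:
    """Error-free reads emulating a PCR-free library.

    Circular molecules: start positions uniform, reads wrap the origin.
    Linear molecules: fragment offsets uniform over [-(read_len-1), L-1] and
    fragments are truncated at both molecule termini — the termini behave as
    real fragment ends, giving uniform coverage with sharp edges at the ends
    of the molecule (the property PAUSE-style repeat detection relies on).
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    L = len(molecule)
    if read_len >= L:
        raise ValueError("read_len must be shorter than the molecule")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * L / read_len))
    reads = []
    if topology == "circular":
        doubled = molecule + molecule
        starts = rng.integers(0, L, size=n_reads)
        for i, s in enumerate(starts):
            reads.append((f"read_{i}", doubled[s : s + read_len]))
    elif topology == "linear":
        offsets = rng.integers(-(read_len - 1), L, size=n_reads)
        for i, u in enumerate(offsets):
            seq = molecule[max(0, u) : min(L, u + read_len)]
            if seq:
                reads.append((f"read_{i}", seq))
    else:
        raise ValueError("topology must be 'circular' or 'linear'")
    if error_rate > 0:
        bases = "ACGT"
        out = []
        for name, seq in reads:
            arr = list(seq)
            for j in np.flatnonzero(rng.random(len(arr)) < error_rate):
                arr[j] = bases[(bases.index(arr[j]) + rng.integers(1, 4)) % 4]
            out.append((name, "".join(arr)))
        reads = out
    return reads


def mutate_family(
    genome: GenomeRecord,
    plan: list[float],
    seed: int = 0,
    indel_rate: float = 0.0,
) -> list[GenomeRecord]:
    """Children of `genome` carrying planned substitution fractions.

    Substituted sites are drawn without replacement, so the realized count is
    exactly ``round(d * L)``; each site is changed to a uniformly chosen
    different base.  Optional indels (small 1-3 bp events) are off by default.
    """
    for d in plan:
        if not 0.0 <= d <= 0.6:
            raise ValueError("divergences must be in [0, 0.6]")
    rng = np.random.default_rng(seed)
    L = len(genome)
    bases = "ACGT"
    children = []
    for ci, d in enumerate(plan):
        n_sub = int(round(d * L))
        arr = list(genome.seq)
        sites = rng.choice(L, size=n_sub, replace=False) if n_sub else []
        for pos in sites:
            alt = bases[(bases.index(arr[pos]) + rng.integers(1, 4)) % 4]
            arr[pos] = alt
        if indel_rate > 0:
            n_ind = rng.poisson(indel_rate * L)
            for _ in range(n_ind):
                pos = int(rng.integers(0, len(arr)))
                if rng.random() < 0.5:
                    del arr[pos : pos + int(rng.integers(1, 4))]
                else:
                    ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
                    arr.insert(pos, ins)
        children.append(
            GenomeRecord(
                id=f"{genome.id}_child{ci}",
                seq="".join(arr),
                topology=genome.topology,
                notes={
                    "parent": genome.id,
                    "planned_divergence": float(d),
                    "n_substitutions": int(n_sub),
                },
            )
        )
    return children


def _stop_key(iv):
    s, e, strand = iv
    return (strand, e if strand == "+" else s)


def _start_key(iv):
    s, e, strand = iv
    return s if strand == "+" else e

def make_evidence(
    truth: SyntheticTruth,
    quality: str = "strong",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic homology/caller evidence table for the truth genes.

    One row per truth gene keyed by (strand, stop); decoy ORFs simply have no
    row (quality "none" emits an empty table).  Columns: strand, stop, start,
    caller_count, evalue, aligned_residues, product, start_votes.
    """
    if quality not in ("strong", "weak", "none"):
        raise ValueError("quality must be strong|weak|none")
    rng = np.random.default_rng(seed)
    rows = []
    if quality != "none":
        for gi, iv in enumerate(truth.gene_intervals):
            strand, stop = _stop_key(iv)
            aa = (abs(iv[1] - iv[0]) + 1) // 3 - 1
            if quality == "strong":
                cc, votes = 6, 6
                evalue = 10.0 ** -rng.uniform(20, 60)
            else:
                cc, votes = int(rng.integers(1, 4)), int(rng.integers(1, 4))
                evalue = 10.0 ** -rng.uniform(3, 8)
            rows.append(
                {
                    "strand": strand,
                    "stop": stop,
                    "start": _start_key(iv),
                    "caller_count": cc,
                    "evalue": evalue,
                    "aligned_residues": aa,
                    "product": PRODUCT_CYCLE[gi % len(PRODUCT_CYCLE)],
                    "start_votes": votes,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "strand", "stop", "start", "caller_count", "evalue",
            "aligned_residues", "product", "start_votes",
        ],
    )


def write_truth_gff3(truth: SyntheticTruth, genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for i, (s, e, strand) in enumerate(truth.gene_intervals):
            fh.write(
                f"{genome.id}\tphagepipe_truth\tgene\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID=truth_gene_{i + 1}\n"
            )
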