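"""Evidence-integrated gene calling.

Each candidate ORF receives an integer score (alpha) summing five evidence
criteria — (a) how many automated callers found it, (b) coding potential
from a self-trained codon-usage model, (c) homology-hit strength, (d) how it
fills coding gaps / overlaps neighbours, (e) operon membership — and
candidates at or above a cutoff (default 8) are kept.  Start codons are then
chosen by a second score combining caller votes, position relative to the
coding-potential rise, homology support, gap/overlap geometry, operon
junctions and a Shine-Dalgarno match.  Putative functions come from the
lowest-E non-"hypothetical" homology hit at E <= 1e-3, with a synteny rule
for the two tail assembly genes, and fall into seven functional categories.

The subscore bands are documented package defaults: the criteria and their
ranges are fixed, the exact band edges are configurable.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import GenomeRecord, revcomp

logger = logging.getLogger(__name__)

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_ORF_LEN = 75  # bp; the shortest credible gene in this genus
DEFAULT_ALPHA_CUTOFF = 8
MAX_SAME_STRAND_OVERLAP = 30  # bp; larger same-strand overlaps conflict
OPERON_OVERLAP_RANGE = (1, 8)  # bp start/stop overlap indicating an operon
GAP_REVIEW_THRESHOLD = 100  # bp; longer coding gaps are flagged for review
SD_CONSENSUS = "AGGAGG"


@dataclass
class OrfCandidate:
    """One (stop, frame) candidate with its in-frame start choices.

    ``stop`` is the 1-based genome coordinate of the last base of the stop
    codon *in reading order*: the rightmost base for "+" ORFs, the leftmost
    for "-" ORFs.  ``starts`` holds the first base of each candidate start
    codon in reading order, ordered longest ORF first.
    """

    genome_id: str
    strand: str
    stop: int
    starts: list
    frame: int = 0
    genome_len: int = 0

    def interval(self, start: int) -> tuple[int, int]:
        lo, hi = (start, self.stop) if self.strand == "+" else (self.stop, start)
        return lo, hi

    def length(self, start: int) -> int:
        lo, hi = self.interval(start)
        if self.genome_len and hi < lo:  # wraps the origin
            return (hi - lo) % self.genome_len + 1
        return hi - lo + 1

    @property
    def key(self):
        return (self.strand, self.stop)


@dataclass
class EvidenceBundle:
    """Per-candidate evidence merged from callers, homology and the
    coding-potential model; keyed by (strand, stop)."""

    caller_count: dict = field(default_factory=dict)
    coding_coverage: dict = field(default_factory=dict)
    best_hit: dict = field(default_factory=dict)  # key -> (evalue, residues, product)
    start_votes: dict = field(default_factory=dict)  # (strand, stop, start) -> 0-6
    behind_rise: dict = field(default_factory=dict)  # (strand, stop, start) -> bool
    hit_residue_support: dict = field(default_factory=dict)  # (strand, stop, start) -> aa

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "EvidenceBundle":
        ev = cls()
        for row in df.itertuples(index=False):
            key = (row.strand, int(row.stop))
            ev.caller_count[key] = int(row.caller_count)
            if not pd.isna(row.evalue):
                ev.best_hit[key] = (float(row.evalue), int(row.aligned_residues), row.product)
            skey = (*key, int(row.start))
            ev.start_votes[skey] = int(row.start_votes)
            ev.hit_residue_support[skey] = int(row.aligned_residues)
        return ev

    @classmethod
    def from_tsv(cls, path) -> "EvidenceBundle":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    def for_candidate(self, cand: OrfCandidate) -> dict:
        key = cand.key
        return {
            "caller_count": self.caller_count.get(key, 0),
            "coding_coverage": self.coding_coverage.get(key, 0.0),
            "best_hit": self.best_hit.get(key),
        }


@dataclass
class AlphaScore:
    a: int = 0  # caller agreement, 0-6
    b: int = 0  # coding potential, 0-5
    c: int = 0  # homology strength, 0-5
    d: int = 0  # gap filling / overlap geometry, 0-5
    e: int = 0  # operon membership, 0 or 2

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d + self.e


@dataclass
class GeneCall:
    genome_id: str
    start: int  # 1-based first base in reading order
    stop: int  # 1-based last base of the stop codon in reading order
    strand: str
    alpha: AlphaScore
    product: str = "hypothetical protein"
    category: str = "unknown"
    start_rationale: dict = field(default_factory=dict)
    flags: set = field(default_factory=set)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.stop) if self.strand == "+" else (self.stop, self.start)

    @property
    def length(self) -> int:
        lo, hi = self.interval
        return hi - lo + 1


def enumerate_orfs(
    genome: GenomeRecord,
    min_len: int = DEFAULT_MIN_ORF_LEN,
    start_codons=START_CODONS,
    circular: bool | None = None,
) -> list[OrfCandidate]:
    """All (stop, frame) ORF candidates on both strands.

    Circular genomes are scanned on the doubled sequence so ORFs crossing the
    origin are found; candidates are unique per (strand, stop mod L).
    """
    if min_len < 60:
        raise ValueError("min_len must be >= 60")
    if circular is None:
        circular = genome.topology == "circular_permuted"
    L = len(genome)
    out: dict[tuple, OrfCandidate] = {}
    for strand in "+-":
        text = genome.seq if strand == "+" else revcomp(genome.seq)
        scan = text + text if circular else text
        n = len(scan)
        for frame in range(3):
            starts_buf: list[int] = []
            for i in range(frame, n - 2, 3):
                codon = scan[i : i + 3]
                if codon in STOP_CODONS:
                    if starts_buf:
                        _add_candidate(
                            out, genome.id, strand, L, circular,
                            starts_buf, i + 2, min_len,
                        )
                    starts_buf = []
                elif codon in start_codons:
                    starts_buf.append(i)
    return sorted(out.values(), key=lambda c: (c.strand, c.stop))


def _add_candidate(out, genome_id, strand, L, circular, starts0, stop_end0, min_len):
    starts0 = [s for s in starts0 if stop_end0 - s + 1 >= min_len]
    if not starts0:
        return
    if circular and (starts0[0] >= L or stop_end0 - starts0[0] + 1 > L):
        return  # duplicate of a candidate seen in the first copy, or over-wrap
    if strand == "+":
        stop = stop_end0 % L + 1 if circular else stop_end0 + 1
        starts = [(s % L) + 1 if circular else s + 1 for s in starts0]
    else:
        # position i in the revcomp text maps to genome coordinate L - (i mod L)
        stop = L - (stop_end0 % L) if circular else L - stop_end0
        starts = [L - (s % L) if circular else L - s for s in starts0]
    key = (strand, stop)
    if key not in out:
        out[key] = OrfCandidate(
            genome_id=genome_id, strand=strand, stop=stop, starts=starts,
            frame=(starts0[0] % 3), genome_len=L,
        )


def coding_potential(
    genome: GenomeRecord,
    candidates: list[OrfCandidate],
    train_min_len: int = 600,
    window: int = 15,
) -> dict:
    """Self-trained codon-usage coding coverage per candidate.

    A log-odds table (long-ORF codon frequencies vs. the genome's base
    composition) is trained on candidates >= ``train_min_len`` bp; each
    candidate's coverage is the fraction of its codons lying in at least one
    sliding ``window``-codon stretch with positive summed log-odds.
    Deterministic; with too few training ORFs every coverage is 0.5.
    """
    if len(genome) < 5000:
        logger.warning("genome < 5 kbp: coding-potential training may be unstable")
    L = len(genome)

    def orf_codons(cand: OrfCandidate) -> list[str]:
        start = cand.starts[0]
        lo, hi = cand.interval(start)
        length = (hi - lo) % L + 1
        text = genome.slice_circular(lo, length)
        if cand.strand == "-":
            text = revcomp(text)
        return [text[i : i + 3] for i in range(0, len(text) - 2, 3)]

    trainers = [c for c in candidates if c.length(c.starts[0]) >= train_min_len]
    if len(trainers) < 3:
        logger.warning("too few long ORFs to train coding potential; uniform prior")
        return {c.key: 0.5 for c in candidates}

    counts: dict[str, float] = {}
    for c in trainers:
        for codon in orf_codons(c)[1:-1]:
            counts[codon] = counts.get(codon, 0.0) + 1.0
    total = sum(counts.values())

    base_freq = {b: max(genome.seq.count(b), 1) / L for b in "ACGT"}
    logodds = {}
    for c1 in "ACGT":
        for c2 in "ACGT":
            for c3 in "ACGT":
                codon = c1 + c2 + c3
                f_coding = (counts.get(codon, 0.0) + 0.5) / (total + 32.0)
                f_bg = base_freq[c1] * base_freq[c2] * base_freq[c3]
                logodds[codon] = np.log(f_coding / f_bg)

    coverages = {}
    for cand in candidates:
        scores = np.array([logodds.get(c, -4.0) for c in orf_codons(cand)])
        n = scores.size
        if n == 0:
            coverages[cand.key] = 0.0
            continue
        w = min(window, n)
        sums = np.convolve(scores, np.ones(w), mode="valid")
        positive = np.zeros(n, dtype=bool)
        for j in np.flatnonzero(sums > 0):
            positive[j : j + w] = True
        coverages[cand.key] = float(positive.mean())
    return coverages


@dataclass
class GeneContext:
    """Relationship of a candidate to its (provisionally) chosen neighbours."""

    prev_gap: int | None = None  # bp to nearest upstream gene; negative = overlap
    next_gap: int | None = None
    operon_overlap: bool = False  # start/stop overlaps a neighbour's stop/start by 1-8 bp


def _hit_score(best_hit) -> int:
    if best_hit is None:
        return 0
    evalue, residues, _ = best_hit
    if evalue <= 1e-20 and residues >= 100:
        return 5
    if evalue <= 1e-10:
        return 4
    if evalue <= 1e-5:
        return 3
    if evalue <= 1e-3:
        return 2
    return 0


def score_orf_alpha(candidate: OrfCandidate, evidence: dict, context: GeneContext) -> AlphaScore:
    """The five-criterion integer score for one candidate ORF."""
    a = int(np.clip(evidence.get("caller_count", 0), 0, 6))
    b = int(round(5 * float(np.clip(evidence.get("coding_coverage", 0.0), 0.0, 1.0))))
    c = _hit_score(evidence.get("best_hit"))

    gaps = [g for g in (context.prev_gap, context.next_gap) if g is not None]
    overlap = max((-g for g in gaps if g < 0), default=0)
    fills_gap = any(g > GAP_REVIEW_THRESHOLD for g in gaps)
    if overlap > MAX_SAME_STRAND_OVERLAP:
        d = 0
    elif overlap >= 5:
        d = 1
    elif fills_gap:
        d = 5
    else:
        d = 3
    e = 2 if context.operon_overlap else 0
    return AlphaScore(a=a, b=b, c=c, d=d, e=e)


def build_context(cand: OrfCandidate, start: int, intervals: list) -> GeneContext:
    """Context of `cand` (at `start`) against accepted gene intervals given
    as (lo, hi) pairs.  ``prev_gap`` is the signed gap to the nearest
    neighbour on the left (negative = overlap), ``next_gap`` to the right."""
    lo, hi = cand.interval(start)
    left = [iv for iv in intervals if iv[0] < lo]
    right = [iv for iv in intervals if iv[0] > lo]
    prev_gap = next_gap = None
    if left:
        plo, phi = max(left, key=lambda iv: iv[1])
        prev_gap = lo - phi - 1
    if right:
        nlo, nhi = min(right, key=lambda iv: iv[0])
        next_gap = nlo - hi - 1
    operon = any(
        g is not None and -OPERON_OVERLAP_RANGE[1] <= g <= -OPERON_OVERLAP_RANGE[0]
        for g in (prev_gap, next_gap)
    )
    return GeneContext(prev_gap=prev_gap, next_gap=next_gap, operon_overlap=operon)


def select_genes(
    scored: list[tuple[OrfCandidate, AlphaScore]],
    cutoff: int = DEFAULT_ALPHA_CUTOFF,
    genome_len: int | None = None,
) -> tuple[list[tuple[OrfCandidate, AlphaScore]], dict]:
    """Keep candidates with alpha >= cutoff, greedily resolving same-strand
    conflicts (overlap > 30 bp) in favour of higher alpha (tie: longer, then
    lower coordinate).  Returns the kept list plus a review report."""
    eligible = [(c, s) for c, s in scored if s.total >= cutoff]
    eligible.sort(
        key=lambda cs: (-cs[1].total, -cs[0].length(cs[0].starts[0]), cs[0].interval(cs[0].starts[0])[0])
    )
    kept: list[tuple[OrfCandidate, AlphaScore]] = []
    for cand, score in eligible:
        # a candidate may escape a conflict by a shorter in-frame start
        allowed = []
        for start in cand.starts:
            lo, hi = cand.interval(start)
            ok = True
            for kc, _ in kept:
                if kc.strand != cand.strand:
                    continue
                klo, khi = kc.interval(kc.starts[0])
                ov = min(hi, khi) - max(lo, klo) + 1
                if ov > MAX_SAME_STRAND_OVERLAP:
                    ok = False
                    break
            if ok:
                allowed.append(start)
        if allowed:
            kept.append((dataclasses.replace(cand, starts=allowed), score))
    kept.sort(key=lambda cs: cs[0].interval(cs[0].starts[0])[0])

    report = {"flagged_single_caller": [], "flagged_short": [], "coding_gaps": []}
    for cand, score in kept:
        if score.a <= 1:
            report["flagged_single_caller"].append(cand.key)
        if cand.length(cand.starts[0]) < 200:
            report["flagged_short"].append(cand.key)
    if genome_len:
        covered = np.zeros(genome_len, dtype=bool)
        for cand, _ in kept:
            lo, hi = cand.interval(cand.starts[0])
            _mark(covered, lo, hi, genome_len)
        report["coding_gaps"] = _gaps_over(covered, GAP_REVIEW_THRESHOLD)
    return kept, report


def _mark(covered: np.ndarray, lo: int, hi: int, L: int) -> None:
    if lo <= hi:
        covered[lo - 1 : hi] = True
    else:  # wraps the origin
        covered[lo - 1 :] = True
        covered[:hi] = True


def _gaps_over(covered: np.ndarray, threshold: int) -> list[tuple[int, int]]:
    gaps = []
    in_gap = False
    for i, c in enumerate(covered):
        if not c and not in_gap:
            in_gap, gs = True, i
        elif c and in_gap:
            in_gap = False
            if i - gs > threshold:
                gaps.append((gs + 1, i))
    if in_gap and covered.size - gs > threshold:
        gaps.append((gs + 1, covered.size))
    return gaps


def shine_dalgarno_score(upstream: str) -> int:
    """Best contiguous AGGAGG match over spacers 4-14 nt in the 20-nt window
    5' of the start codon (no gaps)."""
    upstream = upstream.upper()
    best = 0
    for spacer in range(4, 15):
        hi = len(upstream) - spacer
        lo = hi - len(SD_CONSENSUS)
        if hi <= 0:
            continue
        segment = upstream[max(lo, 0) : hi]
        consensus = SD_CONSENSUS[-len(segment) :] if len(segment) < len(SD_CONSENSUS) else SD_CONSENSUS
        best = max(best, sum(x == y for x, y in zip(segment, consensus)))
    return best


def _residue_band(aa: int) -> int:
    if aa >= 100:
        return 3
    if aa >= 50:
        return 2
    if aa >= 25:
        return 1
    return 0


def _gap_overlap_band(gap: int | None) -> int:
    if gap is None:
        return 0
    if gap < 0:  # overlap
        ov = -gap
        if ov <= 4:
            return 3
        if ov <= MAX_SAME_STRAND_OVERLAP:
            return 1
        return 0
    if gap <= 100:
        return 3
    if gap <= 300:
        return 2
    if gap <= 600:
        return 1
    return 0


def select_start(
    cand: OrfCandidate,
    evidence: EvidenceBundle,
    genome: GenomeRecord,
    accepted_intervals: list,
) -> tuple[int, list[dict]]:
    """Choose the start codon for an accepted candidate.

    Per-start score = caller votes (0-6) + 3 if the start sits before the
    coding-potential rise (-5 if behind it) + homology-residue band (0-3) +
    gap/overlap band (0-3) + 2 for an operon junction + Shine-Dalgarno score.
    Highest wins; ties go to the longer ORF.
    """
    L = len(genome)
    table = []
    for start in cand.starts:
        skey = (cand.strand, cand.stop, start)
        votes = evidence.start_votes.get(skey, 0)
        behind = evidence.behind_rise.get(skey, False)
        residues = evidence.hit_residue_support.get(skey, 0)
        ctx = build_context(cand, start, accepted_intervals)
        upstream = _upstream_window(genome, cand.strand, start, 20)
        sd = shine_dalgarno_score(upstream)
        prev_rel = ctx.prev_gap if cand.strand == "+" else ctx.next_gap
        score = (
            votes
            + (-5 if behind else 3)
            + _residue_band(residues)
            + _gap_overlap_band(prev_rel)
            + (2 if ctx.operon_overlap else 0)
            + sd
        )
        table.append(
            {
                "start": start, "score": score, "votes": votes, "behind_rise": behind,
                "sd": sd, "residue_band": _residue_band(residues),
                "gap_band": _gap_overlap_band(prev_rel),
                "operon": ctx.operon_overlap, "orf_len": cand.length(start),
            }
        )
    table.sort(key=lambda r: (-r["score"], -r["orf_len"], r["start"]))
    return table[0]["start"], table


def _upstream_window(genome: GenomeRecord, strand: str, start: int, width: int) -> str:
    if strand == "+":
        return genome.slice_circular(start - width, width)
    return revcomp(genome.slice_circular(start + 1, width))


def coding_fraction(genome_len: int, genes: list[GeneCall]) -> float:
    """(L - sum of intergenic gaps) / L, a gap being a maximal interval
    covered by no gene on either strand."""
    covered = np.zeros(genome_len, dtype=bool)
    for g in genes:
        lo, hi = g.interval
        if not (1 <= lo <= genome_len and 1 <= hi <= genome_len):
            raise ValueError(f"gene {lo}-{hi} outside genome bounds")
        _mark(covered, lo, hi, genome_len)
    return float(covered.mean())


def assign_function(hits: list[tuple[float, str]], evalue_cutoff: float = 1e-3) -> str:
    """Lowest-E non-"hypothetical" product at E <= cutoff, else
    "hypothetical protein"."""
    usable = [
        (e, p) for e, p in hits
        if e <= evalue_cutoff and "hypothetical" not in p.lower()
    ]
    if not usable:
        return "hypothetical protein"
    return min(usable, key=lambda ep: ep[0])[1]


def assign_tail_assembly_by_synteny(genes: list[GeneCall]) -> list[GeneCall]:
    """Label the two unannotated genes between the major tail protein and the
    tail tape measure protein as tail assembly proteins (iff exactly two)."""
    mtp = [g for g in genes if g.product == "major tail protein"]
    tmp = [g for g in genes if g.product == "tail tape measure protein"]
    if len(mtp) != 1 or len(tmp) != 1 or mtp[0].strand != tmp[0].strand:
        logger.info("tail-assembly synteny rule not applicable: anchors missing/ambiguous")
        return genes
    lo = min(mtp[0].interval[1], tmp[0].interval[1])
    hi = max(mtp[0].interval[0], tmp[0].interval[0])
    between = [g for g in genes if g.interval[0] > lo and g.interval[1] < hi]
    unannotated = [g for g in between if g.product == "hypothetical protein"]
    if len(between) == 2 and len(unannotated) == 2:
        for g in unannotated:
            g.product = "tail assembly protein"
            g.category = categorize_function(g.product)
    else:
        logger.info(
            "tail-assembly synteny rule not met: %d genes between anchors", len(between)
        )
    return genes


_CATEGORY_RULES = (
    ("tRNA", r"tRNA"),
    ("assembly", r"terminase|portal|clp|scaffold|assembly|maturation"),
    ("virion_particle", r"capsid|tail|sheath|tape measure|head|collar|baseplate|virion|structural"),
    ("lysis", r"amidase|holin|lysin|transglycosylase|lysozyme"),
    (
        "replication",
        r"polymerase|helicase|primase|nuclease|methyltransferase|integrase|"
        r"transposase|excisionase|ligase|topoisomerase|recombinase|replication",
    ),
    ("regulation", r"transcriptional regulator|repressor|antirepressor|sigma|\bcro\b|xre"),
    ("host_related", r"toxin|antitoxin|transporter|stress|metallo|bacteriocin|lactamase"),
)


def categorize_function(product: str) -> str:
    for category, pattern in _CATEGORY_RULES:
        if re.search(pattern, product, flags=re.IGNORECASE):
            return category
    return "unknown"


def annotate_genome(
    genome: GenomeRecord,
    evidence: EvidenceBundle,
    cutoff: int = DEFAULT_ALPHA_CUTOFF,
    min_len: int = DEFAULT_MIN_ORF_LEN,
) -> tuple[list[GeneCall], dict]:
    """Full gene-calling pass: enumerate, score, select, pick starts, assign
    products and categories.  Criterion (d)/(e) context is computed against a
    provisional selection made from the context-free criteria."""
    candidates = enumerate_orfs(genome, min_len=min_len)
    evidence.coding_coverage = coding_potential(genome, candidates)

    # pass 1: context-free provisional selection
    provisional = []
    for cand in candidates:
        ev = evidence.for_candidate(cand)
        s = score_orf_alpha(cand, ev, GeneContext())
        provisional.append((cand, s))
    prov_kept, _ = select_genes(provisional, cutoff=cutoff, genome_len=len(genome))
    prov_intervals = sorted(c.interval(c.starts[0]) for c, _ in prov_kept)

    # pass 2: context-aware scoring and final selection
    scored = []
    for cand in candidates:
        ev = evidence.for_candidate(cand)
        others = [iv for iv in prov_intervals if iv != cand.interval(cand.starts[0])]
        ctx = build_context(cand, cand.starts[0], others)
        scored.append((cand, score_orf_alpha(cand, ev, ctx)))
    kept, report = select_genes(scored, cutoff=cutoff, genome_len=len(genome))

    accepted_intervals = sorted(c.interval(c.starts[0]) for c, _ in kept)
    genes = []
    for cand, score in kept:
        others = [iv for iv in accepted_intervals if iv != cand.interval(cand.starts[0])]
        start, table = select_start(cand, evidence, genome, others)
        hit = evidence.best_hit.get(cand.key)
        product = assign_function([(hit[0], hit[2])]) if hit else "hypothetical protein"
        flags = set()
        if score.a <= 1:
            flags.add("single_caller")
        if cand.length(start) < 200:
            flags.add("short_lt_200")
        genes.append(
            GeneCall(
                genome_id=genome.id, start=start, stop=cand.stop, strand=cand.strand,
                alpha=score, product=product,
                start_rationale={"table": table},
                flags=flags,
            )
        )
    genes.sort(key=lambda g: g.interval[0])
    genes = assign_tail_assembly_by_synteny(genes)
    for g in genes:
        g.category = categorize_function(g.product)
    report["coding_fraction"] = coding_fraction(len(genome), genes)
    return genes, report


def write_gff3(genes: list[GeneCall], genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for i, g in enumerate(genes, start=1):
            lo, hi = g.interval
            attrs = (
                f"ID=gene_{i};product={g.product};alpha={g.alpha.total};"
                f"category={g.category}"
            )
            if g.flags:
                attrs += f";flags={','.join(sorted(g.flags))}"
            fh.write(
                f"{genome.id}\tphagepipe\tgene\t{lo}\t{hi}\t{g.alpha.total}\t"
                f"{g.strand}\t0\t{attrs}\n"
            )
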