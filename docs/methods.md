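# Methods

This note documents the models, rubrics and numerical choices behind
`phagepipe`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Genome ends and packaging strategy

**cos detection.** The assembly is treated as circular: the query motif is
scanned against every circular offset (implemented on the doubled sequence),
recording mismatch counts, with at most one mismatch tolerated. The best
occurrence is the one with the fewest mismatches; ties are broken toward the
occurrence nearest upstream of the small-terminase start when an anchor is
supplied, else toward the lowest coordinate. The reported overhang is the
*observed* genome substring, so a single-point variant of the canonical
motif (`CGACGGCCC` for `CGACTGCCC`) is reported as such with
`mismatches = 1`.

A 9-mer within one mismatch of a query occurs ~5 times by chance in a
40-kbp genome (40000 × 28/4⁹), so an inexact hit is only trusted when
confirmed by terminase proximity: the orchestrating classifier accepts
mismatch-1 hits only when an anchor is given and the hit's motif-end →
terminase-start distance is within the confirmation window (default
200 bp; the convention in this genus is exactly 50 bp). Exact hits are
accepted outright. Without this rule a genome that does not carry the motif
at all would be misclassified as cos roughly a third of the time.

**Reorientation** rotates the assembly so base 1 is the first base after
the overhang's final base. It is a pure rotation (base multiset and length
preserved) and is idempotent once the genome is canonical. With the
default spacing this places the small-terminase start at position 51,
i.e. 50 bp downstream of base 1.

**Pile-up.** Reads are placed at the unique position where their first
k-mer (default k = 21) matches the reference exactly, wrapping across the
origin for circular references; reads with ambiguous or absent seed k-mers
are dropped and counted. This deliberately avoids full alignment: the
detection signal is depth geometry, not base-level accuracy, and the
simulated reads are error-free (see below). k = 21 makes a chance duplicate
k-mer in a 55-kbp genome vanishingly rare while tolerating 150-bp reads.

**DTR detection.** The repeat appears as an elevated plateau at about twice
the interior depth. Detection proceeds in three steps:

1. *Run finding with hysteresis.* Candidate runs are grown wherever depth
   ≥ (1 + ratio)/2 × interior median (the midpoint between interior and the
   full threshold) and kept only if they contain at least one position
   reaching ratio × median (ratio default 1.6). Dips shorter than the
   sharpness window are closed. Plain thresholding at 1.6× breaks: at 50×
   coverage the plateau depth is ~100 with sd ~10, so single positions dip
   below 80 regularly and would split the contiguous run.
2. *Boundary snapping.* Each run edge is moved to the largest one-position
   depth step within ±5 sharpness windows. The true boundary step is the
   full interior depth (~50 reads) against per-position start/stop noise of
   ~0.3, so the argmax is essentially always the exact junction — this is
   what makes ±1 bp accuracy achievable.
3. *Sharpness test.* Mean depth inside vs. outside each boundary must
   differ by ≥ 1.5×. Flanks are averaged over 15 sharpness windows
   (300 bp at the default 20 bp): fragment-density noise is correlated on
   the read-length scale, so a 20-bp flank mean at 50× has sd ≈ 9 and would
   reject genuinely sharp repeats in a noticeable fraction of libraries,
   whereas a 300-bp flank mean has sd ≈ 4. The sharpness window itself
   retains its role of bounding how localized the transition must be (via
   the snap range and dip closing).

The detector reports the run length as the repeat length, the run start as
the junction, and the spanned sequence as the repeat.

**Classification precedence** is cos3, then cos5, then DTR (if reads are
given), then unknown. Among motif hits of equal mismatch count cos3 takes
precedence; an exact cos5 hit beats an inexact cos3 hit.

## Gene calling

**ORF enumeration** scans both strands in all frames (across the origin for
circular genomes), producing one candidate per (strand, stop codon) with
every in-frame start (`ATG`/`GTG`/`TTG`) that leaves ≥ 75 bp — the shortest
credible gene in this genus. Candidates are keyed by the stop codon's last
base in reading order, which is invariant to start choice.

**Coding potential** stands in for an external coding-potential program
with a transparent self-trained model: codon frequencies are estimated from
the genome's own long ORFs (≥ 600 bp, which are almost always real genes),
log-odds are taken against the genome's base composition, and a candidate's
*coding coverage* is the fraction of its codons inside at least one sliding
15-codon window with positive summed log-odds. This works because real
coding sequence has biased codon usage; a decoy ORF (a chance stop-free
stretch) scores near or below zero. With fewer than three training ORFs the
model degrades to an uninformative 0.5 for every candidate and logs a
warning.

**The α score** sums five criteria:

| criterion | range | rubric |
|---|---|---|
| (a) caller agreement | 0–6 | count of callers reporting the ORF |
| (b) coding potential | 0–5 | round(5 × coding coverage) |
| (c) homology | 0–5 | E ≤ 1e−20 and ≥ 100 aa → 5; E ≤ 1e−10 → 4; ≤ 1e−5 → 3; ≤ 1e−3 → 2; else 0 |
| (d) gap/overlap | 0–5 | fills a > 100 bp coding gap with overlap ≤ 4 bp → 5; gap-neutral, overlap ≤ 4 → 3; overlap 5–30 → 1; > 30 → 0 |
| (e) operon | 0 or 2 | start/stop overlaps a neighbour's stop/start by 1–8 bp |

The criteria and their ranges are fixed; the published procedure gives the
ranges but not the band edges, so the edges above are documented package
defaults (configurable). Criterion (e)'s weight of 2 lets operon membership
rescue borderline calls without dominating. α is additive and therefore
monotone in every evidence component, which the test suite checks on a full
grid. Candidates with α ≥ 8 (the stated operating point) are kept; the
cutoff is a parameter.

Because criteria (d) and (e) depend on neighbours, scoring runs in two
passes: a provisional selection from the context-free criteria, then
context-aware rescoring against the provisional neighbours and final
selection. Same-strand conflicts (overlap > 30 bp — phage genes seldom
overlap more) are resolved greedily in favour of higher α (ties: longer,
then lower coordinate); a candidate escapes a conflict by falling back to a
shorter in-frame start when one exists. Kept calls with ≤ 1 supporting
caller or length < 200 bp are flagged for review, and every remaining
coding gap > 100 bp is reported.

**Start selection** scores each candidate start as
votes (0–6) + 3 (before the coding-potential rise; −5 behind it)
+ residue-support band (0–3) + gap/overlap band (0–3) + 2 (operon junction)
+ Shine–Dalgarno score (0–6), highest wins, ties to the longer ORF. The
Shine–Dalgarno score is the best contiguous match to `AGGAGG` over spacers
4–14 nt within the 20-nt window 5′ of the start — a transparent replacement
for an opaque desktop-tool parameterization, and the one deliberate
re-specification in this module.

**Products and categories.** The product is the lowest-E non-"hypothetical"
hit at E ≤ 1e−3, else "hypothetical protein". When a genome has exactly one
major tail protein and one tail tape measure protein on the same strand
with exactly two unannotated genes between them, those two become tail
assembly proteins (the conserved Siphoviridae synteny). Categories come
from a keyword rule table over seven classes (assembly, virion particle,
lysis, replication, regulation, host-related, tRNA); assembly patterns are
tested before structural ones so "tail assembly protein" and "capsid
maturation protease" classify as assembly.

**Coding fraction** is (L − Σ gaps)/L with a gap being a maximal interval
covered by no gene on either strand — computed on a position bitmap and
cross-checked against an independent bitmap oracle in the tests.

## Similarity

**ANI** is 100 × identical columns / all columns (gap columns included in
the denominator) of a pairwise global DNA alignment. Whole genomes are
aligned by chaining 12-mer anchors unique in both sequences (longest
collinear chain, merged into exact-match blocks) and aligning inter-anchor
segments with an affine-gap global aligner (match +1.9, mismatch 0, open
−6, extend −0.5). When chained anchors cover < 30% of the shorter sequence
the pair falls back to one full alignment; segments or pairs beyond 6 kbp
use an edit-distance alignment whose extended CIGAR supplies the identity
count. The nucleotide scoring follows the IUB match/mismatch convention;
the gap costs are the package's calibration so that two independent random
sequences measure ≈ 40% ANI — the documented reference behaviour of this
statistic — because the original multiple-alignment tool's effective gap
treatment is not recoverable from its description. The anchored route
reproduces the full-DP route within 0.5 points on kilobase-scale pairs
(tested), and a 40-kbp pair differing at exactly 10 sites yields exactly
99.975.

**AAI** uses BLOSUM62 with affine gaps (−11/−1) and the same
identical-columns-over-all-columns definition; residues outside the matrix
alphabet map to X. The pham linker additionally uses the aligned-column
coverage of the longer protein.

**Contiguous dot-plot identity** chains exact 10-mer matches along
diagonals (gap tolerance 20 bp), marks runs spanning ≥ 50 bp, and reports
the covered fraction of each sequence, symmetrized by the minimum of the
two directions.

## Clustering, phams, trees

Cluster and subcluster assignment is single-linkage transitive closure at
strictly > 60% and > 90% ANI (strict because a borderline genome "just
short" of 90 must stay out); the subcluster closure runs within each
cluster, so nesting holds by construction. Representatives maximize mean
ANI to the rest of their subcluster (ties: lexicographic); clusters take
the name of their largest subcluster's representative (ties: higher mean
ANI to the cluster, then lexicographic). The phenotype rule compares
translated proteomes as multisets and separately reports the ANI > 99.975%
heuristic and whether the two agree.

Phams are connected components of the link graph (AAI ≥ 32.5%, coverage
≥ 50% of the longer protein — documented defaults for the upstream tool's
unstated settings); identical sequences are deduplicated before any
alignment, mirroring the observation that closely related phages share
identical proteins. Gene-content distance is
1 − |S_A∩S_B| / mean(|S_A|, |S_B|) over pham-presence sets, exported as TSV
and as a NEXUS DISTANCES block for splits software. Trees are standard
neighbour joining on that matrix, negative branch lengths clamped to zero,
midpoint-rooted, written as Newick. NJ is used here as a distance-based
summary, not a substitute for model-based phylogenetics.

## Statistics

Gene density is 1000 × genes / length (reported at 2 dp, half-even;
full precision retained), GC is computed over the whole sequence, and the
genes-versus-length regression is ordinary least squares of gene count on
length in kbp with Pearson r and its two-sided p-value. The packaged
48-genome table reproduces slope 1.44, intercept 10.5 (10.456 before
rounding) and r 0.93; its total gene count is 3462. Two published prose
figures do not recompute from the printed table and are reported as
computed with a caveat: the per-genome gene-count *median* is 69 (the
quoted "median of 72" matches the *mean*, 72.125), and 37 of 48 genomes lie
in a strict [35, 45] kbp band (the quoted 40 presumably reflects a looser
band). Histograms use half-open [lo, hi) bins: 1 kbp for genome length,
100 bp for gene length, 5 for gene counts.

## The synthetic-data generator

The generator emulates what the downstream stages actually consume:

* **Gene grid.** Lognormal gene lengths (≥ 150 bp, codon-snapped), Poisson
  intergenic gaps, strands 70/30 forward-biased, a configurable fraction of
  same-strand junctions overlapping by 4 bp via the `ATGA`/`TCAT` junction
  motifs, coding fraction constrained to the genus' 0.85–0.97 range, gene 1
  (the small terminase by convention) starting at base 51. Codons are drawn
  from a fixed lognormally-spread usage table so the coding-potential model
  has a genuine signal; `AGGAGG` ribosome-binding sites are planted at
  spacer 7 where intergenic room allows, so Shine–Dalgarno scoring has one
  too.
* **Packaging.** cos motifs are written so the motif end sits exactly
  `spacing` bp (default 50) upstream of the terminase start, then the
  genome is rotated arbitrarily; placement collides with no gene by
  construction, and a collision raises. DTR packaging emits the collapsed
  assembly plus the linear physical molecule carrying the repeat at both
  ends.
* **Reads.** Error-free by default (an optional uniform error rate exists).
  Circular molecules: uniform wrapped starts. Linear molecules: fragment
  offsets uniform over [−(read_len−1), L−1] with truncation at both
  termini. The truncation models PCR-free fragmentation in which molecule
  ends are real fragment ends; it is what produces uniform coverage up to
  the termini and hence the sharply delimited double-depth plateau —
  simulating only whole reads would ramp the coverage at the ends and bias
  the detected repeat short by tens of bp.
* **Families.** Substitutions are drawn without replacement at exactly
  round(d × L) sites (so counts are testable exactly), transitions and
  transversions unweighted, indels optional and off by default.
* **Evidence.** Per truth gene: caller count, a best hit (E-value, aligned
  residues, product drawn from a realistic phage product cycle) and start
  votes, at three quality levels; decoys get nothing.

What it does *not* emulate — and what passing tests therefore do not show
about real data: sequencing error and quality models, strand-of-origin for
reads, structural variants, prophage integration, repeat families within a
genome, horizontal transfer mosaicism, tRNA genes, and translational
frameshifts. Real evidence tables also carry correlated errors (callers
agreeing on a wrong ORF) that the generator does not model.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to the
smallest regimes that still exercise the mathematics: 40–55 kbp single
genomes for packaging round trips (20 seeds for the DTR sweep), 4-kbp pairs
for the random-ANI calibration (the statistic's value is length-stable well
below the 40-kbp original), and 2.5-kbp genomes for the 12-genome
3-cluster recovery families, where between-cluster pairs need full dynamic
programming. Divergences for those families are 0.02 within subclusters,
0.25 within clusters and 0.5 between clusters, which map to ANI ≈ 98, ≈ 75
and ≤ 50–58 — cleanly straddling the 90/60 thresholds. Every stochastic
step takes an explicit integer seed; identical seeds give byte-identical
outputs, and the pipeline manifest records a checksum per output to make
that checkable.

## Known limitations

* The α band edges and start-score weights are plausible defaults, not
  fitted to curated annotations; on real genomes they should be reviewed
  against a hand-annotated reference.
* The pile-up mapper is seed-exact and single-strand; real libraries need a
  real aligner upstream, with the depth vector fed in as a
  `CoverageProfile`.
* Anchored ANI assumes substitution-dominated divergence; highly
  rearranged pairs fall back to edit-distance alignment whose gap model is
  cruder than the affine aligner's.
* cos classification without a terminase anchor cannot distinguish a
  genuine single-mismatch overhang variant from background; it then
  accepts exact hits only.
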