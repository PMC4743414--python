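# Methods

## Motif model and the balanced threshold

A motif is a position count matrix over {A,C,G,T} (TRANSFAC dialect on
disk; parsing is delegated to `Bio.motifs` with a line-level pre-validation
pass so malformed rows are reported with their line number). Counts are
smoothed with a pseudocount equal to 1 % of the column total, distributed
proportionally to the background composition, and scored as log₂-odds
against the background (uniform by default, overridable per run). Windows
containing N are disqualified (−∞) rather than averaged. On the minus
strand the reverse complement of the window is scored. Ties at one start
position report the + strand before −.

The score cutoff is the *balanced threshold*: with
FPR(t) = P(score ≥ t | background) and FNR(t) = P(score < t | motif), the
smallest grid score t with FPR(t) ≤ ρ·FNR(t), ρ = 100 by default. Both
rates come from the exact distribution of the discretised score, computed
by column-wise convolution: each column's log-odds contribution is assigned
to its nearest 0.1-bit bin (halves up) and the window score is the sum of
per-column bins. The exact DP (no sampling) makes the threshold
reproducible, and the returned threshold is a grid point — no interpolation
between achievable score levels. The strictness convention (≥ for FPR,
< for FNR) makes both rates monotone in t, so the admissible set is an
up-interval and "smallest admissible t" is well defined; the same
convention gives FPR = ρ·FNR at the crossing. Note a consequence worth
knowing: for short or low-information motifs the crossing sits at a
permissive FPR (the rule tolerates 100 false positives per false negative),
so hit densities are governed by motif width and sharpness, not by a fixed
specificity.

## Dimer structures and the overrepresentation test

A dimer structure is an unordered motif pair plus mutual orientation and
spacing, where spacing is the gap in bp between the end of the upstream hit
and the start of the downstream hit (negative = overlap). This end-to-start
convention keeps the ±2 bp matching tolerance meaningful when neighbouring
sites overlap, which they do in the enhanceosome. Every genomic occurrence
has a reverse-complement twin; occurrences are reduced to a canonical form
— the lexicographically smaller of (pwm_a, pwm_b, orientation) between the
occurrence and its reverse-complement image, with orientation ranked
(+,+) < (+,−) < (−,+) < (−,−) — so a structure and its mirror count once.
Homodimer pairs are unordered and a hit never pairs with itself.

Open-chromatin input is ENCODE narrowPeak. Per replicate, up to 50 000
peaks with the highest signalValue are kept (ties broken by coordinate for
stability); peaks whose bases are more than half covered by the supplied
mask (coding/repeat intervals) are dropped whole, and dimer instances that
overlap the mask are removed before counting. Masking at the instance level
(rather than only at the hit level) also guarantees that instances flagged
as within-gene lie wholly in introns when the mask is the exon union.
Candidate pairs are bounded by |spacing| ≤ 50 bp.

Overrepresentation of a structure in a target cell type is tested against
the pooled peaks of all other cell types: with n_t instances in b_t bp of
target open chromatin and n_b instances in b_b bp of background,
X ~ Binomial(n_t + n_b, b_t/(b_t + b_b)) and p = P(X ≥ n_t), an exact
one-sided rate comparison, BH-corrected across the structures tested in
that cell type (no minimum target-instance count by default). This
statistic is this package's own design: it is exact, dependency-free and
reproducible, and it fills the same interface as the internal statistic of
external motif-pair discovery tools without claiming to reproduce one.

## Enhanceosome matching

The two 57-bp enhanceosome sequences are embedded as constants with their
genomic anchors (human hg19 chr9:21,077,989–21,078,045, 44 bp upstream of
*IFNB1*; mouse mm9 chr4, 101 bp upstream of *Ifnb1*). Site coordinates for
HMG-A, ATF2, HMG-B, IRF-A, IRF-B, NFKB and HMG-C are a configurable table;
the defaults transcribe the published architecture (the sites are reported
graphically in the source literature, not as coordinates), with HMG-C
extended 1 bp past the NF-κB site so that maximal-overlap assignment can
distinguish the two nested sites. A genome-wide structure matches an
enhanceosome hit pair when the canonical pair and orientation agree and
|Δ| ≤ 2, where Δ = enhanceosome spacing − structure spacing; positive Δ
means the enhanceosome arrangement is wider. Each hit of a matched pair is
assigned to the site with the largest base overlap (ties to the leftmost
site), and the site pair names the dimer type; pairs outside the four
recognized combinations are "other".

## Genomic context

An instance is represented by its midpoint, floor((start+end)/2) — the
left-of-centre base for even lengths. The midpoint picks the chromatin
state (overlapping segments at the midpoint are a data error; an uncovered
midpoint returns an `Unannotated` sentinel), decides gene and enhancer
membership, and anchors nearest-gene distances (distance to the nearest
gene boundary; ties broken by smaller gene id). Q0 selects genes containing
an instance midpoint; Qi selects each instance's single nearest gene when
its distance is strictly below the Qi threshold, so Q1 ⊆ … ⊆ Q6 for fixed
instances. TSS-window selection counts instance midpoints strictly within
±10 kb of the TSS and requires at least three.

The G-plus binomial test uses p₀ = the G-plus base-pair fraction of the
analyzed segmentation, computable from the input BED — the natural null
when instances are placed without regard to state. Percentages in report
tables round half away from zero.

## Cross-species comparison

GO enrichment is the classical hypergeometric upper tail over a gene
universe with BH FDR (threshold 0.01), without ancestor propagation by
default (a closure flag exists; the annotation table may carry a
child→parent relation). Term sets retained in the two species are compared
by a one-sided Fisher exact test over the union of both species'
assignable terms.

Gene-level similarity under many-to-many orthology first builds the
smallest partitions of the two selected gene sets such that genes
orthologous to a common block share a block — the fixed point of the
iterative join rule, computed as connected components of the bipartite
orthology graph restricted to the two sets (networkx). The 2×2 table counts
a = selected human blocks linked to a selected mouse block, b = unlinked
human blocks, c = unlinked mouse blocks, and N − a − b − c, where N is the
number of equivalence classes of the combined gene universes under the full
orthology relation (a linked human/mouse block pair is one class). The
human side provides the linked count for the table; the mouse-side count is
exposed alongside. All Fisher tests are one-sided (greater), since the
question is over-similarity, and p-values are reported as −log₁₀ p capped
at 320 to keep underflow finite. Under strict 1-1 orthology the
construction reduces exactly to the classical gene-level Fisher test, which
is verified as a property.

## Synthetic study design

The generators emulate the pipeline's input universe at desk scale; the
defaults are the study conditions used by the test-suite and the
acceptance script:

* genome: 1 Mb, single chromosome, i.i.d. bases at GC 0.41 (mammalian
  average);
* open chromatin: 3 cell types × 100 disjoint peaks of 150–400 bp
  (slot placement), gamma-distributed signal values;
* planted dimer: 30 copies in one cell type's peaks, motif words sampled
  per column from the PWMs; the planted pair reads two 12-bp words off the
  human enhanceosome sequence (the ATF-2/c-Jun and IRF-A site regions) and
  plants them 1 bp tighter than their enhanceosome arrangement, so the
  expected match reports Δ = +1;
* synthetic motifs: 95 % dominant-base columns (TRANSFAC-like sharpness;
  many real columns are near-degenerate). Sharpness matters: at soft
  columns (≈85 %) the balanced-ratio-100 rule lands at FPR ≈ 0.1 and
  random co-occurrences swamp any planted signal — a property of the
  threshold rule, not of the implementation;
* genes: 40 disjoint models of 2–10 kb with 1–4 exons; the exon union is
  the mask;
* chromatin states: 200–2 000 bp segments over the 15-label vocabulary with
  quota-steered G-plus assignment, so the realized bp fraction tracks the
  request to within one segment length;
* orthology: block spectrum of (human size, mouse size, count) triples,
  completely connected within a block; leftover genes stay singletons;
* GO: 200 background terms at per-gene rates of 0.5–5 %; a planted term
  annotates its subset at factor × 2.5 % (factor 1 = null).

Each generator draws from its own RNG stream keyed by (seed, generator
name), so adding a generator never perturbs existing outputs, and
identical seeds give byte-identical files.

What the synthetic data does **not** emulate: real DNase signal shapes and
peak clustering, ChromHMM transition structure, GO DAG topology, sequence
composition biases (repeats, CpG islands), or the actual TRANSFAC matrix
content. Passing the planted-truth tests therefore demonstrates that the
statistics recover a known signal under clean conditions — not that the
pipeline's genome-scale counts on real ENCODE data would be reproduced.

A caveat discovered during design and worth keeping in mind when choosing
motif pairs: if the two PWMs of a pair cross-recognize each other's words
(e.g. two IRF-family motifs a few mismatches apart), every planted site
also spawns enriched "shadow" structures at degenerate spacings, which can
outrank the intended structure. This mirrors the real-data practice of
pooling indistinguishable motifs rather than testing them as distinct
pair members.

## Numerical choices and degenerate inputs

* Score discretisation: 0.1-bit bins, nearest-bin assignment with halves
  up; the DP and all enumeration oracles share this stated convention.
* A PWM for which no grid threshold satisfies the balanced condition
  returns the maximal achievable score with a warning.
* Zero open-chromatin bp, empty instance lists for fractions, empty gene
  universes and empty term universes raise errors rather than returning
  NaN.
* BH q-values are clamped to q ≥ p elementwise.
* The config hash covers analysis-relevant parameters only (output paths
  excluded), so re-runs into different directories remain byte-comparable.

## Scales used by the default test run

The test-suite and acceptance script run the full pipeline at the 1 Mb /
3-cell-type / 30-copy scale described above (about 2 s per seeded run) and
the GO calibration at 5 000 genes × 200 terms; oracle-equivalence checks
enumerate all words for motif widths ≤ 5 and 50 random matrices. These
sizes were chosen to make every statistical claim checkable by exhaustive
or closed-form oracles while keeping a complete run interactive.
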