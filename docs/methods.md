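# Methods

scarkit models the computational half of a barcode-based authentication
study: given an aligned multi-species reference panel of a DNA barcode
(nrDNA-ITS for fungi, but nothing is ITS-specific), it designs and
validates species-specific SCAR assays and analyses the quantitative PCR
that would deploy them. This note records the models, the defaults and
why, the numerical choices, and what the synthetic data does and does not
establish.

## Distances and variability

Pairwise distances use either the raw proportion of differing sites
(p-distance) or the Kimura two-parameter correction

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)),

with P the transition and Q the transversion proportion over the L
columns where *both* sequences carry an unambiguous A/C/G/T (pairwise
deletion). Ambiguity codes are excluded from L exactly like gaps — the
conservative, deterministic choice. When the logarithm's argument is
non-positive the pair is saturated and an error is raised rather than a
clipped value returned.

Variability tables report, per species, the mean ± SD of conspecific
pair distances (undefined, reported as NaN, for single-record species)
and of all heterospecific pairs involving the species. The SD uses the
population (n) denominator, matching the convention of the common
barcode-analysis GUIs; an `inter_mode="species_means"` option averages
per-species-pair means instead of pooling all pairs, since both readings
of "interspecific variability" appear in the literature. The default
model for these tables is K2P, consistent with the tree module.

## Neighbor joining and bootstrap

`nj_tree` is the classic Saitou–Nei agglomeration: at each step join the
pair minimising Q(i,j) = (m−2)·d(i,j) − r(i) − r(j); branch lengths from
the standard two-point formulas; the final three nodes resolved by the
closed-form star equations. Two deliberate choices:

- **Determinism.** Q-ties are broken toward the earliest (i, j) pair in
  input order (with a 1e-12 tolerance), so the tree is a pure function
  of the matrix on any platform.
- **Negative branch lengths are kept.** NJ can produce them on
  non-additive input; clamping would silently break the additivity
  invariants the tests rely on (path lengths between leaves reproduce an
  additive input matrix exactly). Rendering clamps to zero only when
  asked (`write_newick(..., clamp_negative=True)`).

Bootstrap support resamples alignment columns with replacement,
recomputes the distance matrix and tree per replicate, and reports for
each internal bipartition of the reference tree the percentage of
replicates containing it. Replicates whose resampled matrix is undefined
(saturation, no comparable sites) are skipped and the denominator
adjusted; the RNG is `numpy.random.default_rng(seed)` so a seed fixes
every replicate. Supports are invariant to the input order of records.

## Diagnostic sites and SCAR design

A column is **diagnostic** for a target species when (i) one state is
carried by at least `min_intraspecific_fixation` (default 1.0 — full
fixation, appropriate for barcodes with near-zero intraspecific
variability) of the target records, and (ii) that state has no IUPAC
overlap with any non-target record's state at the column (a gap only
equals a gap). A gap on either side makes it an indel site, otherwise a
substitution site.

Primer enumeration slides windows over the *ungapped* target reference
(first record of the species), both strands, rejecting windows that
contain ambiguity codes, violate the constraint windows, or overlap an
intraspecifically polymorphic column — a primer that cannot anneal to
every conspecific template is useless regardless of its diagnostic
content. Default constraints (all overridable in `DesignConstraints`):
length 18–23 nt, GC 40–80%, Wallace Tm 52–74 °C (Tm = 2(A+T)+4(G+C);
the design constraint is a balance window, not an absolute thermodynamic
prediction), homopolymer runs ≤ 5, amplicons 80–400 bp, duplex size
separation ≥ 20 bp (resolvable on a 1.5% agarose gel). Indel sites
spanned by a window count toward its diagnostic coverage even though
coordinates are ungapped.

Pairs are ranked by total diagnostic coverage, then 3′-anchoring (a
diagnostic site within the 3 terminal nt), then forward/reverse Tm
balance, then leftmost coordinates; a pair is admissible only if at
least one primer covers ≥ 2 diagnostic substitutions, so a single
mutation in a related species can never create a false positive under
exact annealing. `design_marker_set` validates candidates in rank order
by exact in-silico PCR against the entire panel (every conspecific
template must yield exactly the expected size; any product from any
other template disqualifies), then repeats the search with the first
marker's ±20 bp size band excluded to find the duplex partner. For
speed, pairing first considers the 120 strongest candidates per strand
and falls back to the full set if that subset cannot complete the
duplex; if the full set cannot either, the set is returned flagged
`INFEASIBLE_DUPLEX` rather than silently relaxed.

## In-silico PCR

Binding is evaluated with 4-bit IUPAC masks (a primer base anneals iff
the expansion sets intersect; gaps never match), vectorised over all
template offsets. Reverse primers are matched via their reverse
complement on the plus strand with the 3′ end at the left footprint
edge. Defaults: `max_mismatch=0` for design validation — the strictest
reading of a clean specificity gel — and mismatches forbidden in the
3-nt 3′ window, where a mismatch is most disruptive to extension. The
cross-species audit runs at `max_mismatch=2` and flags templates where
*both* primers are within 1 mismatch, mirroring the rule of thumb that
two substitutions per primer are protective. Amplicon length is the
inclusive span from the forward primer's 5′ end through the reverse
primer's 5′ end (both footprints included), which is how published
amplicon sizes are stated; footprints may not overlap. Any off-target
product in the gel-visible 50–2000 bp range counts as a specificity
failure.

## qPCR standard curves

Ct is regressed on log₁₀(template mass in ng) by ordinary least squares
(scipy `linregress`); R² is the squared Pearson correlation, matching
the "correlation coefficient" language of assay reports. Efficiency is
E = (10^(−1/slope) − 1) × 100, defined only for negative slopes; the
integer report rounds halves away from zero (99.38 → 99, 130.5 → 131).
Quantities are converted to ng before the log (15 pg → 0.015 ng).
Points without a Ct call are dropped with a warning; a series with a
single distinct quantity is rejected as degenerate. The detection limit
reports both the smallest tested quantity called before the Ct cutoff
(default 40 cycles) and the curve-extrapolated quantity at the cutoff,
10^((cutoff − intercept)/slope).

The bundled five-assay Ct table is reproduced by these routines to the
published precision: the refit slopes agree within ±0.002 cycles/decade
(the residual is exactly what two-decimal rounding of the printed Cts
allows), and the published integer efficiencies and five-decimal R²
follow from the refit slopes — strong internal evidence for the
exponential form of the efficiency equation, whose plain-text rendering
in assay write-ups is often garbled.

## Authentication

Two independent routes must agree for a confident call. The **virtual
duplex assay** runs every marker against the (ungapped) sample sequence
at exact matching: a species is called only when both of its markers
produce exactly their expected sizes; multiple species firing yields
`mixed/adulterated` (adulteration detection is the point of the method,
so mixed signals are surfaced, not forced to a single species); no
marker firing with a positive universal-primer control yields
`unresolved` (non-panel species); a failed control invalidates the
sample. The **nearest-reference classification** globally aligns the
query to every reference (match +1, mismatch −1, gap −2) and assigns the
species of the best identity — matches over aligned columns excluding
terminal gaps — when it reaches `min_identity` (default 0.99, the
conventional barcode-identity threshold); exact ties between species are
reported as unresolved rather than broken arbitrarily.

## Synthetic panels

`generate_panel` evolves one random ancestor (default 580 bp core,
58% GC) along a **star-of-stars** genealogy: one branch per species with
a substitution density drawn uniformly from half the interspecific
target range (so species pairs land in 0.09–0.21 substitutions/site),
transitions twice as likely as transversions (so K2P estimation is
well-specified), plus 2 deletions of 1–12 bp per species; then one short
branch per individual (0–0.3% divergence). Conserved flanks carrying
binding sites for the universal barcode primer pair are attached to both
ends and never mutated, emulating the invariant rRNA ends that make the
amplification control work. Every mutation, deletion, branch length and
species-level diagnostic column is recorded as ground truth, and
everything is a deterministic function of the seed.

The star-of-stars choice trades realism for exactness: it reproduces the
divergence *structure* of a real barcode panel (tight species clusters,
well-separated species) while keeping ground truth trivially exact. It
does **not** model concerted evolution of rDNA arrays, rate variation
across sites, insertions (indels are deletions only), sequencing error,
or non-star phylogeny within species. Consequently, passing pipeline
tests show correctness of the algorithms under the stated divergence
regime — they do not show that real panels always admit a feasible
duplex design (a real species with too few diagnostic clusters will be
flagged `INFEASIBLE_DUPLEX`, which is the correct answer, not a bug).

## Problem sizes and tolerances in the test battery

The default panel (6 species × 3 records × ~620 aligned bp) matches the
scale of a real single-locus authentication panel. The property battery
runs NJ recovery on 30–50 random 4–8-leaf additive trees (path lengths
checked to 1e-9), the substring-oracle comparison on 1,000 random
primer/template pairs, the full simulate → design → specificity pipeline
on 20 panel seeds, and noiseless curve recovery to 1e-10; bootstrap
examples use 100–200 replicates, and 1,000 replicates (the conventional
choice for publication trees) remain entirely practical. Monte-Carlo
recovery of programmed divergences is asserted at ±20%, which covers
the binomial sampling noise of ~580-site branches plus multiple-hit
loss not fully restored by the K2P correction.
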