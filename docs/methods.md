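# Methods

This note documents the models, parameter choices and numerical decisions
behind `enscompare`, and what the synthetic validation does and does not
demonstrate about real data.

## Ortholog selection

Records are kept when the homology type is strictly `one2one` and both the
gene-order-conservation and whole-genome-alignment scores are **strictly
greater than** the threshold (default 75 for both; "above 75" is read as
exclusive, and the thresholds are configurable). Exact duplicate pairs are
removed first; after scoring, any gene still appearing in more than one
record disqualifies *every* record it appears in — strictness over
salvage, since an ambiguous assignment poisons the bijection the rest of
the pipeline relies on. Identifiers are opaque strings; no ID conversion
is attempted. Projection of gene-keyed objects through the bijection drops
unmapped genes and reports the count; round-tripping a→b→a is the identity
on the mapped subset.

## Normalization

RPKM uses the literal definition (reads × 10⁹ / (total mapped reads ×
gene length in bp)); zero lengths or totals are hard errors naming the
offending gene or sample. The log transform is log₂(x + 1) by default; the
pseudocount is configurable and recorded in provenance.

The cross-species anchor set is chosen in two steps. *Eligibility*: a gene
must lie within [Q1, Q3] of the expression distribution of **every**
sample. *Conservation*: among eligible genes, the variance across samples
of the within-sample rank (average rank for ties), smallest first, ties
broken by identifier. Scaling multiplies each sample by
(mean of per-sample anchor medians) / (that sample's anchor median),
computed in RPKM space by default (log-space scaling is available and
recorded in provenance). The invariance |median_s − common| / common
< 10⁻⁹ holds by construction for every sample, and positive factors
preserve within-sample rank order.

The every-sample eligibility rule is deliberately strict, and with many
samples (the default synthetic design has 66) the eligible pool can shrink
drastically or empty. The pipeline therefore anchors the medians on all
shared orthologous genes whenever the pool falls below `min_conserved`
(default 50), with a logged warning; the selection operation itself always
enforces the strict rule and errors when asked for more genes than the
pool holds.

## The plumbing differential-expression test

`simple_de` is explicitly a stand-in for a dedicated count-model DE
package, which is out of scope; externally computed DEG tables (TSV with
gene, direction, lfc, p, q) are first-class inputs everywhere a DEG list
is consumed. Three methods are provided on log-space expression:

- **moderated** (default): per-gene pooled variances are shrunk toward a
  common prior fitted by the method of moments on log variances (inverse
  trigamma via Newton iteration); the t statistic gains the prior's
  degrees of freedom. With a few thousand genes sharing a noise regime
  this recovers most of the power a gene-wise test loses to 6-vs-6
  variance estimation, which is precisely the situation the bulk design
  creates.
- **welch**: gene-wise unequal-variance t; constant genes get p = 1 with a
  warning.
- **wilcoxon**: gene-wise rank-sum.

All methods report BH-adjusted q (one family per contrast), and the
direction is the sign of the mean difference (first group relative to
second).

## Distributional similarity

ECDFs use the right-continuous counting definition. The two-sample KS test
is scipy's (exact for small samples, asymptotic otherwise). The paper-gap
decision on chi-squared binning: deciles of the *pooled* sample define the
bins of a 2 × k homogeneity table (uncorrected statistic, df = k − 1);
bins are reduced, with a warning, until every expected count reaches 1,
and fewer than two valid bins is an error. The comparison unit for
region pairs is the per-gene mean of scaled log expression over the
replicate samples of that region. Spearman p-values use the
t-approximation, switching to exact permutation below 10 observations;
constant vectors yield missing correlations rather than errors.

## Enrichment maps and coverage

Over-representation is the one-sided hypergeometric upper tail on the
(DEG ∩ term, DEG \ term, term \ DEG, rest) table against a user-supplied
background, BH-corrected over all terms of the database in one call. A
term with no genes in the background is reported with p = 1 (and a
warning) rather than dropped, so result tables always align with the
database. Term specificity follows the ClueGO-style rule: GO level within
[7, 15], overlap ≥ 1 gene, and overlap strictly exceeding half the term's
full annotation; the level selector returns the smallest level carrying at
least 3 significant terms.

Map edges connect terms with overlap coefficient |A∩B|/min(|A|,|B|) at or
above 0.25 (the EnrichmentMap convention; Jaccard is not used), carrying
the shared-gene count as the linkage weight. "Functional linkage" totals
are ambiguous between edge counts and summed shared genes; both modes are
implemented and every report records its mode, with **weight** the default
because observed linkage magnitudes far exceed plausible edge counts. A
linkage counts as covered when **both** endpoint terms contain a DEG from
the set under test (an `any`-endpoint mode exists for sensitivity
analysis). Coverage is the covered/reference ratio, exactly 1 for the
reference against itself, monotone under subset growth, an explicit error
when the reference covers nothing, and 0 for an empty subset. Manual
curation of off-topic terms is supported only through a user-supplied
exclusion list — nothing is hard-coded.

## Pathway scores

The harmonic mean p-value is the equal-weight combination L / Σ(1/p_i),
bounded by [min p, max p] and robust to the dependence created by scoring
overlapping terms through shared DEGs — the reason it is preferred over
Fisher's method here. The asymptotically-exact tail refinement is left as
a future extension; a reserved flag documents the choice. The up/down
enrichment ratio is computed on −log₁₀(q) (a raw-q mode exists); q = 1 in
the denominator flags the ratio infinite, both-1 flags it undefined, and
the reciprocal identity ratio(a,b)·ratio(b,a) = 1 holds wherever both are
finite and nonzero. The pro/anti ratio counts map nodes shared between a
pathway's term neighborhood (the terms plus their map neighbors by
default) and each signature; node sharing was chosen over gene sharing as
the operational definition, with the neighborhood toggle exposing the
stricter reading. Gene–gene functional similarity is the Jaccard index of
BP annotation sets — a deliberate simplification of information-content
semantic similarity, adequate for ranking but not calibrated against it;
this is a stated limitation.

## Single-cell summaries

Clustering, integration and embedding are consumed as given labels, never
computed. QC keeps cells with detected-gene counts in [200, 2500]
inclusive and mitochondrial share ≤ 5%, then genes detected in ≥ 3
surviving cells (gene filter strictly after cell filter; the output is
independent of input ordering). Markers are one-vs-rest Wilcoxon on
library-size-normalized ln(1+x) expression with BH per cluster; the
reported avg log-fold change is natural-log (the convention of the cited
marker procedure, recorded in the output), and only rows above the 0.25
floor are returned. Ligand–receptor calls use presence (count > 0) in more
than 10% of each subset's cells — the presence threshold is a package
choice, as no expression cutoff is stated for this step — and self-loops
are legitimate calls. The VNS flag is set when *either* the ligand's or
the receptor's DE p-value under stimulation is smaller than without;
both genes' four p-values are recorded so the stricter both-gene rule is
recoverable. Genes absent from a p table are imputed p = 1 with a warning.

The cells-required calculator treats the k cell types as independent, each
at frequency f, and searches incrementally from m for the smallest N with
[P(Binomial(N, f) ≥ m)]^k ≥ c using exact tails. Both standard reference
points — 702 cells (10 types, 2%, ≥6, 95%) and 127 (5 types, 10%, ≥6,
95%) — are reproduced exactly by this model, which anchors the
interpretation; fractions summing above 1 only warn, since independence is
already an approximation.

## Synthetic study design

The bulk generator mirrors the study layout: pig proximal/transverse/
distal colon × {MG, ISG} × (6 naive + 3 VNS replicates), human ascending/
transverse/descending colon MG × 4. One latent log2 expression program
(normal with mean 5, sd 1.0 per gene) is shared by both species through
the ortholog bijection; planted contrasts (region, plexus, VNS; default 80
/60/60 genes, log2 effect 1.5, half up half down) perturb it per group.
Counts are negative binomial (gamma–Poisson, dispersion 0.1) around
length- and depth-weighted means with log-normal library-size variation
(CV 0.25 around 2 M reads); 2000 genes keeps the full run in seconds. The
baseline sd of 1.0 keeps even tail genes at counts where the planted
dispersion, not shot noise, dominates — the regime the stated
effect/dispersion/replicate conditions describe. The ortholog table mixes
the true bijection with 10% sub-threshold-score decoys and 10% non-1:1
decoys that the quality filter must remove.

Gene-set generation plants term databases directly: GO-BP-like terms
(levels 7–15, sizes 10–40) where consecutive pairs share genes at an
exactly constructed overlap coefficient, an optional "focus" mechanism
that seeds a fraction of terms with planted DEGs so over-representation
has real signal, a categorized WikiPathways-like database (9 categories),
and pro/anti-inflammatory signatures. The cell generator plants five
ENS-like types (cholinergic, glutamatergic, nitrergic neurons; two glia)
with disjoint 4-fold marker blocks, Poisson-lognormal counts with 20%
dropout, mitochondrial genes carrying 2% of each cell's signal (a
configurable block at 10% exercises QC), and ligand–receptor pairs that
are near-silent except in their planted source/target types.

Everything planted is recorded in a truth object sufficient to score every
recovery experiment, and a fixed seed reproduces all outputs exactly.

**What the synthetic validation does not show.** The generator produces
clean negative-binomial/Poisson-lognormal noise with independent genes, no
batch structure, no GC/length bias beyond the explicit length weighting,
no ambient RNA or doublets, and planted gene sets far smaller and cleaner
than real annotation databases. Passing tests therefore demonstrate that
the statistics are implemented correctly and behave as designed under
their assumed models — not that those models capture every failure mode of
real cross-species data. Dataset-dependent magnitudes from real studies
(ortholog counts, DEG counts, linkage totals) are not reproduction targets
at this scale.

## Pipeline and numerical conventions

Stages communicate only through written TSV artifacts with provenance
headers (stage, config hash excluding the output path, seed); reruns with
the same config and seed are byte-identical. BH families are fixed as one
family per DEG-list × database call. Multiple-testing q-values are never
recomputed downstream. Degenerate inputs fail loudly with the offending
sample/gene/stage named: zero medians, empty QC output, zero-coverage
references and infeasible synthetic configs are errors, while empty-subset
coverage (0), unenriched ratios (inf/nan flags) and constant-vector
correlations (missing) are defined results. Problem sizes used in the test
and acceptance suites (500–2000 genes, 25–40 terms, 50–150 cells per type)
are the package's desk-scale defaults; all are configurable upward.
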