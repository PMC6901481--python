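# Methods

`pahomics` implements an integrative multi-omics analysis of pulmonary
arterial hypertension (PAH) endothelial cells: differential label-free
proteomics and phosphoproteomics, protein–protein interactome network
proximity with a degree-preserving permutation null, plasma metabolomics
enrichment, metabolite–enzyme network mapping, and the statistics for the
bioenergetic validation assays. Because the underlying study deposited no
raw matrices and the reference interactome cannot be reassembled at the
desk, every analysis runs against synthetic data whose generators encode
the study design explicitly; this note records the models, the defaults and
the reasoning behind every genuinely open choice.

## Synthetic data model (`synthio`)

One root seed drives everything. Each generator derives an independent
substream from `(seed, sha256(stage_name))`, so adding or reordering stages
never perturbs another stage's draws, and identical configurations are
byte-identical on disk.

**Intensity matrices.** Feature baselines are log-normal
(log2 mean 20, SD 2 — the typical LFQ dynamic range of roughly 1e5–1e8).
Within-group variation is multiplicative noise of 0.25 log2 units (~19% CV,
the deep-LFQ regime for cultured-cell replicates), plus additive raw-scale
detector noise with SD 2^14. The additive component matters: with purely
multiplicative noise a plain log2 would already stabilize variance and the
generalized-log transform below would have nothing to do. A configurable
fraction of features (default 170/2556 ≈ 6.7%, the study's differential
fraction) is shifted by ±1 log2 unit in the case group, with random sign.
Default design: 4 case vs 5 control samples.

**Missingness.** Missing-not-at-random dropout follows a logistic curve in
the latent log2 intensity — probability 1/2 at log2 = 16 with unit
steepness, i.e. essentially complete observation above ~2^19 and heavy
dropout below ~2^14 — plus a 2% missing-completely-at-random floor. This
yields ~9% missing cells overall, concentrated in low-abundance features,
which is what feature-wise imputation must cope with in real label-free
data. A fully masked feature has its highest-intensity cell unmasked so
every feature retains one observation. The generators report the complete
(pre-masking) matrix alongside the masked one so imputation error is
measurable.

**Phosphosites.** Residues are drawn S/T/Y with probabilities
0.843/0.147/0.010 (the study's observed tally among localized sites).
Localization probabilities come from a two-component mixture — 85%
Beta(8, 1) (confidently localized) and 15% Beta(1.5, 1.5) — so the strict
">50%" filter removes a realistic minority of sites.

**Interactome.** Preferential attachment (Barabási–Albert, 3 edges per
arriving node) at a desk scale of 3,000 nodes. A scale-free degree
distribution is essential here: degree-binned null sampling is only
meaningfully exercised when degrees are heavy-tailed. Each edge carries one
of the six experimental evidence codes (Y2H, 3D, KS, SIG, APMS, LIT) drawn
from fixed proportions; `PRED` (computationally predicted) edges exist only
in I/O fixtures to exercise the filter.

**Planted structure.** The truly differential proteins and the parents of
the truly differential phosphopeptides are chosen as a *proximal* node-set
pair — both sampled from one breadth-first ball around a random anchor
(the radius grows from 1 until some ball can hold both sets). This encodes
the biological claim under test: the two differential sets occupy the same
network neighbourhood without necessarily overlapping.

**Metabolome, reactions, assays.** Metabolite profiles reuse the
log-normal machinery (30 vs 12 subjects, 20% differential at 1 log2 unit,
0.8 log2 noise — plasma metabolomics is noisier than cell-culture
proteomics; no masking, as platform pipelines deliver imputed tables).
19% of metabolites are "unnamed" and never annotated to pathways. Five of
25 pathways oversample truly differential metabolites (60% of members) so
enrichment has planted signal. The reaction table links enzymes (graph
proteins) to named metabolites, 1 enzyme and 1–3 metabolites per reaction,
bipartite by construction. Dose–response curves are a saturating logistic
in log10(dose + smallest positive dose) over the glucose series
0–100 mM, with subject-level intercepts (SD 10), per-point noise (SD 5),
and group shifts matching the reported bioenergetics (control OCR ≈ 72,
case ≈ 44 pmol O₂/min; ECAR shifted up in the case group).

## Differential expression (`diffexpr`)

The stage order is fixed: normalize → impute → fit variance prior →
moderated t → BH FDR → classify.

**Normalization.** Full maximum-likelihood variance-stabilizing fits are
deliberately avoided in favour of a closed, testable form: each sample is
scaled so its median log-ratio against the geometric-mean pseudo-reference
profile is zero (median-of-ratios calibration), then
`glog2(x; λ) = log2((x + √(x² + λ²))/2)` is applied with λ set to the 5th
percentile of positive calibrated intensities. `glog2` reduces exactly to
`log2` at λ = 0 and flattens the additive-noise variance inflation at low
intensity.

**Imputation.** Feature-wise k-nearest neighbours (k = 10). For each
missing cell, candidate neighbours must be observed in that sample and
share at least two observed samples with the target feature; similarity is
root-mean-square difference over the mutually observed samples (the RMS
normalization keeps neighbours with different overlap sizes comparable —
a raw Euclidean sum would favour small overlaps). Ties break on
lexicographic feature id for determinism. Fallbacks: the feature's own
observed mean when no neighbour qualifies; the global half-minimum when a
feature has no observation at all. Sample-wise neighbours are useless at
4–5 samples per group, hence the feature-wise orientation.

**Variance moderation.** Per-feature pooled residual variances s²_g (df =
n₁+n₂−2) are modelled as s²_g ~ s₀²·F(df, d₀) and the prior (d₀, s₀²)
estimated by moments on log s²_g: the excess dispersion of log variances
over the trigamma(df/2) sampling term equals trigamma(d₀/2), inverted by
Newton iteration at tolerance 1e-8. When the excess is non-positive d₀ = ∞
and s₀² is the arithmetic mean of the s²_g (a consistent estimate of the
common variance that also returns the shared value exactly in the
degenerate all-equal case). The moderated statistic uses
s²_post = (d₀s₀² + df·s²_g)/(d₀+df) and a t reference on d₀+df degrees of
freedom (normal when d₀ = ∞). d₀ = 0 reduces *exactly* to the ordinary
pooled two-sample t — the oracle equivalence the tests enforce.

**Significance.** Benjamini–Hochberg step-up q-values are computed always;
the default classification rule is raw p < 0.05 (matching the study's
reported counts), with `rule="fdr"` available (matching its stated
methods). Both rules are first-class because the source is internally
ambiguous; neither is "the" rule.

**Phosphosites.** Localization filtering is strictly greater-than the
threshold (default 0.5); a site at exactly 50% is dropped. The residue
tally reports counts and one-decimal percentages of retained S/T/Y sites.

## Interactome and network proximity (`interactome`, `proximity`)

The graph layer is an undirected simple graph over opaque protein ids with
per-edge evidence-code sets; predicted edges and self-loops are dropped at
build time and duplicate undirected records merge their evidence.

**Proximity.** For sets A and B mapped into the graph,
d_AB = (1/(|A||B|)) Σ_{a∈A, b∈B} d(a, b), the "Shortest" variant, with
d(·,·) BFS hop distance and |A|, |B| the mapped counts. A node in both sets
contributes its zero self-distance — this is deliberate; the permutation
null reproduces the same overlap (below). The statistic is undefined on
disconnected pairs, so analyses default to the largest connected component;
`allow_disconnected=True` instead drops unreachable pairs from the average
and reports the dropped count.

**Degree-preserving null.** Nodes are partitioned into degree bins by
greedily merging ascending degree values until each bin holds at least
`min_bin_size` nodes (default 100, lowered to max(5, n/50) on small
graphs); a final undersized bin merges backwards. Each permutation redraws
*both* sets: per bin, as many distinct nodes as the two observed sets
jointly need are drawn without replacement and split so that the null pair
preserves each set's size and degree distribution *and* the observed
overlap count between the sets. Preserving the overlap is what makes the
degenerate cases exact (disjoint singletons on a complete graph give a
zero-variance null) and keeps zero-distance self-pairs equally frequent in
null and observed. The observed nodes stay in the sampling pool — removing
them would bias the null upward. `fix_a=True` gives the literature variant
in which only B is redrawn.

**Inference.** z = (d_obs − mean(null))/sd(null) with the sample SD
(n−1 denominator); z is reported as undefined when the null is degenerate.
The empirical p uses the add-one correction,
p = (#{d_null ≤ d_obs}+1)/(n_perm+1), one-sided toward closeness — the
claim under test is proximity, and the add-one floor at 10,000
permutations is ≈1e-4. A `two_sided` flag doubles the smaller tail. The
contrasting Fisher's exact overlap test is two-sided, with the universe
(whole interactome vs quantified proteins) an explicit parameter since
either choice is defensible.

## Metabolomics (`metabnet`)

Metabolite differential abundance uses Welch's unequal-variance t on log2
abundances after per-metabolite half-minimum replacement of zeros — the
conventional choice for platform metabolomics; the moderated t is
available but not the default since metabolite variances are far less
exchangeable than peptide variances. Exact separation (zero variance in
both groups, unequal means) is flagged and floored rather than reported as
p = 0.

Enrichment is a hypergeometric upper tail on the 2×2 of
significant × pathway membership; `N` counts all measured metabolites
(unnamed included — they dilute enrichment exactly as unannotatable
metabolites do in practice), pathway sizes count measured members only.
Fold enrichment is (k/m)/(K/N), and the dysregulation flag is the printed
rule: p < 0.05 and fold enrichment > 1, with fold exactly 1 *not* flagged.

The metabolite–enzyme network is strictly bipartite (mixed-role ids are
rejected). The dysregulated subnetwork keeps every significant node plus
any node whose two nearest *distinct* significant nodes lie within
`max_hops` total (default 2 = one intermediate); components are ranked by
significant-member count, then size, then smallest node id. The node set
is monotone in `max_hops` and `max_hops=0` is the plain induced subgraph.

## Assay statistics (`assays`)

The Wilcoxon rank-sum test uses mid-ranks and full enumeration of all
C(n₁+n₂, n₁) assignments while that count is ≤ 200,000 (e.g. 10 vs 9
subjects → 92,378), falling back to a tie-corrected normal approximation
with continuity correction; two-sided p is twice the smaller tail, capped
at 1.

AUCs use the trapezoid rule on log10(dose + shift), shift defaulting to
the smallest positive dose so the 0 mM point stays finite (doses span
three orders of magnitude, so an identity axis would let the 100 mM
interval dominate). The bootstrap resamples *subjects* (cell lines — the
unit the study's n refers to), not wells, with replacement within each
group; the statistic is the difference of group-mean AUCs and the
two-sided sign-crossing p is 2·min(#{Δ ≥ 0}+1, #{Δ ≤ 0}+1)/(n_boot+1).
Resampling substreams are keyed to each group's subject ids rather than to
the case/control labels, so relabeling the groups flips only the sign of
every replicate and the p-value is exactly invariant. A studentized or
shift-null bootstrap is out of scope by design.

## Pipeline (`pipeline`)

`run_full(config, out_dir)` executes simulate → proteome DE → phospho DE →
proximity (full and mitochondria-restricted) → metabolomics → assays, in
that fixed order, writing each stage's files before the next starts. The
manifest records the merged configuration, the seed, package and library
versions, per-stage status (ok / skipped / error) and a SHA-256 digest of
every output file; a failing stage is recorded and re-raised with all
earlier outputs intact, and reruns from the same seed reproduce every
digest. Configuration is a YAML-compatible nested mapping merged over
defaults. The default permutation count in the pipeline is 2,000 (the
standalone proximity API defaults to 10,000): at the 3,000-node desk scale
the observed z-scores are far below the add-one floor either way, and the
smaller default keeps a full run under ten seconds on one core.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the methods assume —
intensity-dependent missingness, heavy-tailed degrees, planted proximal
differential sets, overlapping-but-distinct omics layers, monotone
dose-response with subject effects. They do not reproduce real pathway
topology, peptide-to-protein inference, correlated co-regulated feature
blocks, or the actual 351,444-edge reference interactome, whose printed
size is treated as descriptive. Passing tests therefore demonstrate
correctness and calibration of the machinery under the stated model, not
recovery of the study's specific biological findings; the headline counts
the pipeline prints at the default scale (e.g. ~290 differential proteins
at raw p < 0.05 out of 2,556) are properties of these simulation settings,
not estimates of the study's values.

## Numerical conventions

Ties in kNN neighbour ranking, component ordering, anchor selection and
bin membership all break lexicographically; every stochastic routine takes
a seed or Generator; trigamma inversion iterates to 1e-8; BH q-values are
computed with a reverse cumulative minimum and are permutation-equivariant;
p-values are never exactly 0 (add-one permutation corrections, floored
exact-separation flags). Problem sizes used in the test suite (500-node
graphs, 200-repeat calibrations, 10,000-feature null panels, 20,000
simulated variances) were chosen so each statistical check has enough
resolution for its 99% binomial band while the whole suite stays
interactive.
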