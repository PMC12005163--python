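# Methods

## The model

The data unit is a gene in a species with four nonnegative counts:
nonsynonymous and synonymous branch-specific divergence (Dn, Ds) and
nonsynonymous and synonymous polymorphism (Pn, Ps). Everything the
framework does rests on one generative assumption: conditional on the
total number of variants N = NS + S in one (gene, species, context)
observation, the nonsynonymous count NS is binomial,

    NS | N  ~  Binomial(N, P),      P = β·α / (β·α + 1),

where α is a single global baseline N:S odds and β is a multiplicative
modifier attached to the *cell* the observation falls in — a cell being
a combination of species, context (divergence vs polymorphism), gene
class (piRNA machinery vs all other genes) and, when modelled, the
nuclear/cytoplasmic compartment of piRNA genes. The model log-likelihood
is the gene-wise sum of log binomial probabilities; an observation with
N = 0 carries no information and contributes exactly 0.

α is fixed at the dataset aggregate (ΣDn + ΣPn)/(ΣDs + ΣPs) and is never
re-optimised. It is a pooled baseline, not an average of per-gene odds:
genes with more variants contribute more. All inference is about the
modifiers β.

Because every observation sharing a modifier shares the same success
probability, each modifier's ML estimate has the closed form

    β̂_k = (pooled NS_k / pooled S_k) / α.

The package uses this closed form by default and keeps an independent
numerical route (L-BFGS-B on log β, enforcing positivity without
constraints) for verification; the two agree to 1e-6 relative tolerance
on identifiable parameters, and the test suite enforces this on a
thousand random datasets. Reported log-likelihoods include the binomial
coefficient, so a single-observation likelihood matches the textbook
binomial expression; the coefficient cancels in every likelihood-ratio
statistic.

Degenerate pools are flagged rather than silently propagated: a pool
with NS = S = 0 is *uninformative* (β reported as 1, contributing zero
log-likelihood); a pool with S = 0 < NS has an unbounded ML
(*unbounded*, β reported as +inf, contributing its supremum 0). Flagged
parameters are excluded from LRT degrees of freedom with a loud warning.

## Model selection

Partition models are nested when every parameter class of the richer
model lies inside one class of the simpler model; this is checked
structurally on the observation assignments, not by name. The LRT
statistic is 2·Δlog L, compared to the upper tail of χ² with degrees of
freedom equal to the number of extra identifiable parameters. Negative
statistics beyond 1e-9 raise; within tolerance they clamp to 0.

The ladder walks tiers of candidate models from coarse to fine: fit all
candidates in a tier, keep the one with the highest likelihood (ties
broken lexicographically by model name for determinism), test it
against the current selection, adopt it if p < threshold (default 0.05,
configurable; no multiple-testing correction is applied across steps —
a deliberate caveat, as stepwise selection inflates the family-wise
error rate). Candidates that do not refine the current selection are
skipped and recorded, which lets a single config describe sibling
branches that become unreachable once another branch is chosen. Four
ladders ship as presets: species × context, divergence × gene class,
polymorphism × gene class, and divergence × compartment (the last meant
for a divergence-only, two-species subset; its polymorphism catch-all
parameter is uninformative there by construction and drops out of the
degrees of freedom). The preset tier structure is a reconstruction of a
stepwise procedure conveyed mostly graphically in the source analyses;
alternative intermediate models can be supplied as user YAML.

## Summary statistics

For species i, with Odds(cell) = β̂·α:

    ζ_i = Odds(div, piRNA) / Odds(div, other)
    χ_i = [Odds(div, piRNA)/Odds(poly, piRNA)] /
          [Odds(div, other)/Odds(poly, other)]

α cancels in both, so they are invariant to rescaling the baseline
(tested to 1e-9). Both can be computed from a fitted model or directly
from pooled counts; the routes agree exactly when the model gives each
involved cell its own parameter, and the shared-parameter ("selected")
structure deliberately ties some of them.

Pooled odds are dominated by high-count genes (a Simpson's-paradox
caveat the dominant-gene preset in the generator reproduces). Two
mitigations are provided. The stratified gene-wise bootstrap (below)
shows whether a few genes drive a contrast. The Tarone–Greenland
weighted neutrality index averages gene-level odds ratios instead of
pooling:

    NI_TG = Σ_i [Ds_i·Pn_i/(Ps_i+Ds_i)] / Σ_i [Dn_i·Ps_i/(Ps_i+Ds_i)],

reported as its reciprocal 1/NI_TG (values above 1 indicate excess
nonsynonymous divergence). Genes with Ps + Ds = 0 carry no weight and
are excluded, with the exclusion count reported; for a single gene with
positive counts the index reduces to the plain cross-ratio
(Dn·Ps)/(Ds·Pn).

## Bootstrap

Genes are resampled with replacement within their class stratum (piRNA
and other separately), each drawn gene carrying all its species' rows
jointly so cross-species gene effects are preserved; stratum sizes are
conserved. For each replicate the chosen model *structure* is refit (no
re-selection), and χ and ζ recorded per species. Internally the
replicate fit uses a weighted-pool shortcut — resampling genes is
equivalent to multinomial gene weights in the pooled counts — which is
exactly equivalent to rebuilding the dataset (tested draw-for-draw) and
makes 10,000 replicates on a genome-scale table take seconds.
Replicates in which a required odds loses its synonymous pool are
dropped and counted. A per-species resampling variant (genes drawn
independently within each species) is available on `resample_dataset`.

A between-species contrast gets a sign-based p-value: the fraction of
replicates whose contrast opposes the direction observed on the
unresampled data, with zero-valued replicate contrasts counted as
opposing (conservative). No add-one correction is applied by default;
one is available behind a flag.

One property of this p-value is worth stating plainly: the tested
direction is chosen by the observed contrast itself. Under an
exchangeable null (no true difference between the species) and an
approximately normal bootstrap distribution centred on the observed
value, p ≈ Φ(−|Z|) = min(U, 1−U) with U uniform — i.e. the null
distribution is Uniform(0, ½) with mean ¼, and P(p < 0.05) ≈ 0.10. The
statistic is therefore anti-conservative by about a factor of two
relative to its nominal level; the test suite asserts this null
behaviour rather than a uniform-on-(0,1) one. Very small p-values
remain meaningful evidence of a directionally stable contrast.

## Synthetic data generator

The generator inverts the likelihood exactly: per gene a Gamma intensity
(shape 1/dispersion, mean 1) shared across species and contexts; per
(species, context) a total N ~ Poisson(context mean × intensity), giving
negative-binomial marginals with gene-linked counts; then
NS ~ Binomial(N, β·α/(β·α+1)) with the cell's true β, and S = N − NS.
Defaults mirror the study design this framework targets: three species
(labelled mel/ana/wil by convention), 31 piRNA genes (11 nuclear, 20
cytoplasmic) among 8,747 orthologs, α = 0.308, negative-binomial
dispersion 0.5, and mean total counts of 8 (divergence) and 25
(polymorphism) per gene per species — chosen as realistic Drosophila
population-genomic magnitudes (hundreds of thousands of variants
genome-wide, sparse per-gene divergence). True modifiers are looked up
hierarchically (species–context–class–compartment down to context-only,
default 1). Seeding spawns one stream per gene from the master seed, so
a gene's counts are unchanged when more genes are added.

What the generator does not emulate: real per-gene selective
heterogeneity within a cell (all genes in a cell share one true β),
linkage between nonsynonymous and synonymous counts beyond the shared
intensity, ascertainment or alignment artefacts, and the real data's
unknown dispersion. Passing tests therefore demonstrate correctness of
the inference machinery under its own assumptions, and calibration of
the LRT at realistic count magnitudes — not robustness to model
misspecification in real variant tables.

## Numerical and design choices

- Closed form is the default fit; numerical optimisation exists to
  verify it and to support future non-decoupling extensions.
- LRT statistics are clamped to 0 within 1e-9; larger negative values
  raise, since they indicate an optimisation failure.
- Ladder ties are broken by model name; reruns are bit-identical given
  the same inputs, threshold and seed.
- Genes present in only some species produce a warning, not an error
  (complete 1:1:1 ortholog tables are the expected input).
- Counts are per-gene totals; no frequency-class filtering (singletons
  retained) is implemented or planned.

## Problem sizes used by the test and analysis runs

Unit and property tests run on datasets of 25–2,000 genes; the LRT
calibration uses 500 null simulations of 200 genes with mean total
counts ≥ 20 per gene; parameter-recovery checks use pools ≥ 10,000
variants per parameter (4,000 genes at mean 120 counts); the analysis
drivers use the full study-scale grid (8,747 genes × 3 species) with
2,000 bootstrap replicates, and the whole suite completes in well under
a minute on one core. These sizes are the package's own choices for
quick, reproducible runs; all are configurable.

## Limitations

- No estimation of selection coefficients or of the fraction of
  adaptive substitutions; the framework does hypothesis testing on N:S
  odds only.
- Pooled β estimates are concatenated-gene quantities; they are not
  averages of per-gene odds, and the NI_TG table should be read
  alongside them.
- χ²-based LRT p-values rely on large pooled counts; with sparse cells
  (e.g. few divergent variants in a small gene class) the bootstrap is
  the more trustworthy of the two procedures.
- The sign p-value's null level is ~2× its nominal value (see above).
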