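# Methods

This note documents the models, numerical choices and limitations behind
`deeppca`. It is the package's own account; every number quoted here is
recomputed by the test suite or `scripts/acceptance.py`.

## The assay and the PPI score

In a deepPCA competition, cells expressing a variant pair grow at a rate
set by the concentration of the reconstituted complex. Writing `f_in`
and `f_out` for a variant's frequency in the input and output
populations and `g_r` for the replicate's population doublings, the
variant's own doublings are `n_i = log2(f_out/f_in) + g_r` and its PPI
score is `n_i / n_wt`, doublings relative to the wild-type interaction.
The published figure defining the score is graphical, so this
generations-relative form is a documented reconstruction; its estimand
equals the simulator's ground truth by construction (below), and the
overall scale cancels in the wild-type normalization. Frequencies are
computed on the full count table (every sequenced molecule counts in the
denominator) *before* filtering.

Filters follow the original analysis: a variant needs ≥ 10 input UMIs in
all three replicates and ≥ 1 output UMI in all three; stop-containing
variants and the wild type are excluded from score tables (the wild-type
counts are kept for normalization). The boundary is inclusive
(`>= min_input`), exposed as `--min-input`.

### Background-growth (mode) correction

Non-interacting variants still divide a few times before intracellular
resources deplete, and this background differs between batches. The
correction aligns the detrimental mode (the left mode of the bimodal
score distribution) across replicates — and, jointly, across libraries —
with the affine map

    corrected = (PPI − s) / (PPI_wt − s),   s = (m − M) / (1 − M),

where `m` is the replicate's mode and `M` the maximum mode across
replicates (and libraries). The map pins the wild type at exactly 1 and
sends a score of `m` to `M`. The mode is the leftmost local maximum of a
Gaussian KDE (Silverman bandwidth, 512 grid points) below a ceiling
(default 0.9). One robustness addition: a qualifying maximum must reach
at least 50% of the densest sub-ceiling maximum, because at moderate
sequencing depth the discreteness of low output counts creates small
satellite bumps to the left of the true detrimental mode. A unimodal
distribution triggers a warning and an identity correction.

## The thermodynamic (global epistasis) model

A two-state dimer equilibrium with growth proportional to complex
concentration plus a background term `b` gives, in dimensionless form
(all concentrations relative to the wild-type complex `AB_wt`, energies
in RT units, RT = 1),

    ddG(p) = log[ (X − p)(Y − p) / ((p(K+1) − K)(X − 1)(Y − 1)) ],

with `K = b/AB_wt`, `X = (K + A_T/AB_wt)/(K+1)`, `Y = (K +
B_T/AB_wt)/(K+1)`. Scores live in the open interval `(K/(K+1),
min(X, Y))`: the floor is pure background growth, the ceiling is the
limiting protein fully in complex. Inverting yields a quadratic whose
*smaller* root is the physical solution (the larger exceeds the
ceiling); it is evaluated in the stable form `2C/(B + sqrt(B² − 4C))`,
and `exp(ddG)` for a double is computed as the product of the singles'
factors, which keeps the grid sweep linear in the number of
observations. Double-mutant energies are additive:
`ddG_d = ddG_s1 + ddG_s2`.

Out-of-interval singles: a score at/below the floor maps to ddG = +inf
and clamps the prediction to the floor; at/above the ceiling, to the
ceiling. The published formula for the upper clamp reads
`min(A_T, B_T)/AB_wt / (b/AB_wt + 1)`, which differs from the analytic
ceiling `min(X, Y)` by the `+K` term in the numerator; we use
`min(X, Y)` (the asymptote the function actually attains). A single at
the floor combined with one at the ceiling has no defined prediction;
`predict_double_ppi` raises by default, while the fitting and residual
paths mark such rows NaN and exclude them.

### Fitting, identifiability, cross-validation

The three parameters are fitted by exhaustive grid search maximizing the
variance explained (1 − SS_res/SS_tot) of observed double-mutant scores,
pooling the three replicates (each double contributes one row per
replicate; predictions use that replicate's single-mutant scores — a
replicate-mean option exists). The reference grid is 1.1–2.0 (step 0.01)
for both abundance parameters and 0.3–1.2 (step 0.001) for background
growth; cross-validation uses 1.1–1.6 / 0.3–1.0 at step 0.01. Ties break
towards lexicographically smallest (bg, a, b), making the fit
deterministic. A coarse-then-fine helper (`fit_params_refine`) cuts cost
when the full grid is too expensive.

Two structural facts about identifiability, established with the
simulator:

* The model is exactly **symmetric in the two abundance parameters**
  (ddG depends on X and Y symmetrically), so (A_T/AB_wt, B_T/AB_wt) is
  identified only as an unordered pair. Recovery is therefore assessed
  on the sorted pair.
* `min(X, Y)` (the ceiling) and `K` (the floor) are well determined, but
  the **larger** abundance parameter affects only mid-range curvature
  and sits on a nearly flat ridge of the objective. With noiseless data
  the generating grid point is recovered exactly, and with 2%
  multiplicative score noise within 3 × 0.01 grid steps; with full
  count-level sampling at realistic depth, the zero-output filter
  truncates floor variants upward and tilts this ridge by several 0.01
  steps. Parameter-recovery checks therefore run on a reduced grid
  (steps 0.05/0.05/0.02) whose resolution reflects what the data
  determine.

Monte-Carlo cross-validation samples half of each protein's single
mutants; doubles built from sampled singles form the training set and
doubles built entirely from held-out singles the test set (sets are
independent by construction). Repeats with an empty set are recorded as
missing; medians summarize.

## Genetic interactions and the permutation FDR

The multiplicative score is `GI_r = PPI_d,r − PPI_s1,r · PPI_s2,r` per
replicate; the thermodynamic residual is observed minus the model
prediction. Both feed the same machinery: a two-sided one-sample t-test
of the replicate scores against 0 (zero-variance rows get p = 1 and a
`degenerate` flag), then a permutation FDR: in each permutation the
scores are shuffled within each replicate column independently, t-tests
are re-run, and at each observed p-value the FDR is the permutation-mean
number of permuted discoveries divided by the real discoveries at that
threshold, clipped to [0, 1]. The estimate is made monotone
non-decreasing in p by a cumulative maximum from the smallest p (a
coherence choice not specified in the source analysis). Discoveries are
counted two-sided jointly; positive and negative calls are reported
separately afterwards. The reference permutation count is 10,000;
validation scenarios use 1,000.

`true_case_estimate` converts a significant-call count and its average
FDR into an expected number of true interactions,
`n_significant × (1 − FDR)`.

## Structural annotation and enrichment

Heptad letters cycle a–g with period 7 from a user-supplied register
offset (offset 0 puts position 1 at *a*); classes are core (a, d),
salt-bridge (e, g) and far-side (b, c, f). Distances are minimal
side-chain heavy-atom distances from a PDB structure via Bio.PDB;
glycine falls back to its alpha-carbon (standard convention; the source
is silent). No structure is bundled — tests use synthetic coordinates,
and any PDB file plus a chain/residue-number mapping TSV works.

Strong interactions are |mean score| > 0.1 with permutation FDR < 0.2
(both strict). Enrichment uses two-sided Fisher exact tests in three
families — each position pair against all others, each unordered
position-type pair, and within-vs-beyond each distance threshold
(defaults 5, 8, 10 Å with 5 Å as the contact definition) — with the
conditional-MLE odds ratio and BH FDR controlled independently per
family and sign (significance at FDR < 0.1). Tests with an empty margin
are skipped with a flag.

## Cis/trans comparisons

Reachability: a substitution is kept iff some codon of the mutant amino
acid is exactly one base from the wild-type codon (standard genetic
code; stops excluded); doubles need both. Matched sub-sampling bins each
library's doubles in 2-D by their two singles' scores (20 even bins
between the pooled min and max single-mutant score), randomizes the
axis assignment of cis pairs per sub-sample (the pair is unordered
within one protein), and down-samples the better-represented library per
bin, making per-bin counts equal by construction. Class proportions are
averaged over sub-samples; the empirical p of a class is the fraction of
sub-samples whose cis−trans difference opposes the mean direction,
reported as `< 1/n_subsamples` when none do.

Variance decomposition reports, as fractions of the non-random variance
(mean squared Pearson correlation between replicate pairs): the
multiplicative model's variance explained, the thermodynamic model's,
its increment, and the residual attributed to structural interactions.
Note the non-random fraction is itself an estimate and can fall below a
model's variance explained in heteroscedastic data; components are
reported, not truncated.

## The synthetic-data generator

`deeppca.simulate` emulates the experiment's generative chain with
defaults chosen as the study conditions:

* **Landscape** — per single mutant, ddG is drawn from a two-component
  mixture: near-neutral N(0, 0.35) and detrimental N(6.0, 1.5), with
  detrimental weight 0.20 (protein A) and 0.15 (protein B), matching the
  reported ~20%/15% severely detrimental substitutions. The neutral
  scale 0.35 makes true single-mutant scores span ≈0.41–1.09 at the
  default parameters — the published single-mutant score range reaches
  1.08 against a ceiling of ≈1.15, so mildly strengthening mutants are
  common, which is also what renders the model's ceiling identifiable.
  The detrimental location 6 RT puts dead variants on the floor with
  essentially no mass near the classification threshold.
* **True parameters** — ThermoParams(1.30, 1.25, 0.700), a point on the
  reference grid with floor ≈ 0.41 and ceiling ≈ 1.15.
* **Structural couplings** — optional: chosen position pairs add a fixed
  ddG (default −1.5 RT) to every mutant pair at those positions; zero by
  default so energies are exactly additive.
* **Growth** — a variant with score p undergoes `d = p·g` doublings over
  `g = 10` wild-type doublings (two competition cycles from OD 0.05 to
  1.6). Per-replicate additive offsets on `d` emulate background-growth
  batch effects for testing the mode correction. The realized population
  doublings `log2(Σ f_i 2^{d_i})` are recorded per replicate and are the
  `g_r` the scoring formula needs — with them, infinite-depth scoring
  reproduces the true scores to machine precision.
* **Sequencing** — input counts are multinomial at the NNS design
  frequencies (codon unit: singles carry 24× or 17× a double's weight),
  output counts multinomial at the post-growth frequencies; depth is per
  sample and replicate. `sampling=False` yields expected counts (the
  infinite-depth limit). Multinomial only — no overdispersion, no
  sequencing errors, no UMI collisions, no indels: raw-read processing
  is upstream of this pipeline's scope.

What passing simulated tests does *not* show about real data: real
libraries have codon-multiplicity structure, position- and
residue-specific effect correlations, amplification noise beyond
multinomial, and model misspecification (e.g. competing homodimer
equilibria), none of which the generator produces.

## Validation scenario sizes

Chosen to exercise the full pipeline at meaningful statistical power:
parameter recovery uses 608 + 608 singles and 1e5 doubles at depth 1e7
(≈ 80 input reads per double, 2,000 per single) with a 30,000-double
fitting subsample; null calibration uses 20 seeds × 2,000 doubles with
1,000 permutations, with residuals computed against the generating
parameters so the null is exact; enrichment recovery uses 8 positions
per protein (23,104 doubles) at depth 1e7 — about the real experiment's
per-variant coverage, below which three-replicate t-tests leave genuine
structural hits hovering at the FDR threshold; mode correction uses
shifts of 0/0.8/1.6 doublings; matched sub-sampling uses 100
sub-samples.

## Known limitations

* The fitted abundance parameters are exchangeable, and the larger one
  is weakly determined (flat ridge) — report `min(X, Y)` and `K` when a
  physical summary is needed.
* The permutation FDR assumes exchangeability of scores within a
  replicate; strong heteroscedasticity (noisy floor variants) makes it
  conservative for mid-range hits.
* The score's zero-output filter truncates the noise distribution of
  floor variants, biasing their kept scores slightly upward; this is a
  property of the filtering rule, not of the estimator.
* Homodimerization of one partner (a competing equilibrium in many bZIP
  pairs) and any growth/complex nonlinearity are not modelled.
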