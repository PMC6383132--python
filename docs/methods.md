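# Methods

`funcdens` implements a structure-informed analysis of missense-variant
function for voltage-gated cardiac ion channels (NaV1.5/SCN5A,
KV7.1/KCNQ1 and, by configuration, any channel with comparable data).
This note documents the models, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Data model

Each *variant functional measurement* is one published electrophysiology
readout: a gene, a residue substitution, a functional parameter (peak
current, late current, V½ of activation/inactivation, recovery from
inactivation, activation/deactivation time constants), the mutant value,
the wild-type value measured in the same publication, and the expression
system. The reduction to one number per variant and parameter is:

1. **WT normalization.** Ratio-scaled parameters (currents, time
   constants) become `100 × mutant/WT` (percent of WT; WT ≡ 100%).
   Voltage-dependence parameters become `mutant − WT` in mV (WT ≡ 0 mV).
   A WT value of zero in ratio mode is a hard error, not a silent NaN.
2. **Cell-system selection.** For each variant and parameter, only
   reports from the highest-preference expression system present are
   kept (defaults: HEK293 for SCN5A, CHO for KCNQ1). When no preferred
   system was used, all reports are kept — preference applies only "when
   available". The fallback for mixed non-preferred systems (keep all)
   is a documented choice; other policies would need a precedence order
   the data do not supply.
3. **Replicate averaging.** Remaining reports are averaged, unweighted
   (weighting by cell counts or variances is not possible from the
   collected fields). The stage order matters and is enforced:
   `select_cell_system` refuses already-aggregated records.

Heteromeric/heterozygous expression records (an optional
`expression_mode` column) are excluded by default; homomeric expression
is the configuration the functional datasets describe most consistently.

## Structural features

Structures are reduced to one site per residue per chain at the
unweighted mean of the residue's heavy-atom coordinates. Mass weighting
changes residue centers by well under the coordinate uncertainty of the
homology models these features are designed for, and the unweighted mean
is reproducible across formats. A plain-text `xyz_table` format
(position, chain, amino acid, x, y, z) round-trips bit-for-bit and keeps
every test and fixture in text form; PDB and mmCIF are parsed with
gemmi.

Distances are Euclidean between residue centers. For homomultimers the
per-position distance collapses the chain copies; the default
`min_over_chains` takes the minimum over all chain pairs (nearest
spatial adjacency, symmetric in chains). The convention is recorded on
the distance map because the triangle inequality is not guaranteed after
min-collapsing. `first_chain` restricts to one protomer; for monomers
the two conventions coincide (tested).

**Burial descriptors.** NeighborCount is a smooth distance-weighted
count of surrounding residues using a cosine switching function: weight
1 up to 4.0 Å, 0 beyond 11.4 Å, `0.5·(cos(π·(d−4)/(11.4−4))+1)` between.
The 11.4 Å outer cutoff is the standard burial cutoff in structure
scoring; the lower bound and functional form follow the published
switching-function convention of that feature family, and both bounds
are configuration keys. NeighborVector is the norm of the weight-scaled
sum of unit displacement vectors to the neighbors divided by
NeighborCount — 0 for an isotropically surrounded (buried) site, 1 for a
site with all neighbors on one side (surface). `aaneigh` and
`aaneighvector` standardize the raw values per amino-acid type,
`(raw − mean_aa)/sd_aa`, so that a buried leucine is less remarkable
than an equally buried aspartate. The propensity table is computed from
the input structure itself by default (structure-local statistics); a
user-supplied table is accepted for reproducibility. Amino acids with
fewer than two observations or zero spread fall back to the global
mean/sd, with a log note.

## Functional density

The package's central feature. For target residue *j* and functional
parameter *x*:

    ρ_jx = Σ_i Δf_xi · w(d_ij) / Σ_i w(d_ij),   w(d) = 1/(1 + exp(d/s))

with scale *s* = 2 Å by default. Three conventions matter:

- **No cutoff.** Every characterized variant contributes; the weight
  decays smoothly from 0.5 at contact and is ~0.27 at 2 Å.
- **Same-mutation exclusion.** A contributor at the target's own residue
  is included (at d = 0) *only if the substitution differs*; the target's
  identical mutation is never a contributor. In-sample feature tables
  therefore never contain the value they are trying to predict.
- **Missingness is explicit.** An empty contributor set yields NaN with
  a `missing` flag, never a silent 0 (0 is a meaningful density value on
  the mV scale).

The exponent argument of the logistic weight (d/s with s = 2) cannot be
pinned down more finely from the available description of this feature
family; the scale is a configuration key so alternatives can be restored
without code changes. The *weight-only density* is the unnormalized sum
Σ w(d_ij) under the same exclusion rule (the normalized form is
identically 1): a measure of how densely characterized the neighborhood
is, used to control for literature sampling bias.

Contributors are sorted canonically before summation so the result is
bitwise invariant to input order, and normalized weights (`Δf · w/Σw`)
make a lone contributor's value come back exactly.

## Relaxed LASSO models

Predictors (external classifier scores, evolutionary rates, burial
features, densities) are centered and scaled to unit variance
(population sd); constant columns are dropped with a warning. Model
fitting is two-stage ("fully relaxed"): a LASSO path selects the
support, and an unpenalized least-squares refit on that support provides
the reported coefficients, t-tests, R² and adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1).

**Penalty choice.** The penalty is chosen by 10-fold cross-validation of
the *relaxed* fit along the path: within each fold, the path is refit by
OLS on each candidate support and held-out error is accumulated per
penalty. The default rule is the largest penalty within one standard
error of the CV minimum. The exact argmin is available
(`lambda_rule="relaxed_min"`, also `"lasso_min"` for the penalized
path), but the relaxed CV curve is nearly flat around its minimum —
adding a spurious predictor changes expected held-out error by O(1/n) —
so the argmin admits noise features in roughly a quarter of
high-signal-to-noise runs, while the one-standard-error rule recovers
the exact planted support essentially always (measured in the test
suite). Empty support at the chosen penalty yields an intercept-only
result, flagged, never an exception.

**Uncertainty.** Adjusted R² gets a case-resampling percentile bootstrap
(default B = 1000) of the relaxed refit with the selection held fixed
from the full-data fit, matching a pipeline in which the relaxed model
is bootstrapped *after* feature selection. Resamples with fewer than two
distinct rows are redrawn. The interval is conditional on the selected
support; the coverage test accordingly uses a generative design whose
true feature is reliably selected, so it measures the interval rather
than selection error.

**Model acceptance.** A model is accepted iff the support is nonempty,
at least one refit coefficient is significant at 0.05 (t-test on the
relaxed fit — the test is a choice; the rule only asks for "a
significant feature"), and the lower 95% bound on adjusted R² exceeds
0.10.

**Nested CV.** Because the density features are computed *from the
response data*, the ordinary in-sample fit is optimistic. `nested_cv_r2`
runs an outer 10-fold CV in which the density (and weight-only) columns
are rebuilt inside each training fold from the training variants alone;
held-out variants get densities computed against the training set, and
pooled out-of-fold predictions give cv R² = 1 − SS_res/SS_tot. Held-out
rows missing a selected feature are dropped (complete-case, logged).
Rows with any missing predictor are likewise dropped before fitting;
per-model variant counts can therefore differ by parameter.

## Loss-of-function classification

A variant is LOF when aggregated peak current < 50 %WT (strict); for
KCNQ1 a V½-activation shift > +10 mV (strict) also qualifies, and
either rule suffices. Values exactly at a threshold are not LOF.
Variants missing every parameter their gene's rule needs are excluded
with a reason, never defaulted. Feature subsets are compared by fitting
one maximum-likelihood logistic model per subset on the *same*
complete-case variant rows (pairing is required by the DeLong test);
separable fits fall back to a small ridge stabilizer, recorded on the
scorer. AUC is computed as the Mann–Whitney rank statistic (identical
to the trapezoidal ROC area, ties half-credited) with a stratified
case-resampling percentile interval (default B = 2000), and paired
models are contrasted with the two-sided DeLong test built from
per-observation placement values. A zero-variance difference (e.g.
identical score vectors) returns z = 0, p = 1, flagged.

## Synthetic data

The generator produces the full input surface — structure file, raw
measurement table, predictor columns — with recorded ground truth, so
every stage is testable without downloads. It emulates: spatially
clustered perturbation ("hotspot") fields on residues; bimodal/skewed
percent-of-WT response distributions; publication-specific WT values
(lognormal) with replicate reports needing normalization and averaging;
mixed expression systems; and predictor columns correlated with the true
effect at configurable strengths plus pure-noise decoys.

Reference conditions (the defaults): a 120-residue self-avoiding coil
confined to a sphere of typical protein density (~134 Å³/residue; bond
length 3.8 Å, excluded volume 3.5 Å) so a contact shell appears at
realistic distances; one hotspot of radius 12 Å in which mean peak
current collapses to 10 %WT against a 100 %WT background
(residue-to-residue sd 5); 150 distinct variants with per-report noise
of 20 %WT; ~1.3 reports per variant; predictor–effect correlations of
−0.5 to +0.45 for four "published score" columns and 0 for two decoys.
Effects live on residues, not variants, so substitutions at one residue
share a spatial effect — the geometry the density feature assumes.
Percent-scale fields and reports are clipped at 0 (currents cannot be
negative). The forced complete-LOF mixture (`bimodal_mixture_weight`)
defaults to 0: under the default hotspot contrast the 0%/100%
bimodality already arises from the spatial field itself, which is the
phenomenon of interest; the mixture models spatially *unstructured* LOF
(e.g. trafficking defects) and is exercised in tests at weight 0.3.

What the generator does **not** emulate: real channel gating physics,
curation bias beyond the mixture component, inter-lab protocol
differences other than WT scale, sequence-derived correlations among the
predictor columns, or imperfect homology-model coordinates. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated geometry and noise model — not that the
features carry this much signal in real channels.

## Test and simulation sizes

The suite's simulation scales are package choices balancing statistical
resolution against runtime: support recovery and interval coverage use
100 seeded replications; nested-CV honesty and the null control use 20
seeds; DeLong calibration uses 2000 paired-null simulations at n = 300.
The nested-CV honesty check runs at 60 variants with 30 %WT noise: with
the dense default bundle the in-sample/out-of-sample gap is smaller than
seed noise, while the sparser design expresses the leakage the check is
about. The acceptance script reports the same quantities at one seed
(n = 150 bundle; 50 recovery runs; 1000 DeLong simulations).

## Known limitations

- Distances use residue centers of mass, not atom-level contacts; the
  multimer min-over-chains collapse discards which protomer pair is
  nearest.
- The bootstrap interval is conditional on the selected support and
  inherits selection instability near the acceptance boundary.
- In-sample classification AUCs (the default mode) are optimistic;
  a cross-validated scoring mode is available but not the default.
- The logistic-weight scale and the burial switching bounds are fixed
  conventions exposed as configuration, not fitted quantities.
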