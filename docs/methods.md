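# Methods

## The estimation problem

Hourly ventilator records give, per admission, a trajectory of settings
(tidal volume Vt, respiratory rate RR, PEEP, peak pressure Ppeak) from
which mechanical power is computed as

    MP (J/min) = 0.098 · Vt[L] · RR · (PEEP + P_insp),   P_insp = Ppeak − PEEP.

Because PEEP + (Ppeak − PEEP) = Ppeak, MP algebraically reduces to
0.098·Vt·RR·Ppeak; the implementation evaluates it through Ppeak to avoid
double-entry inconsistencies, keeping PEEP for the driving-pressure
covariate (Ppeak − PEEP, plateau pressure being unavailable in this data
model). Input files carry Vt in mL and are converted to litres at read
time.

The admission-level outcome is VFD28, ventilator-free days at day 28:
death on or before day 28 scores 0, survivors score
max(0, 28 − ⌈duration/24⌉). This exact convention (death ⇒ 0, ceiling of
ventilated days, single continuous ventilation episode) is the standard
composite; reintubation episodes are out of scope. The hourly intermediary
outcome is the P/F ratio, PaO₂/FiO₂ with FiO₂ as a fraction; FiO₂ values
in (1, 100] are interpreted as percent and divided by 100 (the two
dialects coexist in real exports), and values below 0.21 after
normalisation are rejected. PaO₂/FiO₂ is the primary definition; an
SpO₂-based ratio can be formed from the stored SpO₂ column but is not used
by the models.

The causal questions are: the average effect (ATE) of first-24h median /
maximum / minimum MP on VFD28; conditional effects (CATEs) within
admission-type, diagnosis and P/F strata; and, dynamically, the effect at
each post-intubation hour of exceeding each candidate MP threshold on
next-hour P/F.

## Identification

A directed acyclic graph over the clinical variables encodes the assumed
structure: labs/vitals (WBC, temperature, pH, MAP, PaCO₂ as a dead-space
surrogate) and demographics feed a disease-severity score; severity drives
both the ventilator settings behind MP (clinician policy — the crux of the
confounding) and the oxygenation trajectory, which shapes VFD28. Lung
compliance influences MP but is unmeasured, and a residual frailty node is
unmeasured; both are marked unobserved and can never enter adjustment
sets. The graph ships as an editable plain-text file (`node <name>
observed|unobserved <role>` lines plus `parent -> child` lines,
losslessly round-tripped), since the exact edge list is a clinical
judgement users may wish to revise.

A set Z satisfies the backdoor criterion for (exposure, outcome) iff no
member is a descendant of the exposure and Z d-separates exposure from
outcome in the graph with the exposure's outgoing edges removed.
d-separation delegates to networkx; adjustment-set search is exhaustive
subset enumeration over observed non-descendants with minimality pruning —
exact and fast at the ~20-observed-node scale of clinical DAGs, so no
heuristics are used. Ordering is deterministic (size, then lexicographic).
When no observed set works, a distinct "not identifiable via backdoor"
error is raised rather than returning an empty set, because the empty set
being *valid* (unconfounded exposure) is a different, legitimate answer.

## Estimators

**Backdoor linear regression.** Outcome on treatment plus the adjustment
set, categoricals dummy-coded with the first (alphabetical) level as
reference; solved by least squares on the design matrix and read off as
the treatment coefficient (verified against an explicit normal-equations
solve to 1e-8). CIs are nonparametric percentile bootstrap over
admissions — admissions, not hours, are always the resampling and
fold unit, respecting within-admission correlation. Default B = 500
(B = 200 in bundled configs to keep demo runs brisk); nominal level 95%.
Rank-deficient designs raise an error naming the collinear columns (QR
with pivoting).

**Double machine learning.** Cross-fitted partialling-out with K = 5
folds: nuisance regressions E[Y|Z] and E[T|Z] are fit on K−1 folds and
predicted on the held-out fold; θ = Σ řT·řY / Σ řT² over out-of-fold
residuals. The orthogonality of this moment to nuisance error is what
lets flexible learners absorb nonlinear confounding without biasing θ.
Learner families: `forest` uses depth-controlled random forests
(100 trees, min leaf 10) — a pragmatic causal-forest-style configuration;
full generalized-random-forest splitting theory is deliberately not
implemented and `dml_forest` should be read as "DML with forest
nuisances". `generic` defaults to linear regression and accepts any
scikit-learn regressor factory. The primary CI is the influence-function
variance of the partialling-out moment; a residual-pair bootstrap
(resampling out-of-fold residuals without refitting nuisances — the fast
variant) is reported alongside in `extras`. A treatment residual variance
of ~0 raises a no-overlap error; a constant outcome yields θ = 0 exactly.

Continuous effects are per 1 J/min. `binary_effect_at_threshold` recodes
treatment as 1{MP > θ} and records the coding in the estimate. Subgroup
CATEs rerun the configured estimator within each group with the same seed;
groups below the minimum cell size (default 50) are reported as suppressed
rather than estimated.

## Dynamic grid and trajectories

For each (hour h, threshold θ) cell: treatment = 1{MP at h > θ}, outcome =
P/F at h+1 (lead configurable), adjustment = admission covariates plus the
previous hour's observed state (labs, vitals, prior P/F; hour −1 clamps
to 0). Admissions are restricted to those intubated past the grid horizon
so every cell sees the same population. Cells are independent OLS fits
with classical analytic SEs — per-cell bootstrap across ~1700 cells would
buy little and cost much — and cells with either arm below the minimum
(default 50) are masked with an explicit sentinel, never silent zeros.
Exports (long CSV + dense matrix) round-trip losslessly. Cell estimates
are identical whether computed alone or within a full grid.

The optimal-threshold path takes, per hour, the unmasked threshold
minimising the estimated cell effect, ties broken toward the lowest MP
(least-energy principle); fully masked hours are undefined (NaN), not
errors. Note the argmin convention follows the surface's sign semantics:
on a surface where more-positive values mean better oxygenation one would
maximise instead — the grid exports raw numbers precisely so that the
direction is the caller's explicit choice, and the trajectory optimality
invariant is stated for the lower-is-better convention.

The trajectory simulator starts at a configured initial MP (snapped to the
threshold axis, logged if moved), follows the path, and at each subsequent
hour replaces the setting, with probability `noise_level`, by a uniform
draw from `perturbation_range` (default 5–40 J/min, snapped to the axis).
Noise is i.i.d. per hour; autocorrelated event models are out of scope.
The trajectory never feeds back into re-estimating the surface. Undefined
path hours carry the previous ideal value forward with a warning.

## The synthetic generator

Structural equations follow the DAG above, linear-Gaussian by default.
Key design choice: the observed APACHE II score carries the severity
signal that reaches the ventilator settings, so
{apache_ii, age_band, admission_type, diagnosis_group} is a sufficient
adjustment set *by construction*, and effect-recovery tests are exact
rather than approximate; an additional latent severity term perturbs
outcomes and labs but never the settings (hence is not a confounder).
Marginals are calibrated to a typical mixed ICU: medical fraction 0.42,
hourly MP ≈ 18 (8) J/min overall with the medical arm higher, APACHE II
≈ 23 (8) medical / 17 (6) surgical, age-band frequencies peaking at 60–79.
Exact marginal matching is not a contract.

The VFD28 outcome is generated through its components, not directly: a
latent target v = baseline(severity, diagnosis, age) + effect·MP_median +
noise is mapped to intubation duration 24·(28 − v) and to death when
v < 1, and VFD28 is then *computed* by the mechanics module from
duration/death — exercising the composite logic end to end. The duration
floor equals the MP aggregation window (default 24 h) so the settings that
drove the outcome are always on record; without it, short stays create an
errors-in-variables attenuation of the recovered effect. The default true
ATE is −0.15 days per J/min; a cohort-label → effect map generates
heterogeneous effects, and a step mode (effect = a fixed day cost above
the true threshold) exercises the binary-threshold estimator.

The hourly P/F effect is a hinge: `true_pf_effect`·max(0, MP_{t−1} − θ*)
with θ* = 17 J/min and −1.5 P/F units per excess J/min by default, on an
AR(1) oxygenation process (φ = 0.6) around a severity-dependent baseline —
giving the grid a recoverable change point. The nonlinear-confounding mode
adds a smooth quadratic severity term to both the policy and the outcome
baseline, which linear adjustment cannot absorb but forest nuisances can;
this is the regime in which DML demonstrably beats the linear backdoor.

One global integer seed drives everything through fixed-order child
streams of a numpy SeedSequence. What the generator does *not* emulate:
realistic physiologic waveforms, treatment feedback (settings responding
to the evolving P/F within an admission), drugs/fluids, reintubation, and
informative missingness (the missingness injector is independent
Bernoulli per ventilator field). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated structural
assumptions, not robustness to every failure mode of real ICU data.

## Numerical and procedural choices

- Mortality in the generator is tied to the latent outcome tail (v < 1),
  keeping the death→VFD28=0 rule from distorting the linear effect; the
  resulting mortality is low (~1–2%), a realism trade documented here.
- Inclusion cascade: adult filter (only when a raw age column exists; the
  age-band vocabulary already implies adulthood), then ≥2 complete-MP
  hours per admission, then removal of spontaneous-mode hours with
  re-application of the completeness bar. Step counts are non-increasing
  and logged.
- Descriptive-table tests are two-sample Welch t (normal-style variables),
  Mann–Whitney U (skewed, e.g. intubation duration), Kruskal–Wallis for
  >2 groups, chi-square for categoricals; groups below n = 2 report "NA"
  with the reason. P-values are descriptive; no multiplicity correction.
- The pipeline's default adjustment set is {APACHE II, age band, diagnosis
  group} without admission type: the diagnosis vocabulary is nested within
  admission type (only "other" spans both arms), so including both makes
  subgroup designs exactly collinear whenever a subgroup lacks an "other"
  admission in one arm, and given the other three covariates admission
  type closes no additional backdoor path to VFD28. Callers adjusting a
  P/F outcome should include admission type (it shifts the oxygenation
  baseline directly), as the grid's default adjustment does.
- Pipeline outputs contain no timestamps, so identical config + seed gives
  byte-identical report bodies.
- Test problem sizes (recovery at n = 5000 over 200 replicates with
  B = 200; the nonlinear contrast at n = 2000 over 100 pairs with 60-tree
  forests; the grid at n = 2000) are the package's chosen desk-scale study
  conditions: large enough that Monte-Carlo error is far below the stated
  tolerances, small enough to iterate on.

## Known limitations

- Identification is backdoor-only; no front-door or instrumental-variable
  routes, no structure learning.
- The per-hour grid approximates time-varying treatment with independent
  cross-sectional models; formal g-methods for sustained strategies are
  out of scope, as is smoothing or change-point inference on the surface.
- The forest-based DML is not a full generalized random forest; CATE
  surfaces beyond subgroup conditioning are not provided.
- Exhaustive backdoor enumeration is exponential in observed nodes and
  intended for graphs up to roughly 20 observed variables.
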