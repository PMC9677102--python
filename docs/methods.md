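# Methods

## Model

The weight-status process is a continuous-time, time-homogeneous Markov
chain on three states (1 normal weight, 2 overweight, 3 obese) with
adjacent-only instantaneous transitions: the intensity matrix Q is
tridiagonal, with four free rates q₁₂, q₂₁, q₂₃, q₃₂ (per year) and
diagonal entries equal to the negative row sums. The analysis time scale is
time since each child's first examination, which makes time-homogeneity a
statement about follow-up time rather than calendar age; over a five-to-six
year window in mid-childhood this is the standard working assumption for
this model class.

States are observed only at examination times (interval censoring). The
likelihood is the product over consecutive observation pairs of
P_{s_prev,s_next}(Δt; z) with P(t) = exp(tQ). Observed non-adjacent pairs
(normal at one wave, obese at the next) are perfectly legal data: the
latent path passes through overweight between the examinations, and
P₁₃(Δt) = O(Δt²) > 0 for any Δt > 0.

Covariates enter proportionally per transition, q_rs(z) = q_rs·exp(β_rs z),
evaluated piecewise-constant at the value held at the start of each
interval. One covariate at a time is the intended use (the four β's for the
four transitions are estimated jointly with the intensities); a covariate
matrix is accepted but is beyond the intended design, because strongly
collinear covariates (weight increments, initial BMI, rebound timing) make
joint fits hard to interpret.

## Estimation

Intensities are parameterized as log q, which enforces positivity and
removes the masked cells from the parameter vector entirely. The negative
log-likelihood is minimized with L-BFGS-B using numerically differentiated
gradients; the relative function-tolerance is 1e-8 and starting values are
deterministic crude rates (observed r→s pairs divided by observed time at
risk in r, floored at 1e-3), so a fit is reproducible bit-for-bit from the
data alone. Standard errors come from the inverse of the numerically
differentiated observed information at the optimum
(`statsmodels.tools.numdiff.approx_hess`); the covariance is symmetrized
and pseudo-inverted if the information is singular (boundary fits).
Transitions with zero observed events are reported as boundary estimates
with a warning rather than an error.

The likelihood is evaluated on sufficient statistics: intervals are grouped
by (Δt, covariate value) and each group contributes its 3×3 pair-count
matrix against one matrix exponential. With annual waves and a binary
covariate this costs one or two `expm` calls per likelihood evaluation;
continuous covariates fall back to one `expm` per distinct value, which is
correct but slower. Δt values are rounded to 1e-9 years when grouping to
collapse floating-point noise; this perturbs the likelihood by far less
than the optimizer tolerance.

Model comparison uses the likelihood-ratio test (χ² with df = parameter
difference) and ΔAIC; hazard ratios are exp(β) with Wald 95% CIs (z =
1.96 throughout the package).

## Derived quantities

* Mean sojourn time: −1/q_rr, with delta-method CIs on the log-exit-rate
  scale (the exit rate is a sum of exponentials of the log-intensities, so
  its log-variance follows from the fitted covariance by the chain rule).
* Total length of stay over [0, T]: ∫₀ᵀ P(u) du computed exactly as the
  upper-right block of exp(T·[[Q, I], [0, 0]]); there is no tolerance knob
  to tune, and time conservation (entries summing to T) holds to
  floating-point accuracy. Adaptive quadrature is retained in the test
  suite as an independent oracle, never as the implementation. The
  published length-of-stay column is read as time spent in each state for a
  child starting in normal weight, the reading under which the entries sum
  to the horizon.
* Prevalence projection: π₀ᵀP(t). The validation rule accepts a projection
  if it falls inside the observed 95% CI or differs from the observed value
  by less than 1% of the *predicted* value (relative, exactly as the rule
  is stated).
* CIs for probabilities and lengths of stay use a parametric bootstrap from
  the asymptotic distribution of the fitted log-intensities (default 1,000
  draws); sojourn CIs use the delta method. Both conventions are common for
  this model class and differ only in CI width, not point estimates.

## Classification and cutoff tables

BMI = weight / (height/100)². Cutoff tables map (sex, exam age) to an
overweight threshold c_ow and obesity threshold c_ob over half-open age
brackets that must tile the supported range; classification is inclusive
upward (BMI equal to a threshold takes the heavier class), matching common
growth-reference practice. Official WHO / China Obesity Task Force values
are deliberately **not** hardcoded: they are external standards the user
supplies as config, and baking in guessed numbers would masquerade as
ground truth. Two synthetic fixture tables with plausible shapes ship for
tests and simulation. Mixing standards at an age boundary (e.g. one
reference below age 7, another from 7 up) needs no special support: a
table's brackets may come from different sources, at the cost of a
potential artificial discontinuity the user should be aware of.
Classification uses age at examination, not school grade.

## Adiposity rebound

Each child's BMI-age curve is fit as a quadratic — the minimal family with
an interior minimum — via a linear mixed-effects model with random
intercept, slope and curvature per child (REML, age centred for
conditioning); per-child curves are fixed effects plus BLUPs. If the mixed
fit fails (singular random-effects structure, non-convergence) the fit
falls back to independent per-child least squares and records which path
produced each curve. The rebound age is the vertex −b₁/(2b₂) when b₂ > 0
and the vertex lies in the modeled age window (default 3–20 y); concave or
monotone curves have no BMI nadir and their rebound age is absent, which
counts as "not late". Late rebound means a nadir at or after 7 years.
Because a school-age panel typically starts near 6.8 y, most estimated
nadirs lie before the first observation; they are extrapolations of the
fitted curve and are flagged as such while still being classified, since
that is how the rule is applied in practice.

## Synthetic-cohort generator

The generator emulates the structure of the motivating study design:
2,334 children, six annual waves, first examination at age 6.8 ± 0.15 y,
49.7% girls, 78.9% urban schools, baseline state distribution
(0.711, 0.181, 0.108), and the bundled reference intensity matrix as the
generating truth — so the simulator's summaries are directly comparable to
the reference tables. Latent paths are simulated exactly (Gillespie:
exponential holding times, adjacent jumps) and observed at wave times;
optional spacing jitter (±0.1 y) exercises unequal intervals.

BMI is generated state-consistently: the latent state is drawn first and
the BMI is placed inside that state's cutoff band while tracking a smooth
child-level quadratic curve with a nadir at N(6.7, 1.0) years (a window
consistent with rebound occurring between roughly 4 and 8 years, and
implying a late-rebound share near 38%). This guarantees that
re-classifying the generated anthropometry with the same table reproduces
the generated states exactly, which is what makes end-to-end pipeline tests
sharp; the price is that BMI noise never crosses a cutoff, so the generator
understates real-world classification churn near thresholds. Heights grow
linearly per child (5.7 ± 0.6 cm/y from 116.5 ± 4.8 cm at age 6) with
0.1 cm measurement rounding; weights are backed out from BMI and height and
rounded to 0.01 kg. Band edges sit 0.01 kg/m² clear of the cutoffs so that
measurement rounding cannot flip a state.

What passing tests on this generator do show: the estimator recovers known
intensities at nominal CI coverage from panel data of the study's shape and
size; the classification, rebound and summary stages compose correctly.
What they do not show: robustness to secular BMI trends, pubertal growth
spurts, dropout/attrition, or misclassification near real cutoffs — none of
which the generator emulates.

## Test and verification scales

The acceptance suite runs the parameter-recovery coverage check at 100
replicates of 250 children × 6 waves and the likelihood-ratio calibration
at 100 replicates of 120 children — scales chosen to keep the full suite
fast while leaving the binomial acceptance bands (99% regions around 0.95
coverage and 0.05 rejection) meaningful. Power against a 1.6× hazard ratio
is checked at the full 2,334-child scale. Desk-scale checks (published
probabilities, sojourns, lengths of stay re-derived from the reference
intensity matrices) use tolerances of 0.5 percentage points at one year,
0.7 at five years and 0.02 y for time quantities, which is the rounding
propagation of third-decimal intensities; the normal-weight sojourn exceeds
11 years, so its tolerance is 0.15 y for the same reason.

## Known limitations

* Time-homogeneity is assumed on the follow-up time scale; piecewise or
  age-varying intensities are out of scope.
* No misclassification/hidden-Markov layer: observed states are taken as
  true states.
* The mixed-effects rebound fit estimates a full 3×3 random-effects
  covariance; with few waves per child it can sit at a boundary, in which
  case the OLS fallback (no shrinkage) is used.
* The baseline boys' state distribution, given as rounded proportions
  summing to 0.999, is renormalized to a probability vector.
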