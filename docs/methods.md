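# Methods

## The problem and the model

Antenatal care (ANC) received during pregnancy is widely believed to move
women toward delivering in a health facility rather than at home. The
difficulty in estimating that effect from survey microdata is that the same
unobservables (health motivation, access, household bargaining power) drive
both ANC uptake and the delivery decision, so a single-equation model
conflates the causal effect with selection.

This package separates ANC into two binary dimensions and estimates each
one's effect on institutional delivery twice:

- **D1, the visits dimension** (independent of the health system):
  D1 = 1 if the woman made three or more ANC visits.
- **D2, the care-intensity dimension** (dependent on the health system):
  women are scored on the first principal component of eight binary service
  items (tetanus vaccination; weight, height and blood-pressure measurement;
  urine and blood samples; breastfeeding counselling; information about
  danger signs), the score is cut into L equal-probability levels, and
  D2 = 1 for the highest level.

The **naive model** is a probit,

    Y_i = 1{ D_i * delta + x_i' beta + eps_i > 0 },   eps_i ~ N(0, 1),

with Y = 1 for institutional delivery and x_i the socio-demographic
controls. The **corrected model** is a recursive bivariate probit,

    Y_i = 1{ delta * E_i + x_i' beta1  + eps_i  > 0 }
    E_i = 1{ gamma * Z_i + x_i' beta1' + eps'_i > 0 },
    (eps, eps') ~ BVN(0, 0, 1, 1, rho),

where E is the endogenous ANC dimension and Z — whether the first ANC visit
happened in the first trimester — is the instrument: it enters the exposure
equation only. A standard result for the endogenous-dummy model is that the
likelihood needs no Jacobian correction for the recursion; each observation
contributes log Phi2(q_Y w_Y, q_E w_E, q_Y q_E rho) with q = 2*indicator - 1.
rho is the correlation of the unobservables; the Wald test of exogeneity is
the squared z-statistic of atanh(rho-hat). rho < 0 (motivated-but-remote
women get ANC yet deliver at home, or facility access raises ANC but not
delivery) makes the naive probit *understate* delta; rho > 0 overstates it.

Effects are reported as **counterfactual average predicted probabilities**
(average structural function): p(d) = mean_i Phi(x_i' beta-hat + d *
delta-hat), the population-mean probability if everyone were set to
exposure level d. Observed-subgroup means are also emitted for
transparency; they mix the structural effect with selection and are not
comparable across the two estimators.

## The synthetic-data generator

Real DHS microdata are registered-access, so the package ships a generator
that draws from exactly the structural model above, with every parameter
known. What it emulates and the defaults:

| parameter | default | meaning |
|---|---|---|
| `n` | 5,000 | women (one most-recent live birth each) |
| `delta` | 1.0 | exposure effect on the outcome latent index |
| `rho` | -0.4 | error correlation (the canonical confounded scenario; the negative sign reproduces a naive estimate biased toward zero) |
| `gamma_iv` | 1.0 | instrument strength (a weak preset, 0.1, exists for diagnostics) |
| `first_trimester_rate` | 0.40 | P(Z = 1), independent of both errors — the exclusion restriction holds by construction |
| `beta_outcome`, `beta_treatment` | non-zero on residence, mother's education, wealth quintile | modest, plausible covariate effects; all other covariates have zero structural effect |
| `item_loadings` / `item_intercepts` | 1.0 each / (0.5 … -1.0) | one-factor normal-ogive item model, item_j ~ Bernoulli(Phi(a_j + b_j U)) with U the exposure-equation latent index |
| visit counts | truncated Poisson(4) on {3..12} if E=1, truncated Poisson(1) on {0..2} if E=0 | the >=3 indicator equals E for every row |

Covariate categories and frequencies mimic a South/South-East Asian survey
population (14 categorical covariates: residence, parental education,
mother's age group, working status, birth order, children ever born,
health-care decision involvement, wealth quintile, three media-exposure
indicators, religion, caste). Covariates are mutually independent by
default; a wealth-to-education dependence hook exists but is off. A single
root seed feeds separate sub-streams for covariates, structural draws and
service items, so adding a covariate never perturbs the error draws.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: DHS multistage cluster sampling and weights,
item missingness, measurement error in recalled visit counts, covariate
dependence structures, country heterogeneity, and any violation of the
exclusion restriction (in real data, first-trimester timing may well affect
delivery choice directly; here it cannot). Recovery results certify the
estimator, not the instrument's real-world validity.

## Dimension construction

- PCA is covariance-based on the raw 0/1 items — the same convention as the
  DHS wealth index — not tetrachoric. The first component is oriented so
  its loading sum is positive, making "all services received" the
  highest-scoring pattern; scores are centered.
- Levels are equal-probability quantile cuts (tertiles for L=3, default;
  median split for L=2). A tied score block straddling a cut goes wholly to
  the lower level, so level sizes can differ by the tie-block size — with
  only 8 binary items the score is discrete and tie blocks are real. The
  level rule is recorded in the report metadata.
- Cronbach's alpha uses the standard variance decomposition,
  alpha = k/(k-1) * (1 - sum var(item) / var(total score)). Under the
  default one-factor generator alpha is about 0.82, inside the 0.56–0.87
  range typical of this item set in the surveys the package emulates.

## Estimation and numerics

- **Probit**: BFGS from a zero start with the analytic score; log Phi via
  `scipy.special.log_ndtr` so tails do not underflow; standard errors from
  the inverse observed information (analytic Hessian); gradient tolerance
  1e-8, 200 iterations max. Perfect separation is detected and raised, not
  silently fitted.
- **Bivariate normal CDF**: Owen's-T relation (Owen 1956) through
  `scipy.special.owens_t`, with closed forms on the axes and at |rho| = 1;
  accurate to ~1e-14, validated in the test suite against brute-force 2-D
  Gauss–Legendre quadrature and adaptive dblquad.
- **Biprobit**: parameters (delta, beta1, gamma, beta1', atanh rho);
  atanh rho makes the correlation unconstrained and carries the Wald test
  (the conventional implementation of the rho = 0 test); |atanh rho| is
  bounded at 12 and boundary solutions are flagged non-identified. Start
  values are the two independent probit fits with atanh rho = 0 — at rho=0
  the joint likelihood factorizes into exactly those two probits (asserted
  to 1e-10). Optimization is L-BFGS-B with the analytic score; the observed
  information is a central finite-difference Jacobian of that score; the SE
  of rho is delta-method, (1 - rho^2) * SE(atanh rho). A treatment-equation
  instrument z-statistic below 2 attaches a weak-instrument warning.
- **Degenerate inputs**: one-class outcomes, constant instruments, constant
  care scores, all-identical item rows, zero total score variance and
  rank-deficient designs all raise typed errors naming the problem.

## Simulation study

`simulation_study` runs the generate-fit loop over a (rho, gamma_iv, n)
grid and reports per cell the mean/SD and bias of the naive and corrected
delta estimates, the Wald rejection rate, and 95%-interval coverage for
delta. Problem sizes used by the shipped checks, chosen to give clean
signal at desk scale: type-I calibration with 200 replicates at n = 2,000
(rejection rate ~0.05); label power with 50 replicates at n = 20,000
(~100% "rho<0" at rho = -0.4); the bias sweep with 30 replicates at
n = 4,000 per rho in {-0.4, 0, 0.4} (naive bias ~ -0.57 / 0.00 / +0.66,
monotone); coverage with 100 replicates at n = 5,000 (~0.92–0.95); and one
n = 50,000 recovery run (delta-hat within ~2% of 1.0, rho-hat within ~0.03
of -0.4).

## Known limitations

- The care score is a covariance PCA of binary items; loadings are
  attenuation-biased relative to a tetrachoric analysis, which is
  irrelevant for the quantile-cut D2 but matters if the raw score is
  reused.
- Estimation is unweighted; survey design effects are out of scope.
- A single binary instrument is assumed; the design builder technically
  accepts more columns but no over-identification test is provided.
- With a weak instrument the biprobit likelihood is nearly flat in
  atanh rho; fits are flagged rather than repaired.
- Counterfactual probabilities from the biprobit marginalize the
  unobservable, i.e. they answer a population-intervention question, not a
  conditional-on-history one.
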