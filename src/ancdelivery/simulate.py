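"""Synthetic DHS-like microdata generator with known ground truth.

The generator mirrors the structural model the downstream estimators assume:
a recursive bivariate probit in which a binary exposure E (making three or
more antenatal-care visits) enters the latent index of a binary outcome O
(institutional delivery), the two latent errors are standard bivariate
normal with correlation ``rho``, and a first-trimester-first-visit indicator
Z acts as an instrument — it shifts the exposure index but is drawn
independently of both errors, so the exclusion restriction holds by
construction.  Eight binary ANC service items (tetanus vaccination plus
seven check-up procedures) follow a one-factor normal-ogive model driven by
the exposure-equation latent index, which gives the PCA care-intensity
score and Cronbach's alpha a known structure.

Every draw is reproducible from a single root seed; independent sub-streams
feed covariates, structural errors, visit counts and service items, so
changing one block never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .design import build_design_matrix, dummy_name
from .exceptions import ConfigurationError

ITEM_COLUMNS = (
    "tetanus",
    "weight",
    "height",
    "blood_pressure",
    "urine",
    "blood",
    "breastfeeding_counsel",
    "complication_signs",
)

#: Covariates whose default structural effects are non-zero; the default
#: model specification downstream conditions on exactly these.
DEFAULT_MODEL_COVARIATES = ("residence", "mother_education", "wealth_quintile")


def default_covariate_spec() -> dict[str, dict[str, float]]:
    """Category labels and population frequencies for each covariate.

    First label in each mapping is the reference category.  Frequencies are
    plausible for the rural South/South-East Asian survey populations the
    generator emulates; they are a fixed part of the simulated study design.
    """
    return {
        "residence": {"rural": 0.70, "urban": 0.30},
        "mother_education": {"none": 0.35, "primary": 0.20, "secondary": 0.30, "higher": 0.15},
        "husband_education": {"none": 0.25, "primary": 0.20, "secondary": 0.35, "higher": 0.20},
        "mother_age_group": {"<18": 0.05, "19-24": 0.40, "25-29": 0.30, "30+": 0.25},
        "working_status": {"unemployed": 0.60, "employed": 0.40},
        "birth_order": {"1": 0.30, "2-3": 0.40, "4-5": 0.20, "6+": 0.10},
        "ceb": {"1": 0.25, "2-3": 0.45, "4-5": 0.20, "6+": 0.10},
        "health_decision": {"not_involved": 0.45, "involved": 0.55},
        "wealth_quintile": {"poorest": 0.20, "poorer": 0.20, "middle": 0.20,
                            "richer": 0.20, "richest": 0.20},
        "newspaper": {"no": 0.60, "yes": 0.40},
        "radio": {"no": 0.50, "yes": 0.50},
        "television": {"no": 0.40, "yes": 0.60},
        "religion": {"hindu": 0.50, "muslim": 0.30, "other": 0.20},
        "caste": {"general": 0.30, "sc": 0.20, "st": 0.10, "obc": 0.40},
    }


def _default_beta_outcome() -> dict[str, float]:
    return {
        "intercept": -1.0,
        dummy_name("residence", "urban"): 0.30,
        dummy_name("mother_education", "primary"): 0.15,
        dummy_name("mother_education", "secondary"): 0.30,
        dummy_name("mother_education", "higher"): 0.50,
        dummy_name("wealth_quintile", "poorer"): 0.10,
        dummy_name("wealth_quintile", "middle"): 0.20,
        dummy_name("wealth_quintile", "richer"): 0.30,
        dummy_name("wealth_quintile", "richest"): 0.45,
    }


def _default_beta_treatment() -> dict[str, float]:
    return {
        "intercept": -0.40,
        dummy_name("residence", "urban"): 0.25,
        dummy_name("mother_education", "primary"): 0.20,
        dummy_name("mother_education", "secondary"): 0.40,
        dummy_name("mother_education", "higher"): 0.60,
        dummy_name("wealth_quintile", "poorer"): 0.10,
        dummy_name("wealth_quintile", "middle"): 0.20,
        dummy_name("wealth_quintile", "richer"): 0.35,
        dummy_name("wealth_quintile", "richest"): 0.50,
    }


@dataclass
class VisitRateParams:
    """Visit-count laws conditional on the exposure bit.

    Exposed rows (E=1) draw from a Poisson(``mean_high``) truncated to
    ``range_high`` = {3..12}; unexposed rows from Poisson(``mean_low``)
    truncated to ``range_low`` = {0..2}.  Only the >=3 dichotomy matters
    downstream, so the >=3 indicator equals E for every row.
    """

    mean_high: float = 4.0
    range_high: tuple[int, int] = (3, 12)
    mean_low: float = 1.0
    range_low: tuple[int, int] = (0, 2)

    def validate(self) -> None:
        if self.range_high[0] < 3:
            raise ConfigurationError("high visit range must start at >= 3 visits")
        if self.range_low[1] > 2:
            raise ConfigurationError("low visit range must end at <= 2 visits")
        if self.mean_high <= 0 or self.mean_low < 0:
            raise ConfigurationError("visit-rate means must be positive")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the simulated study population.

    Defaults encode the canonical endogeneity scenario: a unit exposure
    effect ``delta`` on the outcome latent index, error correlation
    ``rho`` = -0.4 (unobservables that raise ANC uptake lower facility
    delivery, the pattern the corrected estimator must undo), and a strong
    instrument ``gamma_iv`` = 1.0; a weak-instrument diagnostic preset is
    available via :func:`weak_instrument_config`.
    """

    n: int = 5_000
    rho: float = -0.4
    delta: float = 1.0
    gamma_iv: float = 1.0
    first_trimester_rate: float = 0.40
    beta_outcome: dict[str, float] = field(default_factory=_default_beta_outcome)
    beta_treatment: dict[str, float] = field(default_factory=_default_beta_treatment)
    item_loadings: tuple[float, ...] = (1.0,) * 8
    item_intercepts: tuple[float, ...] = (0.5, -0.2, -0.5, 0.3, 0.0, 0.0, -0.8, -1.0)
    item_factor: str = "treatment_latent"  # or "independent"
    covariate_spec: dict[str, dict[str, float]] = field(default_factory=default_covariate_spec)
    visit_rate_params: VisitRateParams = field(default_factory=VisitRateParams)
    wealth_education_dependence: float = 0.0
    seed: int = 12345

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if abs(self.rho) > 1:
            raise ConfigurationError(f"|rho| must be <= 1, got {self.rho}")
        if len(self.item_loadings) != 8 or len(self.item_intercepts) != 8:
            raise ConfigurationError("exactly 8 item loadings and 8 intercepts required")
        if not 0.0 <= self.first_trimester_rate <= 1.0:
            raise ConfigurationError("first_trimester_rate must lie in [0, 1]")
        if self.item_factor not in ("treatment_latent", "independent"):
            raise ConfigurationError(f"unknown item_factor {self.item_factor!r}")
        if not 0.0 <= self.wealth_education_dependence <= 1.0:
            raise ConfigurationError("wealth_education_dependence must lie in [0, 1]")
        for cov, freqs in self.covariate_spec.items():
            total = float(sum(freqs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"frequencies for covariate {cov!r} sum to {total}, not 1"
                )
            if any(f < 0 for f in freqs.values()):
                raise ConfigurationError(f"negative frequency in covariate {cov!r}")
        if isinstance(self.visit_rate_params, dict):
            self.visit_rate_params = VisitRateParams(**self.visit_rate_params)
        self.visit_rate_params.validate()

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "item_loadings" in data:
            data["item_loadings"] = tuple(data["item_loadings"])
        if "item_intercepts" in data:
            data["item_intercepts"] = tuple(data["item_intercepts"])
        if "visit_rate_params" in data and isinstance(data["visit_rate_params"], Mapping):
            vr = dict(data["visit_rate_params"])
            for key in ("range_high", "range_low"):
                if key in vr:
                    vr[key] = tuple(vr[key])
            data["visit_rate_params"] = VisitRateParams(**vr)
        return cls(**data)


def weak_instrument_config(**overrides) -> SimulationConfig:
    """Preset with a near-useless instrument (gamma_iv = 0.1) for diagnostics."""
    overrides.setdefault("gamma_iv", 0.1)
    return replace(SimulationConfig(), **overrides)


@dataclass
class GroundTruth:
    """True parameters and latent draws retained for recovery tests."""

    config: SimulationConfig
    eps_outcome: np.ndarray
    eps_treatment: np.ndarray
    xb_outcome: np.ndarray
    xb_treatment: np.ndarray
    latent_treatment: np.ndarray
    treatment: np.ndarray

    def true_average_probability(self, d: int) -> float:
        """Average structural probability of institutional delivery at E = d."""
        return float(ndtr(self.xb_outcome + d * self.config.delta).mean())

    def true_counterfactual_contrast(self) -> float:
        return self.true_average_probability(1) - self.true_average_probability(0)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ("covariates", "structural", "items")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the categorical covariate block.

    Covariates are mutually independent unless the wealth->education
    dependence hook is switched on, in which case women in the top two
    wealth quintiles redraw education from an upshifted distribution with
    probability ``wealth_education_dependence``.
    """
    config.validate()
    n = config.n
    out: dict[str, pd.Categorical] = {}
    for cov, freqs in config.covariate_spec.items():
        labels = list(freqs.keys())
        p = np.asarray(list(freqs.values()), dtype=float)
        p = p / p.sum()  # exact renormalization of float noise
        draws = rng.choice(len(labels), size=n, p=p)
        out[cov] = pd.Categorical.from_codes(draws, categories=labels)
    table = pd.DataFrame(out)

    dep = config.wealth_education_dependence
    if dep > 0 and {"wealth_quintile", "mother_education"} <= set(table.columns):
        labels = list(config.covariate_spec["mother_education"].keys())
        rich = table["wealth_quintile"].isin(["richer", "richest"]).to_numpy()
        redraw = rng.random(n) < dep
        mask = rich & redraw
        if mask.any():
            up = np.array([0.10, 0.15, 0.40, 0.35])[: len(labels)]
            up = up / up.sum()
            new = rng.choice(len(labels), size=int(mask.sum()), p=up)
            codes = table["mother_education"].cat.codes.to_numpy().copy()
            codes[mask] = new
            table["mother_education"] = pd.Categorical.from_codes(codes, categories=labels)
    return table


def _truncated_poisson(rng: np.random.Generator, mean: float, lo: int, hi: int,
                       size: int) -> np.ndarray:
    support = np.arange(lo, hi + 1)
    pmf = stats.poisson.pmf(support, mean)
    if pmf.sum() <= 0:
        raise ConfigurationError("truncated Poisson support has zero mass")
    pmf = pmf / pmf.sum()
    return rng.choice(support, size=size, p=pmf)


def linear_index(config: SimulationConfig, covariates: pd.DataFrame,
                 beta: Mapping[str, float]) -> np.ndarray:
    """X @ beta over the dummy design implied by the covariate spec."""
    design = build_design_matrix(covariates, None, list(config.covariate_spec.keys()))
    vec = np.zeros(design.p)
    unknown = set(beta) - set(design.names)
    if unknown:
        raise ConfigurationError(f"beta names not in design: {sorted(unknown)}")
    for j, name in enumerate(design.names):
        vec[j] = float(beta.get(name, 0.0))
    return design.values @ vec


def generate_exposure_outcome(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw instrument, exposure, outcome and visit counts.

    The latent error pair (eps, eps') is bivariate standard normal with
    correlation rho; the instrument Z is Bernoulli and independent of both
    errors.  Exposure E = 1{gamma_iv*Z + X*beta' + eps' > 0}; outcome
    O = 1{delta*E + X*beta + eps > 0}.  Visit counts are drawn so the >=3
    indicator reproduces E exactly.
    """
    config.validate()
    n = config.n
    xb_outcome = linear_index(config, covariates, config.beta_outcome)
    xb_treatment = linear_index(config, covariates, config.beta_treatment)

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eps_treatment = z1
    eps_outcome = config.rho * z1 + np.sqrt(max(0.0, 1.0 - config.rho**2)) * z2
    first_trimester = (rng.random(n) < config.first_trimester_rate).astype(np.int64)

    latent_treatment = config.gamma_iv * first_trimester + xb_treatment + eps_treatment
    treatment = (latent_treatment > 0).astype(np.int64)
    outcome = (config.delta * treatment + xb_outcome + eps_outcome > 0).astype(np.int64)

    vr = config.visit_rate_params
    visits = np.empty(n, dtype=np.int64)
    high = treatment == 1
    if high.any():
        visits[high] = _truncated_poisson(rng, vr.mean_high, *vr.range_high,
                                          size=int(high.sum()))
    if (~high).any():
        visits[~high] = _truncated_poisson(rng, vr.mean_low, *vr.range_low,
                                           size=int((~high).sum()))

    cols = pd.DataFrame({
        "place_of_delivery": outcome,
        "anc_visits": visits,
        "first_trimester": first_trimester,
    })
    truth = GroundTruth(
        config=config,
        eps_outcome=eps_outcome,
        eps_treatment=eps_treatment,
        xb_outcome=xb_outcome,
        xb_treatment=xb_treatment,
        latent_treatment=latent_treatment,
        treatment=treatment,
    )
    return cols, truth


def generate_service_items(
    config: SimulationConfig,
    treatment_latent: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the 8 binary service items from a one-factor normal-ogive model.

    item_j ~ Bernoulli(Phi(a_j + b_j * U)) with U the exposure-equation
    latent index (default) or an independent standard-normal factor.
    """
    config.validate()
    n = len(treatment_latent)
    if config.item_factor == "independent":
        u = rng.standard_normal(n)
    else:
        u = np.asarray(treatment_latent, dtype=float)
    a = np.asarray(config.item_intercepts)
    b = np.asarray(config.item_loadings)
    probs = ndtr(a[None, :] + u[:, None] * b[None, :])
    draws = (rng.random((n, 8)) < probs).astype(np.int64)
    return pd.DataFrame(draws, columns=list(ITEM_COLUMNS))


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Compose covariates, structural outcomes and service items.

    Returns the microdata table (one row per woman's most recent live
    birth) together with the ground-truth record used by recovery tests.
    """
    config.validate()
    rngs = _substreams(config.seed)
    covariates = generate_covariates(config, rngs["covariates"])
    structural, truth = generate_exposure_outcome(config, covariates, rngs["structural"])
    items = generate_service_items(config, truth.latent_treatment, rngs["items"])
    table = pd.concat([structural, items, covariates], axis=1)
    return table, truth
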