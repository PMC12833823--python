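"""Tabular simulators: survival cohorts, paired raters, feature tables.

These supply the downstream statistics stack with data whose generating
parameters are known, so parameter recovery can be asserted:

* multi-cohort survival tables whose hazard depends log-linearly on the
  mixed tumor-stroma ratio (MTSR, in percentage points) and a binary
  nodal-stage covariate, with independent exponential censoring and
  optional between-cohort heterogeneity of the MTSR effect;
* paired rater measurements with a known additive bias and noise level;
* feature matrices with informative, redundant, and pure-noise columns
  standing in for high-dimensional radiomic descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SurvivalCohortSpec:
    n_subjects: int
    baseline_hazard: float = 0.02  # events per time unit
    beta_mtsr: float = 0.0  # log-hazard per MTSR percentage point
    beta_nstage: float = 0.0  # log-hazard for node-positive disease
    censoring_rate: float = 0.01  # events per time unit; 0 = no censoring
    mtsr_mean: float = 10.0  # %
    mtsr_sd: float = 8.0  # %
    nstage_prevalence: float = 0.3
    heterogeneity_tau2: float = 0.0  # between-cohort variance of beta_mtsr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0 or self.heterogeneity_tau2 < 0:
            raise ValueError("rates and variances must be non-negative")


@dataclass(frozen=True)
class RaterPairSpec:
    n_slides: int
    truth_mean: float = 15.0  # %
    truth_sd: float = 10.0  # %
    rater_bias: float = 0.0  # additive offset of rater 2, %
    rater_noise_sd: float = 2.0  # % per rater
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides < 2:
            raise ValueError("need at least 2 slides")
        if self.rater_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class FeatureTableSpec:
    n_samples: int
    n_informative: int = 5
    n_redundant: int = 5
    n_noise: int = 20
    effect_size: float = 1.0  # standardized mean difference between classes
    redundancy_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("counts must be >= 0")
        if abs(self.redundancy_rho) > 1:
            raise ValueError("|redundancy_rho| must be <= 1")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_survival_cohort(spec: SurvivalCohortSpec) -> pd.DataFrame:
    """One cohort: columns id, time, event, mtsr, nstage.

    Event times are exponential with subject-level hazard
    ``baseline * exp(beta_mtsr * mtsr + beta_nstage * nstage)``; censoring
    is an independent exponential clock. With heterogeneity, the cohort's
    own MTSR effect is ``beta_mtsr + Normal(0, tau2)``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    mtsr = _truncnorm(rng, spec.mtsr_mean, spec.mtsr_sd, 0.0, 100.0, n)
    nstage = (rng.uniform(size=n) < spec.nstage_prevalence).astype(int)
    beta = spec.beta_mtsr
    if spec.heterogeneity_tau2 > 0:
        beta = beta + rng.normal(0.0, np.sqrt(spec.heterogeneity_tau2))
    hazard = spec.baseline_hazard * np.exp(beta * mtsr + spec.beta_nstage * nstage)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "time": np.maximum(time, 1e-9),
            "event": event,
            "mtsr": mtsr,
            "nstage": nstage,
        }
    )


def gen_survival_cohorts(specs: list[SurvivalCohortSpec]) -> list[pd.DataFrame]:
    if not specs:
        raise ValueError("need at least one cohort spec")
    return [gen_survival_cohort(s) for s in specs]


def gen_rater_pairs(spec: RaterPairSpec) -> pd.DataFrame:
    """Paired measurements: columns truth, rater1, rater2 (all %, clipped to [0, 100])."""
    rng = np.random.default_rng(spec.seed)
    truth = _truncnorm(rng, spec.truth_mean, spec.truth_sd, 0.0, 100.0, spec.n_slides)
    r1 = truth + rng.normal(0.0, spec.rater_noise_sd, spec.n_slides) if spec.rater_noise_sd > 0 else truth.copy()
    r2 = truth + spec.rater_bias
    if spec.rater_noise_sd > 0:
        r2 = r2 + rng.normal(0.0, spec.rater_noise_sd, spec.n_slides)
    return pd.DataFrame(
        {"truth": truth, "rater1": np.clip(r1, 0, 100), "rater2": np.clip(r2, 0, 100)}
    )


def gen_feature_table(spec: FeatureTableSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and binary labels.

    Informative columns are shifted by ``effect_size`` standard deviations
    between the two classes; each redundant column is a correlated copy of
    an informative parent (correlation ``redundancy_rho``); noise columns
    are independent of the label.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    y = (np.arange(n) % 2).astype(int)
    y = rng.permutation(y)
    cols: dict[str, np.ndarray] = {}
    informative = []
    for i in range(spec.n_informative):
        x = rng.standard_normal(n) + spec.effect_size * y
        cols[f"info_{i}"] = x
        informative.append(x)
    for i in range(spec.n_redundant):
        if not informative:
            raise ValueError("redundant features need at least one informative parent")
        parent = informative[i % len(informative)]
        rho = spec.redundancy_rho
        noise = rng.standard_normal(n) * parent.std()
        # correlation with the parent is exactly rho; rho = 1 copies it
        cols[f"red_{i}"] = rho * parent + np.sqrt(max(0.0, 1 - rho**2)) * noise
    for i in range(spec.n_noise):
        cols[f"noise_{i}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), y
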