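"""Two-stage meta-analysis of per-cohort log hazard ratios.

Stage one fits a Cox model per cohort; stage two pools the per-cohort
log-HRs (theta_i with standard errors SE_i) by inverse-variance weighting.
Heterogeneity is assessed with Cochran's Q and the I-squared index; the
model-selection gate pools under fixed effects iff I-squared < 25% and the
Q-test p-value exceeds 0.05, and otherwise under DerSimonian-Laird random
effects with the moment estimator of the between-study variance tau-squared.
Small-study (funnel) asymmetry is tested by Egger's regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054


@dataclass(frozen=True)
class MetaResult:
    k: int
    theta: np.ndarray  # per-cohort log-HR
    se: np.ndarray
    fixed_weights: np.ndarray  # 1 / SE^2
    pooled_fixed: float
    se_fixed: float
    pooled_random: float
    se_random: float
    q: float
    q_df: int
    q_p: float
    i2: float  # max(0, (Q - df) / Q), in [0, 1)
    tau2: float  # DerSimonian-Laird
    chosen_model: str  # "fixed" | "random"
    gate: dict  # the gate inputs and verdict

    @property
    def pooled(self) -> float:
        return self.pooled_fixed if self.chosen_model == "fixed" else self.pooled_random

    @property
    def pooled_se(self) -> float:
        return self.se_fixed if self.chosen_model == "fixed" else self.se_random

    @property
    def ci(self) -> tuple[float, float]:
        return (self.pooled - Z95 * self.pooled_se, self.pooled + Z95 * self.pooled_se)


def meta_pool(
    theta: np.ndarray,
    se: np.ndarray,
    i2_gate: float = 0.25,
    qp_gate: float = 0.05,
) -> MetaResult:
    """Pool per-cohort effects; the gate chooses fixed vs. random effects."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    k = len(theta)
    if k < 2:
        raise ValueError("meta-analysis needs at least 2 cohorts")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled_f = float(np.sum(w * theta) / np.sum(w))
    se_f = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - pooled_f) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_r = 1.0 / (se**2 + tau2)
    pooled_r = float(np.sum(w_r * theta) / np.sum(w_r))
    se_r = float(1.0 / np.sqrt(np.sum(w_r)))
    use_fixed = (i2 < i2_gate) and (q_p > qp_gate)
    return MetaResult(
        k=k,
        theta=theta,
        se=se,
        fixed_weights=w,
        pooled_fixed=pooled_f,
        se_fixed=se_f,
        pooled_random=pooled_r,
        se_random=se_r,
        q=q,
        q_df=df,
        q_p=q_p,
        i2=float(i2),
        tau2=float(tau2),
        chosen_model="fixed" if use_fixed else "random",
        gate={"i2": float(i2), "i2_gate": i2_gate, "q_p": q_p, "qp_gate": qp_gate,
              "fixed_selected": bool(use_fixed)},
    )


def egger_test(theta: np.ndarray, se: np.ndarray) -> dict:
    """Egger's regression: standardized effect on precision.

    Regresses theta_i / SE_i on 1 / SE_i; the intercept estimates the
    small-study effect and is t-tested with k - 2 degrees of freedom.
    """
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    k = len(theta)
    if k < 3:
        raise ValueError("Egger's test needs at least 3 studies (df = k - 2 > 0)")
    y = theta / se
    x = 1.0 / se
    xm = x - x.mean()
    slope = float(np.sum(xm * y) / np.sum(xm**2))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (k - 2))
    se_int = float(np.sqrt(s2 * (1.0 / k + x.mean() ** 2 / np.sum(xm**2))))
    t = intercept / se_int
    p = float(2 * stats.t.sf(abs(t), df=k - 2))
    return {"intercept": intercept, "se": se_int, "t": float(t), "p": p, "df": k - 2,
            "slope": slope}


def meta_frame(result: MetaResult, cohort_names: list[str] | None = None) -> pd.DataFrame:
    """Per-cohort table (forest-plot input) with weights under both models."""
    k = result.k
    names = cohort_names if cohort_names is not None else [f"cohort_{i}" for i in range(k)]
    w_r = 1.0 / (result.se**2 + result.tau2)
    return pd.DataFrame(
        {
            "cohort": names,
            "loghr": result.theta,
            "se": result.se,
            "hr": np.exp(result.theta),
            "ci_lower": np.exp(result.theta - Z95 * result.se),
            "ci_upper": np.exp(result.theta + Z95 * result.se),
            "weight_fixed": result.fixed_weights / result.fixed_weights.sum(),
            "weight_random": w_r / w_r.sum(),
        }
    )
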