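"""Survival-evaluation stack for tissue-ratio prognostics.

Covers the full evaluation chain applied to the mixed tumor-stroma ratio:
Cox proportional-hazards models (Efron ties), optimal-cutpoint
stratification by maximally selected rank statistics with a permutation
p-value, Kaplan-Meier curves with the log-rank test, Harrell's C-index,
time-dependent ROC AUC with inverse-probability-of-censoring weights,
a points-based nomogram over a multivariate fit, bootstrap calibration,
decision-curve analysis adapted to censored data, and Schoenfeld-residual
checks of the proportional-hazards assumption.

Cox fitting, Kaplan-Meier estimation, and the concordance index delegate
to lifelines; the time-dependent AUC delegates to scikit-survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

Z95 = 1.959963984540054


@dataclass
class CoxFit:
    covariates: tuple[str, ...]
    beta: pd.Series  # log-hazard per covariate unit
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series  # exp(beta - 1.96 se)
    ci_upper: pd.Series
    p: pd.Series  # Wald
    log_likelihood: float
    c_index: float  # concordance of the linear predictor
    converged: bool
    ties: str = "efron"
    model: CoxPHFitter | None = field(default=None, repr=False)
    data: pd.DataFrame | None = field(default=None, repr=False)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return df[list(self.covariates)].to_numpy(dtype=float) @ self.beta.to_numpy()


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Non-convergence (e.g., monotone likelihood from complete separation)
    yields a flagged result rather than an exception, except when there
    are no events at all.
    """
    if records[event_col].sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    cols = [duration_col, event_col] + list(covariates)
    df = records[cols].astype(float)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    beta = cph.params_
    se = cph.standard_errors_
    return CoxFit(
        covariates=tuple(covariates),
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - Z95 * se),
        ci_upper=np.exp(beta + Z95 * se),
        p=cph.summary["p"],
        log_likelihood=float(cph.log_likelihood_),
        c_index=float(cph.concordance_index_),
        converged=converged,
        model=cph,
        data=df,
    )


# ------------------------------------------------------------- log-rank

def logrank_statistic(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic z = (O1 - E1) / sqrt(V).

    Hypergeometric variance at each distinct event time; sign is positive
    when group 1 experiences more events than expected.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    ut, inv = np.unique(t, return_inverse=True)
    m = len(ut)
    d = np.bincount(inv, weights=e, minlength=m)  # events per time
    d1 = np.bincount(inv, weights=e & g, minlength=m)
    c = np.bincount(inv, minlength=m)  # subjects leaving at each time
    c1 = np.bincount(inv, weights=g, minlength=m)
    n = np.cumsum(c[::-1])[::-1]  # at risk just before each time
    n1 = np.cumsum(c1[::-1])[::-1]
    mask = (d > 0) & (n > 1)
    dm, nm, n1m = d[mask], n[mask], n1[mask]
    e1 = dm * n1m / nm
    v = dm * (n1m / nm) * (1 - n1m / nm) * (nm - dm) / (nm - 1)
    vsum = v.sum()
    if vsum <= 0:
        return 0.0
    return float((d1[mask].sum() - e1.sum()) / np.sqrt(vsum))


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    statistic: float  # max |standardized log-rank|
    p_value: float  # permutation-adjusted
    candidate_range: tuple[float, float]
    n_candidates: int
    n_perm: int
    seed: int


def maxstat_cutpoint(
    records: pd.DataFrame,
    covariate: str,
    duration_col: str = "time",
    event_col: str = "event",
    qrange: tuple[float, float] = (0.10, 0.90),
    n_perm: int = 199,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected rank statistic cutpoint for a continuous covariate.

    Every distinct covariate value inside the quantile range is a candidate
    cutoff; the one maximizing the absolute standardized log-rank statistic
    (split at x > cutoff) is selected. The selection-adjusted p-value is
    estimated by permuting the covariate against (time, event) and
    recording the permutation distribution of the maximal statistic.
    """
    x = records[covariate].to_numpy(dtype=float)
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy()
    lo, hi = np.quantile(x, qrange)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    candidates = candidates[candidates < x.max()]  # a split needs both sides
    if len(candidates) < 2:
        raise ValueError("fewer than 2 distinct candidate cutoffs in the quantile range")

    def max_stat(values: np.ndarray) -> tuple[float, float]:
        best_z, best_c = -np.inf, candidates[0]
        for c in candidates:
            z = abs(logrank_statistic(time, event, values > c))
            if z > best_z:
                best_z, best_c = z, c
        return best_z, best_c

    obs_stat, obs_cut = max_stat(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_stat, _ = max_stat(rng.permutation(x))
        if perm_stat >= obs_stat:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return CutpointResult(
        cutoff=float(obs_cut),
        statistic=float(obs_stat),
        p_value=float(p),
        candidate_range=(float(lo), float(hi)),
        n_candidates=len(candidates),
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class KMResult:
    curves: dict  # group label -> fitted KaplanMeierFitter
    chi2: float
    p_value: float


def km_logrank(
    records: pd.DataFrame,
    group: np.ndarray,
    duration_col: str = "time",
    event_col: str = "event",
) -> KMResult:
    """Product-limit curves per group and the 1-df log-rank test."""
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("log-rank comparison needs exactly 2 groups")
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=float)
    curves = {}
    for lab in labels:
        m = group == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        curves[lab] = kmf
    res = logrank_test(
        time[group == labels[0]], time[group == labels[1]],
        event[group == labels[0]], event[group == labels[1]],
    )
    return KMResult(curves=curves, chi2=float(res.test_statistic), p_value=float(res.p_value))


def concordance_index(
    records: pd.DataFrame,
    risk: np.ndarray,
    duration_col: str = "time",
    event_col: str = "event",
) -> float:
    """Harrell's C: higher risk should predict shorter survival.

    Pairs where the earlier time is censored are unusable; ties in risk
    count one half.
    """
    return float(
        _lifelines_cindex(
            records[duration_col], -np.asarray(risk, dtype=float), records[event_col]
        )
    )


def time_dependent_auc(
    records: pd.DataFrame,
    risk: np.ndarray,
    horizons: list[float],
    duration_col: str = "time",
    event_col: str = "event",
) -> dict[float, float]:
    """Cumulative-case / dynamic-control AUC(t) with IPCW at each horizon.

    Horizons at or beyond the last follow-up time are undefined and
    reported as NaN.
    """
    surv = Surv.from_arrays(
        records[event_col].astype(bool), records[duration_col].astype(float)
    )
    risk = np.asarray(risk, dtype=float)
    out: dict[float, float] = {}
    tmax = records[duration_col].max()
    tmin = records[duration_col].min()
    for t in horizons:
        if t >= tmax or t < tmin:
            out[t] = np.nan
            continue
        try:
            auc, _ = cumulative_dynamic_auc(surv, surv, risk, [t])
            out[t] = float(auc[0])
        except ValueError:
            out[t] = np.nan
    return out


# -------------------------------------------------------------- nomogram

@dataclass
class NomogramModel:
    covariates: tuple[str, ...]
    beta: pd.Series
    ref: pd.Series  # covariate value assigned 0 points
    cov_range: pd.DataFrame  # min/max per covariate
    points_per_lp: float  # points per unit of linear predictor
    mean_lp: float  # training-mean linear predictor (centering)
    baseline_survival: dict[float, float]  # horizon -> S0(t) at mean covariates
    horizons: tuple[float, ...]

    def points(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Per-covariate points (widest contribution spans 0-100) and total."""
        pts = {}
        for c in self.covariates:
            contrib = self.beta[c] * (covariates[c].astype(float) - self.ref[c])
            pts[c] = contrib * self.points_per_lp
        out = pd.DataFrame(pts)
        out["total"] = out.sum(axis=1)
        return out

    def survival_from_points(self, total_points: np.ndarray) -> pd.DataFrame:
        """Invert the points scale back to survival probabilities (lossless)."""
        lp_ref = float(sum(self.beta[c] * self.ref[c] for c in self.covariates))
        lp = np.asarray(total_points, dtype=float) / self.points_per_lp + lp_ref
        return pd.DataFrame(
            {t: self.baseline_survival[t] ** np.exp(lp - self.mean_lp) for t in self.horizons}
        )


def _baseline_survival_at(cph: CoxPHFitter, t: float) -> float:
    bs = cph.baseline_survival_["baseline survival"]
    prior = bs[bs.index <= t]
    return float(prior.iloc[-1]) if len(prior) else 1.0


def build_nomogram(fit: CoxFit, horizons: list[float] = [1.0, 3.0, 5.0]) -> NomogramModel:
    """Points representation of a multivariate Cox fit.

    Each covariate contributes |beta| * range to the linear predictor; the
    widest contribution is scaled to 100 points. Predicted survival is
    S0(t) ** exp(lp - mean lp) with S0 the Breslow baseline at the
    training covariate means (as fit by lifelines).
    """
    if fit.model is None or fit.data is None:
        raise ValueError("CoxFit must carry its model and data to build a nomogram")
    data = fit.data
    cov_range = data[list(fit.covariates)].agg(["min", "max"])
    contribs = {
        c: abs(fit.beta[c]) * (cov_range.loc["max", c] - cov_range.loc["min", c])
        for c in fit.covariates
    }
    widest = max(contribs.values())
    if widest == 0:
        widest = 1.0  # all-null model: flat points scale
    ref = pd.Series(
        {
            c: cov_range.loc["min", c] if fit.beta[c] >= 0 else cov_range.loc["max", c]
            for c in fit.covariates
        }
    )
    mean_lp = float(
        data[list(fit.covariates)].mean().to_numpy() @ fit.beta.to_numpy()
    )
    baseline = {t: _baseline_survival_at(fit.model, t) for t in horizons}
    return NomogramModel(
        covariates=fit.covariates,
        beta=fit.beta,
        ref=ref,
        cov_range=cov_range,
        points_per_lp=100.0 / widest,
        mean_lp=mean_lp,
        baseline_survival=baseline,
        horizons=tuple(horizons),
    )


def predict_nomogram(model: NomogramModel, covariates: pd.DataFrame) -> pd.DataFrame:
    """Survival probabilities at the model horizons, one row per subject."""
    pts = model.points(covariates)
    return model.survival_from_points(pts["total"].to_numpy())


# ----------------------------------------------------------- calibration

def calibration_bootstrap(
    fit: CoxFit,
    horizons: list[float] = [1.0, 3.0, 5.0],
    n_boot: int = 1000,
    n_groups: int = 10,
    seed: int = 0,
) -> dict:
    """Predicted-vs-observed calibration by risk decile, plus slope.

    The apparent calibration slope (refitting the linear predictor on the
    data it was trained on) is 1 by construction; the bootstrap-corrected
    slope refits the model on resamples and evaluates each bootstrap
    model's linear predictor on the original data. ``n_boot = 0`` returns
    the apparent curve only, flagged as such.
    """
    if fit.model is None or fit.data is None:
        raise ValueError("CoxFit must carry its model and data for calibration")
    data = fit.data
    duration_col, event_col = fit.model.duration_col, fit.model.event_col
    sf = fit.model.predict_survival_function(data)
    rows = []
    for t in horizons:
        idx = sf.index[sf.index <= t]
        pred = sf.loc[idx[-1]].to_numpy() if len(idx) else np.ones(len(data))
        order = np.argsort(pred)
        groups = np.array_split(order, n_groups)
        for gi, g in enumerate(groups):
            if len(g) == 0:
                continue
            kmf = KaplanMeierFitter().fit(
                data[duration_col].iloc[g], data[event_col].iloc[g]
            )
            obs = float(kmf.predict(t))
            rows.append(
                {"horizon": t, "decile": gi, "n": len(g),
                 "predicted": float(pred[g].mean()), "observed": obs}
            )
    table = pd.DataFrame(rows)

    slope_corrected = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        slopes = []
        base = data.reset_index(drop=True)
        for _ in range(n_boot):
            boot = base.sample(n=len(base), replace=True, random_state=rng.integers(2**31))
            try:
                bfit = fit_cox(boot, list(fit.covariates), duration_col, event_col)
            except (ValueError, ConvergenceError):
                continue
            lp = bfit.linear_predictor(base)
            if np.std(lp) == 0:
                continue
            sl_df = base[[duration_col, event_col]].copy()
            sl_df["lp"] = lp
            try:
                slopes.append(fit_cox(sl_df, ["lp"], duration_col, event_col).beta["lp"])
            except (ValueError, ConvergenceError):
                continue
        slope_corrected = float(np.mean(slopes)) if slopes else None
    return {
        "table": table,
        "slope_apparent": 1.0,
        "slope_corrected": slope_corrected,
        "apparent_only": n_boot == 0,
        "n_boot": n_boot,
    }


# --------------------------------------------------------- decision curve

def decision_curve(
    records: pd.DataFrame,
    risks: dict[str, np.ndarray],
    horizon: float,
    thresholds: np.ndarray | None = None,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Net benefit NB(p_t) = TP/N - FP/N * p_t / (1 - p_t) under censoring.

    ``risks`` maps model names to predicted event probabilities by the
    horizon. Event status at the horizon is estimated by Kaplan-Meier
    within the treated (risk >= p_t) subset, so censored subjects
    contribute through the survival estimate rather than being dropped.
    Includes treat-all and treat-none reference strategies.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=float)
    n = len(records)

    def km_event_prob(mask: np.ndarray) -> float:
        if mask.sum() == 0:
            return 0.0
        kmf = KaplanMeierFitter().fit(time[mask], event[mask])
        return 1.0 - float(kmf.predict(horizon))

    prevalence = km_event_prob(np.ones(n, dtype=bool))
    rows = []
    for pt in thresholds:
        odds = pt / (1.0 - pt)
        rows.append({"threshold": pt, "model": "treat_none", "net_benefit": 0.0})
        rows.append(
            {"threshold": pt, "model": "treat_all",
             "net_benefit": prevalence - (1.0 - prevalence) * odds}
        )
        for name, risk in risks.items():
            mask = np.asarray(risk, dtype=float) >= pt
            frac = mask.mean()
            if frac == 0:
                nb = 0.0
            else:
                p_event_high = km_event_prob(mask)
                nb = frac * p_event_high - frac * (1.0 - p_event_high) * odds
            rows.append({"threshold": pt, "model": name, "net_benefit": nb})
    return pd.DataFrame(rows)


# ---------------------------------------------------- proportional hazards

def schoenfeld_test(fit: CoxFit) -> pd.DataFrame:
    """Grambsch-Therneau test on Schoenfeld residuals vs. event-time rank.

    One chi-square per covariate plus a global test (df = number of
    covariates), following the cox.zph construction with the rank time
    transform.
    """
    if fit.model is None or fit.data is None:
        raise ValueError("CoxFit must carry its model and data")
    resid = fit.model.compute_residuals(fit.data, "schoenfeld")
    # residuals are indexed by subject; order and rank them by event time
    ev_times = fit.data.loc[resid.index, fit.model.duration_col].to_numpy(dtype=float)
    order = np.argsort(ev_times, kind="stable")
    s = resid.to_numpy(dtype=float)[order]
    d = len(s)
    g = stats.rankdata(ev_times[order], method="average")
    gc = g - g.mean()
    w = gc @ s  # per-covariate score
    v_beta = fit.model.variance_matrix_.to_numpy()
    dsum = float(gc @ gc)
    chi2 = (d / dsum) * w**2 * np.diag(v_beta)
    p = stats.chi2.sf(chi2, df=1)
    cov_names = list(resid.columns)
    rows = [
        {"covariate": c, "chi2": float(chi2[i]), "p": float(p[i]), "df": 1}
        for i, c in enumerate(cov_names)
    ]
    global_chi2 = float((d / dsum) * (w @ v_beta @ w))
    rows.append(
        {"covariate": "GLOBAL", "chi2": global_chi2,
         "p": float(stats.chi2.sf(global_chi2, df=len(cov_names))), "df": len(cov_names)}
    )
    return pd.DataFrame(rows)
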