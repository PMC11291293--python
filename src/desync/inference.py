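"""Mixed-effects inference for scan-level metrics.

The scan-level model regresses an rs-fMRI metric y_ij (FC change, NGSC, or
a per-parcel variant) on drug condition, framewise displacement, task state
and the task × drug interaction, with random intercepts for participant and
for session nested within participant:

    y_ij = β0 + β_drug·drug_ij + β_FD·FD_ij + β_task·task_ij
           + β_task×drug·task_ij·drug_ij + u_0i + v_0j + ε_ij

Fits are delegated to :mod:`statsmodels` MixedLM (REML by default, ML for
likelihood-ratio comparisons).  A fast solver specialized to balanced
participant/session designs (:class:`BalancedNestedLME`) backs the wild
bootstrap, where thousands of refits of the same design are needed.

Also here: the brain–behaviour model for MEQ30 scores, the random-slope
likelihood-ratio test against a 50/50 χ²(1)/χ²(2) mixture, the
persistent-effect contrast, and the 90%-CI equivalence test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "LMEFit",
    "EquivalenceResult",
    "observations_from_scans",
    "build_design",
    "fit_lme",
    "simulate_lme_observations",
    "meq_brain_model",
    "lrt_random_slope",
    "chi2_mixture_sf",
    "label_pre_post",
    "persistent_effect",
    "equivalence_test",
    "BalancedNestedLME",
]

OBS_COLUMNS = ("y", "participant", "session", "condition", "fd", "task")


@dataclass
class LMEFit:
    """Fixed-effect estimates and variance components from one LME fit."""

    terms: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    df: int
    vc_participant: float
    vc_session: float
    vc_residual: float
    log_likelihood: float
    converged: bool
    method: str
    contrast: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def contrast_estimate(self) -> float:
        return self.beta[self.contrast]

    def summary(self) -> pd.DataFrame:
        """Tidy per-term table: estimate, CI, t, df, p."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": [self.beta[t] for t in self.terms],
                "se": [self.se[t] for t in self.terms],
                "ci_low": [self.ci_low[t] for t in self.terms],
                "ci_high": [self.ci_high[t] for t in self.terms],
                "t": [self.t[t] for t in self.terms],
                "df": self.df,
                "p": [self.p[t] for t in self.terms],
            }
        )


@dataclass
class EquivalenceResult:
    ci90: tuple[float, float]
    delta: float
    decision: str        # "equivalent" | "not_equivalent"
    estimate: float


def observations_from_scans(scans, y_values: np.ndarray) -> pd.DataFrame:
    """Assemble the observation table for :func:`fit_lme` from scan records."""
    y_values = np.asarray(y_values, dtype=float)
    if len(scans) != len(y_values):
        raise ValueError("one y value per scan required")
    return pd.DataFrame(
        {
            "y": y_values,
            "participant": [s.participant_id for s in scans],
            "session": [s.session_id for s in scans],
            "condition": [s.condition for s in scans],
            "fd": [s.mean_fd for s in scans],
            "task": [bool(s.task) for s in scans],
        }
    )


def build_design(
    obs: pd.DataFrame, contrast_condition: str = "psilocybin"
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix: intercept, condition dummies (treatment
    coding against baseline), FD, task, and task × contrast-drug."""
    obs = obs.reset_index(drop=True)
    levels = [
        c for c in ("psilocybin", "MTP", "between", "after")
        if (obs["condition"] == c).any()
    ]
    cols = [np.ones(len(obs))]
    names = ["Intercept"]
    for c in levels:
        cols.append((obs["condition"] == c).to_numpy(float))
        names.append(f"drug[{c}]")
    cols.append(obs["fd"].to_numpy(float))
    names.append("fd")
    task = obs["task"].to_numpy(float)
    if task.std() > 0:
        cols.append(task)
        names.append("task")
        inter = task * (obs["condition"] == contrast_condition).to_numpy(float)
        if inter.std() > 0:
            cols.append(inter)
            names.append(f"task:drug[{contrast_condition}]")
    return np.column_stack(cols), names


def _check_obs(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns {missing}")
    out = obs.dropna(subset=["y", "fd"]).reset_index(drop=True)
    if out["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    return out


def _package_mixedlm(
    result, terms: list[str], method: str, contrast: str | None
) -> LMEFit:
    fe = result.fe_params
    se = result.bse_fe
    ci = result.conf_int().loc[fe.index]
    df = int(result.nobs - len(fe))
    tvals = fe / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    vcomp = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    return LMEFit(
        terms=list(fe.index),
        beta=dict(fe),
        se=dict(se),
        ci_low=dict(ci[0]),
        ci_high=dict(ci[1]),
        t=dict(tvals),
        p=dict(zip(fe.index, pvals)),
        df=df,
        vc_participant=float(np.asarray(result.cov_re)[0, 0]),
        vc_session=vcomp,
        vc_residual=float(result.scale),
        log_likelihood=float(result.llf),
        converged=bool(result.converged),
        method=method,
        contrast=contrast,
    )


def fit_lme(
    obs: pd.DataFrame,
    response_name: str = "y",
    contrast_condition: str = "psilocybin",
    *,
    reml: bool = True,
    re_formula: str = "1",
    force_zero_variance: bool = False,
) -> LMEFit:
    """Fit the scan-level mixed model and return estimates for every term.

    Random structure: participant random intercept plus a session variance
    component nested within participant.  ``force_zero_variance`` drops both
    random terms (plain OLS), the degenerate limit used as an oracle check.
    Singular or non-converged fits are flagged via ``converged``/
    ``diagnostics``, never silently.
    """
    obs = _check_obs(obs.rename(columns={response_name: "y"}))
    X, names = build_design(obs, contrast_condition)
    contrast = f"drug[{contrast_condition}]"
    if contrast not in names:
        contrast = None

    if force_zero_variance:
        res = sm.OLS(obs["y"].to_numpy(), X).fit()
        ci = res.conf_int()
        fit = LMEFit(
            terms=names,
            beta=dict(zip(names, res.params)),
            se=dict(zip(names, res.bse)),
            ci_low=dict(zip(names, ci[:, 0])),
            ci_high=dict(zip(names, ci[:, 1])),
            t=dict(zip(names, res.tvalues)),
            p=dict(zip(names, res.pvalues)),
            df=int(res.df_resid),
            vc_participant=0.0,
            vc_session=0.0,
            vc_residual=float(res.mse_resid),
            log_likelihood=float(res.llf),
            converged=True,
            method="OLS",
            contrast=contrast,
        )
        return fit

    data = obs.copy()
    for j, name in enumerate(names):
        data[f"_x{j}"] = X[:, j]
    rhs = " + ".join(f"_x{j}" for j in range(1, len(names)))
    formula = f"y ~ {rhs}" if rhs else "y ~ 1"
    model = smf.mixedlm(
        formula,
        data=data,
        groups=data["participant"],
        re_formula=re_formula,
        vc_formula={"session": "0 + C(session)"},
    )
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # powell/cg find the optimum reliably on this likelihood surface but
        # can diverge to a degenerate point on slope models; fall back.
        for methods in (["powell", "cg"], ["lbfgs"], ["nm"]):
            try:
                candidate = model.fit(reml=reml, method=methods, maxiter=1000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(candidate.llf):
                result = candidate
                break
    if result is None:
        raise RuntimeError("mixed model estimation failed for every optimizer")
    rename = dict(zip([f"_x{j}" for j in range(len(names))], names))
    rename["Intercept"] = "Intercept"
    result.model.data.param_names  # touch to materialize names
    fit = _package_mixedlm(result, names, "REML" if reml else "ML", contrast)
    fit.terms = [rename.get(t, t) for t in fit.terms]
    for attr in ("beta", "se", "ci_low", "ci_high", "t", "p"):
        d = getattr(fit, attr)
        setattr(fit, attr, {rename.get(k, k): v for k, v in d.items()})
    if not fit.converged:
        fit.diagnostics["warning"] = "mixed model did not converge"
    return fit


def simulate_lme_observations(
    *,
    n_participants: int = 6,
    sessions_per_participant: int = 18,
    scans_per_session: int = 2,
    beta: dict[str, float] | None = None,
    sd_participant: float = 2.0,
    sd_session: float = 1.5,
    sd_residual: float = 4.0,
    slope_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw observations directly from the scan-level mixed model.

    Used for parameter-recovery and calibration simulations where the
    coefficients themselves must be known exactly.  The design mirrors the
    crossover schedule (baseline / MTP / between / psilocybin / after
    sessions, last scan of a session is the task scan).  ``slope_sd`` adds a
    participant-specific psilocybin response (random slope).
    """
    from .cohort import default_schedule

    b = {
        "Intercept": 20.0,
        "drug[psilocybin]": 15.0,
        "drug[MTP]": 2.0,
        "drug[between]": 0.0,
        "drug[after]": 0.0,
        "fd": 5.0,
        "task": 2.0,
        "task:drug[psilocybin]": -6.0,
    }
    if beta:
        b.update(beta)
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        order = ("MTP", "psilocybin") if p % 2 == 0 else ("psilocybin", "MTP")
        schedule = default_schedule(sessions_per_participant, order)
        u = rng.normal(0.0, sd_participant)
        slope = rng.normal(0.0, slope_sd) if slope_sd > 0 else 0.0
        for s in range(sessions_per_participant):
            cond = schedule[s]
            v = rng.normal(0.0, sd_session)
            is_drug = cond in ("psilocybin", "MTP")
            for k in range(scans_per_session):
                task = k == scans_per_session - 1 and scans_per_session > 1
                fd = max(0.01, rng.normal(0.15 + 0.08 * is_drug, 0.03))
                psil = cond == "psilocybin"
                y = (
                    b["Intercept"]
                    + b.get(f"drug[{cond}]", 0.0)
                    + (slope if psil else 0.0)
                    + b["fd"] * fd
                    + b["task"] * task
                    + b["task:drug[psilocybin]"] * task * psil
                    + u
                    + v
                    + rng.normal(0.0, sd_residual)
                )
                rows.append(
                    {
                        "y": y,
                        "participant": pid,
                        "session": f"S{s + 1:02d}",
                        "condition": cond,
                        "fd": fd,
                        "task": task,
                    }
                )
    return pd.DataFrame(rows)


def meq_brain_model(
    fc_changes: np.ndarray,
    meq_totals: np.ndarray,
    fds: np.ndarray,
    participants: np.ndarray,
) -> tuple[LMEFit, float]:
    """Brain–behaviour model: MEQ30 total ~ whole-brain FC change + FD,
    participant random intercept.  Returns the fit and the squared
    correlation between fitted and observed scores."""
    df = pd.DataFrame(
        {
            "meq": np.asarray(meq_totals, float),
            "fc": np.asarray(fc_changes, float),
            "fd": np.asarray(fds, float),
            "participant": participants,
        }
    )
    if len(df) < 4:
        raise ValueError("need at least 4 drug sessions")
    if df["fc"].std() == 0:
        raise ValueError("constant predictor")
    predictors = ["fc"] + (["fd"] if df["fd"].std() > 0 else [])
    ols = sm.OLS(df["meq"], sm.add_constant(df[predictors])).fit()
    deterministic = ols.ssr <= 1e-10 * max(float(df["meq"].var()), 1.0)
    if deterministic:
        # perfectly deterministic coupling: random effects unidentified
        res = ols
        fitted = np.asarray(res.fittedvalues)
        names = ["Intercept", *predictors]
        ci = res.conf_int().to_numpy()
        fit = LMEFit(
            terms=names,
            beta=dict(zip(names, res.params)),
            se=dict(zip(names, res.bse)),
            ci_low=dict(zip(names, ci[:, 0])),
            ci_high=dict(zip(names, ci[:, 1])),
            t=dict(zip(names, res.tvalues)),
            p=dict(zip(names, res.pvalues)),
            df=int(res.df_resid),
            vc_participant=0.0,
            vc_session=0.0,
            vc_residual=float(res.mse_resid),
            log_likelihood=float(res.llf),
            converged=True,
            method="OLS",
            contrast="fc",
        )
    else:
        model = smf.mixedlm(
            "meq ~ " + " + ".join(predictors), data=df, groups=df["participant"]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True, method=["powell", "cg"], maxiter=1000)
        fitted = np.asarray(result.fittedvalues)
        fe = result.fe_params
        se = result.bse_fe
        ci = result.conf_int().loc[fe.index]
        dfree = int(result.nobs - len(fe))
        tvals = fe / se
        fit = LMEFit(
            terms=list(fe.index),
            beta=dict(fe),
            se=dict(se),
            ci_low=dict(ci[0]),
            ci_high=dict(ci[1]),
            t=dict(tvals),
            p=dict(zip(fe.index, 2 * stats.t.sf(np.abs(tvals), dfree))),
            df=dfree,
            vc_participant=float(np.asarray(result.cov_re)[0, 0]),
            vc_session=0.0,
            vc_residual=float(result.scale),
            log_likelihood=float(result.llf),
            converged=bool(result.converged),
            method="REML",
            contrast="fc",
        )
    r = np.corrcoef(fitted, df["meq"])[0, 1]
    return fit, float(r**2)


def chi2_mixture_sf(statistic: float) -> float:
    """Tail probability under the 50/50 mixture of χ²(1) and χ²(2).

    The boundary null for testing a random-slope variance (with its
    covariance) sits on the edge of the parameter space, so the usual χ²
    reference is replaced by this equal mixture.
    """
    s = max(float(statistic), 0.0)
    if s == 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(s, 1) + 0.5 * stats.chi2.sf(s, 2))


def lrt_random_slope(
    obs: pd.DataFrame,
    contrast_condition: str = "psilocybin",
    *,
    n_null_draws: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """Likelihood-ratio test for a participant-specific drug response.

    Both models are fit by ML on identical data; the full model adds a
    random slope on the contrast-drug indicator (correlated with the
    participant intercept).  The statistic 2·Δll (floored at 0) is referred
    to the 50/50 χ²(1)/χ²(2) mixture; ``n_null_draws`` > 0 additionally
    returns a simulated-mixture p (Monte-Carlo check of the analytic tail).
    """
    obs = _check_obs(obs)
    obs = obs.copy()
    obs["psil"] = (obs["condition"] == contrast_condition).astype(float)
    if obs["psil"].std() == 0:
        raise ValueError(f"no {contrast_condition} observations")
    reduced = fit_lme(obs, contrast_condition=contrast_condition, reml=False)
    full = fit_lme(
        obs,
        contrast_condition=contrast_condition,
        reml=False,
        re_formula="1 + psil",
    )
    statistic = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = chi2_mixture_sf(statistic)
    if n_null_draws:
        rng = np.random.default_rng(seed)
        pick = rng.integers(1, 3, size=n_null_draws)
        draws = stats.chi2.rvs(pick, random_state=rng)
        p_sim = (1 + np.sum(draws >= statistic)) / (n_null_draws + 1)
        return statistic, float(p), float(p_sim)  # type: ignore[return-value]
    return statistic, float(p)


def label_pre_post(
    meta: pd.DataFrame, drug: str = "psilocybin", window_days: int = 21
) -> pd.Series:
    """Pre/post labels around each participant's drug session.

    All sessions before the drug day (irrespective of crossover order) are
    ``pre``; sessions within ``window_days`` after it are ``post``; the drug
    session itself and later sessions are unlabelled (None).
    Requires columns participant, condition, day.
    """
    labels = pd.Series([None] * len(meta), index=meta.index, dtype=object)
    for pid, grp in meta.groupby("participant"):
        drug_days = grp.loc[grp["condition"] == drug, "day"]
        if drug_days.empty:
            continue
        d0 = drug_days.min()
        pre = grp.index[(grp["day"] < d0) & (grp["condition"] != drug)]
        post = grp.index[
            (grp["day"] > d0)
            & (grp["day"] <= d0 + window_days)
            & (grp["condition"] != drug)
        ]
        labels.loc[pre] = "pre"
        labels.loc[post] = "post"
    return labels


def persistent_effect(obs: pd.DataFrame) -> LMEFit:
    """Pre/post-drug contrast on a regional metric.

    ``obs`` needs columns y, participant, session, fd and phase in
    {pre, post}.  Fits the scan-level LME with a post indicator as the
    condition contrast.
    """
    obs = obs.copy()
    if not {"pre", "post"} <= set(obs["phase"].dropna().unique()):
        raise ValueError("both pre and post labels must be present")
    obs = obs[obs["phase"].isin(["pre", "post"])]
    obs["condition"] = np.where(obs["phase"] == "post", "after", "baseline")
    if "task" not in obs:
        obs["task"] = False
    fit = fit_lme(obs, contrast_condition="after")
    fit.contrast = "drug[after]"
    return fit


def equivalence_test(
    pre_values: np.ndarray,
    post_values: np.ndarray,
    delta: float | None = None,
    *,
    pre_participants: np.ndarray | None = None,
    post_participants: np.ndarray | None = None,
) -> EquivalenceResult:
    """Equivalence decision from the 90% CI of the post − pre contrast.

    ``delta`` defaults to 0.5 · SD of the pre-period values.  When
    participant labels are supplied the contrast comes from a mixed model
    with a participant random intercept; otherwise from OLS on the group
    indicator.  Equivalence is declared iff the whole 90% CI lies inside
    ±delta.
    """
    pre = np.asarray(pre_values, float)
    post = np.asarray(post_values, float)
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("need at least 2 values per group")
    if delta is None:
        sd = pre.std(ddof=1)
        if sd == 0:
            raise ValueError("zero pre-group variance with defaulted delta")
        delta = 0.5 * sd
    y = np.concatenate([pre, post])
    g = np.concatenate([np.zeros(len(pre)), np.ones(len(post))])
    if pre_participants is not None and post_participants is not None:
        part = np.concatenate(
            [np.asarray(pre_participants), np.asarray(post_participants)]
        )
        df = pd.DataFrame({"y": y, "g": g, "participant": part})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(
                "y ~ g", data=df, groups=df["participant"]
            ).fit(reml=True, method=["powell", "cg"], maxiter=1000)
        est = float(res.fe_params["g"])
        se = float(res.bse_fe["g"])
    else:
        res = sm.OLS(y, sm.add_constant(g)).fit()
        est = float(res.params[1])
        se = float(res.bse[1])
    zcrit = stats.norm.ppf(0.95)
    lo, hi = est - zcrit * se, est + zcrit * se
    decision = "equivalent" if (lo > -delta and hi < delta) else "not_equivalent"
    return EquivalenceResult(
        ci90=(lo, hi), delta=float(delta), decision=decision, estimate=est
    )


class BalancedNestedLME:
    """ML estimation of the two-variance-component LME on balanced designs.

    For designs with equal scans per session and equal sessions per
    participant, the participant and session random-intercept structures
    diagonalize simultaneously: an orthonormal basis splits the data into
    within-session contrasts (variance σ²), between-session contrasts
    (σ² + m·τ_s²) and participant-level vectors (σ² + m·τ_s² + s·m·τ_p²).
    The profiled ML criterion then costs O(n·p) per evaluation, which is
    what makes per-parcel wild-bootstrap refitting affordable.

    Cross-checked against statsmodels MixedLM (ML) in the test suite.
    """

    def __init__(
        self,
        X: np.ndarray,
        participant: np.ndarray,
        session: np.ndarray,
    ):
        X = np.asarray(X, float)
        participant = np.asarray(participant)
        session = np.asarray(session)
        n = X.shape[0]
        # session keys are participant-specific (nested)
        skey = np.array([f"{p}//{s}" for p, s in zip(participant, session)])
        sess_ids, sess_inv = np.unique(skey, return_inverse=True)
        part_ids, part_inv = np.unique(participant, return_inverse=True)
        counts = np.bincount(sess_inv)
        if len(set(counts)) != 1:
            raise ValueError("unequal scans per session: design not balanced")
        m = int(counts[0])
        sess_part = np.empty(len(sess_ids), dtype=int)
        for si in range(len(sess_ids)):
            sess_part[si] = part_inv[np.argmax(sess_inv == si)]
        spp = np.bincount(sess_part)
        if len(set(spp)) != 1:
            raise ValueError("unequal sessions per participant: not balanced")
        s_per_p = int(spp[0])

        rows: list[np.ndarray] = []
        strata: list[int] = []

        def helmert(k: int) -> np.ndarray:
            # (k-1) x k orthonormal contrasts orthogonal to the constant
            h = np.zeros((k - 1, k))
            for i in range(1, k):
                h[i - 1, :i] = 1.0
                h[i - 1, i] = -i
                h[i - 1] /= np.sqrt(i * (i + 1))
            return h

        # stratum 0: within-session contrasts
        if m > 1:
            hm = helmert(m)
            for si in range(len(sess_ids)):
                idx = np.where(sess_inv == si)[0]
                for row in hm:
                    v = np.zeros(n)
                    v[idx] = row
                    rows.append(v)
                    strata.append(0)
        # stratum 1: between-session contrasts within participant
        if s_per_p > 1:
            hs = helmert(s_per_p)
            for pi in range(len(part_ids)):
                sess_of_p = np.where(sess_part == pi)[0]
                for row in hs:
                    v = np.zeros(n)
                    for c, si in zip(row, sess_of_p):
                        v[sess_inv == si] = c / np.sqrt(m)
                    rows.append(v)
                    strata.append(1)
        # stratum 2: participant-level vectors (including the grand mean)
        for pi in range(len(part_ids)):
            v = np.zeros(n)
            idx = part_inv == pi
            v[idx] = 1.0 / np.sqrt(idx.sum())
            rows.append(v)
            strata.append(2)

        self.Q = np.array(rows)               # n x n orthonormal
        self.strata = np.array(strata)
        self.m = m
        self.s_per_p = s_per_p
        self.n = n
        self.X = X
        self.Xt = self.Q @ X

    def _g(self, theta: np.ndarray) -> np.ndarray:
        g = np.ones(self.n)
        g[self.strata >= 1] += theta[0]
        g[self.strata == 2] += theta[1]
        return g

    def _profile(self, theta: np.ndarray, yt: np.ndarray):
        g = self._g(theta)
        w = 1.0 / np.sqrt(g)
        P = self.Xt * w[:, None]
        u = yt * w
        beta, *_ = np.linalg.lstsq(P, u, rcond=None)
        resid = u - P @ beta
        rss = float(resid @ resid)
        return g, beta, rss, P

    def nll(self, theta: np.ndarray, yt: np.ndarray) -> float:
        g, _, rss, _ = self._profile(theta, yt)
        sigma2 = rss / self.n
        return 0.5 * (
            self.n * np.log(2 * np.pi * sigma2)
            + np.log(g).sum()
            + self.n
        )

    def fit(self, y: np.ndarray) -> "BalancedFitResult":
        yt = self.Q @ np.asarray(y, float)
        best = None
        for start in ((0.5, 0.5), (2.0, 2.0), (0.01, 0.01)):
            res = optimize.minimize(
                lambda th: self.nll(th, yt),
                x0=np.array(start),
                method="L-BFGS-B",
                bounds=[(0.0, 1e6), (0.0, 1e6)],
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        theta = best.x
        g, beta, rss, P = self._profile(theta, yt)
        sigma2 = rss / self.n
        cov = sigma2 * np.linalg.inv(P.T @ P)
        tau_s2 = sigma2 * theta[0] / self.m
        tau_p2 = sigma2 * theta[1] / (self.m * self.s_per_p)
        fitted = self.X @ beta
        return BalancedFitResult(
            model=self,
            beta=beta,
            cov_beta=cov,
            sigma2=sigma2,
            tau_session2=tau_s2,
            tau_participant2=tau_p2,
            theta=theta,
            log_likelihood=-best.fun,
            fitted_marginal=fitted,
            residuals=np.asarray(y, float) - fitted,
        )

    def gls_t(
        self, theta: np.ndarray, Y: np.ndarray, contrast_index: int
    ) -> np.ndarray:
        """t-statistics for one contrast over many response columns at fixed
        variance-component ratios (the wild-bootstrap fast path).

        ``Y`` is (n_obs, B).  σ² is re-estimated per column from the
        weighted residual sum of squares.
        """
        g = self._g(theta)
        w = 1.0 / np.sqrt(g)
        P = self.Xt * w[:, None]
        U = (self.Q @ Y) * w[:, None]
        M = np.linalg.inv(P.T @ P)
        B = M @ P.T @ U                        # p x B coefficients
        resid = U - P @ B
        sigma2 = (resid**2).sum(axis=0) / self.n
        se = np.sqrt(sigma2 * M[contrast_index, contrast_index])
        return B[contrast_index] / se


@dataclass
class BalancedFitResult:
    model: BalancedNestedLME
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau_session2: float
    tau_participant2: float
    theta: np.ndarray
    log_likelihood: float
    fitted_marginal: np.ndarray
    residuals: np.ndarray

    def t_value(self, index: int) -> float:
        return float(self.beta[index] / np.sqrt(self.cov_beta[index, index]))
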