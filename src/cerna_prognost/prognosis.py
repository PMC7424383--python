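"""Survival analysis: Kaplan-Meier curves, log-rank tests, Cox risk scores.

Hub RNAs are assessed by a median split on their expression followed by a
log-rank test; ceRNA triplets by a multivariate Cox proportional-hazards fit
on the three members' standardized expressions, a per-patient risk score

    RS_j = sum_i beta_i * x_ij

and a median-risk split tested by log-rank. The Cox partial likelihood is
maximized by Newton-Raphson with Breslow handling of tied event times.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.stats import chi2

from .containers import ClinicalTable, ExpressionMatrix, RunConfig
from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateSplitError,
    ValidationError,
)

log = logging.getLogger("cerna_prognost")


@dataclass
class SurvivalSplit:
    """high/low group assignment at the median of a splitting variable."""

    group: pd.Series  # per-patient label in {'high', 'low'}
    split_value: float

    @property
    def high(self) -> list[str]:
        return list(self.group.index[self.group == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.group.index[self.group == "low"])


@dataclass
class LogRankResult:
    observed: dict[str, float]
    expected: dict[str, float]
    chi_square: float
    p: float


@dataclass
class RiskModel:
    """Fitted Cox risk-score model for one ceRNA triplet."""

    features: tuple[str, ...]
    betas: np.ndarray
    risk_scores: pd.Series
    median_rs: float
    split: SurvivalSplit
    logrank: LogRankResult
    converged: bool = True

    @property
    def logrank_p(self) -> float:
        return self.logrank.p

    @property
    def logrank_stat(self) -> float:
        return self.logrank.chi_square


def median_split(x: pd.Series) -> SurvivalSplit:
    """Split patients at the median: high = strictly above, ties go low."""
    x = pd.Series(x, dtype=float)
    if len(x) < 4:
        raise ValidationError(f"median split needs >=4 patients, got {len(x)}")
    if x.nunique() == 1:
        raise DegenerateSplitError("splitting variable is constant")
    med = float(x.median())
    group = pd.Series(np.where(x > med, "high", "low"), index=x.index)
    return SurvivalSplit(group=group, split_value=med)


def _risk_table(times: np.ndarray, events: np.ndarray, groups: np.ndarray):
    """Per-distinct-event-time counts: (t, d_t, n_t, d1_t, n1_t) arrays.

    Group 1 is the lexicographically first label ('high' before 'low').
    """
    labels = np.unique(groups)
    g1 = labels[0]
    event_times = np.unique(times[events == 1])
    rows = []
    for t in event_times:
        at_risk = times >= t
        dying = (times == t) & (events == 1)
        rows.append(
            (
                t,
                dying.sum(),
                at_risk.sum(),
                (dying & (groups == g1)).sum(),
                (at_risk & (groups == g1)).sum(),
            )
        )
    return g1, rows


def logrank_test(split: SurvivalSplit, clin: ClinicalTable) -> LogRankResult:
    """Two-group log-rank test: (sum O1-E1)^2 / sum V, p from chi2 with 1 df."""
    clin = clin.subset(split.group.index)
    groups = split.group.loc[clin.sample_ids].to_numpy()
    labels = sorted(set(groups))
    if len(labels) < 2 or min((groups == l).sum() for l in labels) == 0:
        raise ValidationError("log-rank needs two non-empty groups")
    times, events = clin.times_events()
    g1, rows = _risk_table(times, events, groups)
    o_minus_e = 0.0
    var = 0.0
    o1 = e1 = 0.0
    d_total = 0.0
    for t, d, n, d1, n1 in rows:
        n2 = n - n1
        e = d * n1 / n
        o1 += d1
        e1 += e
        d_total += d
        o_minus_e += d1 - e
        if n > 1:
            var += d * (n - d) * n1 * n2 / (n**2 * (n - 1))
    g2 = [l for l in labels if l != g1][0]
    observed = {g1: float(o1), g2: float(d_total - o1)}
    if min(observed.values()) == 0:
        log.warning("log-rank: a group has zero observed events")
    expected = {g1: float(e1), g2: float(d_total - e1)}
    if var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e**2 / var
        p = float(chi2.sf(stat, 1))
    return LogRankResult(observed=observed, expected=expected,
                         chi_square=float(stat), p=p)


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_t/n_t).

    Returns a step function as a DataFrame (time, n_at_risk, n_events,
    survival), starting from S=1 at t=0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty group for KM estimate")
    rows = [(0.0, int(times.size), 0, 1.0)]
    s = 1.0
    for t in np.unique(times[events == 1]):
        n = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n
        rows.append((float(t), n, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_by_group(split: SurvivalSplit, clin: ClinicalTable) -> dict[str, pd.DataFrame]:
    clin = clin.subset(split.group.index)
    out = {}
    for label in ("high", "low"):
        ids = [s for s in clin.sample_ids if split.group[s] == label]
        sub = clin.subset(ids)
        t, e = sub.times_events()
        out[label] = km_curve(t, e)
    return out


def _cox_loglik(beta, x, times, events):
    """Breslow partial log-likelihood, gradient and Hessian (vectorized).

    Patients are sorted by descending time so risk-set sums S0 = sum w,
    S1 = sum w*x, S2 = sum w*x*x' are cumulative sums read off at the end of
    each tied-time block; a block's d_t events share one risk-set term.
    """
    order = np.argsort(-times, kind="stable")
    x = x[order]
    times = times[order]
    events = events[order].astype(float)
    n, p = x.shape
    eta = np.clip(x @ beta, -200, 200)  # overflow guard for wild Newton steps
    w = np.exp(eta)
    cw0 = np.cumsum(w)
    cw1 = np.cumsum(w[:, None] * x, axis=0)
    cw2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    # last index of each distinct-time block
    ends = np.flatnonzero(np.diff(times) != 0)
    ends = np.append(ends, n - 1)
    starts = np.concatenate(([0], ends[:-1] + 1))
    csum_d = np.concatenate(([0.0], np.cumsum(events)))
    d_t = csum_d[ends + 1] - csum_d[starts]
    keep = d_t > 0
    d_t = d_t[keep]
    s0 = cw0[ends][keep]
    s1 = cw1[ends][keep]
    s2 = cw2[ends][keep]
    ll = float(eta @ events - d_t @ np.log(s0))
    xbar = s1 / s0[:, None]
    grad = (x * events[:, None]).sum(axis=0) - d_t @ xbar
    hess = -np.einsum(
        "t,tij->ij",
        d_t,
        s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :],
    )
    return ll, grad, hess


def fit_cox(
    features: pd.DataFrame,
    clin: ClinicalTable,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool]:
    """Cox proportional-hazards coefficients by Newton-Raphson.

    ``features`` is patients x covariates, standardized (mean 0, sd 1) over
    the included patients; rows are matched to the clinical table by index.
    Returns (beta, converged). Collinear covariates and monotone likelihoods
    (separation) raise with the offending feature named.
    """
    clin = clin.subset(features.index)
    features = features.loc[clin.sample_ids]
    x = features.to_numpy(dtype=float)
    names = list(features.columns)
    times, events = clin.times_events()
    if events.sum() < 10:
        raise ValidationError(
            f"need >=10 events for a stable Cox fit, got {int(events.sum())}"
        )
    # a singular covariance betrays exact collinearity before Newton stalls
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov, tol=1e-10) < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        worst = names[-1]
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if abs(corr[a, b]) > 1 - 1e-10:
                    worst = names[b]
        raise CollinearityError(f"collinear Cox covariates; drop {worst!r}")
    beta = np.zeros(x.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, x, times, events)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(
                f"singular information matrix for features {names}"
            ) from exc
        # halve the step until the partial likelihood improves (tolerating
        # float noise near the optimum, where Newton steps are ~machine eps)
        scale = 1.0
        for _h in range(30):
            ll_new, _, _ = _cox_loglik(beta + scale * step, x, times, events)
            if ll_new >= ll - 1e-10 * max(1.0, abs(ll)):
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.abs(beta).max() > 50:
            imax = int(np.abs(beta).argmax())
            raise ConvergenceError(
                f"monotone likelihood (separation) on feature {names[imax]!r}"
            )
        ll_old = ll
    if not converged:
        ll, grad, _ = _cox_loglik(beta, x, times, events)
        if np.linalg.norm(grad) >= 1e-4:
            raise ConvergenceError(
                f"Cox fit did not converge for features {names}"
            )
    return beta, converged


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with ddof=1 over the included patients."""
    sd = values.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValidationError(f"constant features cannot be standardized: {bad}")
    return (values - values.mean()) / sd


def gene_survival(
    gene: str,
    m: ExpressionMatrix,
    clin: ClinicalTable,
) -> tuple[SurvivalSplit, LogRankResult, dict[str, pd.DataFrame]]:
    """Median-split KM + log-rank for a single RNA's expression (hub analysis)."""
    tumor = [s for s in m.samples_in_group("tumor") if s in clin.df.index]
    expr = m.values.loc[gene, tumor]
    split = median_split(expr)
    lr = logrank_test(split, clin)
    return split, lr, km_by_group(split, clin)


def triplet_risk_analysis(
    triplet,
    lnc_m: ExpressionMatrix,
    mir_m: ExpressionMatrix,
    mrna_m: ExpressionMatrix,
    clin: ClinicalTable,
    cfg: RunConfig | None = None,
    min_patients: int = 20,
) -> RiskModel:
    """Fit the triplet Cox model and test the median-risk split by log-rank.

    The three covariates are the tumor-sample logCPM of the lncRNA, miRNA and
    mRNA, standardized over the patients with clinical records.
    """
    cfg = cfg or RunConfig()
    members = [
        (triplet.lncrna_id, lnc_m),
        (triplet.mirna_id, mir_m),
        (triplet.mrna_id, mrna_m),
    ]
    patients = set(clin.df.index)
    for _gid, m in members:
        patients &= set(m.samples_in_group("tumor"))
    patients = sorted(patients)
    if len(patients) < min_patients:
        raise ValidationError(
            f"only {len(patients)} tumor samples with clinical records; "
            f"need >= {min_patients}"
        )
    feats = pd.DataFrame(
        {gid: m.values.loc[gid, patients] for gid, m in members}, index=patients
    )
    feats = standardize(feats)
    beta, converged = fit_cox(feats, clin.subset(patients))
    rs = pd.Series(feats.to_numpy() @ beta, index=patients, name="risk_score")
    split = median_split(rs)
    lr = logrank_test(split, clin)
    return RiskModel(
        features=tuple(feats.columns),
        betas=beta,
        risk_scores=rs,
        median_rs=split.split_value,
        split=split,
        logrank=lr,
        converged=converged,
    )
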