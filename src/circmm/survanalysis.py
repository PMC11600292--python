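"""Survival machinery.

Kaplan-Meier product-limit estimation, the log-rank test (two or more
groups), univariate Cox proportional hazards (Newton-Raphson on the partial
likelihood, Breslow or Efron tie handling) and maximally selected optimal
cutpoints subject to a minimum group proportion (minprop), as used for
per-circRNA survival screening. Screening p-values are reported unadjusted —
matching the screening convention this reproduces — with a BH-adjusted column
alongside, because maximal selection inflates the type-I error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .grouptests import TestResult, bh_adjust

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Cox partial likelihood failed to converge (e.g. monotone likelihood)."""


@dataclass
class SurvivalData:
    """Right-censored survival times in months with 0/1 event indicators."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.size == 0:
            raise ValueError("no survival observations")
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must align")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise ValueError("survival times must be positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if self.sample_ids is not None and len(self.sample_ids) != self.time.size:
            raise ValueError("sample_ids must align with times")

    def __len__(self) -> int:
        return int(self.time.size)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, time_col: str = "os_months",
                   event_col: str = "event") -> "SurvivalData":
        return cls(frame[time_col].to_numpy(), frame[event_col].to_numpy(),
                   sample_ids=list(frame.index))


@dataclass
class KMCurve:
    """Kaplan-Meier step function over the observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else float("nan")

    @property
    def final_survival(self) -> float:
        return float(self.survival[-1]) if self.survival.size else 1.0


def km_estimate(d: SurvivalData) -> KMCurve:
    """Product-limit estimator with Greenwood variance.

    Subjects censored at an event time are still at risk for that event
    (the standard convention).
    """
    order = np.argsort(d.time, kind="stable")
    t, e = d.time[order], d.event[order]
    times, first = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e, first)
    at_risk = t.size - first
    keep = deaths > 0
    times, deaths, at_risk = times[keep], deaths[keep], at_risk[keep]
    frac = 1.0 - deaths / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = deaths / (at_risk * (at_risk - deaths))
    gw_terms = np.where(at_risk > deaths, gw_terms, np.inf)
    with np.errstate(invalid="ignore"):
        greenwood = surv**2 * np.cumsum(gw_terms)  # 0*inf -> nan once S hits 0
    return KMCurve(times, surv, at_risk, deaths, greenwood, n=t.size)


def _logrank_scan(time: np.ndarray, event: np.ndarray, group1: np.ndarray):
    """Two-group log-rank O-E, V and signed Z for each column of ``group1``.

    ``group1`` is an (n, C) boolean matrix; each column defines one candidate
    grouping. Returns (observed_minus_expected, variance, z) arrays of length C.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    g = np.asarray(group1, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    g = g[order]
    n = t.size
    _, first = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e, first)
    at_risk = n - first
    n1 = np.cumsum(g[::-1], axis=0)[::-1][first]  # in-group at risk per distinct time
    d1 = np.add.reduceat(e[:, None] * g, first, axis=0)
    keep = deaths > 0
    deaths, at_risk, n1, d1 = deaths[keep], at_risk[keep], n1[keep], d1[keep]
    frac = n1 / at_risk[:, None]
    o_minus_e = (d1 - deaths[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = (deaths * (at_risk - deaths) / np.maximum(at_risk - 1, 1))[:, None] * frac * (1 - frac)
    vterm = np.where((at_risk > 1)[:, None], vterm, 0.0)
    var = vterm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, o_minus_e / np.sqrt(var), 0.0)
    return o_minus_e, var, z


def logrank_test(d: SurvivalData, groups) -> TestResult:
    """Log-rank test across two or more groups (chi-square, k-1 df)."""
    labels = pd.Series(list(groups))
    if len(labels) != len(d):
        raise ValueError("group labels must align with survival data")
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("log-rank needs at least two groups")
    if d.event.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    if len(levels) == 2:
        in1 = (labels == levels[0]).to_numpy()
        oe, var, _ = _logrank_scan(d.time, d.event, in1)
        if var[0] <= 0:
            return TestResult(0.0, 1.0, "logrank", int(in1.sum()), int((~in1).sum()))
        chi2 = float(oe[0] ** 2 / var[0])
        p = float(stats.chi2.sf(chi2, df=1))
        return TestResult(chi2, p, "logrank", int(in1.sum()), int((~in1).sum()))
    # k-group version: vector O-E with hypergeometric covariance
    k = len(levels)
    order = np.argsort(d.time, kind="stable")
    t, e = d.time[order], d.event[order]
    G = np.stack([(labels.to_numpy()[order] == lv) for lv in levels], axis=1).astype(float)
    _, first = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e, first)
    at_risk = t.size - first
    n_g = np.cumsum(G[::-1], axis=0)[::-1][first]
    d_g = np.add.reduceat(e[:, None] * G, first, axis=0)
    oe = np.zeros(k)
    cov = np.zeros((k, k))
    for i in range(deaths.size):
        dtot, n = deaths[i], at_risk[i]
        if dtot == 0:
            continue
        frac = n_g[i] / n
        oe += d_g[i] - dtot * frac
        if n > 1:
            adj = dtot * (n - dtot) / (n - 1)
            cov += adj * (np.diag(frac) - np.outer(frac, frac))
    sub = slice(0, k - 1)
    try:
        chi2 = float(oe[sub] @ np.linalg.solve(cov[sub, sub], oe[sub]))
    except np.linalg.LinAlgError:
        chi2 = float(oe[sub] @ np.linalg.pinv(cov[sub, sub]) @ oe[sub])
    p = float(stats.chi2.sf(chi2, df=k - 1))
    sizes = labels.value_counts()
    return TestResult(chi2, p, f"logrank_{k}group", int(sizes.iloc[0]), int(sizes.iloc[1]))


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    se: float
    wald_p: float
    n: int
    n_events: int
    ties: str


def _cox_loglik_derivs(beta: float, t, e, x, ties: str):
    """Partial log-likelihood, score and information for a scalar covariate."""
    order = np.argsort(t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    w = np.exp(beta * xs)
    # suffix sums over risk sets (time >= t_i)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xs)[::-1])[::-1]
    s2 = np.cumsum((w * xs**2)[::-1])[::-1]
    times, first = np.unique(ts, return_index=True)
    ll = 0.0
    score = 0.0
    info = 0.0
    for i, t0 in enumerate(times):
        start = first[i]
        stop = first[i + 1] if i + 1 < times.size else ts.size
        ev = slice(start, stop)
        d_idx = np.nonzero(es[ev])[0] + start
        dcount = d_idx.size
        if dcount == 0:
            continue
        xsum = xs[d_idx].sum()
        S0, S1, S2 = s0[start], s1[start], s2[start]
        if ties == "breslow":
            ll += beta * xsum - dcount * math.log(S0)
            score += xsum - dcount * S1 / S0
            info += dcount * (S2 / S0 - (S1 / S0) ** 2)
        else:  # efron
            wd = w[d_idx]
            t0_, t1_, t2_ = wd.sum(), (wd * xs[d_idx]).sum(), (wd * xs[d_idx] ** 2).sum()
            ll += beta * xsum
            score += xsum
            for j in range(dcount):
                f = j / dcount
                D0 = S0 - f * t0_
                D1 = S1 - f * t1_
                D2 = S2 - f * t2_
                ll -= math.log(D0)
                score -= D1 / D0
                info += D2 / D0 - (D1 / D0) ** 2
    return ll, score, info


def cox_univariate(d: SurvivalData, covariate, ties: str = "breslow",
                   max_iter: int = 50, tol: float = 1e-9) -> CoxResult:
    """Univariate Cox PH fit by Newton-Raphson with step halving."""
    x = np.asarray(covariate, dtype=float)
    if x.shape != d.time.shape:
        raise ValueError("covariate must align with survival data")
    if np.all(x == x[0]):
        raise ValueError("constant covariate")
    if d.event.sum() == 0:
        raise ValueError("no events observed")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    # center and scale for numerical stability
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd
    beta = 0.0
    ll, score, info = _cox_loglik_derivs(beta, d.time, d.event, xs, ties)
    for _ in range(max_iter):
        if info <= 0:
            raise ConvergenceError("non-positive information; cannot maximize")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik_derivs(new_beta, d.time, d.event, xs, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik_derivs(new_beta, d.time, d.event, xs, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > 30:
            raise ConvergenceError(
                "partial likelihood appears monotone (perfect separation of events)"
            )
        if abs(step) < tol:
            break
    else:
        if abs(score) > 1e-4:
            raise ConvergenceError("Newton-Raphson did not converge")
    beta_orig = beta / sd
    se_orig = math.sqrt(1.0 / info) / sd
    wald_p = float(2.0 * stats.norm.sf(abs(beta_orig) / se_orig))
    return CoxResult(beta_orig, math.exp(beta_orig), se_orig, wald_p,
                     n=len(d), n_events=int(d.event.sum()), ties=ties)


@dataclass
class CutpointResult:
    cutpoint: float
    labels: pd.Series  # "high" / "low" per sample
    statistic: float  # signed standardized log-rank Z for the high group
    p_value: float
    n_high: int
    n_low: int


def optimal_cutpoint(d: SurvivalData, expression, minprop: float = 0.2) -> CutpointResult:
    """Maximally selected log-rank cutpoint.

    Candidate cutpoints are midpoints between consecutive distinct sorted
    expression values leaving both groups with at least ceil(minprop*n)
    members; the candidate maximizing |Z| wins, ties resolved toward the
    smallest cutpoint. The reported p is the unadjusted log-rank p at the
    selected cutpoint.
    """
    expr = pd.Series(expression)
    x = expr.to_numpy(dtype=float)
    n = x.size
    if n != len(d):
        raise ValueError("expression must align with survival data")
    if np.unique(x).size < 2:
        raise ValueError("constant expression: no cutpoint exists")
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    min_group = math.ceil(minprop * n)
    n_high = (x[None, :] > mids[:, None]).sum(axis=1)
    admissible = (n_high >= min_group) & ((n - n_high) >= min_group)
    if not admissible.any():
        raise ValueError("no admissible cutpoint under minprop constraint")
    mids = mids[admissible]
    high = x[:, None] > mids[None, :]
    _, _, z = _logrank_scan(d.time, d.event, high)
    zabs = np.abs(z)
    best = np.flatnonzero(zabs >= zabs.max() - 1e-12)[0]  # mids ascending: first = smallest
    cut = float(mids[best])
    in_high = x > cut
    oe, var, _ = _logrank_scan(d.time, d.event, in_high)
    chi2 = float(oe[0] ** 2 / var[0]) if var[0] > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var[0] > 0 else 1.0
    labels = pd.Series(np.where(in_high, "high", "low"), index=expr.index, name="stratum")
    return CutpointResult(cut, labels, float(z[best]), p,
                          int(in_high.sum()), int((~in_high).sum()))


@dataclass
class ScreenResult:
    table: pd.DataFrame
    n_significant: int
    n_favourable_high: int


def _direction(d: SurvivalData, in_high: np.ndarray) -> str:
    km_high = km_estimate(SurvivalData(d.time[in_high], d.event[in_high]))
    km_low = km_estimate(SurvivalData(d.time[~in_high], d.event[~in_high]))
    m_high, m_low = km_high.median(), km_low.median()
    if math.isnan(m_high) and math.isnan(m_low):
        return "favourable_high" if km_high.final_survival > km_low.final_survival else "favourable_low"
    if math.isnan(m_high):
        return "favourable_high"
    if math.isnan(m_low):
        return "favourable_low"
    return "favourable_high" if m_high > m_low else "favourable_low"


def survival_screen(
    circ_counts: pd.DataFrame,
    s: pd.Series,
    d: SurvivalData,
    top_k: int = 100,
    rank_by: str = "abundance",
    de_table: Optional[pd.DataFrame] = None,
    minprop: float = 0.2,
) -> ScreenResult:
    """Optimal-cutpoint survival screening of the top-ranked circRNAs.

    Features are ranked by mean size-factor-normalized count (``abundance``)
    or by a supplied DE table (``de_table``, most significant first). The
    summary counts features with unadjusted log-rank p < 0.05 and, among
    those, features where high expression is the favourable group.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if d.sample_ids is not None:
        missing = set(d.sample_ids) - set(circ_counts.columns)
        if missing:
            raise ValueError(f"survival samples missing from counts: {sorted(missing)}")
        counts = circ_counts[list(d.sample_ids)]
    else:
        if circ_counts.shape[1] != len(d):
            raise ValueError("counts and survival data are not aligned")
        counts = circ_counts
    norm = counts / s[counts.columns]
    if rank_by == "abundance":
        ranking = norm.mean(axis=1).sort_values(ascending=False, kind="stable")
        ordered = list(ranking.index)
    elif rank_by == "de_table":
        if de_table is None:
            raise ValueError("rank_by='de_table' requires de_table")
        de_sorted = de_table.sort_values(["p", "q"], kind="stable")
        ordered = [f for f in de_sorted.index if f in norm.index]
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    if top_k > len(ordered):
        log.warning("top_k=%d exceeds feature count %d; using all", top_k, len(ordered))
        top_k = len(ordered)
    rows = []
    for rank, feat in enumerate(ordered[:top_k], start=1):
        expr = norm.loc[feat]
        try:
            res = optimal_cutpoint(d, expr, minprop=minprop)
        except ValueError:
            rows.append({"feature_id": feat, "rank": rank, "cutpoint": np.nan,
                         "n_high": 0, "n_low": 0, "logrank_stat": np.nan,
                         "p": np.nan, "direction": "undetermined"})
            continue
        in_high = (res.labels == "high").to_numpy()
        rows.append({
            "feature_id": feat, "rank": rank, "cutpoint": res.cutpoint,
            "n_high": res.n_high, "n_low": res.n_low,
            "logrank_stat": res.statistic, "p": res.p_value,
            "direction": _direction(d, in_high),
        })
    table = pd.DataFrame(rows).set_index("feature_id", drop=False)
    valid = table["p"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_adjust(table.loc[valid, "p"].to_numpy())
    table["q_bh"] = q
    sig = table[valid & (table["p"] < 0.05)]
    return ScreenResult(
        table=table,
        n_significant=int(len(sig)),
        n_favourable_high=int((sig["direction"] == "favourable_high").sum()),
    )
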