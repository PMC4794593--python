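"""Rank and survival statistics used by every pipeline stage.

All tests are two-sided at alpha = 0.05 by default and no multiple-testing
correction is applied; report tables carry the number of tests run so users
can correct afterwards.  Conventions are fixed for reproducibility:

* mid-ranks for ties everywhere;
* Mann-Whitney U: exact enumeration when n_a + n_b <= 12 and there are no
  ties, otherwise a normal approximation with tie-corrected variance and a
  0.5 continuity correction;
* Spearman: exact permutation P for n <= 8, otherwise the t approximation
  with n - 2 degrees of freedom;
* Wilcoxon signed rank: zeros dropped, exact sign-pattern enumeration for
  <= 15 nonzero pairs, otherwise normal approximation with tie correction;
* Cox partial likelihood: Newton iterations with Breslow tie handling
  (Efron available), Wald confidence intervals;
* P values are floored at machine epsilon and printed as "<1e-16", never 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatError
from .io_formats import SurvivalRecord, survival_frame

_EPS = np.finfo(float).eps


def _floor_p(p: float) -> float:
    return float(min(1.0, max(p, _EPS)))


def format_p(p: float) -> str:
    """Text form of a P value; tiny values print as an upper bound."""
    return "<1e-16" if p <= 1e-16 else f"{p:.4g}"


def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the average of their rank range."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    sv = v[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# Spearman rank correlation


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    method: str = "approx"


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with two-sided P.

    NaN pairs are removed pairwise.  ``method`` is ``auto`` (exact
    permutation for n <= 8, else t approximation), ``exact`` or ``approx``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise StatError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatError("correlation undefined for a constant vector")
    rx, ry = midranks(x), midranks(y)
    rho = _rank_rho(rx, ry)
    if method == "auto":
        method = "exact" if n <= 8 else "approx"
    if method == "exact":
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    elif method == "approx":
        r = min(max(rho, -1.0), 1.0)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    else:
        raise StatError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, n=n, p_value=_floor_p(p), method=method)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class GroupComparison:
    u_statistic: float
    n_low: int
    n_high: int
    median_low: float
    median_high: float
    p_value: float
    direction: str  # increase / decrease / none, judged at alpha
    alpha: float = 0.05
    method: str = "approx"


def _exact_u_tail_p(u: float, n_a: int, n_b: int) -> float:
    """Two-sided exact P by enumerating all C(N, n_a) group labelings."""
    ranks = np.arange(1, n_a + n_b + 1)
    base = n_a * (n_a + 1) / 2.0
    us = np.fromiter(
        (sum(c) - base for c in itertools.combinations(ranks, n_a)),
        dtype=float,
    )
    total = len(us)
    # the null distribution is symmetric about n_a*n_b/2: sum both tails at
    # the distance of the observed U from the centre
    u_min = min(u, n_a * n_b - u)
    u_max = n_a * n_b - u_min
    p = (np.sum(us <= u_min + 1e-9) + np.sum(us >= u_max - 1e-9)) / total
    return min(1.0, p)


def mann_whitney_u(a, b, alpha: float = 0.05, method: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U comparing group ``b`` ("high") against ``a``.

    U is the statistic of the first group.  ``direction`` is "increase" when
    group b's median exceeds group a's and P < alpha, "decrease" for the
    reverse, otherwise "none".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise StatError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = midranks(combined)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    has_ties = len(np.unique(combined)) < len(combined)
    if method == "auto":
        method = "exact" if (n_a + n_b <= 12 and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise StatError("exact enumeration requires tie-free data")
        p = _exact_u_tail_p(u_a, n_a, n_b)
    elif method == "approx":
        n = n_a + n_b
        mu = n_a * n_b / 2.0
        _, counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            diff = abs(u_a - mu)
            z = max(diff - 0.5, 0.0) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(z)
    else:
        raise StatError(f"unknown method {method!r}")
    p = _floor_p(p)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if p < alpha and med_b > med_a:
        direction = "increase"
    elif p < alpha and med_b < med_a:
        direction = "decrease"
    else:
        direction = "none"
    return GroupComparison(
        u_statistic=u_a,
        n_low=n_a,
        n_high=n_b,
        median_low=med_a,
        median_high=med_b,
        p_value=p,
        direction=direction,
        alpha=alpha,
        method=method,
    )


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed rank


@dataclass
class WilcoxonResult:
    w_statistic: float
    n_nonzero: int
    p_value: float
    method: str = "approx"


def wilcoxon_signed_rank(paired_diffs, alpha: float = 0.05, method: str = "auto") -> WilcoxonResult:
    """Wilcoxon matched-pairs test on paired differences (two-sided).

    Zero differences are dropped; W is the smaller of the positive and
    negative signed-rank sums.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise StatError("all paired differences are zero: test degenerate")
    ranks = midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    if method == "auto":
        method = "exact" if n <= 15 else "approx"
    if method == "exact":
        # All 2^n sign assignments are equally likely under H0.
        total = 2**n
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        hi = ranks.sum() - w
        count = int(np.sum(sums <= w + 1e-9) + np.sum(sums >= hi - 1e-9))
        p = min(1.0, count / total)
    elif method == "approx":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(w - mu) - 0.5, 0.0) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(z)
    else:
        raise StatError(f"unknown method {method!r}")
    return WilcoxonResult(w_statistic=w, n_nonzero=n, p_value=_floor_p(p), method=method)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class SurvivalFit:
    km_curves: dict | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    cox: pd.DataFrame | None = None
    converged: bool = True
    n_events: int = 0
    extras: dict = field(default_factory=dict)


def _times_events(group) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(group, pd.DataFrame):
        return group["time"].to_numpy(float), group["event"].to_numpy(bool)
    times = np.array([r.time for r in group], dtype=float)
    events = np.array([r.event for r in group], dtype=bool)
    return times, events


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate, one row per distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    for t in np.unique(times[events]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def km_logrank(groups: dict | list) -> SurvivalFit:
    """Kaplan-Meier curves per group and the k-sample log-rank test.

    ``groups`` maps a label to a list of SurvivalRecord (or a DataFrame with
    time/event columns); a plain list gets integer labels.
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    if len(groups) < 2:
        raise StatError("log-rank needs >= 2 groups")
    data = {}
    for label, g in groups.items():
        t, e = _times_events(g)
        if len(t) == 0:
            raise StatError(f"group {label!r} is empty")
        data[label] = (t, e)
    labels = list(data)
    total_events = sum(int(e.sum()) for _, e in data.values())
    if total_events == 0:
        raise StatError("no events in any group: log-rank undefined")
    curves = {lab: km_curve(*data[lab]) for lab in labels}
    all_event_times = np.unique(
        np.concatenate([t[e] for t, e in data.values()])
    )
    k = len(labels)
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in all_event_times:
        n_j = np.array([np.sum(tt >= t) for tt, _ in data.values()], dtype=float)
        d_j = np.array([np.sum(ee & (tt == t)) for tt, ee in data.values()], dtype=float)
        n = n_j.sum()
        d = d_j.sum()
        if n <= 1 or d == 0:
            continue
        e_j = d * n_j / n
        o_minus_e += d_j - e_j
        c = d * (n - d) / (n - 1.0)
        cov += c * (np.diag(n_j / n) - np.outer(n_j / n, n_j / n))
    v = cov[: k - 1, : k - 1]
    u = o_minus_e[: k - 1]
    if np.allclose(u, 0.0):
        chi2 = 0.0
    else:
        chi2 = float(u @ np.linalg.pinv(v) @ u)
    p = _floor_p(float(sps.chi2.sf(chi2, df=k - 1)))
    return SurvivalFit(
        km_curves=curves,
        logrank_chi2=max(chi2, 0.0),
        logrank_p=p,
        n_events=total_events,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def cox_ph(
    data,
    covariates: list[str],
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> SurvivalFit:
    """Cox proportional-hazards fit by Newton maximization of the partial
    likelihood.

    ``data`` is a DataFrame with ``time``/``event`` columns or a list of
    SurvivalRecord whose covariates include every requested name.  Ties are
    handled by the Breslow approximation (``ties="efron"`` for Efron).
    Returns hazard ratios with 95% Wald intervals; a fit that fails to
    converge is returned flagged, never silently.
    """
    if not isinstance(data, pd.DataFrame):
        data = survival_frame(data)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise StatError(f"covariates missing from data: {missing}")
    df = data.dropna(subset=["time", "event", *covariates])
    t = df["time"].to_numpy(float)
    e = df["event"].to_numpy(float).astype(bool)
    x = df[covariates].to_numpy(float)
    n, p = x.shape
    if e.sum() == 0:
        raise StatError("no events: Cox model undefined")
    for j, name in enumerate(covariates):
        if np.all(x[:, j] == x[0, j]):
            raise StatError(f"covariate {name!r} is constant")
    # standardize for numerical stability; back-transform at the end
    mean, sd = x.mean(axis=0), x.std(axis=0)
    xs_std = (x - mean) / sd

    order = np.argsort(-t, kind="stable")
    ts, es, xv = t[order], e[order], xs_std[order]
    event_times = np.unique(ts[es])
    # index of last row (0-based) in the risk set for each event time
    risk_idx = np.searchsorted(-ts, -event_times, side="right") - 1
    d_counts = []
    sum_x = []
    w_masks = []
    for tu in event_times:
        mask = es & (ts == tu)
        d_counts.append(int(mask.sum()))
        sum_x.append(xv[mask].sum(axis=0))
        w_masks.append(mask)
    beta = np.zeros(p)
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = xv @ beta
        shift = eta.max()  # overflow guard; added back in every log term
        w = np.exp(eta - shift)
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * xv, axis=0)
        S2 = np.cumsum(np.einsum("i,ij,ik->ijk", w, xv, xv), axis=0)
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for tu_i, tu in enumerate(event_times):
            kidx = risk_idx[tu_i]
            d = d_counts[tu_i]
            sx = sum_x[tu_i]
            if ties == "efron" and d > 1:
                mask = w_masks[tu_i]
                wd = w[mask].sum()
                s1d = (w[mask, None] * xv[mask]).sum(axis=0)
                s2d = np.einsum("i,ij,ik->jk", w[mask], xv[mask], xv[mask])
                ll += float(sx @ beta)
                for l in range(d):
                    f = l / d
                    s0l = S0[kidx] - f * wd
                    s1l = S1[kidx] - f * s1d
                    s2l = S2[kidx] - f * s2d
                    ll -= math.log(s0l) + shift
                    grad_term = s1l / s0l
                    grad -= grad_term
                    hess -= s2l / s0l - np.outer(grad_term, grad_term)
                grad += sx
            else:
                s0 = S0[kidx]
                s1 = S1[kidx]
                s2 = S2[kidx]
                ll += float(sx @ beta) - d * (math.log(s0) + shift)
                grad += sx - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise StatError("singular information matrix (perfect separation?)") from exc
        # step halving if the likelihood does not improve
        scale = 1.0
        while scale > 1e-4:
            new_beta = beta + scale * step
            if _cox_loglik(new_beta, xv, event_times, risk_idx, d_counts, sum_x) >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            loglik = ll
            break
        loglik = ll
    info = -hess
    cov = np.linalg.inv(info)
    se_std = np.sqrt(np.diag(cov))
    # back to original covariate scale
    beta_orig = beta / sd
    se_orig = se_std / sd
    z = beta_orig / se_orig
    pvals = np.array([_floor_p(2.0 * sps.norm.sf(abs(zi))) for zi in z])
    table = pd.DataFrame(
        {
            "coef": beta_orig,
            "hr": np.exp(beta_orig),
            "ci_low": np.exp(beta_orig - 1.959963984540054 * se_orig),
            "ci_high": np.exp(beta_orig + 1.959963984540054 * se_orig),
            "se": se_orig,
            "p_value": pvals,
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return SurvivalFit(cox=table, converged=converged, n_events=int(e.sum()), extras={"loglik": loglik, "n": n})


def _cox_loglik(beta, xv, event_times, risk_idx, d_counts, sum_x) -> float:
    eta = xv @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    S0 = np.cumsum(w)
    ll = 0.0
    for i, _ in enumerate(event_times):
        ll += float(sum_x[i] @ beta) - d_counts[i] * (math.log(S0[risk_idx[i]]) + shift)
    return ll
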