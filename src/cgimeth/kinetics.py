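"""Re-methylation kinetics after 5-aza-dC demethylation.

Cells treated with 5-aza-2'-deoxycytidine passively lose DNA methylation
and then recover it over ~3 weeks. If recovery were driven purely by the
outgrowth of cells that escaped demethylation, every CGI's methylation
trajectory would be proportional to its starting level, so trajectories
normalised to day 0 would be identical across CGIs. The alternative is
that CGIs re-methylate at genuinely different rates (de novo activity).

The two hypotheses are encoded as linear mixed models on the day-0
normalised methylation m over days 3-22 inclusive::

    null:         m ~ t + (1 | CGI)          (random intercept)
    alternative:  m ~ t + (1 + t | CGI)      (random intercept + slope)

Both are fitted by maximum likelihood and compared by a likelihood-ratio
test. The naive chi-square reference (df = number of added covariance
parameters) is conservative because the slope variance sits on the
boundary of its parameter space under the null.

Per-CGI recovery rates are ordinary least-squares slopes of each CGI's
normalised trajectory over days 3-22; the slope is the fraction of day-0
methylation recovered per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "normalise_timecourse",
    "test_rate_heterogeneity",
    "fit_cgi_recovery_rates",
    "compare_rate_groups",
    "HeterogeneityTest",
]


@dataclass(frozen=True)
class HeterogeneityTest:
    """Result of the outgrowth-null vs heterogeneous-rate model comparison."""

    loglik_null: float
    loglik_alt: float
    lr_statistic: float
    df_difference: int
    p_value: float
    n_cgis: int
    timepoints: tuple[float, ...]
    converged: bool


def _timecourse_wide(tc: pd.DataFrame) -> pd.DataFrame:
    """Accept wide (cgi x day) or long (cgi, day, beta) tables; return wide."""
    if {"cgi", "day", "beta"}.issubset(tc.columns):
        wide = tc.pivot(index="cgi", columns="day", values="beta")
    else:
        wide = tc.copy()
    wide.columns = [float(c) for c in wide.columns]
    return wide[sorted(wide.columns)]


def normalise_timecourse(tc: pd.DataFrame, day0_min: float = 0.5) -> pd.DataFrame:
    """Normalise each CGI's trajectory to its own day-0 methylation.

    Only CGIs with day-0 mean methylation strictly greater than
    ``day0_min`` (default 50%) are retained; each retained row is divided
    by its day-0 value, so the normalised day-0 value is exactly 1.
    Normalised values may exceed 1 and are not clipped.

    Accepts a wide (CGI x day) or long (``cgi``, ``day``, ``beta``) table;
    returns a wide table.
    """
    wide = _timecourse_wide(tc)
    if 0.0 not in wide.columns:
        raise ValueError("day 0 must be present for normalisation")
    day0 = wide[0.0]
    included = wide.loc[day0 > day0_min]
    if (included[0.0] <= 0).any():
        raise ValueError("day-0 methylation must be positive for included CGIs")
    return included.div(included[0.0], axis=0)


# ---------------------------------------------------------------------------
# Profiled maximum likelihood for the random-intercept(+slope) model.
#
# Model: y_g = X_g beta + Z_g b_g + e,  b_g ~ N(0, sigma^2 D),  e ~ N(0, sigma^2 I).
# D is parametrised through its Cholesky factor (log-diagonal for
# positivity); beta and sigma^2 are profiled out analytically, leaving a
# 1-parameter (intercept-only) or 3-parameter (correlated intercept+slope)
# optimisation. Groups sharing an observation-time pattern share the
# marginal covariance, so balanced designs cost one small matrix inverse
# per likelihood evaluation.
# ---------------------------------------------------------------------------


def _chol_from_params(params: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(params[idx]) if i == j else params[idx]
            idx += 1
    return L


def _profiled_nll(params, groups, q):
    """Negative profiled log-likelihood over D (beta, sigma^2 profiled out)."""
    L = _chol_from_params(np.asarray(params, dtype=float), q)
    D = L @ L.T
    xtwx = None
    xtwy = None
    logdet_sum = 0.0
    n_total = 0
    cache = []
    for X, Z, Y in groups:  # Y: n_groups_in_pattern x n_t
        n_t = Z.shape[0]
        W = np.eye(n_t) + Z @ D @ Z.T
        Wi = np.linalg.inv(W)
        _, logdetW = np.linalg.slogdet(W)
        g = Y.shape[0]
        logdet_sum += g * logdetW
        n_total += g * n_t
        XtWi = X.T @ Wi
        contrib_xx = g * (XtWi @ X)
        contrib_xy = XtWi @ Y.sum(axis=0)
        xtwx = contrib_xx if xtwx is None else xtwx + contrib_xx
        xtwy = contrib_xy if xtwy is None else xtwy + contrib_xy
        cache.append((X, Wi, Y))
    beta = np.linalg.solve(xtwx, xtwy)
    quad = 0.0
    for X, Wi, Y in cache:
        R = Y - (X @ beta)[None, :]
        quad += float(np.einsum("gi,ij,gj->", R, Wi, R))
    sigma2 = quad / n_total
    nll = 0.5 * (n_total * np.log(2.0 * np.pi * sigma2) + logdet_sum + n_total)
    return nll


def _fit_lmm_ml(long: pd.DataFrame, random_slope: bool) -> tuple[float, bool]:
    """Maximised log-likelihood of m ~ t with random intercept (+ slope) by CGI."""
    q = 2 if random_slope else 1
    # group rows by identical timepoint pattern for shared covariance algebra
    patterns: dict[tuple[float, ...], list[np.ndarray]] = {}
    for _, sub in long.groupby("cgi", sort=False):
        t = tuple(sub["day"].to_numpy(dtype=float))
        patterns.setdefault(t, []).append(sub["m"].to_numpy(dtype=float))
    groups = []
    for t, ys in patterns.items():
        tv = np.asarray(t)
        X = np.column_stack([np.ones(len(tv)), tv])
        Z = X[:, :q].copy()
        groups.append((X, Z, np.vstack(ys)))

    n_par = q * (q + 1) // 2
    starts = [np.full(n_par, -1.0)]
    if n_par == 3:
        starts.append(np.array([0.0, 0.0, 0.0]))
        starts.append(np.array([-3.0, 0.0, -3.0]))
    else:
        starts.append(np.array([0.0]))
    best = None
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                _profiled_nll, x0, args=(groups, q), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
            )
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), bool(best.success)


def test_rate_heterogeneity(
    ntc: pd.DataFrame, t_min: float = 3.0, t_max: float = 22.0
) -> HeterogeneityTest:
    """Likelihood-ratio test of per-CGI recovery-rate heterogeneity.

    Fits the random-intercept (outgrowth null) and correlated
    random-intercept + random-slope models by maximum likelihood on
    normalised methylation at timepoints in ``[t_min, t_max]`` (inclusive)
    and compares them with a chi-square likelihood-ratio test with
    ``df = 2`` (slope variance + intercept-slope covariance). The boundary
    of the variance parameter makes this reference conservative.

    A small p-value rejects the hypothesis that re-methylation is due
    solely to the outgrowth of cells that escaped demethylation.
    """
    wide = _timecourse_wide(ntc)
    days = [d for d in wide.columns if t_min <= d <= t_max]
    if len(days) < 3:
        raise ValueError(f"need >= 3 timepoints in [{t_min}, {t_max}]")
    if wide.shape[0] < 2:
        raise ValueError("random effects are unidentifiable with a single CGI")
    long = (
        wide[days]
        .reset_index()
        .melt(id_vars=wide.index.name or "index", var_name="day", value_name="m")
        .rename(columns={wide.index.name or "index": "cgi"})
        .dropna(subset=["m"])
    )
    ll0, conv0 = _fit_lmm_ml(long, random_slope=False)
    ll1, conv1 = _fit_lmm_ml(long, random_slope=True)
    if not np.isfinite(ll0) or not np.isfinite(ll1):
        raise RuntimeError(
            f"mixed-model fit did not converge (loglik null={ll0}, alt={ll1})"
        )
    lr = max(2.0 * (ll1 - ll0), 0.0)
    df = 2
    p = float(stats.chi2.sf(lr, df))
    return HeterogeneityTest(
        loglik_null=ll0,
        loglik_alt=ll1,
        lr_statistic=lr,
        df_difference=df,
        p_value=p,
        n_cgis=int(wide.shape[0]),
        timepoints=tuple(days),
        converged=conv0 and conv1,
    )


def fit_cgi_recovery_rates(
    ntc: pd.DataFrame,
    t_min: float = 3.0,
    t_max: float = 22.0,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-CGI OLS recovery rates over days ``t_min``..``t_max`` inclusive.

    The slope of each CGI's normalised trajectory is the fraction of its
    day-0 methylation recovered per day. CGIs with fewer than two distinct
    in-range timepoints are skipped (``fitted = False``).

    ``groups`` optionally labels CGIs (e.g. H3K36me3-marked vs other) for
    downstream group contrasts.

    Returns columns ``cgi``, ``slope``, ``intercept``, ``n_points``,
    ``fitted`` and, when provided, ``group``.
    """
    wide = _timecourse_wide(ntc)
    days = np.array([d for d in wide.columns if t_min <= d <= t_max])
    records = []
    for cgi, row in wide[list(days)].iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        t_obs = days[ok]
        if len(np.unique(t_obs)) < 2:
            records.append((cgi, np.nan, np.nan, int(ok.sum()), False))
            continue
        slope, intercept = np.polyfit(t_obs, y[ok], 1)
        records.append((cgi, float(slope), float(intercept), int(ok.sum()), True))
    out = pd.DataFrame(
        records, columns=["cgi", "slope", "intercept", "n_points", "fitted"]
    )
    if groups is not None:
        out["group"] = out["cgi"].map(groups)
    return out


def compare_rate_groups(
    rates: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum comparison of recovery rates by group.

    Returns ``(median_a, median_b, p_value)``.
    """
    a = rates.loc[rates["group"] == group_a, "slope"].dropna().to_numpy()
    b = rates.loc[rates["group"] == group_b, "slope"].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    result = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(result.pvalue)
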