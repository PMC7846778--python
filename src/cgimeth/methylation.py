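"""CGI methylation quantification and differential gain calling.

The central container is the CpG count table: a :class:`pandas.DataFrame`
with columns ``chrom``, ``pos`` (1-based CpG coordinate, strand-combined)
and, per sample, ``{sample}_meth`` / ``{sample}_unmeth`` read counts.

CGI-level methylation is the coverage-weighted mean beta: pooled methylated
reads over pooled total reads across the CpGs inside the island. A CGI is
called a methylation "gainer" between two conditions when the BH-adjusted
two-sided Fisher's exact p-value on the pooled counts is < 0.05 and the
beta difference is >= 0.20 (both thresholds inclusive as written).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

__all__ = [
    "samples_in",
    "filter_cpgs",
    "cgi_weighted_methylation",
    "call_methylation_gain",
    "fisher_two_sided",
    "benjamini_hochberg",
    "call_methylated_by_beta",
    "summarise_clones",
    "mass_spec_5mc_percent",
]


def samples_in(table: pd.DataFrame) -> list[str]:
    """Sample names present in a CpG count table."""
    return [c[: -len("_meth")] for c in table.columns if c.endswith("_meth")]


def filter_cpgs(
    table: pd.DataFrame, min_coverage: int = 10, samples: Iterable[str] | None = None
) -> pd.DataFrame:
    """Keep CpGs with coverage >= ``min_coverage`` in *every* listed sample.

    Coverage is methylated + unmethylated reads; the boundary is inclusive
    (coverage exactly ``min_coverage`` is retained).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    use = list(samples) if samples is not None else samples_in(table)
    known = set(samples_in(table))
    unknown = [s for s in use if s not in known]
    if unknown:
        raise KeyError(f"unknown sample name(s): {unknown}")
    mask = np.ones(len(table), dtype=bool)
    for s in use:
        cov = table[f"{s}_meth"].to_numpy() + table[f"{s}_unmeth"].to_numpy()
        mask &= cov >= min_coverage
    return table.loc[mask].reset_index(drop=True)


def cgi_weighted_methylation(
    table: pd.DataFrame, cgis: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Coverage-weighted mean methylation per CGI per sample.

    Per CGI and sample the weighted mean is pooled methylated reads over
    pooled total reads across contained CpGs (a CpG at 1-based position p
    lies in a half-open island [start, end) when start < p <= end, i.e.
    0-based p-1 in [start, end)). CGIs containing no usable CpGs are
    reported with missing betas, not zeros.

    Returns a long-format frame with columns ``cgi``, ``sample``, ``beta``,
    ``n_cpgs``, ``pooled_meth``, ``pooled_unmeth``.
    """
    samples = samples_in(table)
    pos0 = table["pos"].to_numpy() - 1  # to 0-based
    chroms = table["chrom"].to_numpy()
    rows = []
    for cgi in cgis:
        cgi_id = cgi.name or f"{cgi.chrom}:{cgi.start}-{cgi.end}"
        sel = (chroms == cgi.chrom) & (pos0 >= cgi.start) & (pos0 < cgi.end)
        n = int(sel.sum())
        for s in samples:
            if n == 0:
                rows.append((cgi_id, s, np.nan, 0, 0, 0))
                continue
            meth = int(table.loc[sel, f"{s}_meth"].sum())
            unmeth = int(table.loc[sel, f"{s}_unmeth"].sum())
            beta = meth / (meth + unmeth) if meth + unmeth > 0 else np.nan
            rows.append((cgi_id, s, beta, n, meth, unmeth))
    return pd.DataFrame(
        rows, columns=["cgi", "sample", "beta", "n_cpgs", "pooled_meth", "pooled_unmeth"]
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_two_sided(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    chunk: int = 20_000,
) -> np.ndarray:
    """Two-sided Fisher's exact p for arrays of 2x2 tables [[a, b], [c, d]].

    p is the hypergeometric probability mass of all tables (at the observed
    margins) no more likely than the observed one, with the usual relative
    tolerance on the equality comparison. Vectorised through log-gamma so
    large batches of CGIs are tested in one pass.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    n = a + b + c + d
    row = a + b
    col = a + c
    out = np.empty(len(a), dtype=float)
    for lo in range(0, len(a), chunk):
        sl = slice(lo, lo + chunk)
        ni, ri, ci, ai = n[sl], row[sl], col[sl], a[sl]
        k_min = np.maximum(0, ri + ci - ni)
        k_max = np.minimum(ri, ci)
        width = int((k_max - k_min).max()) + 1 if len(ni) else 1
        k = k_min[:, None] + np.arange(width)[None, :]
        valid = k <= k_max[:, None]
        kc = np.where(valid, k, 0)
        logpmf = (
            gammaln(ci + 1)[:, None]
            - gammaln(kc + 1) - gammaln((ci[:, None] - kc) + 1)
            + gammaln(ni - ci + 1)[:, None]
            - gammaln((ri[:, None] - kc) + 1)
            - gammaln((ni - ci - ri)[:, None] + kc + 1)
            - (gammaln(ni + 1) - gammaln(ri + 1) - gammaln(ni - ri + 1))[:, None]
        )
        pmf = np.where(valid, np.exp(logpmf), 0.0)
        obs = np.take_along_axis(pmf, (ai - k_min)[:, None], axis=1)
        out[sl] = np.minimum(
            (pmf * (pmf <= obs * (1 + 1e-7))).sum(axis=1), 1.0
        )
    return out


def call_methylation_gain(
    meth_a: pd.DataFrame,
    meth_b: pd.DataFrame,
    min_gain: float = 0.20,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Call CGIs gaining methylation from condition A to condition B.

    Inputs are single-sample slices of :func:`cgi_weighted_methylation`
    output (columns ``cgi``, ``pooled_meth``, ``pooled_unmeth``, ``beta``).
    Per CGI a two-sided Fisher's exact test is run on the 2x2 table of
    pooled (methylated, unmethylated) counts by condition; p-values are
    BH-adjusted across all tested CGIs. A CGI is a gainer when
    ``q_value < fdr`` and ``delta_beta >= min_gain``.

    CGIs with missing methylation in either condition are excluded from
    testing and returned with ``tested = False``.
    """
    a = meth_a.set_index("cgi")
    b = meth_b.set_index("cgi")
    common = a.index.intersection(b.index)
    ma = a.loc[common, "pooled_meth"].to_numpy(dtype=np.int64)
    ua = a.loc[common, "pooled_unmeth"].to_numpy(dtype=np.int64)
    mb = b.loc[common, "pooled_meth"].to_numpy(dtype=np.int64)
    ub = b.loc[common, "pooled_unmeth"].to_numpy(dtype=np.int64)
    tested = (ma + ua > 0) & (mb + ub > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(tested, mb / (mb + ub) - ma / (ma + ua), np.nan)
    p = np.full(len(common), np.nan)
    if tested.any():
        p[tested] = fisher_two_sided(mb[tested], ub[tested],
                                     ma[tested], ua[tested])
    out = pd.DataFrame(
        {"cgi": common, "delta_beta": delta, "p_value": p, "tested": tested}
    ).reset_index(drop=True)
    out["q_value"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q_value"] = benjamini_hochberg(out.loc[tested, "p_value"])
    # small epsilon keeps the inclusive >= boundary robust to float
    # rounding in the beta difference (e.g. 0.3 - 0.1 < 0.2 in binary)
    out["is_gainer"] = (out["q_value"] < fdr) & (out["delta_beta"] >= min_gain - 1e-12)
    out["is_gainer"] = out["is_gainer"].fillna(False)
    return out


def call_methylated_by_beta(
    beta_matrix: pd.DataFrame, threshold: float = 0.3
) -> tuple[pd.DataFrame, pd.Series]:
    """Binary methylation calls on a CGI x sample beta matrix.

    A CGI is methylated in a sample when ``beta >= threshold`` (inclusive).
    Missing betas stay missing and are excluded from the per-CGI frequency
    denominator. Returns ``(flags, frequency)``.
    """
    values = beta_matrix.to_numpy(dtype=float)
    if np.nanmin(values) < 0 or np.nanmax(values) > 1:
        raise ValueError("betas must lie in [0, 1] or be missing")
    flags = beta_matrix >= threshold
    flags = flags.where(beta_matrix.notna())
    n_called = flags.notna().sum(axis=1)
    frequency = flags.sum(axis=1, skipna=True) / n_called
    return flags, frequency


def summarise_clones(
    clones: pd.DataFrame, max_error_fraction: float = 0.25
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Per-clone and per-CpG methylation from bisulfite-PCR clone calls.

    ``clones`` is a clone x CpG-position matrix with entries 1 (methylated),
    0 (unmethylated) or NaN (sequencing error / missing). Clones whose
    error fraction is >= ``max_error_fraction`` (inclusive, so exactly 25%
    errors is excluded at the default) are dropped before summarising.

    Returns ``(per_clone_mean, per_position_mean, excluded_clone_ids)``.
    """
    error_frac = clones.isna().sum(axis=1) / clones.shape[1]
    excluded = error_frac[error_frac >= max_error_fraction].index.tolist()
    kept = clones.drop(index=excluded)
    per_clone = kept.mean(axis=1, skipna=True)
    per_position = kept.mean(axis=0, skipna=True)
    return per_clone, per_position, [str(c) for c in excluded]


def mass_spec_5mc_percent(area_5mc: float, area_g: float) -> float:
    """Global 5mC level: 100 x (5-methylcytosine peak area / guanine peak area)."""
    if area_g <= 0:
        raise ValueError("guanine peak area must be > 0")
    if area_5mc < 0:
        raise ValueError("peak areas must be >= 0")
    return 100.0 * area_5mc / area_g
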