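"""ChIP-seq signal quantification with spike-in (ChIP-Rx) scaling.

Per-region signal is an input-normalised scaled count: ChIP and input
counts each get a 0.5 offset (so empty input windows cannot divide by
zero), are scaled to counts per 10 million mapped reads, and the ChIP
value is divided by the input value. Regions covered in no sample should
be removed before analysis (:func:`covered_regions`).

Between-sample quantitative scaling uses a foreign-genome chromatin
spike-in: the scaling factor for sample n against a reference is the
ratio of spike-in reads per 10^7 in the two ChIP runs divided by the same
ratio in the input runs (the input correction cancels differences in the
spike-in mixing proportion). With this definition a sample with globally
higher target occupancy has *fewer* spike-in reads per 10^7 and S < 1, so
its signal is divided by S (multiplied by 1/S) to land on the reference
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ChipSampleCounts",
    "NormalisedSignal",
    "RxScaling",
    "covered_regions",
    "normalised_signal",
    "rx_scaling_factor",
    "apply_rx_scaling",
    "decile_association",
    "fit_histone_model",
    "qpcr_percent_input",
    "heatmap_matrix",
]

_SCALE_BASIS = 1e7  # counts per 10 million mapped reads


@dataclass
class ChipSampleCounts:
    """Per-region read counts for one ChIP or input run.

    ``target_mapped_total`` and ``spikein_mapped_total`` are the run's
    total mapped reads on the target and spike-in genomes; the scaling
    basis for per-10^7 normalisation is their sum (the run's total mapped
    reads).
    """

    sample_id: str
    role: str  # "ChIP" | "input"
    counts: pd.Series  # indexed by region id
    target_mapped_total: int
    spikein_mapped_total: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("ChIP", "input"):
            raise ValueError("role must be 'ChIP' or 'input'")
        if self.target_mapped_total <= 0:
            raise ValueError("target_mapped_total must be > 0")
        if self.spikein_mapped_total < 0:
            raise ValueError("spikein_mapped_total must be >= 0")

    @property
    def total_mapped(self) -> int:
        return self.target_mapped_total + self.spikein_mapped_total

    @property
    def drptm(self) -> float:
        """Spike-in reads per 10^7 total mapped reads in this run."""
        if self.spikein_mapped_total <= 0:
            raise ValueError(
                f"run {self.sample_id}/{self.role} has no spike-in reads"
            )
        return _SCALE_BASIS * self.spikein_mapped_total / self.total_mapped


@dataclass
class NormalisedSignal:
    """Input-normalised per-region ChIP signal (unitless ratio)."""

    sample_id: str
    values: pd.Series
    offset: float = 0.5
    scale_basis: float = _SCALE_BASIS


@dataclass
class RxScaling:
    """Spike-in scaling factors S_n relative to a reference sample."""

    reference: str
    factors: dict[str, float] = field(default_factory=dict)

    def factor(self, sample_id: str) -> float:
        return self.factors[sample_id]

    def correction(self, sample_id: str) -> float:
        """Multiplier 1/S_n that places a sample on the reference scale."""
        return 1.0 / self.factors[sample_id]


def covered_regions(samples: list[ChipSampleCounts]) -> pd.Index:
    """Region ids with non-zero coverage in at least one sample."""
    total = None
    for s in samples:
        total = s.counts if total is None else total.add(s.counts, fill_value=0)
    return total.index[total > 0]


def normalised_signal(
    chip: ChipSampleCounts, input_: ChipSampleCounts, offset: float = 0.5
) -> NormalisedSignal:
    """Offset, per-10^7 scale, and input-normalise a ChIP run.

    value = [(c_ChIP + offset) * 1e7 / total_ChIP] /
            [(c_input + offset) * 1e7 / total_input]
    """
    if not chip.counts.index.equals(input_.counts.index):
        raise ValueError("ChIP and input runs cover different region sets")
    chip_scaled = (chip.counts + offset) * _SCALE_BASIS / chip.total_mapped
    input_scaled = (input_.counts + offset) * _SCALE_BASIS / input_.total_mapped
    return NormalisedSignal(chip.sample_id, chip_scaled / input_scaled, offset=offset)


def rx_scaling_factor(
    samples: dict[str, tuple[ChipSampleCounts, ChipSampleCounts]], reference: str
) -> RxScaling:
    """Input-corrected spike-in scaling factors.

    ``samples`` maps sample id to its (ChIP, input) run pair. For sample n
    against the reference:

        S_n = (dRPTM_ChIP-n / dRPTM_ChIP-ref) / (dRPTM_IN-n / dRPTM_IN-ref)

    where dRPTM is spike-in reads per 10^7 mapped reads of that run.
    The reference factor is exactly 1.
    """
    if reference not in samples:
        raise KeyError(f"reference sample {reference!r} not among samples")
    for sid, pair in samples.items():
        if len(pair) != 2:
            raise ValueError(f"sample {sid!r} must provide a (ChIP, input) pair")
    chip_ref, in_ref = samples[reference]
    factors = {}
    for sid, (chip_n, in_n) in samples.items():
        if sid == reference:
            factors[sid] = 1.0
        else:
            factors[sid] = (chip_n.drptm / chip_ref.drptm) / (in_n.drptm / in_ref.drptm)
    return RxScaling(reference=reference, factors=factors)


def apply_rx_scaling(signal: NormalisedSignal, factor: float) -> NormalisedSignal:
    """Multiply a sample's normalised signal by a scaling factor.

    Pass ``RxScaling.correction(sample)`` (= 1/S) to place a sample on the
    reference scale; replicate means are taken after scaling.
    """
    return NormalisedSignal(
        signal.sample_id, signal.values * factor,
        offset=signal.offset, scale_basis=signal.scale_basis,
    )


def decile_association(
    signal: pd.Series,
    response: pd.Series,
    n_groups: int = 10,
) -> tuple[pd.Series, pd.DataFrame, float, float]:
    """Rank CGIs by a signal, split into equal groups, and correlate.

    CGIs are ranked by ``signal`` and split into ``n_groups`` equally sized
    groups (remainder spread over the lowest groups); group summaries are
    the median and quartiles of ``response``. The Spearman correlation is
    computed over CGIs, not groups.

    Returns ``(group_assignment, group_summaries, rho, p_value)``.
    """
    signal, response = signal.align(response, join="inner")
    n = len(signal)
    if n < n_groups:
        raise ValueError(f"need >= {n_groups} observations, got {n}")
    if signal.nunique() < n_groups:
        warnings.warn("heavy ties in signal make rank groups degenerate")
    order = signal.rank(method="first").astype(int) - 1  # 0..n-1
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    edges = np.cumsum([0] + sizes)
    group = pd.Series(
        np.searchsorted(edges, order.to_numpy(), side="right") - 1,
        index=signal.index, name="group",
    )
    summaries = (
        pd.DataFrame({"group": group, "response": response})
        .groupby("group")["response"]
        .agg(median="median", q25=lambda x: x.quantile(0.25),
             q75=lambda x: x.quantile(0.75), n="size")
        .reset_index()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(signal.to_numpy(), response.to_numpy())
    return group, summaries, float(rho), float(p)


def fit_histone_model(response: pd.Series, predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS of a ChIP signal (e.g. DNMT3B level) on standardised histone marks.

    Predictors are z-scored so coefficients are comparable across marks.
    Returns a table with ``coef``, ``stderr``, ``t``, ``p`` per predictor
    (plus the intercept) and a ``collinear`` flag set when the design's
    condition number exceeds 1e6.
    """
    response, predictors = response.align(predictors, join="inner", axis=0)
    if predictors.shape[0] <= predictors.shape[1]:
        raise ValueError("need more observations than predictors")
    sds = predictors.std(ddof=0)
    if (sds == 0).any():
        raise ValueError(f"constant predictor(s): {list(sds.index[sds == 0])}")
    z = (predictors - predictors.mean()) / sds
    X = sm.add_constant(z)
    fit = sm.OLS(response.to_numpy(dtype=float), X).fit()
    cond = np.linalg.cond(X.to_numpy())
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "stderr": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    out["collinear"] = cond > 1e6
    out.attrs["condition_number"] = float(cond)
    out.attrs["r_squared"] = float(fit.rsquared)
    return out


def qpcr_percent_input(
    ct_ip: float, ct_input: float, input_fraction: float = 1.0
) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    The input Ct is first adjusted to represent 100% of chromatin
    (subtracting log2(1/input_fraction) cycles), then
    percent = 100 * 2^(ct_input_adjusted - ct_ip), assuming primer
    efficiency 2.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adjusted = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (ct_input_adjusted - ct_ip))


def heatmap_matrix(
    window_signal: pd.DataFrame, cap_quantile: float = 0.9
) -> tuple[pd.DataFrame, float, float, bool]:
    """Region x window matrix with a quantile-capped display range.

    Rows are ordered by mean signal (descending), ties broken by region id
    for determinism. The display maximum is the ``cap_quantile`` quantile
    (linear interpolation) of all values; values themselves are not
    truncated. Returns ``(matrix, display_min, display_max, degenerate)``
    where ``degenerate`` flags an empty display range.
    """
    values = window_signal.to_numpy(dtype=float)
    display_min = float(np.nanmin(values))
    display_max = float(np.nanquantile(values, cap_quantile))
    degenerate = display_max <= display_min
    order = (
        window_signal.mean(axis=1)
        .to_frame("mean")
        .assign(region=window_signal.index.astype(str))
        .sort_values(["mean", "region"], ascending=[False, True])
        .index
    )
    return window_signal.loc[order], display_min, display_max, degenerate
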