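"""Synthetic data generators with machine-readable ground truth.

Every downstream stage of the pipeline (gain calling, re-methylation
kinetics, spike-in ChIP scaling, term enrichment) is exercisable on the
output of these generators, whose truth tables record exactly what each
stage should recover. All generators are pure functions of their config
(including the seed): the same config reproduces identical output.

What is emulated, and what is not: per-CpG counts are binomial at a
CGI-level beta with Poisson (>= 1) coverage — no bisulfite conversion
error, no fragment-level sampling, no CpG density structure. Time-course
methylation follows the proportional-outgrowth null or a Gaussian
random-slope alternative with Gaussian observation noise on the beta
scale, clipped to [0, 1]. ChIP libraries are multinomial reads over
target regions plus a spike-in mass fraction — counts, not alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .ontology import TermGraph

__all__ = [
    "MethSimConfig",
    "KineticsSimConfig",
    "ChipSimConfig",
    "SimulatedMethylation",
    "SimulatedTimecourse",
    "SimulatedChip",
    "SimulatedOntology",
    "simulate_cpg_counts",
    "simulate_timecourse",
    "simulate_chip_experiment",
    "simulate_ontology",
]

DEFAULT_TIMEPOINTS = (0.0, 3.0, 6.0, 10.0, 14.0, 18.0, 22.0)


# ---------------------------------------------------------------------------
# RRBS-like CpG counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethSimConfig:
    """Two-condition per-CpG bisulfite count simulation.

    ``baseline_beta`` is either a single beta applied to all CGIs or a
    ``(low, high, p_high)`` mixture of a low and a high methylation mode.
    Gainer CGIs get ``beta + gain_size`` in condition B; the config is
    rejected when that exceeds 1 for any eligible CGI.
    """

    n_cgis: int = 500
    cpgs_per_cgi: int | tuple[int, int] = 8
    coverage_mean: float = 30.0
    baseline_beta: float | tuple[float, float, float] = 0.1
    gainer_fraction: float = 0.2
    gain_size: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cgis < 1:
            raise ValueError("n_cgis must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0 <= self.gainer_fraction <= 1:
            raise ValueError("gainer_fraction must be in [0, 1]")
        if not 0 <= self.gain_size <= 1:
            raise ValueError("gain_size must be in [0, 1]")
        betas = (
            (self.baseline_beta,)
            if isinstance(self.baseline_beta, (int, float))
            else self.baseline_beta[:2]
        )
        for b in betas:
            if not 0 <= b <= 1:
                raise ValueError("baseline betas must be in [0, 1]")
            if self.gainer_fraction > 0 and b + self.gain_size > 1:
                raise ValueError(
                    f"gain_size {self.gain_size} pushes beta {b} above 1"
                )


class SimulatedMethylation(NamedTuple):
    table_a: pd.DataFrame  # CpG count table, condition A (sample "A")
    table_b: pd.DataFrame  # CpG count table, condition B (sample "B")
    truth: pd.DataFrame  # cgi, is_gainer, beta_a, beta_b
    cgis: list[GenomicInterval]


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson coverage truncated at >= 1 (zero-coverage CpGs are unobserved)."""
    cov = rng.poisson(mean, size=size)
    while (zero := cov == 0).any():
        cov[zero] = rng.poisson(mean, size=int(zero.sum()))
    return cov


def simulate_cpg_counts(cfg: MethSimConfig) -> SimulatedMethylation:
    """Simulate paired-condition CpG count tables with known gainers.

    Per CpG the methylated count is Binomial(coverage, beta of its CGI in
    that condition); gainer CGIs have beta_B - beta_A = ``gain_size``.
    CGIs are laid out on "chr1" with CpGs every 2 bp.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cgis
    if isinstance(cfg.cpgs_per_cgi, int):
        n_cpgs = np.full(n, cfg.cpgs_per_cgi)
    else:
        lo, hi = cfg.cpgs_per_cgi
        n_cpgs = rng.integers(lo, hi + 1, size=n)

    if isinstance(cfg.baseline_beta, (int, float)):
        beta_a = np.full(n, float(cfg.baseline_beta))
    else:
        lo, hi, p_high = cfg.baseline_beta
        beta_a = np.where(rng.random(n) < p_high, hi, lo)

    n_gainers = int(round(cfg.gainer_fraction * n))
    gainers = np.zeros(n, dtype=bool)
    eligible = np.flatnonzero(beta_a + cfg.gain_size <= 1.0)
    if n_gainers > len(eligible):
        raise ValueError("not enough CGIs can gain without beta exceeding 1")
    if n_gainers:
        gainers[rng.choice(eligible, size=n_gainers, replace=False)] = True
    beta_b = beta_a + np.where(gainers, cfg.gain_size, 0.0)

    cgis, rows_a, rows_b = [], [], []
    truth_rows = []
    spacing = 10_000
    for i in range(n):
        name = f"CGI_{i:05d}"
        start = i * spacing
        k = int(n_cpgs[i])
        end = start + 2 * k
        cgis.append(GenomicInterval("chr1", start, end, name=name))
        pos = start + 1 + 2 * np.arange(k)  # 1-based CpG positions
        for cond, beta, sink in (("A", beta_a[i], rows_a), ("B", beta_b[i], rows_b)):
            cov = _truncated_poisson(rng, cfg.coverage_mean, k)
            meth = rng.binomial(cov, beta)
            sink.append(
                pd.DataFrame(
                    {"chrom": "chr1", "pos": pos,
                     f"{cond}_meth": meth, f"{cond}_unmeth": cov - meth}
                )
            )
        truth_rows.append((name, bool(gainers[i]), float(beta_a[i]), float(beta_b[i])))

    truth = pd.DataFrame(truth_rows, columns=["cgi", "is_gainer", "beta_a", "beta_b"])
    return SimulatedMethylation(
        table_a=pd.concat(rows_a, ignore_index=True),
        table_b=pd.concat(rows_b, ignore_index=True),
        truth=truth,
        cgis=cgis,
    )


# ---------------------------------------------------------------------------
# 5-aza-dC recovery time course
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsSimConfig:
    """Post-demethylation recovery trajectories.

    Under ``outgrowth_null`` every CGI's expected normalised trajectory is
    identical (common residual level and recovery slope); under
    ``heterogeneous`` per-CGI slopes are Gaussian with sd ``rate_sd``.
    ``group_offsets`` optionally assigns a marker label (e.g. H3K36me3 vs
    other) to a fraction of CGIs with an additive rate offset.
    """

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_cgis: int = 200
    day0_beta: tuple[float, float] = (0.55, 0.95)  # uniform range
    regime: str = "outgrowth_null"
    # default rate restores ~97% of day-0 methylation by day 22 (cells
    # recover to near-untreated levels within ~3 weeks) and keeps raw
    # trajectories below the beta ceiling, so clipping never distorts
    # the proportional-outgrowth structure
    mean_rate: float = 0.025  # fraction of day-0 methylation per day
    rate_sd: float = 0.0
    noise_sd: float = 0.02  # Gaussian, beta scale
    residual_level: float = 0.5  # normalised level reached at day 3
    group_offsets: tuple[tuple[str, float, float], ...] = ()  # (label, frac, offset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("outgrowth_null", "heterogeneous"):
            raise ValueError("regime must be outgrowth_null or heterogeneous")
        if self.rate_sd < 0:
            raise ValueError("rate_sd must be >= 0")
        if self.regime == "outgrowth_null" and self.rate_sd != 0:
            raise ValueError("outgrowth_null requires rate_sd = 0")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be sorted")
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include day 0")
        if sum(3.0 <= t <= 22.0 for t in self.timepoints) < 3:
            raise ValueError("need >= 3 timepoints in [3, 22]")


class SimulatedTimecourse(NamedTuple):
    table: pd.DataFrame  # wide: cgi x day, raw betas
    truth: pd.DataFrame  # cgi, day0, slope, group


def simulate_timecourse(cfg: KineticsSimConfig) -> SimulatedTimecourse:
    """Simulate per-CGI methylation recovery after demethylation.

    Raw methylation is m(c, t) = m0_c * n_c(t) for t > 0 with
    n_c(t) = residual_level + s_c * (t - 3), plus Gaussian observation
    noise, clipped to [0, 1]. Slopes s_c are the configured mean rate
    (identical under the outgrowth null) plus a Gaussian deviate with sd
    ``rate_sd`` and any group offset.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cgis
    m0 = rng.uniform(*cfg.day0_beta, size=n)

    labels = np.array(["other"] * n, dtype=object)
    offsets = np.zeros(n)
    if cfg.group_offsets:
        free = np.arange(n)
        rng.shuffle(free)
        pos = 0
        for label, frac, offset in cfg.group_offsets:
            k = int(round(frac * n))
            idx = free[pos : pos + k]
            labels[idx] = label
            offsets[idx] = offset
            pos += k

    slopes = np.full(n, cfg.mean_rate) + offsets
    if cfg.regime == "heterogeneous" and cfg.rate_sd > 0:
        slopes = slopes + rng.normal(0.0, cfg.rate_sd, size=n)

    days = np.asarray(cfg.timepoints)
    traj = np.empty((n, len(days)))
    for j, t in enumerate(days):
        if t == 0:
            # day 0 is the normalisation anchor and carries no observation
            # noise: noise here would leak a spurious per-CGI scale factor
            # (hence slope heterogeneity) into the normalised trajectories,
            # breaking the outgrowth-null invariant that they share one slope
            traj[:, j] = m0
            continue
        norm = cfg.residual_level + slopes * (t - 3.0)
        expected = m0 * norm
        noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        traj[:, j] = np.clip(expected + noise, 0.0, 1.0)

    index = [f"CGI_{i:05d}" for i in range(n)]
    table = pd.DataFrame(traj, index=pd.Index(index, name="cgi"), columns=days)
    truth = pd.DataFrame(
        {"cgi": index, "day0": m0, "slope": slopes, "group": labels}
    )
    return SimulatedTimecourse(table=table, truth=truth)


# ---------------------------------------------------------------------------
# ChIP-Rx experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipSimConfig:
    """Spike-in ChIP experiment over CGIs.

    Per-CGI signal is Gamma distributed; a paired covariate (e.g.
    methylation gain) is coupled to the signal through ``coupling``
    ("identity", "linear" with ``coupling_noise_sd``, or "none").
    ``global_fold_change`` multiplies the target-genome signal of the
    non-reference sample; the spike-in mass is unchanged, so the scaling
    factor truth reflects the fold change.
    """

    n_cgis: int = 1000
    signal_shape: float = 2.0  # Gamma shape of per-CGI signal
    coupling: str = "identity"
    coupling_noise_sd: float = 0.0
    library_size: int = 1_000_000
    spikein_fraction: float = 1.0 / 21.0  # 20:1 target:spike-in cell ratio
    global_fold_change: float = 1.0
    input_library_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if not 0 < self.spikein_fraction < 1:
            raise ValueError("spikein_fraction must be in (0, 1)")
        if self.coupling not in ("identity", "linear", "none"):
            raise ValueError("coupling must be identity, linear or none")
        if self.global_fold_change <= 0:
            raise ValueError("global_fold_change must be > 0")


class SimulatedChip(NamedTuple):
    samples: dict  # sample id -> (ChipSampleCounts ChIP, ChipSampleCounts input)
    regions: list[GenomicInterval]
    truth: pd.DataFrame  # cgi, signal, covariate
    scaling_truth: dict  # sample id -> expected S vs reference "ref"


def _split_library(
    rng: np.random.Generator, library_size: int, spike_mass: float, target_mass: float
) -> tuple[int, int]:
    spike_prob = spike_mass / (spike_mass + target_mass)
    spike = int(rng.binomial(library_size, spike_prob))
    spike = min(max(spike, 1), library_size - 1)  # both genomes observed
    return library_size - spike, spike


def simulate_chip_experiment(cfg: ChipSimConfig) -> SimulatedChip:
    """Simulate a two-sample spike-in ChIP experiment with inputs.

    Samples "ref" and "treat" share per-CGI signal; "treat" carries the
    global fold change. Target reads multinomial over CGIs proportional
    to signal; inputs uniform over CGIs. ``scaling_truth`` records the
    closed-form expected scaling factor under the per-10^7-of-total-reads
    convention: S_treat = (M_T + M_D) / (fold * M_T + M_D) with target
    mass M_T and spike mass M_D (inputs are symmetric and cancel), so the
    implied fold change is ~1/S.
    """
    from .chip import ChipSampleCounts  # local import to avoid cycle

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cgis
    signal = rng.gamma(cfg.signal_shape, 1.0, size=n)
    if cfg.coupling == "identity":
        covariate = signal.copy()
    elif cfg.coupling == "linear":
        covariate = signal + rng.normal(0.0, cfg.coupling_noise_sd, size=n)
    else:
        covariate = rng.gamma(cfg.signal_shape, 1.0, size=n)

    width = 1000
    regions = [
        GenomicInterval("chr1", i * 5000, i * 5000 + width, name=f"CGI_{i:05d}")
        for i in range(n)
    ]
    ids = [r.name for r in regions]

    target_mass = 1.0 - cfg.spikein_fraction
    spike_mass = cfg.spikein_fraction
    input_size = cfg.input_library_size or cfg.library_size
    p_signal = signal / signal.sum()
    p_uniform = np.full(n, 1.0 / n)

    samples = {}
    for sid, fold in (("ref", 1.0), ("treat", cfg.global_fold_change)):
        t_reads, d_reads = _split_library(
            rng, cfg.library_size, spike_mass, fold * target_mass
        )
        chip_counts = rng.multinomial(t_reads, p_signal)
        chip = ChipSampleCounts(
            sample_id=sid, role="ChIP",
            counts=pd.Series(chip_counts, index=ids),
            target_mapped_total=t_reads, spikein_mapped_total=d_reads,
        )
        ti, di = _split_library(rng, input_size, spike_mass, target_mass)
        input_counts = rng.multinomial(ti, p_uniform)
        inp = ChipSampleCounts(
            sample_id=sid, role="input",
            counts=pd.Series(input_counts, index=ids),
            target_mapped_total=ti, spikein_mapped_total=di,
        )
        samples[sid] = (chip, inp)

    fold = cfg.global_fold_change
    expected_s = (target_mass + spike_mass) / (fold * target_mass + spike_mass)
    truth = pd.DataFrame({"cgi": ids, "signal": signal, "covariate": covariate})
    return SimulatedChip(
        samples=samples,
        regions=regions,
        truth=truth,
        scaling_truth={"ref": 1.0, "treat": float(expected_s)},
    )


def chip_fragments(
    chip_counts: pd.Series,
    regions: list[GenomicInterval],
    fragment_length: int = 150,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Materialise per-region counts as fragment intervals (for BED export)."""
    rng = np.random.default_rng(seed)
    frags = []
    by_id = {r.name: r for r in regions}
    for rid, k in chip_counts.items():
        r = by_id[rid]
        starts = rng.integers(r.start, max(r.end - fragment_length, r.start) + 1, size=int(k))
        frags.extend(
            GenomicInterval(r.chrom, int(s), int(s) + fragment_length)
            for s in starts
        )
    return frags


# ---------------------------------------------------------------------------
# Ontology with planted enrichment
# ---------------------------------------------------------------------------


class SimulatedOntology(NamedTuple):
    graph: TermGraph
    assignments: dict  # gene -> frozenset of direct terms
    planted_term: str
    planted_genes: frozenset


def simulate_ontology(
    n_terms: int, depth: int, n_genes: int, seed: int = 0
) -> SimulatedOntology:
    """Random single-root DAG with a planted enriched term.

    Every term is reachable from the root. Genes get 1-3 random direct
    terms; an additional planted gene set (about a quarter of the genes)
    is annotated to one designated term so that downstream enrichment of
    a target drawn from the planted genes flags that term.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    terms = [f"T{idx:04d}" for idx in range(n_terms)]
    root = terms[0]
    levels = {root: 0}
    edges: list[tuple[str, str, str]] = []
    for t in terms[1:]:
        candidates = [u for u in levels if levels[u] < depth]
        parents = rng.choice(
            candidates, size=min(len(candidates), int(rng.integers(1, 3))),
            replace=False,
        )
        for p in parents:
            relation = "is_a" if rng.random() < 0.8 else "part_of"
            edges.append((t, str(p), relation))
        levels[t] = max(levels[str(p)] for p in parents) + 1
    graph = TermGraph.from_edges(edges, terms=terms)

    genes = [f"G{idx:04d}" for idx in range(n_genes)]
    assignments: dict[str, frozenset[str]] = {}
    for g in genes:
        k = min(int(rng.integers(1, 4)), n_terms)
        assignments[g] = frozenset(str(t) for t in rng.choice(terms, size=k, replace=False))

    planted_term = terms[-1] if n_terms > 1 else root
    n_planted = max(min(n_genes // 4, n_genes), 1)
    planted_genes = frozenset(
        str(g) for g in rng.choice(genes, size=n_planted, replace=False)
    )
    for g in planted_genes:
        assignments[g] = assignments[g] | {planted_term}
    return SimulatedOntology(
        graph=graph,
        assignments=assignments,
        planted_term=planted_term,
        planted_genes=planted_genes,
    )
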