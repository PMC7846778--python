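"""End-to-end orchestration of the synthetic analysis stages.

``run_pipeline`` executes the requested stages in dependency order on
synthetic inputs (all randomness flows from the single config seed),
writing plain-text TSV/JSON artifacts plus a run manifest. Outputs are
deterministic: rerunning with an identical config and seed reproduces
byte-identical files. Stage wall-clock timings go to the log stream only,
never into output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chip import normalised_signal, rx_scaling_factor, apply_rx_scaling, decile_association
from .io import write_bismark_cov, write_bed, write_json
from .kinetics import normalise_timecourse, test_rate_heterogeneity, fit_cgi_recovery_rates
from .methylation import filter_cpgs, cgi_weighted_methylation, call_methylation_gain
from .ontology import enrich_terms, collapse_similar_terms
from .simulate import (
    MethSimConfig, KineticsSimConfig, ChipSimConfig,
    simulate_cpg_counts, simulate_timecourse, simulate_chip_experiment,
    simulate_ontology,
)

logger = logging.getLogger("cgimeth")

STAGES = ("simulate", "methylation", "gain", "kinetics", "chip", "enrich")

_STAGE_DEPS = {
    "simulate": (),
    "methylation": ("simulate",),
    "gain": ("methylation",),
    "kinetics": ("simulate",),
    "chip": ("simulate",),
    "enrich": ("gain",),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes for a synthetic end-to-end run.

    The threshold defaults are the analysis constants used throughout:
    coverage >= 10 in all samples, gain >= 0.20 at FDR 0.05, array-beta
    call at 0.3, day-0 filter at 0.5 with the day 3-22 fitting range, ChIP
    offset 0.5, 10 rank groups, Wang similarity 0.7 and a 10-CGI
    background floor for term testing.
    """

    n_cgis: int = 500
    min_coverage: int = 10
    min_gain: float = 0.20
    fdr: float = 0.05
    beta_threshold: float = 0.3
    day0_min: float = 0.5
    t_min: float = 3.0
    t_max: float = 22.0
    offset: float = 0.5
    n_groups: int = 10
    wang_threshold: float = 0.7
    min_background: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 <= self.min_gain <= 1:
            raise ValueError("min_gain must be in [0, 1]")
        if not 0 <= self.beta_threshold <= 1:
            raise ValueError("beta_threshold must be in [0, 1]")
        if self.t_min >= self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the selected stages; returns the manifest dictionary.

    Stages run in dependency order (simulate -> methylation -> gain ->
    kinetics/chip/enrich); requesting a stage without its prerequisite in
    the same run raises an error naming the gap.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
    selected = [s for s in STAGES if s in stages]
    for s in selected:
        missing = [d for d in _STAGE_DEPS[s] if d not in selected]
        if missing:
            raise ValueError(f"stage {s!r} requires stage(s) {missing} in the same run")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": selected,
        "stage_rows": {},
        "outputs": {},
    }
    state: dict = {}

    for stage in selected:
        t0 = time.perf_counter()
        rows = _RUNNERS[stage](config, outdir, state, manifest)
        logger.info("stage %s: %d rows out in %.2fs", stage, rows,
                    time.perf_counter() - t0)
        manifest["stage_rows"][stage] = rows

    for f in sorted(outdir.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _checksum(f)
    write_json(manifest, outdir / "manifest.json")
    return manifest


def _stage_simulate(config, outdir, state, manifest):
    sim = simulate_cpg_counts(
        MethSimConfig(n_cgis=config.n_cgis, seed=config.seed)
    )
    state["meth_sim"] = sim
    write_bismark_cov(sim.table_a, outdir / "counts_A.cov", "A")
    write_bismark_cov(sim.table_b, outdir / "counts_B.cov", "B")
    write_bed(sim.cgis, outdir / "cgis.bed")
    sim.truth.to_csv(outdir / "meth_truth.tsv", sep="\t", index=False)

    kin = simulate_timecourse(
        KineticsSimConfig(
            n_cgis=max(config.n_cgis // 2, 10),
            regime="heterogeneous", rate_sd=0.01, seed=config.seed + 1,
            group_offsets=(("H3K36me3", 0.15, 0.01),),
        )
    )
    state["kin_sim"] = kin
    kin.table.to_csv(outdir / "timecourse.tsv", sep="\t")
    kin.truth.to_csv(outdir / "kinetics_truth.tsv", sep="\t", index=False)

    chip = simulate_chip_experiment(
        ChipSimConfig(n_cgis=config.n_cgis, global_fold_change=2.0,
                      seed=config.seed + 2)
    )
    state["chip_sim"] = chip
    chip.truth.to_csv(outdir / "chip_truth.tsv", sep="\t", index=False)

    onto = simulate_ontology(n_terms=50, depth=4, n_genes=200,
                             seed=config.seed + 3)
    state["onto_sim"] = onto
    return config.n_cgis


def _stage_methylation(config, outdir, state, manifest):
    sim = state["meth_sim"]
    table = sim.table_a.merge(sim.table_b, on=["chrom", "pos"])
    n_before = len(table)
    table = filter_cpgs(table, min_coverage=config.min_coverage)
    logger.info("coverage filter: %d of %d CpGs retained", len(table), n_before)
    meth = cgi_weighted_methylation(table, sim.cgis)
    state["cgi_meth"] = meth
    meth.to_csv(outdir / "cgi_methylation.tsv", sep="\t", index=False)
    return len(meth)


def _stage_gain(config, outdir, state, manifest):
    meth = state["cgi_meth"]
    calls = call_methylation_gain(
        meth[meth["sample"] == "A"], meth[meth["sample"] == "B"],
        min_gain=config.min_gain, fdr=config.fdr,
    )
    state["gain_calls"] = calls
    calls.to_csv(outdir / "gain_calls.tsv", sep="\t", index=False)
    return len(calls)


def _stage_kinetics(config, outdir, state, manifest):
    kin = state["kin_sim"]
    ntc = normalise_timecourse(kin.table, day0_min=config.day0_min)
    het = test_rate_heterogeneity(ntc, t_min=config.t_min, t_max=config.t_max)
    groups = kin.truth.set_index("cgi")["group"]
    rates = fit_cgi_recovery_rates(ntc, t_min=config.t_min,
                                   t_max=config.t_max, groups=groups)
    rates.to_csv(outdir / "recovery_rates.tsv", sep="\t", index=False)
    write_json(
        {
            "loglik_null": het.loglik_null, "loglik_alt": het.loglik_alt,
            "lr_statistic": het.lr_statistic, "df": het.df_difference,
            "p_value": het.p_value, "n_cgis": het.n_cgis,
            "timepoints": list(het.timepoints),
        },
        outdir / "heterogeneity_test.json",
    )
    return len(rates)


def _stage_chip(config, outdir, state, manifest):
    chip = state["chip_sim"]
    scaling = rx_scaling_factor(chip.samples, reference="ref")
    signals = {}
    for sid, (c, i) in chip.samples.items():
        sig = normalised_signal(c, i, offset=config.offset)
        signals[sid] = apply_rx_scaling(sig, scaling.correction(sid))
    df = pd.DataFrame({sid: s.values for sid, s in signals.items()})
    df.index.name = "cgi"
    df.to_csv(outdir / "chip_signal.tsv", sep="\t")
    write_json({"reference": scaling.reference, "factors": scaling.factors},
               outdir / "rx_scaling.json")
    sig = signals["ref"].values
    cov = chip.truth.set_index("cgi")["covariate"]
    _, summaries, rho, p = decile_association(sig, cov, n_groups=config.n_groups)
    summaries.to_csv(outdir / "decile_summaries.tsv", sep="\t", index=False)
    write_json({"spearman_rho": rho, "p_value": p}, outdir / "decile_association.json")
    return len(df)


def _stage_enrich(config, outdir, state, manifest):
    onto = state["onto_sim"]
    calls = state["gain_calls"]
    genes = sorted(onto.assignments)
    rng = np.random.default_rng(config.seed + 4)
    cgi_to_genes = {
        cgi: [genes[i] for i in rng.choice(len(genes), size=2, replace=False)]
        for cgi in calls["cgi"]
    }
    # couple the planted term to gainers so the enrichment has signal
    planted_genes = sorted(onto.planted_genes)
    for cgi, gain in zip(calls["cgi"], calls["is_gainer"]):
        if gain and planted_genes:
            cgi_to_genes[cgi] = [planted_genes[int(rng.integers(len(planted_genes)))],
                                 cgi_to_genes[cgi][1]]
    target = calls.loc[calls["is_gainer"], "cgi"].tolist()
    results = enrich_terms(
        target, calls["cgi"].tolist(), cgi_to_genes, onto.assignments,
        graph=onto.graph, min_background=config.min_background, fdr=config.fdr,
    )
    results = collapse_similar_terms(results, onto.graph,
                                     threshold=config.wang_threshold)
    results.to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
    return len(results)


_RUNNERS = {
    "simulate": _stage_simulate,
    "methylation": _stage_methylation,
    "gain": _stage_gain,
    "kinetics": _stage_kinetics,
    "chip": _stage_chip,
    "enrich": _stage_enrich,
}
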