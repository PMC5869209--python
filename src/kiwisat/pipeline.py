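"""End-to-end orchestration: simulate or load tables, run every analysis
stage, write result tables and a run log."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import (
    ConsensusCaller,
    classify_success,
    error_rates,
    filter_samples,
    quality_index,
)
from .identity import SexCaller, match_genotypes
from .ordination import genetic_distance, pcoa
from .panel import default_kiwi_panel
from .popgen import allele_frequencies, cumulative_pi, diversity_stats
from .qpcr import inhibition_test, quantify_run
from .simulate import (
    ErrorModel,
    PopulationSpec,
    simulate_individuals,
    simulate_populations,
    simulate_qpcr,
    simulate_replicates,
)
from . import tables

logger = logging.getLogger(__name__)

STAGES = ("consensus", "errors", "divstats", "pi", "sex", "match", "pcoa", "qpcr")


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the configured stages and write all result tables to `out_dir`.

    `config` either names input tables (``inputs: {replicates: path, ...}``)
    or a simulation block (``simulate: {...}``). Stage names outside the
    known set raise; any stage failure propagates with its stage name
    attached. Returns the result bundle as a dict of DataFrames/objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage name(s): {unknown}")

    panel = default_kiwi_panel()
    bundle: dict = {}
    reference = None
    qpcr_run = None

    if "simulate" in config:
        sim = config["simulate"]
        pops = [PopulationSpec(**p) for p in sim["populations"]]
        model = simulate_populations(
            panel,
            pops,
            n_alleles=sim.get("n_alleles", 6),
            concentration=sim.get("concentration", 1.0),
            private_allele_plan=sim.get("private_allele_plan"),
            inbreeding_f=sim.get("inbreeding_f"),
            seed=seed,
        )
        truth = simulate_individuals(
            model,
            sim.get("n_per_population", 20),
            sex_ratio=sim.get("sex_ratio", 0.5),
            seed=seed + 1,
        )
        em = ErrorModel(**sim.get("error", {}))
        reps = simulate_replicates(truth, em, panel, seed=seed + 2)
        bundle["truth"] = truth
        tables.write_genotype_table(tables.genotypes_from_truth(truth), out / "truth.csv")
        tables.write_replicate_table(reps, out / "replicates.csv")
        if sim.get("qpcr"):
            qpcr_run = simulate_qpcr(seed=seed + 3, **sim["qpcr"])
            tables.write_qpcr_table(qpcr_run, out / "qpcr_plate.csv")
    elif "inputs" in config:
        inp = config["inputs"]
        reps = tables.read_replicate_table(inp["replicates"])
        if inp.get("reference"):
            reference = tables.read_genotype_table(inp["reference"])
        if inp.get("qpcr"):
            qpcr_run = tables.read_qpcr_table(inp["qpcr"])
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")
    bundle["replicates"] = reps

    cc_cfg = config.get("consensus", {})
    genotypes = None
    for stage in stages:
        try:
            if stage == "consensus":
                caller = ConsensusCaller(
                    het_min=cc_cfg.get("het_min", 2), hom_min=cc_cfg.get("hom_min", 3)
                ).fit(reps, reference=reference)
                cons = filter_samples(
                    caller.consensus_, cc_cfg.get("max_failed_loci", 2)
                )
                qi = quality_index(reps, cons)
                flags, frac = classify_success(
                    qi.per_sample, cc_cfg.get("qi_threshold", 0.75)
                )
                bundle.update(consensus=cons, qi=qi, success=flags, success_fraction=frac)
                genotypes = cons
                tables.write_genotype_table(cons.drop(columns=["source", "flag"]),
                                            out / "consensus.csv")
                cons[["sample", "locus", "source", "flag"]].to_csv(
                    out / "consensus_flags.csv", index=False)
                flags.to_csv(out / "qi_samples.csv", index=False)
                qi.per_sample_locus.to_csv(out / "qi_sample_loci.csv", index=False)
            elif stage == "errors":
                er = error_rates(reps, _need(bundle, "consensus", stage))
                bundle["error_rates"] = er
                er.summary().to_csv(out / "error_rates.csv", index=False)
                er.ado_by_locus.rename("ado").to_frame().join(
                    er.fa_by_locus.rename("fa")
                ).to_csv(out / "error_rates_by_locus.csv")
            elif stage == "divstats":
                af = allele_frequencies(_autosomal(genotypes, panel))
                ds = diversity_stats(af, _autosomal(genotypes, panel))
                bundle.update(allele_frequencies=af, diversity=ds)
                ds.per_population.to_csv(out / "diversity.csv", index=False)
            elif stage == "pi":
                af_all = allele_frequencies(_need_geno(genotypes, stage))
                pis = {
                    pop: cumulative_pi(af_all, pop)
                    for pop in af_all.freqs["population"].unique()
                }
                bundle["pi"] = pis
                pd.concat(
                    [r.cumulative.assign(population=pop) for pop, r in pis.items()]
                ).to_csv(out / "pi_cumulative.csv", index=False)
            elif stage == "sex":
                sex_reps = reps[reps["locus"] == panel.sex_locus.name]
                calls = SexCaller().fit().predict(sex_reps)
                bundle["sex_calls"] = calls
                calls.to_csv(out / "sex_calls.csv", index=False)
            elif stage == "match":
                matches = match_genotypes(_need_geno(genotypes, stage))
                bundle["matches"] = matches
                matches.to_csv(out / "matches.csv", index=False)
            elif stage == "pcoa":
                dm = genetic_distance(_need_geno(genotypes, stage), scaling="mean")
                ord_ = pcoa(dm)
                bundle["pcoa"] = ord_
                ord_.to_frame().to_csv(out / "pcoa_coordinates.csv")
            elif stage == "qpcr":
                if qpcr_run is None:
                    logger.info("no qPCR table; stage skipped")
                    continue
                curve, quant = quantify_run(qpcr_run)
                inhib = inhibition_test(qpcr_run)
                bundle.update(qpcr_curve=curve, quantification=quant, inhibition=inhib)
                pd.DataFrame(
                    {"slope": [curve.slope_], "intercept": [curve.intercept_],
                     "r_squared": [curve.r_squared_], "efficiency": [curve.efficiency_]}
                ).to_csv(out / "qpcr_curve.csv", index=False)
                quant.to_csv(out / "qpcr_quant.csv", index=False)
                inhib.to_csv(out / "qpcr_inhibition.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    log = {
        "kiwisat_version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config": _jsonable(config),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle


def _need(bundle: dict, key: str, stage: str):
    if key not in bundle:
        raise ValueError(f"stage '{stage}' requires '{key}' from an earlier stage")
    return bundle[key]


def _need_geno(genotypes, stage):
    if genotypes is None:
        raise ValueError(f"stage '{stage}' requires the consensus stage first")
    return genotypes


def _autosomal(genotypes: pd.DataFrame, panel) -> pd.DataFrame:
    return genotypes[genotypes["locus"] != panel.sex_locus.name]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
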