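"""End-to-end pipeline: simulate -> QC -> diel statistics -> experiment.

A :class:`RunConfig` carries one master seed and per-stage parameter blocks;
every stage draws its randomness from named substreams of the master seed,
so rerunning a config reproduces all outputs.  Outputs are plain-text tables
plus a JSON manifest echoing the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, dielstats, experiment, io, qc, synthdata
from .experiment import build_pool, run_selection_experiment

#: analysis thresholds (defaults follow the study design)
DEFAULT_THRESHOLDS = {
    "poor_mae": 5.0,            # held-out MAE at or above this is a poor prediction
    "consistency": 0.8,         # fraction of replicates agreeing on the predictor
    "amplitude_min": 2.0,       # diel amplitude filter (log2 units, strict >)
    "expressed_min": 1.0,       # grand-mean expression filter (strict >)
    "corr_threshold": 0.5,      # |r| screen for temperature-tracking genes
    "specific_diff": 2.0,       # cultivar-specific: between-cultivar mean gap
    "specific_low": 0.5,        # cultivar-specific: ceiling for the low cultivar
    "lookback_h": 72.0,         # meteorological history available to models
}

_SYNTH_DEFAULTS = {
    "n_temperature": 4, "n_radiation": 4, "n_neither": 2,
    "noise_sd": 0.3, "target_snr": 6.0,
    "n_field": 400, "n_test": 200, "cultivars": 2,
}
_EXPERIMENT_DEFAULTS = {
    "pools": ["gc", "field", "mixed"], "sizes": [64], "reps": 5,
    "nm_maxiter": 40, "paired": False,
}
_QC_DEFAULTS = {"inject_swaps": [], "flag_threshold": None}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fieldfit_run"
    thresholds: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    stages: list = field(default_factory=lambda: ["synth", "qc", "dielstats",
                                                  "experiment"])

    def __post_init__(self):
        for name, defaults in (("thresholds", DEFAULT_THRESHOLDS),
                               ("synth", _SYNTH_DEFAULTS),
                               ("experiment", _EXPERIMENT_DEFAULTS),
                               ("qc", _QC_DEFAULTS)):
            block = dict(defaults)
            given = getattr(self, name)
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown key(s) in config block {name!r}: "
                                 f"{sorted(unknown)}")
            block.update(given)
            setattr(self, name, block)
        bad = set(self.stages) - {"synth", "qc", "dielstats", "experiment"}
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig(**raw)


def _substream(seed: int, name: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(abs(hash(name)) % 2**31,))
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages; returns the run directory."""
    out = io.ensure_dir(config.out_dir)
    log_path = out / "log.jsonl"
    logf = open(log_path, "w", encoding="utf-8")

    def log(stage, **kw):
        rec = {"stage": stage, "time": time.time(), **kw}
        logf.write(json.dumps(rec, default=str) + "\n")
        logf.flush()

    s = config.synth
    conditions = synthdata.enumerate_conditions()
    io.write_condition_table(conditions, out / "conditions.csv")

    ref_seed = _substream(config.seed, "truth")
    gc_probe = synthdata.simulate_gc_study(conditions[:4], [], seed=0)
    truth = synthdata.make_truth_genes(
        s["n_temperature"], s["n_radiation"], s["n_neither"],
        reference=gc_probe.samples, seed=ref_seed,
        noise_sd=s["noise_sd"], target_snr=s["target_snr"],
    )
    gc = synthdata.simulate_gc_study(conditions, truth,
                                     seed=_substream(config.seed, "gc"),
                                     cultivars=s["cultivars"])
    fd = synthdata.simulate_field_study(truth, n_samples=s["n_field"],
                                        seed=_substream(config.seed, "field"))
    test = synthdata.simulate_field_study(truth, n_samples=s["n_test"],
                                          seed=_substream(config.seed, "test"))
    io.write_study(gc.study, out / "gc_matrix.tsv", out / "gc_meta.tsv")
    io.write_study(fd.study, out / "field_matrix.tsv", out / "field_meta.tsv")
    io.write_env_series(fd.envs[0], out / "field_env.csv")
    log("synth", n_conditions=len(conditions), n_gc=len(gc.samples),
        n_field=len(fd.samples), n_test=len(test.samples))

    report: dict = {}
    if "qc" in config.stages:
        study = gc.study
        for a, b in config.qc["inject_swaps"]:
            study = synthdata.inject_plate_swap(study, a, b)
        preds = qc.loo_plate_temperature(study,
                                         seed=_substream(config.seed, "qc"))
        proposal = qc.infer_swaps(preds, config.qc["flag_threshold"])
        _, accepted = qc.verify_correction(study, proposal)
        report["qc"] = {
            "plate_mae": {p.plate_id: p.mae for p in preds},
            "flag_threshold": proposal.threshold,
            "flagged": proposal.flagged,
            "proposed_pairs": proposal.pairs,
            "correction_accepted": accepted,
        }
        log("qc", **report["qc"])

    if "dielstats" in config.stages:
        expressed = dielstats.filter_expressed(gc.study)
        amp = dielstats.amplitude_table(gc.study, genes=expressed)
        amp.to_csv(out / "amplitude.tsv", sep="\t", index=False)
        pos, neg, r = dielstats.temp_correlation_screen(
            gc.study, threshold=config.thresholds["corr_threshold"]
        )
        r.to_frame().assign(
            set=np.where(r > config.thresholds["corr_threshold"], "positive",
                         np.where(r < -config.thresholds["corr_threshold"],
                                  "negative", "-"))
        ).to_csv(out / "temp_corr.tsv", sep="\t")
        report["dielstats"] = {"n_expressed": len(expressed),
                               "n_positive": len(pos), "n_negative": len(neg)}
        log("dielstats", **report["dielstats"])

    if "experiment" in config.stages:
        e = config.experiment
        pool_map = {
            "gc": build_pool("gc", [gc]),
            "field": build_pool("field", [fd]),
            "mixed": build_pool("mixed", [gc, fd]),
        }
        pools = [pool_map[p] for p in e["pools"]]
        genes = [t.gene_id for t in truth]
        result = run_selection_experiment(
            genes, pools, sizes=tuple(e["sizes"]), reps=e["reps"],
            test=(test.expr, test.samples),
            seed=_substream(config.seed, "experiment"),
            nm_maxiter=e["nm_maxiter"], paired=e["paired"],
        )
        io.write_selection_summaries(result.summaries,
                                     out / "selection_summary.tsv")
        result.records.to_csv(out / "selection_records.tsv", sep="\t",
                              index=False)
        report["experiment"] = {
            "n_genes": len(genes), "excluded": sorted(result.excluded),
        }
        log("experiment", **report["experiment"])

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "report": report,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logf.close()
    return out
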