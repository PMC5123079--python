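"""End-to-end pipeline orchestration.

Runs the analysis stages in order — simulate behaviour, fit conditional
accuracy functions, fit the drift-diffusion models, fit the pupil GLM,
simulate the leaky competing accumulator — with deterministic per-stage
seeding, plain-text outputs (CSV/JSON) and a checksummed manifest.

Per-stage seeds are derived from the global seed by stable hashing of the
stage name, so adding or removing a stage does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import caf as caf_mod
from . import ddm as ddm_mod
from . import lca as lca_mod
from . import pupil as pupil_mod
from . import synth

log = logging.getLogger("urgeflow.pipeline")

__all__ = ["run_pipeline", "stage_seed", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "fit_caf", "fit_ddm", "fit_pupil", "run_lca")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stable across sessions), < 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg, outdir: Path, seed: int) -> list[Path]:
    gen = synth.default_config(n_trials=int(cfg.get("n_trials", 1000)), seed=seed)
    trials = synth.generate_behavior(gen)
    out = outdir / "trials.csv"
    synth.write_trials(trials, out)
    return [out]


def _stage_fit_caf(cfg, outdir: Path, seed: int) -> list[Path]:
    trials = synth.read_trials(outdir / "trials.csv")
    results = {}
    paths = []
    for regime, sub in trials.groupby("regime"):
        fit = caf_mod.fit_piecewise_caf(sub, seed=seed)
        results[regime] = {
            **{k: getattr(fit, k) for k in ("alpha", "beta0", "beta1", "beta2", "sse", "n_trials")},
            "accuracy_at_deadline_pct": caf_mod.accuracy_at_deadline(fit),
        }
        binned = caf_mod.binned_caf(sub, n_bins=min(25, len(sub) // 4))
        bpath = outdir / f"caf_bins_{regime}.csv"
        binned.to_csv(bpath, index=False)
        paths.append(bpath)
    out = outdir / "caf.json"
    out.write_text(json.dumps(results, indent=2))
    return [out] + paths


def _stage_fit_ddm(cfg, outdir: Path, seed: int) -> list[Path]:
    trials = synth.read_trials(outdir / "trials.csv")
    sub = trials[trials["regime"] == "DL"]
    results = {}
    for model in ("urgency", "standard"):
        fit = ddm_mod.fit_mle(
            sub, model=model, seed=seed,
            n_starts=int(cfg.get("ddm_starts", 2)),
            maxfev=int(cfg.get("ddm_maxfev", 150)),
        )
        entry = {"loglik": fit.loglik, "bic": fit.bic, "n_free": fit.n_free,
                 "params": asdict(fit.params)}
        if fit.urgency:
            entry["urgency"] = {k: asdict(v) for k, v in fit.urgency.items()}
        results[model] = entry
    results["delta_bic_urgency_minus_standard"] = (
        results["urgency"]["bic"] - results["standard"]["bic"]
    )
    out = outdir / "ddm_fits.json"
    out.write_text(json.dumps(results, indent=2))
    return [out]


def _stage_fit_pupil(cfg, outdir: Path, seed: int) -> list[Path]:
    irf = pupil_mod.IRFParams()
    rng = np.random.default_rng(seed)
    n_subj = int(cfg.get("pupil_subjects", 8))
    shape = int(cfg.get("pupil_shape", 2))
    sessions = [
        synth.generate_pupil_session(
            shape, (1.2, 0.8, 1.5), irf,
            rng.lognormal(np.log(0.7), 0.3, int(cfg.get("pupil_trials", 30))),
            noise_sd=float(cfg.get("pupil_noise", 1.0)), seed=int(rng.integers(2**31)),
        )
        for _ in range(n_subj)
    ]
    report = pupil_mod.select_model(sessions, irf)
    table = pd.DataFrame(report["delta_bic"], columns=[f"shape_{s}" for s in report["shapes"]])
    tpath = outdir / "pupil_delta_bic.csv"
    table.to_csv(tpath, index=False)
    out = outdir / "pupil_fit.json"
    out.write_text(json.dumps({
        "generating_shape": shape,
        "winner": int(report["winner"]),
        "p_vs_winner": {str(k): v for k, v in report["p_vs_winner"].items()},
    }, indent=2))
    return [out, tpath]


def _stage_run_lca(cfg, outdir: Path, seed: int) -> list[Path]:
    p = lca_mod.LCAParams()
    sched = lca_mod.GainSchedule()
    n = int(cfg.get("lca_trials", 2000))
    frames = [
        lca_mod.simulate_lca_trials(p, sched, regime, n, seed=stage_seed(seed, regime))
        for regime in ("FR", "DL")
    ]
    trials = pd.concat(frames, ignore_index=True)
    sims = outdir / "lca_trials.csv"
    trials.to_csv(sims, index=False)
    summaries = lca_mod.dynamics_summaries(trials)
    out = outdir / "lca_summary.json"
    out.write_text(json.dumps(summaries, indent=2))
    return [out, sims]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit_caf": _stage_fit_caf,
    "fit_ddm": _stage_fit_ddm,
    "fit_pupil": _stage_fit_pupil,
    "run_lca": _stage_run_lca,
}

_STAGE_INPUTS = {
    "fit_caf": ("trials.csv",),
    "fit_ddm": ("trials.csv",),
}


def run_pipeline(config: dict) -> dict:
    """Run the configured stages in order and return the output manifest.

    ``config`` keys: ``stages`` (ordered list, default all), ``seed``
    (global seed), ``outdir``, plus per-stage options. Each stage's inputs
    must exist before it runs; a stage failure halts the run with the stage
    name. The manifest maps each output file to its SHA-256 checksum;
    rerunning with the same seed reproduces identical checksums.
    """
    stages = list(config.get("stages", DEFAULT_STAGES))
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    outdir = Path(config.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    manifest: dict[str, str] = {}
    for stage in stages:
        for req in _STAGE_INPUTS.get(stage, ()):
            if not (outdir / req).exists():
                raise FileNotFoundError(
                    f"stage {stage!r}: required input {req!r} not found in {outdir}"
                )
        log.info("running stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir, stage_seed(seed, stage))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for path in outputs:
            manifest[path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
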