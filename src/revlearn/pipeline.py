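"""End-to-end orchestration: simulate -> fit -> compare -> behavior -> rsa.

A run is fully determined by (config, seed). Each stage writes plain-text
artifacts (CSV tables, JSON summaries) into the output directory and the
run manifest records the config hash, the seed and every stage output.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import agents as agents_mod
from . import behavior as behavior_mod
from . import comparison as comparison_mod
from . import inference as inference_mod
from . import rsa as rsa_mod
from .task import TaskConfig, design_input_sequence, generate_design

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "task": {},  # TaskConfig field overrides
    "agents": {
        "model": "hgf",
        "n_subjects": 12,
        "params": {"zeta": 0.5},  # perceptual params default to Bayes-optimal
        "bayes_optimal_perceptual": True,
    },
    "fitting": {"models": ["rw", "hgf"], "n_restarts": 4},
    "bms": {"alpha0": 1.0, "n_dirichlet_samples": 100_000},
    "rsa": {
        "n_subjects": 12,
        "n_voxels": 100,
        "stim_signal": 0.0,
        "outcome_signal": 1.0,
        "noise_sd": 1.0,
        "epoch_pair": "LE-RN",
        "n_perm": 2000,
    },
}

_PERCEPTUAL_PARAM = {"rw": "alpha", "hgf": "omega"}


def make_config(overrides: dict | None = None) -> dict:
    """Default config with a nested dict of overrides merged in."""

    def merge(base, extra):
        out = copy.deepcopy(base)
        for k, v in (extra or {}).items():
            if k not in base:
                raise KeyError(f"unknown config field {k!r}")
            # task overrides and agent params are free-form leaf dicts
            if (
                isinstance(v, dict)
                and isinstance(base[k], dict)
                and k not in ("params", "task")
            ):
                out[k] = merge(base[k], v)
            else:
                out[k] = copy.deepcopy(v)
        return out

    cfg = merge(DEFAULT_CONFIG, overrides)
    if cfg["agents"]["model"] not in agents_mod.AGENTS:
        raise ValueError(
            f"agents.model: unknown model {cfg['agents']['model']!r}; "
            f"choose from {sorted(agents_mod.AGENTS)}"
        )
    for m in cfg["fitting"]["models"]:
        if m not in agents_mod.AGENTS:
            raise ValueError(f"fitting.models: unknown model {m!r}")
    return cfg


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def simulate_cohort(config: dict, seed: int | None = None) -> pd.DataFrame:
    """Simulate the configured cohort; one fresh design per subject."""
    cfg = config["agents"]
    master = np.random.SeedSequence(config["seed"] if seed is None else seed)
    task_cfg = TaskConfig(**config["task"])
    model = cfg["model"]
    frames = []
    for subj, child in enumerate(master.spawn(cfg["n_subjects"]), start=1):
        design_ss, agent_ss = child.spawn(2)
        design = generate_design(task_cfg, design_ss)
        params = dict(cfg.get("params") or {})
        if cfg.get("bayes_optimal_perceptual", True) and model in _PERCEPTUAL_PARAM:
            name = _PERCEPTUAL_PARAM[model]
            if name not in params:
                seqs = [design_input_sequence(b) for b in design]
                params[name] = inference_mod.bayes_optimal_params(model, seqs)
        frames.append(
            agents_mod.simulate(model, design, seed=agent_ss, subject=subj, **params)
        )
    return pd.concat(frames, ignore_index=True)


def fit_cohort(config: dict, trials: pd.DataFrame) -> pd.DataFrame:
    """Fit each configured model to each subject; one row per subject x model."""
    rows = []
    fit_cfg = config["fitting"]
    for subj, grp in trials.groupby("subject", sort=False):
        for model in fit_cfg["models"]:
            fit = inference_mod.fit_map(
                model,
                grp,
                n_restarts=fit_cfg["n_restarts"],
                seed=int(config["seed"]) + int(subj),
            )
            row = {
                "subject": subj,
                "model": model,
                "nll": fit.nll,
                "log_joint": fit.log_joint,
                "lme": fit.lme,
                "bic": fit.bic,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
            row.update({f"param_{k}": v for k, v in fit.params.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def bms_stage(config: dict, fits: pd.DataFrame) -> dict:
    models = config["fitting"]["models"]
    lme = fits.pivot(index="subject", columns="model", values="lme")[models].to_numpy()
    res = comparison_mod.rfx_bms(
        lme,
        alpha0=config["bms"]["alpha0"],
        seed=config["seed"],
        n_dirichlet_samples=config["bms"]["n_dirichlet_samples"],
    )
    out = {
        "models": list(models),
        "alpha": res.alpha.tolist(),
        "expected_frequencies": res.expected_frequencies.tolist(),
        "exceedance": res.exceedance.tolist(),
    }
    if len(models) == 2:
        out["delta_lme"] = comparison_mod.lme_diff(lme)["delta_lme"].tolist()
        out["n_favoring_first"] = comparison_mod.lme_diff(lme)["n_favoring_first"]
    return out


def behavior_stage(config: dict, trials: pd.DataFrame) -> dict:
    summary = behavior_mod.summarize(trials)
    return {
        "p_stay_given_correct": summary.p_stay_given_correct,
        "p_stay_given_wrong": summary.p_stay_given_wrong,
        "proportion_correct": summary.proportion_correct,
        "curve_offsets": summary.curve_offsets.tolist(),
        "curve_accuracy": summary.curve_accuracy.tolist(),
    }


def rsa_stage(config: dict) -> dict:
    cfg = config["rsa"]
    subjects = rsa_mod.synth_patterns(
        n_subjects=cfg["n_subjects"],
        n_voxels=cfg["n_voxels"],
        stim_signal=cfg["stim_signal"],
        outcome_signal=cfg["outcome_signal"],
        noise_sd=cfg["noise_sd"],
        epoch_pair=cfg["epoch_pair"],
        seed=config["seed"],
    )
    rdms = [
        rsa_mod.empirical_rdm(pre, post, cfg["epoch_pair"]) for pre, post in subjects
    ]
    out = {"epoch_pair": cfg["epoch_pair"], "n_subjects": cfg["n_subjects"]}
    for selectivity in ("stimulus", "outcome"):
        model = rsa_mod.model_rdm(selectivity)
        res = rsa_mod.group_inference(
            model=model,
            subject_rdms=rdms,
            n_perm=cfg["n_perm"],
            seed=config["seed"],
        )
        out[selectivity] = {
            "group_mean": res.group_mean,
            "signed_rank_p": res.signed_rank_p,
            "permutation_p": res.permutation_p,
            "n_permutations": res.n_permutations,
        }
    return out


_STAGES = ["simulate", "fit", "bms", "behavior", "rsa"]


def run_pipeline(config: dict | None = None, out_dir: str | Path = "runs/latest") -> Path:
    """Execute all stages, writing artifacts and a manifest into out_dir.

    Any stage failure aborts with the stage name; artifacts already written
    by earlier stages are preserved.
    """
    config = make_config(config if isinstance(config, dict) else None) if not _is_made(config) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config["seed"],
        "config_hash": config_hash(config),
        "config": config,
        "outputs": {},
    }
    state: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    def _simulate():
        trials = simulate_cohort(config)
        path = out / "trials.csv"
        trials.to_csv(path, index=False)
        manifest["outputs"]["simulate"] = path.name
        state["trials"] = trials

    def _fit():
        fits = fit_cohort(config, state["trials"])
        path = out / "fits.csv"
        fits.to_csv(path, index=False)
        manifest["outputs"]["fit"] = path.name
        state["fits"] = fits

    def _bms():
        res = bms_stage(config, state["fits"])
        path = out / "bms.json"
        path.write_text(json.dumps(res, indent=2))
        manifest["outputs"]["bms"] = path.name

    def _behavior():
        res = behavior_stage(config, state["trials"])
        path = out / "behavior.json"
        path.write_text(json.dumps(res, indent=2))
        manifest["outputs"]["behavior"] = path.name

    def _rsa():
        res = rsa_stage(config)
        path = out / "rsa.json"
        path.write_text(json.dumps(res, indent=2))
        manifest["outputs"]["rsa"] = path.name

    for name, fn in zip(_STAGES, [_simulate, _fit, _bms, _behavior, _rsa]):
        stage(name, fn)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _is_made(config) -> bool:
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)
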