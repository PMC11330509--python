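"""End-to-end analysis pipeline on generated data.

``run_pipeline`` chains every stage of the package on one synthetic
dataset: generation, psychometric quality control, choice-GLM history
kernels per environment and per split (day within a regular streak,
post-regularity neutral sessions), agent fitting with nested model
comparison, GLM-HMM engagement labelling, and the dQ / dDA analyses.
All randomness flows from one master seed recorded in the manifest;
results are written as JSON, trial tables as CSV.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, hmm, photometry, psychometric
from .agents import AgentParams
from .fitting import (SimConfig, compare_models, compute_summary_statistics,
                      fit_agent)
from .io import write_json, write_sessions
from .synth import GeneratorConfig, generate_behavior_dataset, \
    generate_photometry_dataset


@dataclass
class PipelineConfig:
    """Sizes and budgets for one pipeline run (defaults: laptop scale)."""

    seed: int = 0
    generator: GeneratorConfig | None = None
    glm_penalty: float | None = 1e-3   # None = 10-fold CV per split
    burn_in_sessions: int = 5
    fit_models: bool = True
    fit_maxfev: int = 60               # per start; small default budget
    fit_starts: int = 2
    fit_sim_days: int = 30
    hmm_inits: int = 3
    photometry_sessions: int = 4


def _day_splits(trials: pd.DataFrame) -> dict:
    """Regular sessions by day within a streak (adaptation time course)."""
    env_of = trials.groupby("session_id", sort=True)["environment"].first()
    streak = {}
    run = 0
    prev = None
    for sid, env in env_of.items():
        run = run + 1 if env == prev and env != "neutral" else 1
        streak[sid] = run
        prev = env
    out = {}
    for env in ("repeating", "alternating"):
        for day in (1, 2, 3):
            sids = [s for s, e in env_of.items()
                    if e == env and streak[s] == day]
            sub = trials[trials["session_id"].isin(sids)]
            if len(sub):
                out[f"{env}_day{day}"] = sub
    return out


def _kernel_json(fit: glm.HistoryKernelFit) -> dict:
    return {"w_contrast": {f"{k:+g}": float(v)
                           for k, v in fit.w_contrast.items()},
            "w_correct": fit.w_correct.tolist(),
            "w_error": fit.w_error.tolist(),
            "w0": fit.w0, "penalty": fit.penalty}


def run_pipeline(outdir, config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage and write results under ``outdir``.

    Returns the results dictionary that is also written to
    ``results.json``.  Stage failures abort with the stage name in the
    exception message.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator or GeneratorConfig(seed=cfg.seed)
    results: dict = {"seed": cfg.seed, "stages": []}
    log: list[str] = []

    def stage(name):
        log.append(f"[{time.strftime('%H:%M:%S')}] stage {name}")
        results["stages"].append(name)

    try:
        stage("generate")
        trials, trace = generate_behavior_dataset(gen)
        write_sessions(trials, outdir / "sessions.csv")
        trace.to_csv(outdir / "trace.csv", index=False)
        log.append(f"  generated {len(trials)} trials / "
                   f"{trials.session_id.nunique()} sessions")
    except Exception as e:
        raise RuntimeError("pipeline stage 'generate' failed") from e

    try:
        stage("qc")
        kept, report = psychometric.apply_exclusion(trials)
        results["qc"] = {
            "n_sessions_total": report.n_sessions_total,
            "n_sessions_excluded": report.n_sessions_excluded,
            "n_trials_total": report.n_trials_total,
            "n_trials_excluded_rt": report.n_trials_excluded_rt,
        }
        log.append(f"  excluded {report.n_sessions_excluded} out of "
                   f"{report.n_sessions_total} sessions; "
                   f"{report.n_trials_excluded_rt} slow trials")
    except Exception as e:
        raise RuntimeError("pipeline stage 'qc' failed") from e

    try:
        stage("glm")
        levels = np.sort(kept["signed_contrast"].unique())
        analyzed = kept[kept["session_id"] >= cfg.burn_in_sessions]
        from .fitting import environment_splits
        splits = environment_splits(kept, cfg.burn_in_sessions)
        splits.update(_day_splits(analyzed))
        kernels = {}
        for name, sub in splits.items():
            if len(sub) < 800:
                continue
            design = glm.build_design_matrix(sub, contrast_levels=levels)
            fit = glm.fit_choice_glm(design, penalty=cfg.glm_penalty,
                                     seed=cfg.seed)
            kernels[name] = _kernel_json(fit)
        results["kernels"] = kernels
        write_json(kernels, outdir / "kernels.json")
    except Exception as e:
        raise RuntimeError("pipeline stage 'glm' failed") from e

    if cfg.fit_models:
        try:
            stage("fit_agents")
            sim_cfg = SimConfig(n_days=cfg.fit_sim_days,
                                trials_per_session=gen.trials_per_session,
                                burn_in_sessions=cfg.burn_in_sessions)
            empirical = compute_summary_statistics(
                kept, penalty=0.0, burn_in_sessions=cfg.burn_in_sessions)
            from .fitting import default_starts
            fits = {}
            for variant in ("single", "multi"):
                starts = default_starts(variant)[-cfg.fit_starts:]
                fits[variant] = fit_agent(empirical, variant, starts=starts,
                                          sim_config=sim_cfg, seed=cfg.seed,
                                          maxfev=cfg.fit_maxfev)
            comp = compare_models(fits["single"].cost, fits["multi"].cost,
                                  empirical.n_summaries,
                                  fits["single"].k_params,
                                  fits["multi"].k_params)
            results["model_fits"] = {
                v: {"params": asdict(f.params), "cost": f.cost}
                for v, f in fits.items()}
            results["model_comparison"] = comp
            write_json(results["model_fits"] | {"comparison": comp},
                       outdir / "fit.json")
        except Exception as e:
            raise RuntimeError("pipeline stage 'fit_agents' failed") from e

    try:
        stage("hmm")
        neutral = kept[kept["environment"] == "neutral"]
        hfit = hmm.fit_glm_hmm(neutral, n_init=cfg.hmm_inits, seed=cfg.seed)
        labels, post = hmm.decode_states(hfit, neutral)
        results["hmm"] = {
            "weights": hfit.weights.tolist(),
            "transmat": hfit.transmat.tolist(),
            "loglik": hfit.loglik,
            "p_engaged": float((labels == 0).mean()),
        }
        engaged = neutral[labels == 0]
        disengaged = neutral[labels == 1]
        rep = {}
        for name, sub in (("engaged", engaged), ("disengaged", disengaged)):
            if len(sub) > 50:
                tab = glm.repetition_by_condition(sub, "error_run", max_run=3)
                rep[name] = tab.to_dict(orient="list")
        results["hmm"]["repetition_after_errors"] = rep
        write_json(results["hmm"], outdir / "hmm.json")
    except Exception as e:
        raise RuntimeError("pipeline stage 'hmm' failed") from e

    try:
        stage("delta_q")
        neutral_mask = (trials["environment"] == "neutral").to_numpy()
        tneu = trials[neutral_mask]
        q_pre = trace["Q_pre"].to_numpy()[neutral_mask]
        q_c = trace["Q_C"].to_numpy()[neutral_mask]
        dq_pre = photometry.delta_curve(q_pre, tneu)
        dq_post = photometry.delta_curve(q_c, tneu)
        results["delta_q"] = {
            "pre_choice": dq_pre["delta"].tolist(),
            "post_choice": dq_post["delta"].tolist(),
        }
    except Exception as e:
        raise RuntimeError("pipeline stage 'delta_q' failed") from e

    try:
        stage("photometry")
        neutral_sids = sorted(
            trials.loc[trials.environment == "neutral", "session_id"]
            .unique())[:cfg.photometry_sessions]
        sel = trials["session_id"].isin(neutral_sids).to_numpy()
        sub_trials = trials[sel].reset_index(drop=True)
        sub_trace = trace[sel].reset_index(drop=True)
        session = generate_photometry_dataset(sub_trace, sub_trials, gen)
        t, sig, ctl = session.common_grid()
        dff = photometry.compute_dff(sig, ctl, fs=session.fs)
        mat, lags, keep_idx, dropped = photometry.align_events(
            dff, session.stim_onsets, fs=session.fs)
        scal = photometry.stimulus_response(
            mat, lags, session.stim_onsets[keep_idx],
            session.outcome_times[keep_idx])
        dda = photometry.delta_curve(scal,
                                     sub_trials.iloc[keep_idx])
        results["delta_da"] = {"delta": dda["delta"].tolist(),
                               "n_events_dropped": dropped}
        write_json(results["delta_da"] | {"delta_q": results["delta_q"]},
                   outdir / "delta.json")
    except Exception as e:
        raise RuntimeError("pipeline stage 'photometry' failed") from e

    write_json(results, outdir / "results.json")
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return results
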