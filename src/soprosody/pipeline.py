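"""End-to-end orchestration: generate -> manipulate -> simulate -> filter
-> fit -> compare -> report.

A :class:`RunConfig` fully determines a run (one root seed, generator
parameter blocks, prior scales, sampler settings); every artifact is
stamped with the config hash and seed.  Stages communicate through files
in the output directory, so any later stage can be re-run from cached
inputs.  Stage order:

1.  ``simulate-contours`` — synthetic f0 contours per condition
2.  ``fit-fpca``          — FPCA model + scores of the contour set
3.  ``build-stimuli``     — 30 restyled stimulus records (+ Praat exports)
4.  ``simulate-responses``— filler-accuracy table + forced-choice trials
5.  ``filter``            — attention-check participant retention
6.  ``fit-models``        — m0–m3 posteriors under the inference prior
7.  ``bayes-factors``     — 3 evaluated terms x 3 priors BF table
8.  ``report``            — text summary + forest-style figures
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import choice_model as cm
from . import praat_io, simulate
from .contours import Contour, fit_fpca, normalize_time
from .errors import SoprosodyError
from .simulate import ContourGenParams, GenerativeParams
from .specs import OBJECTIVE_SPEC, SUBJECTIVE_SPEC
from .stimuli import SegmentedToken, StimulusRecord, build_stimulus_set, export_praat

__all__ = ["RunConfig", "STAGES", "run_pipeline", "report"]

STAGES = ("simulate-contours", "fit-fpca", "build-stimuli",
          "simulate-responses", "filter", "fit-models", "bayes-factors",
          "report")

_EVALUATED_TERMS = (
    ("prosody", "m1", "m0"),
    ("participant_sd_prosody", "m2", "m1"),
    ("pair_sd_prosody", "m3", "m2"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 1
    n_participants: int = 55
    n_contours_per_condition: int = 15
    inference_prior_sd: float = 1.5
    bf_prior_sds: tuple[float, ...] = cm.BAYES_FACTOR_SDS
    models: tuple[str, ...] = cm.MODEL_LADDER
    sampler: dict = field(default_factory=lambda: dict(cm.REDUCED_SETTINGS))
    generative: GenerativeParams = field(default_factory=GenerativeParams)
    contour_gen: ContourGenParams = field(default_factory=ContourGenParams)
    gap_ms: float = 80.0
    bf_cv_tol: float = 0.10
    out_dir: str = "soprosody_run"

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["contour_gen"] = {
            k: v for k, v in doc["contour_gen"].items()
            if not callable(v) and k not in ("mean_shape", "comp_shapes")}
        return doc

    def config_hash(self) -> str:
        doc = self.to_dict()
        doc.pop("out_dir", None)  # where a run lands does not define it
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _contours_to_frame(contours: list[Contour]) -> pd.DataFrame:
    rows = [{"label": c.label, "time_ms": t, "f0_st": v}
            for c in contours for t, v in zip(c.times, c.values)]
    return pd.DataFrame(rows)


def _contours_from_frame(df: pd.DataFrame) -> list[Contour]:
    out = []
    for label, grp in df.groupby("label", sort=True):
        out.append(Contour(times=grp["time_ms"].to_numpy(),
                           values=grp["f0_st"].to_numpy(), label=str(label)))
    return out


# --------------------------------------------------------------------- stages


def _stage_contours(config: RunConfig, out: Path) -> dict:
    contours = simulate.gen_contours(
        config.n_contours_per_condition, config.contour_gen, seed=config.seed)
    _contours_to_frame(contours).to_csv(out / "contours.csv", index=False)
    return {"n_contours": len(contours)}


def _stage_fpca(config: RunConfig, out: Path) -> dict:
    contours = _contours_from_frame(pd.read_csv(out / "contours.csv"))
    normalized = [normalize_time(c, config.contour_gen.grid_size)
                  for c in contours]
    model, scores = fit_fpca(normalized, n_components=3)
    praat_io.model_to_json(model, out / "fpca_model.json")
    pd.DataFrame({
        "label": [c.label for c in contours],
        "s1": [s.s1 for s in scores],
        "s2": [s.s2 for s in scores],
        "s3": [s.s3 for s in scores],
    }).to_csv(out / "scores.csv", index=False)
    return {"score_sds": model.score_sds.tolist()}


def _stage_stimuli(config: RunConfig, out: Path) -> dict:
    model = praat_io.model_from_json(out / "fpca_model.json")
    contours = _contours_from_frame(pd.read_csv(out / "contours.csv"))
    sources = [c for c in contours if c.label.startswith("objective")]
    sources = sources[:15]
    clips = []
    for i, conn_contour in enumerate(sources, start=1):
        dur = conn_contour.duration_ms
        token = SegmentedToken(
            segments=(("s", 0.4 * dur), ("oʊ", 0.6 * dur)),
            contour=conn_contour)
        clause_t = np.linspace(0.0, 1500.0, 31)
        clause = Contour(times=clause_t, values=2.0 - clause_t / 1000.0,
                         label=f"clause_{i:02d}")
        clips.append(StimulusRecord(
            clip_id=f"pair{i:02d}", pair_id=i, condition="source",
            event_clause_contour=clause, connective=token,
            gap_ms=config.gap_ms))
    records = build_stimulus_set(clips, model,
                                 (SUBJECTIVE_SPEC, OBJECTIVE_SPEC),
                                 grid_size=config.contour_gen.grid_size)
    stim_dir = out / "stimuli"
    manifest = []
    for rec in records:
        paths = export_praat(rec, stim_dir)
        manifest.append({
            "clip_id": rec.clip_id, "pair_id": rec.pair_id,
            "condition": rec.condition, "gap_ms": rec.gap_ms,
            "connective_duration_ms": rec.connective.total_duration_ms,
            "segments": list(rec.connective.segments),
            "pitch_tier": paths["pitch_tier"].name,
            "textgrid": paths["textgrid"].name,
        })
    (out / "stimulus_manifest.json").write_text(json.dumps(
        {**_stamp(config), "records": manifest}, indent=1, ensure_ascii=False))
    return {"n_stimuli": len(records)}


def _stage_responses(config: RunConfig, out: Path) -> dict:
    gen = dataclasses.replace(config.generative, seed=config.seed)
    fillers = simulate.gen_filler_accuracies(seed=config.seed)
    fillers = fillers.iloc[: config.n_participants]
    trials = simulate.gen_responses(config.n_participants, gen)
    fillers.to_csv(out / "filler_accuracies.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    return {"n_trials": len(trials), "n_participants": config.n_participants}


def _stage_filter(config: RunConfig, out: Path) -> dict:
    fillers = pd.read_csv(out / "filler_accuracies.csv")
    retained = cm.filter_participants(fillers)
    pd.DataFrame({"participant": retained}).to_csv(
        out / "retained_participants.csv", index=False)
    return {"n_retained": int(retained.size)}


def _retained_trials(out: Path) -> pd.DataFrame:
    trials = pd.read_csv(out / "trials.csv")
    retained = pd.read_csv(out / "retained_participants.csv")["participant"]
    return trials[trials["participant"].isin(set(retained))].reset_index(drop=True)


def _fit_seed(config: RunConfig, model: str, prior_sd: float) -> int:
    blob = f"{config.seed}:{model}:{prior_sd}"
    return int(hashlib.sha256(blob.encode()).hexdigest(), 16) % (2 ** 31)


def _stage_fit(config: RunConfig, out: Path) -> dict:
    data = _retained_trials(out)
    prior = cm.PriorSpec(config.inference_prior_sd)
    diagnostics = {}
    slopes_written = False
    for name in config.models:
        fr = cm.fit(name, data, prior, seed=_fit_seed(config, name, prior.sd),
                    on_fail="warn", **config.sampler)
        summ = cm.summarize_effects(fr)
        table = summ.table.copy()
        table.to_csv(out / f"posterior_summary_{name}.csv")
        extra = {
            **_stamp(config), "model": name, "prior_sd": prior.sd,
            "odds": summ.odds, "odds_cri": summ.odds_cri,
            "odds_ratio_mean_of_exp": summ.odds_ratio,
            "odds_ratio_exp_of_mean": summ.odds_ratio_exp_of_mean,
            "odds_ratio_cri": summ.odds_ratio_cri,
        }
        (out / f"effects_{name}.json").write_text(
            json.dumps(extra, indent=1, default=float))
        if summ.participant_slopes is not None and name == config.models[-1]:
            summ.participant_slopes.to_csv(out / "participant_slopes.csv")
            slopes_written = True
        diagnostics[name] = {
            "divergences": fr.report.n_divergent,
            "max_rhat": fr.report.max_rhat,
            "min_ess_bulk": fr.report.min_ess_bulk,
            "min_ess_tail": fr.report.min_ess_tail,
            "n_kept_draws": fr.report.n_kept_draws,
            "contract_passed": fr.report.passed,
        }
    (out / "diagnostics.json").write_text(
        json.dumps({**_stamp(config), "models": diagnostics}, indent=1))
    return {"models": list(config.models),
            "participant_slopes": slopes_written}


def _stage_bayes_factors(config: RunConfig, out: Path) -> dict:
    data = _retained_trials(out)
    rows = []
    for prior_sd in config.bf_prior_sds:
        prior = cm.PriorSpec(prior_sd)
        fits = {name: cm.fit(name, data, prior,
                             seed=_fit_seed(config, name, prior_sd),
                             on_fail="warn", **config.sampler)
                for name in config.models}
        for term, with_name, without_name in _EVALUATED_TERMS:
            if with_name not in fits or without_name not in fits:
                continue
            bf = cm.bayes_factor_from_fits(
                fits[with_name], fits[without_name],
                seed=_fit_seed(config, f"bf_{term}", prior_sd),
                cv_tol=config.bf_cv_tol)
            rows.append({
                "parameter": term, "prior": f"Normal(0, {prior_sd})",
                "bf10": bf.bf10, "band": bf.band,
                "model_with": with_name, "model_without": without_name,
            })
    pd.DataFrame(rows).to_csv(out / "bayes_factors.csv", index=False)
    return {"n_cells": len(rows)}


def _stage_report(config: RunConfig, out: Path) -> dict:
    return report(out, config)


def report(out_dir: str | Path, config: RunConfig) -> dict:
    """Render the human-readable summary and forest-style figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    required = ["effects_m0.json", "bayes_factors.csv"]
    for name in required:
        if not (out / name).exists():
            raise SoprosodyError(f"reporting requires {name}; run earlier stages")
    footer = f"[config {config.config_hash()} | seed {config.seed}]"
    lines = ["Prosody and causality interpretation: pipeline report", "=" * 54]
    m0 = json.loads((out / "effects_m0.json").read_text())
    lines.append(
        f"Baseline (m0): odds of a subjective choice {m0['odds']:.2f} "
        f"(95% CrI [{m0['odds_cri'][0]:.2f}, {m0['odds_cri'][1]:.2f}]); "
        f"odds of an objective choice {cm.reciprocal_odds(m0['odds']):.2f}.")
    final = config.models[-1]
    eff = json.loads((out / f"effects_{final}.json").read_text())
    if eff.get("odds_ratio_mean_of_exp") is not None:
        lo, hi = eff["odds_ratio_cri"]
        spans_one = lo <= 1.0 <= hi
        lines.append(
            f"Prosody effect ({final}): odds ratio "
            f"{eff['odds_ratio_mean_of_exp']:.2f} (mean of exponentiated "
            f"draws; exp of mean {eff['odds_ratio_exp_of_mean']:.2f}), "
            f"95% CrI [{lo:.2f}, {hi:.2f}]"
            + (" — the CrI spans 1: no clear prosody effect."
               if spans_one else "."))
    lines.append(footer)
    bf = pd.read_csv(out / "bayes_factors.csv")
    lines.append("\nBayes factors (BF10):")
    lines.append(bf.to_string(index=False))
    lines.append(footer)

    figures = []
    summ_path = out / f"posterior_summary_{final}.csv"
    if summ_path.exists():
        table = pd.read_csv(summ_path).set_index("parameter")
        fig, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1))
        ypos = np.arange(len(table))[::-1]
        ax.hlines(ypos, table["q2.5"], table["q97.5"], lw=1)
        ax.hlines(ypos, table["q25"], table["q75"], lw=3)
        ax.plot(table["mean"], ypos, "o", color="black")
        ax.axvline(0, ls=":", color="grey")
        ax.set_yticks(ypos, table.index)
        ax.set_xlabel("posterior (log-odds / SD scale)")
        ax.set_title(f"Population-level parameters ({final})  {footer}",
                     fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "forest_population.png", dpi=120)
        plt.close(fig)
        figures.append("forest_population.png")
    slopes_path = out / "participant_slopes.csv"
    if slopes_path.exists():
        sl = pd.read_csv(slopes_path)
        fig, ax = plt.subplots(figsize=(6, 0.18 * len(sl) + 1.2))
        ypos = np.arange(len(sl))[::-1]
        ax.hlines(ypos, sl["q2.5"], sl["q97.5"], lw=0.8)
        ax.hlines(ypos, sl["q25"], sl["q75"], lw=2.2)
        ax.plot(sl["mean"], ypos, ".", color="black")
        ax.axvline(0, ls=":", color="grey")
        ax.set_yticks(ypos, sl["participant"], fontsize=6)
        ax.set_xlabel("prosody slope (log-odds)")
        ax.set_title(f"Per-participant prosody slopes  {footer}", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "forest_participants.png", dpi=120)
        plt.close(fig)
        figures.append("forest_participants.png")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return {"report": "report.txt", "figures": figures}


_STAGE_FNS = {
    "simulate-contours": _stage_contours,
    "fit-fpca": _stage_fpca,
    "build-stimuli": _stage_stimuli,
    "simulate-responses": _stage_responses,
    "filter": _stage_filter,
    "fit-models": _stage_fit,
    "bayes-factors": _stage_bayes_factors,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the pipeline (or a subset of stages) and return the run log.

    Artifacts land in ``config.out_dir``; the machine-readable run log
    (stage, duration, outputs) is written to ``run_log.json`` there.
    """
    stages = tuple(stages) if stages else STAGES
    unknown = [s for s in stages if s not in _STAGE_FNS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(
        {**_stamp(config), "config": config.to_dict()}, indent=1, default=str))
    log: list[dict] = []
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            info = _STAGE_FNS[stage](config, out)
        except Exception as exc:
            raise SoprosodyError(f"stage '{stage}' failed: {exc}") from exc
        log.append({"stage": stage, **_stamp(config),
                    "duration_s": round(time.perf_counter() - t0, 3),
                    **info})
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return {"out_dir": str(out), "log": log}
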