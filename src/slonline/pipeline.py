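"""End-to-end orchestration: design → simulate → preprocess → stats.

Every run writes its artifacts (CSV/JSON) plus a manifest capturing the
config snapshot, the master seed, package versions and a SHA-256 hash of
each artifact, so a rerun with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__, seeding
from .config import design_from_mapping
from .designs import generate_session, get_preset, trials_to_frame
from .errors import PipelineError, SlonlineError
from .io import write_trials
from .observer import ObserverParams, simulate_responses
from .preprocess import FilterConfig, filters_for, preprocess
from .group_stats import friedman_accuracy, rm_anova_rt, summarize_conditions
from .trajectory import TrajectoryModelSpec, fit_rt_trajectory, sp2_encompassing

DEFAULT_STAGES = ("design", "simulate", "preprocess", "stats")


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"name": name, "outputs": outputs})

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _contrast_rows(omnibus, pairwise):
    rows = [dataclasses.asdict(omnibus)]
    rows += [dataclasses.asdict(r) for r in pairwise]
    return rows


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute the configured stages, writing artifacts under ``out_dir``.

    ``config`` keys: ``design`` (mapping or preset name), ``n_subjects``,
    ``seed``, optional ``observer`` (ObserverParams fields), ``filters``
    (FilterConfig fields), ``stages`` and ``stats`` (subset of
    {"group", "trajectory"}).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config=config,
        seed=seed,
        versions={
            "slonline": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        started=datetime.now(timezone.utc).isoformat(),
    )
    stages = tuple(config.get("stages", DEFAULT_STAGES))

    design_cfg = config.get("design", "exp1a")
    if isinstance(design_cfg, str):
        spec = get_preset(design_cfg)
    else:
        spec = design_from_mapping(design_cfg)
    n_subjects = int(config.get("n_subjects", 1))
    params = ObserverParams(**config.get("observer", {}))
    filt_cfg = config.get("filters")
    filters = (
        FilterConfig(**filt_cfg) if filt_cfg is not None else filters_for(spec.name)
    )

    table = None
    processed = None
    stage = "init"
    try:
        if "design" in stages:
            stage = "design"
            frames = []
            for i in range(n_subjects):
                rng = seeding.substream(seed, "design", i)
                frames.append(
                    trials_to_frame(generate_session(spec, f"sub{i:03d}", rng))
                )
            from .designs import TRIAL_COLUMNS

            table = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=TRIAL_COLUMNS)
            )
            path = out / "trials.csv"
            write_trials(table, path)
            manifest.add_stage("design", {"trials.csv": _sha256(path)})

        if "simulate" in stages:
            stage = "simulate"
            frames = []
            for sid, sub in table.groupby("subject_id", sort=False):
                i = int(sid.removeprefix("sub"))
                frames.append(
                    simulate_responses(sub, params, seeding.substream(seed, "observe", i))
                )
            table = (
                pd.concat(frames, ignore_index=True)
                if frames
                else simulate_responses(table, params, seeding.substream(seed, "observe", 0))
            )
            path = out / "responses.csv"
            write_trials(table, path)
            manifest.add_stage("simulate", {"responses.csv": _sha256(path)})

        if "preprocess" in stages:
            stage = "preprocess"
            processed, report = preprocess(table, filters)
            path = out / "preprocessed.csv"
            write_trials(processed, path)
            rpath = out / "exclusion_report.json"
            report.to_json(rpath)
            manifest.add_stage(
                "preprocess",
                {"preprocessed.csv": _sha256(path), "exclusion_report.json": _sha256(rpath)},
            )

        if "stats" in stages:
            stage = "stats"
            which = config.get(
                "stats", ["trajectory"] if spec.warmup_cycles else ["group"]
            )
            outputs = {}
            results = {}
            if "group" in which:
                summaries = summarize_conditions(processed)
                omni_rt, pair_rt = rm_anova_rt(summaries)
                omni_acc, pair_acc = friedman_accuracy(summaries)
                results["group"] = {
                    "rt": _contrast_rows(omni_rt, pair_rt),
                    "accuracy": _contrast_rows(omni_acc, pair_acc),
                }
            if "trajectory" in which:
                fit = fit_rt_trajectory(processed, TrajectoryModelSpec.full())
                comp = sp2_encompassing(processed)
                results["trajectory"] = {
                    "type3": fit.type3.to_dict(orient="records"),
                    "emm": fit.emm.to_dict(orient="records"),
                    "trends": fit.trends.to_dict(orient="records"),
                    "trend_contrasts": fit.trend_contrasts.to_dict(orient="records"),
                    "df_method": fit.df_method,
                    "encompassing": {
                        "r2_linear": comp.r2_linear,
                        "r2_log": comp.r2_log,
                        "r2_combined": comp.r2_combined,
                        "p_lin_vs_comb": comp.p_lin_vs_comb,
                        "p_log_vs_comb": comp.p_log_vs_comb,
                        "verdict": comp.verdict,
                    },
                }
            path = out / "stats.json"
            path.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
            outputs["stats.json"] = _sha256(path)
            manifest.add_stage("stats", outputs)
    except SlonlineError as err:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        raise PipelineError(stage, str(err), manifest) from err

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(out / "manifest.json")
    return manifest
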