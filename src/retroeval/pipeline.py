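"""Orchestration: simulate -> fit -> compare -> report at desk scale.

A :class:`RunConfig` fully determines a run: the synthetic cohort (size,
ground truth, noise), which model families to fit, and where to write the
report bundle. Each participant gets an RNG stream derived from
(master seed, participant index), so growing the cohort never perturbs
existing participants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import estimators
from .discounting import fit_discounting, fit_wp_pd_mix, split_lambda_groups
from .linear_models import (
    fit_absolute_preference,
    fit_lambda,
    fit_linear_weights,
    fit_windowed_preference_weights,
)
from .stats import compare_models_ttest, correlation_test, wm_preference_vector
from .synthetic_data import (
    GroundTruth,
    ParticipantConfig,
    TaskPlan,
    cohort_seed,
    generate_participant,
)

BASIC = {"peak": estimators.peak, "end": estimators.end,
         "peak_end": estimators.peak_end, "average": estimators.average}


@dataclass
class RunConfig:
    master_seed: int = 0
    n_participants: int = 10
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    rating_noise_sd: float = 0.5
    stages: tuple = ("basic", "linear")  # + "windowed", "discounting", "combined"
    out_dir: str | None = None
    # desk-scale optimizer knobs
    max_iter: int = 5000
    max_k: int = 49
    min_samples: int = 30
    plan: TaskPlan = field(default_factory=TaskPlan)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ground_truth" in raw:
            raw["ground_truth"] = GroundTruth(**raw["ground_truth"])
        if "plan" in raw:
            raw["plan"] = TaskPlan(**raw["plan"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = dataclasses.asdict(self)
        blob.pop("out_dir", None)  # where a run lands does not change it
        blob = json.dumps(blob, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _participant_config(cfg: RunConfig, index: int) -> ParticipantConfig:
    return ParticipantConfig(
        seed=cohort_seed(cfg.master_seed, index),
        ground_truth=cfg.ground_truth,
        rating_noise_sd=cfg.rating_noise_sd,
        plan=cfg.plan,
    )


def analyze_participant(data, cfg: RunConfig) -> dict:
    """Fit the configured model families for one synthetic participant."""
    out: dict = {"participant": data.seq4[0].participant_id}
    y4 = np.array([tr.remembered_utility for tr in data.seq4])
    yc = np.array([tr.remembered_utility for tr in data.continued])

    if "basic" in cfg.stages:
        out["basic_seq4"] = {
            name: correlation_test([f(tr.sequence) for tr in data.seq4], y4).pearson
            for name, f in BASIC.items()
        }
        out["basic_continued"] = {
            name: correlation_test(
                [f(tr.sequence) for tr in data.continued], yc
            ).pearson
            for name, f in BASIC.items()
        }

    if "linear" in cfg.stages:
        fo = fit_linear_weights(data.seq4, "order")
        fp = fit_linear_weights(data.seq4, "relative_preference")
        mix = fit_lambda(data.seq4, fo.weights.deviations, fp.weights.deviations)
        fa = fit_absolute_preference(data.seq4)
        out["linear"] = {
            "order_weights": fo.weights.w.tolist(),
            "order_corr": fo.correlation,
            "pref_weights": fp.weights.w.tolist(),
            "pref_corr": fp.correlation,
            "lambda": mix.extras["lambda"].lam,
            "combined_corr": mix.correlation,
            "abs_pref_weights": fa.weights.w.tolist(),
            "abs_pref_corr": fa.correlation,
        }

    wp_fit = None
    if "windowed" in cfg.stages or "combined" in cfg.stages:
        spec = estimators.select_window_size(
            data.continued, "preference_dependent",
            min_samples=cfg.min_samples, max_k=cfg.max_k,
        )
        wp_fit = fit_windowed_preference_weights(data.continued, spec.L)
        out["windowed"] = {"L": spec.L, "wp_corr": wp_fit.correlation}

    pd_fit = sd_fit = None
    if "discounting" in cfg.stages or "combined" in cfg.stages:
        sd_fit = fit_discounting(data.continued, "SD", max_iter=cfg.max_iter)
        pd_fit = fit_discounting(data.continued, "PD", max_iter=cfg.max_iter)
        out["discounting"] = {
            "sd_r": float(sd_fit.params.r),
            "sd_corr": sd_fit.correlation,
            "sd_sse": sd_fit.sse,
            "pd_knots": pd_fit.params.r.tolist(),
            "pd_corr": pd_fit.correlation,
            "pd_sse": pd_fit.sse,
        }

    if "combined" in cfg.stages:
        mix = fit_wp_pd_mix(data.continued, wp_fit, pd_fit)
        out["combined"] = {"lambda": mix.lam, "corr": mix.correlation}

    wm = wm_preference_vector(data.wm4, n_groups=4)
    out["wm"] = {
        "accuracy": wm.accuracy.tolist(),
        "variance": wm.variance,
    }
    return out


def run_experiment(config: RunConfig) -> dict:
    """Simulate a cohort, fit the requested models, and build the report."""
    per = []
    for i in range(config.n_participants):
        data = generate_participant(_participant_config(config, i), f"p{i:03d}")
        per.append(analyze_participant(data, config))

    report: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_participants": config.n_participants,
        "participants": per,
    }

    if "basic" in config.stages and len(per) >= 2:
        names = list(BASIC)
        mat = {n: [p["basic_seq4"][n] for p in per] for n in names}
        report["basic_mean_corr_seq4"] = {n: float(np.mean(mat[n])) for n in names}
        tests = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                try:
                    t, p = compare_models_ttest(mat[a], mat[b])
                    tests[f"{a}_vs_{b}"] = {"t": t, "p": p}
                except Exception as exc:  # degenerate pairs stay reported
                    tests[f"{a}_vs_{b}"] = {"error": str(exc)}
        report["basic_ttests_seq4"] = tests

    if "combined" in config.stages:
        lams = [p["combined"]["lambda"] for p in per]
        g1, g2 = split_lambda_groups(lams)
        report["lambda"] = {"values": lams, "group1": g1, "group2": g2}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n"
        )
    return report
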