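"""End-to-end orchestration: cohort -> ETS sampling -> FC -> metrics -> results directory.

A pipeline run is fully described by an AnalysisConfig (which round-trips
through JSON) and is deterministic given its seeds: rerunning the same
config produces byte-identical result files.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ets import (FCMatrix, SamplingSpec, compute_ets, compute_rss,
                  estimate_fc, rank_time_points, select_time_points,
                  aggregate_fc)
from .fingerprint import bootstrap_identification, identify
from .io import write_cohort, write_fc_table, write_json
from .model_compare import rope_compare
from .prediction import (CVSpec, REGRESSION_ALPHA_GRID, run_prediction_cv)
from .preprocess import clean_run, rss_motion_correlation
from .sc_coupling import sc_fc_correlation
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)


def default_sampling_specs(n_bins: int = 20,
                           thresholds=(5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
                           bins=(1,), bin_pairs=()) -> list[SamplingSpec]:
    specs = [SamplingSpec("full")]
    for pct in thresholds:
        specs.append(SamplingSpec("sequential_hacf", threshold_pct=pct))
        specs.append(SamplingSpec("sequential_lacf", threshold_pct=pct))
    for b in bins:
        specs.append(SamplingSpec("individual_bin", bin=b, n_bins=n_bins))
    for b1, b2 in bin_pairs:
        specs.append(SamplingSpec("combined_bins", bin_pair=(b1, b2),
                                  n_bins=n_bins))
    return specs


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; JSON-serialisable and lossless."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None      # load instead of generate when set
    sampling: list[SamplingSpec] = field(
        default_factory=lambda: default_sampling_specs())
    apply_cleaning: bool = False
    band: tuple[float, float] = (0.008, 0.08)
    run_fingerprint: bool = True
    n_boot: int = 0                    # 0 = point estimates only
    run_prediction: bool = True
    cv_scheme: str = "grouped_kfold"
    cv_k_outer: int = 10
    cv_k_inner: int = 5
    cv_n_repeats: int = 1
    alpha_grid: list[float] = field(
        default_factory=lambda: list(REGRESSION_ALPHA_GRID))
    metrics: list[str] = field(default_factory=lambda: ["pearson_r"])
    run_rope: bool = True
    rope_halfwidth: float = 0.05
    run_sc: bool = True
    run_rss_fd: bool = True
    seed: int = 0
    out_dir: str = "cofluct_results"
    write_cohort_files: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sampling"] = [vars(s) for s in self.sampling]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = dict(cohort)
            if "target_spec" in cohort:
                cohort["target_spec"] = [tuple(t) for t in cohort["target_spec"]]
            cohort = CohortConfig(**cohort)
        sampling = [
            SamplingSpec(**{k: (tuple(v) if k == "bin_pair" and v is not None
                                else v) for k, v in s.items()})
            for s in d.pop("sampling", [])
        ]
        band = tuple(d.pop("band", (0.008, 0.08)))
        return cls(cohort=cohort, sampling=sampling, band=band, **d)

    def to_json(self, path: str | Path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compute_spec_fcs(cohort: SyntheticCohort, specs: list[SamplingSpec],
                     apply_cleaning: bool = False,
                     band: tuple[float, float] = (0.008, 0.08)
                     ) -> tuple[dict[str, dict], dict]:
    """Per-run ETS/RSS once, then FC per sampling spec.

    Returns ({spec_label: {run_key: FCMatrix}}, {run_key: rss_values}).
    """
    runs = cohort.runs
    if apply_cleaning:
        runs = {k: clean_run(r, design=None, band=band)
                for k, r in sorted(runs.items())}
    rankings: dict[tuple, np.ndarray] = {}
    rss_traces: dict[tuple, np.ndarray] = {}
    for key, run in sorted(runs.items()):
        rss = compute_rss(compute_ets(run))
        rss_traces[key] = rss.values
        rankings[key] = rank_time_points(rss)
    fcs: dict[str, dict] = {}
    for spec in specs:
        label = spec.label()
        per_run = {}
        for key, run in sorted(runs.items()):
            idx = select_time_points(rankings[key], spec)
            per_run[key] = estimate_fc(run, idx, provenance={"spec": label})
        fcs[label] = per_run
    return fcs, rss_traces


def _day_vectors(per_run_fcs: dict) -> tuple[list[str], np.ndarray, np.ndarray]:
    per_day = aggregate_fc(per_run_fcs, level="per_day")
    subjects = sorted({s for (s, _d) in per_day})
    day1 = np.vstack([per_day[(s, 1)].vec for s in subjects])
    day2 = np.vstack([per_day[(s, 2)].vec for s in subjects])
    return subjects, day1, day2


def run_pipeline(config: AnalysisConfig) -> Path:
    """Execute the configured analysis and write a flat results directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_dir is not None:
        from .io import load_cohort
        cohort = load_cohort(config.cohort_dir)
    else:
        cohort = generate_cohort(config.cohort)
    if config.write_cohort_files:
        write_cohort(cohort, out / "cohort")

    try:
        fcs, rss_traces = compute_spec_fcs(
            cohort, config.sampling, config.apply_cleaning, config.band)
    except Exception as err:
        raise RuntimeError(f"stage ets_sampling failed: {err}") from err

    results: dict = {"specs": [s.label() for s in config.sampling]}

    if config.run_rss_fd:
        corrs = [rss_motion_correlation(rss_traces[k], cohort.fd_series[k])
                 for k in sorted(rss_traces)]
        results["rss_fd"] = {"mean": float(np.mean(corrs)),
                             "sd": float(np.std(corrs)),
                             "per_run": [float(c) for c in corrs]}

    if config.run_fingerprint:
        fp = {}
        for label, per_run in fcs.items():
            _, day1, day2 = _day_vectors(per_run)
            ident = identify(day1, day2)
            entry = {"i_acc": ident.i_acc, "i_self": ident.i_self,
                     "i_other": ident.i_other, "i_diff": ident.i_diff}
            if config.n_boot:
                boot = bootstrap_identification(
                    day1, day2, n_boot=config.n_boot, seed=config.seed)
                entry["bootstrap"] = boot.summary()
            fp[label] = entry
        results["fingerprint"] = fp

    prediction_scores: dict[str, dict[str, list[float]]] = {}
    if config.run_prediction and len(cohort.phenotypes.columns):
        subjects = cohort.subjects
        groups = np.array([cohort.families[s] for s in subjects])
        cv = CVSpec(scheme=config.cv_scheme, k_outer=config.cv_k_outer,
                    n_repeats=config.cv_n_repeats, k_inner=config.cv_k_inner,
                    groups=groups if config.cv_scheme == "grouped_kfold"
                    else None, seed=config.seed)
        confounds = cohort.confounds.loc[subjects].values
        pred = {}
        for label, per_run in fcs.items():
            per_subject = aggregate_fc(per_run, level="per_subject")
            feat = np.vstack([per_subject[(s,)].vec for s in subjects])
            write_fc_table({s: per_subject[(s,)] for s in subjects},
                           out / f"fc_{label}.tsv", provenance={"spec": label})
            pred[label] = {}
            prediction_scores[label] = {}
            for target in cohort.phenotypes.columns:
                y = cohort.phenotypes[target].loc[subjects].values
                res = run_prediction_cv(feat, y, confounds, cv,
                                        model="kernel_ridge",
                                        grid=config.alpha_grid,
                                        metrics=config.metrics)
                pred[label][target] = res.summary()
                prediction_scores[label][target] = \
                    res.fold_scores[config.metrics[0]]
        results["prediction"] = pred

    if config.run_rope and prediction_scores and "full" in prediction_scores:
        n = len(cohort.subjects)
        n_test = max(n // config.cv_k_outer, 1)
        rope = {}
        for label, per_target in prediction_scores.items():
            if label == "full":
                continue
            rope[label] = {}
            for target, scores in per_target.items():
                full_scores = prediction_scores["full"][target]
                r = rope_compare(np.array(scores), np.array(full_scores),
                                 rope_halfwidth=config.rope_halfwidth,
                                 n_train=n - n_test, n_test=n_test)
                rope[label][target] = r.as_dict()
        results["rope"] = rope

    if config.run_sc and cohort.sc:
        sc_res = {}
        for label, per_run in fcs.items():
            per_subject = aggregate_fc(per_run, level="per_subject")
            corrs = [sc_fc_correlation(per_subject[(s,)], cohort.sc[s])
                     for s in cohort.subjects]
            sc_res[label] = {"mean": float(np.mean(corrs)),
                             "sd": float(np.std(corrs)),
                             "per_subject": [float(c) for c in corrs]}
        results["sc_coupling"] = sc_res

    write_json(results, out / "results.json")
    config.to_json(out / "config.json")
    write_json({"package": "cofluct", "version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__, "seed": config.seed},
               out / "log.json")
    logger.info("pipeline complete: %s", out)
    return out
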