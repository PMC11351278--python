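"""End-to-end orchestration: gaze -> events -> trials -> features ->
baseline classification -> PSO selection -> selected-subset classification.

The stage chain is deterministic given a master seed: the cohort
simulator, every CV repetition and the PSO search all derive their
randomness from it, and baseline and PSO-selected classifications share
fold seeds so their comparison is paired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import CVConfig, DimensionResult, METRIC_NAMES, run_repeated
from .event_detection import EventDetectionConfig, detect_events
from .features import FEATURE_NAMES, FeatureConfig, compute_features
from .gaze_io import ScreenGeometry
from .pso_selection import PSOConfig, PSOResult, select_features
from .synthetic_data import (
    ClassEffectSpec,
    CohortData,
    CohortSpec,
    ScanpathParams,
    generate_cohort,
)
from .trial_builder import (
    CLASS_HIGH,
    CLASS_LOW,
    DIMENSION_NAMES,
    apply_inclusion,
    extract_window,
    label_trials,
    screen_trial,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "build_feature_table",
    "dimension_datasets",
    "load_run_config",
    "run_full",
    "summarize_mask_stability",
    "write_report",
]

logger = logging.getLogger("gazemind")


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: ClassEffectSpec | None = None
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    scanpath: ScanpathParams = field(default_factory=ScanpathParams)
    events: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    dimensions: Sequence[str] = DIMENSION_NAMES
    max_unclassified_fraction: float = 0.5
    min_trials_per_class: int = 10
    windows_only: bool = False
    nested_selection: bool = False
    seed: int = 0


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Top-level keys mirror the RunConfig fields (cohort, geometry,
    scanpath, events, features, cv, pso, dimensions, seed, ...); each
    section holds keyword arguments for the corresponding config
    dataclass, and omitted keys keep their defaults.  ``effects:
    default`` selects the packaged effect table, ``effects: null`` (or
    omission) the null model.
    """
    import yaml

    from .synthetic_data import DEFAULT_EFFECTS

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {
        "cohort": CohortSpec,
        "geometry": ScreenGeometry,
        "scanpath": ScanpathParams,
        "events": EventDetectionConfig,
        "features": FeatureConfig,
        "cv": CVConfig,
        "pso": PSOConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            section = raw[name]
            if "probe_interval_s" in (section or {}):
                section["probe_interval_s"] = tuple(section["probe_interval_s"])
            kwargs[name] = cls(**(section or {}))
    effects = raw.get("effects")
    if effects == "default":
        kwargs["effects"] = DEFAULT_EFFECTS
    elif isinstance(effects, dict):
        from .synthetic_data import ParamShift

        kwargs["effects"] = {dim: ParamShift(**shift) for dim, shift in effects.items()}
    for key in ("dimensions", "max_unclassified_fraction", "min_trials_per_class",
                "windows_only", "nested_selection", "seed"):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "dimensions" else raw[key]
    return RunConfig(**kwargs)


@dataclass
class RunReport:
    """Baseline and PSO-selected results for every analyzed dimension."""

    baseline: dict[str, DimensionResult]
    selected: dict[str, DimensionResult]
    masks: dict[str, list[str]]
    pso: dict[str, PSOResult]
    included: dict[str, set[str]]
    feature_table: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# cohort -> trial/feature table
# ---------------------------------------------------------------------------

def build_feature_table(
    cohort: CohortData,
    event_cfg: EventDetectionConfig = EventDetectionConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
    max_unclassified_fraction: float = 0.5,
) -> pd.DataFrame:
    """Detect events per trace, cut pre-probe windows and compute features.

    Returns one row per kept probe: trial keys, the 29 features and one
    label column per thought dimension.  Screened-out windows (too much
    unclassified time) are dropped and logged.
    """
    spec = cohort.spec
    rows = []
    n_screened = 0
    for key, group in cohort.probes.groupby("trace_key", sort=True):
        samples = cohort.traces[key]
        events, _, _, membership = detect_events(samples, cohort.geometry, event_cfg)
        windows = []
        for probe in group.itertuples(index=False):
            w = extract_window(
                events, samples, float(probe.t_sec), spec.window_s,
                membership=membership, participant=str(probe.participant),
                session=str(probe.session),
            )
            windows.append(w)
        label_trials(windows, group)
        for w in windows:
            if not screen_trial(w, max_unclassified_fraction):
                n_screened += 1
                continue
            feats = compute_features(w, feature_cfg)
            row = {
                "participant": w.participant,
                "session": w.session,
                "t_probe": w.t_probe,
                "unclassified_fraction": w.unclassified_fraction,
                **feats.to_dict(),
            }
            for dim, label in w.labels.items():
                row[f"label_{dim}"] = label
            rows.append(row)
    table = pd.DataFrame(rows)
    logger.info("feature table: %d trials kept, %d screened out", len(table), n_screened)
    return table


def dimension_datasets(
    table: pd.DataFrame,
    dimension: str,
    min_trials_per_class: int = 10,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-participant (X, y) for one dimension, after the inclusion filter.

    y is 0 for the low-end class, 1 for the high-end class; discarded
    trials never enter.
    """
    col = f"label_{dimension}"
    usable = table[table[col].isin([CLASS_LOW, CLASS_HIGH])]
    long = usable[["participant", col]].rename(columns={col: "label"})
    long = long.assign(dimension=dimension)
    included = apply_inclusion(long, min_trials_per_class)[dimension]
    datasets = {}
    for pid, group in usable.groupby("participant"):
        if str(pid) not in included:
            continue
        X = group[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = (group[col] == CLASS_HIGH).to_numpy(dtype=int)
        datasets[str(pid)] = (X, y)
    return datasets


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_full(config: RunConfig) -> RunReport:
    """Execute the whole stage chain on a simulated cohort."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    logger.info("simulating cohort: %d participants x %d sessions x %d probes",
                config.cohort.n_participants, config.cohort.n_sessions,
                config.cohort.probes_per_session)
    cohort = generate_cohort(
        config.cohort, config.effects, config.geometry, config.scanpath,
        windows_only=config.windows_only, rng=rng,
    )
    table = build_feature_table(cohort, config.events, config.features,
                                config.max_unclassified_fraction)

    baseline: dict[str, DimensionResult] = {}
    selected: dict[str, DimensionResult] = {}
    masks: dict[str, list[str]] = {}
    pso_results: dict[str, PSOResult] = {}
    included: dict[str, set[str]] = {}
    cv_cfg = replace(config.cv, seed=config.seed)
    for d_idx, dim in enumerate(config.dimensions):
        datasets = dimension_datasets(table, dim, config.min_trials_per_class)
        included[dim] = set(datasets)
        if not datasets:
            logger.warning("dimension %s: no participant passed inclusion; skipped", dim)
            continue
        logger.info("dimension %s: %d participants included", dim, len(datasets))
        baseline[dim] = run_repeated(datasets, cv_cfg)
        pso_cfg = replace(config.pso, seed=int(np.random.SeedSequence(
            entropy=config.seed, spawn_key=(1, d_idx)).generate_state(1)[0] % (2**31 - 1)))
        result = select_features(datasets, len(FEATURE_NAMES), pso_cfg, cv_cfg,
                                 nested=config.nested_selection)
        pso_results[dim] = result
        masks[dim] = [FEATURE_NAMES[i] for i in result.mask]
        # same cv seed as baseline -> identical fold splits, paired comparison
        selected[dim] = run_repeated(datasets, cv_cfg, feature_mask=result.mask)

    return RunReport(baseline=baseline, selected=selected, masks=masks,
                     pso=pso_results, included=included, feature_table=table,
                     seed=config.seed)


def summarize_mask_stability(
    masks: Sequence[Sequence[int]], n_features: int = len(FEATURE_NAMES)
) -> pd.Series:
    """Selection frequency of each feature across repeated PSO runs."""
    if len(masks) < 2:
        raise ValueError("mask stability needs at least two PSO runs")
    counts = np.zeros(n_features)
    for mask in masks:
        counts[np.asarray(mask, dtype=int)] += 1
    return pd.Series(counts / len(masks), index=list(FEATURE_NAMES)[:n_features])


def report_frame(report: RunReport) -> pd.DataFrame:
    """Long-form metrics table: dimension x condition x metric x mean/max/min."""
    rows = []
    for condition, results in (("all_features", report.baseline), ("pso_subset", report.selected)):
        for dim, res in results.items():
            for metric in METRIC_NAMES:
                rows.append({
                    "dimension": dim,
                    "condition": condition,
                    "metric": metric,
                    "mean": res.summary.loc[metric, "mean"],
                    "max": res.summary.loc[metric, "max"],
                    "min": res.summary.loc[metric, "min"],
                    "n_participants": res.n_participants,
                })
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir) -> None:
    """Write report CSV/JSON artifacts (metrics table, masks, run metadata)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_frame(report).to_csv(out / "report_dimension_metrics.csv", index=False)
    with open(out / "masks.json", "w") as fh:
        json.dump(report.masks, fh, indent=2)
    meta = {
        "seed": report.seed,
        "n_trials": int(len(report.feature_table)),
        "included": {d: sorted(p) for d, p in report.included.items()},
        "pso": {d: {"gbest_fitness": r.gbest_fitness,
                    "n_iterations": r.n_iterations,
                    "stop_reason": r.stop_reason}
                for d, r in report.pso.items()},
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
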