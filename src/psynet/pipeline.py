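"""End-to-end orchestration: simulate -> sex filter -> outcome labeling
-> baseline scan -> dyad/triad screen -> networks -> metrics -> BEST.

Every stage writes its outputs under the configured directory and is
recorded in a JSON manifest (package version, seed, config hash, output
checksums, record counts, warnings). The manifest contains nothing
time-dependent, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .baseline import DEFAULT_PRIOR, baseline_scan, write_baseline
from .best import BestConfig, compare_all_metrics
from .cohort import (
    Cohort,
    CohortValidationError,
    Outcome,
    read_catalog,
    read_cohort,
    sex_association_filter,
    write_catalog,
    write_cohort,
)
from .interactions import dyad_scan, triad_scan, write_interactions
from .network import (
    METRICS,
    build_network,
    compute_all_metrics,
    metrics_to_frame,
    shared_characteristics,
    write_network,
)
from .outcomes import HealthyRanges, classify_outcomes, derive_threshold
from .simulate import SimulationScenario, default_scenario, generate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "sex_filter", "label", "baseline", "dyads", "triads", "network", "best")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str | Path = "psynet_out"
    cohort_path: Optional[str] = None
    catalog_path: Optional[str] = None
    scenario: Optional[SimulationScenario] = None
    use_default_scenario: bool = False
    threshold: Optional[float] = None  # supplied when no labs are present
    prior: tuple[float, float] = DEFAULT_PRIOR
    min_prob: float = 0.9
    min_occurrences: int = 6
    sex_alpha: float = 0.05
    best: BestConfig = field(default_factory=BestConfig)
    rng_seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if not 0 < self.min_prob < 1:
            raise ValueError("min_prob must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.scenario is None and not self.use_default_scenario and self.cohort_path is None:
            raise ValueError("need either a cohort path or a simulation scenario")


def _config_digest(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("out_dir", None)

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in sorted(x.items(), key=lambda kv: str(kv[0]))}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (frozenset, set)):
            return sorted(x)
        if isinstance(x, Path):
            return str(x)
        return x

    blob = json.dumps(clean(d), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "psynet_version": __version__,
        "rng_seed": config.rng_seed,
        "config_sha256": _config_digest(config),
        "stages": {},
    }
    timings: dict[str, float] = {}
    enabled = set(config.stages)
    cohort: Optional[Cohort] = None
    stage = "init"
    try:
        # ------------------------------------------------- simulate / load
        if "simulate" in enabled and (config.scenario is not None or config.use_default_scenario):
            stage = "simulate"
            t0 = time.perf_counter()
            scenario = config.scenario or default_scenario(config.rng_seed)
            cohort, gt = generate_cohort(scenario)
            write_cohort(cohort, out / "cohort.csv")
            write_catalog(cohort.catalog, out / "catalog.csv")
            gt.to_json(out / "ground_truth.json")
            manifest["stages"]["simulate"] = {
                "n_records": len(cohort),
                "outputs": _outputs(out, ["cohort.csv", "catalog.csv", "ground_truth.json"]),
            }
            timings["simulate"] = time.perf_counter() - t0
        elif config.cohort_path is not None:
            stage = "load"
            catalog = read_catalog(config.catalog_path)
            cohort = read_cohort(config.cohort_path, catalog)
            manifest["stages"]["load"] = {"n_records": len(cohort)}
        if cohort is None:
            raise CohortValidationError("no cohort available (enable simulate or give a path)")

        # ------------------------------------------------------ sex filter
        if "sex_filter" in enabled:
            stage = "sex_filter"
            t0 = time.perf_counter()
            sf = sex_association_filter(cohort, config.sex_alpha)
            cohort = cohort.with_catalog(sf.retained)
            (out / "sex_filter.json").write_text(
                json.dumps(
                    {
                        "alpha": config.sex_alpha,
                        "removed": [{"id": c, "p_value": p} for c, p in sf.removed],
                        "n_retained": len(sf.retained),
                        "warnings": list(sf.warnings),
                    },
                    indent=1, sort_keys=True,
                )
                + "\n"
            )
            manifest["stages"]["sex_filter"] = {
                "n_removed": len(sf.removed),
                "n_retained": len(sf.retained),
                "warnings": list(sf.warnings),
                "outputs": _outputs(out, ["sex_filter.json"]),
            }
            timings["sex_filter"] = time.perf_counter() - t0

        # --------------------------------------------------------- labeling
        if "label" in enabled:
            stage = "label"
            t0 = time.perf_counter()
            has_labs = any(r.labs is not None for r in cohort.records)
            if has_labs:
                tr = derive_threshold(cohort, HealthyRanges())
                threshold = tr.threshold
                tr.to_json(out / "threshold.json")
                thr_outputs = _outputs(out, ["threshold.json"])
            elif config.threshold is not None:
                threshold = config.threshold
                thr_outputs = {}
            else:
                raise CohortValidationError(
                    "no lab panels in cohort and no threshold supplied"
                )
            labels = classify_outcomes(cohort, threshold)
            cohort = cohort.with_labels(labels)
            write_cohort(cohort, out / "cohort_labeled.csv")
            n_impv = sum(1 for v in labels.values() if v is Outcome.IMPV)
            manifest["stages"]["label"] = {
                "threshold": threshold,
                "n_impv": n_impv,
                "n_mc": len(labels) - n_impv,
                "outputs": {**thr_outputs, **_outputs(out, ["cohort_labeled.csv"])},
            }
            timings["label"] = time.perf_counter() - t0
        if cohort.outcome_labels is None:
            raise CohortValidationError("cohort is unlabeled and the label stage is disabled")

        # --------------------------------------------------------- baseline
        baseline_results = None
        if "baseline" in enabled:
            stage = "baseline"
            t0 = time.perf_counter()
            baseline_results, flagged = baseline_scan(cohort, config.prior, config.min_prob)
            write_baseline(baseline_results, out / "baseline.csv")
            manifest["stages"]["baseline"] = {
                "n_characteristics": len(baseline_results),
                "n_flagged": len(flagged),
                "outputs": _outputs(out, ["baseline.csv"]),
            }
            timings["baseline"] = time.perf_counter() - t0

        # ------------------------------------------------------ interactions
        for name, scan in (("dyads", dyad_scan), ("triads", triad_scan)):
            if name in enabled:
                stage = name
                if baseline_results is None:
                    raise CohortValidationError(f"{name} stage requires the baseline stage")
                t0 = time.perf_counter()
                res = scan(cohort, baseline_results, config.prior,
                           config.min_prob, config.min_occurrences)
                files = [f"{name}.csv"]
                if name == "dyads":
                    write_interactions(res, out / "dyads.csv",
                                       out / "dyads_edges.graphml", out / "dyads_edges.tsv")
                    files += ["dyads_edges.graphml", "dyads_edges.tsv"]
                else:
                    write_interactions(res, out / "triads.csv")
                counts = {
                    d: sum(1 for r in res if r.designation == d)
                    for d in ("Stay", "Swap", "Discarded")
                }
                manifest["stages"][name] = {
                    "n_tuples": len(res),
                    "designations": counts,
                    "outputs": _outputs(out, files),
                }
                timings[name] = time.perf_counter() - t0

        # ---------------------------------------------------------- network
        nets = None
        metric_dists = None
        if "network" in enabled:
            stage = "network"
            t0 = time.perf_counter()
            shared = shared_characteristics(cohort)
            nets = {
                g: build_network(cohort, g, shared) for g in ("IMPV", "MC")
            }
            dists = {}
            for g, net in nets.items():
                write_network(net, out / f"network_{g.lower()}.graphml",
                              out / f"network_{g.lower()}.tsv")
                dists[g] = compute_all_metrics(net)
            frame = metrics_to_frame(
                [d for g in nets for d in dists[g].values()]
            )
            frame.to_csv(out / "metrics.csv", index=False)
            manifest["stages"]["network"] = {
                "n_shared": len(shared),
                "n_edges": {g: nets[g].graph.number_of_edges() for g in nets},
                "outputs": _outputs(
                    out,
                    ["network_impv.graphml", "network_impv.tsv",
                     "network_mc.graphml", "network_mc.tsv", "metrics.csv"],
                ),
            }
            timings["network"] = time.perf_counter() - t0
            metric_dists = dists

        # ------------------------------------------------------------- BEST
        if "best" in enabled:
            stage = "best"
            if metric_dists is None:
                raise CohortValidationError("best stage requires the network stage")
            t0 = time.perf_counter()
            best_cfg = self_seed(config.best, config.rng_seed)
            pairs = [(metric_dists["IMPV"][m], metric_dists["MC"][m]) for m in METRICS]
            results, report = compare_all_metrics(pairs, best_cfg)
            report.to_csv(out / "best.csv", index=False)
            manifest["stages"]["best"] = {
                "n_metrics": len(results),
                "n_hdi_excluding_zero": int(
                    sum(1 for r in results if r.hdi_low > 0 or r.hdi_high < 0)
                ),
                "outputs": _outputs(out, ["best.csv"]),
            }
            timings["best"] = time.perf_counter() - t0

        skipped = [s for s in ALL_STAGES if s not in enabled]
        manifest["skipped_stages"] = skipped
        blob = json.dumps(manifest, sort_keys=True, default=str).encode()
        manifest["manifest_sha256"] = hashlib.sha256(blob).hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
        )
        (out / "timings.json").write_text(json.dumps(timings, indent=1) + "\n")
        for s, dt in timings.items():
            logger.info("stage %s: %.2fs", s, dt)
        return manifest
    except Exception as exc:  # annotate with the failing stage
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc


def self_seed(best: BestConfig, seed: int) -> BestConfig:
    """Tie the BEST seed to the pipeline seed unless explicitly set."""
    if best.rng_seed != 0:
        return best
    return dataclasses.replace(best, rng_seed=seed)


def _outputs(out: Path, names: list[str]) -> dict[str, str]:
    return {n: _sha256(out / n) for n in names if (out / n).exists()}


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (flat keys; 'best' nested)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    best_kwargs = raw.pop("best", {}) or {}
    best = BestConfig(**best_kwargs)
    prior = tuple(raw.pop("prior", DEFAULT_PRIOR))
    stages = tuple(raw.pop("stages", ALL_STAGES))
    return PipelineConfig(best=best, prior=prior, stages=stages, **raw)
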