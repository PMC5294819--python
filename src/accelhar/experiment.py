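"""Full study-replica orchestration: data, features, protocols, report.

``run_experiment`` generates (or loads) a two-context cohort, extracts
the 178-feature bank, runs the three validation protocols for every
requested classifier, and writes a deterministic JSON report plus a
classifier-by-protocol accuracy grid.  A single global seed fans out to
per-stage seeds through a stable hash, so each stage is independently
reproducible and two runs with the same config produce byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

from . import __version__
from .classifiers import CLASSIFIER_KINDS, ClassifierSpec
from .features import FeatureDataset, build_dataset
from .metrics import cross_context, format_percent, kfold_cv, metrics_report
from .synthetic import (
    Cohort,
    SyntheticConfig,
    config_from_yaml,
    default_config,
    generate_cohort,
)

logger = logging.getLogger("accelhar")

PROTOCOLS = ("inlab_cv", "lab_to_home", "home_cv")


def stage_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Everything that determines one experiment run."""

    synthetic: SyntheticConfig | None = None
    feature_csv_lab: str | None = None
    feature_csv_home: str | None = None
    classifiers: Sequence[ClassifierSpec] = field(
        default_factory=lambda: [ClassifierSpec(kind="svm")]
    )
    folds: int = 10
    ci_method: str = "clopper_pearson"
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("classifier list must be nonempty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        from_files = self.feature_csv_lab is not None and self.feature_csv_home is not None
        if self.synthetic is None and not from_files:
            self.synthetic = default_config(seed=self.seed)

    def canonical(self) -> dict:
        """JSON-serialisable view used for hashing and provenance."""
        syn = None
        if self.synthetic is not None:
            syn = {
                "n_subjects": self.synthetic.n_subjects,
                "clips_per_activity_lab": self.synthetic.clips_per_activity_lab,
                "clips_per_activity_home": self.synthetic.clips_per_activity_home,
                "sample_rate_hz": self.synthetic.sample_rate_hz,
                "clip_seconds": self.synthetic.clip_seconds,
                "subject_sd": self.synthetic.subject_sd,
                "seed": self.synthetic.seed,
                "total_clips_lab": self.synthetic.total_clips_lab,
                "total_clips_home": self.synthetic.total_clips_home,
                "context_shift": vars(self.synthetic.context_shift).copy(),
                "activity_params": {
                    k: {
                        "gravity_axis_weights": list(p.gravity_axis_weights),
                        "osc_freq_hz": p.osc_freq_hz,
                        "osc_amp_g": p.osc_amp_g,
                        "noise_sd_g": p.noise_sd_g,
                        "tremor_amp_g": p.tremor_amp_g,
                        "sway_amp_g": p.sway_amp_g,
                        "sway_peak_hz": p.sway_peak_hz,
                        "sway_width_hz": p.sway_width_hz,
                        "impact_amp_g": p.impact_amp_g,
                    }
                    for k, p in sorted(self.synthetic.activity_params.items())
                },
            }
        return {
            "synthetic": syn,
            "feature_csv_lab": self.feature_csv_lab,
            "feature_csv_home": self.feature_csv_home,
            "classifiers": [vars(s).copy() for s in self.classifiers],
            "folds": self.folds,
            "ci_method": self.ci_method,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def experiment_config_from_yaml(path: str) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "synthetic" in doc and doc["synthetic"] is not None:
        if isinstance(doc["synthetic"], str):
            kwargs["synthetic"] = config_from_yaml(doc["synthetic"])
        else:
            tmp = doc["synthetic"]
            shift = tmp.pop("context_shift", None)
            if shift is not None:
                from .synthetic import ContextShift

                tmp["context_shift"] = ContextShift(**shift)
            kwargs["synthetic"] = SyntheticConfig(**tmp)
    for key in ("feature_csv_lab", "feature_csv_home", "folds", "ci_method", "out_dir", "seed", "log_level"):
        if key in doc:
            kwargs[key] = doc[key]
    if "classifiers" in doc:
        specs = []
        for entry in doc["classifiers"]:
            if isinstance(entry, str):
                specs.append(ClassifierSpec(kind=entry))
            else:
                specs.append(ClassifierSpec(**entry))
        kwargs["classifiers"] = specs
    return ExperimentConfig(**kwargs)


def _load_datasets(config: ExperimentConfig) -> tuple[FeatureDataset, FeatureDataset]:
    if config.feature_csv_lab is not None and config.feature_csv_home is not None:
        logger.info("loading feature matrices from CSV")
        return (
            FeatureDataset.from_csv(config.feature_csv_lab),
            FeatureDataset.from_csv(config.feature_csv_home),
        )
    syn = replace(config.synthetic, seed=stage_seed(config.seed, "cohort"))
    t0 = time.perf_counter()
    cohort: Cohort = generate_cohort(syn)
    logger.info(
        "generated cohort: %d lab / %d home clips in %.1fs",
        len(cohort.lab),
        len(cohort.home),
        time.perf_counter() - t0,
    )
    t0 = time.perf_counter()
    lab = build_dataset(cohort.lab)
    home = build_dataset(cohort.home)
    logger.info("extracted features in %.1fs", time.perf_counter() - t0)
    return lab, home


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all protocol x classifier combinations; return the report dict.

    The report carries, per entry, the confusion matrix and all derived
    metrics, plus provenance (config hash, package version, seeds).  When
    ``config.out_dir`` is set the report is also written to
    ``report.json`` and the accuracy grid to ``accuracy_grid.txt``.
    """
    logging.basicConfig(level=config.log_level)
    lab, home = _load_datasets(config)

    entries: dict[str, dict] = {}
    for spec in config.classifiers:
        for protocol in PROTOCOLS:
            cv_seed = stage_seed(config.seed, f"{protocol}:{spec.kind}")
            run_spec = replace(spec, seed=cv_seed)
            t0 = time.perf_counter()
            if protocol == "inlab_cv":
                cm = kfold_cv(lab, run_spec, folds=config.folds, seed=cv_seed)
            elif protocol == "home_cv":
                cm = kfold_cv(home, run_spec, folds=config.folds, seed=cv_seed)
            else:
                cm = cross_context(lab, home, run_spec)
            entry = metrics_report(cm, ci_method=config.ci_method)
            logger.info(
                "%s / %s: accuracy %s (%.1fs)",
                protocol,
                spec.kind,
                entry["accuracy_pct"],
                time.perf_counter() - t0,
            )
            entries[f"{protocol}/{spec.kind}"] = entry

    best = {
        protocol: max(
            (s.kind for s in config.classifiers),
            key=lambda k: entries[f"{protocol}/{k}"]["accuracy"],
        )
        for protocol in PROTOCOLS
    }
    report = {
        "provenance": {
            "config": config.canonical(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "entries": entries,
        "best_classifier": best,
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        path = os.path.join(config.out_dir, "report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(os.path.join(config.out_dir, "accuracy_grid.txt"), "w") as fh:
            fh.write(accuracy_grid(report))
            fh.write("\n")
        logger.info("report written to %s", path)
    return report


def accuracy_grid(report: dict) -> str:
    """Protocol-by-classifier percentage grid in the study's layout."""
    kinds = [s["kind"] for s in report["provenance"]["config"]["classifiers"]]
    labels = {
        "inlab_cv": "Within-subject, in-lab",
        "lab_to_home": "Train in-lab, test at-home",
        "home_cv": "Within-subject, at-home",
    }
    width = max(len(v) for v in labels.values()) + 2
    lines = ["".ljust(width) + "".join(k.rjust(22) for k in kinds)]
    for protocol in PROTOCOLS:
        cells = []
        for k in kinds:
            pct = format_percent(report["entries"][f"{protocol}/{k}"]["accuracy"])
            flag = "*" if report["best_classifier"][protocol] == k else " "
            cells.append(f"{pct}{flag}".rjust(22))
        lines.append(labels[protocol].ljust(width) + "".join(cells))
    lines.append("(* best classifier per validation protocol)")
    return "\n".join(lines)
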