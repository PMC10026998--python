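"""Study orchestration: generate cohorts, normalize, moderate, report.

``run_study`` reproduces the full simulation design in one call: for
every configured dataset it generates (or loads) the scores, optionally
rank-normalizes them, computes descriptives and the PC1 moderator, runs
the 13-fit moderation grid, and writes one report CSV and one
descriptives JSON per dataset plus a run manifest.  Failures are
isolated per dataset.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohorts import (
    CaseSelectionParams,
    Cohort,
    CorrelationSpec,
    TaskDensityParams,
    TrueSlodrParams,
    apply_case_selection,
    apply_task_density,
    sample_mvn,
    simulate_true_slodr,
)
from .io import read_cohort_csv, write_cohort_csv
from .mcfa import McfaSettings, ModerationReport, moderation_report
from .moderator import pc1_scores
from .scaling import DescriptivesReport, describe, normalize_cohort

logger = logging.getLogger("slodrlab")

__all__ = ["DatasetSpec", "StudyConfig", "run_study", "make_fixtures", "build_cohort"]

GENERATORS = ("case-selection", "task-density", "true-slodr", "external")


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset of the study: a generator (or external CSV) plus options."""

    label: str
    generator: str
    n: int = 10_000
    seed: int = 0
    normalize: bool = False
    path: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.generator not in GENERATORS:
            raise ValueError(f"generator must be one of {GENERATORS}")
        if self.generator == "external" and not self.path:
            raise ValueError("external datasets need a path")


@dataclass(frozen=True)
class StudyConfig:
    """The full study: dataset list plus MCFA settings."""

    datasets: tuple
    mcfa: McfaSettings = McfaSettings()

    def __post_init__(self):
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ValueError("dataset labels must be unique")
        object.__setattr__(self, "datasets", tuple(self.datasets))

    @classmethod
    def default(cls, seed: int = 0, n_true_slodr: int = 10_000,
                n_task_density: int = 11_338,
                case_selection: CaseSelectionParams = CaseSelectionParams()) -> "StudyConfig":
        """The four fully synthetic datasets of the simulation design."""
        return cls(
            datasets=(
                DatasetSpec("true-slodr", "true-slodr", n=n_true_slodr, seed=seed),
                DatasetSpec("task-density", "task-density", n=n_task_density,
                            seed=seed + 1),
                DatasetSpec(
                    "case-selection", "case-selection",
                    n=case_selection.n_initial, seed=seed + 2,
                    params={"retained_count": case_selection.retained_count},
                ),
                DatasetSpec(
                    "case-selection-normalized", "case-selection",
                    n=case_selection.n_initial, seed=seed + 2, normalize=True,
                    params={"retained_count": case_selection.retained_count},
                ),
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        datasets = tuple(DatasetSpec(**d) for d in raw.get("datasets", []))
        mcfa = McfaSettings(**raw.get("mcfa", {}))
        return cls(datasets=datasets, mcfa=mcfa)

    def to_dict(self) -> dict:
        return {
            "datasets": [asdict(d) for d in self.datasets],
            "mcfa": asdict(self.mcfa),
        }


def build_cohort(spec: DatasetSpec) -> Cohort:
    """Materialize one dataset according to its spec."""
    p = dict(spec.params)
    if spec.generator == "external":
        cohort = read_cohort_csv(spec.path)
    elif spec.generator == "true-slodr":
        params = TrueSlodrParams(**{k: v for k, v in p.items()})
        cohort = simulate_true_slodr(params, spec.n, spec.seed)
    elif spec.generator == "task-density":
        corr = p.pop("correlations", None)
        cspec = (CorrelationSpec(np.asarray(corr)) if corr is not None
                 else CorrelationSpec.task_density_default())
        td = TaskDensityParams(
            left_exponent=p.pop("left_exponent", 1.08),
            right_exponent=p.pop("right_exponent", 0.93),
        )
        cohort = apply_task_density(sample_mvn(cspec, spec.n, spec.seed), td)
    else:  # case-selection
        corr = p.pop("correlations", None)
        cspec = (CorrelationSpec(np.asarray(corr)) if corr is not None
                 else CorrelationSpec.case_selection_default())
        default = CaseSelectionParams()
        if spec.n == default.n_initial:
            retained_default = default.retained_count
        else:  # keep the design's retention fraction at other sizes
            retained_default = round(
                spec.n * default.retained_count / default.n_initial
            )
        sel = CaseSelectionParams(
            n_initial=spec.n,
            retained_count=p.pop("retained_count", retained_default),
            selection_rule=p.pop("selection_rule", "retain_lowest_count"),
            threshold=p.pop("threshold", 0.3),
        )
        cohort = apply_case_selection(sample_mvn(cspec, spec.n, spec.seed), sel)
    if spec.normalize:
        cohort = normalize_cohort(cohort)
    return cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config: StudyConfig, out_dir) -> tuple:
    """Run every dataset through descriptives -> moderator -> moderation grid.

    Returns ({label: ModerationReport}, {label: DescriptivesReport},
    manifest dict).  A failing dataset is logged and skipped; the others
    proceed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict = {}
    descriptives: dict = {}
    checksums: dict = {}
    errors: dict = {}
    for spec in config.datasets:
        try:
            cohort = build_cohort(spec)
            desc = describe(cohort)
            mod = pc1_scores(cohort)
            report = moderation_report(cohort, mod, spec.label, settings=config.mcfa)
            for row in report.rows:
                for variant in ("loading", "residual", "both"):
                    logger.info(
                        "fit dataset=%s indicator=%s variant=%s dbic=%.1f converged=%s",
                        spec.label, row["indicator"], variant,
                        row.get(f"dbic_{variant}", float("nan")),
                        row.get(f"converged_{variant}"),
                    )
            cohort_path = out / f"cohort_{spec.label}.csv"
            write_cohort_csv(cohort, cohort_path)
            report_path = out / f"report_{spec.label}.csv"
            report.to_dataframe().to_csv(report_path, index=False, float_format="%.6g")
            desc_path = out / f"descriptives_{spec.label}.json"
            with open(desc_path, "w") as fh:
                json.dump(desc.to_dict(), fh, indent=2)
            for pth in (cohort_path, report_path, desc_path):
                checksums[pth.name] = _sha256(pth)
            reports[spec.label] = report
            descriptives[spec.label] = desc
        except Exception as exc:
            logger.error("dataset %s failed: %s", spec.label, exc)
            errors[spec.label] = str(exc)
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "checksums": checksums,
        "errors": errors,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return reports, descriptives, manifest


def make_fixtures(seed: int = 0, n: int = 500, out_dir=None) -> dict:
    """Miniature cohorts (one per generator) for tests and examples."""
    cs = apply_case_selection(
        sample_mvn(CorrelationSpec.case_selection_default(), int(n * 1.4), seed),
        CaseSelectionParams(n_initial=int(n * 1.4), retained_count=n),
    )
    td = apply_task_density(
        sample_mvn(CorrelationSpec.task_density_default(), n, seed + 1),
        TaskDensityParams(),
    )
    ts = simulate_true_slodr(TrueSlodrParams(), n, seed + 2)
    fixtures = {"case-selection": cs, "task-density": td, "true-slodr": ts}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, cohort in fixtures.items():
            write_cohort_csv(cohort, out / f"fixture_{label}.csv")
    return fixtures
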