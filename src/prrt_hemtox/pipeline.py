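"""End-to-end pipeline: simulate -> segment -> grade -> stats.

Every stage writes its artifacts to the output directory and the run ends
with a manifest (inputs, options, seed, SHA-256 checksums, package version).
The manifest carries no timestamps, so identical configs and seeds produce
byte-identical manifests; stage timings go to the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort
from .grading import (
    GradingRules,
    grade_profile,
    labs_from_frame,
    labs_to_frame,
    courses_from_frame,
    courses_to_frame,
    load_default_rules,
    profiles_to_frame,
    PARAMETERS,
)
from .phantom import PhantomSpec, generate_phantom
from .segmentation import (
    build_liver_histogram,
    compile_volume_report,
    fit_three_gaussians,
    identify_normal_component,
    liver_tumour_volume,
    segment_lesion_40pct,
)
from .stats import baseline_nadir_association, compare_groups, summarize_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "build_cohort_table"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see ``RunConfig.from_file``)."""

    out_dir: str
    seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    bin_width: float = 0.1
    threshold_fraction: float = 0.40
    connectivity: int = 26
    normal_component: str | int = "auto"
    grading_rules: str | None = None  # path to a rules JSON; None -> packaged CTCAE v5

    def __post_init__(self) -> None:
        self.seed = int(self.seed)
        if self.grading_rules is not None and not os.path.exists(self.grading_rules):
            raise FileNotFoundError(f"grading rules file not found: {self.grading_rules}")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) else json.load(fh)
        return cls(**raw)

    def rules(self) -> GradingRules:
        if self.grading_rules is None:
            return load_default_rules()
        return GradingRules.from_json(self.grading_rules)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write_json(obj, path: str) -> str:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
    return path


def build_cohort_table(cohort: Cohort, profiles_df: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: grade group, baseline and nadir labs, covariates."""
    base_rows = []
    for s in cohort.labs:
        row = {"patient_id": s.patient_id}
        for p in PARAMETERS:
            row[f"baseline_{p}"] = s.baseline(p)[1]
        base_rows.append(row)
    table = pd.DataFrame(base_rows).merge(profiles_df, on="patient_id").merge(cohort.patients, on="patient_id")
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    notes: list[str] = []
    rules = config.rules()

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name, t0):
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)

    # -- simulate phantom -------------------------------------------------
    t0 = stage("simulate-phantom")
    try:
        pspec = PhantomSpec(**{**config.phantom, "seed": config.phantom.get("seed", config.seed)})
        vol, truth = generate_phantom(pspec)
        artifacts.update(vol.save_nifti(config.out_dir, stem="phantom"))
        artifacts["phantom_truth"] = _write_json(
            {"spec": pspec.to_json(), "truth": truth}, os.path.join(config.out_dir, "phantom_truth.json")
        )
    except Exception as e:
        raise RuntimeError(f"stage simulate-phantom failed: {e}") from e
    done("simulate-phantom", t0)

    # -- simulate cohort ---------------------------------------------------
    t0 = stage("simulate-cohort")
    try:
        cspec_kwargs = {**config.cohort, "seed": config.cohort.get("seed", config.seed + 1)}
        cspec = CohortSpec.from_json(cspec_kwargs) if "parameters" in cspec_kwargs else CohortSpec(**cspec_kwargs)
        cohort = generate_cohort(cspec)
        labs_path = os.path.join(config.out_dir, "labs.csv")
        labs_to_frame(cohort.labs).to_csv(labs_path, index=False)
        course_path = os.path.join(config.out_dir, "course.csv")
        courses_to_frame(cohort.courses).to_csv(course_path, index=False)
        patients_path = os.path.join(config.out_dir, "patients.csv")
        cohort.patients.to_csv(patients_path, index=False)
        artifacts.update({"labs": labs_path, "course": course_path, "patients": patients_path})
    except Exception as e:
        raise RuntimeError(f"stage simulate-cohort failed: {e}") from e
    done("simulate-cohort", t0)

    # -- segment -----------------------------------------------------------
    t0 = stage("segment")
    try:
        hist = build_liver_histogram(vol, "liver", bin_width=config.bin_width)
        pd.DataFrame({"bin_left": hist.edges[:-1], "bin_right": hist.edges[1:], "count": hist.counts}).to_csv(
            os.path.join(config.out_dir, "liver_histogram.csv"), index=False
        )
        artifacts["liver_histogram"] = os.path.join(config.out_dir, "liver_histogram.csv")
        fit = fit_three_gaussians(hist)
        if not fit.converged:
            notes.append("three-Gaussian liver fit did not converge; best iterate used")
        override = None if config.normal_component == "auto" else int(config.normal_component)
        identify_normal_component(fit, override)
        liver_ml, tumour_mask = liver_tumour_volume(vol, "liver", fit)
        artifacts["mixture_fit"] = _write_json(fit.to_json(), os.path.join(config.out_dir, "mixture_fit.json"))
        import nibabel as nib

        tm_path = os.path.join(config.out_dir, "liver_tumour_mask.nii")
        nib.save(nib.Nifti1Image(tumour_mask.astype("uint8"), vol.affine), tm_path)
        artifacts["liver_tumour_mask"] = tm_path

        segments, compartments, seg_info = [], [], []
        for les, info in zip(pspec.lesions, truth["lesions"]):
            name = info["name"]
            if not vol.mask(name).any():
                notes.append(f"{name} mask empty; skipped")
                continue
            seg = segment_lesion_40pct(
                vol, name, threshold_fraction=config.threshold_fraction,
                connectivity=config.connectivity, lesion_id=name,
            )
            segments.append(seg)
            compartments.append(les.compartment)
            seg_info.append(
                {
                    "lesion_id": name,
                    "compartment": les.compartment,
                    "suvpeak": seg.suvpeak,
                    "threshold": seg.threshold,
                    "volume_ml": seg.volume_ml,
                    "peak_center": list(seg.peak_center),
                }
            )
        report = compile_volume_report(liver_ml, segments, compartments)
        artifacts["volume_report"] = _write_json(
            {"report": report.to_json(), "lesions": seg_info}, os.path.join(config.out_dir, "volume_report.json")
        )
    except Exception as e:
        raise RuntimeError(f"stage segment failed: {e}") from e
    done("segment", t0)

    # -- grade -------------------------------------------------------------
    t0 = stage("grade")
    try:
        labs = labs_from_frame(pd.read_csv(artifacts["labs"]))
        courses = {c.patient_id: c for c in courses_from_frame(pd.read_csv(artifacts["course"]))}
        profiles = [grade_profile(s, courses[s.patient_id], rules) for s in labs]
        profiles_df = profiles_to_frame(profiles)
        prof_path = os.path.join(config.out_dir, "grade_profiles.csv")
        profiles_df.to_csv(prof_path, index=False)
        artifacts["grade_profiles"] = prof_path
        timeline = {p.patient_id: p.per_cycle for p in profiles}
        artifacts["timeline"] = _write_json(timeline, os.path.join(config.out_dir, "timeline.json"))
    except Exception as e:
        raise RuntimeError(f"stage grade failed: {e}") from e
    done("grade", t0)

    # -- stats -------------------------------------------------------------
    t0 = stage("stats")
    try:
        table = build_cohort_table(cohort, profiles_df)
        table_path = os.path.join(config.out_dir, "cohort_table.csv")
        table.to_csv(table_path, index=False)
        artifacts["cohort_table"] = table_path
        comparisons, associations = [], []
        if table["grade_group"].nunique() >= 2:
            for p in PARAMETERS:
                comparisons.append(compare_groups(table, f"baseline_{p}", "grade_group").to_json())
            comparisons.append(compare_groups(table, "sex", "grade_group", kind="categorical").to_json())
            for extra in ("age", "gfr", "total_volume_ml"):
                comparisons.append(compare_groups(table, extra, "grade_group").to_json())
        else:
            notes.append("fewer than 2 grade groups; group comparisons skipped")
        for p in PARAMETERS:
            associations.append(
                baseline_nadir_association(table, f"baseline_{p}", f"{p}_nadir", parameter=p).to_json()
            )
        artifacts["stats"] = _write_json(
            {"comparisons": comparisons, "associations": associations},
            os.path.join(config.out_dir, "stats_results.json"),
        )
        summarize_cohort(
            table.drop(columns=["patient_id"]), group_col="grade_group"
        ).to_csv(os.path.join(config.out_dir, "cohort_summary.csv"), index=False)
        artifacts["cohort_summary"] = os.path.join(config.out_dir, "cohort_summary.csv")
    except Exception as e:
        raise RuntimeError(f"stage stats failed: {e}") from e
    done("stats", t0)

    manifest = {
        "package": "prrt-hemtox",
        "version": __version__,
        "seed": config.seed,
        "options": {
            "bin_width": config.bin_width,
            "threshold_fraction": config.threshold_fraction,
            "connectivity": config.connectivity,
            "normal_component": config.normal_component,
            "grading_rules": config.grading_rules or "packaged:ctcae_v5",
        },
        "phantom_spec": pspec.to_json(),
        "cohort_spec": cspec.to_json(),
        "notes": sorted(notes),
        "artifacts": {
            name: {"path": os.path.relpath(path, config.out_dir), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    _write_json(manifest, os.path.join(config.out_dir, "manifest.json"))
    return manifest
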