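"""End-to-end orchestration: simulate -> reformat -> measure -> analyze -> report.

Two run modes mirror the two halves of the synthetic module:

* ``score_level`` — draw replicate cohorts of contrast-ratio scores per
  subgroup preset, report mean AUCs over replicates, and run the full
  diagnostic analysis (ROC, closest-corner cutoff, performance with exact
  CIs, paired AUC comparison, univariate screening at p < 0.2, logistic
  model) on one representative cohort with covariates attached.
* ``image_level`` — build digital vessel phantoms, fit the centerline,
  reformat perpendicular slices, trace regions from ground-truth labels and
  measure each patient's POR/CR profile.

Re-running with the same config and seed reproduces all CSV/JSON outputs
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagstats, plaque_metrics, synth
from .reformation import fit_centerline, reformat_stack

__all__ = [
    "RunConfig",
    "HISTORICAL_CONTROL",
    "measure_phantom_patient",
    "analyze_cohort",
    "report_tables",
    "run_pipeline",
]

log = logging.getLogger("plaquecr")

#: Published 2D single-slice historical-control row (n = 80), consumed as
#: printed constants for the CI-overlap comparisons; these patients' raw data
#: are not re-analyzed here.
HISTORICAL_CONTROL = {
    "n": 80,
    "auc": 0.821,
    "auc_ci": [0.723, 0.901],
    "sensitivity": {"value": 1.00, "ci": [0.85, 1.00]},
    "specificity": {"value": 0.49, "ci": [0.36, 0.63]},
    "ppv": {"value": 0.44, "ci": [0.31, 0.59]},
    "npv": {"value": 1.00, "ci": [0.88, 1.00]},
    "cutoff": 1.16,
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str = "score_level"  # or "image_level"
    seed: int = 0
    out_dir: str = "runs/run0"
    # score-level options
    n_replicates: int = 1000
    subgroups: tuple[str, ...] = ("full_cohort", "identified", "nonidentified")
    enforce_order: bool = False
    # image-level options
    phantom_specs: tuple[synth.PhantomSpec, ...] = ()
    fov_mm: float = 40.0
    in_plane_spacing_mm: float = 0.5
    slice_spacing_mm: float = 1.0
    half_window_mm: float = 25.0
    identification_threshold_mm: float = 2.0
    cutoff_rule: str = "closest_corner"

    def __post_init__(self) -> None:
        if self.mode not in ("score_level", "image_level"):
            raise ValueError(f"invalid config field mode={self.mode!r}")
        for name in (
            "half_window_mm",
            "slice_spacing_mm",
            "in_plane_spacing_mm",
            "identification_threshold_mm",
            "fov_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid config field {name}: must be positive")
        ratio = self.half_window_mm / self.slice_spacing_mm
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "invalid config field half_window_mm: "
                "must be an integer multiple of slice_spacing_mm"
            )
        if self.cutoff_rule != "closest_corner":
            raise ValueError(f"invalid config field cutoff_rule={self.cutoff_rule!r}")
        if self.n_replicates < 1:
            raise ValueError("invalid config field n_replicates: must be >= 1")

    @property
    def half_window_slices(self) -> int:
        return int(round(self.half_window_mm / self.slice_spacing_mm))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom_specs"] = [dataclasses.asdict(s) for s in self.phantom_specs]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        specs = tuple(
            synth.PhantomSpec(**{**s, "plaque_z": tuple(s.get("plaque_z", (20.0, 60.0)))})
            for s in raw.pop("phantom_specs", [])
        )
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"invalid config field {sorted(bad)[0]!r}")
        if "subgroups" in raw:
            raw["subgroups"] = tuple(raw["subgroups"])
        return cls(phantom_specs=specs, **raw)


def _subgroup_presets(name: str) -> tuple[synth.ScorePreset, synth.ScorePreset]:
    """(occupation preset, intensity preset) for a named subgroup."""
    if name == "identified":
        p = synth.COHORT_PRESETS["identified"]
        return p, p
    return (
        synth.COHORT_PRESETS[f"{name}_max_occupation"],
        synth.COHORT_PRESETS[f"{name}_max_intensity"],
    )


def measure_phantom_patient(
    phantom: synth.Phantom, config: RunConfig | None = None
) -> plaque_metrics.PatientPlaqueProfile:
    """Run one phantom through centerline fit, reformation and measurement."""
    config = config or RunConfig(mode="image_level")
    path = fit_centerline(
        phantom.centerline_points, sample_spacing=config.slice_spacing_mm
    )
    stack = reformat_stack(
        phantom.volume,
        path,
        fov=config.fov_mm,
        in_plane_spacing=config.in_plane_spacing_mm,
    )
    # phantom ground-truth labels -> trace codes (plaque / vessel / muscle)
    lab = np.rint(phantom.labels.data).astype(int)
    trace = np.zeros_like(lab)
    trace[lab == synth.LABEL_PLAQUE] = plaque_metrics.TRACE_PLAQUE
    trace[(lab == synth.LABEL_LUMEN) | (lab == synth.LABEL_WALL)] = (
        plaque_metrics.TRACE_VESSEL
    )
    trace[lab == synth.LABEL_MUSCLE] = plaque_metrics.TRACE_MUSCLE
    label_volume = dataclasses.replace(phantom.labels, data=trace)
    label_stack = reformat_stack(
        label_volume,
        path,
        fov=config.fov_mm,
        in_plane_spacing=config.in_plane_spacing_mm,
        order=0,
        fill=0.0,
    )
    traces = plaque_metrics.traces_from_labels(stack, label_stack)
    return plaque_metrics.profile_patient(
        stack,
        traces,
        half_window_mm=config.half_window_mm,
        identification_threshold_mm=config.identification_threshold_mm,
    )


def _metric_dict(m: diagstats.Metric) -> dict:
    return {
        "value": None if not m.defined else round(m.value, 6),
        "ci": None if not m.defined else [round(m.ci[0], 6), round(m.ci[1], 6)],
        "k": m.k,
        "n": m.n,
        "defined": m.defined,
    }


def analyze_cohort(cohort: pd.DataFrame, covariates: list[str] | None = None) -> dict:
    """Full diagnostic analysis of one cohort table.

    ROC analysis per score, DeLong paired comparison between the two CR
    scores, and — when covariate columns are present — univariate screening
    at p < 0.2 followed by the multivariate logistic model (screened
    covariates plus CR_max_intensity, the score with the larger AUC).
    """
    labels = cohort["mes"].to_numpy()
    out: dict = {"n_pos": int(labels.sum()), "n_neg": int(len(labels) - labels.sum())}
    for score in ("cr_max_occ", "cr_max_int"):
        r = diagstats.roc_analysis(cohort[score], labels)
        out[score] = {
            "auc": round(r.auc, 6),
            "auc_ci": [round(r.auc_ci[0], 6), round(r.auc_ci[1], 6)],
            "cutoff": round(r.cutoff, 6),
            **{k: _metric_dict(v) for k, v in r.performance.items()},
        }
    paired = diagstats.compare_auc_paired(
        cohort["cr_max_int"], cohort["cr_max_occ"], labels
    )
    out["paired_auc"] = {
        "delta": round(paired.delta, 6),
        "ci": [round(paired.ci[0], 6), round(paired.ci[1], 6)],
        "p": round(paired.p, 6),
    }
    if covariates:
        screen = diagstats.univariate_screen(cohort, covariates)
        out["univariate_screen"] = [
            {
                "covariate": r.covariate,
                "test": r.test,
                "p": round(float(r.p), 6),
                "included": bool(r.included),
            }
            for r in screen.itertuples()
        ]
        selected = [r.covariate for r in screen.itertuples() if r.included]
        model_vars = selected + ["cr_max_int"]
        try:
            fit = diagstats.logistic_fit(cohort[model_vars], labels)
            out["logistic_model"] = {
                var: {
                    "odds_ratio": round(float(row["odds_ratio"]), 6),
                    "ci": [
                        round(float(row["or_ci_low"]), 6),
                        round(float(row["or_ci_high"]), 6),
                    ],
                    "p": round(float(row["p"]), 6),
                }
                for var, row in fit.iterrows()
            }
        except diagstats.SeparationError as exc:
            out["logistic_model"] = {"separation": str(exc)}
    return out


def report_tables(analyses: dict[str, dict]) -> dict:
    """Human-readable report mirroring the diagnostic-performance table layout.

    ``analyses`` maps subgroup name (full_cohort / identified /
    nonidentified) to :func:`analyze_cohort` output.  Missing subgroups are
    omitted with a note.  Historical-control comparisons use the CI-overlap
    rule against the published 2D single-slice row.
    """
    expected = ("full_cohort", "identified", "nonidentified")
    report: dict = {"columns": {}, "comparisons": {}, "notes": []}
    for name in expected:
        if name in analyses:
            report["columns"][name] = analyses[name]
        else:
            report["notes"].append(f"subgroup {name!r} missing; column omitted")
    full = analyses.get("full_cohort")
    if full is not None:
        report["comparisons"]["full_cohort_int_vs_occ_p"] = full["paired_auc"]["p"]
        hist = HISTORICAL_CONTROL
        for score, tag in (("cr_max_occ", "occ"), ("cr_max_int", "int")):
            report["comparisons"][f"{tag}_vs_historical_auc"] = (
                diagstats.compare_to_historical(
                    (full[score]["auc"], tuple(full[score]["auc_ci"])),
                    (hist["auc"], tuple(hist["auc_ci"])),
                )
            )
            for metric in ("sensitivity", "specificity", "ppv", "npv"):
                m = full[score][metric]
                if m["value"] is None:
                    continue
                report["comparisons"][f"{tag}_vs_historical_{metric}"] = (
                    diagstats.compare_to_historical(
                        (m["value"], tuple(m["ci"])),
                        (hist[metric]["value"], tuple(hist[metric]["ci"])),
                    )
                )
    non = analyses.get("nonidentified")
    if non is not None:
        report["comparisons"]["nonidentified_int_vs_occ_p"] = non["paired_auc"]["p"]
    report["historical_control"] = HISTORICAL_CONTROL
    return report


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run and write all artifacts to the run directory.

    Artifacts: ``config.json`` (with hash and seed), ``cohort_<name>.csv`` /
    ``report.json`` (score_level) or ``profiles.csv`` (image_level), and
    ``run.log``.  On failure the directory is marked with a ``FAILED`` file
    and completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg = config.to_dict()
        cfg["config_hash"] = config.config_hash()
        _write_json(out / "config.json", cfg)
        log.info("config hash %s seed %d mode %s", cfg["config_hash"], config.seed, config.mode)
        if config.mode == "score_level":
            _run_score_level(config, out)
        else:
            _run_image_level(config, out)
        (out / "FAILED").unlink(missing_ok=True)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("run failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_score_level(config: RunConfig, out: Path) -> None:
    mean_aucs: dict[str, dict] = {}
    analyses: dict[str, dict] = {}
    for gi, name in enumerate(config.subgroups):
        preset_occ, preset_int = _subgroup_presets(name)
        aucs_occ = np.empty(config.n_replicates)
        aucs_int = np.empty(config.n_replicates)
        first_cohort = None
        for r in range(config.n_replicates):
            seed = np.random.SeedSequence([config.seed, gi, r])
            cohort = synth.simulate_scores(
                preset_occ,
                preset_int,
                enforce_order=config.enforce_order,
                seed=np.random.default_rng(seed),
            )
            labels = cohort["mes"].to_numpy()
            aucs_occ[r] = diagstats.auc(cohort["cr_max_occ"], labels)
            aucs_int[r] = diagstats.auc(cohort["cr_max_int"], labels)
            if r == 0:
                first_cohort = cohort
        mean_aucs[name] = {
            "replicates": config.n_replicates,
            "mean_auc_cr_max_occ": round(float(aucs_occ.mean()), 6),
            "mean_auc_cr_max_int": round(float(aucs_int.mean()), 6),
            "theoretical_auc_cr_max_occ": round(preset_occ.theoretical_auc(), 6),
            "theoretical_auc_cr_max_int": round(preset_int.theoretical_auc(), 6),
        }
        cov = synth.simulate_covariates(
            synth.DEFAULT_COVARIATES,
            first_cohort["mes"],
            seed=np.random.default_rng(np.random.SeedSequence([config.seed, gi, 10**6])),
        )
        cohort = pd.concat([first_cohort, cov], axis=1)
        cohort.to_csv(out / f"cohort_{name}.csv", index=False)
        analyses[name] = analyze_cohort(cohort, covariates=list(synth.DEFAULT_COVARIATES))
        log.info("subgroup %s: mean AUCs %s", name, mean_aucs[name])
    report = report_tables(analyses)
    report["mean_auc_over_replicates"] = mean_aucs
    _write_json(out / "report.json", report)


def _run_image_level(config: RunConfig, out: Path) -> None:
    if not config.phantom_specs:
        raise ValueError("invalid config field phantom_specs: empty in image_level mode")
    rows = []
    for i, spec in enumerate(config.phantom_specs):
        phantom = synth.simulate_phantom(spec)
        profile = measure_phantom_patient(phantom, config)
        log.info(
            "patient %d: window candidates %d, identified %s",
            i,
            profile.n_window_candidates,
            profile.identified,
        )
        rows.append({"patient_id": i, **profile.to_row()})
        per_slice = pd.DataFrame(
            {
                "slice": np.arange(len(profile.por)),
                "z_mm": np.arange(len(profile.por)) * config.slice_spacing_mm,
                "por": profile.por,
                "plaque_mean": profile.plaque_mean,
            }
        )
        per_slice.to_csv(out / f"patient_{i}_slices.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)
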