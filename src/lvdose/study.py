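"""Dose-ladder robustness study.

For each synthetic case, the ED and ES phases are scanned once at the
standard dose and emulated at every lower tube current; each observer
segments every rung, functional metrics are computed per dose, and every
low-dose result is compared against the *same observer's* standard-dose
result of the same case: per-class Dice overlap and signed metric deltas
Delta = metric(dose) - metric(standard), in percentage points.  Per-dose
aggregates (mean +/- SD of Delta and |Delta|, 90th percentile of |Delta|)
feed an explicit acceptability rule that locates the lowest tube current
at which functional analysis is still trustworthy.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ct_sim, metrics as metrics_mod, phantom
from .views import ViewConfig
from .volumes import Grid, MYOCARDIUM, BLOOD_POOL

METRIC_NAMES = ("ef", "gls", "cs_basal", "cs_middle", "cs_apical",
                "wt_basal", "wt_middle", "wt_apical")

#: Metrics entering the default acceptability rule; WT is excluded by
#: default because of its intrinsically higher variability.
DEFAULT_THRESHOLD_METRICS = ("ef", "gls", "cs_basal", "cs_middle", "cs_apical")

#: Default P90 |Delta| acceptability tolerance, percentage points.
DEFAULT_TOLERANCE_PP = 2.5

STANDARD_ONLY = "standard-only"


@dataclass
class StudyReport:
    """Per-case records plus configuration; aggregates via :func:`aggregate_deltas`."""

    records: pd.DataFrame        # one row per (case, observer, dose)
    dose_list_mA: list
    observer_names: list
    config: dict
    failures: pd.DataFrame | None = None

    @property
    def standard_dose(self) -> float:
        return self.dose_list_mA[0]


def run_study(cohort, observers, geometry: ct_sim.ScanGeometry,
              acq_standard: ct_sim.AcquisitionSpec, dose_list_mA,
              seed: int, grid: Grid | None = None,
              view_config: ViewConfig | None = None) -> StudyReport:
    """Run the full ladder experiment over a phantom cohort.

    ``observers`` maps name -> observer (anything with ``.segment``).
    The first entry of ``dose_list_mA`` is the standard dose.  Observer or
    measurement failures are recorded per (case, observer, dose) rather
    than silently dropped.  Fully reproducible from ``seed``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must contain at least one case")
    if not observers:
        raise ValueError("at least one observer is required")
    dose_list_mA = [float(d) for d in dose_list_mA]
    grid = grid or Grid.centered(64, 2.25)
    view_config = view_config or ViewConfig()
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(cohort))]

    rows, failures = [], []
    for ci, (spec, cseed) in enumerate(zip(cohort, case_seeds)):
        case_id = f"case{ci:03d}"
        ladders = {}
        truth = {}
        for pi, phase in enumerate(phantom.PHASES):
            labels, image = phantom.voxelize_phase(spec, phase, grid)
            truth[phase] = labels
            ladders[phase] = ct_sim.emulate_dose_ladder(
                image, geometry, acq_standard, dose_list_mA, seed=cseed + pi)

        gt = phantom.analytic_ground_truth(spec).as_flat_dict()
        for name, obs in observers.items():
            segs = {}
            per_dose_metrics = {}
            sd_axis = None  # SD-derived planes are reused down the ladder
            for mA in dose_list_mA:
                # segmentation and measurement are recorded independently: a
                # failed functional analysis (the expected outcome at very
                # low dose) still leaves the segmentation-overlap comparison
                try:
                    seg_ed = obs.segment(ladders["ED"][mA])
                    seg_es = obs.segment(ladders["ES"][mA])
                    segs[mA] = (seg_ed, seg_es)
                except Exception as exc:
                    failures.append({"case": case_id, "observer": name, "dose_mA": mA,
                                     "stage": "segmentation", "error": str(exc)})
                    continue
                try:
                    if mA == dose_list_mA[0]:
                        # the standard-dose rung defines this case/observer's
                        # long axis and plane placements; lower rungs reuse
                        # them so dose deltas compare corresponding planes
                        from .views import estimate_long_axis
                        sd_axis = estimate_long_axis(seg_ed)
                    elif sd_axis is None:
                        raise RuntimeError("no standard-dose reference axis for this case")
                    fm = metrics_mod.compute_all(seg_ed, seg_es, view_config,
                                                 axis=sd_axis)
                    per_dose_metrics[mA] = fm.as_flat_dict()
                except Exception as exc:
                    failures.append({"case": case_id, "observer": name, "dose_mA": mA,
                                     "stage": "measurement", "error": str(exc)})
            sd = dose_list_mA[0]
            if sd not in segs:
                continue  # standard dose failed: no reference for this case/observer
            for mA in dose_list_mA:
                if mA not in segs:
                    continue
                row = {"case": case_id, "observer": name, "dose_mA": mA,
                       "is_standard": mA == sd}
                if mA == sd:
                    dice_myo = dice_pool = 1.0
                else:
                    dice_myo = 0.5 * (
                        metrics_mod.dice(segs[mA][0], segs[sd][0], MYOCARDIUM)
                        + metrics_mod.dice(segs[mA][1], segs[sd][1], MYOCARDIUM))
                    dice_pool = 0.5 * (
                        metrics_mod.dice(segs[mA][0], segs[sd][0], BLOOD_POOL)
                        + metrics_mod.dice(segs[mA][1], segs[sd][1], BLOOD_POOL))
                row["dice_vs_sd_myocardium"] = dice_myo
                row["dice_vs_sd_blood_pool"] = dice_pool
                # agreement with the generator's ground-truth labels (the
                # luxury of a synthetic cohort; not available clinically)
                for cls, tag in ((MYOCARDIUM, "myocardium"), (BLOOD_POOL, "blood_pool")):
                    row[f"dice_vs_truth_{tag}"] = 0.5 * (
                        metrics_mod.dice(segs[mA][0], truth["ED"], cls)
                        + metrics_mod.dice(segs[mA][1], truth["ES"], cls))
                has_ref = sd in per_dose_metrics
                for m in METRIC_NAMES:
                    value = per_dose_metrics.get(mA, {}).get(m, np.nan)
                    row[m] = value
                    row[f"delta_{m}"] = (value - per_dose_metrics[sd][m]
                                         if has_ref and mA in per_dose_metrics else np.nan)
                    row[f"gt_{m}"] = gt[m]
                rows.append(row)

    records = pd.DataFrame(rows)
    config = {
        "n_cases": len(cohort), "dose_list_mA": dose_list_mA, "seed": seed,
        "case_seeds": case_seeds,
        "grid": {"shape": list(grid.shape), "spacing": list(grid.spacing)},
        "geometry": {"n_detectors": geometry.n_detectors,
                     "detector_pitch_mm": geometry.detector_pitch_mm,
                     "n_angles": geometry.n_angles,
                     "mu_water_per_mm": geometry.mu_water_per_mm},
        "acquisition": {"tube_current_mA": acq_standard.tube_current_mA,
                        "I0_ref": acq_standard.I0_ref,
                        "electronic_noise_sd": acq_standard.electronic_noise_sd},
        "view_config": {"sax_fractions": dict(view_config.sax_fractions),
                        "long_axis_azimuth_deg": dict(view_config.long_axis_azimuth_deg),
                        "pixel_spacing_mm": view_config.pixel_spacing_mm,
                        "slab_thickness_mm": view_config.slab_thickness_mm},
        "strain_convention": "Lagrangian, ED reference, shortening negative",
        "threshold_rule": "lowest mA with P90(|delta|) <= tolerance at this and "
                          "every higher dose, per configured metric set "
                          "(one formalization of a narrative acceptability judgement)",
    }
    return StudyReport(
        records=records, dose_list_mA=dose_list_mA,
        observer_names=list(observers), config=config,
        failures=pd.DataFrame(failures) if failures else None,
    )


def aggregate_deltas(report: StudyReport) -> pd.DataFrame:
    """Per (observer, dose, metric): mean/SD of the signed deltas, mean/SD of
    |delta| and the linear-interpolation 90th percentile of |delta|."""
    if report.records.empty or report.records["case"].nunique() < 2:
        raise ValueError("aggregation requires a report with at least two cases")
    rows = []
    for (obs, mA), grp in report.records.groupby(["observer", "dose_mA"]):
        for m in METRIC_NAMES:
            d = grp[f"delta_{m}"].to_numpy(dtype=float)
            d = d[np.isfinite(d)]
            if d.size == 0:
                continue
            rows.append({
                "observer": obs, "dose_mA": mA, "metric": m, "n": d.size,
                "mean_delta": d.mean(), "sd_delta": d.std(ddof=0),
                "mean_abs_delta": np.abs(d).mean(), "sd_abs_delta": np.abs(d).std(ddof=0),
                "p90_abs_delta": float(np.percentile(np.abs(d), 90, method="linear")),
            })
    return pd.DataFrame(rows)


def find_dose_threshold(summary: pd.DataFrame, tolerances: dict | float | None = None,
                        metric_set=DEFAULT_THRESHOLD_METRICS) -> dict:
    """Lowest acceptable tube current per observer.

    Acceptability at a dose requires P90(|delta|) <= tolerance for every
    metric in ``metric_set`` at that dose *and every higher non-standard
    dose* (a monotone rule).  Returns {observer: mA or "standard-only"}.
    """
    metric_set = tuple(metric_set)
    if not metric_set:
        raise ValueError("threshold metric set must not be empty")
    if tolerances is None:
        tolerances = DEFAULT_TOLERANCE_PP
    if not isinstance(tolerances, dict):
        tolerances = {m: float(tolerances) for m in metric_set}
    missing = [m for m in metric_set if m not in tolerances]
    if missing:
        raise ValueError(f"no tolerance configured for metrics: {missing}")

    out = {}
    for obs, grp in summary.groupby("observer"):
        doses = sorted(grp["dose_mA"].unique(), reverse=True)
        low_doses = doses[1:]  # exclude the standard (reference) dose
        threshold = STANDARD_ONLY
        for mA in low_doses:
            sub = grp[grp["dose_mA"] == mA].set_index("metric")["p90_abs_delta"]
            ok = all(m in sub.index and sub[m] <= tolerances[m] for m in metric_set)
            if not ok:
                break
            threshold = mA
        out[obs] = threshold
    return out


def export_report(report: StudyReport, out_dir: str, make_figures: bool = False) -> dict:
    """Write per-case and summary CSVs plus a JSON manifest (and optional
    per-dose box-plot figures).  Returns the written paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    cases_csv = os.path.join(out_dir, "cases.csv")
    report.records.to_csv(cases_csv, index=False)
    paths["cases"] = cases_csv

    summary = aggregate_deltas(report)
    summary_csv = os.path.join(out_dir, "summary.csv")
    summary.to_csv(summary_csv, index=False)
    paths["summary"] = summary_csv

    thresholds = find_dose_threshold(summary)
    manifest = {"config": report.config, "dose_list_mA": report.dose_list_mA,
                "observers": report.observer_names,
                "detected_threshold_mA": thresholds,
                "n_failures": 0 if report.failures is None else len(report.failures)}
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = manifest_path

    if report.failures is not None:
        fail_csv = os.path.join(out_dir, "failures.csv")
        report.failures.to_csv(fail_csv, index=False)
        paths["failures"] = fail_csv

    if make_figures:
        paths["figures"] = _boxplot_figures(report, out_dir)
    return paths


def _boxplot_figures(report: StudyReport, out_dir: str) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    low = [d for d in report.dose_list_mA[1:]]
    for obs in report.observer_names:
        sub = report.records[(report.records["observer"] == obs)
                             & (~report.records["is_standard"])]
        if sub.empty:
            continue
        fig, axes = plt.subplots(2, 4, figsize=(16, 7), sharex=True)
        for ax, m in zip(axes.ravel(), METRIC_NAMES):
            data = [sub[sub["dose_mA"] == d][f"delta_{m}"].dropna() for d in low]
            ax.boxplot(data, tick_labels=[f"{d:g}" for d in low])
            ax.axhline(0.0, color="grey", lw=0.5)
            ax.set_title(m)
            ax.set_xlabel("tube current (mA)")
            ax.set_ylabel("delta vs standard dose (pp)")
        fig.suptitle(f"Observer: {obs} - metric deltas vs standard dose")
        fig.tight_layout()
        p = os.path.join(out_dir, f"deltas_{obs.replace(' ', '_')}.png")
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written


def load_report(out_dir: str) -> StudyReport:
    """Re-load an exported report (CSV/JSON round trip)."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    records = pd.read_csv(os.path.join(out_dir, "cases.csv"))
    fail_path = os.path.join(out_dir, "failures.csv")
    failures = pd.read_csv(fail_path) if os.path.exists(fail_path) else None
    return StudyReport(records=records, dose_list_mA=manifest["dose_list_mA"],
                       observer_names=manifest["observers"],
                       config=manifest["config"], failures=failures)
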