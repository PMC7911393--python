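"""Pipeline stages: simulate -> segment -> aggregate -> agreement -> prognosis.

Each stage reads and writes only its declared files inside one output
directory, so stages can be re-run and tested in isolation:

    volumes/patient_XXXX.nii.gz   simulated SUV volumes (NIfTI-1)
    truth.csv                     ground-truth lesion table
    boxes.csv                     observer lesion boxes (voxel indices)
    liver.csv                     liver ROI definition per patient
    cohort.csv                    outcome records
    lesions.csv                   per-lesion segmentation results
    mtv.csv                       tidy per-patient total MTV table
    descriptive.csv / agreement.csv / comparisons.csv / bland_altman.csv
    cutoffs.csv / cox.csv / km.csv
    results.json                  machine-readable summary of all statistics

All randomness derives from one master seed; per-stage seeds are spawned
deterministically, so repeated runs with the same config and seed emit
byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import prognosis as prog
from .aggregate import total_mtv
from .config import RunConfig
from .phantom import (LiverSpec, ObserverModel, PhantomConfig, SurvivalConfig,
                      simulate_cohort)
from .segment import LiverStats, MethodSpec, compute_liver_stats
from .volume import LesionBox, read_nifti, write_nifti

log = logging.getLogger("petmtv")

BOX_COLUMNS = ["patient_id", "observer", "box_id", "lesion_id", "label",
               "low_i", "low_j", "low_k", "high_i", "high_j", "high_k"]
COHORT_COLUMNS = ["patient_id", "true_total_volume_cm3", "time_years", "event",
                  "ipi_high", "ct_chop", "volume_group_high"]


def method_specs(config: RunConfig) -> list[MethodSpec]:
    return [MethodSpec(name=name, psf_fwhm_mm=config.phantom.psf_fwhm_mm,
                       **sec.model_dump())
            for name, sec in config.methods.items()]


def observer_models(config: RunConfig) -> tuple[ObserverModel, ObserverModel]:
    return tuple(ObserverModel(box_margin_jitter=o.box_margin_jitter,
                               split_merge_probability=o.split_merge_probability)
                 for o in config.observers)  # type: ignore[return-value]


def _phantom_base(config: RunConfig) -> PhantomConfig:
    ph = config.phantom
    center = ph.liver.center_mm
    if center is None:
        extent = [ph.spacing[a] * (ph.shape[a] - 1) for a in range(3)]
        center = (0.8 * extent[0], 0.8 * extent[1], 0.5 * extent[2])
    return PhantomConfig(shape=tuple(ph.shape), spacing=tuple(ph.spacing),
                         background=ph.background, psf_fwhm_mm=ph.psf_fwhm_mm,
                         noise_sd=ph.noise_sd,
                         liver=LiverSpec(center_mm=tuple(center),
                                         radius_mm=ph.liver.radius_mm,
                                         mean_suv=ph.liver.mean_suv,
                                         sd_suv=ph.liver.sd_suv))


def _survival_config(config: RunConfig) -> SurvivalConfig:
    s = config.survival
    return SurvivalConfig(baseline_hazard=s.baseline_hazard, coef_volume=s.coef_volume,
                          coef_ipi=s.coef_ipi, coef_ct=s.coef_ct,
                          p_ipi_high=s.p_ipi_high, p_ct_chop=s.p_ct_chop,
                          volume_cutoff_cm3=s.volume_cutoff_cm3,
                          censor_low_years=s.censor_low_years,
                          censor_high_years=s.censor_high_years)


def _stage_seed(seed: int, stage: str) -> int:
    children = np.random.SeedSequence(seed).spawn(8)
    order = ["simulate", "segment", "aggregate", "agreement", "prognosis",
             "bootstrap", "spare1", "spare2"]
    return int(children[order.index(stage)].generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# IO helpers with validation


def read_boxes_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in BOX_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"boxes table {path} is missing column {col!r}")
    for ax in "ijk":
        bad = df[f"low_{ax}"] >= df[f"high_{ax}"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"boxes table {path}: low_{ax} >= high_{ax} for patient "
                f"{int(row['patient_id'])} box {int(row['box_id'])}")
    return df


def read_cohort_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort table {path} is missing column {col!r}")
    return df


def _boxes_for(df: pd.DataFrame, patient_id: int, observer: int) -> list[LesionBox]:
    sel = df[(df.patient_id == patient_id) & (df.observer == observer)]
    return [LesionBox(low=(int(r.low_i), int(r.low_j), int(r.low_k)),
                      high=(int(r.high_i), int(r.high_j), int(r.high_k)),
                      lesion_id=int(r.lesion_id), label=str(r.label) if r.label else "")
            for r in sel.itertuples()]


def _liver_stats_for(volume, liver_row) -> LiverStats:
    # measure inside 70% of the anatomical radius to stay on the uptake
    # plateau, away from PSF edge roll-off
    return compute_liver_stats(volume,
                               center_mm=(liver_row.cx, liver_row.cy, liver_row.cz),
                               radius_mm=0.7 * liver_row.radius_mm)


# ---------------------------------------------------------------------------
# Stages


def simulate_stage(config: RunConfig, seed: int, outdir: Path) -> None:
    """Generate the cohort and write volumes, truth, boxes and outcomes."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    truth_rows, box_rows, cohort_rows, liver_rows = [], [], [], []
    cohort = simulate_cohort(config.phantom.n_patients, observer_models(config),
                             survival_config=_survival_config(config),
                             phantom_base=_phantom_base(config),
                             seed=_stage_seed(seed, "simulate"))
    for bundle in cohort:
        pid = bundle.record.patient_id
        write_nifti(bundle.volume, outdir / "volumes" / f"patient_{pid:04d}.nii.gz")
        for lid, les in enumerate(bundle.truth.lesions):
            truth_rows.append({
                "patient_id": pid, "lesion_id": lid,
                "cx_mm": les.center_mm[0], "cy_mm": les.center_mm[1],
                "cz_mm": les.center_mm[2], "radius_mm": les.radius_mm,
                "uptake": les.uptake,
                "cluster_id": -1 if les.cluster_id is None else les.cluster_id,
                "true_volume_cm3": les.true_volume_cm3})
        for obs_id, boxes in bundle.boxes.items():
            for bid, box in enumerate(boxes):
                box_rows.append({
                    "patient_id": pid, "observer": obs_id, "box_id": bid,
                    "lesion_id": box.lesion_id, "label": box.label,
                    "low_i": box.low[0], "low_j": box.low[1], "low_k": box.low[2],
                    "high_i": box.high[0], "high_j": box.high[1], "high_k": box.high[2]})
        liver = bundle.truth.liver
        liver_rows.append({"patient_id": pid, "cx": liver.center_mm[0],
                           "cy": liver.center_mm[1], "cz": liver.center_mm[2],
                           "radius_mm": liver.radius_mm})
        cohort_rows.append({
            "patient_id": pid,
            "true_total_volume_cm3": bundle.record.true_total_volume_cm3,
            "time_years": bundle.record.time_years, "event": bundle.record.event,
            "ipi_high": bundle.record.ipi_high, "ct_chop": bundle.record.ct_chop,
            "volume_group_high": bundle.record.volume_group_high})
        log.info("simulate patient=%d lesions=%d", pid, len(bundle.truth.lesions))
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(box_rows).to_csv(outdir / "boxes.csv", index=False)
    pd.DataFrame(liver_rows).to_csv(outdir / "liver.csv", index=False)
    pd.DataFrame(cohort_rows).to_csv(outdir / "cohort.csv", index=False)


def _iter_patients(config: RunConfig, outdir: Path):
    boxes_df = read_boxes_csv(outdir / "boxes.csv")
    liver_df = pd.read_csv(outdir / "liver.csv").set_index("patient_id")
    for path in sorted((outdir / "volumes").glob("patient_*.nii.gz")):
        pid = int(path.stem.split("_")[1].split(".")[0])
        volume = read_nifti(path)
        liver = _liver_stats_for(volume, liver_df.loc[pid])
        yield pid, volume, liver, boxes_df


def segment_stage(config: RunConfig, outdir: Path) -> None:
    """Per-lesion segmentation audit table (method, threshold, voxels, cm^3)."""
    outdir = Path(outdir)
    specs = method_specs(config)
    rows = []
    from .segment import segment_lesion

    for pid, volume, liver, boxes_df in _iter_patients(config, outdir):
        for obs_id in (1, 2):
            boxes = _boxes_for(boxes_df, pid, obs_id)
            for bid, box in enumerate(boxes):
                for spec in specs:
                    try:
                        mask = segment_lesion(volume, box, spec, liver=liver,
                                              exclusion=boxes)
                    except (ValueError, RuntimeError) as exc:
                        raise RuntimeError(
                            f"segment stage: patient {pid} observer {obs_id} "
                            f"box {bid} method {spec.name}: {exc}") from exc
                    vol_cm3 = (mask.flags["volume_cm3"] if spec.name == "fitting"
                               else mask.n_voxels * volume.voxel_volume_cm3)
                    rows.append({"patient_id": pid, "observer": obs_id,
                                 "box_id": bid, "method": spec.name,
                                 "threshold": mask.threshold,
                                 "n_voxels": mask.n_voxels,
                                 "volume_cm3": vol_cm3})
                    log.info("segment patient=%d obs=%d box=%d method=%s T=%.3g vox=%d",
                             pid, obs_id, bid, spec.name, mask.threshold, mask.n_voxels)
    pd.DataFrame(rows).to_csv(outdir / "lesions.csv", index=False)


def aggregate_stage(config: RunConfig, outdir: Path) -> None:
    """Patient-level total MTV per (method, observer), union aggregation."""
    outdir = Path(outdir)
    specs = method_specs(config)
    rows = []
    for pid, volume, liver, boxes_df in _iter_patients(config, outdir):
        for obs_id in (1, 2):
            boxes = _boxes_for(boxes_df, pid, obs_id)
            for spec in specs:
                try:
                    mtv = total_mtv(volume, boxes, spec, liver=liver)
                except RuntimeError as exc:
                    raise RuntimeError(
                        f"aggregate stage: patient {pid} observer {obs_id} "
                        f"method {spec.name}: {exc}") from exc
                rows.append({"patient_id": pid, "observer": obs_id,
                             "method": spec.name, "mtv_cm3": mtv,
                             "spleen_included": False, "marrow_included": False})
    pd.DataFrame(rows).to_csv(outdir / "mtv.csv", index=False)


def _paired(mtv: pd.DataFrame, method: str) -> np.ndarray:
    wide = mtv[mtv.method == method].pivot(index="patient_id", columns="observer",
                                           values="mtv_cm3").sort_index()
    return wide[[1, 2]].to_numpy()


def agreement_stage(config: RunConfig, seed: int, outdir: Path,
                    plots: bool = True) -> dict:
    """Descriptive, agreement and between-method comparison tables."""
    outdir = Path(outdir)
    mtv = pd.read_csv(outdir / "mtv.csv")
    methods = list(config.methods)
    n_boot = config.stats.n_boot
    level = config.stats.level
    boot_seed = _stage_seed(seed, "bootstrap")

    desc = (mtv.groupby(["method", "observer"])["mtv_cm3"]
            .agg(mean="mean", sd="std", min="min",
                 q1=lambda s: s.quantile(0.25), median="median",
                 q3=lambda s: s.quantile(0.75), max="max")
            .reset_index())
    desc.to_csv(outdir / "descriptive.csv", index=False)

    pairs = {m: _paired(mtv, m) for m in methods}
    agree_rows, ba_rows = [], []
    for m in methods:
        for coef in ("icc", "tau"):
            res = agr.agreement_with_ci(pairs[m], coefficient=coef, n_boot=n_boot,
                                        level=level, seed=boot_seed)
            agree_rows.append({"method": m, "coefficient": coef,
                               "estimate": res.estimate, "ci_lower": res.ci_lower,
                               "ci_upper": res.ci_upper, "n_boot": n_boot})
        ba = agr.bland_altman(pairs[m])
        ba_rows.append({"method": m, "bias": ba.bias, "sd": ba.sd,
                        "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
                        "n_outside": len(ba.outside_limits)})
        if plots:
            _bland_altman_plot(ba, m, outdir / f"bland_altman_{m}.png")
    agree_df = pd.DataFrame(agree_rows)
    agree_df.to_csv(outdir / "agreement.csv", index=False)
    pd.DataFrame(ba_rows).to_csv(outdir / "bland_altman.csv", index=False)

    comp_rows = []
    if len(methods) >= 2:
        for coef in ("icc", "tau"):
            comps = agr.compare_agreement(pairs, coefficient=coef, n_boot=n_boot,
                                          level=level, seed=boot_seed)
            for c in comps:
                comp_rows.append({"coefficient": coef, "method_a": c.method_a,
                                  "method_b": c.method_b, "delta": c.delta,
                                  "ci_lower": c.ci_lower, "ci_upper": c.ci_upper,
                                  "p_raw": c.p_raw, "p_hochberg": c.p_hochberg})
    pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)

    means = {m: (float(desc[(desc.method == m) & (desc.observer == 1)]["mean"].iloc[0]),
                 float(desc[(desc.method == m) & (desc.observer == 2)]["mean"].iloc[0]))
             for m in methods}
    return {"descriptive": desc.to_dict("records"),
            "agreement": agree_rows,
            "comparisons": comp_rows,
            "bland_altman": ba_rows,
            "evaluator_mean_difference": agr.evaluator_mean_difference(means)}


def _bland_altman_plot(ba, method: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.points[:, 0], ba.points[:, 1], s=12, alpha=0.7)
    for y, style in ((ba.bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of observers (cm$^3$)")
    ax.set_ylabel("difference obs1 $-$ obs2 (cm$^3$)")
    ax.set_title(method)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def prognosis_stage(config: RunConfig, outdir: Path) -> dict:
    """Cut-off, survival and classification-disagreement tables."""
    outdir = Path(outdir)
    mtv = pd.read_csv(outdir / "mtv.csv")
    cohort = read_cohort_csv(outdir / "cohort.csv").set_index("patient_id").sort_index()
    horizon = config.survival.horizon_years
    times, events = prog.censor_at(cohort.time_years.to_numpy(),
                                   cohort.event.to_numpy(), horizon=horizon)
    outcome, evaluable, n_excl = prog.pfs_event_at_horizon(times, events, horizon)

    methods = list(config.methods)
    cut_rows, km_rows = [], []
    results: dict = {"n_excluded_from_roc": n_excl}
    for m in methods:
        arr = _paired(mtv, m)  # rows sorted by patient_id, matching cohort order
        mean_mtv = arr.mean(axis=1)
        try:
            roc_mean = prog.roc_optimal_cutoff(mean_mtv[evaluable], outcome,
                                               source="mean-of-observers",
                                               n_excluded=n_excl)
        except ValueError as exc:  # tiny smoke cohorts can be single-class
            log.warning("prognosis stage: ROC skipped for %s: %s", m, exc)
            continue
        roc1 = prog.roc_optimal_cutoff(arr[evaluable, 0], outcome, source="observer1",
                                       n_excluded=n_excl)
        roc2 = prog.roc_optimal_cutoff(arr[evaluable, 1], outcome, source="observer2",
                                       n_excluded=n_excl)
        low1 = int((arr[:, 0] < roc1.cutoff_cm3).sum())
        low2 = int((arr[:, 1] < roc2.cutoff_cm3).sum())
        cut_rows.append({
            "method": m, "se_pct": roc_mean.sensitivity_pct,
            "sp_pct": roc_mean.specificity_pct, "mean_auc": roc_mean.auc,
            "cutoff_cm3": roc_mean.cutoff_cm3, "cutoff_1_cm3": roc1.cutoff_cm3,
            "cutoff_2_cm3": roc2.cutoff_cm3,
            "abs_delta_cutoff_cm3": prog.cutoff_disagreement(roc1.cutoff_cm3,
                                                             roc2.cutoff_cm3),
            "low_mtv_1": low1, "low_mtv_2": low2,
            "abs_delta_low_mtv": prog.classification_disagreement(
                arr[:, 0], arr[:, 1], roc1.cutoff_cm3, roc2.cutoff_cm3)})

        high = mean_mtv >= roc_mean.cutoff_cm3
        if high.any() and (~high).any() and events.sum() > 0:
            chi2, p = prog.log_rank(times[~high], events[~high],
                                    times[high], events[high])
            km_low = prog.km_curve(times[~high], events[~high])
            km_high = prog.km_curve(times[high], events[high])
            km_rows.append({"method": m,
                            "pfs5_low_pct": km_low.survival_pct_at(horizon),
                            "pfs5_high_pct": km_high.survival_pct_at(horizon),
                            "logrank_chi2": chi2, "logrank_p": p})
    cut_df = pd.DataFrame(cut_rows)
    cut_df.to_csv(outdir / "cutoffs.csv", index=False)
    pd.DataFrame(km_rows).to_csv(outdir / "km.csv", index=False)

    # multivariate Cox with the reference method's MTV group + clinical covariates
    ref = "percent41" if "percent41" in methods else methods[0]
    cox_result = None
    pd.DataFrame().to_csv(outdir / "cox.csv")
    if not cut_df.empty and (cut_df.method == ref).any():
        arr = _paired(mtv, ref)
        cutoff = float(cut_df[cut_df.method == ref]["cutoff_cm3"].iloc[0])
        sample = pd.DataFrame({
            "time_years": times, "event": events,
            "mtv_high": (arr.mean(axis=1) >= cutoff).astype(int),
            "ipi_high": cohort.ipi_high.to_numpy(),
            "ct_chop": cohort.ct_chop.to_numpy()})
        try:
            fit = prog.cox_fit(sample, ["mtv_high", "ipi_high", "ct_chop"])
            fit.to_frame().to_csv(outdir / "cox.csv")
            cox_result = fit.to_frame().reset_index().to_dict("records")
        except (ValueError, RuntimeError) as exc:  # tiny smoke cohorts may separate
            log.warning("prognosis stage: Cox fit skipped: %s", exc)

    median_fu, reached = prog.reverse_km_median_followup(
        cohort.time_years.to_numpy(), cohort.event.to_numpy())
    results.update({"cutoffs": cut_rows, "km": km_rows, "cox": cox_result,
                    "cox_reference_method": ref,
                    "median_followup_years": median_fu,
                    "median_followup_reached": reached})
    return results


def simulate_and_measure(n: int, methods: list[MethodSpec],
                         observers: tuple[ObserverModel, ObserverModel],
                         survival_config: SurvivalConfig | None = None,
                         phantom_base: PhantomConfig | None = None,
                         seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory cohort measurement: tidy MTV table + outcome table.

    Streams patients so only one volume is held at a time; used by the
    larger simulation experiments where the per-patient NIfTI round-trip of
    the staged pipeline would dominate.
    """
    from .aggregate import measure_patient
    from .phantom import simulate_cohort as _simulate

    mtv_rows, cohort_rows = [], []
    for bundle in _simulate(n, observers, survival_config=survival_config,
                            phantom_base=phantom_base, seed=seed):
        liver_spec = bundle.truth.liver
        liver = compute_liver_stats(bundle.volume, liver_spec.center_mm,
                                    0.7 * liver_spec.radius_mm)
        pm = measure_patient(bundle.volume, bundle.boxes, methods, liver=liver,
                             patient_id=bundle.record.patient_id)
        for (method, obs_id), value in pm.mtv_cm3.items():
            mtv_rows.append({"patient_id": pm.patient_id, "observer": obs_id,
                             "method": method, "mtv_cm3": value})
        rec = bundle.record
        cohort_rows.append({"patient_id": rec.patient_id,
                            "true_total_volume_cm3": rec.true_total_volume_cm3,
                            "time_years": rec.time_years, "event": rec.event,
                            "ipi_high": rec.ipi_high, "ct_chop": rec.ct_chop,
                            "volume_group_high": rec.volume_group_high})
    return pd.DataFrame(mtv_rows), pd.DataFrame(cohort_rows)


def run_pipeline(config: RunConfig, seed: int, outdir: str | Path,
                 plots: bool = True) -> dict:
    """Run every stage and write a consolidated ``results.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simulate_stage(config, seed, outdir)
    segment_stage(config, outdir)
    aggregate_stage(config, outdir)
    results = {"seed": seed, "n_patients": config.phantom.n_patients,
               "methods": list(config.methods)}
    results["agreement"] = agreement_stage(config, seed, outdir, plots=plots)
    results["prognosis"] = prognosis_stage(config, outdir)
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
    return results


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
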