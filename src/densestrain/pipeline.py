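"""Orchestration: simulate -> reconstruct -> strain -> statistics, reproducibly.

A run is fully determined by its :class:`RunConfig` plus seed: the top-level
seed deterministically spawns per-subject and per-stage sub-seeds. The
results bundle is a directory of CSV/HDF5/JSON files plus a manifest echoing
the configuration, package versions and per-stage measurement counts
(attempted vs succeeded), mirroring clinical success-rate accounting.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, anatomy, io as dio, scar_stats, strain_core
from .anatomy import SA_KIND
from .phantom import CohortSpec, Subject, generate_cohort
from .recon import reconstruct_displacement
from .strain_core import deformation_gradient, global_strain, segment_layer_summary, subject_table

__all__ = ["RunConfig", "analyze_subject", "run_pipeline", "validate_bundle"]

log = logging.getLogger("densestrain")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run (serializable to JSON)."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    radius_px: float = 2.0
    min_pixels: int = 10
    specificity: float = 0.80
    differential: bool = True
    engineering_strain: bool = False
    icc_rescan_subjects: int = 9
    simulate: bool = True
    reconstruct: bool = True
    strain: bool = True
    stats: bool = True
    write_hdf5: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("contraction_scale_range", "sector_width_deg_range",
                        "sector_depth", "mixed_scale_range", "grid_shape"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            d["cohort"] = CohortSpec(**c)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def analyze_subject(subject: Subject, config: RunConfig | None = None) -> pd.DataFrame:
    """Reconstruct and summarize one subject into its 128-row strain table."""
    config = config or RunConfig()
    rows = []
    for k, sl in enumerate(subject.slices):
        images = sl.images
        contours = sl.contours
        mask = images.mask
        spacing = images.pixel_spacing_mm
        field_dec = reconstruct_displacement(images)
        tf = deformation_gradient(field_dec, radius_px=config.radius_px)
        kind = images.meta.get("slice_kind", contours.slice_kind)
        ref_angle = contours.reference_angle_deg
        if kind == SA_KIND:
            centroid = contours.centroid_mm
            segs = anatomy.assign_segments(mask, contours.level, ref_angle,
                                           centroid_mm=centroid,
                                           pixel_spacing_mm=spacing)
            layers = anatomy.transmural_depth(contours, mask, spacing)
            frames = anatomy.local_frames(mask, centroid, spacing)
            label = f"sa_{contours.level}"
        else:
            centroid = contours.centroid_mm
            segs = anatomy.assign_segments_la(mask, contours.view,
                                              center_x_mm=centroid[0],
                                              pixel_spacing_mm=spacing)
            layers = None
            frames = anatomy.local_frames_la(mask, centroid[0], spacing)
            label = f"la_{contours.view}"
        rows.extend(segment_layer_summary(
            tf, segs, layers, frames, kind, min_pixels=config.min_pixels,
            slice_label=label, subject_id=subject.subject_id,
            engineering=config.engineering_strain))
    return subject_table(rows, subject.subject_id)


def _stats_stage(strain_df: pd.DataFrame, scar_df: pd.DataFrame,
                 groups: dict, config: RunConfig):
    """Reference table, raw and differential ROC per combination, group tests."""
    control_ids = [s for s, g in groups.items() if g == "control"]
    reference = scar_stats.build_reference(strain_df, control_ids)

    merged = strain_df.merge(scar_df[["subject_id", "segment_id", "endpoint"]],
                             on=["subject_id", "segment_id"], how="left")
    merged["group"] = merged["subject_id"].map(groups)
    merged = merged.merge(reference[["segment_id", "layer", "direction", "reference_mean"]],
                          on=["segment_id", "layer", "direction"], how="left")
    merged["differential_pct"] = scar_stats.differential_strain(
        merged["strain_pct"], merged["reference_mean"])

    # segments entering the ROC: scar-group endpoint positives vs all control
    pos = merged[(merged["group"] == "scar") & merged["endpoint"] & ~merged["missing"]]
    neg = merged[(merged["group"] == "control") & ~merged["missing"]]
    roc_rows = []
    for layer, direction in strain_core.ALL_COMBINATIONS:
        for differential in ([False, True] if config.differential else [False]):
            col = "differential_pct" if differential else "strain_pct"
            p = pos[(pos["layer"] == layer) & (pos["direction"] == direction)][col]
            n = neg[(neg["layer"] == layer) & (neg["direction"] == direction)][col]
            values = np.concatenate([p.to_numpy(), n.to_numpy()])
            labels = np.concatenate([np.ones(len(p), bool), np.zeros(len(n), bool)])
            try:
                rr = scar_stats.strain_roc(values, labels, direction,
                                           differential=differential,
                                           specificity=config.specificity)
            except ValueError as exc:
                log.warning("ROC skipped for %s/%s (%s)", layer, direction, exc)
                continue
            roc_rows.append({
                "layer": layer, "direction": direction,
                "differential": differential,
                "auc": rr.auc, "cutoff": rr.cutoff_natural, "rule": rr.rule,
                "sensitivity": rr.sensitivity, "specificity": rr.specificity,
                "n_positive": rr.n_positive, "n_negative": rr.n_negative,
            })
    roc_df = pd.DataFrame(roc_rows)

    # global strain per subject, compared across groups per direction
    globals_rows = []
    for sid, sub in strain_df.groupby("subject_id"):
        g = global_strain(sub)
        g["group"] = groups.get(sid)
        globals_rows.append(g)
    globals_df = pd.concat(globals_rows, ignore_index=True)
    comp_rows = []
    for direction, sub in globals_df.groupby("direction"):
        by_group = {g: s["global_strain_pct"].to_numpy()
                    for g, s in sub.groupby("group")}
        try:
            anova, pairwise = scar_stats.group_compare(by_group)
        except ValueError:
            continue
        pairwise.insert(0, "direction", direction)
        pairwise["anova_f"] = anova["f"]
        pairwise["anova_p"] = anova["p"]
        comp_rows.append(pairwise)
    compare_df = (pd.concat(comp_rows, ignore_index=True)
                  if comp_rows else pd.DataFrame())
    return reference, roc_df, globals_df, compare_df, merged


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages and write the results bundle.

    Returns a dict of the main in-memory products (tables, manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "version": __version__,
                      "numpy": np.__version__, "stages": {}}

    if not config.simulate:
        raise ValueError("run_pipeline currently requires the simulate stage "
                         "(external input ingestion is an extension point)")
    log.info("simulating cohort (seed=%s)", config.cohort.seed)
    subjects = generate_cohort(config.cohort)
    groups = {s.subject_id: s.group for s in subjects}
    pd.DataFrame([{"subject_id": k, "group": v} for k, v in groups.items()]
                 ).to_csv(outdir / "groups.csv", index=False)
    scar_df = scar_stats.scar_table({s.subject_id: s.scar_fractions for s in subjects})
    scar_df.to_csv(outdir / "scar.csv", index=False)
    if config.write_hdf5:
        subj_dir = outdir / "subjects"
        subj_dir.mkdir(exist_ok=True)
        for s in subjects:
            dio.write_subject_h5(subj_dir / f"{s.subject_id}.h5", s)
            dio.contours_to_csv(s.slices[0].contours,
                                subj_dir / f"{s.subject_id}_contours_sa_basal.csv")
    manifest["stages"]["simulate"] = {"n_subjects": len(subjects)}

    if not (config.reconstruct and config.strain):
        manifest["stages"]["strain"] = "disabled"
        _write_manifest(outdir, manifest)
        return {"subjects": subjects, "manifest": manifest}

    tables = []
    for s in subjects:
        log.info("analysing %s", s.subject_id)
        tables.append(analyze_subject(s, config))
    strain_df = pd.concat(tables, ignore_index=True)
    strain_df.to_csv(outdir / "strain.csv", index=False)
    bullseye = strain_df[strain_df["layer"] == "transmural"][
        ["subject_id", "direction", "segment_id", "segment_name", "strain_pct"]]
    bullseye.to_csv(outdir / "bullseye.csv", index=False)
    attempted = len(strain_df)
    succeeded = int((~strain_df["missing"]).sum())
    manifest["stages"]["strain"] = {
        "measurements_attempted": attempted,
        "measurements_succeeded": succeeded,
        "success_rate": succeeded / attempted if attempted else np.nan,
    }
    log.info("strain success rate %.1f%% (%d/%d)",
             100 * succeeded / attempted, succeeded, attempted)

    if config.stats:
        reference, roc_df, globals_df, compare_df, merged = _stats_stage(
            strain_df, scar_df, groups, config)
        reference.to_csv(outdir / "reference.csv", index=False)
        roc_df.to_csv(outdir / "roc.csv", index=False)
        globals_df.to_csv(outdir / "global_strain.csv", index=False)
        compare_df.to_csv(outdir / "groups_compare.csv", index=False)
        manifest["stages"]["stats"] = {"n_roc_rows": len(roc_df)}

        icc_df = pd.DataFrame()
        if config.icc_rescan_subjects > 0:
            icc_df = _scan_rescan_icc(config, subjects, strain_df)
            icc_df.to_csv(outdir / "icc.csv", index=False)
            manifest["stages"]["icc"] = {"n_rescanned": int(min(
                config.icc_rescan_subjects, len(subjects)))}
    else:
        manifest["stages"]["stats"] = "disabled"
        roc_df = reference = globals_df = compare_df = merged = None
        icc_df = None

    _write_manifest(outdir, manifest)
    return {"subjects": subjects, "strain": strain_df, "scar": scar_df,
            "roc": roc_df, "reference": reference, "globals": globals_df,
            "compare": compare_df, "icc": icc_df, "manifest": manifest}


def _scan_rescan_icc(config: RunConfig, subjects, strain_df) -> pd.DataFrame:
    """Re-acquire a subset with fresh noise and compute per-direction ICC(2,1).

    Emulates a scan-rescan experiment: identical subjects and geometry, new
    acquisition noise, agreement measured on segmental transmural strain.
    """
    n = min(config.icc_rescan_subjects, len(subjects))
    rescan_spec = replace(config.cohort,
                          n_control=min(n, config.cohort.n_control),
                          n_mixed=0,
                          n_scar=max(0, n - config.cohort.n_control),
                          noise_seed=(config.cohort.seed + 1) % (2 ** 31))
    rescanned = generate_cohort(rescan_spec)
    tables = [analyze_subject(s, config) for s in rescanned]
    rescan_df = pd.concat(tables, ignore_index=True)
    ids = {s.subject_id for s in rescanned}
    first = strain_df[strain_df["subject_id"].isin(ids)
                      & (strain_df["layer"] == "transmural")]
    second = rescan_df[rescan_df["layer"] == "transmural"]
    rows = []
    for direction in ("radial_sa", "circumferential", "longitudinal", "radial_la"):
        a = first[first["direction"] == direction].set_index(["subject_id", "segment_id"])["strain_pct"]
        b = second[second["direction"] == direction].set_index(["subject_id", "segment_id"])["strain_pct"]
        joined = pd.concat([a, b], axis=1, keys=["scan1", "scan2"]).dropna()
        if len(joined) < 2:
            continue
        res = scar_stats.icc(joined.to_numpy())
        rows.append({"direction": direction, "icc": res.icc,
                     "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                     "n_measurements": res.n_subjects, "model": res.model})
    return pd.DataFrame(rows)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def validate_bundle(path) -> dict:
    """Schema and invariant checks over a results bundle directory."""
    path = Path(path)
    checks: list[dict] = []

    def check(name, ok, detail=""):
        checks.append({"name": name, "ok": bool(ok), "detail": detail})

    if not path.is_dir():
        return {"passed": False,
                "checks": [{"name": "bundle_exists", "ok": False,
                            "detail": f"{path} is not a directory"}]}

    for fname in ("manifest.json", "groups.csv", "scar.csv"):
        check(f"exists:{fname}", (path / fname).exists())

    strain_path = path / "strain.csv"
    check("exists:strain.csv", strain_path.exists())
    if strain_path.exists():
        df = pd.read_csv(strain_path)
        needed = {"subject_id", "segment_id", "layer", "direction",
                  "strain_pct", "n_pixels", "missing"}
        check("strain schema", needed <= set(df.columns),
              f"missing columns: {needed - set(df.columns)}")
        if needed <= set(df.columns):
            combos = set(map(tuple, df[["layer", "direction"]].drop_duplicates()
                             .itertuples(index=False)))
            extra = combos - set(strain_core.ALL_COMBINATIONS)
            check("8 layer/direction combinations", not extra,
                  f"unexpected combinations: {sorted(extra)}")
            per_subject = df.groupby("subject_id").size()
            check("128 rows per subject", bool((per_subject == 128).all()),
                  f"row counts: {sorted(per_subject.unique())}")
            seg_ok = df["segment_id"].between(1, 16).all()
            check("segment ids 1-16", bool(seg_ok))

    scar_path = path / "scar.csv"
    if scar_path.exists():
        sdf = pd.read_csv(scar_path)
        if "scar_fraction" in sdf.columns:
            check("scar fractions in [0,1]",
                  bool(sdf["scar_fraction"].between(0, 1).all()))

    roc_path = path / "roc.csv"
    if roc_path.exists():
        rdf = pd.read_csv(roc_path)
        if "auc" in rdf.columns and len(rdf):
            check("AUC in [0,1]", bool(rdf["auc"].between(0, 1).all()))

    subj_dir = path / "subjects"
    if subj_dir.is_dir():
        import h5py
        for h5 in sorted(subj_dir.glob("*.h5")):
            try:
                with h5py.File(h5, "r") as f:
                    _ = f.attrs["subject_id"]
                ok, detail = True, ""
            except Exception as exc:  # truncated / corrupt file
                ok, detail = False, f"{h5.name}: {exc}"
            check(f"hdf5 readable:{h5.name}", ok, detail)

    return {"passed": all(c["ok"] for c in checks), "checks": checks}
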