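"""End-to-end driver: simulate -> track -> reconstruct -> localise -> stats.

Per subject the reconstruction runs the two-seed strategy for each
hemisphere's tract (four tracking runs in total): the left DTCp is seeded
from left M1 (waypoints: right cerebellum + left thalamus) and from the
right cerebellum (waypoints: left M1 + left thalamus); mirrored on the
right.  Both raw maps are summed and normalised to build the combined tract
reconstruction, which is intersected with the ipsilateral thalamic mask and
adaptively thresholded to extract the connectivity-defined Vim.

Reported coordinates follow the stereotactic convention: AP relative to the
anterior commissure (posterior negative), ML relative to the mid-commissural
sagittal plane (left negative), SI relative to the axial AC-PC plane
(inferior negative).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .atlas import atlas_vim_coordinates
from .io import RunConfig, save_config, write_phantom, write_volume
from .localise import NoConnectivityError, VimResult, localise_vim
from .phantom import Phantom, sample_cohort, sample_test_retest_pair
from .tracking import PICoMap, TrackingParams, reconstruct_dtcp, track_seed_region


def _tracking_runs(phantom: Phantom, hemisphere: str):
    m = phantom.masks
    if hemisphere == "L":
        m1, thal, cereb = m.m1_L, m.thalamus_L, m.cerebellum_R
        excl = [m.exclusion_contralateral_cerebrum_L, m.exclusion_ipsilateral_cerebellum_L]
    else:
        m1, thal, cereb = m.m1_R, m.thalamus_R, m.cerebellum_L
        excl = [m.exclusion_contralateral_cerebrum_R, m.exclusion_ipsilateral_cerebellum_R]
    yield m1, [cereb, thal], excl  # Seed: M1; waypoints: contralateral cerebellum + thalamus
    yield cereb, [m1, thal], excl  # Seed: cerebellum; waypoints: contralateral M1 + thalamus


def track_dtcp(
    phantom: Phantom,
    hemisphere: str,
    params: TrackingParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PICoMap, dict]:
    """Reconstruct one hemisphere's combined, normalised tract map."""
    params = params or TrackingParams()
    rng = rng or np.random.default_rng(0)
    maps, logs = [], []
    for seed_mask, waypoints, exclusions in _tracking_runs(phantom, hemisphere):
        t0 = time.perf_counter()
        pico, counts = track_seed_region(
            seed_mask, waypoints, exclusions, phantom.masks.csf_termination,
            phantom.fibre_field, params, rng,
        )
        counts["runtime_s"] = round(time.perf_counter() - t0, 3)
        maps.append(pico)
        logs.append(counts)
    combined, status = reconstruct_dtcp(maps[0], maps[1])
    return combined, {"runs": logs, "reconstruction": status}


def localise_subject(
    phantom: Phantom,
    params: TrackingParams | None = None,
    rng: np.random.Generator | None = None,
    fraction: float = 0.2,
) -> dict[str, tuple[PICoMap, VimResult]]:
    """Track and localise both hemispheres of one subject."""
    out = {}
    for hemi in ("L", "R"):
        combined, _ = track_dtcp(phantom, hemi, params, rng)
        thal = phantom.masks.thalamus_L if hemi == "L" else phantom.masks.thalamus_R
        out[hemi] = (combined, localise_vim(combined, thal, fraction, hemisphere=hemi))
    return out


def _report_coords(phantom: Phantom, world: np.ndarray) -> dict[str, float]:
    ac = phantom.landmarks.ac
    return {
        "ml": float(world[0]),
        "ap": float(world[1] - ac[1]),
        "si": float(world[2]),
    }


def _result_to_dict(r: st.TestResult) -> dict:
    d = dataclasses.asdict(r)
    if isinstance(d.get("degrees_of_freedom"), tuple):
        d["degrees_of_freedom"] = list(d["degrees_of_freedom"])
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, reconstruct and localise every subject, run the
    statistics suite, and write all tables/volumes under the output
    directory.  Returns the report bundle (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    cohort = sample_cohort(config.phantom, config.n_subjects, config.seed)
    track_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    rows, exclusions, logs = [], [], {}
    for phantom in cohort:
        if config.write_volumes:
            write_phantom(phantom, outdir / "phantoms")
        for hemi in ("L", "R"):
            try:
                combined, log = track_dtcp(phantom, hemi, config.tracking, track_rng)
                thal = (phantom.masks.thalamus_L if hemi == "L"
                        else phantom.masks.thalamus_R)
                vim = localise_vim(combined, thal, config.localisation_fraction,
                                   hemisphere=hemi)
            except NoConnectivityError as err:
                exclusions.append({"subject": phantom.subject_id, "hemisphere": hemi,
                                   "reason": str(err)})
                continue
            logs[f"{phantom.subject_id}_{hemi}"] = log
            if config.write_volumes:
                sdir = outdir / "phantoms" / phantom.subject_id
                write_volume(combined.data, phantom.grid.affine,
                             sdir / f"dtcp_{hemi}.nii.gz")
                write_volume(vim.roi, phantom.grid.affine,
                             sdir / f"vim_roi_{hemi}.nii.gz")
            truth = (phantom.truth.true_vim_centroid_L if hemi == "L"
                     else phantom.truth.true_vim_centroid_R)
            row = {
                "subject": phantom.subject_id,
                "hemisphere": hemi,
                **_report_coords(phantom, vim.centroid_world),
                "volume_mm3": vim.roi_volume_mm3,
                "intersection_volume_mm3": vim.intersection_volume_mm3,
                "max_pico_in_intersection": vim.max_pico_in_intersection,
                "dtcp_norm_max": combined.norm_max,
                "truth_ml": truth[0],
                "truth_ap": float(truth[1] - phantom.landmarks.ac[1]),
                "truth_si": truth[2],
            }
            for side in ("L", "R"):
                mask = phantom.masks.scp_L if side == "L" else phantom.masks.scp_R
                row[f"scp_{side}_volume_mm3"] = st.integrate_jacobian(
                    phantom.jacobian, mask, phantom.grid.affine)
            row.update(phantom.truth.confounds)
            rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "vim_centroids.csv", index=False)
    report = cohort_statistics(table, cohort[0].landmarks,
                               config.atlas_ml_offset_mm)
    report["exclusions"] = exclusions
    report["n_subjects_requested"] = config.n_subjects
    report["seed"] = config.seed
    (outdir / "stats.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "tracking_log.json").write_text(json.dumps(logs, indent=2, sort_keys=True))
    manifest = {
        "package": "cdvim",
        "version": _package_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_rows": len(rows),
        "n_exclusions": len(exclusions),
        "samples_per_voxel": config.tracking.samples_per_voxel,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("cdvim")
    except PackageNotFoundError:
        return "unknown"


def cohort_statistics(
    table: pd.DataFrame, landmarks, atlas_ml_offset_mm: float = 12.5
) -> dict:
    """The statistics suite over a per-subject-hemisphere centroid table."""
    report: dict = {"hemispheres": {}}
    atlas = atlas_vim_coordinates(landmarks, atlas_ml_offset_mm)
    ac_y = landmarks.ac[1]

    per_hemi: dict[str, pd.DataFrame] = {}
    for hemi in ("L", "R"):
        sub = table[table.hemisphere == hemi].sort_values("subject")
        per_hemi[hemi] = sub
        if len(sub) < 2:
            report["hemispheres"][hemi] = {"n": int(len(sub)),
                                           "note": "too few subjects for statistics"}
            continue
        pts = sub[["ml", "ap", "si"]].to_numpy(dtype=float)
        mean = pts.mean(axis=0)
        disp = st.cohort_dispersion(pts, mean)
        atlas_world = atlas.left if hemi == "L" else atlas.right
        atlas_rep = np.array([atlas_world[0], atlas_world[1] - ac_y, atlas_world[2]])
        entry = {
            "n": int(len(sub)),
            "mean_coordinates": dict(zip(("ml", "ap", "si"), mean.round(6).tolist())),
            "sd_coordinates": dict(zip(("ml", "ap", "si"),
                                       pts.std(axis=0, ddof=1).round(6).tolist())),
            "dispersion_vs_mean": dataclasses.asdict(disp),
            "atlas_target": dict(zip(("ml", "ap", "si"), atlas_rep.round(6).tolist())),
            "dispersion_vs_atlas": dataclasses.asdict(st.cohort_dispersion(pts, atlas_rep)),
            "median_volume_mm3": float(sub["volume_mm3"].median()),
        }
        if len(sub) >= 3:
            entry["atlas_offset_tests"] = {
                k: _result_to_dict(v)
                for k, v in st.atlas_offset_test(pts, atlas_rep).items()
            }
        if len(sub) >= 4:
            vals, vecs = st.principal_directions(pts)
            entry["principal_directions"] = {
                "eigenvalues": vals.round(6).tolist(),
                "eigenvectors": vecs.round(6).tolist(),
            }
        if len(sub) >= 4:
            disp_rows = [st.displacement(p, mean).as_dict() for p in pts]
            disp_df = pd.DataFrame(disp_rows)
            conf_df = sub[list(st.CONFOUND_NAMES)].reset_index(drop=True)
            try:
                entry["confound_screen"] = [
                    _result_to_dict(r)
                    for r in st.confound_screen(conf_df, disp_df, hemisphere=hemi)
                ]
            except ValueError as err:
                entry["confound_screen_error"] = str(err)
        report["hemispheres"][hemi] = entry

    # paired hemisphere tests require both sides localised for each subject
    common = sorted(set(per_hemi["L"].subject) & set(per_hemi["R"].subject))
    if len(common) >= 4:
        lef = per_hemi["L"].set_index("subject").loc[common]
        rig = per_hemi["R"].set_index("subject").loc[common]
        lpts = lef[["ml", "ap", "si"]].to_numpy(dtype=float)
        rpts = rig[["ml", "ap", "si"]].to_numpy(dtype=float)
        report["hemispheric_position_tests"] = {
            k: _result_to_dict(v)
            for k, v in st.hemispheric_position_test(lpts, rpts).items()
        }
        variance = {}
        for axis, col in (("ap", 1), ("ml", 0), ("si", 2)):
            a = np.abs(lpts[:, col]) if axis == "ml" else lpts[:, col]
            b = np.abs(rpts[:, col]) if axis == "ml" else rpts[:, col]
            try:
                variance[axis] = _result_to_dict(st.hemispheric_variance_test(a, b))
            except ValueError as err:
                variance[axis] = {"error": str(err)}
        report["hemispheric_variance_tests"] = variance
        if len(common) >= 6:
            report["volume_asymmetry"] = _result_to_dict(st.volume_asymmetry_test(
                lef["volume_mm3"].to_numpy(), rig["volume_mm3"].to_numpy()))
        scp_vol = pd.DataFrame({"L": lef["scp_L_volume_mm3"].to_numpy(),
                                "R": lef["scp_R_volume_mm3"].to_numpy()})
        pico = pd.DataFrame({"L": lef["dtcp_norm_max"].to_numpy(),
                             "R": rig["dtcp_norm_max"].to_numpy()})
        try:
            report["scp_pico_correlation"] = {
                k: _result_to_dict(v)
                for k, v in st.scp_pico_correlation(scp_vol, pico).items()
            }
        except ValueError as err:
            report["scp_pico_correlation"] = {"error": str(err)}
    return report


def run_test_retest(config: RunConfig, n_pairs: int = 10) -> dict:
    """Track and localise scan pairs, then compare within-subject to
    between-subject displacements with the left-tailed Wilcoxon."""
    pairs = sample_test_retest_pair(config.phantom, n_pairs, config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cents: dict[str, dict[int, list[np.ndarray]]] = {
        "L": {1: [], 2: []}, "R": {1: [], 2: []}}
    for scan1, scan2 in pairs:
        for idx, phantom in ((1, scan1), (2, scan2)):
            res = localise_subject(phantom, config.tracking, rng,
                                   config.localisation_fraction)
            for hemi in ("L", "R"):
                cents[hemi][idx].append(res[hemi][1].centroid_world)
    report = {}
    for hemi in ("L", "R"):
        s1 = np.asarray(cents[hemi][1])
        s2 = np.asarray(cents[hemi][2])
        report[hemi] = retest_statistics(s1, s2)
    return report


def retest_statistics(scan1: np.ndarray, scan2: np.ndarray) -> dict:
    """Within- vs between-subject displacement comparison for one
    hemisphere's paired centroids ((n, 3) world mm each)."""
    scan1 = np.asarray(scan1, float)
    scan2 = np.asarray(scan2, float)
    mean1 = scan1.mean(axis=0)
    within = pd.DataFrame([st.displacement(a, b).as_dict()
                           for a, b in zip(scan1, scan2)])
    between = pd.DataFrame([st.displacement(a, mean1).as_dict() for a in scan1])
    tests = st.test_retest_comparison(within, between)
    return {k: _result_to_dict(v) for k, v in tests.items()}
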