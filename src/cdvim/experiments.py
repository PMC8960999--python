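"""End-to-end evaluation experiments on synthetic phantoms.

Each function runs one self-contained study at a stated problem size and
returns plain numbers: formula worked examples, localisation recovery
against ground truth, threshold scale invariance, type-I calibration of the
statistics suite, cohort variance recovery, the peduncle-bottleneck sweep,
test-retest detection power, and tracker correctness checks.  They are used
by the acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np

from . import stats as st
from .atlas import atlas_vim_coordinates
from .localise import localise_vim
from .phantom import (
    Landmarks,
    PhantomConfig,
    build_phantom,
    sample_cohort,
    sample_retest_truths,
)
from .pipeline import track_dtcp
from .tracking import PICoMap, TrackingParams, track_seed_region


def atlas_worked_example() -> dict[str, float]:
    """Atlas formula on midsagittal landmarks 24 mm apart: the target should
    sit 24/3 - 2 = 6 mm anterior to the PC at +/-12.5 mm laterally, SI 0."""
    lm = Landmarks(ac=np.array([0.0, 12.0, 0.0]), pc=np.array([0.0, -12.0, 0.0]))
    tgt = atlas_vim_coordinates(lm)
    return {
        "ml_offset_mm": float(abs(tgt.right[0])),
        "ap_anterior_to_pc_mm": float(tgt.right[1] - lm.pc[1]),
        "si_mm": float(tgt.right[2]),
        "acpc_length_mm": tgt.acpc_length_mm,
    }


def _zero_noise_config() -> PhantomConfig:
    return PhantomConfig(dispersion_deg=0.0, jitter_sd_mm=(0.0, 0.0, 0.0))


def localisation_recovery(n: int = 5, seed: int = 0) -> dict[str, float]:
    """Track a zero-jitter, zero-dispersion cohort at desk-scale sampling and
    measure the worst centroid error against ground truth (mm)."""
    cfg = _zero_noise_config()
    params = TrackingParams()
    cohort = sample_cohort(cfg, n, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    errs = []
    for phantom in cohort:
        for hemi in ("L", "R"):
            combined, _ = track_dtcp(phantom, hemi, params, rng)
            thal = phantom.masks.thalamus_L if hemi == "L" else phantom.masks.thalamus_R
            vim = localise_vim(combined, thal, hemisphere=hemi)
            truth = getattr(phantom.truth, f"true_vim_centroid_{hemi}")
            errs.append(float(np.linalg.norm(vim.centroid_world - truth)))
    return {"max_centroid_error_mm": max(errs), "mean_centroid_error_mm": float(np.mean(errs)),
            "n_centroids": len(errs)}


def threshold_scale_invariance(seed: int = 0, scales=(0.1, 3.0, 10.0)) -> dict[str, float]:
    """Rescale a tract map by constants and check the binary ROI and centroid
    are bit-identical (returns the worst centroid shift, exactly 0 when the
    adaptive threshold is truly relative)."""
    cfg = _zero_noise_config()
    phantom = build_phantom(cfg, seed)
    combined, _ = track_dtcp(phantom, "L", TrackingParams(),
                             np.random.default_rng(seed + 1))
    thal = phantom.masks.thalamus_L
    base = localise_vim(combined, thal)
    max_shift = 0.0
    rois_identical = True
    for c in scales:
        scaled = PICoMap(combined.grid, combined.data * c, state=combined.state)
        res = localise_vim(scaled, thal)
        rois_identical &= bool(np.array_equal(res.roi, base.roi))
        max_shift = max(max_shift,
                        float(np.abs(res.centroid_world - base.centroid_world).max()))
    return {"max_centroid_shift_mm": max_shift,
            "rois_identical": float(rois_identical)}


def calibration_suite(n: int = 100, reps: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Type-I error of the four inferential tests under simulated nulls."""
    out = {}
    for i, test in enumerate(("paired_t", "pitman_morgan", "regression_f", "wilcoxon_left")):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 20 + i]))
        out[f"type1_{test}"] = st.null_rejection_rate(test, n=n, reps=reps, rng=rng)
    out["n_pairs"] = n
    out["reps"] = reps
    return out


def variance_recovery(
    n: int = 100, seed: int = 0, sds=(1.1, 1.2, 1.3)
) -> dict[str, float]:
    """Generate a cohort with known per-axis centroid SDs (ML, AP, SI order
    here: the stated values are AP/ML/SI = 1.1/1.2/1.3), track and localise
    every subject, and compare estimated SDs and RMS ED with the generator
    truth.  Tracking runs at desk-scale samples with zero dispersion."""
    ap, ml, si = sds
    cfg = PhantomConfig(dispersion_deg=0.0, jitter_sd_mm=(ml, ap, si))
    params = TrackingParams()
    cohort = sample_cohort(cfg, n, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    cents = []
    for phantom in cohort:
        combined, _ = track_dtcp(phantom, "L", params, rng)
        vim = localise_vim(combined, phantom.masks.thalamus_L)
        cents.append(vim.centroid_world)
    cents = np.asarray(cents)
    est_sd = cents.std(axis=0, ddof=1)  # (ML, AP, SI)
    disp = st.cohort_dispersion(cents, cents.mean(axis=0))
    return {
        "estimated_sd_ap_mm": float(est_sd[1]),
        "estimated_sd_ml_mm": float(est_sd[0]),
        "estimated_sd_si_mm": float(est_sd[2]),
        "rms_ed_mm": disp.rms_ed,
        "predicted_rms_ed_mm": float(np.linalg.norm(sds)),
        "n": n,
    }


def scp_bottleneck_sweep(
    widths_voxels=(1, 2, 3), reps: int = 20, seed: int = 0
) -> dict[str, float]:
    """Median peak connectivity of the combined tract reconstruction as a
    function of peduncular waist width (in voxels), under the default
    orientation dispersion.  The narrower the waist, the fewer samples
    survive the bottleneck."""
    params = TrackingParams()
    out = {}
    medians = []
    for w in widths_voxels:
        cfg = PhantomConfig(scp_width_mm=w * 1.25, jitter_sd_mm=(0.0, 0.0, 0.0))
        vals = []
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 40, w, rep]))
            phantom = build_phantom(cfg, rng)
            combined, _ = track_dtcp(phantom, "L", params, rng)
            vals.append(combined.norm_max)
        med = float(np.median(vals))
        out[f"median_max_pico_width_{w}vox"] = med
        medians.append(med)
    out["monotone_nondecreasing"] = float(
        all(b >= a for a, b in zip(medians, medians[1:]))
    )
    out["reps_per_width"] = reps
    return out


def retest_detection(
    n_pairs: int = 44, reps: int = 100, seed: int = 0,
    within_sd: float = 0.5, between_sd: float = 1.5,
) -> dict[str, float]:
    """Fraction of simulation repetitions in which the left-tailed Wilcoxon
    on Euclidean displacements (within-subject scan pair vs scan1 against the
    cohort mean) is significant at 0.05."""
    cfg = PhantomConfig(
        jitter_sd_mm=(between_sd,) * 3, retest_noise_sd_mm=(within_sd,) * 3
    )
    hits = 0
    last_p = np.nan
    for rep in range(reps):
        truths = sample_retest_truths(
            cfg, n_pairs, np.random.default_rng(np.random.SeedSequence([seed, 50, rep]))
        )
        res = _retest_tests(truths["L"])
        last_p = res["ed"].p_value
        hits += res["ed"].p_value < st.ALPHA
    return {"significant_fraction": hits / reps, "n_pairs": n_pairs,
            "reps": reps, "example_p": float(last_p)}


def _retest_tests(scans: dict[int, np.ndarray]) -> dict[str, st.TestResult]:
    import pandas as pd

    s1, s2 = scans[1], scans[2]
    mean1 = s1.mean(axis=0)
    within = pd.DataFrame([st.displacement(a, b).as_dict() for a, b in zip(s1, s2)])
    between = pd.DataFrame([st.displacement(a, mean1).as_dict() for a in s1])
    return st.test_retest_comparison(within, between)


def tracker_correctness(seed: int = 0) -> dict[str, float]:
    """Three mechanical checks of the tracker: the curvature gate rejects a
    90-degree bend, an unreachable waypoint zeroes the map, and visitation
    fractions at reduced sampling agree with full-protocol sampling within
    binomial confidence bounds."""
    from .grid import default_grid
    from .phantom import MAX_POPULATIONS, FibreField
    from .tracking import propagate_streamline

    # --- 90-degree bend ----------------------------------------------------
    grid = default_grid((41, 41, 41), 1.0)
    dirs = np.zeros((*grid.dims, MAX_POPULATIONS, 3), dtype=np.float32)
    fracs = np.zeros((*grid.dims, MAX_POPULATIONS), dtype=np.float32)
    disp = np.zeros((*grid.dims, MAX_POPULATIONS), dtype=np.float32)
    dirs[:20, 20, 20, 0] = (1, 0, 0)
    dirs[20:, 20, 20, 0] = (0, 1, 0)  # right-angle turn at x index 20
    fracs[:, 20, 20, 0] = 0.6
    fld = FibreField(grid, dirs, fracs, disp)
    sl = propagate_streamline(grid.voxel_to_world([5, 20, 20]), fld, {},
                              TrackingParams(), np.random.default_rng(seed))
    bend_rejected = float(sl.status == "rejected_curvature")

    # --- unreachable waypoint ----------------------------------------------
    cfg = _zero_noise_config()
    phantom = build_phantom(cfg, seed)
    unreachable = np.zeros(phantom.grid.dims, dtype=bool)
    unreachable[0, 0, 0] = True
    pico, _ = track_seed_region(
        phantom.masks.m1_L, [unreachable], [], phantom.masks.csf_termination,
        phantom.fibre_field, TrackingParams(), np.random.default_rng(seed),
    )
    waypoint_zeroed = float(pico.data.max() == 0.0)

    # --- reduced-sample equivalence ----------------------------------------
    pcfg = PhantomConfig(jitter_sd_mm=(0.0, 0.0, 0.0))
    ph = build_phantom(pcfg, seed)
    masks = ph.masks
    way = [masks.cerebellum_R, masks.thalamus_L]
    excl = [masks.exclusion_contralateral_cerebrum_L,
            masks.exclusion_ipsilateral_cerebellum_L]
    maps = {}
    totals = {}
    for spv in (250, 5000):
        params = TrackingParams(samples_per_voxel=spv)
        m, _ = track_seed_region(masks.m1_L, way, excl, masks.csf_termination,
                                 ph.fibre_field, params,
                                 np.random.default_rng(np.random.SeedSequence([seed, spv])))
        maps[spv] = m.data
        totals[spv] = int(masks.m1_L.sum()) * spv
    support = (maps[250] > 0) | (maps[5000] > 0)
    p_pool = (maps[250] * totals[250] + maps[5000] * totals[5000])[support] / (
        totals[250] + totals[5000])
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / totals[250] + 1 / totals[5000]))
    z = np.abs(maps[250][support] - maps[5000][support]) / np.maximum(se, 1e-12)
    within_bounds = float(np.mean(z <= 4.0))
    return {
        "bend_rejected": bend_rejected,
        "waypoint_zeroed_map": waypoint_zeroed,
        "reduced_sample_agreement_fraction": within_bounds,
        "n_support_voxels": int(support.sum()),
    }
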