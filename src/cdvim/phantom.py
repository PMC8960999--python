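"""Synthetic fibre phantoms with a known dentato-thalamo-cortical pathway.

Each phantom emulates one subject's diffusion-derived inputs: a voxel grid
with a world affine, a per-voxel multi-fibre orientation field forming a
decussating M1 -> SCP -> contralateral-cerebellum tract through the thalamus,
the binary seed/waypoint/exclusion/termination masks the tracking strategy
needs, AC/PC landmarks, a Jacobian-determinant field, and a ground-truth
record (true Vim centroids, applied jitter, confound scalars).

Geometry: each hemisphere's pathway is a monotone piecewise-cubic (PCHIP)
tube from a primary-motor-cortex patch down through the ipsilateral thalamus
box, narrowing to the superior-cerebellar-peduncle waist, crossing the
midline exactly once, and ending in the contralateral cerebellum blob.  The
"left" circuit is the left DTCp: M1_L and thalamus_L with the decussation
leading to the *right* SCP and *right* cerebellum (and vice versa), matching
the anatomy of the decussating pathway.

All randomness flows through one ``numpy.random.Generator`` passed
explicitly; cohort members get independent child generators spawned from the
seed so results are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .grid import VolumeGrid, default_grid

MAX_POPULATIONS = 3

# Canonical Vim centroids (world mm, MCP origin): ML, AP, SI. These are the
# cohort-average connectivity-defined coordinates reported for healthy adults,
# re-expressed relative to the MCP with a 26 mm AC-PC distance (AP values in
# the source convention are measured from the AC).
_CANONICAL_VIM_LEFT = (-13.71, -5.78, 2.67)
_CANONICAL_VIM_RIGHT = (13.09, -4.61, 3.94)
_ACPC_HALF_LENGTH = 13.0  # mm; AC at +13 y, PC at -13 y


@dataclass(frozen=True)
class FibreField:
    """Per-voxel fibre populations (up to three), standing in for a
    ball-and-sticks posterior: mean direction, volume fraction, angular
    dispersion."""

    grid: VolumeGrid
    directions: np.ndarray  # (X, Y, Z, MAX_POPULATIONS, 3) unit vectors (or 0)
    fractions: np.ndarray  # (X, Y, Z, MAX_POPULATIONS) in [0, 1], sum <= 1
    dispersion_deg: np.ndarray  # (X, Y, Z, MAX_POPULATIONS) >= 0

    def __post_init__(self) -> None:
        expect = (*self.grid.dims, MAX_POPULATIONS)
        if self.fractions.shape != expect or self.dispersion_deg.shape != expect:
            raise ValueError("fraction/dispersion arrays do not match the grid")
        if self.directions.shape != (*expect, 3):
            raise ValueError("direction array does not match the grid")
        if np.any(self.fractions < 0) or np.any(self.fractions.sum(axis=-1) > 1 + 1e-6):
            raise ValueError("fractions must be >= 0 and sum to <= 1 per voxel")
        if np.any(self.dispersion_deg < 0):
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class MaskSet:
    """Named binary volumes sharing one grid.

    ``exclusion_contralateral_cerebrum_L`` etc. are named by the *tract* they
    protect: the mask applied when tracking the left DTCp (and therefore
    covering the right cerebrum).
    """

    grid: VolumeGrid
    m1_L: np.ndarray
    m1_R: np.ndarray
    thalamus_L: np.ndarray
    thalamus_R: np.ndarray
    cerebellum_L: np.ndarray
    cerebellum_R: np.ndarray
    exclusion_contralateral_cerebrum_L: np.ndarray
    exclusion_contralateral_cerebrum_R: np.ndarray
    exclusion_ipsilateral_cerebellum_L: np.ndarray
    exclusion_ipsilateral_cerebellum_R: np.ndarray
    csf_termination: np.ndarray
    scp_L: np.ndarray
    scp_R: np.ndarray

    def named(self) -> dict[str, np.ndarray]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "grid"
        }

    def __post_init__(self) -> None:
        for name, mask in self.named().items():
            if mask.shape != self.grid.dims:
                raise ValueError(f"mask {name} does not match the grid dims")
        for name in ("thalamus_L", "thalamus_R", "scp_L", "scp_R"):
            if not getattr(self, name).any():
                raise ValueError(f"mask {name} is empty")


@dataclass(frozen=True)
class Landmarks:
    """AC and PC world coordinates (mm)."""

    ac: np.ndarray
    pc: np.ndarray

    def __post_init__(self) -> None:
        ac = np.asarray(self.ac, dtype=float).reshape(3)
        pc = np.asarray(self.pc, dtype=float).reshape(3)
        if np.allclose(ac, pc):
            raise ValueError("AC and PC coincide")
        object.__setattr__(self, "ac", ac)
        object.__setattr__(self, "pc", pc)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth recorded at generation time."""

    true_vim_centroid_L: np.ndarray  # world mm
    true_vim_centroid_R: np.ndarray
    tract_skeleton_L: np.ndarray  # (n, 3) ordered world points, M1 -> cerebellum
    tract_skeleton_R: np.ndarray
    scp_width_mm: dict[str, float]  # keyed by the side of the SCP itself
    jitter_applied: dict[str, np.ndarray]  # per circuit, world-mm offset
    confounds: dict[str, float]


@dataclass(frozen=True)
class Phantom:
    subject_id: str
    grid: VolumeGrid
    fibre_field: FibreField
    masks: MaskSet
    landmarks: Landmarks
    jacobian: np.ndarray  # strictly positive scalar volume
    truth: PhantomTruth


@dataclass(frozen=True)
class PhantomConfig:
    """Generator parameters (all lengths in mm unless noted).

    Jitter SDs/offsets are per world axis (ML, AP, SI).  ``scp_width_mm`` is
    the full width (diameter) of the tube at the peduncular waist.
    """

    dims: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 1.25
    vim_centroid_L: tuple[float, float, float] = _CANONICAL_VIM_LEFT
    vim_centroid_R: tuple[float, float, float] = _CANONICAL_VIM_RIGHT
    tube_radius_mm: float = 3.2
    scp_width_mm: float = 3.0
    dispersion_deg: float = 8.0
    fibre_fraction: float = 0.6
    # inter-subject jitter of the whole circuit geometry, world axes (ML, AP, SI)
    jitter_sd_mm: tuple[float, float, float] = (1.22, 1.14, 1.33)
    jitter_mean_L_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jitter_mean_R_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # within-subject (scan-to-scan) noise for test-retest pairs
    retest_noise_sd_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    thalamus_half_extent_mm: tuple[float, float, float] = (8.0, 10.0, 8.0)
    m1_radius_mm: float = 3.5
    cerebellum_radius_mm: float = 6.0
    scp_mask_half_length_mm: float = 3.0
    jacobian_scp_bump: float = 1.0  # multiplicative factor inside SCP masks
    # confound distributions: movement surrogates log-normal (log-mm params),
    # ROI volumes and TIV normal (mm^3)
    movement_log_mu: float = -1.0
    movement_log_sigma: float = 0.4
    m1_volume_mean: float = 9500.0
    m1_volume_sd: float = 1000.0
    cerebellum_volume_mean: float = 140000.0
    cerebellum_volume_sd: float = 15000.0
    tiv_mean: float = 1.42e6
    tiv_sd: float = 0.14e6
    # optional coupling: adds coeff * z(confound) mm to the AP jitter of both
    # circuits, for testing that the confound screen detects real coupling
    confound_coupling: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if any(int(d) < 40 for d in self.dims):
            raise ValueError("phantom grid must be at least 40 voxels per axis")
        if self.tube_radius_mm < self.voxel_mm:
            raise ValueError("tube radius must be at least one voxel")
        if self.scp_width_mm < self.voxel_mm:
            raise ValueError("SCP width must be at least one voxel")


class PhantomGeometryError(ValueError):
    """Raised when the configured tube leaves the grid."""


_WAIST_KNOT = 4  # index of the SCP waist in the knot list below


def _circuit_knots(cfg: PhantomConfig, circuit: str) -> np.ndarray:
    """Control points (world mm) for one DTCp, ordered M1 -> cerebellum.

    The course is two straight arms: cortex straight down through the Vim to
    a bend point beneath the thalamus box, then across the midline into the
    contralateral cerebellum.  Guard knots 5.5 mm either side of the bend
    keep the PCHIP interpolant exactly linear away from a short smoothed
    corner, so the tube crosses the thalamus as one straight chord.  The SCP
    waist sits on the lower arm where it reaches 4 mm across the midline.
    The medio-lateral coordinate is strictly monotone across the knots, so
    the tube crosses the midline exactly once.
    """
    vim = np.asarray(cfg.vim_centroid_L if circuit == "L" else cfg.vim_centroid_R, float)
    s = -1.0 if circuit == "L" else 1.0  # sign of the ipsilateral ML side
    m1 = np.array([s * 20.0, -12.0, 32.0])
    cereb = np.array([-s * 15.0, -30.0, -28.0])
    u_up = (m1 - vim) / np.linalg.norm(m1 - vim)
    # bend point 15 mm below the Vim on the cortical line, i.e. beneath the
    # thalamus box, so the tube crosses the box as one straight chord
    bend = vim - 15.0 * u_up
    u_dn = (cereb - bend) / np.linalg.norm(cereb - bend)
    # waist: the point of the lower arm 4 mm across the midline
    t_waist = (-s * 4.0 - bend[0]) / u_dn[0]
    waist = bend + t_waist * u_dn
    guard_up = bend + 5.5 * u_up
    guard_dn = bend + 5.5 * u_dn
    return np.array([m1, guard_up, bend, guard_dn, waist, cereb])


def _radius_profile(cfg: PhantomConfig) -> np.ndarray:
    """Tube radius at each knot; the waist carries half the SCP width.

    The radius is constant from cortex to below the bend so the thalamic
    chord of the tube is a uniform cylinder."""
    r = cfg.tube_radius_mm
    return np.array([r, r, r, r, cfg.scp_width_mm / 2.0, 1.5 * r])


@dataclass(frozen=True)
class _Tube:
    points: np.ndarray  # (n, 3) world, densely sampled along arclength
    tangents: np.ndarray  # (n, 3) unit
    radii: np.ndarray  # (n,)
    arclength: np.ndarray  # (n,)
    waist_arclength: float


def _build_tube(cfg: PhantomConfig, circuit: str, offset: np.ndarray) -> _Tube:
    knots = _circuit_knots(cfg, circuit) + offset
    radii = _radius_profile(cfg)
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(knots, axis=0), axis=1))]
    interp = PchipInterpolator(chord, knots, axis=0)
    rad_interp = PchipInterpolator(chord, radii)
    s = np.arange(0.0, chord[-1], 0.25)
    pts = interp(s)
    tan = interp.derivative()(s)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return _Tube(pts, tan, rad_interp(s), s, waist_arclength=float(chord[_WAIST_KNOT]))


def _geometry_key(cfg: PhantomConfig) -> tuple:
    """Fields of the config that determine the canonical tube geometry."""
    return (
        cfg.vim_centroid_L,
        cfg.vim_centroid_R,
        cfg.tube_radius_mm,
        cfg.scp_width_mm,
        cfg.thalamus_half_extent_mm,
    )


_LAYOUT_CACHE: dict[tuple, dict] = {}


def _canonical_layout(cfg: PhantomConfig, circuit: str) -> dict:
    """Zero-jitter thalamus-box centre and true Vim centroid for one circuit.

    The true centroid is the volume centroid of the continuous tube clipped
    by the thalamus box, evaluated by quadrature on a 0.4 mm lattice tied to
    the box.  The box centre is iterated so the centroid of the tube-box
    intersection lands on the configured canonical Vim coordinate (the tube
    bends at the thalamus, so a box centred on the waypoint itself would have
    a biased intersection centroid).  Because lattice, box and tube all move
    rigidly with jitter, the jittered truth is exactly canonical + jitter.
    """
    key = (_geometry_key(cfg), circuit)
    if key in _LAYOUT_CACHE:
        return _LAYOUT_CACHE[key]
    vim = np.asarray(cfg.vim_centroid_L if circuit == "L" else cfg.vim_centroid_R, float)
    half = np.asarray(cfg.thalamus_half_extent_mm, float)
    tube = _build_tube(cfg, circuit, np.zeros(3))
    tree = cKDTree(tube.points)
    axes = [np.arange(-h + 0.2, h, 0.4) for h in half]
    lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    centre = vim.copy()
    centroid = vim
    for _ in range(8):
        pts = lattice + centre
        dist, idx = tree.query(pts)
        inside = dist <= tube.radii[idx]
        if not inside.any():
            raise PhantomGeometryError(f"tube {circuit} misses its thalamus box")
        centroid = pts[inside].mean(axis=0)
        err = vim - centroid
        if np.linalg.norm(err) < 0.05:
            break
        centre = centre + err
    layout = {"box_centre": centre, "true_centroid": centroid}
    _LAYOUT_CACHE[key] = layout
    return layout


def true_vim_centroids(
    cfg: PhantomConfig, jitter: dict[str, np.ndarray] | None = None
) -> dict[str, np.ndarray]:
    """Analytic true centroids (canonical quadrature centroid + jitter).

    This is the fast truth-only path used for cohort-level statistics that do
    not need voxel volumes; ``build_phantom`` records the same values."""
    jitter = jitter or {"L": np.zeros(3), "R": np.zeros(3)}
    return {
        c: _canonical_layout(cfg, c)["true_centroid"] + np.asarray(jitter[c], float)
        for c in ("L", "R")
    }


def _ball(grid_pts: np.ndarray, centre: np.ndarray, radius: float) -> np.ndarray:
    d2 = ((grid_pts - centre) ** 2).sum(axis=-1)
    return d2 <= radius * radius


def _box(grid_pts: np.ndarray, centre: np.ndarray, half: np.ndarray) -> np.ndarray:
    return np.all(np.abs(grid_pts - centre) <= half, axis=-1)


def build_phantom(
    config: PhantomConfig | None = None,
    seed: int | np.random.Generator = 0,
    *,
    subject_id: str = "sub-000",
    jitter: dict[str, np.ndarray] | None = None,
    confounds: dict[str, float] | None = None,
) -> Phantom:
    """Generate one subject.

    ``jitter`` maps circuit ("L"/"R") to a world-mm offset applied rigidly to
    that circuit's geometry (tube and its attached masks).  When omitted both
    offsets are zero, so the true centroids equal the configured canonical
    centroids up to voxel discretisation of the thalamus-tube intersection.
    """
    cfg = config or PhantomConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = default_grid(cfg.dims, cfg.voxel_mm)
    pts = grid.voxel_centres_world()  # (X, Y, Z, 3)
    flat_pts = pts.reshape(-1, 3)

    if jitter is None:
        jitter = {"L": np.zeros(3), "R": np.zeros(3)}
    jitter = {k: np.asarray(v, dtype=float).reshape(3) for k, v in jitter.items()}

    tubes = {c: _build_tube(cfg, c, jitter[c]) for c in ("L", "R")}
    for c, tube in tubes.items():
        lo = grid.voxel_to_world(np.zeros(3)) - cfg.voxel_mm / 2
        hi = grid.voxel_to_world(np.asarray(grid.dims, float) - 1) + cfg.voxel_mm / 2
        if np.any(tube.points < lo) or np.any(tube.points > hi):
            raise PhantomGeometryError(f"circuit {c} tube leaves the grid")

    # --- fibre field: tangent populations inside each tube -----------------
    directions = np.zeros((*grid.dims, MAX_POPULATIONS, 3), dtype=np.float32)
    fractions = np.zeros((*grid.dims, MAX_POPULATIONS), dtype=np.float32)
    dispersion = np.zeros((*grid.dims, MAX_POPULATIONS), dtype=np.float32)
    in_tube: dict[str, np.ndarray] = {}
    nearest_s: dict[str, np.ndarray] = {}
    skel_dist: dict[str, np.ndarray] = {}
    for c, tube in tubes.items():
        tree = cKDTree(tube.points)
        dist, idx = tree.query(flat_pts)
        inside = dist <= tube.radii[idx]
        in_tube[c] = inside.reshape(grid.dims)
        nearest_s[c] = idx.reshape(grid.dims)
        skel_dist[c] = dist.reshape(grid.dims)
    both = in_tube["L"] & in_tube["R"]
    for pop, c in enumerate(("L", "R")):
        sel = in_tube[c]
        frac = np.where(both[sel], 0.45, cfg.fibre_fraction)
        tang = tubes[c].tangents[nearest_s[c][sel]]
        # single-population voxels use slot 0; crossing voxels use slot 0/1
        slot = np.zeros(sel.sum(), dtype=int) if c == "L" else np.where(both[sel], 1, 0)
        ii, jj, kk = np.nonzero(sel)
        directions[ii, jj, kk, slot] = tang.astype(np.float32)
        fractions[ii, jj, kk, slot] = frac.astype(np.float32)
        dispersion[ii, jj, kk, slot] = cfg.dispersion_deg
    field = FibreField(grid, directions, fractions, dispersion)

    # --- masks -------------------------------------------------------------
    def circuit_masks(c: str) -> dict[str, np.ndarray]:
        off = jitter[c]
        knots = _circuit_knots(cfg, c) + off
        s_ml = -1.0 if c == "L" else 1.0
        box_centre = _canonical_layout(cfg, c)["box_centre"] + off
        thal = _box(pts, box_centre, np.asarray(cfg.thalamus_half_extent_mm))
        m1 = _ball(pts, knots[0], cfg.m1_radius_mm)
        cereb = _ball(pts, knots[-1], cfg.cerebellum_radius_mm)
        # contralateral cerebrum: everything supratentorial on the far side
        contra_cerebrum = (pts[..., 0] * s_ml <= -4.0) & (pts[..., 2] >= -5.0)
        # ipsilateral cerebellum: infratentorial region on the seed's side
        ipsi_cerebellum = (pts[..., 0] * s_ml >= 6.0) & (pts[..., 2] <= -20.0)
        # SCP of the *contralateral* side: tube voxels near the waist
        tube = tubes[c]
        s_vox = tube.arclength[nearest_s[c]]
        scp = in_tube[c] & (np.abs(s_vox - tube.waist_arclength) <= cfg.scp_mask_half_length_mm)
        return {
            "thalamus": thal,
            "m1": m1,
            "cerebellum_contra": cereb,
            "excl_contra_cerebrum": contra_cerebrum,
            "excl_ipsi_cerebellum": ipsi_cerebellum,
            "scp_contra": scp,
        }

    cm = {c: circuit_masks(c) for c in ("L", "R")}

    # CSF shell wrapping each SCP waist (the peduncle is surrounded by CSF),
    # kept >= 1.5 mm clear of both tubes.
    csf = np.zeros(grid.dims, dtype=bool)
    for c, tube in tubes.items():
        near_waist = np.abs(tube.arclength[nearest_s[c]] - tube.waist_arclength) <= 6.0
        r = tube.radii[nearest_s[c]]
        csf |= near_waist & (skel_dist[c] >= r + 1.5) & (skel_dist[c] <= r + 4.5)
    csf &= ~(in_tube["L"] | in_tube["R"])

    masks = MaskSet(
        grid=grid,
        m1_L=cm["L"]["m1"],
        m1_R=cm["R"]["m1"],
        thalamus_L=cm["L"]["thalamus"],
        thalamus_R=cm["R"]["thalamus"],
        # cerebellum masks named by their own side: the left DTCp targets the
        # right cerebellum, so circuit L's contralateral blob is cerebellum_R
        cerebellum_R=cm["L"]["cerebellum_contra"],
        cerebellum_L=cm["R"]["cerebellum_contra"],
        exclusion_contralateral_cerebrum_L=cm["L"]["excl_contra_cerebrum"],
        exclusion_contralateral_cerebrum_R=cm["R"]["excl_contra_cerebrum"],
        exclusion_ipsilateral_cerebellum_L=cm["L"]["excl_ipsi_cerebellum"],
        exclusion_ipsilateral_cerebellum_R=cm["R"]["excl_ipsi_cerebellum"],
        csf_termination=csf,
        scp_R=cm["L"]["scp_contra"],
        scp_L=cm["R"]["scp_contra"],
    )

    # --- Jacobian field ----------------------------------------------------
    jac = np.ones(grid.dims, dtype=np.float64)
    if cfg.jacobian_scp_bump != 1.0:
        jac[masks.scp_L | masks.scp_R] *= cfg.jacobian_scp_bump

    # --- truth -------------------------------------------------------------
    for c in ("L", "R"):
        if not (in_tube[c] & cm[c]["thalamus"]).any():
            raise PhantomGeometryError(f"tube {c} misses its thalamus box")
    centroids = true_vim_centroids(cfg, jitter)

    if confounds is None:
        confounds = _draw_confounds(cfg, rng)

    truth = PhantomTruth(
        true_vim_centroid_L=centroids["L"],
        true_vim_centroid_R=centroids["R"],
        tract_skeleton_L=tubes["L"].points,
        tract_skeleton_R=tubes["R"].points,
        scp_width_mm={"R": cfg.scp_width_mm, "L": cfg.scp_width_mm},
        jitter_applied={c: jitter[c].copy() for c in ("L", "R")},
        confounds=dict(confounds),
    )
    landmarks = Landmarks(
        ac=np.array([0.0, _ACPC_HALF_LENGTH, 0.0]),
        pc=np.array([0.0, -_ACPC_HALF_LENGTH, 0.0]),
    )
    return Phantom(subject_id, grid, field, masks, landmarks, jac, truth)


_CONFOUND_NAMES = (
    "movement_rms_first_volume",
    "movement_rms_preceding_volume",
    "m1_volume",
    "cerebellum_volume",
    "tiv",
)


def _draw_confounds(cfg: PhantomConfig, rng: np.random.Generator) -> dict[str, float]:
    return {
        "movement_rms_first_volume": float(
            rng.lognormal(cfg.movement_log_mu + 0.3, cfg.movement_log_sigma)
        ),
        "movement_rms_preceding_volume": float(
            rng.lognormal(cfg.movement_log_mu, cfg.movement_log_sigma)
        ),
        "m1_volume": float(rng.normal(cfg.m1_volume_mean, cfg.m1_volume_sd)),
        "cerebellum_volume": float(
            rng.normal(cfg.cerebellum_volume_mean, cfg.cerebellum_volume_sd)
        ),
        "tiv": float(rng.normal(cfg.tiv_mean, cfg.tiv_sd)),
    }


def _draw_jitter(
    cfg: PhantomConfig, rng: np.random.Generator, confounds: dict[str, float]
) -> dict[str, np.ndarray]:
    sd = np.asarray(cfg.jitter_sd_mm, dtype=float)
    out = {
        "L": rng.normal(np.asarray(cfg.jitter_mean_L_mm, float), sd),
        "R": rng.normal(np.asarray(cfg.jitter_mean_R_mm, float), sd),
    }
    if cfg.confound_coupling is not None:
        name, coeff = cfg.confound_coupling
        mu, sigma = _confound_moments(cfg, name)
        z = (confounds[name] - mu) / sigma
        for c in ("L", "R"):
            out[c] = out[c] + np.array([0.0, coeff * z, 0.0])
    return out


def _confound_moments(cfg: PhantomConfig, name: str) -> tuple[float, float]:
    if name.startswith("movement"):
        mu = cfg.movement_log_mu + (0.3 if name.endswith("first_volume") else 0.0)
        s = cfg.movement_log_sigma
        m = float(np.exp(mu + s**2 / 2))
        v = float((np.exp(s**2) - 1) * np.exp(2 * mu + s**2))
        return m, np.sqrt(v)
    table = {
        "m1_volume": (cfg.m1_volume_mean, cfg.m1_volume_sd),
        "cerebellum_volume": (cfg.cerebellum_volume_mean, cfg.cerebellum_volume_sd),
        "tiv": (cfg.tiv_mean, cfg.tiv_sd),
    }
    return table[name]


def sample_cohort_truths(
    config: PhantomConfig | None = None, n: int = 100, seed: int | np.random.Generator = 0
) -> dict[str, np.ndarray]:
    """True centroids for a cohort, computed analytically (no voxel volumes).

    Draws the same jitter/confound sequence as ``sample_cohort`` and returns
    per-hemisphere (n, 3) centroid arrays plus the confound table rows.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    cfg = config or PhantomConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cents = {"L": [], "R": []}
    confs = []
    for _ in range(n):
        confounds = _draw_confounds(cfg, rng)
        jit = _draw_jitter(cfg, rng, confounds)
        truths = true_vim_centroids(cfg, jit)
        for c in ("L", "R"):
            cents[c].append(truths[c])
        confs.append(confounds)
    return {
        "L": np.asarray(cents["L"]),
        "R": np.asarray(cents["R"]),
        "confounds": confs,
    }


def sample_retest_truths(
    config: PhantomConfig | None = None, n: int = 44, seed: int | np.random.Generator = 0
) -> dict[str, dict[int, np.ndarray]]:
    """True centroids for test-retest scan pairs (analytic path).

    Same sampling scheme as ``sample_test_retest_pair``: one subject-level
    jitter per pair, independent within-subject noise per scan.  Returns
    ``{"L": {1: (n,3), 2: (n,3)}, "R": {...}}``.
    """
    if n < 2:
        raise ValueError("a test-retest cohort needs at least 2 subjects")
    cfg = config or PhantomConfig()
    within = np.asarray(cfg.retest_noise_sd_mm, dtype=float)
    between = np.asarray(cfg.jitter_sd_mm, dtype=float)
    if np.any(within >= between):
        raise ValueError(
            "within-subject noise SD must be below the between-subject jitter SD"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {"L": {1: [], 2: []}, "R": {1: [], 2: []}}
    for _ in range(n):
        confounds = _draw_confounds(cfg, rng)
        base = _draw_jitter(cfg, rng, confounds)
        for scan in (1, 2):
            noisy = {c: base[c] + rng.normal(0.0, within) for c in ("L", "R")}
            truths = true_vim_centroids(cfg, noisy)
            for c in ("L", "R"):
                out[c][scan].append(truths[c])
    return {
        c: {scan: np.asarray(v) for scan, v in scans.items()}
        for c, scans in out.items()
    }


def sample_cohort(
    config: PhantomConfig | None = None, n: int = 10, seed: int | np.random.Generator = 0
) -> list[Phantom]:
    """Draw ``n`` subjects with independent circuit jitter and confounds."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    cfg = config or PhantomConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n):
        confounds = _draw_confounds(cfg, rng)
        jit = _draw_jitter(cfg, rng, confounds)
        out.append(
            build_phantom(
                cfg, rng, subject_id=f"sub-{i:03d}", jitter=jit, confounds=confounds
            )
        )
    return out


def sample_test_retest_pair(
    config: PhantomConfig | None = None, n: int = 10, seed: int | np.random.Generator = 0
) -> list[tuple[Phantom, Phantom]]:
    """Draw ``n`` scan pairs: one subject-level geometry per pair, each scan
    re-generated with independent within-subject noise added to the jitter."""
    if n < 2:
        raise ValueError("a test-retest cohort needs at least 2 subjects")
    cfg = config or PhantomConfig()
    within = np.asarray(cfg.retest_noise_sd_mm, dtype=float)
    between = np.asarray(cfg.jitter_sd_mm, dtype=float)
    if np.any(within >= between):
        raise ValueError(
            "within-subject noise SD must be below the between-subject jitter SD"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        confounds = _draw_confounds(cfg, rng)
        base = _draw_jitter(cfg, rng, confounds)
        scans = []
        for scan in (1, 2):
            noisy = {c: base[c] + rng.normal(0.0, within) for c in ("L", "R")}
            scans.append(
                build_phantom(
                    cfg,
                    rng,
                    subject_id=f"sub-{i:03d}_scan-{scan}",
                    jitter=noisy,
                    confounds=confounds,
                )
            )
        pairs.append(tuple(scans))
    return pairs
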