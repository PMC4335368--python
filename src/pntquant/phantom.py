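"""Digital short-axis cine phantom of the left ventricle.

The phantom models the LV cavity as a truncated half-ellipsoid (base plane at
z = 0, apex at z = long_axis_length) wrapped in a concentric myocardial shell.
Papillary muscles are vertical cylinders inside the blood pool and
trabeculations are radial sinusoidal ridges of the endocardial surface.
Through the cardiac cycle the in-plane cavity scale follows a raised-cosine
time course solved so that the blood-only cavity volume realises the requested
ejection fraction exactly; the trabecular ridge amplitude interpolates from
its end-diastolic to its (smaller) end-systolic value, emulating systolic
compaction of trabeculae into the compact wall.

Images are produced by supersampled voxelization of the continuous geometry
(partial-volume averaging within the excited slice thickness only; the
inter-slice gap is not imaged) followed by additive Gaussian noise. Ground
truth is computed by radial-interval quadrature of the same continuous
geometry and is therefore independent of the voxel grid.

A matched through-plane aortic velocity series is generated with a parabolic
(Poiseuille) profile whose per-phase amplitude is scaled to the systolic rate
of cavity-volume loss, so that before noise the forward-flow integral equals
the true stroke volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy.optimize import brentq

from .exceptions import GeometryError, ValidationError
from .quantify import MYOCARDIAL_DENSITY

# ground-truth label codes
LABEL_BACKGROUND = 0
LABEL_BLOOD = 1
LABEL_MYOCARDIUM = 2
LABEL_PNT = 3

# quadrature resolution for ground-truth volumes (z samples x angular samples)
_QUAD_NZ = 241
_QUAD_NTHETA = 480


@dataclass
class PhantomSpec:
    """Geometric, kinematic and imaging parameters of one phantom subject.

    Lengths in mm, intensities in arbitrary units, velocities in cm/s.
    """

    long_axis_length: float = 90.0
    cavity_semiaxes_ed: tuple[float, float] = (30.0, 30.0)
    wall_thickness_ed: float = 7.0
    wall_thickness_es: float = 9.5
    ejection_fraction_true: float = 0.67
    papillary_count: int = 2
    papillary_radius: float = 5.0
    papillary_length: float = 40.0
    trabecular_amplitude_ed: float = 2.5
    trabecular_amplitude_es: float = 2.5
    trabecular_angular_frequency: int = 12
    n_phases: int = 20
    pixel_spacing: float = 1.5
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    blood_intensity: float = 500.0
    myocardium_intensity: float = 200.0
    noise_sd: float = 20.0
    supersampling_factor: int = 2
    # --- plumbing beyond the basic anatomy ---
    es_phase_fraction: float = 0.4          # position of end-systole in the cycle
    heart_period_ms: float = 1000.0
    papillary_center_fraction: float = 0.5  # radial position of papillary axes
    papillary_base_fraction: float = 0.15   # z of papillary base, fraction of long axis
    vessel_radius: float = 15.0             # ascending aorta lumen radius
    velocity_noise_sd: float = 2.0          # cm/s, phase-contrast velocity noise
    matrix_size: int | None = None          # in-plane matrix; None = auto-fit

    def validate(self) -> None:
        a, b = self.cavity_semiaxes_ed
        positives = {
            "long_axis_length": self.long_axis_length,
            "cavity_semiaxis_a": a,
            "cavity_semiaxis_b": b,
            "wall_thickness_ed": self.wall_thickness_ed,
            "wall_thickness_es": self.wall_thickness_es,
            "pixel_spacing": self.pixel_spacing,
            "slice_thickness": self.slice_thickness,
            "vessel_radius": self.vessel_radius,
            "heart_period_ms": self.heart_period_ms,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ValidationError(f"{name} must be > 0, got {value}")
        if self.slice_gap < 0:
            raise ValidationError("slice_gap must be >= 0")
        if not 0 < self.ejection_fraction_true < 1:
            raise ValidationError("ejection_fraction_true must be in (0, 1)")
        if self.papillary_count < 0:
            raise ValidationError("papillary_count must be >= 0")
        if self.papillary_count and (self.papillary_radius < 0 or self.papillary_length <= 0):
            raise ValidationError("papillary radius/length must be positive")
        if self.trabecular_amplitude_ed < 0 or self.trabecular_amplitude_es < 0:
            raise ValidationError("trabecular amplitudes must be >= 0")
        if self.trabecular_amplitude_es > self.trabecular_amplitude_ed + 1e-9:
            raise ValidationError(
                "trabecular_amplitude_es must not exceed trabecular_amplitude_ed "
                "(systolic compaction)"
            )
        if self.n_phases < 2:
            raise ValidationError("n_phases must be >= 2")
        if self.blood_intensity <= self.myocardium_intensity:
            raise ValidationError("blood_intensity must exceed myocardium_intensity")
        if self.noise_sd < 0 or self.velocity_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.supersampling_factor < 1:
            raise ValidationError("supersampling_factor must be >= 1")
        if not 0 < self.es_phase_fraction < 1:
            raise ValidationError("es_phase_fraction must be in (0, 1)")


@dataclass
class CineStack:
    """4D bSSFP-like intensity stack [phase, slice, row, col] with geometry."""

    intensities: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    slice_gap: float
    phase_duration: float  # ms

    @property
    def n_phases(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[1]

    @property
    def slice_spacing(self) -> float:
        """Effective centre-to-centre slice spacing (thickness + gap)."""
        return self.slice_thickness + self.slice_gap


@dataclass
class GroundTruth:
    """Analytic ground truth for one phantom subject (pre-noise geometry)."""

    labels: np.ndarray                     # [phase, slice, row, col] uint8
    cavity_volume_per_phase: np.ndarray    # ml, blood only (P&T excluded)
    pnt_volume_per_phase: np.ndarray       # ml, papillary + trabecular tissue
    wall_volume: float                     # ml, compact shell at ED
    total_lvm_true: float                  # g, (wall + P&T at ED) * density
    true_sv: float                         # ml
    true_pnt_mass_fraction: float          # fraction of total LVM
    ed_phase: int = 0

    @property
    def es_phase(self) -> int:
        return int(np.argmin(self.cavity_volume_per_phase))


@dataclass
class VelocitySeries:
    """Through-plane phase-contrast velocity maps [phase, row, col] in cm/s."""

    velocities: np.ndarray
    pixel_spacing: float
    phase_duration: float  # ms
    vessel_mask_true: np.ndarray


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    height: float  # cm
    weight: float  # kg
    cine: CineStack
    velocity: VelocitySeries
    truth: GroundTruth
    spec: PhantomSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ValidationError("height and weight must be positive")


# ---------------------------------------------------------------------------
# cycle kinematics
# ---------------------------------------------------------------------------

def contraction_fractions(n_phases: int, es_phase_fraction: float) -> tuple[np.ndarray, int]:
    """Raised-cosine contraction fraction g(p) with g=0 at ED (phase 0) and
    g=1 at end-systole; returns (g, es_phase_index)."""
    p_es = max(1, int(round(es_phase_fraction * n_phases)))
    p_es = min(p_es, n_phases - 1)
    p = np.arange(n_phases)
    g = np.empty(n_phases)
    sys_part = p <= p_es
    g[sys_part] = 0.5 * (1.0 - np.cos(np.pi * p[sys_part] / p_es))
    g[~sys_part] = 0.5 * (1.0 + np.cos(np.pi * (p[~sys_part] - p_es) / (n_phases - p_es)))
    return g, p_es


def _papillary_angles(count: int) -> np.ndarray:
    # anterolateral / posteromedial placement for the usual two muscles
    return np.deg2rad(100.0 + 360.0 * np.arange(count) / max(count, 1))


# ---------------------------------------------------------------------------
# continuous geometry: classification and quadrature
# ---------------------------------------------------------------------------

def _phase_geometry(spec: PhantomSpec, s: float, amp: float):
    """Precompute per-phase scalars used by both the classifier and quadrature."""
    a, b = spec.cavity_semiaxes_ed
    c = spec.long_axis_length
    angles = _papillary_angles(spec.papillary_count)
    rbar = s * np.sqrt(a * b)
    f = spec.papillary_center_fraction
    # papillary axis positions in normalized (u, v) coordinates
    pcu = f * np.cos(angles)
    pcv = f * np.sin(angles)
    pr_n = spec.papillary_radius / rbar if spec.papillary_count else 0.0
    z0 = spec.papillary_base_fraction * c
    z1 = z0 + spec.papillary_length
    return a * s, b * s, c, rbar, pcu, pcv, pr_n, z0, z1


def classify_points(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    spec: PhantomSpec,
    s: float,
    amp: float,
    wall: float,
) -> np.ndarray:
    """Classify physical points into {background, blood, myocardium, pnt}.

    ``s`` is the in-plane cavity scale, ``amp`` the trabecular amplitude (mm)
    and ``wall`` the wall thickness (mm) at the evaluated phase.
    """
    a_s, b_s, c, rbar, pcu, pcv, pr_n, z0, z1 = _phase_geometry(spec, s, amp)
    k = spec.trabecular_angular_frequency

    out = np.full(np.broadcast(x, y, z).shape, LABEL_BACKGROUND, dtype=np.uint8)
    above_base = z >= 0.0

    u = x / a_s
    v = y / b_s
    rho = np.hypot(u, v)
    with np.errstate(invalid="ignore"):
        rho_e = np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))
    in_long = above_base & (z <= c)

    theta = np.arctan2(v, u)
    # ridge depth scales as amp/s: trabecular tissue volume is conserved under
    # cavity contraction, so compaction is governed by the amplitude alone
    h = amp * np.maximum(np.sin(k * theta), 0.0) / (s * rbar)
    h = np.minimum(h, 0.6 * rho_e)
    rho_t = rho_e - h

    # epicardial half-ellipsoid (includes the apical cap beyond z = c)
    epi = (
        above_base
        & ((x / (a_s + wall)) ** 2 + (y / (b_s + wall)) ** 2 + (z / (c + wall)) ** 2 <= 1.0)
    )

    in_blood_zone = in_long & (rho <= rho_t)
    in_trab_zone = in_long & (rho > rho_t) & (rho <= rho_e)

    out[epi] = LABEL_MYOCARDIUM
    out[in_trab_zone] = LABEL_PNT

    if spec.papillary_count:
        pap = np.zeros_like(in_blood_zone)
        in_z = above_base & (z >= z0) & (z <= z1)
        for cu, cv in zip(pcu, pcv):
            pap |= in_z & ((u - cu) ** 2 + (v - cv) ** 2 <= pr_n**2)
        out[in_blood_zone & pap] = LABEL_PNT
        out[in_blood_zone & ~pap] = LABEL_BLOOD
    else:
        out[in_blood_zone] = LABEL_BLOOD
    return out


def _cavity_measures(spec: PhantomSpec, s: float, amp: float) -> tuple[float, float]:
    """Blood-only and P&T volumes (ml) at cavity scale ``s`` and trabecular
    amplitude ``amp``, by radial-interval quadrature of the continuous model."""
    a, b = spec.cavity_semiaxes_ed
    c = spec.long_axis_length
    a_s, b_s, _, rbar, pcu, pcv, pr_n, z0, z1 = _phase_geometry(spec, s, amp)
    k = spec.trabecular_angular_frequency

    z = np.linspace(0.0, c, _QUAD_NZ)
    theta = (np.arange(_QUAD_NTHETA) + 0.5) * (2.0 * np.pi / _QUAD_NTHETA)
    dtheta = 2.0 * np.pi / _QUAD_NTHETA

    rho_e = np.sqrt(np.clip(1.0 - (z / c) ** 2, 0.0, None))[:, None]      # (nz, 1)
    # depth amp/s in physical units (tissue conservation, cf. classify_points)
    h = amp * np.maximum(np.sin(k * theta), 0.0)[None, :] / (s * rbar)     # (1, nt)
    h = np.minimum(h, 0.6 * rho_e)
    rho_t = rho_e - h                                                      # (nz, nt)

    blood_m = 0.5 * rho_t**2
    pnt_m = 0.5 * (rho_e**2 - rho_t**2)

    if spec.papillary_count and pr_n > 0:
        in_z = ((z >= z0) & (z <= z1))[:, None]
        ce, se = np.cos(theta)[None, :], np.sin(theta)[None, :]
        for cu, cv in zip(pcu, pcv):
            proj = cu * ce + cv * se
            disc = proj**2 - (cu**2 + cv**2 - pr_n**2)
            hit = (disc > 0.0) & in_z
            sq = np.sqrt(np.clip(disc, 0.0, None))
            r1 = np.clip(proj - sq, 0.0, rho_t)
            r2 = np.clip(proj + sq, 0.0, rho_t)
            seg = np.where(hit, 0.5 * (r2**2 - r1**2), 0.0)
            blood_m -= seg
            pnt_m += seg

    area_scale = a_s * b_s * dtheta
    blood_area = area_scale * blood_m.sum(axis=1)   # mm^2 per z
    pnt_area = area_scale * pnt_m.sum(axis=1)
    blood_ml = float(np.trapezoid(blood_area, z)) / 1000.0
    pnt_ml = float(np.trapezoid(pnt_area, z)) / 1000.0
    return blood_ml, pnt_ml


def _wall_volume_ml(spec: PhantomSpec, s: float, wall: float) -> float:
    """Compact-shell volume (ml): epicardial minus smooth-cavity half-ellipsoid."""
    a, b = spec.cavity_semiaxes_ed
    c = spec.long_axis_length
    v_epi = (2.0 / 3.0) * np.pi * (a * s + wall) * (b * s + wall) * (c + wall)
    v_cav = (2.0 / 3.0) * np.pi * (a * s) * (b * s) * c
    return (v_epi - v_cav) / 1000.0


def _solve_scale(spec: PhantomSpec, amp: float, blood_target_ml: float) -> float:
    """In-plane cavity scale whose blood-only volume equals the target."""
    fun = lambda s: _cavity_measures(spec, s, amp)[0] - blood_target_ml
    return brentq(fun, 0.05, 1.5, xtol=1e-5)


def phase_parameters(spec: PhantomSpec) -> dict:
    """Solve the cavity scale, trabecular amplitude and wall thickness for
    every phase so that the blood-volume curve realises the true EF."""
    g, p_es = contraction_fractions(spec.n_phases, spec.es_phase_fraction)
    amp = spec.trabecular_amplitude_ed + (
        spec.trabecular_amplitude_es - spec.trabecular_amplitude_ed
    ) * g
    wall = spec.wall_thickness_ed + (spec.wall_thickness_es - spec.wall_thickness_ed) * g

    blood_ed, pnt_ed = _cavity_measures(spec, 1.0, amp[0])
    targets = blood_ed * (1.0 - spec.ejection_fraction_true * g)
    s = np.ones(spec.n_phases)
    blood = np.empty(spec.n_phases)
    pnt = np.empty(spec.n_phases)
    blood[0], pnt[0] = blood_ed, pnt_ed
    for p in range(1, spec.n_phases):
        s[p] = _solve_scale(spec, amp[p], targets[p])
        blood[p], pnt[p] = _cavity_measures(spec, s[p], amp[p])
    return {
        "g": g,
        "es_phase": p_es,
        "scale": s,
        "amplitude": amp,
        "wall": wall,
        "blood_ml": blood,
        "pnt_ml": pnt,
    }


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _image_grid(spec: PhantomSpec):
    a, b = spec.cavity_semiaxes_ed
    c = spec.long_axis_length
    extent = 2.0 * (max(a, b) + spec.wall_thickness_ed)
    if spec.matrix_size is None:
        n = int(np.ceil((extent + 24.0) / spec.pixel_spacing))
        n += n % 2
    else:
        n = int(spec.matrix_size)
        if n * spec.pixel_spacing < extent + 4.0:
            raise GeometryError(
                f"field of view {n * spec.pixel_spacing:.0f} mm cannot contain the "
                f"ventricle (epicardial extent {extent:.0f} mm)"
            )
    coords = (np.arange(n) - (n - 1) / 2.0) * spec.pixel_spacing
    spacing = spec.slice_thickness + spec.slice_gap
    z_top = c + spec.wall_thickness_ed
    # each slice's excited slab sits centred in the spacing cell it represents
    n_slices = int(np.ceil(z_top / spacing)) + 1
    z_centers = spacing / 2.0 + spacing * np.arange(n_slices)
    return coords, z_centers


def _voxelize_phase(
    spec: PhantomSpec, coords: np.ndarray, z_centers: np.ndarray,
    s: float, amp: float, wall: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-volume intensities and majority labels for one phase."""
    ss = spec.supersampling_factor
    offsets = ((np.arange(ss) + 0.5) / ss - 0.5)
    xy_off = offsets * spec.pixel_spacing
    z_off = offsets * spec.slice_thickness  # sample within the excited slab only

    nz, nxy = len(z_centers), len(coords)
    counts = np.zeros((4, nz, nxy, nxy), dtype=np.int32)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")  # rows = y, cols = x
    for dz in z_off:
        zz = (z_centers + dz)[:, None, None]
        for dy in xy_off:
            for dx in xy_off:
                labels = classify_points(
                    xx[None, :, :] + dx, yy[None, :, :] + dy,
                    np.broadcast_to(zz, (nz, nxy, nxy)),
                    spec, s, amp, wall,
                )
                for cls in range(4):
                    counts[cls] += labels == cls
    total = ss**3
    f_blood = counts[LABEL_BLOOD] / total
    f_tissue = (counts[LABEL_MYOCARDIUM] + counts[LABEL_PNT]) / total
    intensity = f_blood * spec.blood_intensity + f_tissue * spec.myocardium_intensity
    labels = np.argmax(counts, axis=0).astype(np.uint8)
    return intensity.astype(np.float64), labels


# ---------------------------------------------------------------------------
# aortic velocity series
# ---------------------------------------------------------------------------

def _vessel_profile(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit parabolic profile (peak 1) averaged over pixels, its coordinates,
    and the centre-inside vessel mask."""
    r = spec.vessel_radius
    px = spec.pixel_spacing
    n = int(np.ceil((2.0 * r + 18.0) / px))
    n += n % 2
    coords = (np.arange(n) - (n - 1) / 2.0) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    sub = 4
    off = ((np.arange(sub) + 0.5) / sub - 0.5) * px
    profile = np.zeros((n, n))
    for dy in off:
        for dx in off:
            d2 = (xx + dx) ** 2 + (yy + dy) ** 2
            profile += np.clip(1.0 - d2 / r**2, 0.0, None) * (d2 <= r**2)
    profile /= sub**2
    mask = (xx**2 + yy**2) <= r**2
    return profile, coords, mask


def _build_velocity(
    spec: PhantomSpec, blood_ml: np.ndarray, es_phase: int, rng: np.random.Generator,
) -> VelocitySeries:
    profile, _, mask = _vessel_profile(spec)
    px_area = spec.pixel_spacing**2                       # mm^2
    dt_s = spec.heart_period_ms / spec.n_phases / 1000.0  # s
    unit_integral = profile.sum() * px_area               # mm^2 (flow per unit peak mm/s)

    vel = np.zeros((spec.n_phases,) + profile.shape)
    for p in range(es_phase):
        dv_mm3 = (blood_ml[p] - blood_ml[p + 1]) * 1000.0
        if dv_mm3 <= 0:
            continue
        q_mm3_s = dv_mm3 / dt_s
        v_peak_mm_s = q_mm3_s / unit_integral
        vel[p] = profile * (v_peak_mm_s / 10.0)           # cm/s
    if spec.velocity_noise_sd > 0:
        vel = vel + rng.normal(0.0, spec.velocity_noise_sd, size=vel.shape)
    return VelocitySeries(
        velocities=vel,
        pixel_spacing=spec.pixel_spacing,
        phase_duration=spec.heart_period_ms / spec.n_phases,
        vessel_mask_true=mask,
    )


# ---------------------------------------------------------------------------
# top-level builder
# ---------------------------------------------------------------------------

def build_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[CineStack, VelocitySeries, GroundTruth]:
    """Render one subject: cine stack, aortic velocity series and ground truth.

    Deterministic for a fixed (spec, seed) pair; all randomness (imaging and
    velocity noise) is drawn from a single generator seeded with ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    params = phase_parameters(spec)
    coords, z_centers = _image_grid(spec)

    n = len(coords)
    intensities = np.empty((spec.n_phases, len(z_centers), n, n))
    labels = np.empty((spec.n_phases, len(z_centers), n, n), dtype=np.uint8)
    for p in range(spec.n_phases):
        intensities[p], labels[p] = _voxelize_phase(
            spec, coords, z_centers,
            params["scale"][p], params["amplitude"][p], params["wall"][p],
        )
    if spec.noise_sd > 0:
        intensities = np.maximum(
            intensities + rng.normal(0.0, spec.noise_sd, size=intensities.shape), 0.0
        )

    cine = CineStack(
        intensities=intensities,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
        phase_duration=spec.heart_period_ms / spec.n_phases,
    )

    blood = params["blood_ml"]
    pnt = params["pnt_ml"]
    wall_ed = _wall_volume_ml(spec, 1.0, spec.wall_thickness_ed)
    lvm = (wall_ed + pnt[0]) * MYOCARDIAL_DENSITY
    truth = GroundTruth(
        labels=labels,
        cavity_volume_per_phase=blood,
        pnt_volume_per_phase=pnt,
        wall_volume=wall_ed,
        total_lvm_true=lvm,
        true_sv=float(blood.max() - blood.min()),
        true_pnt_mass_fraction=float(pnt[0] * MYOCARDIAL_DENSITY / lvm) if lvm > 0 else 0.0,
    )

    velocity = _build_velocity(spec, blood, params["es_phase"], rng)
    return cine, velocity, truth


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------
#
# Calibration is by construction: per-subject anatomical targets are sampled
# from the cohort distributions below, then the geometric parameters of the
# PhantomSpec (cavity radius, wall thickness, trabecular amplitudes, papillary
# radius) are solved deterministically so the analytic ground truth hits the
# targets. Between-subject SDs correspond to reported cohort SEMs scaled by
# sqrt(n = 20), truncated to plausible ranges.

_PRESET_TARGETS: dict[str, dict] = {
    "control": {
        "edv_ml": (163.0, 26.8, (110.0, 216.0)),
        "lvm_g": (130.0, 26.8, (76.0, 184.0)),
        "ef": (0.67, 0.045, (0.55, 0.79)),
        "pnt_fraction": (0.13, 0.089, (0.04, 0.22)),
        "long_axis_mm": (90.0, 5.0, (75.0, 105.0)),
        "compaction_ml": None,  # no systolic amplitude compaction beyond geometry
    },
    "fabry": {
        "edv_ml": (127.0, 31.3, (65.0, 189.0)),
        "lvm_g": (178.0, 62.6, (96.0, 260.0)),
        "ef": (0.73, 0.045, (0.61, 0.85)),
        "pnt_fraction": (0.20, 0.045, (0.08, 0.32)),
        "long_axis_mm": (85.0, 5.0, (70.0, 100.0)),
        # volume of P&T merging into the wall between ED and ES
        "compaction_ml": (11.0, 5.0, (2.0, 20.0)),
    },
}

_PAPILLARY_MASS_SHARE = 0.35   # papillary share of total P&T volume
_PAPILLARY_LENGTH_FRACTION = 0.45
_WALL_THICKENING = 1.35        # systolic wall thickening factor


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _solve_spec(
    edv_ml: float, lvm_g: float, ef: float, pnt_fraction: float,
    long_axis_mm: float, compaction_ml: float | None, **overrides,
) -> PhantomSpec:
    """Solve PhantomSpec geometry from anatomical targets."""
    c = long_axis_mm
    myo_vol = lvm_g / MYOCARDIAL_DENSITY * 1000.0          # mm^3
    pnt_vol = myo_vol * pnt_fraction
    wall_vol = myo_vol - pnt_vol
    v_smooth = edv_ml * 1000.0 + pnt_vol
    a = float(np.sqrt(3.0 * v_smooth / (2.0 * np.pi * c)))

    wall = brentq(
        lambda w: (2.0 / 3.0) * np.pi * ((a + w) ** 2 * (c + w) - a**2 * c) - wall_vol,
        0.1, 40.0,
    )

    pap_vol = _PAPILLARY_MASS_SHARE * pnt_vol
    pap_len = _PAPILLARY_LENGTH_FRACTION * c
    pap_r = float(np.sqrt(pap_vol / (2.0 * np.pi * pap_len)))
    trab_vol = pnt_vol - pap_vol
    # first-order estimate of the ridge amplitude, then secant-correct the
    # total P&T volume against the quadrature (papillary clipping, curvature)
    amp = 2.0 * trab_vol / (np.pi * a * c)

    spec = PhantomSpec(
        long_axis_length=c,
        cavity_semiaxes_ed=(a, a),
        wall_thickness_ed=float(wall),
        wall_thickness_es=float(wall) * _WALL_THICKENING,
        ejection_fraction_true=ef,
        papillary_radius=pap_r,
        papillary_length=pap_len,
        trabecular_amplitude_ed=float(amp),
        trabecular_amplitude_es=float(amp),
        **overrides,
    )
    for _ in range(4):
        _, pnt_meas = _cavity_measures(spec, 1.0, spec.trabecular_amplitude_ed)
        err = pnt_vol / 1000.0 - pnt_meas
        if abs(err) < 0.05:
            break
        # ridge volume responds ~linearly to amplitude; papillary part is fixed
        trab_meas = max(pnt_meas - pap_vol / 1000.0, 1e-6)
        new_amp = spec.trabecular_amplitude_ed * max((trab_meas + err) / trab_meas, 0.05)
        new_amp = float(np.clip(new_amp, 0.0, 0.35 * a))
        spec = replace(spec, trabecular_amplitude_ed=new_amp, trabecular_amplitude_es=new_amp)

    if compaction_ml is not None:
        spec = _solve_compaction(spec, compaction_ml)
    return spec


def _solve_compaction(spec: PhantomSpec, compaction_ml: float) -> PhantomSpec:
    """Choose the ES trabecular amplitude so that the apparent P&T volume
    drops by ``compaction_ml`` between ED and ES."""
    blood_ed, pnt_ed = _cavity_measures(spec, 1.0, spec.trabecular_amplitude_ed)
    target_es = max(pnt_ed - compaction_ml, 0.0)
    blood_target = blood_ed * (1.0 - spec.ejection_fraction_true)

    amp_es = spec.trabecular_amplitude_ed
    for _ in range(5):
        trial = replace(spec, trabecular_amplitude_es=min(amp_es, spec.trabecular_amplitude_ed))
        s_es = _solve_scale(trial, trial.trabecular_amplitude_es, blood_target)
        _, pnt_es = _cavity_measures(trial, s_es, trial.trabecular_amplitude_es)
        err = pnt_es - target_es
        at_ceiling = trial.trabecular_amplitude_es >= spec.trabecular_amplitude_ed - 1e-9
        # cavity shrinkage alone may already compact more than requested (err < 0
        # at the ED amplitude); the amplitude cannot be raised further then
        if abs(err) <= 0.1 or trial.trabecular_amplitude_es <= 1e-3 or (err < 0 and at_ceiling):
            amp_es = trial.trabecular_amplitude_es
            break
        pap_floor = max(pnt_es - _trab_component(trial, s_es), 0.0)
        trab_needed = max(target_es - pap_floor, 0.0)
        trab_now = max(pnt_es - pap_floor, 1e-6)
        amp_es = trial.trabecular_amplitude_es * min(trab_needed / trab_now, 1.0)
    return replace(spec, trabecular_amplitude_es=float(min(amp_es, spec.trabecular_amplitude_ed)))


def _trab_component(spec: PhantomSpec, s: float) -> float:
    """Trabecular (ridge-only) P&T volume at scale s, by differencing."""
    _, pnt_with = _cavity_measures(spec, s, spec.trabecular_amplitude_es)
    no_trab = replace(spec, trabecular_amplitude_ed=0.0, trabecular_amplitude_es=0.0)
    _, pnt_without = _cavity_measures(no_trab, s, 0.0)
    return max(pnt_with - pnt_without, 0.0)


@dataclass
class CohortPreset:
    """Distribution over PhantomSpec for one study group."""

    name: str
    targets: dict = field(repr=False, default_factory=dict)
    spec_overrides: dict = field(default_factory=dict)

    def _draw_targets(self, rng: np.random.Generator) -> dict:
        drawn = {}
        for key, entry in self.targets.items():
            if entry is None:
                drawn[key] = None
            else:
                mean, sd, bounds = entry
                drawn[key] = _truncated_normal(rng, mean, sd, bounds)
        return drawn

    def sample(self, rng: np.random.Generator) -> PhantomSpec:
        return _solve_spec(**self._draw_targets(rng), **self.spec_overrides)

    @property
    def mean_spec(self) -> PhantomSpec:
        means = {
            k: (None if v is None else v[0]) for k, v in self.targets.items()
        }
        return _solve_spec(**means, **self.spec_overrides)


def preset(name: str, **spec_overrides) -> CohortPreset:
    """Cohort preset ('control' or 'fabry') calibrated to the study groups."""
    if name not in _PRESET_TARGETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(_PRESET_TARGETS)}")
    return CohortPreset(name=name, targets=dict(_PRESET_TARGETS[name]),
                        spec_overrides=spec_overrides)


def generate_cohort(
    name: str, n: int, seed: int, **spec_overrides
) -> list[SubjectRecord]:
    """Draw ``n`` independent subjects from a cohort preset.

    Per-subject seeds derive deterministically from the master seed; heights
    and weights follow a truncated adult-male normal distribution
    (178 +/- 7 cm, 80 +/- 10 kg).
    """
    if n < 0:
        raise ValidationError("cohort size must be >= 0")
    pre = preset(name, **spec_overrides)
    records: list[SubjectRecord] = []
    children = np.random.SeedSequence(seed).spawn(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        spec = pre.sample(rng)
        height = _truncated_normal(rng, 178.0, 7.0, (150.0, 210.0))
        weight = _truncated_normal(rng, 80.0, 10.0, (45.0, 130.0))
        subject_seed = int(child.generate_state(1)[0] % (2**31))
        cine, velocity, truth = build_phantom(spec, subject_seed)
        records.append(
            SubjectRecord(
                subject_id=f"{name}{i:03d}",
                group=name,
                height=height,
                weight=weight,
                cine=cine,
                velocity=velocity,
                truth=truth,
                spec=spec,
                seed=subject_seed,
            )
        )
    return records
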