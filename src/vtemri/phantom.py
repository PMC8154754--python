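"""Synthetic dual-echo thigh phantom with known multi-compartment T2*.

The generator emulates the structure of a bilateral sciatic-nerve
variable-TE study: a circular thigh cross-section (muscle bounded by a thin
fascia and a subcutaneous fat ring) containing a nerve with fascicular
substructure, extruded along the slice direction. Signal follows a
multi-compartment mono-exponential decay per tissue,

    S(TE) = s0 * suppression * sum_c f_c * exp(-TE / T2*_c),

partial volume is produced by rasterizing on a supersampled in-plane grid
and block-averaging, and magnitude noise is Rician. Cohorts of subjects with
demographics and per-subject nerve aT2* draws, and simulated "reader"
segmentations at a target Dice overlap, complete the study structure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .core import DualEchoStudy, VoxelMask
from .roi import dice_index


# --------------------------------------------------------------------------
# tissue and geometry specifications

@dataclass(frozen=True)
class TissueSpec:
    """One tissue: proton-density amplitude and T2* compartments.

    ``components`` is a tuple of ``(fraction, t2star_ms)`` pairs whose
    fractions sum to one. ``suppression`` scales the amplitude (used to
    emulate binomial fat suppression, e.g. 0.05 for fat).
    """

    name: str
    s0: float
    components: tuple[tuple[float, float], ...]
    suppression: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError(f"{self.name}: s0 must be >= 0")
        if self.components:
            total = sum(f for f, _ in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: compartment fractions sum to {total}, not 1")
            if any(t2 <= 0 for _, t2 in self.components):
                raise ValueError(f"{self.name}: every T2* must be > 0")

    def signal(self, te_ms) -> float:
        """Noiseless signal at echo time ``te_ms`` (ms); s0-scaled."""
        amp = self.s0 * self.suppression
        if not self.components:
            return amp * np.ones_like(np.asarray(te_ms, dtype=float)) if np.ndim(te_ms) else amp
        out = sum(f * np.exp(-np.asarray(te_ms, dtype=float) / t2)
                  for f, t2 in self.components)
        return amp * out


def default_tissues() -> dict[str, TissueSpec]:
    """Default tissue model of the thigh phantom.

    Nerve is a two-pool mixture (70% fascicular water at 50 ms, 30%
    connective/myelin short pool at 2 ms), consistent with whole-nerve T2 in
    the 45-70 ms range and fascicle-scale T2* of ~16-22 ms; fascicles drawn
    inside the nerve are pure long pool, so the interior shows substructure
    on the subtraction image. Muscle is a single 28 ms pool, fascia/tendon a
    1.5 ms collagen pool (bright on subtraction), fat is suppressed to 5%
    amplitude. Air carries no signal. The nerve amplitude is below muscle so
    that nerve/muscle contrast-to-noise resembles in-vivo values (~0.37).
    """
    return {
        "air": TissueSpec("air", 0.0, ((1.0, 1.0),)),
        "fat": TissueSpec("fat", 1000.0, ((1.0, 30.0),), suppression=0.05),
        "fascia": TissueSpec("fascia", 900.0, ((1.0, 1.5),)),
        "muscle": TissueSpec("muscle", 1000.0, ((1.0, 28.0),)),
        "nerve": TissueSpec("nerve", 650.0, ((0.7, 50.0), (0.3, 2.0))),
        "fascicle": TissueSpec("fascicle", 650.0, ((1.0, 50.0),)),
    }


@dataclass(frozen=True)
class ThighGeometry:
    """Parametric 2D thigh cross-section (mm), extruded along slices.

    Distances are relative to the in-plane image centre. The nerve runs
    parallel to the slice axis (i.e. the main field), so every slice shares
    the same cross-section.
    """

    muscle_radius_mm: float = 24.0
    fascia_thickness_mm: float = 1.5
    fat_thickness_mm: float = 3.0
    nerve_center_mm: tuple[float, float] = (7.0, -7.0)
    nerve_radius_mm: float = 3.85
    n_fascicles: int = 7
    fascicle_radius_mm: float = 0.8


@dataclass
class PhantomConfig:
    """Full phantom description: grid, echo times, tissues, geometry, noise."""

    grid: tuple[int, int, int] = (96, 96, 12)
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 5.0)
    te1: float = 0.98
    te2: float = 5.37
    tissues: dict[str, TissueSpec] = field(default_factory=default_tissues)
    geometry: ThighGeometry = field(default_factory=ThighGeometry)
    noise_sigma: float = 12.0
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.te1 < self.te2):
            raise ValueError(f"need te2 > te1 > 0, got {self.te1}/{self.te2}")
        if any(n < 8 for n in self.grid):
            raise ValueError(f"grid dims must be >= 8, got {self.grid}")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def delta_te(self) -> float:
        return self.te2 - self.te1

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (self.grid[0] * self.voxel_size[0], self.grid[1] * self.voxel_size[1])


@dataclass
class PhantomGroundTruth:
    """Per-voxel tissue fractions, the true nerve mask, and the analytic
    two-point aT2* of the noiseless nerve signal (the recovery oracle)."""

    fractions: dict[str, np.ndarray]
    label_names: tuple[str, ...]
    label_map: np.ndarray
    true_nerve_mask: VoxelMask
    effective_at2_ms: float


# --------------------------------------------------------------------------
# rasterization

def _fascicle_centers(geom: ThighGeometry) -> list[tuple[float, float]]:
    """Deterministic fascicle layout: one central, the rest on a ring."""
    cx, cy = geom.nerve_center_mm
    n = geom.n_fascicles
    if n <= 0:
        return []
    centers = [(cx, cy)]
    ring = n - 1
    r = 0.55 * geom.nerve_radius_mm
    for i in range(ring):
        th = 2 * math.pi * i / ring
        centers.append((cx + r * math.cos(th), cy + r * math.sin(th)))
    return centers[:n]


def build_label_map(config: PhantomConfig) -> PhantomGroundTruth:
    """Rasterize the thigh geometry into per-voxel tissue fractions.

    Rasterization happens on an in-plane grid refined by ``supersample``
    then block-averages the one-hot labels, producing partial-volume
    fractions at tissue boundaries (exact 0/1 labels when supersample=1).
    The nerve mask contains voxels whose nerve+fascicle fraction exceeds
    0.5. Raises if the nerve circle extends beyond the field of view.
    """
    nx, ny, nz = config.grid
    dx, dy, _ = config.voxel_size
    geom = config.geometry
    s = config.supersample

    cx0 = (nx - 1) / 2 * dx
    cy0 = (ny - 1) / 2 * dy
    ncx, ncy = geom.nerve_center_mm[0] + cx0, geom.nerve_center_mm[1] + cy0
    rn = geom.nerve_radius_mm
    fov_x, fov_y = config.fov_mm
    # voxel centres span [0, (n-1)*d]; require the nerve circle inside the FOV
    if not (rn <= ncx <= (nx - 1) * dx - rn and rn <= ncy <= (ny - 1) * dy - rn):
        raise ValueError(
            f"nerve geometry outside grid: circle centre ({ncx:.1f}, {ncy:.1f}) mm "
            f"radius {rn:.1f} mm exceeds FOV {fov_x:.1f} x {fov_y:.1f} mm")

    # supersampled in-plane centre coordinates (mm)
    sub = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(nx)[:, None] + sub[None, :]).ravel() * dx
    ys = (np.arange(ny)[:, None] + sub[None, :]).ravel() * dy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    r_thigh = np.hypot(gx - cx0, gy - cy0)
    r_nerve = np.hypot(gx - ncx, gy - ncy)

    names = tuple(config.tissues.keys())
    idx = {n: i for i, n in enumerate(names)}
    lab = np.full(gx.shape, idx["air"], dtype=np.int8)
    rm = geom.muscle_radius_mm
    lab[r_thigh <= rm + geom.fascia_thickness_mm + geom.fat_thickness_mm] = idx["fat"]
    lab[r_thigh <= rm + geom.fascia_thickness_mm] = idx["fascia"]
    lab[r_thigh <= rm] = idx["muscle"]
    lab[r_nerve <= rn] = idx["nerve"]
    if geom.n_fascicles > 0 and "fascicle" in idx:
        for fx, fy in _fascicle_centers(geom):
            d = np.hypot(gx - (fx + cx0), gy - (fy + cy0))
            lab[(d <= geom.fascicle_radius_mm) & (r_nerve <= rn)] = idx["fascicle"]

    fractions: dict[str, np.ndarray] = {}
    for name in names:
        onehot = (lab == idx[name]).astype(float)
        frac2d = onehot.reshape(nx, s, ny, s).mean(axis=(1, 3))
        fractions[name] = np.repeat(frac2d[:, :, None], nz, axis=2)

    stack = np.stack([fractions[n] for n in names], axis=-1)
    label_map = np.asarray(names)[np.argmax(stack, axis=-1)]

    nerve_frac = fractions["nerve"] + fractions.get("fascicle", 0.0)
    mask = VoxelMask(data=nerve_frac > 0.5, label="nerve", reader="truth")
    if mask.is_empty:
        raise ValueError("nerve geometry produced an empty mask")

    truth = PhantomGroundTruth(
        fractions=fractions, label_names=names, label_map=label_map,
        true_nerve_mask=mask, effective_at2_ms=float("nan"))
    truth.effective_at2_ms = _effective_at2(truth, config)
    return truth


def noiseless_signal(truth: PhantomGroundTruth, config: PhantomConfig,
                     te_ms: float) -> np.ndarray:
    """Noiseless volume at an arbitrary echo time (partial-volume weighted)."""
    out = np.zeros(config.grid, dtype=float)
    for name, frac in truth.fractions.items():
        tissue = config.tissues[name]
        out += frac * tissue.signal(te_ms)
    return out


def _effective_at2(truth: PhantomGroundTruth, config: PhantomConfig) -> float:
    """Analytic two-point aT2* of the mean noiseless nerve-mask signal."""
    sel = truth.true_nerve_mask.data
    s1 = noiseless_signal(truth, config, config.te1)[sel].mean()
    s2 = noiseless_signal(truth, config, config.te2)[sel].mean()
    if not 0 < s2 < s1:
        raise ValueError("nerve signal does not decay between echoes")
    return float(-config.delta_te / np.log(s2 / s1))


def simulate_signal(truth: PhantomGroundTruth, config: PhantomConfig,
                    subject_id: str = "", side: str = "right") -> DualEchoStudy:
    """Noiseless dual-echo study from ground-truth fractions."""
    if truth.true_nerve_mask.shape != tuple(config.grid):
        raise ValueError("ground truth and config grids differ")
    return DualEchoStudy(
        echo1=noiseless_signal(truth, config, config.te1),
        echo2=noiseless_signal(truth, config, config.te2),
        te1=config.te1, te2=config.te2, voxel_size=config.voxel_size,
        subject_id=subject_id, side=side)


def add_rician_noise(study: DualEchoStudy, sigma: float, seed: int) -> DualEchoStudy:
    """Rician magnitude noise, independent per echo.

    Each voxel value s becomes sqrt((s + g1)^2 + g2^2) with g1, g2
    independent N(0, sigma^2) draws — the magnitude of a complex signal with
    Gaussian channel noise. In signal-free background this reduces to a
    Rayleigh distribution with mean sigma*sqrt(pi/2).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return study.with_volumes(study.echo1.copy(), study.echo2.copy())
    rng = np.random.default_rng(seed)
    out = []
    for echo in (study.echo1, study.echo2):
        g1 = rng.normal(0.0, sigma, echo.shape)
        g2 = rng.normal(0.0, sigma, echo.shape)
        out.append(np.hypot(echo + g1, g2))
    return study.with_volumes(out[0], out[1])


def sigma_for_snr(nerve_mean: float, target_snr: float) -> float:
    """Channel sigma giving a target SNR (nerve mean / raw Rayleigh background SD)."""
    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    return nerve_mean / (target_snr * math.sqrt(2 - math.pi / 2))


# --------------------------------------------------------------------------
# simulated reader segmentations

def _perturb_mask(mask: np.ndarray, amplitude: float, smooth_sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Boundary perturbation: signed distance map plus a smooth random
    field, per slice (random local erode/dilate).

    The perturbed region keeps the per-slice voxel count of the original
    (the top-n voxels of the perturbed level-set function), so reader
    variability moves the boundary without systematically inflating the
    area of convex ROIs.
    """
    out = np.empty_like(mask)
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        n_true = int(sl.sum())
        if n_true == 0:
            out[:, :, z] = sl
            continue
        signed = distance_transform_edt(sl) - distance_transform_edt(~sl)
        f = gaussian_filter(rng.standard_normal(sl.shape), smooth_sigma)
        sd = f.std()
        if sd > 0:
            f /= sd
        level = signed + amplitude * f
        keep = np.argpartition(level.ravel(), -n_true)[-n_true:]
        new = np.zeros(sl.size, dtype=bool)
        new[keep] = True
        out[:, :, z] = new.reshape(sl.shape)
    return out


def _mean_dice(mask: VoxelMask, amplitude: float, smooth_sigma: float,
               rng: np.random.Generator, n_draws: int) -> float:
    vals = []
    for _ in range(n_draws):
        pert = _perturb_mask(mask.data, amplitude, smooth_sigma, rng)
        if not pert.any():
            vals.append(0.0)
            continue
        vals.append(dice_index(mask, VoxelMask(pert, label=mask.label)))
    return float(np.mean(vals))


def simulate_reader_masks(true_mask: VoxelMask, target_dice: float,
                          n_readers: int, seed: int,
                          smooth_sigma: float = 2.0,
                          calibration_draws: int = 16) -> list[VoxelMask]:
    """Simulate manual segmentations with a target expected Dice vs truth.

    The boundary is perturbed with a smooth random field added to the
    signed distance transform; the field amplitude is calibrated by
    bisection so that the expected Dice against ``true_mask`` approximates
    ``target_dice``. ``target_dice=1`` returns exact copies.
    """
    if not 0 < target_dice <= 1:
        raise ValueError(f"target_dice must be in (0, 1], got {target_dice}")
    if true_mask.is_empty:
        raise ValueError("true mask is empty")
    if n_readers < 1:
        raise ValueError("n_readers must be >= 1")

    if target_dice == 1.0:
        return [VoxelMask(true_mask.data.copy(), label=true_mask.label,
                          reader=f"sim{i + 1}") for i in range(n_readers)]

    ss = np.random.SeedSequence(seed)
    cal_rng, draw_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    # bracket then bisect on the field amplitude (voxel units)
    lo, hi = 0.0, 1.0
    while _mean_dice(true_mask, hi, smooth_sigma, cal_rng, calibration_draws) > target_dice:
        hi *= 2.0
        if hi > 64.0:
            break
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        d = _mean_dice(true_mask, mid, smooth_sigma, cal_rng, calibration_draws)
        if d > target_dice:
            lo = mid
        else:
            hi = mid
    amplitude = 0.5 * (lo + hi)

    masks = []
    for i in range(n_readers):
        pert = _perturb_mask(true_mask.data, amplitude, smooth_sigma, draw_rng)
        if not pert.any():  # degenerate draw: fall back to the truth
            pert = true_mask.data.copy()
        masks.append(VoxelMask(pert, label=true_mask.label, reader=f"sim{i + 1}"))
    return masks


# --------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSpec:
    """Statistical structure of a simulated bilateral cohort.

    Ages, weights and heights match a two-group healthy-volunteer design
    (a young group in their early twenties and a senior group over 45).
    Per-subject nerve aT2* is drawn around side-specific scenario means
    (right/left), with a between-subject random effect and a smaller
    side-specific residual; nerve calibre is drawn from a CSA distribution.
    """

    n_young: int = 10
    n_senior: int = 5
    sex_ratio: float = 0.6            # fraction male, applied per group
    young_age_range: tuple[int, int] = (21, 26)
    senior_age_range: tuple[int, int] = (46, 62)
    height_mean_m: float = 1.75
    height_sd_m: float = 0.08
    bmi_mean: float = 21.9
    bmi_sd: float = 1.2               # weight = BMI * height^2 (keeps BMI realistic)
    side_mean_at2_ms: tuple[float, float] = (17.25, 18.57)  # (right, left)
    between_subject_sd_ms: float = 3.5
    within_side_sd_ms: float = 4.0
    csa_mean_mm2: float = 46.5
    csa_sd_mm2: float = 7.0          # between-subject calibre spread
    csa_side_sd_mm2: float = 3.0     # left/right asymmetry within a subject
    n_repeat_scans: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_senior < 0 or self.n_repeat_scans < 0:
            raise ValueError("counts must be >= 0")
        if self.young_age_range[1] >= self.senior_age_range[0]:
            raise ValueError("age ranges must not overlap")
        if min(self.between_subject_sd_ms, self.within_side_sd_ms,
               self.bmi_sd, self.height_sd_m, self.csa_sd_mm2) < 0:
            raise ValueError("spread parameters must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_senior


@dataclass
class SideData:
    study: DualEchoStudy          # noisy acquisition
    noiseless: DualEchoStudy
    truth: PhantomGroundTruth
    true_at2_ms: float
    config: PhantomConfig         # the per-subject/side phantom description


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    sex: str
    age: int
    weight_kg: float
    height_m: float
    bmi: float
    sides: dict[str, SideData]
    retest: dict[str, DualEchoStudy] = field(default_factory=dict)


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    table: pd.DataFrame
    spec: CohortSpec
    config: PhantomConfig

    @property
    def n_studies(self) -> int:
        return sum(len(s.sides) for s in self.subjects)


def _subject_config(config: PhantomConfig, at2_ms: float, radius_mm: float,
                    side: str) -> PhantomConfig:
    """Per-subject/side config: single-pool nerve at the drawn aT2*, drawn
    calibre, nerve mirrored across the midline for the left side."""
    tissues = dict(config.tissues)
    nerve = tissues["nerve"]
    tissues["nerve"] = TissueSpec("nerve", nerve.s0, ((1.0, at2_ms),))
    tissues["fascicle"] = TissueSpec("fascicle", nerve.s0, ((1.0, at2_ms),))
    cx, cy = config.geometry.nerve_center_mm
    center = (cx, cy) if side == "right" else (-cx, cy)
    geom = replace(config.geometry, nerve_radius_mm=radius_mm, nerve_center_mm=center)
    return replace(config, tissues=tissues, geometry=geom)


def generate_cohort(spec: CohortSpec, config: PhantomConfig) -> Cohort:
    """Simulate a bilateral cohort of dual-echo studies with ground truth.

    Every stochastic choice is derived from ``spec.seed`` through spawned
    sub-seeds, so the whole cohort is reproducible bit-for-bit. Each
    subject/side study uses a single-pool nerve whose T2* equals the drawn
    subject aT2* (the recovery oracle is then exact), embedded in the
    standard muscle/fascia/fat cross-section.
    """
    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = ss.spawn(spec.n_subjects)

    groups = ["young"] * spec.n_young + ["senior"] * spec.n_senior
    subjects: list[SubjectRecord] = []
    rows = []
    for i, group in enumerate(groups):
        srng = np.random.default_rng(subject_seeds[i])
        sid = f"sub-{i + 1:02d}"
        n_group = spec.n_young if group == "young" else spec.n_senior
        i_group = i if group == "young" else i - spec.n_young
        n_male = round(spec.sex_ratio * n_group)
        sex = "M" if i_group < n_male else "F"
        lo, hi = (spec.young_age_range if group == "young"
                  else spec.senior_age_range)
        age = int(srng.integers(lo, hi + 1))
        height = float(np.clip(srng.normal(spec.height_mean_m, spec.height_sd_m),
                               1.45, 2.05))
        bmi = float(np.clip(srng.normal(spec.bmi_mean, spec.bmi_sd), 16.0, 32.0))
        weight = bmi * height**2

        subj_effect = srng.normal(0.0, spec.between_subject_sd_ms)
        csa_base = srng.normal(spec.csa_mean_mm2, spec.csa_sd_mm2)

        sides: dict[str, SideData] = {}
        retest: dict[str, DualEchoStudy] = {}
        for j, side in enumerate(("right", "left")):
            at2 = spec.side_mean_at2_ms[j] + subj_effect + \
                srng.normal(0.0, spec.within_side_sd_ms)
            at2 = float(np.clip(at2, 6.0, 60.0))
            csa = float(np.clip(csa_base + srng.normal(0.0, spec.csa_side_sd_mm2),
                                20.0, 85.0))
            radius = math.sqrt(csa / math.pi)
            cfg = _subject_config(config, at2, radius, side)
            truth = build_label_map(cfg)
            clean = simulate_signal(truth, cfg, subject_id=sid, side=side)
            noise_seed = int(srng.integers(0, 2**31 - 1))
            noisy = add_rician_noise(clean, cfg.noise_sigma, noise_seed)
            sides[side] = SideData(study=noisy, noiseless=clean, truth=truth,
                                   true_at2_ms=at2, config=cfg)
            if i < spec.n_repeat_scans:
                retest_seed = int(srng.integers(0, 2**31 - 1))
                retest[side] = add_rician_noise(clean, cfg.noise_sigma, retest_seed)

        subjects.append(SubjectRecord(
            subject_id=sid, group=group, sex=sex, age=age, weight_kg=weight,
            height_m=height, bmi=bmi, sides=sides, retest=retest))
        rows.append(dict(subject_id=sid, group=group, sex=sex, age=age,
                         weight_kg=round(weight, 2), height_m=round(height, 3),
                         bmi=round(bmi, 2)))

    table = pd.DataFrame(rows, columns=["subject_id", "group", "sex", "age",
                                        "weight_kg", "height_m", "bmi"])
    return Cohort(subjects=subjects, table=table, spec=spec, config=config)
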