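"""Synthetic study data: score-level cohort simulation and digital phantoms.

The patient-level data behind the carotid-plaque study design this package
implements are not publicly deposited, so two generators stand in for them:

* **Score-level cohorts** — per-patient contrast ratios (CR_max_occupation,
  CR_max_intensity) and the binary MES outcome, drawn from group-conditional
  presets.  The default normal presets are calibrated through the binormal
  closed form ``AUC = Phi((mu_pos - mu_neg) / sqrt(sd^2 + sd^2))`` so that the
  expected discrimination reproduces the published AUC structure (0.941 and
  0.885 in the full cohort of 19 MES-positive / 56 MES-negative patients;
  0.901 and 0.824 in the non-identified subgroup of 11/32).  The identified
  subgroup (8/24) uses disjoint uniform supports, giving AUC exactly 1.
* **Digital vessel phantoms** — 3D intensity volumes with a vessel tube,
  an angular plaque wedge whose thickness profile prescribes the per-slice
  POR, an intensity profile with a designed peak slice, and an adjacent
  muscle cylinder fixed at intensity 100 so the designed CR is read directly.
  Ground-truth label volumes and centerline points let every reformation and
  measurement stage be checked against designed values.

Covariate columns (age, risk factors, lesion geometry, ulceration, ...)
follow group-conditional prevalence/mean models whose defaults match the
published risk-factor table of the same cohorts.

Every generator takes an explicit integer seed; a fixed seed fixes every
output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reformation import VolumeGrid

__all__ = [
    "ScorePreset",
    "CovariateModel",
    "BinaryCovariate",
    "ContinuousCovariate",
    "PhantomSpec",
    "Phantom",
    "COHORT_PRESETS",
    "DEFAULT_COVARIATES",
    "simulate_scores",
    "simulate_covariates",
    "simulate_phantom",
]


@dataclass(frozen=True)
class ScorePreset:
    """Group-conditional score distribution for one CR score.

    ``family="normal"`` draws Normal(mean_pos, sd) / Normal(mean_neg, sd);
    ``family="uniform"`` draws from per-group bounds (used for the identified
    subgroup whose supports are disjoint).
    """

    n_pos: int
    n_neg: int
    family: str = "normal"
    mean_pos: float | None = None
    mean_neg: float | None = None
    sd: float = 0.20
    pos_bounds: tuple[float, float] | None = None
    neg_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both groups need at least one patient")
        if self.family == "normal":
            if self.mean_pos is None or self.mean_neg is None:
                raise ValueError("normal family requires mean_pos and mean_neg")
            if self.sd <= 0:
                raise ValueError("sd must be positive")
        elif self.family == "uniform":
            for b in (self.pos_bounds, self.neg_bounds):
                if b is None or not b[0] < b[1]:
                    raise ValueError("uniform family requires lower < upper bounds")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    def theoretical_auc(self) -> float:
        """P(score_pos > score_neg) under the preset (binormal closed form,
        or the overlap integral for the uniform family)."""
        if self.family == "normal":
            return float(
                norm.cdf((self.mean_pos - self.mean_neg) / (self.sd * np.sqrt(2.0)))
            )
        (a, b), (c, d) = self.pos_bounds, self.neg_bounds  # type: ignore[misc]
        if a >= d:
            return 1.0
        if b <= c:
            return 0.0
        # P(X > Y) = E_Y[ clip((b - Y)/(b - a), 0, 1) ], Y ~ U(c, d)
        ys = np.linspace(c, d, 20001)
        return float(np.trapezoid(np.clip((b - ys) / (b - a), 0, 1), ys) / (d - c))

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if self.family == "normal":
            pos = rng.normal(self.mean_pos, self.sd, self.n_pos)
            neg = rng.normal(self.mean_neg, self.sd, self.n_neg)
        else:
            pos = rng.uniform(*self.pos_bounds, self.n_pos)  # type: ignore[misc]
            neg = rng.uniform(*self.neg_bounds, self.n_neg)  # type: ignore[misc]
        return pos, neg


#: Presets calibrated to the published cohort structure: 19/56 MES+/MES-
#: patients overall, of whom 8/24 fall in the identified subgroup (max-POR
#: and max-intensity slices within 2 mm) and 11/32 in the non-identified one.
COHORT_PRESETS: dict[str, ScorePreset] = {
    # full cohort: target AUC 0.941 (max intensity), 0.885 (max occupation)
    "full_cohort_max_intensity": ScorePreset(19, 56, mean_pos=1.742, mean_neg=1.300),
    "full_cohort_max_occupation": ScorePreset(19, 56, mean_pos=1.640, mean_neg=1.300),
    # non-identified subgroup: target AUC 0.901 / 0.824
    "nonidentified_max_intensity": ScorePreset(11, 32, mean_pos=1.664, mean_neg=1.300),
    "nonidentified_max_occupation": ScorePreset(11, 32, mean_pos=1.563, mean_neg=1.300),
    # identified subgroup: disjoint supports, AUC exactly 1 on every draw
    "identified": ScorePreset(
        8, 24, family="uniform", pos_bounds=(1.70, 2.20), neg_bounds=(1.00, 1.50)
    ),
}


def simulate_scores(
    preset_occ: ScorePreset,
    preset_int: ScorePreset,
    enforce_order: bool = False,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw one cohort of (CR_max_occupation, CR_max_intensity, MES) rows.

    With ``enforce_order`` unset (calibration mode) the two scores are drawn
    independently from their presets, so each marginal matches its preset
    exactly.  With it set, CR_max_intensity is drawn from its preset and
    CR_max_occupation obtained by subtracting a non-negative exponential
    decrement, enforcing the row-wise ordering CR_int >= CR_occ that the
    measurement stage guarantees.
    """
    if (preset_occ.n_pos, preset_occ.n_neg) != (preset_int.n_pos, preset_int.n_neg):
        raise ValueError("presets disagree on cohort size (n_pos/n_neg)")
    rng = np.random.default_rng(seed)
    n_pos, n_neg = preset_int.n_pos, preset_int.n_neg
    pos_int, neg_int = preset_int.draw(rng)
    if enforce_order:
        if preset_occ.family != "normal" or preset_int.family != "normal":
            raise ValueError("enforce_order requires normal presets")
        scale_pos = max(preset_int.mean_pos - preset_occ.mean_pos, 1e-9)
        scale_neg = max(preset_int.mean_neg - preset_occ.mean_neg, 1e-9)
        pos_occ = pos_int - rng.exponential(scale_pos, n_pos)
        neg_occ = neg_int - rng.exponential(scale_neg, n_neg)
    else:
        pos_occ, neg_occ = preset_occ.draw(rng)
    df = pd.DataFrame(
        {
            "patient_id": np.arange(n_pos + n_neg),
            "cr_max_occ": np.concatenate([pos_occ, neg_occ]),
            "cr_max_int": np.concatenate([pos_int, neg_int]),
            "mes": np.concatenate(
                [np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
            ),
        }
    )
    return df


@dataclass(frozen=True)
class BinaryCovariate:
    """Bernoulli covariate with MES-conditional prevalences."""

    prevalence_pos: float
    prevalence_neg: float

    def __post_init__(self) -> None:
        for p in (self.prevalence_pos, self.prevalence_neg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class ContinuousCovariate:
    """Normal covariate with MES-conditional mean and SD."""

    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float

    def __post_init__(self) -> None:
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise ValueError("covariate sd must be positive")


CovariateModel = Mapping[str, BinaryCovariate | ContinuousCovariate]

#: MES-conditional covariate distributions matching the published risk-factor
#: table (counts out of 19 MES-positive and 56 MES-negative patients).
DEFAULT_COVARIATES: CovariateModel = {
    "age": ContinuousCovariate(69.6, 7.8, 69.9, 6.8),
    "male_sex": BinaryCovariate(18 / 19, 50 / 56),
    "hypertension": BinaryCovariate(18 / 19, 50 / 56),
    "diabetes": BinaryCovariate(9 / 19, 17 / 56),
    "dyslipidemia": BinaryCovariate(5 / 19, 19 / 56),
    "symptomatic_lesion": BinaryCovariate(16 / 19, 31 / 56),
    "stenosis_pct": ContinuousCovariate(85.9, 9.6, 87.9, 8.7),
    "lesion_length_mm": ContinuousCovariate(53.6, 11.8, 55.6, 10.1),
    "distal_end_height": ContinuousCovariate(2.8, 1.1, 2.7, 0.8),
    "tortuosity_deg": ContinuousCovariate(109.3, 27.2, 112.0, 24.9),
    "ulceration": BinaryCovariate(10 / 19, 13 / 56),
}


def simulate_covariates(
    model: CovariateModel,
    labels,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw one covariate column per model entry, conditional on the MES label."""
    labels = np.asarray(labels).astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name, spec in model.items():
        if isinstance(spec, BinaryCovariate):
            p = np.where(labels == 1, spec.prevalence_pos, spec.prevalence_neg)
            cols[name] = (rng.random(len(labels)) < p).astype(int)
        else:
            mu = np.where(labels == 1, spec.mean_pos, spec.mean_neg)
            sd = np.where(labels == 1, spec.sd_pos, spec.sd_neg)
            cols[name] = rng.normal(mu, sd)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Digital vessel phantoms
# ---------------------------------------------------------------------------

# label codes in the ground-truth volume
LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_WALL = 2
LABEL_PLAQUE = 3
LABEL_MUSCLE = 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity design of one digital vessel phantom.

    The vessel is a tube of outer radius ``vessel_radius`` around a straight
    (or circular-arc) centerline; the wall is an annulus of ``wall_thickness``;
    the plaque is an angular wedge growing inward from the wall over
    ``plaque_z`` with a triangular thickness profile peaking at ``z_por_peak``
    (this prescribes the per-slice POR).  The plaque intensity falls off
    linearly from ``cr_target * muscle_intensity`` at ``z_intensity_peak``
    with slope ``intensity_slope`` per mm, floored at ``intensity_base``.
    A muscle cylinder of triangular radius profile (largest at
    ``z_muscle_peak``) sits at ``muscle_offset`` from the vessel centre and is
    fixed at ``muscle_intensity`` (default 100) so CR targets are read
    directly.  Intensities are arbitrary units; noise is additive Gaussian.
    """

    voxel_size: float = 0.5
    shape: tuple[int, int, int] = (96, 96, 160)
    path: str = "straight"  # or "curved"
    curvature_radius: float = 400.0  # mm, curved path only
    vessel_center: tuple[float, float] = (16.0, 24.0)  # mm, in-plane
    vessel_radius: float = 5.0
    wall_thickness: float = 1.0
    plaque_z: tuple[float, float] = (20.0, 60.0)
    plaque_angle: tuple[float, float] = (0.0, 180.0)  # degrees
    plaque_thickness_max: float = 3.0
    z_por_peak: float = 40.0
    cr_target: float = 1.85
    z_intensity_peak: float = 40.0
    intensity_slope: float = 2.2  # units per mm away from the peak
    intensity_base: float = 120.0
    muscle_intensity: float = 100.0
    muscle_offset: tuple[float, float] = (16.0, 0.0)  # mm from vessel centre
    muscle_radius_max: float = 7.0
    muscle_radius_slope: float = 0.05  # mm radius loss per mm along z
    muscle_radius_min: float = 3.0
    z_muscle_peak: float = 40.0
    lumen_intensity: float = 5.0
    wall_intensity: float = 60.0
    background_intensity: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        z0, z1 = self.plaque_z
        length = self.shape[2] * self.voxel_size
        if not 0.0 <= z0 < z1 <= length:
            raise ValueError("plaque extent must lie inside the grid")
        if not z0 <= self.z_intensity_peak <= z1:
            raise ValueError("intensity peak must lie inside the plaque extent")
        if not z0 <= self.z_por_peak <= z1:
            raise ValueError("POR peak must lie inside the plaque extent")
        if self.plaque_thickness_max > self.vessel_radius - self.wall_thickness:
            raise ValueError("plaque thicker than the sub-wall cross-section")
        for v in (
            self.cr_target * self.muscle_intensity,
            self.intensity_base,
            self.muscle_intensity,
            self.lumen_intensity,
            self.wall_intensity,
            self.background_intensity,
        ):
            if v < 0:
                raise ValueError("intensities must be non-negative")

    # --- designed profiles, all functions of arc length s (mm) ---

    def plaque_thickness(self, s: np.ndarray) -> np.ndarray:
        z0, z1 = self.plaque_z
        half = max(self.z_por_peak - z0, z1 - self.z_por_peak)
        t = self.plaque_thickness_max * (1.0 - np.abs(s - self.z_por_peak) / half)
        return np.where((s >= z0) & (s <= z1), np.maximum(t, 0.0), 0.0)

    def plaque_intensity(self, s: np.ndarray) -> np.ndarray:
        peak = self.cr_target * self.muscle_intensity
        return np.maximum(
            peak - self.intensity_slope * np.abs(s - self.z_intensity_peak),
            self.intensity_base,
        )

    def muscle_radius(self, s: np.ndarray) -> np.ndarray:
        return np.maximum(
            self.muscle_radius_max
            - self.muscle_radius_slope * np.abs(s - self.z_muscle_peak),
            self.muscle_radius_min,
        )

    def designed_por(self, s: np.ndarray) -> np.ndarray:
        """Analytic per-slice POR (%) implied by the thickness profile."""
        t = self.plaque_thickness(np.asarray(s, dtype=float))
        r_in = self.vessel_radius - self.wall_thickness
        dphi = np.deg2rad(self.plaque_angle[1] - self.plaque_angle[0])
        plaque_area = 0.5 * dphi * (r_in**2 - (r_in - t) ** 2)
        vessel_area = np.pi * self.vessel_radius**2
        return plaque_area / vessel_area * 100.0


@dataclass
class Phantom:
    """A simulated volume with its ground truth."""

    volume: VolumeGrid
    labels: VolumeGrid
    centerline_points: np.ndarray  # reference points on the true axis (mm)
    designed: pd.DataFrame  # per-slice z_mm, por (%), plaque_intensity


def _tube_coordinates(spec: PhantomSpec, x, y, z):
    """(s, radial distance, tube angle) of every voxel w.r.t. the vessel axis."""
    cx, cy = spec.vessel_center
    if spec.path == "straight":
        s = z
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        return s, r, phi
    if spec.path != "curved":
        raise ValueError(f"unknown path kind {spec.path!r}")
    # circular arc in the x-z plane: starts at (cx, cy, 0) with tangent +z,
    # bending toward +x with radius R
    big_r = spec.curvature_radius
    centre_x, centre_z = cx + big_r, 0.0
    vx, vz = x - centre_x, z - centre_z
    rho = np.hypot(vx, vz)
    alpha = np.arctan2(vz, -vx)  # 0 at the start of the arc
    s = big_r * alpha
    d_plane = rho - big_r  # signed offset in the bending plane
    r = np.hypot(d_plane, y - cy)
    phi = np.arctan2(y - cy, d_plane)
    return s, r, phi


def _centerline_points(spec: PhantomSpec, step: float = 8.0) -> np.ndarray:
    # last voxel centre along z; keeps the fitted path inside the volume
    length = (spec.shape[2] - 1) * spec.voxel_size
    cx, cy = spec.vessel_center
    if spec.path == "straight":
        zs = np.append(np.arange(0.0, length - 1e-9, step), length)
        return np.column_stack([np.full_like(zs, cx), np.full_like(zs, cy), zs])
    big_r = spec.curvature_radius
    smax = big_r * np.arcsin(min((length - spec.voxel_size) / big_r, 1.0))
    ss = np.arange(0.0, smax, step)
    alpha = ss / big_r
    xs = cx + big_r * (1.0 - np.cos(alpha))
    zs = big_r * np.sin(alpha)
    return np.column_stack([xs, np.full_like(ss, cy), zs])


def simulate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the phantom onto its voxel grid.

    Voxels are classified by their centre point; labels are mutually
    exclusive and cover the grid.  Voxel centres sit at multiples of the
    voxel size, so a straight phantom reformatted along its own axis is
    sampled exactly at voxel centres (no interpolation blur), making
    designed CR values exactly recoverable.
    """
    nx, ny, nz = spec.shape
    h = spec.voxel_size
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    x, y, z = ix * h, iy * h, iz * h

    s, r, phi = _tube_coordinates(spec, x, y, z)
    in_axis = (s >= 0) & (s <= nz * h)

    r_in = spec.vessel_radius - spec.wall_thickness
    t = spec.plaque_thickness(s)
    a0, a1 = np.deg2rad(spec.plaque_angle)
    ang = np.mod(phi - a0, 2 * np.pi)
    in_wedge = ang <= (a1 - a0) + 1e-12

    vessel = in_axis & (r <= spec.vessel_radius)
    wall = vessel & (r > r_in)
    plaque = vessel & in_wedge & (t > 0) & (r <= r_in) & (r > r_in - t)
    lumen = vessel & ~wall & ~plaque

    mx, my = spec.muscle_offset
    cx, cy = spec.vessel_center
    if spec.path == "straight":
        rm = np.hypot(x - (cx + mx), y - (cy + my))
        sm = z
    else:
        # curved phantoms offset the muscle tube in y (a true parallel tube)
        sm, r_tube, phi_tube = _tube_coordinates(
            replace(spec, vessel_center=(cx + mx, cy + my)), x, y, z
        )
        rm = r_tube
    muscle = ~vessel & in_axis & (rm <= spec.muscle_radius(sm))

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[muscle] = LABEL_MUSCLE
    labels[lumen] = LABEL_LUMEN
    labels[wall] = LABEL_WALL
    labels[plaque] = LABEL_PLAQUE

    intensity = np.full(spec.shape, spec.background_intensity, dtype=float)
    intensity[muscle] = spec.muscle_intensity
    intensity[lumen] = spec.lumen_intensity
    intensity[wall] = spec.wall_intensity
    intensity[plaque] = spec.plaque_intensity(s)[plaque]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, spec.shape)
        intensity = np.maximum(intensity, 0.0)

    z_design = np.arange(0.0, (nz - 1) * h + 1e-9, 1.0)
    designed = pd.DataFrame(
        {
            "z_mm": z_design,
            "por": spec.designed_por(z_design),
            "plaque_intensity": np.where(
                spec.plaque_thickness(z_design) > 0,
                spec.plaque_intensity(z_design),
                np.nan,
            ),
        }
    )
    if np.nanmin(designed["por"]) < 0 or np.nanmax(designed["por"]) > 100:
        raise AssertionError("designed POR outside [0, 100]")

    return Phantom(
        volume=VolumeGrid.from_array(intensity, h),
        labels=VolumeGrid.from_array(labels, h),
        centerline_points=_centerline_points(spec),
        designed=designed,
    )
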