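"""Per-patient plaque scores from traced regions on reformatted slices.

On every reformatted axial slice the plaque and the outer-wall-bounded vessel
cross-section are traced (here: supplied as a co-registered integer label
stack).  From these the pipeline derives, per patient:

* per-slice POR — plaque occupation rate, plaque area / vessel area x 100 (%);
* the max-POR slice, and the max-plaque-intensity slice searched within a
  window of ±25 mm around it (51 candidate slices at 1.0 mm spacing);
* the "identification" flag — whether those two slices lie within 0–2 mm of
  each other;
* a single muscle denominator — the mean sternocleidomastoid intensity on the
  in-window slice where the traced muscle is largest;
* CR_max_occupation and CR_max_intensity — mean plaque intensity at the
  max-POR slice and at the max-intensity slice, each divided by that same
  muscle denominator.

All maxima break ties toward the lowest (most caudal) slice index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reformation import ReformattedStack

__all__ = [
    "TRACE_PLAQUE",
    "TRACE_VESSEL",
    "TRACE_MUSCLE",
    "SliceTrace",
    "PatientPlaqueProfile",
    "NoPlaqueError",
    "traces_from_labels",
    "compute_por",
    "compute_cr",
    "select_max_por_slice",
    "select_max_intensity_slice",
    "assess_identification",
    "select_muscle_reference",
    "profile_patient",
]

# trace label codes (label stacks co-registered to the reformatted stack)
TRACE_PLAQUE = 1
TRACE_VESSEL = 2
TRACE_MUSCLE = 3


class NoPlaqueError(ValueError):
    """No slice carries a plaque trace."""


@dataclass
class SliceTrace:
    """Traced regions and ROI statistics for one reformatted slice."""

    index: int
    pixel_area: float  # mm^2 per in-plane pixel
    plaque_area: float  # mm^2
    vessel_area: float  # mm^2
    muscle_area: float  # mm^2
    plaque_mean: float  # mean plaque intensity; NaN when no plaque traced
    muscle_mean: float  # mean muscle intensity; NaN when no muscle traced

    def __post_init__(self) -> None:
        if self.vessel_area > 0 and self.plaque_area > self.vessel_area + 1e-9:
            raise ValueError(
                f"slice {self.index}: plaque area exceeds vessel area "
                "(plaque must lie within the vessel cross-section)"
            )


def traces_from_labels(
    stack: ReformattedStack, label_stack: ReformattedStack
) -> list[SliceTrace]:
    """Build per-slice traces from an integer label stack.

    Codes: 1 plaque, 2 vessel (outer-wall-bounded cross-section, *excluding*
    the plaque pixels which carry their own code), 3 muscle.  Intensity means
    ignore NaN out-of-volume sentinels.
    """
    if stack.data.shape != label_stack.data.shape:
        raise ValueError("label stack is not co-registered to the image stack")
    px = stack.pixel_area
    traces = []
    labels = np.rint(np.asarray(label_stack.data)).astype(int)
    for k in range(stack.n_slices):
        img = stack.data[k]
        lab = labels[k]
        plaque = lab == TRACE_PLAQUE
        vessel = plaque | (lab == TRACE_VESSEL)
        muscle = lab == TRACE_MUSCLE
        traces.append(
            SliceTrace(
                index=k,
                pixel_area=px,
                plaque_area=float(np.count_nonzero(plaque)) * px,
                vessel_area=float(np.count_nonzero(vessel)) * px,
                muscle_area=float(np.count_nonzero(muscle)) * px,
                plaque_mean=float(np.nanmean(img[plaque])) if plaque.any() else np.nan,
                muscle_mean=float(np.nanmean(img[muscle])) if muscle.any() else np.nan,
            )
        )
    return traces


def compute_por(plaque_area: float, vessel_area: float) -> float:
    """Plaque occupation rate: plaque area / vessel area x 100 (%)."""
    if vessel_area <= 0:
        raise ValueError("vessel area must be positive")
    if plaque_area < 0:
        raise ValueError("plaque area must be non-negative")
    if plaque_area > vessel_area + 1e-9:
        raise ValueError("plaque area exceeds vessel area")
    return min(plaque_area / vessel_area, 1.0) * 100.0


def compute_cr(plaque_intensity: float, muscle_intensity: float) -> float:
    """Contrast ratio: mean plaque intensity / mean muscle intensity."""
    if muscle_intensity <= 0:
        raise ValueError("muscle intensity must be positive")
    return plaque_intensity / muscle_intensity


def select_max_por_slice(por: np.ndarray) -> int:
    """Index of the maximum POR; ties break to the lowest (caudal) index."""
    por = np.asarray(por, dtype=float)
    if por.size == 0 or np.all(np.isnan(por)) or np.nanmax(por) <= 0:
        raise NoPlaqueError("no slice carries plaque")
    return int(np.argmax(np.nan_to_num(por, nan=-np.inf)))


def window_indices(
    center_index: int, n_slices: int, half_window: int = 25
) -> np.ndarray:
    """Candidate slice indices within ±half_window of the center, clipped."""
    lo = center_index - half_window
    hi = center_index + half_window
    if lo < 0 or hi > n_slices - 1:
        clipped = np.arange(max(lo, 0), min(hi, n_slices - 1) + 1)
        warnings.warn(
            f"search window [{lo}, {hi}] clipped to the stack; "
            f"{clipped.size} candidate slices instead of {2 * half_window + 1}",
            stacklevel=2,
        )
        return clipped
    return np.arange(lo, hi + 1)


def select_max_intensity_slice(
    plaque_means: np.ndarray, center_index: int, half_window: int = 25
) -> int:
    """Index of the max mean plaque intensity within the slice window.

    Only plaque-bearing slices (non-NaN mean) inside
    ``[center - half_window, center + half_window]`` compete; ties break to
    the lowest index.
    """
    plaque_means = np.asarray(plaque_means, dtype=float)
    if not 0 <= center_index < plaque_means.size:
        raise ValueError("center_index outside the stack")
    idx = window_indices(center_index, plaque_means.size, half_window)
    vals = plaque_means[idx]
    if np.all(np.isnan(vals)):
        raise NoPlaqueError("window contains no plaque-bearing slice")
    return int(idx[np.argmax(np.nan_to_num(vals, nan=-np.inf))])


def assess_identification(
    index_max_por: int,
    index_max_intensity: int,
    slice_spacing: float = 1.0,
    threshold_mm: float = 2.0,
) -> tuple[float, bool]:
    """Distance (mm) between the two landmark slices and the identification flag.

    The flag is inclusive at the threshold: 0–2 mm counts as identified.
    """
    distance = abs(index_max_por - index_max_intensity) * slice_spacing
    return float(distance), bool(distance <= threshold_mm)


def select_muscle_reference(
    traces: list[SliceTrace], indices: np.ndarray
) -> tuple[int, float]:
    """In-window slice where the traced muscle is largest, and its mean intensity.

    This single mean is the denominator for both CR scores.  Ties break to
    the lowest index.
    """
    areas = np.array([traces[i].muscle_area for i in indices], dtype=float)
    if areas.size == 0 or np.nanmax(areas) <= 0:
        raise ValueError("no muscle traced inside the search window")
    best = int(indices[int(np.argmax(areas))])
    return best, float(traces[best].muscle_mean)


@dataclass
class PatientPlaqueProfile:
    """All per-patient quantities derived from one reformatted stack."""

    por: np.ndarray  # per-slice POR (%); NaN where no vessel traced
    plaque_mean: np.ndarray  # per-slice mean plaque intensity
    index_max_por: int
    index_max_intensity: int
    slice_distance_mm: float
    identified: bool
    por_max_occupation: float
    por_max_intensity: float
    muscle_index: int
    muscle_mean: float
    cr_max_occupation: float
    cr_max_intensity: float
    n_window_candidates: int

    def validate(self) -> None:
        finite = self.por[np.isfinite(self.por)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise AssertionError("POR outside [0, 100]")
        if self.por_max_intensity > self.por_max_occupation + 1e-9:
            raise AssertionError("POR at intensity peak exceeds the POR maximum")
        if self.cr_max_intensity < self.cr_max_occupation - 1e-12:
            raise AssertionError("CR_max_intensity below CR_max_occupation")
        if self.identified and self.slice_distance_mm > 2.0:
            raise AssertionError("identified profile with distance > 2 mm")

    def to_row(self) -> dict:
        # short column names shared with the score-level cohort CSVs
        return {
            "por_max_occ": self.por_max_occupation,
            "por_max_int": self.por_max_intensity,
            "cr_max_occ": self.cr_max_occupation,
            "cr_max_int": self.cr_max_intensity,
            "slice_distance_mm": self.slice_distance_mm,
            "identified": int(self.identified),
            "index_max_por": self.index_max_por,
            "index_max_intensity": self.index_max_intensity,
            "muscle_index": self.muscle_index,
            "muscle_mean": self.muscle_mean,
        }


def profile_patient(
    stack: ReformattedStack,
    traces: list[SliceTrace],
    half_window_mm: float = 25.0,
    identification_threshold_mm: float = 2.0,
) -> PatientPlaqueProfile:
    """Assemble the full per-patient profile from per-slice traces.

    CR_max_occupation uses the plaque intensity at the max-POR slice and
    CR_max_intensity the intensity at the in-window max-intensity slice; both
    share the single muscle denominator from :func:`select_muscle_reference`.
    """
    if len(traces) != stack.n_slices:
        raise ValueError("traces are not aligned to the stack slices")
    ratio = half_window_mm / stack.slice_spacing
    half_window = int(round(ratio))
    if abs(ratio - half_window) > 1e-9:
        raise ValueError("window half-width must be a multiple of slice spacing")

    por = np.array(
        [
            compute_por(t.plaque_area, t.vessel_area) if t.vessel_area > 0 else np.nan
            for t in traces
        ]
    )
    means = np.array([t.plaque_mean for t in traces], dtype=float)

    i_por = select_max_por_slice(por)
    window = window_indices(i_por, stack.n_slices, half_window)
    i_int = select_max_intensity_slice(means, i_por, half_window)
    distance, identified = assess_identification(
        i_por, i_int, stack.slice_spacing, identification_threshold_mm
    )
    i_muscle, muscle_mean = select_muscle_reference(traces, window)

    profile = PatientPlaqueProfile(
        por=por,
        plaque_mean=means,
        index_max_por=i_por,
        index_max_intensity=i_int,
        slice_distance_mm=distance,
        identified=identified,
        por_max_occupation=float(por[i_por]),
        por_max_intensity=float(por[i_int]),
        muscle_index=i_muscle,
        muscle_mean=muscle_mean,
        cr_max_occupation=compute_cr(means[i_por], muscle_mean),
        cr_max_intensity=compute_cr(means[i_int], muscle_mean),
        n_window_candidates=int(window.size),
    )
    profile.validate()
    return profile
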