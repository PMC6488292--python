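"""Image-derived measurements: occupancy, DAG, densities and receptor counts.

Implements the measurement chain used on TIRF/RICM time courses of cells on
ligand-functionalized supported lipid bilayers:

* flat-field correction against dye-slide reference images,
* RICM footprint segmentation with a surrounding "ribbon" background mask,
* receptor occupancy as the background-subtracted ligand-channel enrichment
  under the footprint, normalized for laser-power fluctuations tracked by the
  integrated whole-field fluorescence,
* steady-state DAG reporter level with PP2 (Src-kinase-inhibited) baseline
  subtraction and reset-pulse drift correction,
* absolute ligand surface density from single-molecule counting calibration,
* absolute receptor counts per cell from antibody-binding-capacity beads.

Negative corrected values are retained (never clipped) so downstream fit
residuals stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import dilation, disk

__all__ = [
    "MaskPair",
    "DagTrace",
    "DensityCalibration",
    "BeadCalibration",
    "flat_field_correct",
    "segment_masks",
    "measure_occupancy",
    "measure_dag",
    "normalize_dag",
    "NormalizedDag",
    "estimate_lov2_density",
    "count_surface_receptors",
    "quantify_timecourse",
]


@dataclass(frozen=True)
class MaskPair:
    """Cell-footprint mask and its surrounding ribbon background mask."""

    cell_mask: np.ndarray
    ribbon_mask: np.ndarray
    touches_edge: bool = False

    def __post_init__(self) -> None:
        cm = np.asarray(self.cell_mask, dtype=bool)
        rm = np.asarray(self.ribbon_mask, dtype=bool)
        if cm.shape != rm.shape:
            raise ValueError("cell and ribbon masks must have the same shape")
        if np.any(cm & rm):
            raise ValueError("cell and ribbon masks must be disjoint")
        object.__setattr__(self, "cell_mask", cm)
        object.__setattr__(self, "ribbon_mask", rm)


@dataclass(frozen=True)
class DagTrace:
    """Per-frame mean DAG-reporter intensity with correction metadata.

    ``values`` are mean reporter intensities inside the cell mask, one per
    frame of the whole time course.  ``reset_pulse_indices`` mark the frames
    measured at the end of each fixed 'reset' light pulse; the drift
    correction compares the reset value of the measured block against the mean
    of the final three reset values.  ``steady_state_window`` is the number of
    final frames averaged as the steady-state response (default 6, the last
    ~50 s of a 3-minute hold).
    """

    values: np.ndarray
    reset_pulse_indices: tuple[int, ...] = ()
    pp2_baseline: float = 0.0
    steady_state_window: int = 6

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not (1 <= self.steady_state_window <= v.size):
            raise ValueError(
                f"steady_state_window {self.steady_state_window} exceeds trace length {v.size}"
            )
        for i in self.reset_pulse_indices:
            if not (0 <= i < v.size):
                raise ValueError(f"reset pulse index {i} out of range")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "reset_pulse_indices", tuple(self.reset_pulse_indices))


@dataclass(frozen=True)
class DensityCalibration:
    """Single-molecule counting calibration of ligand surface density.

    A trace-labeled ligand fraction is counted molecule-by-molecule; the total
    density at bilayer saturation is recovered from the dilution factor, the
    stock concentrations and the labeling efficiency.
    """

    counted_density: float  # molecules/um^2 of the counted trace label
    dilution_factor: float
    conc_cy3: float
    conc_a488: float
    labeled_fraction: float

    def __post_init__(self) -> None:
        for name in ("counted_density", "dilution_factor", "conc_cy3", "conc_a488"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.labeled_fraction <= 1):
            raise ValueError("labeled_fraction must be in (0, 1]")

    @property
    def saturation_density(self) -> float:
        return (
            self.counted_density
            * self.dilution_factor
            * self.conc_cy3
            / (self.labeled_fraction * self.conc_a488)
        )


@dataclass(frozen=True)
class BeadCalibration:
    """Antibody-binding-capacity bead standards for absolute receptor counts."""

    points: tuple[tuple[float, float], ...]  # (MFI, antibody binding capacity)
    background_mfi: float = 0.0

    def __post_init__(self) -> None:
        pts = tuple((float(m), float(a)) for m, a in self.points)
        if len(pts) < 3:
            raise ValueError("need >= 3 bead calibration points")
        if any(m <= 0 or a <= 0 for m, a in pts):
            raise ValueError("bead MFI and binding capacities must be positive")
        if self.background_mfi < 0:
            raise ValueError("background_mfi must be >= 0")
        object.__setattr__(self, "points", pts)


def flat_field_correct(
    frame: np.ndarray, dye_frame: np.ndarray, camera_offset: float
) -> np.ndarray:
    """Divide out illumination inhomogeneity using a dye-slide reference.

    ``(frame - offset) / (dye_frame - offset)`` elementwise; the camera offset
    (dark image level) is subtracted from both first.
    """
    frame = np.asarray(frame, dtype=float)
    dye = np.asarray(dye_frame, dtype=float)
    if frame.shape != dye.shape:
        raise ValueError(f"frame {frame.shape} and dye frame {dye.shape} shapes differ")
    denom = dye - camera_offset
    bad = denom <= 0
    if np.any(bad):
        raise ValueError(
            f"dye reference has {int(bad.sum())} pixels with non-positive signal "
            "after offset subtraction"
        )
    return (frame - camera_offset) / denom


def segment_masks(
    ricm_frame: np.ndarray,
    threshold: float | None = None,
    ribbon_inner_px: int = 2,
    ribbon_outer_px: int = 6,
) -> MaskPair:
    """Threshold an RICM image into a cell-footprint mask plus background ribbon.

    The footprint appears dark in RICM, so pixels below the threshold (Otsu's
    method unless a fixed value is given) form the candidate mask; the largest
    connected component is kept and its holes filled.  The ribbon is the
    dilation by ``ribbon_outer_px`` minus the dilation by ``ribbon_inner_px``,
    i.e. a band of width ``outer - inner`` standing off ``inner`` pixels from
    the footprint.
    """
    img = np.asarray(ricm_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("ricm_frame must be 2-D")
    if not (1 <= ribbon_inner_px < ribbon_outer_px):
        raise ValueError("need 1 <= ribbon_inner_px < ribbon_outer_px")
    if np.ptp(img) == 0:
        raise ValueError("blank RICM frame; cannot segment")
    thr = float(threshold) if threshold is not None else float(threshold_otsu(img))
    raw = img < thr
    if not raw.any():
        raise ValueError("empty mask after thresholding")
    labels = label(raw)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    cell = labels == int(np.argmax(counts))
    cell = ndimage.binary_fill_holes(cell)

    edge = np.zeros_like(cell)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    touches = bool(np.any(cell & edge))

    outer = dilation(cell, disk(ribbon_outer_px))
    inner = dilation(cell, disk(ribbon_inner_px))
    ribbon = outer & ~inner
    if not ribbon.any():
        raise ValueError("ribbon mask is empty (footprint fills the frame?)")
    return MaskPair(cell_mask=cell, ribbon_mask=ribbon, touches_edge=touches)


def measure_occupancy(
    tirf488_frame: np.ndarray,
    masks: MaskPair,
    wholefield_series: np.ndarray,
    frame_index: int,
) -> float:
    """Receptor occupancy (a.u.) from one ligand-channel frame.

    Mean intensity in the cell mask minus mean intensity in the ribbon
    (free-ligand background), divided by the whole-field laser factor of this
    frame.  The whole-field series is normalized internally to its time-course
    mean, so only relative laser fluctuations matter.  Values may be negative
    under noise and are never clamped.
    """
    frame = np.asarray(tirf488_frame, dtype=float)
    if not masks.cell_mask.any() or not masks.ribbon_mask.any():
        raise ValueError("empty cell or ribbon mask")
    series = np.asarray(wholefield_series, dtype=float)
    if not (0 <= frame_index < series.size):
        raise ValueError(f"frame_index {frame_index} out of range for whole-field series")
    factor = series[frame_index] / series.mean()
    enrichment = frame[masks.cell_mask].mean() - frame[masks.ribbon_mask].mean()
    return float(enrichment / factor)


def measure_dag(
    trace: DagTrace, drift_correction: bool = True, current_reset: int | None = None
) -> float:
    """Steady-state DAG level from a reporter trace.

    Mean of the final ``steady_state_window`` frames, minus the PP2 baseline,
    minus the drift estimate.  Drift is the reset-pulse value of the measured
    block (by default the last reset pulse) minus the mean of the final three
    reset-pulse values, i.e. the reference is end-anchored where the drift has
    stabilized.
    """
    v = trace.values
    signal = float(v[-trace.steady_state_window :].mean())
    drift = 0.0
    if drift_correction:
        resets = trace.reset_pulse_indices
        if len(resets) < 3:
            raise ValueError(
                f"drift correction needs >= 3 reset pulses, got {len(resets)}"
            )
        reset_vals = v[list(resets)]
        idx = len(resets) - 1 if current_reset is None else current_reset
        if not (0 <= idx < len(resets)):
            raise ValueError(f"current_reset {current_reset} out of range")
        drift = float(reset_vals[idx] - reset_vals[-3:].mean())
    return signal - trace.pp2_baseline - drift


@dataclass(frozen=True)
class NormalizedDag:
    """Normalized DAG values with the scheme and reference recorded."""

    values: np.ndarray
    scheme: str
    reference: float | None


def normalize_dag(values, scheme: str, context: dict | None = None) -> NormalizedDag:
    """Normalize DAG values relative to saturation, to PP2, or not at all.

    ``context`` supplies the reference: ``{'saturation': v_sat}`` or
    ``{'pp2': v_pp2}``.
    """
    v = np.asarray(values, dtype=float)
    context = context or {}
    if scheme == "none":
        return NormalizedDag(values=v, scheme="none", reference=None)
    if scheme not in ("saturation", "pp2"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    if scheme not in context:
        raise ValueError(f"normalization scheme {scheme!r} requires a {scheme!r} reference value")
    ref = float(context[scheme])
    if not ref > 0:
        raise ValueError("normalization reference must be positive")
    return NormalizedDag(values=v / ref, scheme=scheme, reference=ref)


def estimate_lov2_density(cal: DensityCalibration, fraction_of_saturation: float) -> float:
    """Absolute ligand density (molecules/um^2) at a working concentration.

    The single-molecule-counted density of the trace label, scaled by the
    dilution factor, stock concentration ratio and labeling efficiency, gives
    the density at bilayer saturation; multiplying by the measured fraction of
    saturation gives the working density.
    """
    if not (0 < fraction_of_saturation <= 1):
        raise ValueError("fraction_of_saturation must be in (0, 1]")
    return cal.saturation_density * fraction_of_saturation


def count_surface_receptors(
    cal: BeadCalibration, cell_mfi: float, no_primary_mfi: float = 0.0
) -> tuple[float, float]:
    """Absolute surface receptor count range from bead-calibrated flow MFI.

    Fits ``log(ABC) ~ log(MFI)`` by ordinary least squares over the bead
    standards (background MFI subtracted), converts the cell MFI to bound
    primary antibodies, subtracts non-specific binding predicted at the
    no-primary control MFI, and reports a ``(count, 2*count)`` range because a
    bivalent IgG primary can engage one or two receptors.
    """
    if cell_mfi <= no_primary_mfi:
        raise ValueError(
            f"cell MFI {cell_mfi} does not exceed the no-primary control {no_primary_mfi}; "
            "no specific signal"
        )
    mfi = np.array([p[0] for p in cal.points]) - cal.background_mfi
    abc = np.array([p[1] for p in cal.points])
    if np.any(mfi <= 0):
        raise ValueError("bead MFI must exceed background MFI")
    slope, intercept = np.polyfit(np.log(mfi), np.log(abc), 1)

    def predict(m: float) -> float:
        return float(np.exp(intercept + slope * np.log(m)))

    total = predict(cell_mfi - cal.background_mfi)
    nonspecific = (
        predict(no_primary_mfi - cal.background_mfi)
        if no_primary_mfi > cal.background_mfi
        else 0.0
    )
    low = max(total - nonspecific, 0.0)
    return low, 2.0 * low


def quantify_timecourse(tc, ribbon_inner_px: int = 2, ribbon_outer_px: int = 6):
    """Run the full measurement chain on an image time course.

    Flat-field corrects all channels, segments the footprint from the first
    RICM frame, tracks laser power via the integrated whole-field TIRF488
    signal, and returns ``(occupancy_series, dag_trace)`` where
    ``occupancy_series`` is one occupancy value per frame and ``dag_trace`` is
    a :class:`DagTrace` of per-frame mean reporter intensities (PP2 baseline
    and reset metadata left for the caller).
    """
    corrected = {
        name: np.stack(
            [flat_field_correct(f, tc.dye_reference[name], tc.camera_offset) for f in stack]
        )
        for name, stack in tc.channels.items()
    }
    masks = segment_masks(
        corrected["RICM"][0], ribbon_inner_px=ribbon_inner_px, ribbon_outer_px=ribbon_outer_px
    )
    t488 = corrected["TIRF488"]
    wholefield = t488.sum(axis=(1, 2))
    occupancy = np.array(
        [measure_occupancy(t488[i], masks, wholefield, i) for i in range(t488.shape[0])]
    )
    dag_means = np.array([f[masks.cell_mask].mean() for f in corrected["TIRF561"]])
    window = min(6, dag_means.size)
    dag_trace = DagTrace(values=dag_means, steady_state_window=window)
    return occupancy, dag_trace
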