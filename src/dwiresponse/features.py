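"""ROI feature extraction and per-patient feature tables.

Turns parametric maps, tumor masks and contrast-enhanced MRI
measurements into the tidy per-patient, per-timepoint feature table the
group statistics and response model operate on. Features per lesion and
timepoint: the mean of each of the seven diffusion parameters over the
tumor ROI, the longest lesion diameter (mm, measured in-plane by
radiological convention), and the relative enhancement ratio (RER, %).
Longitudinal "delta" features are follow-up minus baseline in the
feature's native units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .exceptions import GridError, IntegrityError, InvalidSignalError
from . import signal_models

TIMEPOINTS = ("pre", "mid", "post")

#: units carried with every feature in tabular output
FEATURE_UNITS: dict[str, str] = {
    "adc_0_1000": "1e-3 mm^2/s",
    "adc_200_1000": "1e-3 mm^2/s",
    "adc_all": "1e-3 mm^2/s",
    "d_star": "1e-3 mm^2/s",
    "f": "",
    "ddc": "1e-3 mm^2/s",
    "alpha": "",
    "size": "mm",
    "rer": "%",
}


@dataclass(frozen=True)
class TumorROI:
    """A tumor mask on the acquisition grid with physical voxel spacing."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (2.6, 2.6, 3.0)
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 3:
            raise GridError("ROI mask must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise GridError("voxel spacing must be positive")


@dataclass(frozen=True)
class LesionFeatures:
    """Per-timepoint lesion measurements: seven DWI map means over the
    ROI plus CE-MRI size (mm) and relative enhancement ratio (%)."""

    dwi: Mapping[str, float]
    size: float | None = None
    rer: float | None = None

    def get(self, name: str) -> float | None:
        if name == "size":
            return self.size
        if name == "rer":
            return self.rer
        return self.dwi.get(name)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: per-timepoint features, biomarkers, pCR label."""

    id: str
    features: Mapping[str, LesionFeatures]
    er: bool
    pr: bool
    her2: bool
    ki67_high: bool
    pcr: bool

    def __post_init__(self) -> None:
        if "pre" not in self.features:
            raise IntegrityError(f"patient {self.id}: pre-treatment features required")
        unknown = set(self.features) - set(TIMEPOINTS)
        if unknown:
            raise IntegrityError(f"patient {self.id}: unknown timepoints {unknown}")


@dataclass(frozen=True)
class DeltaFeature:
    """A longitudinal change: follow-up minus baseline, native units."""

    feature: str
    timepoint: str  # "mid" | "post"
    value: float


# ---------------------------------------------------------------------------
# operations


def roi_mean(
    param_map: np.ndarray,
    roi: TumorROI,
    valid: np.ndarray | None = None,
) -> float:
    """Mean of a parameter map over the in-mask voxels with valid fits.

    All in-mask voxels are pooled (volume weighted); voxels with failed
    fits (``valid`` False, or NaN in the map) are excluded, and the
    exclusion is warned about. Returns NaN for an empty ROI.
    """
    param_map = np.asarray(param_map, dtype=float)
    if param_map.shape != roi.mask.shape:
        raise GridError("map and ROI mask do not share a grid")
    sel = roi.mask.copy()
    if valid is not None:
        sel &= np.asarray(valid).astype(bool)
    vals = param_map[sel]
    n_excluded = int(np.isnan(vals).sum()) + int(roi.mask.sum() - sel.sum())
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        warnings.warn("ROI contains no valid voxels; mean is absent", stacklevel=2)
        return float("nan")
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} voxels without valid fits from ROI mean",
            stacklevel=2,
        )
    return float(vals.mean())


def longest_diameter(roi: TumorROI, mode: str = "inplane") -> float:
    """Longest lesion diameter in mm between in-mask voxel centers.

    ``mode='inplane'`` (default, radiological convention) measures the
    maximum pairwise distance within each axial section and takes the
    maximum across sections; ``mode='3d'`` uses full 3D distances.
    A single-voxel lesion has diameter 0 under the center-distance
    convention; an empty mask yields NaN.
    """
    if not roi.mask.any():
        warnings.warn("empty ROI has no diameter", stacklevel=2)
        return float("nan")
    spacing = np.asarray(roi.spacing, dtype=float)
    coords = np.column_stack(np.nonzero(roi.mask)).astype(float) * spacing
    if mode == "3d":
        return _max_pairwise(coords)
    if mode != "inplane":
        raise ValueError(f"unknown diameter mode {mode!r}")
    best = 0.0
    for z in np.unique(coords[:, 2]):
        plane = coords[coords[:, 2] == z, :2]
        best = max(best, _max_pairwise(plane))
    return best


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def rer(si_pre: float, si_post: float) -> float:
    """Relative enhancement ratio, ((SI_post - SI_pre) / SI_pre) x 100."""
    if si_pre <= 0:
        raise InvalidSignalError("pre-contrast signal intensity must be positive")
    return float((si_post - si_pre) / si_pre * 100.0)


def delta(
    baseline: float,
    followup: float,
    feature: str = "",
    timepoint: str = "mid",
) -> DeltaFeature:
    """Longitudinal change, follow-up minus baseline (native units)."""
    return DeltaFeature(
        feature=feature, timepoint=timepoint, value=float(followup) - float(baseline)
    )


def extract_lesion_features(
    maps: "signal_models.ParametricMaps",
    roi: TumorROI,
    si_pre: float | None = None,
    si_post: float | None = None,
    diameter_mode: str = "inplane",
) -> LesionFeatures:
    """Assemble a LesionFeatures record from fitted maps and CE inputs."""
    dwi = {
        name: roi_mean(maps[name], roi, valid=maps.converged)
        for name in signal_models.MAP_NAMES
    }
    size = longest_diameter(roi, mode=diameter_mode) if roi.mask.any() else None
    enhancement = rer(si_pre, si_post) if si_pre is not None and si_post is not None else None
    return LesionFeatures(dwi=dwi, size=size, rer=enhancement)


# ---------------------------------------------------------------------------
# cohort tables


def assemble_features(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tidy long-format feature table for a cohort.

    One row per patient x timepoint x feature for every observed value,
    plus ``delta_<feature>`` rows at mid/post for patients with the
    corresponding follow-up. Columns: patient_id, timepoint, feature,
    value, units.
    """
    records = list(records)
    seen: set[str] = set()
    rows: list[tuple] = []
    for rec in records:
        if rec.id in seen:
            raise IntegrityError(f"duplicate patient id {rec.id!r}")
        seen.add(rec.id)
        base = rec.features["pre"]
        for tp in TIMEPOINTS:
            lesion = rec.features.get(tp)
            if lesion is None:
                continue
            for name, units in FEATURE_UNITS.items():
                val = lesion.get(name)
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    continue
                rows.append((rec.id, tp, name, float(val), units))
                if tp != "pre":
                    bval = base.get(name)
                    if bval is not None and not np.isnan(bval):
                        d = delta(bval, val, feature=name, timepoint=tp)
                        rows.append(
                            (rec.id, tp, f"delta_{name}", d.value, units)
                        )
    return pd.DataFrame(
        rows, columns=["patient_id", "timepoint", "feature", "value", "units"]
    )


def covariates_table(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Clinical-pathologic covariate table (one row per patient)."""
    rows = [
        (
            rec.id,
            int(rec.er),
            int(rec.pr),
            int(rec.her2),
            int(rec.ki67_high),
            int(rec.pcr),
        )
        for rec in records
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "er", "pr", "her2", "ki67_class", "pcr"]
    )


def feature_matrix(
    features: pd.DataFrame,
    timepoint: str,
    names: Sequence[str],
) -> pd.DataFrame:
    """Wide patient x feature matrix for one timepoint."""
    sub = features[
        (features["timepoint"] == timepoint) & (features["feature"].isin(names))
    ]
    dup = sub.duplicated(subset=["patient_id", "feature"])
    if dup.any():
        raise IntegrityError("duplicate patient-timepoint-feature rows")
    return sub.pivot(index="patient_id", columns="feature", values="value")
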