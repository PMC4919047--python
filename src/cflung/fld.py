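"""Fractional lung-water-density (FLD) mapping from two-echo gradient-echo MRI.

A fast gradient-echo sequence alternates between two echo times (default
1.0 and 1.8 ms) while the lung signal decays mono-exponentially with
T2*.  Back-extrapolating each voxel to TE = 0 removes the T2* decay;
dividing by the signal of a 100%-water reference phantom in the field of
view converts the extrapolated signal into the fraction of the voxel
occupied by water, FLD in [0, 1] (0 = air, 1 = pure fluid).  The median
FLD over a region (mFLD) is the summary statistic, reported at FRC and
TLC, together with the FRC-to-TLC ratio (the mFLD ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .regions import RegionMasks

#: relative tolerance above which S(TE2) > S(TE1) is flagged non-decaying
RISING_SIGNAL_TOL = 0.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition parameters (times in ms, geometry explicit).

    Voxel dimensions are never derived from ``fov_cm``/``matrix``; they are
    carried explicitly on each image stack.
    """

    te1_ms: float = 1.0
    te2_ms: float = 1.8
    tr_ms: float = 10.0
    flip_deg: float = 10.0
    slice_thickness_mm: float = 15.0
    fov_cm: float = 40.0
    matrix: Tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not (0 < self.te1_ms < self.te2_ms):
            raise ValueError(
                f"need 0 < te1_ms < te2_ms, got {self.te1_ms}, {self.te2_ms}"
            )
        if self.slice_thickness_mm <= 0 or self.fov_cm <= 0:
            raise ValueError("geometry must be positive")


@dataclass
class MultiEchoStack:
    """Co-registered magnitude images at two echo times plus masks."""

    image_te1: np.ndarray
    image_te2: np.ndarray
    lung_mask: np.ndarray
    phantom_mask: np.ndarray
    voxel_dims_mm: Tuple[float, float, float]
    volume_state: str  # "FRC" or "TLC"
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        shapes = {
            np.shape(a)
            for a in (self.image_te1, self.image_te2, self.lung_mask, self.phantom_mask)
        }
        if len(shapes) != 1:
            raise ValueError(f"arrays must share shape, got {shapes}")
        if np.any(np.asarray(self.image_te1) < 0) or np.any(np.asarray(self.image_te2) < 0):
            raise ValueError("magnitude images must be non-negative")
        if np.any(np.asarray(self.lung_mask, bool) & np.asarray(self.phantom_mask, bool)):
            raise ValueError("lung and phantom masks must be disjoint")
        if self.volume_state not in ("FRC", "TLC"):
            raise ValueError(f"volume_state must be FRC or TLC, got {self.volume_state!r}")


@dataclass
class FldMap:
    """Per-voxel fractional water density with validity flags.

    Voxels whose two-echo fit is unusable (rising signal, zero second
    echo, FLD above ``fld_cap``) are flagged invalid, never zeroed.
    """

    fld: np.ndarray
    valid_mask: np.ndarray
    volume_state: str
    voxel_dims_mm: Tuple[float, float, float]
    calibration: Dict[str, float]


@dataclass(frozen=True)
class RegionalFldSummary:
    """Median FLD per region at both lung volumes, and their ratio."""

    subject_id: str
    region: str  # "central" or "peripheral"
    mfld_frc: float
    mfld_tlc: float
    mfld_ratio: float
    thoracic_volume_L: Dict[str, float]


def extrapolate_te0(
    s1: np.ndarray,
    s2: np.ndarray,
    te1_ms: float,
    te2_ms: float,
    rising_tol: float = RISING_SIGNAL_TOL,
) -> Tuple[np.ndarray, np.ndarray]:
    """Back-extrapolate a two-echo mono-exponential to TE = 0.

    With S(TE) = S0 * exp(-TE/T2*), two echoes give exactly

        S0 = S1 * (S1/S2)**(TE1 / (TE2 - TE1)).

    Vectorised; returns ``(s0, valid)``.  A voxel is invalid when the
    signal rises between echoes beyond ``rising_tol`` (no physical decay
    constant) or when S2 = 0 with S1 > 0 (infinite decay).  S1 = S2 = 0
    is a valid zero-signal voxel (S0 = 0).
    """
    if not (0 < te1_ms < te2_ms):
        raise ValueError(f"need 0 < te1_ms < te2_ms, got {te1_ms}, {te2_ms}")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    expo = te1_ms / (te2_ms - te1_ms)

    zero = (s1 == 0) & (s2 == 0)
    rising = s2 > s1 * (1.0 + rising_tol)
    dead = (s2 == 0) & (s1 > 0)
    valid = ~(rising | dead)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s2 > 0, s1 / np.where(s2 > 0, s2, 1.0), 1.0)
        s0 = np.where(valid & ~zero, s1 * ratio ** expo, 0.0)
    s0 = np.where(zero, 0.0, s0)
    s0 = np.where(~valid, np.nan, s0)
    return s0, valid


class FldQuantifier(BaseEstimator, TransformerMixin):
    """Two-echo stack -> calibrated FLD map transformer.

    Parameters
    ----------
    calibration_mode : {"te0", "mean_signal"}
        ``"te0"`` (default) extrapolates the phantom itself to TE = 0,
        so the correction factor is exactly 1.  ``"mean_signal"``
        references the raw mean phantom signal at the first echo and
        requires a user-supplied empirical ``correction_factor`` (the
        scheme used with a long-T2* phantom whose decay between echoes
        is negligible).
    correction_factor : float
        Multiplies the phantom reference; must be 1 in ``"te0"`` mode.
    fld_cap : float
        FLD values above this are flagged invalid (QC for noise
        outliers), not clipped.

    Attributes
    ----------
    phantom_reference_ : float
        Signal corresponding to 100% water, learned in :meth:`fit`.
    """

    def __init__(
        self,
        calibration_mode: str = "te0",
        correction_factor: float = 1.0,
        fld_cap: float = 1.2,
    ) -> None:
        self.calibration_mode = calibration_mode
        self.correction_factor = correction_factor
        self.fld_cap = fld_cap

    def fit(self, stack: MultiEchoStack, y=None) -> "FldQuantifier":
        """Learn the 100%-water reference signal from the phantom voxels."""
        if self.calibration_mode not in ("te0", "mean_signal"):
            raise ValueError(f"unknown calibration_mode {self.calibration_mode!r}")
        pm = np.asarray(stack.phantom_mask, bool)
        if not pm.any():
            raise ValueError("empty phantom mask")
        if self.calibration_mode == "te0":
            s0, valid = extrapolate_te0(
                np.asarray(stack.image_te1)[pm],
                np.asarray(stack.image_te2)[pm],
                stack.acq.te1_ms,
                stack.acq.te2_ms,
            )
            if not valid.any():
                raise ValueError("no valid phantom voxel for TE0 extrapolation")
            ref = float(np.mean(s0[valid]))
        else:
            ref = float(np.mean(np.asarray(stack.image_te1)[pm]))
        ref *= self.correction_factor
        if ref <= 0:
            raise ValueError(f"phantom reference must be positive, got {ref}")
        self.phantom_reference_ = ref
        return self

    def transform(self, stack: MultiEchoStack) -> FldMap:
        """Map a stack to per-voxel FLD using the fitted phantom reference."""
        if not hasattr(self, "phantom_reference_"):
            raise RuntimeError("FldQuantifier must be fit before transform")
        img1 = np.asarray(stack.image_te1, dtype=float)
        img2 = np.asarray(stack.image_te2, dtype=float)
        s0, valid = extrapolate_te0(img1, img2, stack.acq.te1_ms, stack.acq.te2_ms)
        fld = s0 / self.phantom_reference_
        over_cap = valid & (fld > self.fld_cap)
        valid = valid & ~over_cap
        return FldMap(
            fld=fld,
            valid_mask=valid,
            volume_state=stack.volume_state,
            voxel_dims_mm=stack.voxel_dims_mm,
            calibration={
                "phantom_s0": self.phantom_reference_ / self.correction_factor,
                "correction_factor": self.correction_factor,
            },
        )


def compute_fld_map(
    stack: MultiEchoStack,
    correction_factor: float = 1.0,
    calibration_mode: str = "te0",
    fld_cap: float = 1.2,
) -> FldMap:
    """Calibrated FLD map of a stack (self-calibrating convenience wrapper)."""
    q = FldQuantifier(
        calibration_mode=calibration_mode,
        correction_factor=correction_factor,
        fld_cap=fld_cap,
    )
    return q.fit(stack).transform(stack)


def _region_median(fld_map: FldMap, mask: np.ndarray, region: str) -> float:
    sel = np.asarray(mask, bool) & np.asarray(fld_map.valid_mask, bool)
    if not sel.any():
        raise ValueError(f"region {region!r} has zero valid voxels")
    return float(np.median(np.asarray(fld_map.fld)[sel]))


def summarize_region_fld(
    fld_frc: FldMap,
    fld_tlc: FldMap,
    regions_frc: RegionMasks,
    regions_tlc: Optional[RegionMasks] = None,
    subject_id: str = "",
) -> Dict[str, RegionalFldSummary]:
    """mFLD at FRC and TLC, and the mFLD ratio, per region.

    ``regions_tlc`` defaults to ``regions_frc`` (shared geometry).  The
    lungs deform between volumes, so separate masks per acquisition are
    the normal case.  Thoracic volumes come from the lung masks.
    """
    if fld_frc.volume_state != "FRC" or fld_tlc.volume_state != "TLC":
        raise ValueError("maps must be labelled FRC and TLC respectively")
    if regions_tlc is None:
        regions_tlc = regions_frc
    if np.shape(fld_frc.fld) != np.shape(regions_frc.lung_mask):
        raise ValueError("FRC map and region masks must share geometry")
    if np.shape(fld_tlc.fld) != np.shape(regions_tlc.lung_mask):
        raise ValueError("TLC map and region masks must share geometry")

    from .regions import region_volume

    vol = {
        "FRC": region_volume(regions_frc.lung_mask, fld_frc.voxel_dims_mm),
        "TLC": region_volume(regions_tlc.lung_mask, fld_tlc.voxel_dims_mm),
    }
    out: Dict[str, RegionalFldSummary] = {}
    for region in ("central", "peripheral"):
        m_frc = _region_median(fld_frc, getattr(regions_frc, f"{region}_mask"), region)
        m_tlc = _region_median(fld_tlc, getattr(regions_tlc, f"{region}_mask"), region)
        out[region] = RegionalFldSummary(
            subject_id=subject_id,
            region=region,
            mfld_frc=m_frc,
            mfld_tlc=m_tlc,
            mfld_ratio=m_frc / m_tlc,
            thoracic_volume_L=vol,
        )
    return out
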