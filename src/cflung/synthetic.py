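"""Synthetic data with known ground truth for every pipeline stage.

Three generators live here:

* a compartmental tidal nitrogen-washout simulator (:func:`simulate_washout`)
  whose per-breath dilution is exact and closed-form, so FRC/LCI/Scond*
  recovery can be tested against analytic truth;
* a two-echo gradient-echo MR signal generator (:func:`simulate_mge_stack`)
  that inverts the quantification model voxel-by-voxel; and
* a cohort generator (:func:`generate_cohort`) producing subject tables
  with configurable group effects and cross-metric coupling.

Washout model
-------------
The lung is a set of parallel alveolar compartments, compartment *i*
holding a share ``frc_fraction[i]`` of the total FRC and receiving a
share ``ventilation_fraction[i]`` of each breath's alveolar tidal volume
``VT - VD``.  Breathing pure O2, the compartment N2 fraction follows the
discrete dilution

    C[i, n] = C[i, n-1] * FRC_i / (FRC_i + v_i * (VT - VD))

Expired gas consists of the dead-space gas (the previous inspirate,
N2-free) over the first ``VD`` litres, then a ventilation-weighted
alveolar mixture whose composition drifts linearly across the expiration
according to each compartment's ``intra_breath_slope_coeff``.  Slope
coefficients are centred so the flow-composition weights sum to one at
every point of the expiration; this keeps the model mass-conserving and
makes a homogeneous (single-compartment) lung produce exactly flat
alveolar plateaus.  Unequal specific ventilation plus slope coefficients
aligned with the slow compartments produce normalised phase-III slopes
(Sn) that rise with lung turnover — the signature that Scond* measures.
Re-inspired dead-space gas is not returned to the alveoli, which keeps
the dilution update above exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fld import AcquisitionParams, MultiEchoStack
from .mbw import WashoutTrace

__all__ = [
    "LungModelParams",
    "FldTruth",
    "CohortEffects",
    "simulate_washout",
    "simulate_mge_stack",
    "generate_cohort",
    "make_lung_fld_truth",
    "default_cohort_effects",
]


# --------------------------------------------------------------------------
# washout


@dataclass(frozen=True)
class Compartment:
    """One parallel lung unit of the washout model."""

    frc_fraction: float
    ventilation_fraction: float
    intra_breath_slope_coeff: float = 0.0


@dataclass(frozen=True)
class LungModelParams:
    """Parameters of the compartmental washout model.

    Units: volumes in L, ``resp_rate`` in breaths/min, ``sample_rate``
    in Hz, concentrations as fractions.  ``c0_n2`` defaults to the
    resident alveolar N2 fraction when breathing air.
    """

    frc_total: float = 3.0
    compartments: Tuple[Compartment, ...] = (Compartment(1.0, 1.0, 0.0),)
    dead_space: float = 0.15
    tidal_volume: float = 1.0
    resp_rate: float = 12.0
    c0_n2: float = 0.78
    conc_noise_sd: float = 0.0
    flow_noise_sd: float = 0.0
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frc_total <= 0:
            raise ValueError("frc_total must be positive")
        if len(self.compartments) == 0:
            raise ValueError("invalid model: zero compartments")
        ff = sum(c.frc_fraction for c in self.compartments)
        vf = sum(c.ventilation_fraction for c in self.compartments)
        if abs(ff - 1.0) > 1e-9 or abs(vf - 1.0) > 1e-9:
            raise ValueError("frc_fraction and ventilation_fraction must each sum to 1")
        if self.dead_space < 0:
            raise ValueError("dead_space must be >= 0")
        if self.tidal_volume <= self.dead_space:
            raise ValueError("no alveolar ventilation (tidal_volume <= dead_space)")
        if not 0 < self.c0_n2 <= 1:
            raise ValueError("c0_n2 must be in (0, 1]")

    @staticmethod
    def two_compartment(
        frc_total: float = 3.0,
        slow_frc_fraction: float = 0.5,
        fast_vent_fraction: float = 0.7,
        slope_contrast: float = 1.4,
        **kwargs,
    ) -> "LungModelParams":
        """Two parallel units with unequal specific ventilation.

        The slow unit (low specific ventilation) carries the positive
        intra-breath slope coefficient, so it empties late in each
        expiration — the mechanism that makes Sn rise with turnover.
        """
        vf = fast_vent_fraction
        comps = (
            Compartment(1.0 - slow_frc_fraction, vf, 0.0),
            Compartment(slow_frc_fraction, 1.0 - vf, slope_contrast),
        )
        return LungModelParams(frc_total=frc_total, compartments=comps, **kwargs)


def _centred_slopes(params: LungModelParams) -> np.ndarray:
    """Slope coefficients centred so flow-composition weights sum to 1."""
    v = np.array([c.ventilation_fraction for c in params.compartments])
    s = np.array([c.intra_breath_slope_coeff for c in params.compartments])
    s = s - float(np.dot(v, s))
    if np.any(np.abs(s) > 2.0 + 1e-12):
        raise ValueError(
            "centred intra-breath slope coefficients must lie in [-2, 2] "
            "to keep flow-composition weights non-negative"
        )
    return s


def washout_concentration_series(
    params: LungModelParams, n_breaths_max: int = 60
) -> Dict[str, np.ndarray]:
    """Closed-form per-breath state of the noiseless washout model.

    Returns per-breath compartment concentrations (post-dilution), the
    ventilation-weighted mean alveolar expirate, the end-tidal value
    (end of expiration, including intra-breath drift), the mean expired
    concentration over the whole expiration (dead space included) and
    the alveolar phase-III slope in 1/L.  This is the analytic oracle
    the trace analyser is tested against.
    """
    frc = params.frc_total * np.array([c.frc_fraction for c in params.compartments])
    v = np.array([c.ventilation_fraction for c in params.compartments])
    s = _centred_slopes(params)
    vt_alv = params.tidal_volume - params.dead_space

    dilution = frc / (frc + v * vt_alv)
    conc = np.full(len(frc), params.c0_n2)
    rows = []
    for n in range(1, n_breaths_max + 1):
        conc = conc * dilution
        mean_alv = float(np.dot(v, conc))
        # C(x) = sum_i v_i (1 + s_i (x - 1/2)) C_i over alveolar fraction x
        drift = float(np.dot(v * s, conc))
        end_tidal = mean_alv + 0.5 * drift
        mean_exp = mean_alv * vt_alv / params.tidal_volume
        s3 = drift / vt_alv  # d C / d v_alv, 1/L
        rows.append((n, conc.copy(), mean_alv, drift, end_tidal, mean_exp, s3))
        # run until the mean expirate falls to 2% AND the end-tidal LCI
        # threshold (1/40 of the start) has held for two consecutive
        # breaths, so the index is computable from every simulated trace
        # (operators likewise wash out beyond the nominal criterion)
        et_below = [r[4] < params.c0_n2 / 40.0 for r in rows[-2:]]
        if mean_exp < 0.02 and len(et_below) == 2 and all(et_below):
            break
    return {
        "breath": np.array([r[0] for r in rows]),
        "compartment_conc": np.stack([r[1] for r in rows]),
        "mean_alveolar": np.array([r[2] for r in rows]),
        "drift": np.array([r[3] for r in rows]),
        "end_tidal": np.array([r[4] for r in rows]),
        "mean_expired": np.array([r[5] for r in rows]),
        "s3": np.array([r[6] for r in rows]),
    }


def simulate_washout(params: LungModelParams, n_breaths_max: int = 60) -> WashoutTrace:
    """Simulate a tidal N2 washout trace (flow + N2 fraction at the mouth).

    Square-wave flow (equal inspiratory/expiratory duration) with
    amplitude adjusted so trapezoidal integration of the sampled flow
    reproduces the tidal volume exactly; phase boundaries carry explicit
    zero-flow samples.  The washout stops at the first breath whose mean
    expired N2 falls below 2%, or at ``n_breaths_max``.  Expiration is
    positive flow.  Deterministic for a fixed seed.
    """
    state = washout_concentration_series(params, n_breaths_max)
    n_breaths = len(state["breath"])
    rng = np.random.default_rng(params.seed)

    fs = params.sample_rate
    dt = 1.0 / fs
    t_phase = 60.0 / params.resp_rate / 2.0
    n_phase = max(int(round(t_phase * fs)), 4)
    # boundary samples are zero-flow; amplitude fixes the trapezoid integral
    amp = params.tidal_volume / ((n_phase - 1) * dt)
    vt_alv = params.tidal_volume - params.dead_space
    v = np.array([c.ventilation_fraction for c in params.compartments])
    s = _centred_slopes(params)

    times: List[np.ndarray] = []
    flows: List[np.ndarray] = []
    n2s: List[np.ndarray] = []
    t0 = 0.0
    for b in range(n_breaths):
        conc = state["compartment_conc"][b]
        # inspiration: pure O2 at the mouth; the zero-flow boundary sample
        # still carries the previous breath's end-expiratory gas
        t_in = t0 + dt * np.arange(n_phase)
        f_in = np.full(n_phase, -amp)
        f_in[0] = 0.0
        n2_in = np.zeros(n_phase)
        if b > 0:
            n2_in[0] = state["end_tidal"][b - 1]
        # expiration
        t_ex = t0 + t_phase + dt * np.arange(n_phase)
        f_ex = np.full(n_phase, amp)
        f_ex[0] = 0.0
        # cumulative expired volume at each sample (trapezoid of sampled flow)
        cumvol = np.concatenate(([0.0], np.cumsum((f_ex[1:] + f_ex[:-1]) / 2 * dt)))
        n2_ex = np.zeros(n_phase)
        alv = cumvol >= params.dead_space if params.dead_space == 0 else cumvol > params.dead_space
        x = (cumvol[alv] - params.dead_space) / vt_alv  # alveolar fraction in [0,1]
        n2_ex[alv] = np.dot(v, conc) + np.dot(v * s, conc) * (x - 0.5)
        times.append(np.concatenate([t_in, t_ex]))
        flows.append(np.concatenate([f_in, f_ex]))
        n2s.append(np.concatenate([n2_in, n2_ex]))
        t0 += 2 * t_phase

    time = np.concatenate(times)
    flow = np.concatenate(flows)
    n2 = np.concatenate(n2s)
    if params.flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, params.flow_noise_sd, flow.shape)
    if params.conc_noise_sd > 0:
        n2 = np.clip(n2 + rng.normal(0.0, params.conc_noise_sd, n2.shape), 0.0, 1.0)
    return WashoutTrace(
        time_s=time,
        flow_L_per_s=flow,
        n2_frac=n2,
        sample_rate_hz=fs,
        meta={"model": "compartmental", "n_breaths": n_breaths, "seed": params.seed},
    )


# --------------------------------------------------------------------------
# MRI


@dataclass
class FldTruth:
    """Ground-truth water-fraction image for the MR generator.

    ``fld`` in [0, 1]; phantom voxels must be exactly 1 (pure water).
    ``t2star_ms`` applies to non-phantom voxels; the phantom has its own
    (long) decay constant.  ``noise_sd`` is the additive Gaussian SD on
    each magnitude image, in signal units.
    """

    fld: np.ndarray
    t2star_ms: np.ndarray
    gain: float
    phantom_region: np.ndarray
    phantom_t2star_ms: float = 50.0
    noise_sd: float = 0.0
    lung_region: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.fld = np.asarray(self.fld, dtype=float)
        self.t2star_ms = np.asarray(self.t2star_ms, dtype=float)
        self.phantom_region = np.asarray(self.phantom_region, dtype=bool)
        if self.fld.shape != self.t2star_ms.shape or self.fld.shape != self.phantom_region.shape:
            raise ValueError("fld, t2star_ms and phantom_region must share shape")
        if np.any(self.fld < 0) or np.any(self.fld > 1):
            raise ValueError("fld must lie in [0, 1]")
        if np.any(self.t2star_ms <= 0) or self.phantom_t2star_ms <= 0:
            raise ValueError("T2* must be positive")
        if not np.allclose(self.fld[self.phantom_region], 1.0):
            raise ValueError("phantom voxels must have fld = 1")
        if self.lung_region is None:
            self.lung_region = (self.fld > 0) & ~self.phantom_region
        else:
            self.lung_region = np.asarray(self.lung_region, dtype=bool)


def simulate_mge_stack(
    truth: FldTruth,
    acq: Optional[AcquisitionParams] = None,
    voxel_dims_mm: Tuple[float, float, float] = (6.25, 6.25, 15.0),
    volume_state: str = "FRC",
) -> MultiEchoStack:
    """Forward-model a two-echo magnitude stack from a truth image.

    Per voxel, ``S(TE) = fld * gain * exp(-TE / T2*)`` plus additive
    Gaussian noise (clipped at zero: magnitude images are non-negative).
    Phantom voxels use the phantom decay constant.
    """
    acq = acq or AcquisitionParams()
    t2 = np.where(truth.phantom_region, truth.phantom_t2star_ms, truth.t2star_ms)
    rng = np.random.default_rng(truth.seed)
    images = []
    for te in (acq.te1_ms, acq.te2_ms):
        sig = truth.fld * truth.gain * np.exp(-te / t2)
        if truth.noise_sd > 0:
            sig = sig + rng.normal(0.0, truth.noise_sd, sig.shape)
        images.append(np.clip(sig, 0.0, None))
    return MultiEchoStack(
        image_te1=images[0],
        image_te2=images[1],
        lung_mask=truth.lung_region,
        phantom_mask=truth.phantom_region,
        voxel_dims_mm=voxel_dims_mm,
        volume_state=volume_state,
        acq=acq,
    )


def make_lung_fld_truth(
    shape: Tuple[int, int] = (64, 64),
    mean_fld: float = 0.20,
    fld_gradient: float = 0.10,
    gain: float = 1000.0,
    t2star_ms: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FldTruth:
    """Elliptical synthetic lung with a gravity-like FLD gradient plus a
    rectangular 100%-water phantom strip along the anterior edge.

    Purely a convenience for tests and demonstrations; not a model of
    real anatomy.
    """
    rows, cols = np.indices(shape)
    r0, c0 = shape[0] / 2.0, shape[1] / 2.0 - 4
    lung = ((rows - r0) / (shape[0] * 0.38)) ** 2 + (
        (cols - c0) / (shape[1] * 0.30)
    ) ** 2 <= 1.0
    phantom = np.zeros(shape, dtype=bool)
    phantom[2:6, shape[1] - 8 : shape[1] - 2] = True
    lung &= ~phantom
    fld = np.zeros(shape)
    grad = (rows - rows[lung].min()) / max(np.ptp(rows[lung]), 1)
    fld[lung] = np.clip(mean_fld + fld_gradient * (grad[lung] - 0.5), 0.02, 0.95)
    fld[phantom] = 1.0
    t2 = np.full(shape, t2star_ms)
    return FldTruth(
        fld=fld,
        t2star_ms=t2,
        gain=gain,
        phantom_region=phantom,
        noise_sd=noise_sd,
        lung_region=lung,
        seed=seed,
    )


# --------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class MetricSpec:
    """Group means and SDs of one subject-level metric."""

    control_mean: float
    cf_mean: float
    control_sd: float
    cf_sd: float
    floor: Optional[float] = None  # physical lower bound, if any


# Defaults emulate a small adult CF-vs-control study: group means/SDs of
# spirometry, washout indices and regional lung-water metrics, with the
# ratio columns computed per subject rather than drawn.
_DEFAULT_METRICS: Dict[str, MetricSpec] = {
    "age_yr": MetricSpec(32.5, 28.3, 8.2, 5.3, floor=18.0),
    "weight_kg": MetricSpec(71.5, 62.7, 10.2, 7.9, floor=35.0),
    "height_cm": MetricSpec(172.1, 169.9, 7.6, 8.5, floor=140.0),
    "fev1_pct": MetricSpec(93.3, 69.6, 6.2, 23.9, floor=15.0),
    "fvc_pct": MetricSpec(94.4, 80.1, 7.2, 18.8, floor=20.0),
    "fef2575_pct": MetricSpec(90.0, 53.5, 18.8, 37.4, floor=5.0),
    "lci": MetricSpec(6.0, 9.9, 0.3, 3.9, floor=3.0),
    "scond_star": MetricSpec(0.03, 0.14, 0.01, 0.06, floor=0.0),
    "sacin_star": MetricSpec(0.11, 0.31, 0.04, 0.28, floor=0.0),
    "central_mfld_frc": MetricSpec(0.23, 0.25, 0.03, 0.03, floor=0.02),
    "central_mfld_tlc": MetricSpec(0.11, 0.18, 0.01, 0.04, floor=0.02),
    "peripheral_mfld_frc": MetricSpec(0.19, 0.17, 0.03, 0.03, floor=0.02),
    "peripheral_mfld_tlc": MetricSpec(0.06, 0.10, 0.01, 0.03, floor=0.02),
    "thoracic_frc_L": MetricSpec(1.43, 2.21, 0.48, 0.68, floor=0.5),
    "thoracic_tlc_L": MetricSpec(4.00, 3.77, 0.63, 0.80, floor=1.5),
}

#: within-group couplings (target, predictor, correlation); applied in order
_DEFAULT_COUPLINGS: Tuple[Tuple[str, str, float], ...] = (
    ("scond_star", "central_mfld_tlc", 0.6),
    ("sacin_star", "peripheral_mfld_tlc", 0.3),
    ("lci", "scond_star", 0.7),
    ("fev1_pct", "lci", -0.7),
)


@dataclass(frozen=True)
class CohortEffects:
    """Configuration of the cohort generator.

    ``metrics`` maps metric name to group means/SDs; ``couplings`` lists
    ``(target, predictor, rho)`` within-group correlations applied in
    order (each target keeps its configured group mean and SD while
    acquiring correlation ``rho`` with the already-generated predictor).
    """

    n_cf: int = 12
    n_control: int = 12
    metrics: Dict[str, MetricSpec] = field(
        default_factory=lambda: dict(_DEFAULT_METRICS)
    )
    couplings: Tuple[Tuple[str, str, float], ...] = _DEFAULT_COUPLINGS
    p_female: Tuple[float, float] = (0.5, 8 / 12)  # (control, CF)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cf < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        for name, m in self.metrics.items():
            if m.control_sd < 0 or m.cf_sd < 0:
                raise ValueError(f"negative SD for metric {name!r}")
        for target, predictor, rho in self.couplings:
            if not -1 < rho < 1:
                raise ValueError(f"coupling rho must be in (-1, 1), got {rho}")
            if target not in self.metrics or predictor not in self.metrics:
                raise ValueError(f"unknown metric in coupling {(target, predictor)}")

    def null(self) -> "CohortEffects":
        """Same cohort with all group effects and couplings removed."""
        metrics = {
            k: replace(m, cf_mean=m.control_mean, cf_sd=m.control_sd)
            for k, m in self.metrics.items()
        }
        return replace(self, metrics=metrics, couplings=())


def default_cohort_effects(seed: int = 0, **kwargs) -> CohortEffects:
    return CohortEffects(seed=seed, **kwargs)


def generate_cohort(effects: CohortEffects) -> pd.DataFrame:
    """Draw one subject table from the configured linear-Gaussian model.

    Returns one row per subject with group label, demographics, MBW
    indices and regional mFLD metrics; mFLD ratios and BMI are computed
    per subject.  Byte-identical CSV output for a fixed seed.
    """
    rng = np.random.default_rng(effects.seed)
    n = effects.n_control + effects.n_cf
    group = np.array(["control"] * effects.n_control + ["CF"] * effects.n_cf)
    is_cf = group == "CF"

    cols: Dict[str, np.ndarray] = {}
    for name, m in effects.metrics.items():
        mean = np.where(is_cf, m.cf_mean, m.control_mean)
        sd = np.where(is_cf, m.cf_sd, m.control_sd)
        cols[name] = mean + sd * rng.standard_normal(n)

    # couplings: re-express target as mean + rho-scaled predictor deviation
    for target, predictor, rho in effects.couplings:
        mt = effects.metrics[target]
        mp = effects.metrics[predictor]
        t_mean = np.where(is_cf, mt.cf_mean, mt.control_mean)
        t_sd = np.where(is_cf, mt.cf_sd, mt.control_sd)
        p_mean = np.where(is_cf, mp.cf_mean, mp.control_mean)
        p_sd = np.where(is_cf, mp.cf_sd, mp.control_sd)
        z_pred = np.divide(
            cols[predictor] - p_mean, p_sd, out=np.zeros(n), where=p_sd > 0
        )
        cols[target] = t_mean + t_sd * (
            rho * z_pred + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        )

    for name, m in effects.metrics.items():
        if m.floor is not None:
            cols[name] = np.maximum(cols[name], m.floor)

    p_fem = np.where(is_cf, effects.p_female[1], effects.p_female[0])
    sex = np.where(rng.random(n) < p_fem, "F", "M")

    df = pd.DataFrame(
        {
            "id": [f"S{i+1:03d}" for i in range(n)],
            "group": group,
            "sex": sex,
        }
    )
    for name in effects.metrics:
        df[name] = cols[name]
    df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    df["central_mfld_ratio"] = df["central_mfld_frc"] / df["central_mfld_tlc"]
    df["peripheral_mfld_ratio"] = df["peripheral_mfld_frc"] / df["peripheral_mfld_tlc"]
    return df
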