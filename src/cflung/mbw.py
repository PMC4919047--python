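"""Multiple-breath nitrogen washout analysis.

From a recorded trace of flow and N2 fraction at the mouth, this module
segments breaths, and computes:

* **FRC** by N2 mass balance: net expired N2 volume divided by the drop
  in alveolar N2 concentration;
* **LCI** (lung clearance index): cumulative expired volume in units of
  FRC ("turnover", TO) at the first breath whose end-tidal N2 falls
  below 1/40 of the starting concentration;
* per-breath **phase-III slopes**: the least-squares slope of the
  alveolar plateau of N2 fraction against expired volume, normalised by
  the window-mean concentration (Sn);
* **Scond*** — the rate at which Sn rises with turnover, fitted over
  TO in [1.5, 3.0] — and **Sacin*** — the first breath's Sn minus the
  Scond* contribution.  A replicate is accepted when the Sn-vs-TO
  regression has R^2 > 0.5; indices are averaged over replicates with
  Scond*/Sacin* restricted to accepted ones.

The Sn-vs-TO fit is ordinary least squares throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats
from sklearn.base import BaseEstimator


@dataclass
class WashoutTrace:
    """Flow and N2 fraction sampled at the mouth (expiration positive)."""

    time_s: np.ndarray
    flow_L_per_s: np.ndarray
    n2_frac: np.ndarray
    sample_rate_hz: float
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow_L_per_s = np.asarray(self.flow_L_per_s, dtype=float)
        self.n2_frac = np.asarray(self.n2_frac, dtype=float)
        if not (self.time_s.shape == self.flow_L_per_s.shape == self.n2_frac.shape):
            raise ValueError("time, flow and n2 arrays must share length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("non-monotone time")
        if np.any((self.n2_frac < 0) | (self.n2_frac > 1)):
            raise ValueError("n2_frac out of range [0, 1]")


@dataclass
class BreathTable:
    """Per-breath decomposition of a washout trace.

    ``df`` columns: ``index, v_insp, v_exp, cev, c_mean_exp, c_et`` and,
    after slope analysis, ``s3, sn, flagged`` and after FRC, ``to``.
    ``expirograms[i]`` is ``(expired_volume_L, n2_frac)`` sample pairs of
    breath *i*.
    """

    df: pd.DataFrame
    expirograms: List[Tuple[np.ndarray, np.ndarray]]

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class MbwIndices:
    """Summary indices of one washout replicate (or replicate average)."""

    frc_L: float
    lci: float
    scond_star: float
    sacin_star: float
    fit_r2: float
    n_breaths: int
    accepted: bool


# --------------------------------------------------------------------------
# breath segmentation


def _turning_points(vol: np.ndarray, min_vol_L: float) -> List[int]:
    """Indices of alternating extrema of the cumulative-volume curve,
    keeping only reversals larger than ``min_vol_L`` (hysteresis)."""
    pts: List[int] = []
    direction = 0  # +1 rising (expiration), -1 falling (inspiration)
    cand = cand_max = cand_min = 0
    for k in range(1, len(vol)):
        if direction == 0:
            if vol[k] > vol[cand_max]:
                cand_max = k
            if vol[k] < vol[cand_min]:
                cand_min = k
            if vol[cand_max] - vol[k] > min_vol_L:
                pts.append(cand_max)
                direction, cand = -1, k
            elif vol[k] - vol[cand_min] > min_vol_L:
                pts.append(cand_min)
                direction, cand = 1, k
        elif direction == 1:
            if vol[k] > vol[cand]:
                cand = k
            elif vol[cand] - vol[k] > min_vol_L:
                pts.append(cand)
                direction, cand = -1, k
        else:
            if vol[k] < vol[cand]:
                cand = k
            elif vol[k] - vol[cand] > min_vol_L:
                pts.append(cand)
                direction, cand = 1, k
    if direction != 0 and cand != pts[-1]:
        pts.append(cand)
    return pts


def segment_breaths(trace: WashoutTrace, min_vol_L: float = 0.05) -> BreathTable:
    """Split a trace into breaths at flow reversals.

    Reversals are detected on the cumulative-volume curve (trapezoidal
    integral of flow) with a volume hysteresis of ``min_vol_L``, which
    makes the segmentation robust to flow noise around zero.  A breath
    is an inspiration segment immediately followed by an expiration
    segment.

    Raises
    ------
    ValueError
        If no complete breath is found.
    """
    vol = np.concatenate(
        ([0.0], integrate.cumulative_trapezoid(trace.flow_L_per_s, trace.time_s))
    )
    pts = _turning_points(vol, min_vol_L)

    rows = []
    expirograms: List[Tuple[np.ndarray, np.ndarray]] = []
    cev = 0.0
    for a, b, c in zip(pts, pts[1:], pts[2:]):
        v_ab = vol[b] - vol[a]
        v_bc = vol[c] - vol[b]
        if not (v_ab < 0 < v_bc):  # need inspiration followed by expiration
            continue
        seg = slice(b, c + 1)
        v = vol[seg] - vol[b]
        n2 = trace.n2_frac[seg]
        v_exp = v[-1]
        cev += v_exp
        c_mean = float(np.trapezoid(n2, v) / v_exp)
        tail = v >= 0.95 * v_exp
        c_et = float(np.mean(n2[tail])) if tail.any() else float(n2[-1])
        rows.append(
            {
                "index": len(rows),
                "v_insp": -v_ab,
                "v_exp": v_exp,
                "cev": cev,
                "c_mean_exp": c_mean,
                "c_et": c_et,
            }
        )
        expirograms.append((v, n2))
    if not rows:
        raise ValueError("no complete breath found")
    return BreathTable(df=pd.DataFrame(rows), expirograms=expirograms)


# --------------------------------------------------------------------------
# indices


def compute_frc(
    breaths: BreathTable,
    c_start: float,
    c_end: float,
    c_insp: float = 0.0,
) -> float:
    """FRC from N2 mass balance over the washout.

    ``FRC = sum(v_exp * c_mean_exp - v_insp * c_insp) / (c_start - c_end)``
    with ``c_insp = 0`` for washout with pure O2.
    """
    if c_end < 0 or c_start <= c_end:
        raise ValueError(f"need c_start > c_end >= 0, got {c_start}, {c_end}")
    df = breaths.df
    n2_net = float(np.sum(df["v_exp"] * df["c_mean_exp"] - df["v_insp"] * c_insp))
    return n2_net / (c_start - c_end)


def compute_lci(
    breaths: BreathTable,
    frc_L: float,
    c_start: float,
    interpolate: bool = False,
) -> float:
    """Lung turnovers needed for end-tidal N2 to reach ``c_start / 40``.

    The crossing breath must have the following breath (if any) also
    below threshold, guarding against noise.  With ``interpolate`` the
    turnover is linearly interpolated in end-tidal concentration between
    the crossing breath and its predecessor.
    """
    if frc_L <= 0:
        raise ValueError("frc_L must be positive")
    threshold = c_start / 40.0
    c_et = breaths.df["c_et"].to_numpy()
    cev = breaths.df["cev"].to_numpy()
    if c_et[0] < threshold:
        raise ValueError("already cleared: trace starts below the LCI threshold")
    below = c_et < threshold
    hit: Optional[int] = None
    for i in np.flatnonzero(below):
        if i == len(c_et) - 1 or below[i + 1]:
            hit = int(i)
            break
    if hit is None:
        raise ValueError("LCI threshold never reached within trace")
    if interpolate and hit > 0 and c_et[hit - 1] > threshold:
        f = (c_et[hit - 1] - threshold) / (c_et[hit - 1] - c_et[hit])
        cev_x = cev[hit - 1] + f * (cev[hit] - cev[hit - 1])
        return float(cev_x / frc_L)
    return float(cev[hit] / frc_L)


def phase3_normalized_slopes(
    breaths: BreathTable,
    window: Tuple[float, float] = (0.50, 0.95),
    min_samples: int = 5,
) -> BreathTable:
    """Alveolar-plateau slope (S3) and normalised slope (Sn) per breath.

    S3 is the least-squares slope of N2 fraction vs expired volume over
    the fractional-volume window (default 50-95% of the expired volume);
    Sn divides by the window-mean N2 fraction.  Breaths smaller than
    half the median expired volume are flagged and carry NaN slopes.
    """
    f_lo, f_hi = window
    if not (0 <= f_lo < f_hi <= 1):
        raise ValueError(f"window must satisfy 0 <= lo < hi <= 1, got {window}")
    df = breaths.df.copy()
    med_vexp = float(df["v_exp"].median())
    flagged = (df["v_exp"] < 0.5 * med_vexp).to_numpy()
    s3 = np.full(len(df), np.nan)
    sn = np.full(len(df), np.nan)
    for i, (v, n2) in enumerate(breaths.expirograms):
        if flagged[i]:
            continue
        sel = (v >= f_lo * v[-1]) & (v <= f_hi * v[-1])
        if sel.sum() < min_samples:
            raise ValueError(
                f"breath {i}: fewer than {min_samples} samples in phase-III window"
            )
        slope, _ = np.polyfit(v[sel], n2[sel], 1)
        mean_c = float(np.mean(n2[sel]))
        s3[i] = slope
        sn[i] = slope / mean_c if mean_c > 0 else np.nan
    df["s3"] = s3
    df["sn"] = sn
    df["flagged"] = flagged
    return BreathTable(df=df, expirograms=breaths.expirograms)


@dataclass(frozen=True)
class _ScondFit:
    scond_star: float
    sacin_star: float
    fit_r2: float
    n_window: int
    accepted: bool


def compute_scond_sacin(
    breaths: BreathTable,
    to_window: Tuple[float, float] = (1.5, 3.0),
    r2_min: float = 0.5,
) -> _ScondFit:
    """Conducting- and acinar-zone heterogeneity indices.

    Scond* is the OLS slope of Sn vs turnover over breaths with TO in
    ``to_window``; the fit's R^2 gates acceptance (R^2 > ``r2_min``).
    Sacin* is the first breath's Sn minus Scond* times its turnover.
    A constant Sn series (zero residual variance) is a perfect
    degenerate fit: Scond* = 0 with R^2 = 1.
    """
    df = breaths.df
    for col in ("sn", "to"):
        if col not in df.columns:
            raise ValueError(f"breath table lacks column {col!r}; run the "
                             "slope analysis and FRC computation first")
    usable = ~df["flagged"] & df["sn"].notna()
    win = usable & df["to"].between(*to_window)
    if win.sum() < 3:
        raise ValueError(
            f"need >= 3 usable breaths with turnover in {to_window}, got {int(win.sum())}"
        )
    to = df.loc[win, "to"].to_numpy()
    sn = df.loc[win, "sn"].to_numpy()
    if np.ptp(sn) < 1e-12:  # constant Sn: slope 0, perfect fit
        scond, r2 = 0.0, 1.0
    else:
        res = stats.linregress(to, sn)
        scond, r2 = float(res.slope), float(res.rvalue**2)
    first = int(np.flatnonzero(usable.to_numpy())[0])
    sacin = float(df["sn"].iloc[first] - scond * df["to"].iloc[first])
    return _ScondFit(
        scond_star=scond,
        sacin_star=sacin,
        fit_r2=r2,
        n_window=int(win.sum()),
        accepted=bool(r2 > r2_min),
    )


def average_replicates(replicates: Sequence[MbwIndices]) -> MbwIndices:
    """Average indices over replicates (typically a triplicate).

    FRC and LCI average over all replicates; Scond*/Sacin* (and the fit
    R^2) only over replicates accepted by the R^2 > 0.5 rule.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    accepted = [r for r in replicates if r.accepted]
    if not accepted:
        raise ValueError("zero accepted replicates for Scond*/Sacin* averaging")
    return MbwIndices(
        frc_L=float(np.mean([r.frc_L for r in replicates])),
        lci=float(np.mean([r.lci for r in replicates])),
        scond_star=float(np.mean([r.scond_star for r in accepted])),
        sacin_star=float(np.mean([r.sacin_star for r in accepted])),
        fit_r2=float(np.mean([r.fit_r2 for r in accepted])),
        n_breaths=int(round(np.mean([r.n_breaths for r in replicates]))),
        accepted=True,
    )


class MbwAnalyzer(BaseEstimator):
    """End-to-end washout analyser (trace -> indices).

    Parameters
    ----------
    c_start : float
        Alveolar N2 fraction at the start of the washout (resident
        fraction when breathing air).
    min_vol_L : float
        Hysteresis volume for breath detection.
    s3_window : (float, float)
        Fractional expired-volume window of the phase-III fit.
    to_window : (float, float)
        Turnover window of the Scond* fit.
    r2_min : float
        Acceptance threshold on the Sn-vs-TO fit R^2.
    interpolate_lci : bool
        Interpolate the LCI threshold crossing between breaths.
    """

    def __init__(
        self,
        c_start: float = 0.78,
        min_vol_L: float = 0.05,
        s3_window: Tuple[float, float] = (0.50, 0.95),
        to_window: Tuple[float, float] = (1.5, 3.0),
        r2_min: float = 0.5,
        interpolate_lci: bool = False,
    ) -> None:
        self.c_start = c_start
        self.min_vol_L = min_vol_L
        self.s3_window = s3_window
        self.to_window = to_window
        self.r2_min = r2_min
        self.interpolate_lci = interpolate_lci

    def fit(self, X=None, y=None) -> "MbwAnalyzer":
        """No-op; the analyser has no trainable state."""
        return self

    def analyze(self, trace: WashoutTrace) -> Tuple[MbwIndices, BreathTable]:
        """Run the full analysis and return indices plus the breath table."""
        bt = segment_breaths(trace, min_vol_L=self.min_vol_L)
        bt = phase3_normalized_slopes(bt, window=self.s3_window)
        c_end = float(bt.df["c_et"].iloc[-1])
        frc = compute_frc(bt, c_start=self.c_start, c_end=c_end)
        bt.df["to"] = bt.df["cev"] / frc
        lci = compute_lci(
            bt, frc_L=frc, c_start=self.c_start, interpolate=self.interpolate_lci
        )
        fit = compute_scond_sacin(bt, to_window=self.to_window, r2_min=self.r2_min)
        indices = MbwIndices(
            frc_L=frc,
            lci=lci,
            scond_star=fit.scond_star,
            sacin_star=fit.sacin_star,
            fit_r2=fit.fit_r2,
            n_breaths=len(bt),
            accepted=fit.accepted,
        )
        return indices, bt

    def transform(self, traces):
        """Analyse a sequence of traces; returns a list of MbwIndices."""
        return [self.analyze(t)[0] for t in traces]
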