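"""Assay-level derived quantities.

Four small calculators used downstream of wet-lab measurements:

* qPCR relative expression by the comparative Ct method, 2**(-dCt) with
  dCt = Ct(target) - Ct(reference housekeeping gene);
* proliferation ratios N_t / N_0 against a reference timepoint;
* cell major-axis-length (MAL) box summaries: median, central 50% box,
  central 98% whiskers;
* lactate-transport kinetics from a BCECF intracellular pH trace:
  resting proton concentration, maximum d[H]/dt after lactate onset, the
  resting-to-extremum influx excursion, and the post-minus-pre resting
  shift. pH converts to [H] as 10**(9 - pH) nM.

Quantiles use linear interpolation between closest order statistics;
derivatives are central differences on the sampled [H], with optional
moving-average smoothing (off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative transcript abundance 2**(-(ct_target - ct_reference))."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_target - ct_reference))


def qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``relative_expression`` column to a (sample_id, ct_target,
    ct_reference) table."""
    out = table.copy()
    out["relative_expression"] = [
        relative_expression(t, r) for t, r in zip(out["ct_target"], out["ct_reference"])
    ]
    return out


@dataclass
class ProliferationSeries:
    timepoints_h: list[float]
    counts: list[float]
    ratios: list[float]
    reference_timepoint_h: float


def proliferation_ratios(counts_by_timepoint: dict[float, float],
                         reference_timepoint: float = 3.0) -> ProliferationSeries:
    """Cell-count ratios N_t / N_0, with N_0 the count at the reference
    timepoint (3 h by convention: attached cells before the first division)."""
    if reference_timepoint not in counts_by_timepoint:
        raise ValueError(f"reference timepoint {reference_timepoint} h absent from counts")
    n0 = counts_by_timepoint[reference_timepoint]
    if not (n0 > 0):
        raise ValueError("reference count must be positive")
    times = sorted(counts_by_timepoint)
    counts = [float(counts_by_timepoint[t]) for t in times]
    if any(c < 0 for c in counts):
        raise ValueError("cell counts must be non-negative")
    return ProliferationSeries(
        timepoints_h=[float(t) for t in times],
        counts=counts,
        ratios=[c / n0 for c in counts],
        reference_timepoint_h=float(reference_timepoint),
    )


@dataclass
class MALSummary:
    """Box-plot summary of per-cell major-axis lengths (um)."""

    n: int
    median: float
    box_low: float    # 25th percentile
    box_high: float   # 75th percentile
    whisker_low: float   # 1st percentile
    whisker_high: float  # 99th percentile

    def to_dict(self) -> dict:
        return asdict(self)


def mal_summary(lengths_um) -> MALSummary:
    """Median, central-50% box and central-98% whiskers of MAL values.

    Linear interpolation between closest order statistics; at least 5
    values are required for the whiskers to be meaningful.
    """
    x = np.asarray(lengths_um, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 lengths, got {x.size}")
    if not np.isfinite(x).all() or (x <= 0).any():
        raise ValueError("lengths must be finite and positive")
    qs = np.percentile(x, [1, 25, 50, 75, 99], method="linear")
    return MALSummary(n=int(x.size), median=float(qs[2]),
                      box_low=float(qs[1]), box_high=float(qs[3]),
                      whisker_low=float(qs[0]), whisker_high=float(qs[4]))


# --------------------------------------------------------------------------
# intracellular pH kinetics


def ph_to_proton(ph):
    """pH -> proton concentration in nM: 10**(9 - pH)."""
    ph = np.asarray(ph, dtype=float)
    if not np.isfinite(ph).all():
        raise ValueError("pH values must be finite")
    out = np.power(10.0, 9.0 - ph)
    return float(out) if out.ndim == 0 else out


def proton_to_ph(h_nm):
    """Proton concentration in nM -> pH: 9 - log10([H])."""
    h = np.asarray(h_nm, dtype=float)
    if not np.isfinite(h).all() or (h <= 0).any():
        raise ValueError("[H] must be finite and positive")
    out = 9.0 - np.log10(h)
    return float(out) if out.ndim == 0 else out


@dataclass
class KineticMetrics:
    """Summary of one lactate-perfusion [H] trace (all concentrations nM)."""

    resting_h_pre: float
    max_dh_dt: float          # nM/s, within the lactate window
    delta_h_influx: float     # magnitude of resting-to-extremum excursion
    delta_h_resting: float    # post-lactate minus pre-lactate resting, signed
    extremum_direction: str   # 'rise' (acidification) or 'fall'
    t_on: float
    t_off: float
    resting_window_s: float

    def to_dict(self) -> dict:
        return asdict(self)


def lactate_kinetics(time_s, ph, t_on: float, t_off: float,
                     resting_window_s: float = 30.0,
                     smooth_window: int | None = None) -> KineticMetrics:
    """Kinetic summary of a lactate-perfusion pH trace.

    Converts pH to [H], then reports the mean resting [H] over the
    ``resting_window_s`` seconds before ``t_on``, the maximum
    central-difference d[H]/dt strictly inside (t_on, t_off), the
    magnitude of the excursion from resting to the in-window extremum,
    and the signed difference between the final-window resting [H] and
    the pre-lactate resting [H]. ``smooth_window`` (odd sample count)
    applies a moving average to [H] before differentiation.
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(ph, dtype=float)
    if t.size != p.size or t.size < 5:
        raise ValueError("time and pH arrays must be equal length (>= 5)")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    step = float(dt[0])
    if not (t[0] <= t_on - resting_window_s and t_on < t_off <= t[-1] - resting_window_s):
        raise ValueError("trace too short for the requested windows")

    h = ph_to_proton(p)
    pre = (t >= t_on - resting_window_s) & (t < t_on)
    post = t >= t[-1] - resting_window_s
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("resting windows contain fewer than 2 samples")
    resting_pre = float(h[pre].mean())
    resting_post = float(h[post].mean())

    hs = h
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd sample count")
        kernel = np.ones(smooth_window) / smooth_window
        hs = np.convolve(h, kernel, mode="same")

    dh = np.empty_like(hs)
    dh[1:-1] = (hs[2:] - hs[:-2]) / (2 * step)
    dh[0] = dh[-1] = np.nan
    window = (t > t_on) & (t < t_off)
    inner = window & ~np.isnan(dh)
    if not inner.any():
        raise ValueError("no interior samples inside the lactate window")
    max_dh = float(np.nanmax(dh[inner]))

    excursions = h[window] - resting_pre
    i_ext = int(np.argmax(np.abs(excursions)))
    delta_influx = float(abs(excursions[i_ext]))
    direction = "rise" if excursions[i_ext] >= 0 else "fall"

    return KineticMetrics(
        resting_h_pre=resting_pre,
        max_dh_dt=max_dh,
        delta_h_influx=delta_influx,
        delta_h_resting=resting_post - resting_pre,
        extremum_direction=direction,
        t_on=float(t_on), t_off=float(t_off),
        resting_window_s=float(resting_window_s),
    )
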