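"""Cq calling and PCR-efficiency estimation from raw amplification curves.

The quantification cycle (Cq) is called with a derivative-threshold rule:
take the first difference of the fluorescence series, estimate a baseline
from the derivative over cycles 3-10 (mean and sample SD), and call the
first cycle after the baseline window whose derivative exceeds
``mean + k * SD`` (k = 6 by default).  The fractional Cq is obtained by
linear interpolation of the derivative across the threshold; an
integer-cycle mode is available behind a flag.

PCR efficiency is a QC quantity: the per-cycle amplification gain
``10**slope - 1`` from a log10-linear fit of baseline-subtracted
fluorescence between the Cq and the cycle of maximum derivative.  It never
enters the downstream classifier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CqResult", "derivative", "call_cq", "efficiency", "call_cq_table"]

#: Default baseline window (inclusive cycle range) for the derivative noise.
DEFAULT_BASELINE_WINDOW = (3, 10)
#: Default threshold multiple of the baseline-derivative SD.
DEFAULT_K = 6.0


@dataclass
class CqResult:
    """Outcome of Cq calling on one curve.

    ``cq`` is None for a no-call (the derivative never exceeded the
    threshold after the baseline window).  ``efficiency`` is None until
    computed (or when undefined).  ``baseline_mean``/``baseline_sd`` describe
    the first-difference derivative over the baseline window (RFU/cycle).
    """

    cq: float | None
    baseline_mean: float
    baseline_sd: float
    max_derivative_cycle: int
    efficiency: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def called(self) -> bool:
        return self.cq is not None


def derivative(fluorescence) -> np.ndarray:
    """First-difference derivative d(c) = F(c) - F(c-1) for c = 2..n.

    ``fluorescence`` is indexed by cycle starting at 1; the returned array
    has length n-1 and position i holds the derivative at cycle i+2.
    """
    f = np.asarray(fluorescence, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValueError("need a 1-D fluorescence series with >= 2 cycles")
    if not np.all(np.isfinite(f)):
        raise ValueError("fluorescence contains non-finite values")
    return np.diff(f)


def call_cq(
    fluorescence,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    k: float = DEFAULT_K,
    integer_cq: bool = False,
) -> CqResult:
    """Call the quantification cycle of one amplification curve.

    The threshold is ``mean + k * sd`` of the derivative over
    ``baseline_window`` (sample SD, ddof=1).  The crossing search starts at
    the first cycle after the window, so the threshold is never tested
    against the cycles that defined it.  With ``integer_cq`` the first
    crossing cycle itself is reported; otherwise the derivative is linearly
    interpolated across the threshold, so ``cq`` lies in ``(c*-1, c*]``.
    """
    f = np.asarray(fluorescence, dtype=float)
    n = f.size
    lo, hi = baseline_window
    if not (2 <= lo <= hi <= n):
        raise ValueError(
            f"baseline window {baseline_window} must lie within cycles 2..{n}"
        )
    d = derivative(f)

    def d_at(c: int) -> float:  # derivative at cycle c (c >= 2)
        return d[c - 2]

    base = d[lo - 2 : hi - 1]
    baseline_mean = float(np.mean(base))
    baseline_sd = float(np.std(base, ddof=1)) if base.size > 1 else 0.0
    threshold = baseline_mean + k * baseline_sd
    max_derivative_cycle = int(np.argmax(d)) + 2

    flags: list[str] = []
    cq: float | None = None
    for c in range(hi + 1, n + 1):
        if d_at(c) > threshold:
            if integer_cq:
                cq = float(c)
            else:
                prev = d_at(c - 1)
                denom = d_at(c) - prev
                if denom > 0 and prev < threshold:
                    cq = (c - 1) + (threshold - prev) / denom
                else:
                    # derivative was already at/above threshold at the window
                    # edge, or is non-increasing: pin to the crossing cycle
                    cq = float(c)
                    flags.append("interp_clamped")
            break
    if cq is None:
        flags.append("no_call")
        if baseline_sd == 0.0:
            flags.append("degenerate_baseline")
    return CqResult(
        cq=cq,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        max_derivative_cycle=max_derivative_cycle,
        flags=flags,
    )


def efficiency(
    fluorescence,
    cq_result: CqResult,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    linear: bool = False,
) -> float | None:
    """Per-cycle amplification gain over the exponential phase.

    Fits the least-squares slope of ``log10(F(c) - baseline)`` against cycle
    over ``[ceil(cq), max_derivative_cycle]`` and returns ``10**slope - 1``
    (1.0 = perfect doubling).  ``baseline`` is the mean fluorescence over the
    baseline window; points that are non-positive after subtraction are
    excluded.  Returns None (and flags the CqResult) when the Cq was not
    called or fewer than two usable points remain.  With ``linear`` the raw
    fluorescence slope is returned instead (no standard exponential model).
    """
    if not cq_result.called:
        cq_result.flags.append("efficiency_undefined")
        return None
    f = np.asarray(fluorescence, dtype=float)
    lo, hi = baseline_window
    start = math.ceil(cq_result.cq)
    stop = cq_result.max_derivative_cycle
    cycles = np.arange(start, stop + 1)
    if cycles.size < 2:
        cq_result.flags.append("efficiency_undefined")
        return None
    baseline_fluor = float(np.mean(f[lo - 1 : hi]))
    y = f[cycles - 1] - baseline_fluor
    if linear:
        slope = stats.linregress(cycles, f[cycles - 1]).slope
        eff = float(slope)
    else:
        keep = y > 0
        if keep.sum() < 2:
            cq_result.flags.append("efficiency_undefined")
            return None
        slope = stats.linregress(cycles[keep], np.log10(y[keep])).slope
        eff = float(10.0**slope - 1.0)
    if not linear and not (0.0 <= eff <= 1.1):
        warnings.warn(
            f"PCR efficiency {eff:.3f} outside the plausible range [0, 1.1]",
            stacklevel=2,
        )
    cq_result.efficiency = eff
    return eff


def call_cq_table(
    curves: pd.DataFrame,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    k: float = DEFAULT_K,
    integer_cq: bool = False,
    with_efficiency: bool = True,
) -> pd.DataFrame:
    """Call Cq (and efficiency) for every curve in a long-format table.

    ``curves`` must have columns ``sample_id, aptamer_id, cycle,
    fluorescence``.  Returns one row per (sample, aptamer) with columns
    ``cq`` (NaN for no-call), ``efficiency``, ``baseline_mean``,
    ``baseline_sd``, ``max_derivative_cycle`` and semicolon-joined ``flags``.
    """
    required = {"sample_id", "aptamer_id", "cycle", "fluorescence"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curve table missing columns: {sorted(missing)}")
    rows = []
    for (sid, apt), grp in curves.groupby(["sample_id", "aptamer_id"], sort=True):
        f = grp.sort_values("cycle")["fluorescence"].to_numpy()
        res = call_cq(f, baseline_window=baseline_window, k=k, integer_cq=integer_cq)
        if with_efficiency:
            efficiency(f, res, baseline_window=baseline_window)
        rows.append(
            {
                "sample_id": sid,
                "aptamer_id": apt,
                "cq": np.nan if res.cq is None else res.cq,
                "efficiency": np.nan if res.efficiency is None else res.efficiency,
                "baseline_mean": res.baseline_mean,
                "baseline_sd": res.baseline_sd,
                "max_derivative_cycle": res.max_derivative_cycle,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
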