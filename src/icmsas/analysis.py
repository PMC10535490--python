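"""Curve-level statistics for contrast-variation and fibrillization SANS.

* integrated small-q intensity and the sqrt(I_integ)-vs-%D2O match-point
  regression used in contrast variation,
* Porod (log-log) slope fitting and its mass-fractal reading
  (fractal dimension D = -slope for slopes between -3 and -1),
* interference-peak detection on a power-law + constant baseline,
* Bragg spacing d = 2 pi / q and harmonic-order assignment of peak
  series (first/second-order peaks of a periodic super-assembly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .contrast import MatchPointFit
from .io import ScatteringCurve

#: default small-q integration band for match-point work, A^-1
MATCH_BAND = (0.0065, 0.009)


@dataclass
class PorodFit:
    slope: float
    stderr: float
    q_window: tuple
    intercept_log10: float = 0.0

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")

    @property
    def fractal_dimension(self) -> float | None:
        """Mass-fractal dimension -slope, defined for slopes in (-3, -1)."""
        return -self.slope if -3.0 < self.slope < -1.0 else None


@dataclass
class Peak:
    q: float
    height: float
    width: float
    order: int | None = None  # harmonic index, None = unassigned


@dataclass
class PeakReport:
    peaks: list
    baseline: dict = field(default_factory=dict)  # {'A', 'p', 'c'}
    periodicity: float | None = None              # A, from harmonic fit

    def __post_init__(self):
        qs = [p.q for p in self.peaks]
        if any(b <= a for a, b in zip(qs, qs[1:])):
            raise ValueError("peak positions must be strictly increasing")
        if self.periodicity is not None and self.periodicity <= 0:
            raise ValueError("periodicity must be positive")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.q for p in self.peaks])


def integrate_band(curve: ScatteringCurve, q_lo: float, q_hi: float) -> float:
    """Trapezoidal integral of I(q) over [q_lo, q_hi].

    Band edges inside the grid are included by linear interpolation.
    """
    if q_hi <= q_lo:
        raise ValueError("q_hi must exceed q_lo")
    lo = max(q_lo, curve.q[0])
    hi = min(q_hi, curve.q[-1])
    if hi <= lo:
        raise ValueError("integration band does not overlap the curve")
    inner = curve.q[(curve.q > lo) & (curve.q < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, curve.q, curve.intensity)
    return float(np.trapezoid(vals, grid))


def fit_match_point(series, q_lo: float = MATCH_BAND[0],
                    q_hi: float = MATCH_BAND[1]) -> MatchPointFit:
    """Contrast-match-point regression from a D2O contrast series.

    For each (d2o_percent, curve) pair, v = sqrt(I_integ) over the small-q
    band is computed; v is proportional to |contrast|, i.e. |a f + b| in
    the D2O percentage f.  The two-branch absolute-value model is fitted
    by nonlinear least squares (robust when all measurements sit on one
    side of the match point) and the match point is -b/a, which may
    exceed 100% D2O.
    """
    series = list(series)
    fr = np.array([float(f) for f, _ in series])
    if len(np.unique(fr)) < 3:
        raise ValueError("need >= 3 distinct D2O fractions")
    v = np.array([np.sqrt(max(integrate_band(c, q_lo, q_hi), 0.0))
                  for _, c in series])

    # profile the match point: for fixed mp, the amplitude k of
    # v = k |f - mp| has a closed form, leaving a 1-D search in mp
    # (the |.| model is non-smooth, so joint gradient fits stall)
    def k_of(mp):
        d = np.abs(fr - mp)
        denom = d @ d
        return (v @ d) / denom if denom > 0 else 0.0

    def sse(mp):
        r = k_of(mp) * np.abs(fr - mp) - v
        return r @ r

    grid = np.linspace(-50.0, 200.0, 2001)
    mp = grid[int(np.argmin([sse(m) for m in grid]))]
    res = optimize.minimize_scalar(sse, bracket=(mp - 0.5, mp, mp + 0.5)
                                   if sse(mp - 0.5) > sse(mp) < sse(mp + 0.5)
                                   else None,
                                   bounds=(mp - 1.0, mp + 1.0),
                                   method="bounded")
    mp = float(res.x)
    k = k_of(mp)
    if k <= 1e-12 * (np.abs(v).max() + 1e-30):
        raise ValueError("no contrast variation across the series (a ~ 0)")
    a, b = k, -k * mp  # v = |a f + b|

    dof = max(len(fr) - 2, 1)
    r = k * np.abs(fr - mp) - v
    s2 = (r @ r) / dof
    jac = np.column_stack([np.abs(fr - mp), -k * np.sign(fr - mp)])
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        mp_err = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        mp_err = float("nan")

    warning = None
    if (fr < mp).all() or (fr > mp).all():
        span = max(fr.max() - fr.min(), 1e-30)
        overshoot = mp - fr.max() if mp > fr.max() else fr.min() - mp
        if overshoot > 0.5 * span:
            warning = ("match point extrapolated far beyond the measured "
                       "D2O range; leverage is poor")
    return MatchPointFit(float(mp), mp_err, float(a), float(b),
                         (q_lo, q_hi), warning)


def porod_slope(curve: ScatteringCurve, q_window) -> PorodFit:
    """Ordinary least-squares slope of log10 I vs log10 q in a q-window."""
    lo, hi = q_window
    mask = (curve.q >= lo) & (curve.q <= hi)
    if mask.sum() < 5:
        raise ValueError("need >= 5 points inside the Porod window")
    i = curve.intensity[mask]
    if np.any(i <= 0):
        raise ValueError("nonpositive intensities inside the Porod window")
    res = stats.linregress(np.log10(curve.q[mask]), np.log10(i))
    return PorodFit(float(res.slope), float(res.stderr), (lo, hi),
                    float(res.intercept))


def _baseline_power_flat(q, i):
    """Robust fit of I ~ A q^p + c over the full window.

    Soft-L1 loss on log-residuals downweights the peak regions, so the
    baseline tracks the aggregate power-law + flat background underneath.
    """
    ipos = np.maximum(i, 1e-300)
    res0 = stats.linregress(np.log(q), np.log(ipos))
    p0 = [np.exp(res0.intercept), res0.slope, max(ipos.min() * 0.1, 1e-12)]

    def resid(pars):
        la, p, lc = pars
        model = np.exp(la) * q ** p + np.exp(lc)
        return np.log(model) - np.log(ipos)

    sol = optimize.least_squares(
        resid, [np.log(p0[0]), p0[1], np.log(p0[2])],
        loss="soft_l1", f_scale=0.1, max_nfev=2000)
    if not sol.success and not np.all(np.isfinite(sol.x)):
        raise RuntimeError("baseline fit diverged")
    la, p, lc = sol.x
    return np.exp(la), p, np.exp(lc)


def detect_peaks(curve: ScatteringCurve,
                 min_prominence: float = 0.05) -> PeakReport:
    """Find interference peaks above a power-law + flat baseline.

    The baseline A q^p + c is fitted robustly over the whole curve; local
    maxima of I - baseline whose prominence exceeds ``min_prominence``
    times the local baseline are reported, positions refined by 3-point
    parabolic interpolation.
    """
    if len(curve) < 20:
        raise ValueError("need >= 20 points for peak detection")
    q, i = curve.q, curve.intensity
    a, p, c = _baseline_power_flat(q, i)
    base = a * q ** p + c
    excess = i - base

    # point-noise scale from the second difference (trend-free); peaks on
    # the lightly smoothed excess must clear both the prominence fraction
    # and ~4x this noise floor
    d2 = i[:-2] - 2 * i[1:-1] + i[2:]
    rel_resid = d2 / (np.sqrt(6.0) * np.maximum(base[1:-1], 1e-300))
    noise_rel = 1.4826 * np.median(np.abs(rel_resid))
    smoothed = signal.savgol_filter(excess, 7, 2) if len(excess) >= 7 \
        else excess

    idx, props = signal.find_peaks(smoothed, prominence=0.0)
    peaks = []
    dq_local = np.gradient(q)
    for j, prom in zip(idx, props["prominences"]):
        if prom < max(min_prominence, 4.0 * noise_rel) * base[j]:
            continue
        width_samples = signal.peak_widths(smoothed, [j],
                                           rel_height=0.5)[0][0]
        if width_samples < 2.5:  # single-point spikes are noise
            continue
        # a correlation peak needs at least ~2 repeat distances of
        # coherence (FWHM < q/2); broader bumps are baseline-model
        # mismatch (e.g. a Guinier knee), not interference peaks
        fwhm = width_samples * dq_local[j]
        if fwhm > 0.5 * q[j]:
            continue
        # parabolic refinement in q
        if 0 < j < len(q) - 1:
            y0, y1, y2 = smoothed[j - 1], smoothed[j], smoothed[j + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            qpk = q[j] + delta * 0.5 * (q[min(j + 1, len(q) - 1)] - q[max(j - 1, 0)])
        else:
            qpk = q[j]
        peaks.append(Peak(float(qpk), float(smoothed[j]), float(fwhm)))
    peaks.sort(key=lambda pk: pk.q)
    return PeakReport(peaks, baseline={"A": a, "p": p, "c": c})


def bragg_spacing(q_peak: float) -> float:
    """Real-space correlation distance d = 2 pi / q, A."""
    if q_peak <= 0:
        raise ValueError("q_peak must be positive")
    return 2.0 * np.pi / q_peak


def assign_harmonics(report: PeakReport, tol: float = 0.1,
                     max_order: int = 4) -> PeakReport:
    """Assign integer harmonic orders n_i to peaks, q_i ~ n_i q0.

    Candidate fundamentals q_i / n are scored by the number of peaks they
    assign within relative tolerance ``tol`` (ties broken by total
    residual); the fundamental is then refined by least squares over the
    assigned peaks and the periodicity 2 pi / q0 recorded.  Peaks that fit
    no order remain unassigned (order None).
    """
    if not report.peaks:
        return report
    qs = report.positions
    qmin = qs.min()

    best = None  # (n_assigned, -total_resid, q0, orders)
    for qi in qs:
        for n in range(1, max_order + 1):
            q0 = qi / n
            if q0 > qmin * (1 + tol) or q0 <= 0:
                continue
            orders, resid, count = [], 0.0, 0
            for qj in qs:
                m = int(round(qj / q0))
                if 1 <= m <= max_order and abs(qj - m * q0) <= tol * qj:
                    orders.append(m)
                    resid += abs(qj - m * q0)
                    count += 1
                else:
                    orders.append(None)
            key = (count, -resid)
            if best is None or key > best[0]:
                best = (key, q0, orders)

    _, q0, orders = best
    assigned = [(m, qj) for m, qj in zip(orders, qs) if m is not None]
    if assigned:
        ns = np.array([m for m, _ in assigned], dtype=float)
        qa = np.array([qj for _, qj in assigned])
        q0 = float((ns @ qa) / (ns @ ns))
    new_peaks = [Peak(pk.q, pk.height, pk.width, m)
                 for pk, m in zip(report.peaks, orders)]
    return PeakReport(new_peaks, dict(report.baseline),
                      periodicity=bragg_spacing(q0))
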