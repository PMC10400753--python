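"""Cardiac-cycle phase analysis of left-ventricular time-volume curves.

A time-volume curve (TVC) samples the LV cavity volume across one R-R
interval of an ECG-gated cine acquisition, with the first sample at the
R wave (end-diastole).  The cycle is segmented into its four phases --
isovolumetric contraction (IVC), ejection, isovolumetric relaxation (IVR)
and filling -- by a continuous four-segment piecewise linear regression
(PLR): breakpoints are searched exhaustively on the sample grid, the
least-squares fit is computed for every candidate triple, and the
minimum-SSE fit satisfying the physiologic slope-sign constraints
(ejection slope negative, filling slope positive, isovolumetric slopes
smaller in magnitude than both) is returned.

From the fit the standard haemodynamic indices are derived: ESV, EDV,
SV = EDV - ESV, EF = 100*SV/EDV, CO = SV*HR, CI = CO/BSA with the Meeh
allometric body-surface area BSA = k * mass^(2/3) (k = 9.8 cm^2/g^(2/3)
by default), ejection and filling rates as PLR segment slopes normalised
to SV and the R-R interval, phase durations as % of R-R, and the E/A
ratio of early to atrial peak filling rate from a dV/dt curve.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "TimeVolumeCurve",
    "PLRFit",
    "HemodynamicIndices",
    "SubjectMeta",
    "EAResult",
    "DegenerateCurveError",
    "PLRFitError",
    "fit_plr",
    "derive_indices",
    "ea_ratio",
    "read_tvc_tsv",
    "write_tvc_tsv",
]

#: Meeh constant for murine body-surface area, cm^2 / g^(2/3).
DEFAULT_MEEH_K = 9.8

#: Minimum number of samples per PLR segment.
MIN_SEGMENT_SAMPLES = 2


class DegenerateCurveError(ValueError):
    """Raised when the TVC amplitude is below the noise floor."""


class PLRFitError(RuntimeError):
    """Raised when no breakpoint candidate satisfies the slope constraints."""


@dataclass(frozen=True)
class TimeVolumeCurve:
    """LV volume (ul) sampled at times (ms) within one R-R interval."""

    times: np.ndarray
    volumes: np.ndarray
    rr: float                   # ms
    hr: float | None = None     # bpm; derived from rr when omitted

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if t.size < 16:
            raise ValueError("a TVC needs at least 16 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if t[0] < 0 or t[-1] > self.rr:
            raise ValueError("times must lie within [0, rr]")
        if np.any(v <= 0):
            raise ValueError("volumes must be positive")
        hr = self.hr
        if hr is None:
            hr = 60000.0 / self.rr
        elif abs(hr - 60000.0 / self.rr) > 0.01 * hr:
            raise ValueError("hr and rr are inconsistent (|hr - 60000/rr| > 1%)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "hr", float(hr))


@dataclass(frozen=True)
class PLRFit:
    """Continuous 4-segment piecewise-linear model of a TVC.

    breakpoints are the phase-boundary positions as fractions of R-R:
    (IVC end, ejection end, IVR end, 1.0); slopes are ul/ms per segment
    in phase order (IVC, ejection, IVR, filling).
    """

    breakpoints: tuple          # 4 fractions of R-R
    slopes: tuple               # 4 slopes, ul/ms
    sse: float                  # ul^2
    rr: float                   # ms
    coef: tuple                 # (b0, b1, b2, b3, b4) of the hinge basis
    n_segments: int = 4

    @property
    def breakpoint_times(self):
        """Interior phase boundaries in ms."""
        return tuple(b * self.rr for b in self.breakpoints[:3])

    def predict(self, times):
        """Evaluate the fitted piecewise-linear volume at the given times (ms)."""
        t = np.asarray(times, dtype=float)
        b0, b1, b2, b3, b4 = self.coef
        t1, t2, t3 = self.breakpoint_times
        return (b0 + b1 * t
                + b2 * np.maximum(t - t1, 0.0)
                + b3 * np.maximum(t - t2, 0.0)
                + b4 * np.maximum(t - t3, 0.0))


@dataclass(frozen=True)
class SubjectMeta:
    """Per-animal covariates needed to index cardiac output to body size."""

    body_mass: float                    # g
    meeh_k: float = DEFAULT_MEEH_K      # cm^2 / g^(2/3)
    bsa_override: float | None = None   # cm^2

    def __post_init__(self):
        if self.body_mass <= 0 or self.meeh_k <= 0:
            raise ValueError("body_mass and meeh_k must be positive")

    @property
    def bsa(self) -> float:
        if self.bsa_override is not None:
            return float(self.bsa_override)
        return self.meeh_k * self.body_mass ** (2.0 / 3.0)


@dataclass(frozen=True)
class HemodynamicIndices:
    esv: float          # ul
    edv: float          # ul
    sv: float           # ul
    ef: float           # %
    co: float           # ml/min
    ci: float           # ul/min/cm^2
    er: float           # ejection rate, % of SV per R-R
    fr: float           # filling rate, % of SV per R-R
    et: float           # % of R-R
    ivrt: float         # % of R-R
    ft: float           # % of R-R
    ivct: float         # % of R-R
    bsa: float          # cm^2
    ea_ratio: float | None = None

    def to_dict(self):
        d = {k: getattr(self, k) for k in
             ("esv", "edv", "sv", "ef", "co", "ci", "er", "fr",
              "et", "ivrt", "ft", "ivct", "bsa", "ea_ratio")}
        return d


@dataclass(frozen=True)
class EAResult:
    """Early (E) / atrial (A) peak filling-rate ratio."""

    ratio: float | None
    e_peak: float | None
    a_peak: float | None
    fused: bool = False


# ---------------------------------------------------------------------------
# Piecewise linear regression
# ---------------------------------------------------------------------------

def _candidate_grid(n: int, stride: int, min_seg: int):
    idx = np.arange(min_seg, n - min_seg, stride)
    cands = [(i, j, k) for i, j, k in itertools.combinations(idx, 3)
             if j - i >= min_seg and k - j >= min_seg]
    return np.asarray(cands, dtype=np.intp)


def _batched_plr_solutions(t, v, tau):
    """Least-squares solutions of the continuous 4-segment model for every
    candidate breakpoint triple, assembled from suffix moment sums in O(1)
    per candidate.

    Basis: [1, t, (t-t1)+, (t-t2)+, (t-t3)+]; ``tau`` is (m, 3) with
    arbitrary breakpoint positions inside the sampled span.  Returns
    (beta (m, 5), sse (m,)).
    """
    n = t.size
    # suffix sums S*(i) = sum over samples j >= i
    def suffix(x):
        return np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])

    s0 = suffix(np.ones(n))
    s1 = suffix(t)
    s2 = suffix(t * t)
    sv = suffix(v)
    stv = suffix(t * v)
    sv2 = float(np.sum(v * v))

    m = tau.shape[0]
    # hinge h_a(t) = (t - tau_a)+ is nonzero for samples strictly after tau_a
    idx = np.searchsorted(t, tau, side="right")     # (m, 3)
    i1, i2, i3 = idx[:, 0], idx[:, 1], idx[:, 2]

    def h_sum(ia, ta):          # sum h_a
        return s1[ia] - ta * s0[ia]

    def hh_sum(ia, ta, ib, tb):  # sum h_a*h_b with tau_a <= tau_b
        return s2[ib] - (ta + tb) * s1[ib] + ta * tb * s0[ib]

    def th_sum(ia, ta):         # sum t*h_a
        return s2[ia] - ta * s1[ia]

    def hv_sum(ia, ta):         # sum v*h_a
        return stv[ia] - ta * sv[ia]

    A = np.empty((m, 5, 5))
    b = np.empty((m, 5))
    A[:, 0, 0] = float(n)
    A[:, 0, 1] = A[:, 1, 0] = s1[0]
    A[:, 1, 1] = s2[0]
    cols = [(i1, tau[:, 0]), (i2, tau[:, 1]), (i3, tau[:, 2])]
    for a, (ia, ta) in enumerate(cols, start=2):
        A[:, 0, a] = A[:, a, 0] = h_sum(ia, ta)
        A[:, 1, a] = A[:, a, 1] = th_sum(ia, ta)
        b[:, a] = hv_sum(ia, ta)
    for a in range(3):
        for bb in range(a, 3):
            ia, ta = cols[a]
            ib, tb = cols[bb]
            val = hh_sum(ia, ta, ib, tb)
            A[:, 2 + a, 2 + bb] = val
            A[:, 2 + bb, 2 + a] = val
    b[:, 0] = sv[0]
    b[:, 1] = stv[0]

    try:
        beta = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.empty((m, 5))
        for q in range(m):
            beta[q] = np.linalg.lstsq(A[q], b[q], rcond=None)[0]
    sse = sv2 - np.einsum("mi,mi->m", beta, b)
    return beta, np.maximum(sse, 0.0)


def _segment_slopes(beta):
    s_ivc = beta[:, 1]
    s_ej = beta[:, 1] + beta[:, 2]
    s_ivr = s_ej + beta[:, 3]
    s_fill = s_ivr + beta[:, 4]
    return s_ivc, s_ej, s_ivr, s_fill


def _evaluate_candidates(t, v, tau):
    """Solve all candidates and return (beta, sse-with-inf-at-infeasible)."""
    beta, sse = _batched_plr_solutions(t, v, tau)
    s_ivc, s_ej, s_ivr, s_fill = _segment_slopes(beta)
    feasible = (
        (s_ej < 0) & (s_fill > 0)
        & (np.abs(s_ivc) < np.abs(s_ej)) & (np.abs(s_ivc) < np.abs(s_fill))
        & (np.abs(s_ivr) < np.abs(s_ej)) & (np.abs(s_ivr) < np.abs(s_fill))
        & np.isfinite(sse)
    )
    return beta, np.where(feasible, sse, np.inf)


def fit_plr(tvc: TimeVolumeCurve, candidate_stride: int = 1,
            refine_levels: int = 0, refine_factor: int = 5) -> PLRFit:
    """Fit the four-phase piecewise-linear model to a TVC.

    Breakpoints are searched exhaustively over sample-time candidates
    (optionally thinned by ``candidate_stride``); the minimum-SSE fit
    subject to the slope-sign constraints is returned, ties broken toward
    earlier breakpoints.  ``refine_levels`` > 0 additionally polishes the
    optimum on progressively finer local grids (step shrunk by
    ``refine_factor`` per level), releasing the breakpoints from the frame
    grid; SSE is non-increasing across refinement.

    Raises
    ------
    DegenerateCurveError
        If the volume amplitude is zero or below 3x the residual SD.
    PLRFitError
        If no candidate satisfies the physiologic constraints.
    """
    t, v = tvc.times, tvc.volumes
    amplitude = float(v.max() - v.min())
    if amplitude <= 1e-9 * max(abs(v).max(), 1.0):
        raise DegenerateCurveError("volume trace has (near-)zero amplitude")

    cands = _candidate_grid(t.size, candidate_stride, MIN_SEGMENT_SAMPLES)
    if cands.size == 0:
        raise PLRFitError("too few samples for a 4-segment fit")
    tau = t[cands]                               # (m, 3)
    beta, sse_f = _evaluate_candidates(t, v, tau)
    if not np.isfinite(sse_f).any():
        raise PLRFitError(
            "no breakpoint candidate satisfies the slope-sign constraints")
    best = int(np.argmin(sse_f))     # candidates are lexicographic: first = earliest
    best_tau, best_beta, best_sse = tau[best], beta[best], sse_f[best]

    # local sub-frame refinement around the coarse optimum
    step = float(np.median(np.diff(t)))
    lo, hi = t[1], t[-2]
    for _ in range(refine_levels):
        fine = step / refine_factor
        offsets = np.arange(-refine_factor, refine_factor + 1) * fine
        grids = [np.clip(best_tau[a] + offsets, lo, hi) for a in range(3)]
        mesh = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
        ok = (np.diff(mesh, axis=1) > 0.5 * fine).all(axis=1)
        mesh = mesh[ok]
        if not mesh.size:
            break
        beta_r, sse_r = _evaluate_candidates(t, v, mesh)
        j = int(np.argmin(sse_r))
        if sse_r[j] < best_sse:
            best_tau, best_beta, best_sse = mesh[j], beta_r[j], sse_r[j]
        step = fine

    s = _segment_slopes(best_beta[None, :])
    fit = PLRFit(
        breakpoints=(best_tau[0] / tvc.rr, best_tau[1] / tvc.rr,
                     best_tau[2] / tvc.rr, 1.0),
        slopes=tuple(float(x[0]) for x in s),
        sse=float(best_sse),
        rr=tvc.rr,
        coef=tuple(float(c) for c in best_beta),
    )
    resid_sd = np.sqrt(fit.sse / max(t.size - 5, 1))
    fitted_amplitude = float(np.ptp(fit.predict(t)))
    if fitted_amplitude < 3.0 * resid_sd:
        raise DegenerateCurveError(
            f"model-explained amplitude {fitted_amplitude:.3g} ul below noise "
            f"floor (3 x residual SD {resid_sd:.3g} ul)")
    return fit


def _steepest_filling_subslope(tvc: TimeVolumeCurve, fit: PLRFit) -> float:
    """Steepest sub-slope of a (possibly biphasic) filling phase: 2-segment
    continuous PLR restricted to the filling window, max of the two slopes."""
    t3 = fit.breakpoint_times[2]
    sel = tvc.times >= t3
    t, v = tvc.times[sel], tvc.volumes[sel]
    if t.size < 2 * MIN_SEGMENT_SAMPLES + 2:
        return fit.slopes[3]
    best_sse, best_slopes = np.inf, None
    for i in range(MIN_SEGMENT_SAMPLES, t.size - MIN_SEGMENT_SAMPLES):
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - t[i], 0.0)])
        beta, res, *_ = np.linalg.lstsq(X, v, rcond=None)
        sse = float(res[0]) if res.size else float(np.sum((X @ beta - v) ** 2))
        if sse < best_sse:
            best_sse = sse
            best_slopes = (beta[1], beta[1] + beta[2])
    return float(max(best_slopes))


def derive_indices(tvc: TimeVolumeCurve, fit: PLRFit, meta: SubjectMeta,
                   biphasic_filling: bool = False,
                   ea: EAResult | None = None) -> HemodynamicIndices:
    """Haemodynamic indices from a fitted TVC.

    Volume is constant during the isovolumetric phases, so EDV and ESV are
    the fitted IVC and IVR plateau levels (the fitted value at each
    segment's midpoint, i.e. the segment mean) -- far less noise-sensitive
    than the fitted corner vertices and exact on noiseless curves.
    CO = SV*HR; CI indexes CO to the Meeh body-surface area.  ER and FR are
    the ejection/filling PLR slopes normalised to SV and R-R (reported as
    % of SV per R-R); with ``biphasic_filling`` FR uses the steepest
    filling sub-slope, which is what a high-frame-rate acquisition resolves
    as the early-filling peak.
    """
    t1, t2, t3 = fit.breakpoint_times
    edv, esv = (float(x) for x in fit.predict([0.5 * t1, 0.5 * (t2 + t3)]))
    sv = edv - esv
    if sv <= 0:
        raise ValueError("non-positive stroke volume")
    ef = 100.0 * sv / edv
    co = sv * tvc.hr / 1000.0           # ml/min
    bsa = meta.bsa
    ci = co * 1000.0 / bsa              # ul/min/cm^2

    er = 100.0 * abs(fit.slopes[1]) * tvc.rr / sv
    fill_slope = (_steepest_filling_subslope(tvc, fit) if biphasic_filling
                  else fit.slopes[3])
    fr = 100.0 * fill_slope * tvc.rr / sv

    b1, b2, b3, _ = fit.breakpoints
    ivct = 100.0 * b1
    et = 100.0 * (b2 - b1)
    ivrt = 100.0 * (b3 - b2)
    ft = 100.0 - (ivct + et + ivrt)     # exact partition of the cycle

    return HemodynamicIndices(
        esv=esv, edv=edv, sv=sv, ef=ef, co=co, ci=ci, er=er, fr=fr,
        et=et, ivrt=ivrt, ft=ft, ivct=ivct, bsa=bsa,
        ea_ratio=None if ea is None else ea.ratio)


def ea_ratio(times, dvdt, prominence_fraction: float = 0.1) -> EAResult:
    """E/A ratio from a dV/dt curve over the filling phase.

    The two most prominent local maxima of dV/dt, in temporal order, are the
    early (E) and atrial (A) filling peaks; the ratio E/A is returned.  When
    only one peak has prominence above ``prominence_fraction`` of the dV/dt
    range the peaks are considered fused (as in restrictive filling) and the
    ratio is reported absent.
    """
    times = np.asarray(times, dtype=float)
    dvdt = np.asarray(dvdt, dtype=float)
    if times.size < 8:
        raise ValueError("need at least 8 samples spanning the filling phase")
    span = float(dvdt.max() - dvdt.min())
    if span <= 0:
        return EAResult(ratio=None, e_peak=None, a_peak=None, fused=True)
    peaks, props = find_peaks(dvdt, prominence=prominence_fraction * span)
    if peaks.size < 2:
        e = float(dvdt[peaks[0]]) if peaks.size else None
        return EAResult(ratio=None, e_peak=e, a_peak=None, fused=True)
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    e_idx, a_idx = int(np.min(top2)), int(np.max(top2))
    e, a = float(dvdt[e_idx]), float(dvdt[a_idx])
    return EAResult(ratio=e / a, e_peak=e, a_peak=a, fused=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_tvc_tsv(tvc: TimeVolumeCurve, path):
    df = pd.DataFrame({
        "frame_index": np.arange(tvc.times.size),
        "time_ms": tvc.times,
        "volume_ul": tvc.volumes,
    })
    df.to_csv(path, sep="\t", index=False)


def read_tvc_tsv(path, rr: float | None = None, hr: float | None = None,
                 meta_path=None) -> TimeVolumeCurve:
    """Read a TVC from a (frame_index, time_ms, volume_ul) TSV.

    rr/hr may be given directly or in a JSON sidecar with keys
    ``rr_ms`` and optionally ``hr_bpm``.
    """
    df = pd.read_csv(path, sep="\t")
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        rr = meta.get("rr_ms", rr)
        hr = meta.get("hr_bpm", hr)
    if rr is None:
        raise ValueError("the R-R interval (rr_ms) is required")
    return TimeVolumeCurve(times=df["time_ms"].to_numpy(),
                           volumes=df["volume_ul"].to_numpy(),
                           rr=float(rr), hr=hr)
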