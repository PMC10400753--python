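"""Harmonic-phase (HARP) strain analysis of SPAMM-tagged cine MRI.

SPAMM tagging imprints a periodic saturation grid on the myocardium at the
R wave; the grid is carried along by the tissue, so its local spatial phase
is a material marker.  HARP isolates one tag harmonic in the 2-D Fourier
spectrum with a band-pass filter around the tag wavevector k; the phase of
the filtered complex image is (up to wrapping) phi(x) = 2*pi*k.X(x), where
X(x) is the material (reference) position of the tissue at spatial point x.
Wrap-aware spatial phase gradients therefore give

    grad Phi = 2*pi * K * F^-1,

with K the 2x2 matrix of tag wavevectors (rows) and F the deformation
gradient.  The "peak-combination" variant extracts both conjugate (+k, -k)
harmonics and averages their phase gradients, cancelling the asymmetry bias
of the band-pass window.  From F the Lagrangian strain E = (F'F - I)/2 and
the engineering radial/circumferential strains

    Err = sqrt(1 + 2 e_r' E e_r) - 1,   Ecc analogously,

are evaluated about the LV centre, averaged in eight 45-degree sectors, and
condensed into the clinical per-cycle indices (Es, Ees, Epost, PSI =
(Epost - Ees)/Emax, TpeakSI = Tpeak/RR, strain rates SRmax/SRe/SRa, SRe/a,
systolic stretch SS).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "TaggedFrameStack",
    "PhaseMaps",
    "StrainField",
    "SegmentStrainCurves",
    "StrainIndices",
    "TagDetectionError",
    "harp_phase_maps",
    "strain_field",
    "segment_strain_curves",
    "strain_indices",
    "annular_mask",
    "read_stack",
    "write_stack",
]


class TagDetectionError(RuntimeError):
    """Raised when no harmonic peak is found near the nominal tag wavevector."""


@dataclass(frozen=True)
class TaggedFrameStack:
    """A tagged short-axis cine: frames (n, H, W), pixel spacing in mm,
    frame times as fractions of R-R, and the two nominal tag wavevectors
    (rows of a 2x2 matrix, cycles/mm, in (row, col) frequency convention)."""

    frames: np.ndarray
    pixel_spacing: float
    frame_times: np.ndarray
    tag_wavevectors: np.ndarray

    def __post_init__(self):
        fr = np.asarray(self.frames, dtype=float)
        ft = np.asarray(self.frame_times, dtype=float)
        kv = np.asarray(self.tag_wavevectors, dtype=float)
        if fr.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        n, h, w = fr.shape
        if h != w or h % 2:
            raise ValueError("frames must be square with even side")
        if ft.shape != (n,) or np.any(ft < 0) or np.any(ft >= 1) or np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be increasing fractions of R-R in [0, 1)")
        if kv.shape != (2, 2) or np.any(np.linalg.norm(kv, axis=1) <= 0):
            raise ValueError("tag_wavevectors must be two nonzero 2-vectors")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "frame_times", ft)
        object.__setattr__(self, "tag_wavevectors", kv)

    @property
    def n_frames(self):
        return self.frames.shape[0]

    @property
    def fov_mm(self):
        return self.frames.shape[1] * self.pixel_spacing


@dataclass(frozen=True)
class PhaseMaps:
    """Wrapped harmonic-phase images per tag direction.

    ``phase_pos``/``phase_neg`` have shape (2, n_frames, H, W) holding the
    phases extracted at the +k and -k conjugate harmonics; ``peaks`` are the
    detected +k peak positions (cycles/mm) and ``radius`` the band-pass
    radii, one per direction.
    """

    phase_pos: np.ndarray
    phase_neg: np.ndarray
    peaks: np.ndarray              # (2, 2) detected +k peaks, cycles/mm
    radius: np.ndarray             # (2,) filter radii, cycles/mm
    pixel_spacing: float
    frame_times: np.ndarray


@dataclass(frozen=True)
class StrainField:
    """Per-frame engineering strain maps (%) about the LV centre."""

    err: np.ndarray                # (n_frames, H, W), %
    ecc: np.ndarray                # (n_frames, H, W), %
    lv_center: tuple               # (row, col) pixels
    mask: np.ndarray               # bool (H, W)
    frame_times: np.ndarray
    deformation_warning: bool = False


@dataclass(frozen=True)
class SegmentStrainCurves:
    """Sector-averaged strain curves: (n_segments, n_frames) per component."""

    err: np.ndarray
    ecc: np.ndarray
    angular_bounds: np.ndarray     # (n_segments + 1,) degrees, CCW
    frame_times: np.ndarray
    sector_pixels: np.ndarray      # (n_segments,) pixel counts
    missing: tuple = ()            # indices of empty sectors

    def global_mean(self, component: str = "cc"):
        """Area-weighted mean over sectors == plain mask mean, per frame."""
        curves = self.ecc if component == "cc" else self.err
        w = self.sector_pixels.astype(float)
        ok = w > 0
        return (curves[ok] * w[ok, None]).sum(axis=0) / w[ok].sum()


@dataclass(frozen=True)
class StrainIndices:
    es: float          # peak systolic strain, %
    ees: float         # end-systolic strain, %
    epost: float       # maximal post-systolic strain, %
    emax: float        # max |strain| over the cycle, %
    tpeak: float       # time of |strain| max, fraction of R-R
    tpeak_si: float    # TpeakSI = Tpeak/RR (already a fraction)
    psi: float         # (Epost - Ees)/Emax
    srmax: float       # systolic strain rate extremum, %/R-R
    sre: float         # early-diastolic strain rate, %/R-R
    sra: float         # atrial-diastolic strain rate, %/R-R
    sre_a: float       # SRe/SRa
    ss: float          # systolic stretch, %
    end_systole: float
    flags: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Phase extraction
# ---------------------------------------------------------------------------

def _freq_grids(n: int, pixel_spacing: float):
    f = np.fft.fftfreq(n, d=pixel_spacing)       # cycles/mm
    return np.meshgrid(f, f, indexing="ij")      # (row-freq, col-freq)

def _raised_cosine_window(fu, fv, center, radius):
    d = np.hypot(fu - center[0], fv - center[1])
    w = np.where(d <= radius, np.cos(np.pi * d / (2.0 * radius)) ** 2, 0.0)
    return w


def harp_phase_maps(stack: TaggedFrameStack, search_tolerance: float = 0.2,
                    min_peak_snr: float = 5.0) -> PhaseMaps:
    """Extract wrapped harmonic-phase maps for both tag directions.

    For each direction the first-harmonic peak nearest the nominal tag
    wavevector is located in the frame-0 spectrum (within
    ``search_tolerance`` of |k|), an isotropic raised-cosine band-pass of
    radius |k_peak|/2 is applied to every frame, and the phase of the
    inverse transform is kept.  The conjugate (-k) harmonic is extracted
    with the mirrored window for peak combination downstream.
    """
    n, h, w = stack.frames.shape
    fu, fv = _freq_grids(h, stack.pixel_spacing)
    spectra = np.fft.fft2(stack.frames)          # (n, H, W)
    mag0 = np.abs(spectra[0])
    background = np.median(mag0)

    phase_pos = np.empty((2, n, h, w))
    phase_neg = np.empty((2, n, h, w))
    peaks = np.empty((2, 2))
    radii = np.empty(2)
    for d in range(2):
        k_nom = stack.tag_wavevectors[d]
        k_abs = np.linalg.norm(k_nom)
        dist = np.hypot(fu - k_nom[0], fv - k_nom[1])
        region = dist <= search_tolerance * k_abs
        if not region.any():
            raise TagDetectionError("search region around nominal wavevector is empty")
        cand = np.where(region, mag0, -np.inf)
        idx = np.unravel_index(np.argmax(cand), cand.shape)
        if mag0[idx] <= 0 or mag0[idx] < min_peak_snr * background:
            snr = mag0[idx] / background if background > 0 else 0.0
            raise TagDetectionError(
                f"no harmonic peak within {search_tolerance:.0%} of the nominal "
                f"tag wavevector (peak/background {snr:.2f})")
        k_peak = np.array([fu[idx], fv[idx]])
        radius = 0.5 * np.linalg.norm(k_peak)
        win_pos = _raised_cosine_window(fu, fv, k_peak, radius)
        win_neg = _raised_cosine_window(fu, fv, -k_peak, radius)
        zp = np.fft.ifft2(spectra * win_pos)
        zn = np.fft.ifft2(spectra * win_neg)
        phase_pos[d] = np.angle(zp)
        phase_neg[d] = np.angle(zn)
        peaks[d] = k_peak
        radii[d] = radius

    return PhaseMaps(phase_pos=phase_pos, phase_neg=phase_neg, peaks=peaks,
                     radius=radii, pixel_spacing=stack.pixel_spacing,
                     frame_times=stack.frame_times.copy())


def _wrap(a):
    return np.angle(np.exp(1j * a))


def _wrap_gradient(phi, spacing):
    """Wrap-aware spatial gradient of a wrapped phase image.

    One-pixel forward/backward differences are each re-wrapped into
    (-pi, pi] and averaged (one-sided at the borders), so phase steps of up
    to pi per pixel are handled without unwrapping.
    """
    out = []
    for ax in (0, 1):
        d = _wrap(np.diff(phi, axis=ax)) / spacing
        g = np.empty_like(phi)
        mid = [slice(None)] * phi.ndim
        mid[ax] = slice(1, -1)
        lead = [slice(None)] * phi.ndim
        lead[ax] = slice(1, None)
        lag = [slice(None)] * phi.ndim
        lag[ax] = slice(None, -1)
        g[tuple(mid)] = 0.5 * (d[tuple(lead)] + d[tuple(lag)])
        first = [slice(None)] * phi.ndim
        first[ax] = slice(0, 1)
        last = [slice(None)] * phi.ndim
        last[ax] = slice(-1, None)
        g[tuple(first)] = np.take(d, [0], axis=ax)
        g[tuple(last)] = np.take(d, [-1], axis=ax)
        out.append(g)
    return out  # (d/drow, d/dcol)


# ---------------------------------------------------------------------------
# Strain reconstruction
# ---------------------------------------------------------------------------

def annular_mask(shape, center, inner_frac: float = 0.25, outer_frac: float = 0.75,
                 border: int = 3):
    """Annular myocardium stand-in mask; radii are fractions of half the side."""
    h, w = shape
    r = np.hypot(*np.meshgrid(np.arange(h) - center[0], np.arange(w) - center[1],
                              indexing="ij"))
    half = min(h, w) / 2.0
    m = (r >= inner_frac * half) & (r <= outer_frac * half)
    m[:border] = m[-border:] = False
    m[:, :border] = m[:, -border:] = False
    return m


def strain_field(phases: PhaseMaps, center=None, mask=None,
                 det_bounds=(0.2, 5.0), det_warn_fraction: float = 0.1) -> StrainField:
    """Radial/circumferential engineering strain maps from HARP phases.

    The phase-gradient matrix G(x) = grad Phi / (2*pi) equals K F^-1; the
    frame-0 gradient G0(x) is used as the local effective wavevector matrix
    (it equals K up to filter bias, which cancels), so F = G^-1 G0 and the
    reference frame has identically zero strain by construction.  Gradients
    of the +k and -k phases are averaged (peak combination).
    """
    nph, n, h, w = phases.phase_pos.shape
    K = phases.peaks
    if abs(np.linalg.det(K / np.linalg.norm(K, axis=1, keepdims=True))) < 0.1:
        raise ValueError("tag wavevectors are (nearly) collinear")
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if mask is None:
        mask = annular_mask((h, w), center)
    mask = np.asarray(mask, dtype=bool)

    # G[t] : (H, W, 2, 2), row d = grad of phase of direction d (cycles/mm)
    G = np.empty((n, h, w, 2, 2))
    for d in range(2):
        for t in range(n):
            gp = _wrap_gradient(phases.phase_pos[d, t], phases.pixel_spacing)
            gn = _wrap_gradient(phases.phase_neg[d, t], phases.pixel_spacing)
            # -k harmonic carries phase -2*pi*k.X: subtract its gradient
            G[t, :, :, d, 0] = (gp[0] - gn[0]) / (4.0 * np.pi)
            G[t, :, :, d, 1] = (gp[1] - gn[1]) / (4.0 * np.pi)

    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    rad = np.hypot(rows, cols)
    rad = np.where(rad == 0, 1.0, rad)
    e_r = np.stack([rows / rad, cols / rad], axis=-1)          # (H, W, 2)
    e_c = np.stack([-e_r[..., 1], e_r[..., 0]], axis=-1)

    G0 = G[0]
    err = np.empty((n, h, w))
    ecc = np.empty((n, h, w))
    warn = False
    for t in range(n):
        F = np.linalg.solve(G[t], G0)          # F = G^-1 G0, per pixel
        detf = np.linalg.det(F)
        inside = mask & ((detf < det_bounds[0]) | (detf > det_bounds[1]))
        if mask.sum() and inside.sum() > det_warn_fraction * mask.sum():
            warn = True
        C = np.einsum("...ji,...jk->...ik", F, F)              # F' F
        stretch_r = np.sqrt(np.clip(np.einsum("...i,...ij,...j->...", e_r, C, e_r),
                                    0.0, None))
        stretch_c = np.sqrt(np.clip(np.einsum("...i,...ij,...j->...", e_c, C, e_c),
                                    0.0, None))
        err[t] = (stretch_r - 1.0) * 100.0
        ecc[t] = (stretch_c - 1.0) * 100.0
    if warn:
        warnings.warn("deformation gradient determinant outside "
                      f"{det_bounds} at >{det_warn_fraction:.0%} of mask pixels; "
                      "strain maps may be unreliable", RuntimeWarning)
    return StrainField(err=err, ecc=ecc, lv_center=tuple(center), mask=mask,
                       frame_times=phases.frame_times.copy(),
                       deformation_warning=warn)


def segment_strain_curves(fieldmap: StrainField, n_segments: int = 8,
                          start_angle_deg: float = 90.0) -> SegmentStrainCurves:
    """Sector-averaged strain curves in ``n_segments`` equal angular sectors
    encircling the myocardial cross-section.

    Sector 1 starts at ``start_angle_deg`` (default 90 deg, anterior) and
    sectors are ordered counterclockwise in image orientation (y up).
    Empty sectors are flagged and carry NaN curves.
    """
    h = fieldmap.err.shape[1]
    w = fieldmap.err.shape[2]
    c0, c1 = fieldmap.lv_center
    y_up = -(np.arange(h)[:, None] - c0)
    x_rt = np.arange(w)[None, :] - c1
    theta = np.degrees(np.arctan2(y_up, x_rt))                 # (-180, 180]
    sector = np.floor(((theta - start_angle_deg) % 360.0) / (360.0 / n_segments))
    sector = sector.astype(int)

    n = fieldmap.err.shape[0]
    err = np.full((n_segments, n), np.nan)
    ecc = np.full((n_segments, n), np.nan)
    counts = np.zeros(n_segments, dtype=int)
    missing = []
    for s in range(n_segments):
        sel = fieldmap.mask & (sector == s)
        counts[s] = sel.sum()
        if counts[s] == 0:
            missing.append(s)
            continue
        err[s] = fieldmap.err[:, sel].mean(axis=1)
        ecc[s] = fieldmap.ecc[:, sel].mean(axis=1)
    if missing:
        warnings.warn(f"empty myocardial sectors {missing}: excluded from the "
                      "global average", RuntimeWarning)
    bounds = start_angle_deg + np.arange(n_segments + 1) * (360.0 / n_segments)
    return SegmentStrainCurves(err=err, ecc=ecc, angular_bounds=bounds,
                               frame_times=fieldmap.frame_times.copy(),
                               sector_pixels=counts, missing=tuple(missing))


# ---------------------------------------------------------------------------
# Per-cycle indices
# ---------------------------------------------------------------------------

def strain_indices(curve, frame_times, end_systole: float | None = None) -> StrainIndices:
    """Clinical strain indices from one segment-averaged strain curve.

    ``curve`` is in % and ``frame_times`` in fractions of R-R.  The
    dominant deformation sign (sign of the largest-|.| strain) orients the
    extrema: Es and Epost are the dominant-signed extrema over the systolic
    window [0, end_systole] and the post-systolic window [end_systole, 1]
    (the end-systolic instant belongs to both, so a curve peaking exactly
    at end-systole has Epost = Ees); strain rates are centred finite
    differences of strain vs cycle fraction.  With no end-systole supplied,
    the time of the global |strain| extremum is used.
    """
    y = np.asarray(curve, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    if y.shape != t.shape or y.ndim != 1 or y.size < 4:
        raise ValueError("curve and frame_times must be equal-length 1-D arrays (>= 4)")
    flags = []

    ipeak = int(np.argmax(np.abs(y)))
    tpeak = float(t[ipeak])
    emax = float(np.abs(y[ipeak]))
    dom = 1.0 if y[ipeak] >= 0 else -1.0
    if end_systole is None:
        end_systole = tpeak
        flags.append("end_systole defaulted to global strain extremum time")

    ees = float(np.interp(end_systole, t, y))
    sys_mask = t <= end_systole
    post_mask = t >= end_systole
    sys_vals = np.concatenate([y[sys_mask], [ees]])
    post_vals = np.concatenate([y[post_mask], [ees]])
    es = float(dom * np.max(dom * sys_vals))
    epost = float(dom * np.max(dom * post_vals))
    psi = (epost - ees) / emax if emax > 0 else np.nan
    ss = float(max(0.0, np.max(-dom * sys_vals)))

    rate = np.gradient(y, t)
    n_dia = int(np.sum(t > end_systole))
    if n_dia < 3:
        flags.append("fewer than 3 diastolic samples: rate indices undefined")
        srmax = sre = sra = sre_a = float("nan")
    else:
        srmax = float(dom * np.max(dom * rate[sys_mask])) if sys_mask.any() else float("nan")
        mid_dia = end_systole + (1.0 - end_systole) / 2.0
        early = (t > end_systole) & (t <= mid_dia)
        late = t > mid_dia
        sre = float(rate[early][np.argmax(-dom * rate[early])]) if early.any() else float("nan")
        sra = float(rate[late][np.argmax(-dom * rate[late])]) if late.any() else float("nan")
        sre_a = sre / sra if (np.isfinite(sra) and sra != 0) else float("nan")

    return StrainIndices(es=es, ees=ees, epost=epost, emax=emax, tpeak=tpeak,
                         tpeak_si=tpeak, psi=float(psi), srmax=srmax, sre=sre,
                         sra=sra, sre_a=sre_a, ss=ss,
                         end_systole=float(end_systole), flags=tuple(flags))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(stack: TaggedFrameStack, tif_path, geom_path):
    tifffile.imwrite(tif_path, stack.frames.astype(np.float32))
    geom = {
        "pixel_spacing_mm": stack.pixel_spacing,
        "frame_times": stack.frame_times.tolist(),
        "tag_wavevectors_cycles_per_mm": stack.tag_wavevectors.tolist(),
    }
    with open(geom_path, "w") as fh:
        json.dump(geom, fh, indent=1)


def read_stack(tif_path, geom_path) -> TaggedFrameStack:
    frames = tifffile.imread(tif_path)
    with open(geom_path) as fh:
        geom = json.load(fh)
    return TaggedFrameStack(
        frames=np.asarray(frames, dtype=float),
        pixel_spacing=float(geom["pixel_spacing_mm"]),
        frame_times=np.asarray(geom["frame_times"], dtype=float),
        tag_wavevectors=np.asarray(geom["tag_wavevectors_cycles_per_mm"], dtype=float),
    )
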