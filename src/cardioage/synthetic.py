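"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Each generator is a pure function of its config (which carries the seed):
identical configs give identical outputs.  All randomness flows from the
single seed through ``numpy.random.SeedSequence`` spawning, one child
stream per independent purpose, so adding noise to one output never
perturbs another.

The defaults emulate the study conditions: ~22-60 cine frames per cardiac
cycle with FVB-like volumes and phase fractions; a 192x192, 30x30 mm
tagged acquisition with a 0.6 mm tag period and 0.2 mm line width; a
54,532-gene negative-binomial count matrix over genotype x age groups with
planted ageing- and HF-dependent differential-expression sets; ellipse/
annulus capillary masks with an exact-fraction collagen paint; and linear
fluorescence kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw as skdraw

from .assays import KineticTrace
from .cycle import TimeVolumeCurve
from .harp import TaggedFrameStack
from .transcriptome import CountMatrix

__all__ = [
    "CycleSimConfig",
    "TagSimConfig",
    "CountSimConfig",
    "MaskSimConfig",
    "PlantedSet",
    "TruthRecord",
    "Deformation",
    "Identity",
    "Translation",
    "UniformStretch",
    "RadialStretch",
    "gen_time_volume_curve",
    "gen_tagged_sequence",
    "gen_count_matrix",
    "gen_histology_masks",
    "gen_kinetic_trace",
]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one generator call, serialisable to JSON."""

    generator: str
    params: dict

    def to_json(self) -> str:
        return json.dumps({"generator": self.generator, "params": self.params},
                          sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TruthRecord":
        d = json.loads(s)
        return cls(generator=d["generator"], params=d["params"])

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


# ---------------------------------------------------------------------------
# Time-volume curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleSimConfig:
    """LV time-volume-curve phantom.

    Defaults follow the wild-type FVB condition: EDV 53 ul, ESV 15 ul,
    R-R 123 ms (HR ~488 bpm) and phase fractions (IVC, ejection, IVR,
    filling) = (0.10, 0.30, 0.25, 0.35) of R-R.  ``e_peak``/``a_peak``
    (ul/s) switch the filling phase to a biphasic early/atrial pattern.
    """

    edv: float = 53.0               # ul
    esv: float = 15.0               # ul
    phase_fractions: tuple = (0.10, 0.30, 0.25, 0.35)
    rr: float = 123.0               # ms
    hr: float | None = None         # bpm, derived from rr when omitted
    n_frames: int = 60
    noise_sd: float = 1.0           # ul
    e_peak: float | None = None     # ul/s
    a_peak: float | None = None     # ul/s
    seed: int = 0

    def __post_init__(self):
        pf = tuple(float(f) for f in self.phase_fractions)
        if len(pf) != 4 or any(f <= 0 for f in pf):
            raise ValueError("phase_fractions must be 4 positive fractions")
        if abs(sum(pf) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if not (self.edv > self.esv > 0):
            raise ValueError("need edv > esv > 0")
        if self.n_frames < 16:
            raise ValueError("need n_frames >= 16")
        if (self.e_peak is None) != (self.a_peak is None):
            raise ValueError("e_peak and a_peak must be given together")
        object.__setattr__(self, "phase_fractions", pf)


def _biphasic_fill_volume(tau, ft, sv, e_peak, a_peak):
    """Cumulative volume gained during filling at time ``tau`` (ms) after
    filling onset: dV/dt is two triangular pulses (E then A) each of width
    ft/2, with peak heights scaled by a common factor so the total fill
    equals SV (the E/A peak ratio is preserved exactly)."""
    w = ft / 2.0
    scale = sv / (0.5 * w * (e_peak + a_peak))
    pe, pa = e_peak * scale, a_peak * scale

    def tri_integral(x, width, peak):
        # integral of a symmetric triangle of given base width and peak
        x = np.clip(x, 0.0, width)
        half = width / 2.0
        up = np.minimum(x, half)
        dn = np.clip(x - half, 0.0, half)
        return peak / half * up ** 2 / 2.0 + peak * dn - peak / half * dn ** 2 / 2.0

    return tri_integral(tau, w, pe) + tri_integral(tau - w, w, pa), (pe, pa)


def gen_time_volume_curve(config: CycleSimConfig):
    """Piecewise-linear (optionally biphasic-filling) TVC plus truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    f_ivc, f_ej, f_ivr, f_fill = config.phase_fractions
    rr, edv, esv = config.rr, config.edv, config.esv
    sv = edv - esv
    b1, b2, b3 = f_ivc, f_ivc + f_ej, f_ivc + f_ej + f_ivr
    t1, t2, t3 = b1 * rr, b2 * rr, b3 * rr

    times = np.arange(config.n_frames) * rr / config.n_frames
    vol = np.empty_like(times)
    ivc = times < t1
    ej = (times >= t1) & (times < t2)
    ivr = (times >= t2) & (times < t3)
    fill = times >= t3
    vol[ivc] = edv
    vol[ej] = edv - sv * (times[ej] - t1) / (t2 - t1)
    vol[ivr] = esv
    biphasic = config.e_peak is not None
    if biphasic:
        # peaks given in ul/s; the fill integral works in ms
        gained, (pe_ms, pa_ms) = _biphasic_fill_volume(
            times[fill] - t3, rr - t3, sv,
            config.e_peak / 1000.0, config.a_peak / 1000.0)
        vol[fill] = esv + gained
        e_eff, a_eff = pe_ms * 1000.0, pa_ms * 1000.0
    else:
        vol[fill] = esv + sv * (times[fill] - t3) / (rr - t3)
        e_eff = a_eff = None

    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, vol.shape)
        vol = np.maximum(vol, 1e-3)     # volumes stay positive

    tvc = TimeVolumeCurve(times=times, volumes=vol, rr=rr, hr=config.hr)
    truth = TruthRecord("gen_time_volume_curve", _jsonable({
        "edv": edv, "esv": esv, "sv": sv,
        "breakpoints": [b1, b2, b3, 1.0],
        "breakpoint_frames": [b1 * config.n_frames, b2 * config.n_frames,
                              b3 * config.n_frames],
        "slopes_ul_per_ms": [0.0, -sv / (t2 - t1), 0.0,
                             None if biphasic else sv / (rr - t3)],
        "ef_percent": 100.0 * sv / edv,
        "phase_fractions": list(config.phase_fractions),
        "rr": rr, "n_frames": config.n_frames, "noise_sd": config.noise_sd,
        "e_peak_eff": e_eff, "a_peak_eff": a_eff,
        "ea_ratio": (e_eff / a_eff) if biphasic else None,
        "seed": config.seed,
    }))
    return tvc, truth


# ---------------------------------------------------------------------------
# Tagged phantoms
# ---------------------------------------------------------------------------

class Deformation:
    """Spatial -> material map, scaled by s in [0, 1] across frames."""

    def material(self, yc, xc, s):      # coordinates about the image centre, mm
        raise NotImplementedError

    def describe(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Identity(Deformation):
    def material(self, yc, xc, s):
        return yc, xc

    def describe(self):
        return {"kind": "identity"}


@dataclass(frozen=True)
class Translation(Deformation):
    """Rigid translation by (t_row, t_col) mm at full scale."""

    t_row: float
    t_col: float

    def material(self, yc, xc, s):
        return yc - s * self.t_row, xc - s * self.t_col

    def describe(self):
        return {"kind": "translation", "t_row": self.t_row, "t_col": self.t_col}


@dataclass(frozen=True)
class UniformStretch(Deformation):
    """Uniform stretch by (lambda_r, lambda_c) about the centre."""

    lambda_r: float
    lambda_c: float

    def __post_init__(self):
        if self.lambda_r <= 0 or self.lambda_c <= 0:
            raise ValueError("stretch ratios must be positive (no folding)")

    def material(self, yc, xc, s):
        lr = 1.0 + s * (self.lambda_r - 1.0)
        lc = 1.0 + s * (self.lambda_c - 1.0)
        return yc / lr, xc / lc

    def describe(self):
        return {"kind": "uniform_stretch", "lambda_r": self.lambda_r,
                "lambda_c": self.lambda_c}


@dataclass(frozen=True)
class RadialStretch(Deformation):
    """Analytic radial profile: material radius R = r / (1 + amp*exp(-(r/sigma)^2))."""

    amp: float
    sigma_mm: float

    def __post_init__(self):
        # folding check: spatial radius must be monotone in material radius
        r = np.linspace(1e-6, 10 * self.sigma_mm, 4096)
        rmat = r / (1.0 + self.amp * np.exp(-(r / self.sigma_mm) ** 2))
        if np.any(np.diff(rmat) <= 0):
            raise ValueError("radial profile folds (negative Jacobian)")

    def material(self, yc, xc, s):
        r = np.hypot(yc, xc)
        shrink = 1.0 + s * self.amp * np.exp(-(r / self.sigma_mm) ** 2)
        return yc / shrink, xc / shrink

    def describe(self):
        return {"kind": "radial", "amp": self.amp, "sigma_mm": self.sigma_mm}


@dataclass(frozen=True)
class TagSimConfig:
    """SPAMM tag-grid phantom: 30x30 mm FOV, 192x192 matrix, 0.6 mm tag
    period, 0.2 mm line width by default."""

    fov_mm: float = 30.0
    matrix: int = 192
    tag_span_mm: float = 0.6
    tag_line_mm: float = 0.2
    deformation: Deformation = field(default_factory=Identity)
    n_frames: int = 2
    noise_sd: float = 0.0
    tag_depth: float = 0.8
    seed: int = 0

    def __post_init__(self):
        cycles = self.fov_mm / self.tag_span_mm
        if abs(cycles - round(cycles)) > 1e-6:
            raise ValueError("fov_mm / tag_span_mm must be an integer "
                             "(periodic wrap at the edges)")
        if self.matrix % 2:
            raise ValueError("matrix must be even")
        if not 0 < self.tag_line_mm < self.tag_span_mm:
            raise ValueError("need 0 < tag_line_mm < tag_span_mm")


def _tag_profile_coeffs(span, line, n_harmonics, n_quad=4096):
    """Fourier cosine coefficients b_0..b_M of the raised-cosine-squared tag
    line bump (width ``line``, period ``span``), computed by quadrature."""
    u = (np.arange(n_quad) + 0.5) / n_quad * span - span / 2.0
    bump = np.where(np.abs(u) <= line / 2.0,
                    np.cos(np.pi * u / line) ** 2, 0.0)
    m = np.arange(n_harmonics + 1)
    cosines = np.cos(2.0 * np.pi * m[:, None] * u[None, :] / span)
    return (bump[None, :] * cosines).mean(axis=1)       # b_m, b_0 = mean


def _tag_profile(u, span, depth, coeffs):
    """Band-limited tag line profile: 1 - depth * (truncated Fourier series
    of the raised-cosine-squared bump).  Truncation at the acquisition
    Nyquist mimics the k-space coverage of the scanner, so the sampled
    phantom is alias-free and its harmonics are spectral deltas."""
    series = np.full_like(u, coeffs[0])
    for m in range(1, len(coeffs)):
        series = series + 2.0 * coeffs[m] * np.cos(2.0 * np.pi * m * u / span)
    return 1.0 - depth * series


def gen_tagged_sequence(config: TagSimConfig):
    """Tagged frame stack: frame 0 an undeformed square tag grid, later
    frames the grid advected by the deformation ramped linearly from 0
    (frame 0) to full (last frame); Gaussian intensity noise added last."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.matrix
    ps = config.fov_mm / n
    coord = (np.arange(n) + 0.5) * ps - config.fov_mm / 2.0
    yc, xc = np.meshgrid(coord, coord, indexing="ij")

    # keep tag harmonics below the acquisition Nyquist (with headroom for
    # compressive deformations shifting them up)
    cycles = config.fov_mm / config.tag_span_mm
    max_h = max(1, int((n / 2 - 1) / (1.5 * cycles)))
    coeffs = _tag_profile_coeffs(config.tag_span_mm, config.tag_line_mm, max_h)

    frames = np.empty((config.n_frames, n, n))
    scales = (np.arange(config.n_frames) / max(config.n_frames - 1, 1)
              if config.n_frames > 1 else np.zeros(1))
    for t, s in enumerate(scales):
        ym, xm = config.deformation.material(yc, xc, s)
        frames[t] = (_tag_profile(ym, config.tag_span_mm, config.tag_depth, coeffs)
                     * _tag_profile(xm, config.tag_span_mm, config.tag_depth, coeffs))
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, frames.shape)

    k = 1.0 / config.tag_span_mm
    stack = TaggedFrameStack(
        frames=frames, pixel_spacing=ps,
        frame_times=np.arange(config.n_frames) / config.n_frames,
        tag_wavevectors=np.array([[k, 0.0], [0.0, k]]))
    truth = TruthRecord("gen_tagged_sequence", _jsonable({
        "deformation": config.deformation.describe(),
        "frame_scales": scales,
        "tag_cycles_per_fov": config.fov_mm / config.tag_span_mm,
        "fov_mm": config.fov_mm, "matrix": config.matrix,
        "tag_span_mm": config.tag_span_mm, "tag_line_mm": config.tag_line_mm,
        "noise_sd": config.noise_sd, "seed": config.seed,
    }))
    return stack, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSet:
    """A named planted DE gene set: ``n_genes`` genes get a 2^logfc mean
    shift in every (genotype, age) group listed in ``groups``."""

    name: str
    n_genes: int
    logfc: float
    groups: tuple               # of (genotype, age)

    def __post_init__(self):
        if not np.isfinite(self.logfc):
            raise ValueError("planted logFC must be finite")
        object.__setattr__(self, "groups", tuple((g, a) for g, a in self.groups))


def default_planted_sets(n_per_set: int = 50, logfc: float = 2.0):
    """Planted sets emulating the study's signature structure: an
    aged-only set (wild-type 14 m only), an ageing set (wild-type 8-14 m),
    a persistent HF set (transgenic at every age) and an age-specific HF
    set (transgenic 12 m only)."""
    return (
        PlantedSet("aged_only", n_per_set, logfc, (("FVB", 14),)),
        PlantedSet("ageing", n_per_set, logfc,
                   (("FVB", 8), ("FVB", 10), ("FVB", 12), ("FVB", 14))),
        PlantedSet("hf_persistent", n_per_set, logfc,
                   tuple(("Tgaq44", a) for a in (4, 6, 8, 10, 12, 14))),
        PlantedSet("hf_age_specific", n_per_set, logfc, (("Tgaq44", 12),)),
    )


@dataclass(frozen=True)
class CountSimConfig:
    """Negative-binomial count phantom over a genotype x age design.

    Defaults: 54,532 reference genes; FVB and Tgaq44 at 4-14 months,
    n = 5 per group; library sizes lognormal around 2e7; NB dispersion
    0.05 (variance = mu + phi*mu^2).
    """

    n_genes: int = 54532
    groups: tuple = tuple((g, a, 5) for g in ("FVB", "Tgaq44")
                          for a in (4, 6, 8, 10, 12, 14))
    lib_size_mean: float = 2e7
    lib_size_sigma: float = 0.15        # lognormal sigma of library sizes
    nb_dispersion: float = 0.05
    expr_sigma: float = 3.0             # lognormal sigma of baseline expression
    planted_sets: tuple = field(default_factory=default_planted_sets)
    planted_min_cpm: float = 5.0        # planted genes drawn above this baseline cpm
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for g, a, n in self.groups:
            if n < 2:
                raise ValueError("each group needs n >= 2")
        total = sum(ps.n_genes for ps in self.planted_sets)
        if total > self.n_genes:
            raise ValueError("planted sets exceed the gene count")


def gen_count_matrix(config: CountSimConfig):
    """NB-distributed counts with planted per-group mean shifts of 2^logFC."""
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_lib, rng_counts, rng_pick = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    genes = np.array([f"gene{i:05d}" for i in range(config.n_genes)])
    baseline = rng_base.lognormal(mean=0.0, sigma=config.expr_sigma,
                                  size=config.n_genes)
    baseline /= baseline.sum()

    # disjoint planted memberships, drawn without replacement from genes
    # expressed above the floor (a shift planted on an undetectable gene
    # could never be recovered and would not be a meaningful truth)
    eligible = np.nonzero(baseline * 1e6 >= config.planted_min_cpm)[0]
    n_planted = sum(ps.n_genes for ps in config.planted_sets)
    if eligible.size < n_planted:
        raise ValueError(
            f"only {eligible.size} genes pass the planted-set expression floor "
            f"(cpm >= {config.planted_min_cpm}); need {n_planted}")
    order = rng_pick.permutation(eligible)
    memberships = {}
    pos = 0
    for ps in config.planted_sets:
        memberships[ps.name] = sorted(order[pos:pos + ps.n_genes].tolist())
        pos += ps.n_genes

    sample_ids, genotypes, ages = [], [], []
    for g, a, n in config.groups:
        for r in range(n):
            sample_ids.append(f"{g}_{a}m_r{r + 1}")
            genotypes.append(g)
            ages.append(a)
    n_samples = len(sample_ids)
    lib_sizes = rng_lib.lognormal(np.log(config.lib_size_mean),
                                  config.lib_size_sigma, n_samples)

    # per-group fold-change multipliers on the planted genes
    log2fc = np.zeros((config.n_genes, n_samples))
    for ps in config.planted_sets:
        idx = memberships[ps.name]
        for j, (g, a) in enumerate(zip(genotypes, ages)):
            if (g, a) in ps.groups:
                log2fc[idx, j] += ps.logfc
    mu = baseline[:, None] * lib_sizes[None, :] * (2.0 ** log2fc)

    phi = config.nb_dispersion
    if phi > 0:
        lam = rng_counts.gamma(shape=1.0 / phi, scale=phi * mu)
    else:
        lam = mu
    counts = rng_counts.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                            columns=sample_ids),
        samples=pd.DataFrame({"genotype": genotypes, "age": ages},
                             index=pd.Index(sample_ids, name="sample")))
    truth = TruthRecord("gen_count_matrix", _jsonable({
        "memberships": {k: [genes[i] for i in v] for k, v in memberships.items()},
        "planted": [{"name": ps.name, "logfc": ps.logfc,
                     "groups": list(ps.groups)} for ps in config.planted_sets],
        "lib_sizes": lib_sizes,
        "nb_dispersion": phi,
        "n_genes": config.n_genes,
        "seed": config.seed,
    }))
    return cm, truth


# ---------------------------------------------------------------------------
# Histology masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSimConfig:
    """Capillary/collagen mask phantom.

    Capillaries are non-overlapping ellipse annuli; the cutting-plane class
    mix (longitudinal/oblique/transverse) controls the aspect-ratio draw;
    collagen is painted as smoothed-noise blobs thresholded to the target
    fraction, enforced exactly by final pixel selection.
    """

    shape: tuple = (512, 512)
    pixel_size: float = 1.0             # um
    n_capillaries: int = 30
    orientation_mix: tuple = (0.2, 0.4, 0.4)    # longitudinal, oblique, transverse
    radius_mean: float = 4.0            # px, minor semi-axis
    radius_sd: float = 1.0
    lumen_fraction: float = 0.7         # probability a capillary has a lumen
    lumen_scale: float = 0.5            # lumen semi-axes relative to the wall
    collagen_fraction: float = 0.0496   # of (collagen + myocardium)
    min_separation: int = 3             # px between capillary walls
    max_tries: int = 2000
    seed: int = 0

    def __post_init__(self):
        mix = tuple(float(f) for f in self.orientation_mix)
        if len(mix) != 3 or any(f < 0 for f in mix) or abs(sum(mix) - 1) > 1e-9:
            raise ValueError("orientation_mix must be 3 non-negative fractions summing to 1")
        if not 0 <= self.lumen_fraction <= 1 or not 0 <= self.collagen_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        object.__setattr__(self, "orientation_mix", mix)


_AR_RANGES = {"longitudinal": (3.0, 6.0), "oblique": (1.6, 2.8),
              "transverse": (1.0, 1.4)}


def gen_histology_masks(config: MaskSimConfig):
    """Labelled capillary-wall mask, lumen mask, collagen and myocardium
    masks, plus a truth table of per-component class/areas/distances."""
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_coll = [np.random.default_rng(s) for s in ss.spawn(2)]
    h, w = config.shape

    walls = np.zeros((h, w), dtype=np.int32)
    lumen = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)
    classes = ["longitudinal", "oblique", "transverse"]
    records = []
    comp_pixels = {}
    label = 0
    tries = 0
    while label < config.n_capillaries:
        if tries >= config.max_tries:
            raise RuntimeError(
                f"could not place {config.n_capillaries} non-overlapping "
                f"capillaries in {config.max_tries} tries")
        tries += 1
        cls = classes[rng_place.choice(3, p=config.orientation_mix)]
        ar = rng_place.uniform(*_AR_RANGES[cls])
        minor = max(2.0, rng_place.normal(config.radius_mean, config.radius_sd))
        major = minor * ar
        if 2 * (major + 2) >= min(h, w):
            continue            # shape cannot fit; costs one try
        angle = rng_place.uniform(0, np.pi)
        r0 = rng_place.uniform(major + 2, h - major - 2)
        c0 = rng_place.uniform(major + 2, w - major - 2)
        rr_px, cc_px = skdraw.ellipse(r0, c0, major, minor, shape=(h, w),
                                      rotation=angle)
        cand = np.zeros((h, w), dtype=bool)
        cand[rr_px, cc_px] = True
        grown = ndi.binary_dilation(cand, iterations=config.min_separation)
        if (grown & occupied).any():
            continue
        has_lumen = rng_place.random() < config.lumen_fraction
        lum = np.zeros((h, w), dtype=bool)
        if has_lumen:
            lr, lc = skdraw.ellipse(r0, c0, major * config.lumen_scale,
                                    minor * config.lumen_scale, shape=(h, w),
                                    rotation=angle)
            lum[lr, lc] = True
            lum &= cand
        wall = cand & ~lum
        label += 1
        walls[wall] = label
        lumen |= lum
        occupied |= cand
        comp_pixels[label] = np.argwhere(wall)
        records.append({"id": label, "class": cls,
                        "wall_area_px": int(wall.sum()),
                        "lumen_area_px": int(lum.sum()),
                        "center": [float(r0), float(c0)],
                        "aspect_ratio": float(ar)})

    # nearest edge-to-edge distances among oblique/transverse components
    inplane = [r["id"] for r in records if r["class"] in ("oblique", "transverse")]
    trees = {i: cKDTree(comp_pixels[i]) for i in inplane}
    dist = {}
    for i in inplane:
        best = np.inf
        for j in inplane:
            if i != j:
                best = min(best, float(trees[j].query(comp_pixels[i], k=1)[0].min()))
        dist[i] = best if np.isfinite(best) else None
    for r in records:
        r["nearest_edge_px"] = dist.get(r["id"])

    # collagen: smooth noise field thresholded to the exact target fraction
    tissue = ~occupied
    n_tissue = int(tissue.sum())
    n_coll = int(round(config.collagen_fraction * n_tissue))
    fieldmap = ndi.gaussian_filter(rng_coll.normal(size=(h, w)), sigma=8.0)
    vals = fieldmap[tissue]
    collagen = np.zeros((h, w), dtype=bool)
    if n_coll > 0:
        cutoff = np.partition(vals, -n_coll)[-n_coll]
        sel = tissue & (fieldmap >= cutoff)
        # resolve threshold ties to hit the count exactly
        extra = int(sel.sum()) - n_coll
        if extra > 0:
            ties = np.argwhere(sel & (fieldmap == cutoff))
            for r_, c_ in ties[:extra]:
                sel[r_, c_] = False
        collagen = sel
    myocardium = tissue & ~collagen

    truth = TruthRecord("gen_histology_masks", _jsonable({
        "components": records,
        "collagen_fraction": n_coll / max(n_tissue, 1),
        "collagen_px": int(collagen.sum()),
        "myocardium_px": int(myocardium.sum()),
        "pixel_size": config.pixel_size,
        "seed": config.seed,
    }))
    return walls, lumen, collagen, myocardium, truth


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------

def gen_kinetic_trace(slope: float, intercept: float = 100.0,
                      duration: float = 30.0, n_points: int = 31,
                      noise_sd: float = 0.0, seed: int = 0):
    """Linear fluorescence kinetic (RFU vs minutes) plus Gaussian noise."""
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.linspace(0.0, duration, n_points)
    f = intercept + slope * t
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, f.shape)
    trace = KineticTrace(times=t, fluorescence=f)
    truth = TruthRecord("gen_kinetic_trace", _jsonable({
        "slope": slope, "intercept": intercept, "duration": duration,
        "n_points": n_points, "noise_sd": noise_sd, "seed": seed,
    }))
    return trace, truth
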