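"""Closed-form perfusion and enzyme-assay computations.

ACE (angiotensin-converting enzyme) activity is obtained from the linear
slope of a fluorogenic substrate-conversion kinetic read in a plate reader:

    activity = slope / F_1umol * Y

where ``F_1umol`` is the fluorescence intensity corresponding to 1 umol of
converted substrate (an instrument calibration that must be supplied) and
``Y`` is the dilution factor of the assayed matrix (33.33 for plasma, 10
for tissue homogenates).  Plasma activity is reported in U/L, tissue
activity in U/g.

Coronary-flow responses from the retrogradely perfused (Langendorff) heart
are summarised by the hyperaemic flow increment dCF = peak - baseline
(optionally normalised to ventricle mass) and the coronary flow reserve
peak/baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KineticTrace",
    "ACEResult",
    "FlowResponse",
    "DILUTION_FACTORS",
    "fit_kinetic_slope",
    "ace_activity",
    "flow_response",
]

#: Matrix-specific dilution factors Y of the ACE activity formula.
DILUTION_FACTORS = {"plasma": 33.33, "tissue": 10.0}

#: Units the activity is reported in, per matrix type.
ACTIVITY_UNITS = {"plasma": "U/L", "tissue": "U/g"}


@dataclass(frozen=True)
class KineticTrace:
    """A fluorescence-vs-time kinetic read.

    times are in minutes, fluorescence in relative fluorescence units (RFU).
    """

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fluorescence must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValueError("a kinetic trace needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class ACEResult:
    slope: float            # RFU/min
    f_1umol: float          # RFU per umol converted substrate
    dilution_y: float       # dimensionless
    activity: float         # U/L (plasma) or U/g (tissue)
    matrix_type: str
    units: str


@dataclass(frozen=True)
class FlowResponse:
    baseline_cf: float          # ml/min
    peak_cf: float              # ml/min
    ventricle_mass: float       # g
    delta_cf: float             # ml/min
    delta_cf_per_g: float       # ml/min/g
    reserve: float              # dimensionless, peak/baseline
    warnings: tuple = field(default_factory=tuple)


def fit_kinetic_slope(trace: KineticTrace, linear_range_curvature: float | None = None):
    """Ordinary least-squares slope of a kinetic trace, with standard error.

    Parameters
    ----------
    trace
        The fluorescence kinetic.
    linear_range_curvature
        If given, points after the running second difference (normalised to
        the initial rate) first exceeds this threshold are dropped, trimming
        the read to its linear range.  Off by default: the assay protocol
        records the plain linear slope.

    Returns
    -------
    (slope, stderr) in RFU/min.
    """
    t, f = trace.times, trace.fluorescence
    if linear_range_curvature is not None and t.size >= 4:
        d2 = np.abs(np.diff(f, 2)) / np.maximum(np.abs(np.diff(f[:2])[0]), 1e-12)
        bad = np.nonzero(d2 > linear_range_curvature)[0]
        if bad.size:
            stop = max(3, bad[0] + 2)
            t, f = t[:stop], f[:stop]
    res = stats.linregress(t, f)
    return float(res.slope), float(res.stderr)


def ace_activity(slope: float, f_1umol: float, matrix_type: str,
                 dilution_y: float | None = None) -> ACEResult:
    """ACE activity from a kinetic slope: activity = slope / f_1umol * Y."""
    if f_1umol <= 0:
        raise ValueError("f_1umol (fluorescence of 1 umol converted substrate) must be > 0")
    if matrix_type not in DILUTION_FACTORS:
        raise ValueError(f"unknown matrix_type {matrix_type!r}; expected one of "
                         f"{sorted(DILUTION_FACTORS)}")
    y = DILUTION_FACTORS[matrix_type] if dilution_y is None else float(dilution_y)
    activity = slope / f_1umol * y
    return ACEResult(slope=float(slope), f_1umol=float(f_1umol), dilution_y=y,
                     activity=float(activity), matrix_type=matrix_type,
                     units=ACTIVITY_UNITS[matrix_type])


def flow_response(baseline_cf: float, peak_cf: float, ventricle_mass: float) -> FlowResponse:
    """Hyperaemic coronary-flow response of an isolated perfused heart.

    delta_cf = peak - baseline (ml/min), also normalised to ventricle mass;
    reserve = peak / baseline.  A reserve below 1 (peak under baseline) is
    physiologically suspicious and is flagged rather than rejected.
    """
    if baseline_cf <= 0:
        raise ValueError("baseline coronary flow must be > 0")
    if ventricle_mass <= 0:
        raise ValueError("ventricle mass must be > 0")
    delta = peak_cf - baseline_cf
    reserve = peak_cf / baseline_cf
    warns = ()
    if peak_cf < baseline_cf:
        warns = ("peak coronary flow below baseline: reserve < 1",)
    return FlowResponse(baseline_cf=float(baseline_cf), peak_cf=float(peak_cf),
                        ventricle_mass=float(ventricle_mass), delta_cf=float(delta),
                        delta_cf_per_g=float(delta / ventricle_mass),
                        reserve=float(reserve), warnings=warns)
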