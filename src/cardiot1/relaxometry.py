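"""Voxelwise and sample-wise T1/R1 estimation.

Implements the spoiled-gradient-echo (SPGR) signal model, variable-flip-angle
(VFA/DESPOT1) T1 fitting, inversion-recovery snapshot-FLASH T1 fitting with
Look-Locker correction, rate-map conversion, ΔR1 maps, and in vitro
relaxivity calibration by linear regression of R1 on concentration.

Units are explicit throughout: T1 in milliseconds, R1 in s⁻¹ (so that
R1 = 1000 / T1_ms), relaxivity in mM⁻¹ s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ImageSeries",
    "RelaxationMap",
    "RelaxivityFit",
    "IRFitResult",
    "spgr_signal",
    "fit_t1_vfa",
    "fit_t1_ir",
    "r1_map",
    "delta_r1",
    "calibrate_relaxivity",
]

T1_UNIT = "ms"
R1_UNIT = "s^-1"


@dataclass
class ImageSeries:
    """Stack of 3D magnitude volumes indexed by flip angle or inversion time.

    Parameters
    ----------
    volumes : ndarray, shape (n, nx, ny, nz)
        One magnitude volume per entry of ``axis_values``.
    axis_meaning : {"flip_angle", "inversion_time"}
        What the leading axis indexes.
    axis_values : array-like
        Flip angles in degrees or inversion times in ms, strictly increasing.
    tr_ms, te_ms : float
        Repetition and echo time (ms); TR > TE > 0.
    spacing_mm : tuple of float
        Voxel size along each spatial axis.
    """

    volumes: np.ndarray
    axis_meaning: str
    axis_values: np.ndarray
    tr_ms: float
    te_ms: float = 2.0
    spacing_mm: tuple = (0.1, 0.1, 0.5)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        if self.axis_meaning not in ("flip_angle", "inversion_time"):
            raise ValueError(f"unknown axis_meaning {self.axis_meaning!r}")
        if self.volumes.ndim < 2:
            raise ValueError("volumes must be a stack of >=1D images")
        if len(self.axis_values) != self.volumes.shape[0]:
            raise ValueError("axis_values length must match number of volumes")
        if len(self.axis_values) and np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis_values must be strictly increasing")
        if not (self.tr_ms > self.te_ms > 0):
            raise ValueError("require TR > TE > 0")

    @property
    def shape(self):
        return self.volumes.shape[1:]


@dataclass
class RelaxationMap:
    """Voxelwise relaxation field (T1 in ms, or R1 in s⁻¹).

    ``unit`` is an explicit tag ("ms" or "s^-1"); conversions go through
    :func:`r1_map` only.  ``valid_mask`` marks voxels whose fit converged
    inside bounds; all statistics downstream restrict to it.
    """

    value: np.ndarray
    unit: str = T1_UNIT
    m0: np.ndarray | None = None
    fit_r2: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.unit not in (T1_UNIT, R1_UNIT):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.value) & (self.value > 0)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.value.shape:
            raise ValueError("valid_mask shape mismatch")


@dataclass
class RelaxivityFit:
    """Linear calibration R1 = baseline + r1 · [CA]."""

    r1_relaxivity: float  # mM^-1 s^-1
    r1_baseline: float  # s^-1
    r_squared: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    n: int = 0


@dataclass
class IRFitResult:
    """Three-parameter |A − B·exp(−TI/T1*)| fit with Look-Locker correction."""

    t1_ms: float
    t1_star_ms: float
    a: float
    b: float
    fit_r2: float
    converged: bool


def spgr_signal(m0, t1_ms, tr_ms, alpha_deg):
    """Spoiled gradient-echo steady-state magnitude.

    S = m0 · sin α · (1 − E1) / (1 − E1 · cos α),  E1 = exp(−TR/T1).

    All arguments broadcast; T1 and TR in ms, α in degrees.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    alpha_deg = np.asarray(alpha_deg, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if np.any((alpha_deg <= 0) | (alpha_deg >= 180)):
        raise ValueError("alpha_deg must lie in (0, 180)")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def _despot1_linear(signals, sin_a, tan_a, tr_ms):
    """Linearized DESPOT1: regress S/sin α on S/tan α; slope = E1.

    signals: (n_angles, n_vox). Returns (t1_ms, m0) arrays with NaN where
    the linearization is degenerate.
    """
    y = signals / sin_a[:, None]
    x = signals / tan_a[:, None]
    n = signals.shape[0]
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
        ok = (slope > 0) & (slope < 1)
        t1 = np.where(ok, -tr_ms / np.log(np.clip(slope, 1e-12, 1 - 1e-12)), np.nan)
        m0 = np.where(ok, intercept / (1.0 - np.clip(slope, 1e-12, 1 - 1e-12)), np.nan)
    return t1, m0


def fit_t1_vfa(
    series: ImageSeries,
    t1_bounds=(100.0, 6000.0),
    refine: bool = True,
    mask: np.ndarray | None = None,
    xtol: float = 1e-10,
    max_nfev: int = 200,
) -> RelaxationMap:
    """Variable-flip-angle T1/M0 map from an SPGR flip-angle series.

    Per voxel the linearized DESPOT1 solution (regress S/sin α on S/tan α,
    T1 = −TR/ln slope) initializes a bounded nonlinear least-squares fit of
    the SPGR closed form; the linearization alone is fragile with only a few
    flip angles under noise.  Voxels that are all-zero, non-finite, or whose
    refined T1 pins at a bound are excluded from ``valid_mask`` (no
    exception is raised for them).

    The fit treats the magnitudes as Gaussian-noise observations of the
    SPGR signal; at low per-image SNR the Rician noise floor biases T1
    estimates (see the methods note), which is why acquisition-scale noise
    levels matter more than estimator choice here.

    ``mask`` (boolean, image-shaped) restricts fitting to tissue voxels —
    background voxels of noisy magnitude images are pure noise floor and
    fitting them costs far more time than it is worth.
    """
    if series.axis_meaning != "flip_angle":
        raise ValueError("series must be indexed by flip_angle")
    if len(series.axis_values) < 2:
        raise ValueError("need at least 2 flip angles")
    lo, hi = t1_bounds
    if not (0 < lo < hi):
        raise ValueError("invalid t1_bounds")

    shape = series.shape
    n_vox = int(np.prod(shape))
    signals = series.volumes.reshape(len(series.axis_values), n_vox)
    a_rad = np.deg2rad(series.axis_values)
    sin_a, tan_a = np.sin(a_rad), np.tan(a_rad)
    tr = series.tr_ms

    finite = np.isfinite(signals)
    fittable = (finite.sum(axis=0) >= 2) & (np.nanmax(np.abs(signals), axis=0) > 0)
    if mask is not None:
        if mask.shape != shape:
            raise ValueError("mask shape must match the image grid")
        fittable &= np.asarray(mask, dtype=bool).reshape(n_vox)

    t1_lin, m0_lin = _despot1_linear(np.where(finite, signals, 0.0), sin_a, tan_a, tr)

    t1 = np.full(n_vox, np.nan)
    m0 = np.full(n_vox, np.nan)
    r2 = np.full(n_vox, np.nan)
    valid = np.zeros(n_vox, dtype=bool)

    def model(params, s):
        return spgr_signal(params[1], params[0], tr, series.axis_values) - s

    for i in np.flatnonzero(fittable):
        s = signals[:, i]
        t1_0 = t1_lin[i]
        m0_0 = m0_lin[i]
        if not np.isfinite(t1_0):
            t1_0 = float(np.sqrt(lo * hi))
        t1_0 = float(np.clip(t1_0, lo, hi))
        if not (np.isfinite(m0_0) and m0_0 > 0):
            m0_0 = float(max(np.max(s), 1e-12) / max(np.max(sin_a), 1e-3))
        if refine:
            try:
                res = optimize.least_squares(
                    model,
                    x0=[t1_0, m0_0],
                    args=(s,),
                    bounds=([lo, 0.0], [hi, np.inf]),
                    xtol=xtol,
                    ftol=xtol,
                    gtol=xtol,
                    max_nfev=max_nfev,
                )
                t1_i, m0_i = res.x
                converged = bool(res.success)
            except Exception:  # numerical failure -> invalid voxel
                continue
        else:
            t1_i, m0_i, converged = t1_0, m0_0, True
        pred = spgr_signal(m0_i, t1_i, tr, series.axis_values)
        ss_res = float(np.sum((s - pred) ** 2))
        ss_tot = float(np.sum((s - s.mean()) ** 2))
        t1[i], m0[i] = t1_i, m0_i
        r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        margin = 1e-6 * (hi - lo)
        valid[i] = converged and (lo + margin < t1_i < hi - margin) and m0_i > 0

    return RelaxationMap(
        value=t1.reshape(shape),
        unit=T1_UNIT,
        m0=m0.reshape(shape),
        fit_r2=np.clip(r2, 0.0, 1.0).reshape(shape),
        valid_mask=valid.reshape(shape),
    )


def _ir_model(ti, a, b, t1_star):
    return a - b * np.exp(-ti / t1_star)


def fit_t1_ir(
    ti_ms,
    signal,
    look_locker_correction: bool = True,
) -> IRFitResult:
    """Inversion-recovery T1 from a magnitude snapshot-FLASH TI series.

    Fits the three-parameter model |A − B·exp(−TI/T1*)|.  Magnitude bias is
    handled by polarity restoration: samples before the candidate null point
    are sign-flipped and the signed exponential is fitted; candidate flip
    positions around the signal minimum are tried and the best residual wins.
    The Look-Locker apparent-time correction T1 = T1* · (B/A − 1) converts
    the readout-shortened recovery time back to true T1; it can be disabled
    for a conventional (unperturbed) inversion-recovery series.
    """
    ti = np.asarray(ti_ms, dtype=float)
    s = np.asarray(signal, dtype=float)
    order = np.argsort(ti)
    ti, s = ti[order], s[order]
    if ti.size < 4:
        raise ValueError("need at least 4 TI samples")
    if np.any(ti <= 0):
        raise ValueError("inversion times must be positive")

    i_min = int(np.argmin(np.abs(s)))
    candidates = sorted({max(0, i_min - 1), i_min, min(ti.size, i_min + 1), min(ti.size, i_min + 2)})

    best = None
    a0 = float(np.max(np.abs(s)))
    for k in candidates:
        signed = s.copy()
        signed[:k] *= -1.0
        # init from null-point heuristic: s(TI_null)=0 with B≈2A
        ti_null = ti[i_min]
        t1s0 = max(ti_null / np.log(2.0), ti[0] / 2.0)
        try:
            popt, _ = optimize.curve_fit(
                _ir_model,
                ti,
                signed,
                p0=[a0, 2.0 * a0, t1s0],
                maxfev=5000,
            )
        except Exception:
            continue
        resid = signed - _ir_model(ti, *popt)
        rss = float(np.sum(resid**2))
        if best is None or rss < best[0]:
            best = (rss, popt, signed)

    if best is None:
        return IRFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    rss, (a, b, t1_star), signed = best
    ss_tot = float(np.sum((signed - signed.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else (1.0 if rss == 0 else 0.0)
    converged = np.isfinite([a, b, t1_star]).all() and a > 0 and t1_star > 0
    if look_locker_correction:
        t1 = t1_star * (b / a - 1.0) if converged else np.nan
    else:
        t1 = t1_star
    if converged and t1 <= 0:
        converged = False
    return IRFitResult(float(t1), float(t1_star), float(a), float(b), float(np.clip(r2, 0, 1)), bool(converged))


def r1_map(relax: RelaxationMap) -> RelaxationMap:
    """Convert a T1 map (ms) to an R1 map (s⁻¹), or vice versa.

    R1 = 1000 / T1_ms, so the conversion is an involution.  Invalid voxels
    propagate unchanged.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(relax.valid_mask, 1000.0 / relax.value, np.nan)
    unit = R1_UNIT if relax.unit == T1_UNIT else T1_UNIT
    return RelaxationMap(
        value=value,
        unit=unit,
        m0=relax.m0,
        fit_r2=relax.fit_r2,
        valid_mask=relax.valid_mask.copy(),
    )


def delta_r1(pre: RelaxationMap, post: RelaxationMap) -> RelaxationMap:
    """Voxelwise ΔR1 = R1_post − R1_pre on the intersection of valid masks."""
    if pre.value.shape != post.value.shape:
        raise ValueError("pre and post maps are on different grids")
    if pre.unit != R1_UNIT or post.unit != R1_UNIT:
        raise ValueError("delta_r1 requires rate maps (unit 's^-1')")
    valid = pre.valid_mask & post.valid_mask
    value = np.where(valid, post.value - pre.value, np.nan)
    return RelaxationMap(value=value, unit=R1_UNIT, valid_mask=valid)


def calibrate_relaxivity(concentrations_mM, r1_s) -> RelaxivityFit:
    """In vitro relaxivity: OLS of R1 (s⁻¹) on concentration (mM).

    Concentration is the controlled variable in a phantom-tube calibration,
    so ordinary least squares is appropriate (unlike the in vivo comparison,
    where both axes carry error and Deming regression is used).
    """
    c = np.asarray(concentrations_mM, dtype=float)
    r1 = np.asarray(r1_s, dtype=float)
    if c.size != r1.size:
        raise ValueError("concentration and R1 arrays must have equal length")
    if c.size < 3:
        raise ValueError("need at least 3 calibration samples")
    if np.ptp(c) == 0:
        raise ValueError("concentrations must not all be equal")
    res = stats.linregress(c, r1)
    fitted = res.intercept + res.slope * c
    return RelaxivityFit(
        r1_relaxivity=float(res.slope),
        r1_baseline=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=r1 - fitted,
        n=int(c.size),
    )
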