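"""Digital left-ventricle phantom with known-truth relaxation and Gd maps.

The phantom is a stack of short-axis slices: an annular myocardium around a
blood pool, one solid apex slice, and an angular infarct sector with elevated
pre-contrast T1, concentrated contrast agent, and reduced systolic wall
thickening.  Tissue values are piecewise constant so regional statistics have
exact ground truths.  From the truth object the module synthesizes noisy SPGR
magnitude images at several flip angles, inversion-recovery snapshot-FLASH
tube series, and virtual ex vivo sector measurements (tissue mass and Gd mass
per angular sector, emulating ICP-MS of a cut mid-ventricular slice).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import GdMeasurement
from .relaxometry import ImageSeries, spgr_signal

__all__ = [
    "InfarctSector",
    "PhantomSpec",
    "PhantomTruth",
    "make_heart_phantom",
    "synthesize_vfa_images",
    "synthesize_ir_series",
    "virtual_icpms",
    "default_ti_list",
]

# Remote myocardium thickens by this factor of ED thickness at ES when the
# infarct_thickening_fraction is 1 (healthy): SWT = 65%.
HEALTHY_THICKENING = 0.65

GD_MOLAR_MASS_G_MOL = 157.25  # Gd
TISSUE_DENSITY_G_ML = 1.05  # myocardium specific gravity

BACKGROUND, BLOOD_POOL, MYOCARDIUM = 0, 1, 2

SECTOR_NAMES_4 = ("anterior", "septal", "posterior", "lateral")


@dataclass
class InfarctSector:
    """Angular extent of the lesion: center/width in degrees (grid angle
    convention: counterclockwise from +x, as viewed from the apex), and the
    inclusive range of LV slice indices it spans (None = all LV slices)."""

    center_angle_deg: float = 315.0  # anterolateral / inferolateral wall
    width_deg: float = 90.0
    slice_range: tuple | None = None


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of the digital heart.

    Radii in mm; T1 in ms; concentrations in mM; noise_sigma is the Rician
    noise scale as a fraction of M0.  Default tissue T1 values are the murine
    9.4 T day-1 post-infarct values (infarct 2030 ms, remote 1761 ms), blood
    ~2300 ms; default Gd levels put ΔR1 near 0.60 s⁻¹ in the lesion and
    0.15 s⁻¹ in remote tissue at the default in vivo relaxivity.
    """

    grid_shape: tuple = (64, 64, 12)
    voxel_size: tuple = (0.1, 0.1, 0.5)  # mm
    n_slices_lv: int = 10
    endo_radius_ed: float = 1.0
    epi_radius_ed: float = 1.8
    endo_radius_es: float = 0.5
    epi_radius_es: float = 1.82  # remote ES wall 1.32 mm = 1.65 x ED wall
    infarct_sector: InfarctSector = field(default_factory=InfarctSector)
    infarct_thickening_fraction: float = 0.1
    t1_remote_ms: float = 1761.0
    t1_infarct_ms: float = 2030.0
    t1_blood_ms: float = 2300.0
    gd_peak_mM: float = 0.566
    gd_background_mM: float = 0.142
    relaxivity_mM_s: float = 1.06  # true in vivo r1 used to derive post maps
    noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.infarct_sector, (tuple, list)):
            self.infarct_sector = InfarctSector(*self.infarct_sector)
        for name in ("endo_radius_ed", "epi_radius_ed", "endo_radius_es", "epi_radius_es"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epi_radius_ed <= self.endo_radius_ed:
            raise ValueError("epi_radius_ed must exceed endo_radius_ed")
        if self.epi_radius_es <= self.endo_radius_es:
            raise ValueError("epi_radius_es must exceed endo_radius_es")
        if self.wall_es_remote < self.wall_ed - 1e-12:
            raise ValueError("epi_radius_es/endo_radius_es: remote ES wall must be >= ED wall")
        for name in ("t1_remote_ms", "t1_infarct_ms", "t1_blood_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gd_peak_mM", "gd_background_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.infarct_thickening_fraction <= 1.0):
            raise ValueError("infarct_thickening_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.n_slices_lv + 2 > self.grid_shape[2]:
            raise ValueError("n_slices_lv does not fit in grid_shape with padding")

    @property
    def wall_ed(self) -> float:
        return self.epi_radius_ed - self.endo_radius_ed

    @property
    def wall_es_remote(self) -> float:
        return self.epi_radius_es - self.endo_radius_es

    @property
    def wall_es_infarct(self) -> float:
        return self.wall_ed * (1.0 + HEALTHY_THICKENING * self.infarct_thickening_fraction)

    @property
    def lv_slices(self) -> range:
        z0 = (self.grid_shape[2] - self.n_slices_lv) // 2
        return range(z0, z0 + self.n_slices_lv)

    @property
    def apex_slice(self) -> int:
        return self.lv_slices[0]


@dataclass
class PhantomTruth:
    """Ground-truth fields of the phantom on the image grid."""

    mask_ed: np.ndarray  # 0 background / 1 blood pool / 2 myocardium
    mask_es: np.ndarray
    t1_pre_map: np.ndarray  # ms; NaN outside tissue
    t1_post_map: np.ndarray
    gd_map: np.ndarray  # mM; 0 outside tissue
    sector_of_voxel: np.ndarray  # 4-sector id (0..3, -1 outside myocardium)
    rv_insertion_angle_deg: float
    spacing_mm: tuple
    spec: PhantomSpec | None = None


def _grid_polar(spec: PhantomSpec):
    nx, ny, _ = spec.grid_shape
    dx, dy, _ = spec.voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(xx, yy)
    theta = np.degrees(np.arctan2(yy, xx)) % 360.0
    return r, theta


def _in_sector(theta_deg, center_deg, width_deg):
    d = (theta_deg - center_deg + 180.0) % 360.0 - 180.0
    return np.abs(d) <= width_deg / 2.0


def make_heart_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build ED/ES label masks and ground-truth T1/Gd maps.

    Post-contrast T1 follows R1_post = R1_pre + r1_true · [Gd] voxelwise.
    In the infarct sector the ES wall thickness is
    ED · (1 + 0.65 · infarct_thickening_fraction), so systolic wall
    thickening spans 0–65% as the fraction goes from 0 (akinetic) to 1
    (healthy, indistinguishable from remote).
    """
    r, theta = _grid_polar(spec)
    nz = spec.grid_shape[2]
    shape = spec.grid_shape

    mask_ed = np.zeros(shape, dtype=np.int8)
    mask_es = np.zeros(shape, dtype=np.int8)

    sl = spec.infarct_sector
    lesion_slices = set(spec.lv_slices if sl.slice_range is None else range(sl.slice_range[0], sl.slice_range[1] + 1))
    in_lesion_angle = _in_sector(theta, sl.center_angle_deg, sl.width_deg)

    for z in spec.lv_slices:
        if z == spec.apex_slice:
            mask_ed[:, :, z] = np.where(r < spec.epi_radius_ed, MYOCARDIUM, BACKGROUND)
            mask_es[:, :, z] = np.where(r < spec.epi_radius_es, MYOCARDIUM, BACKGROUND)
            continue
        mask_ed[:, :, z] = np.where(
            r < spec.endo_radius_ed,
            BLOOD_POOL,
            np.where(r < spec.epi_radius_ed, MYOCARDIUM, BACKGROUND),
        )
        thick = np.full(r.shape, spec.wall_es_remote)
        if z in lesion_slices:
            thick = np.where(in_lesion_angle, spec.wall_es_infarct, thick)
        mask_es[:, :, z] = np.where(
            r < spec.endo_radius_es,
            BLOOD_POOL,
            np.where(r < spec.endo_radius_es + thick, MYOCARDIUM, BACKGROUND),
        )

    # Tissue maps live on the ED geometry (T1 scans are reconstructed at
    # matching anatomy; systole only matters for wall thickening).
    t1_pre = np.full(shape, np.nan)
    gd = np.zeros(shape)
    lesion3d = np.zeros(shape, dtype=bool)
    for z in lesion_slices:
        if 0 <= z < nz:
            lesion3d[:, :, z] = in_lesion_angle

    myo = mask_ed == MYOCARDIUM
    blood = mask_ed == BLOOD_POOL
    t1_pre[myo] = np.where(lesion3d[myo], spec.t1_infarct_ms, spec.t1_remote_ms)
    t1_pre[blood] = spec.t1_blood_ms
    gd[myo] = np.where(lesion3d[myo], spec.gd_peak_mM, spec.gd_background_mM)
    gd[blood] = spec.gd_background_mM

    with np.errstate(invalid="ignore", divide="ignore"):
        r1_pre = 1000.0 / t1_pre  # s^-1
        t1_post = 1000.0 / (r1_pre + spec.relaxivity_mM_s * gd)

    rv_angle = 0.0
    rel = (theta - rv_angle + 45.0) % 360.0
    sector2d = np.floor(rel / 90.0).astype(np.int8)  # 0 ant, 1 sept, 2 post, 3 lat
    sector = np.where(myo, sector2d[:, :, None], -1).astype(np.int8)

    return PhantomTruth(
        mask_ed=mask_ed,
        mask_es=mask_es,
        t1_pre_map=t1_pre,
        t1_post_map=t1_post,
        gd_map=gd,
        sector_of_voxel=sector,
        rv_insertion_angle_deg=rv_angle,
        spacing_mm=tuple(spec.voxel_size),
        spec=spec,
    )


def _rician(values, sigma, rng):
    """Magnitude of a complex Gaussian perturbation of a real signal."""
    if sigma == 0:
        return values.copy()
    n1 = rng.normal(0.0, sigma, size=values.shape)
    n2 = rng.normal(0.0, sigma, size=values.shape)
    return np.hypot(values + n1, n2)


def synthesize_vfa_images(
    truth: PhantomTruth,
    tr_ms: float = 10.0,
    flip_angles_deg=(2.0, 8.0, 14.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
    contrast: str = "pre",
    blood_mode: str = "bright",
    m0: float = 1.0,
) -> ImageSeries:
    """SPGR magnitude volume per flip angle from the phantom truth.

    ``contrast`` selects the pre- or post-contrast T1 map; ``blood_mode``
    "black" zeroes the blood-pool signal (the wall-delineation scan),
    "bright" keeps it.  Noise is Rician: the magnitude of the signal plus a
    complex Gaussian of per-channel SD ``noise_sigma`` (in units of M0).
    """
    flips = np.asarray(flip_angles_deg, dtype=float)
    if flips.size == 0:
        raise ValueError("flip_angles_deg must not be empty")
    if np.any((flips <= 0) | (flips >= 90)):
        raise ValueError("flip angles must lie in (0, 90) degrees")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if contrast not in ("pre", "post"):
        raise ValueError("contrast must be 'pre' or 'post'")
    if blood_mode not in ("bright", "black"):
        raise ValueError("blood_mode must be 'bright' or 'black'")

    t1 = truth.t1_pre_map if contrast == "pre" else truth.t1_post_map
    m0_map = np.where(truth.mask_ed != BACKGROUND, m0, 0.0)
    if blood_mode == "black":
        m0_map = np.where(truth.mask_ed == BLOOD_POOL, 0.0, m0_map)

    t1_safe = np.where(np.isfinite(t1) & (t1 > 0), t1, 1.0)
    rng = np.random.default_rng(seed)
    vols = np.empty((flips.size,) + truth.mask_ed.shape)
    for i, alpha in enumerate(flips):
        clean = spgr_signal(m0_map, t1_safe, tr_ms, alpha)
        vols[i] = _rician(clean, noise_sigma * m0, rng)
    return ImageSeries(
        volumes=vols,
        axis_meaning="flip_angle",
        axis_values=flips,
        tr_ms=tr_ms,
        te_ms=min(2.0, tr_ms / 2),
        spacing_mm=truth.spacing_mm,
    )


def default_ti_list(n: int = 60, first_ms: float = 72.0, last_ms: float = 4792.0) -> np.ndarray:
    """Default inversion-time grid: n TIs linearly spanning [first, last] ms."""
    return np.linspace(first_ms, last_ms, n)


def synthesize_ir_series(
    t1_values_ms,
    ti_list_ms=None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    readout_flip_deg: float = 15.0,
    readout_tr_ms: float = 4.0,
    n_segments: int = 32,
    m0: float = 1.0,
) -> pd.DataFrame:
    """Magnitude inversion-recovery snapshot-FLASH series per tube.

    The segmented low-flip readout drives recovery toward a reduced steady
    state at an apparent rate 1/T1* = 1/T1 − ln(cos α)/(TR·N_seg), the
    Look-Locker effect with the RF energy spread over the segmented readout.
    The noiseless signal is |A − B·exp(−TI/T1*)| with A = M0·T1*/T1 and
    B = A + M0 (ideal inversion), so the standard correction
    T1 = T1*·(B/A − 1) is exact on this generator.  Noise is Rician with SD
    ``noise_sigma`` in units of M0.  Returns a tidy table with columns
    sample_id, ti_ms, signal.
    """
    t1s = np.asarray(t1_values_ms, dtype=float)
    if np.any(t1s <= 0):
        raise ValueError("t1_values_ms must be positive")
    ti = default_ti_list() if ti_list_ms is None else np.asarray(ti_list_ms, dtype=float)
    if np.any(ti <= 0):
        raise ValueError("ti_list_ms must be positive")
    rate_readout = -np.log(np.cos(np.deg2rad(readout_flip_deg))) / (readout_tr_ms * n_segments)
    rng = np.random.default_rng(seed)
    rows = []
    for tube, t1 in enumerate(t1s):
        t1_star = 1.0 / (1.0 / t1 + rate_readout)
        a = m0 * t1_star / t1
        b = a + m0
        clean = np.abs(a - b * np.exp(-ti / t1_star))
        noisy = _rician(clean, noise_sigma * m0, rng)
        for ti_i, s_i in zip(ti, noisy):
            rows.append((tube, ti_i, s_i))
    return pd.DataFrame(rows, columns=["sample_id", "ti_ms", "signal"])


def virtual_icpms(
    truth: PhantomTruth,
    slice_height_mm: float = 2.5,
    n_sectors: int = 4,
    cut_angle_offset_deg: float = 0.0,
    seed: int = 0,
    rel_noise: float = 0.0,
) -> list[GdMeasurement]:
    """Cut a virtual mid-ventricular slice into angular sectors and weigh it.

    The slice ``slice_height_mm`` above the apex is selected, its myocardial
    voxels are partitioned into ``n_sectors`` equal angular sectors anchored
    at the RV-insertion angle plus ``cut_angle_offset_deg`` (the offset
    emulates misalignment of the physical cutting relative to the imaging
    frame), and per sector the tissue mass (voxel volume × 1.05 g/ml) and Gd
    mass (∫[Gd]·dV × 157.25 g/mol) are returned.  With ``rel_noise`` > 0 a
    multiplicative Gaussian error is applied to the Gd masses (measurement
    noise); at the default 0 the sector masses sum exactly to the slice
    totals for any offset.
    """
    spec = truth.spec
    dz = truth.spacing_mm[2]
    apex = spec.apex_slice if spec is not None else int(np.argmax((truth.mask_ed != 0).any(axis=(0, 1))))
    z = apex + int(round(slice_height_mm / dz))
    lv = sorted({int(k) for k in np.flatnonzero((truth.mask_ed != 0).any(axis=(0, 1)))})
    if z not in lv:
        raise ValueError(f"slice_height_mm={slice_height_mm} falls outside the LV (slice index {z})")
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")

    nx, ny, _ = truth.mask_ed.shape
    dx, dy = truth.spacing_mm[0], truth.spacing_mm[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    theta = np.degrees(np.arctan2(yy, xx)) % 360.0

    myo = truth.mask_ed[:, :, z] == MYOCARDIUM
    gd = truth.gd_map[:, :, z]
    vox_vol_ul = dx * dy * dz  # mm^3 == µl

    span = 360.0 / n_sectors
    start = truth.rv_insertion_angle_deg + cut_angle_offset_deg
    if n_sectors == 4:
        start -= span / 2.0  # center the anterior sector on the anchor
    rel = (theta - start) % 360.0
    sector_idx = np.minimum((rel // span).astype(int), n_sectors - 1)

    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_sectors):
        sel = myo & (sector_idx == k)
        n_vox = int(sel.sum())
        tissue_mg = n_vox * vox_vol_ul * TISSUE_DENSITY_G_ML  # µl * mg/µl
        gd_nmol = float(gd[sel].sum()) * vox_vol_ul  # mM * µl = nmol
        gd_ng = gd_nmol * GD_MOLAR_MASS_G_MOL
        if rel_noise > 0:
            gd_ng *= max(0.0, 1.0 + rng.normal(0.0, rel_noise))
        name = SECTOR_NAMES_4[k] if n_sectors == 4 else f"sector_{k}"
        out.append(GdMeasurement(sector_id=name, gd_mass_ng=gd_ng, tissue_mass_mg=tissue_mg))
    return out
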