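"""Synthetic multi-parametric MRI phantom with ground truth.

The phantom emulates a high-grade glioma study on an anisotropic grid
(default 64 x 64 x 10 voxels at 1 x 1 x 3 mm): an ellipsoidal brain with
a cortical grey-matter shell, ventricular CSF, two vessels, and a
ring-enhancing lesion -- necrotic core, enhancing rim, edema halo --
optionally with a detached necrotic satellite pocket embedded in the
rim.  Channels are piecewise-constant per tissue plus i.i.d. Gaussian
noise (clipped at 0).  The per-tissue intensity table encodes the usual
qualitative contrasts (rim enhances on T1C and rCBV, necrosis and CSF
are ADC-bright, edema is FLAIR-bright) with partial per-channel overlap
between confusable pairs so that classes separate jointly but not in any
single channel.

Matched raw DWI / DSC series can be generated for the same geometry so
the quantitative-map fitting is exercised end to end with known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .features import MPMRIStudy
from .initialization import PATHOLOGICAL_LABELS, SeedSet
from .metrics import sample_seeds
from .preprocess import DSCSeries, DWISeries

log = logging.getLogger(__name__)

CHANNELS = ("T1", "T1C", "FLAIR", "rCBV", "ADC", "b0")
TISSUES = ("wm", "gm", "csf", "vessel", "active_tumor", "necrosis", "edema")
_TISSUE_ID = {name: i + 1 for i, name in enumerate(TISSUES)}  # 0 = background

#: per-tissue mean intensity per channel (arbitrary units on a [0, 1] scale)
DEFAULT_INTENSITIES: Dict[str, Tuple[float, ...]] = {
    #          T1    T1C   FLAIR rCBV  ADC   b0
    "wm":     (0.70, 0.70, 0.35, 0.25, 0.30, 0.40),
    "gm":     (0.55, 0.55, 0.45, 0.35, 0.35, 0.50),
    "csf":    (0.15, 0.15, 0.10, 0.05, 0.95, 0.90),
    "vessel": (0.45, 0.85, 0.40, 0.90, 0.30, 0.45),
    "active_tumor": (0.40, 0.90, 0.65, 0.75, 0.45, 0.55),
    "necrosis":     (0.20, 0.15, 0.55, 0.10, 0.85, 0.70),
    "edema":        (0.35, 0.30, 0.80, 0.30, 0.65, 0.65),
}

#: per-tissue ADC in mm^2/s (typical literature magnitudes)
DEFAULT_ADC: Dict[str, float] = {
    "wm": 0.7e-3, "gm": 0.8e-3, "csf": 3.0e-3, "vessel": 0.9e-3,
    "active_tumor": 1.0e-3, "necrosis": 2.2e-3, "edema": 1.4e-3,
}

#: per-tissue peak relaxivity change (1/ms) of the first-pass bolus
DEFAULT_PERFUSION: Dict[str, float] = {
    "wm": 0.004, "gm": 0.006, "csf": 0.001, "vessel": 0.020,
    "active_tumor": 0.012, "necrosis": 0.001, "edema": 0.005,
}


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of the synthetic study."""

    shape: Tuple[int, int, int] = (64, 64, 10)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    brain_radii_mm: Tuple[float, float, float] = (30.0, 31.0, 20.0)
    gm_shell_fraction: float = 0.82  # WM inside this fraction of the brain ellipsoid
    ventricle_offset_mm: Tuple[float, float, float] = (7.0, -8.0, 0.0)
    ventricle_radii_mm: Tuple[float, float, float] = (4.0, 7.0, 6.0)
    vessel_xy_mm: Tuple[Tuple[float, float], ...] = ((18.0, -12.0), (10.0, 20.0))
    vessel_radius_mm: float = 1.8
    # compartment thicknesses chosen to exceed the 5x5 in-plane averaging
    # mixing width so every tissue class keeps a pure interior
    lesion_center_mm: Tuple[float, float, float] = (-9.0, 5.0, 0.0)
    necrosis_radius_mm: float = 6.5
    rim_radius_mm: float = 11.0
    edema_radius_mm: float = 16.5
    satellite_center_mm: Optional[Tuple[float, float, float]] = None
    satellite_radius_mm: float = 2.5
    intensities: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sigma: float = 0.05
    adc_mm2s: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ADC))
    perfusion_amp: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PERFUSION))
    leakage_k2: float = 0.02  # injected K2 in active tumor for the raw DSC series
    echo_time_ms: float = 30.0
    n_timepoints: int = 90
    n_baseline: int = 10
    seed: int = 0
    n_seeds_per_class: int = 3

    def __post_init__(self) -> None:
        if not (self.necrosis_radius_mm < self.rim_radius_mm < self.edema_radius_mm):
            raise ValueError("radii must be ordered core < rim < halo")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for t, means in self.intensities.items():
            if any(v < 0 for v in means):
                raise ValueError(f"negative mean intensity for tissue {t!r}")


@dataclass
class PhantomData:
    """A generated study with its ground truth."""

    study: MPMRIStudy
    truth_masks: Dict[str, np.ndarray]
    seeds: SeedSet
    tissue_labels: np.ndarray  # 0 background, 1.. per TISSUES
    nonenh_mask: np.ndarray  # non-enhancing brain voxels (for leakage fitting)


def _grid_mm(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    cx, cy, cz = (nx - 1) / 2 * dx, (ny - 1) / 2 * dy, (nz - 1) / 2 * dz
    x = np.arange(nx)[:, None, None] * dx - cx
    y = np.arange(ny)[None, :, None] * dy - cy
    z = np.arange(nz)[None, None, :] * dz - cz
    return x, y, z


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def tissue_volume(spec: PhantomSpec) -> np.ndarray:
    """Integer tissue-label volume per the phantom geometry."""
    x, y, z = _grid_mm(spec)
    brain = _ellipsoid(x, y, z, (0, 0, 0), spec.brain_radii_mm)
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[brain] = _TISSUE_ID["gm"]
    wm = _ellipsoid(
        x, y, z, (0, 0, 0), tuple(r * spec.gm_shell_fraction for r in spec.brain_radii_mm)
    )
    labels[wm] = _TISSUE_ID["wm"]
    for sign in (+1, -1):
        off = spec.ventricle_offset_mm
        vent = _ellipsoid(x, y, z, (sign * off[0], off[1], off[2]), spec.ventricle_radii_mm)
        labels[vent & brain] = _TISSUE_ID["csf"]
    for vx, vy in spec.vessel_xy_mm:
        vessel = ((x - vx) ** 2 + (y - vy) ** 2) <= spec.vessel_radius_mm**2
        labels[np.broadcast_to(vessel, spec.shape) & brain] = _TISSUE_ID["vessel"]

    c = spec.lesion_center_mm
    r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    edema = r2 <= spec.edema_radius_mm**2
    if np.any(edema & ~brain):
        raise ValueError("lesion extends outside the brain; adjust geometry")
    labels[edema] = _TISSUE_ID["edema"]
    labels[r2 <= spec.rim_radius_mm**2] = _TISSUE_ID["active_tumor"]
    labels[r2 <= spec.necrosis_radius_mm**2] = _TISSUE_ID["necrosis"]
    if spec.satellite_center_mm is not None:
        s = spec.satellite_center_mm
        sat = ((x - s[0]) ** 2 + (y - s[1]) ** 2 + (z - s[2]) ** 2) <= spec.satellite_radius_mm**2
        if np.any(sat & ~brain):
            raise ValueError("satellite extends outside the brain")
        labels[sat] = _TISSUE_ID["necrosis"]
    return labels


def generate_study(spec: PhantomSpec) -> PhantomData:
    """Generate channels, ground-truth masks and a default seed set.

    Channel volumes are the tissue-mean table plus i.i.d. Gaussian noise
    of standard deviation ``noise_sigma`` (clipped at 0); everything is
    deterministic given ``spec.seed``.  Default seeds are
    ``n_seeds_per_class`` voxels sampled uniformly from each nonempty
    pathological truth mask.
    """
    rng = np.random.default_rng(spec.seed)
    labels = tissue_volume(spec)
    brain = labels > 0

    channels: Dict[str, np.ndarray] = {}
    mean_lut = np.zeros((len(TISSUES) + 1, len(CHANNELS)))
    for t, means in spec.intensities.items():
        mean_lut[_TISSUE_ID[t]] = means
    for ci, name in enumerate(CHANNELS):
        vol = mean_lut[labels, ci]
        if spec.noise_sigma > 0:
            vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
        channels[name] = np.clip(vol, 0.0, None)

    truth = {name: labels == _TISSUE_ID[name] for name in PATHOLOGICAL_LABELS}
    study = MPMRIStudy(
        channels=channels, spacing=spec.spacing, brain_mask=brain,
        slice_range=(0, spec.shape[2]),
    )
    seeds = sample_seeds(truth, rng, spec.n_seeds_per_class)
    nonenh = brain & (labels != _TISSUE_ID["active_tumor"]) & (labels != _TISSUE_ID["vessel"])
    return PhantomData(
        study=study, truth_masks=truth, seeds=seeds, tissue_labels=labels,
        nonenh_mask=nonenh,
    )


def _bolus_shape(spec: PhantomSpec) -> np.ndarray:
    """Unit-peak gamma-variate first-pass curve, zero during baseline."""
    t = np.arange(spec.n_timepoints, dtype=float)
    t0 = float(spec.n_baseline)
    alpha, tp = 3.0, 6.0  # shape and time-to-peak (s)
    s = np.zeros_like(t)
    tt = (t - t0) / tp
    rise = t > t0
    s[rise] = tt[rise] ** alpha * np.exp(alpha * (1.0 - tt[rise]))
    return s


def generate_raw(
    spec: PhantomSpec, noise_sigma: float = 0.0
) -> Tuple[DWISeries, DSCSeries]:
    """Raw DWI and DSC series consistent with the phantom's tissue maps.

    DWI signals decay mono-exponentially with the per-tissue ADC at
    b = 0 / 500 / 1000 s/mm^2.  The DSC voxel curves follow a shared
    gamma-variate bolus scaled by the per-tissue perfusion amplitude;
    active tumor additionally receives a leakage term with the known
    ``spec.leakage_k2`` relative to the non-enhancing average curve.
    ``noise_sigma`` adds Gaussian noise on the signals (fraction of the
    local baseline signal).
    """
    rng = np.random.default_rng(spec.seed + 1)
    labels = tissue_volume(spec)
    brain = labels > 0

    adc_lut = np.zeros(len(TISSUES) + 1)
    amp_lut = np.zeros(len(TISSUES) + 1)
    for t_name in TISSUES:
        adc_lut[_TISSUE_ID[t_name]] = spec.adc_mm2s[t_name]
        amp_lut[_TISSUE_ID[t_name]] = spec.perfusion_amp[t_name]
    adc_map = adc_lut[labels]
    amp_map = amp_lut[labels]

    bvalues = np.array([0.0, 500.0, 1000.0])
    s0 = np.where(brain, 1000.0, 1.0)
    dwi = s0[..., None] * np.exp(-adc_map[..., None] * bvalues[None, None, None, :])
    if noise_sigma > 0:
        dwi = np.clip(dwi + rng.normal(0, noise_sigma * 1000.0, dwi.shape), 1e-3, None)
    dwi_series = DWISeries(volumes=dwi, bvalues=bvalues, spacing=spec.spacing)

    bolus = _bolus_shape(spec)  # unit peak
    nonenh = brain & (labels != _TISSUE_ID["active_tumor"]) & (labels != _TISSUE_ID["vessel"])
    avg_amp = float(amp_map[nonenh].mean())
    avg_curve = avg_amp * bolus
    from scipy.integrate import cumulative_trapezoid

    integral = cumulative_trapezoid(avg_curve, dx=1.0, initial=0.0)
    # voxel relaxivity curves: amp * bolus, plus leakage in active tumor
    curves = amp_map[..., None] * bolus[None, None, None, :]
    enh = labels == _TISSUE_ID["active_tumor"]
    curves[enh] -= spec.leakage_k2 * integral[None, :]
    te = spec.echo_time_ms
    base = np.where(brain, 500.0, 1.0)
    dsc = base[..., None] * np.exp(-te * curves)
    if noise_sigma > 0:
        dsc = np.clip(dsc + rng.normal(0, noise_sigma * 500.0, dsc.shape), 1e-3, None)
    dsc_series = DSCSeries(volumes=dsc, n_baseline=spec.n_baseline, echo_time=te)
    return dwi_series, dsc_series
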