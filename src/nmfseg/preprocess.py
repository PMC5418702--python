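"""Quantitative map derivation from raw diffusion and perfusion series.

Two maps feed the feature set:

* **ADC** from multi-b-value DWI via weighted linear least squares on the
  log-signal (mono-exponential decay ``S(b) = S0 exp(-ADC b)``).  The
  weights ``exp(2 X beta_LLS)`` counteract the heteroscedasticity that the
  log transform induces (low signals have inflated log-variance).
* **rCBV** from a dynamic susceptibility-contrast series, corrected for
  contrast-agent leakage with the Boxerman two-regressor model: the
  voxel relaxivity curve is regressed on the whole-brain average curve of
  non-enhancing voxels and on (minus) its running time-integral, giving a
  perfusion weight K1 and a leakage weight K2; only the K1 term is kept
  when integrating to rCBV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

log = logging.getLogger(__name__)


@dataclass
class DWISeries:
    """Diffusion-weighted series: one volume per b-value.

    ``volumes`` has shape ``(nx, ny, nz, nb)``; ``bvalues`` in s/mm^2.
    """

    volumes: np.ndarray
    bvalues: Sequence[float]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.volumes.ndim != 4 or self.volumes.shape[3] != len(self.bvalues):
            raise ValueError("volumes must be (nx, ny, nz, nb) matching bvalues")
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be non-negative")
        if len(np.unique(self.bvalues)) < 2:
            raise ValueError("need at least two distinct b-values")


@dataclass
class DSCSeries:
    """Dynamic susceptibility-contrast series sampled at 1 s intervals.

    ``volumes`` has shape ``(nx, ny, nz, nt)``; the first ``n_baseline``
    time points are pre-contrast; ``echo_time`` (TE) is in ms.
    """

    volumes: np.ndarray
    n_baseline: int
    echo_time: float

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (nx, ny, nz, nt)")
        nt = self.volumes.shape[3]
        if not (2 <= self.n_baseline < nt):
            raise ValueError(f"n_baseline must be in [2, {nt}), got {self.n_baseline}")
        if self.echo_time <= 0:
            raise ValueError("echo_time must be positive")


def fit_adc(series: DWISeries, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the apparent diffusion coefficient by weighted linear LS.

    Per masked voxel the log-signal ``y = log S`` is modelled as
    ``y = X beta`` with design columns ``[1, -b]`` so ``beta[1]`` is the
    ADC in mm^2/s.  An ordinary LS pass provides ``beta_LLS``; the WLS
    pass uses weights ``diag(exp(2 X beta_LLS))``.  Negative ADC values
    are clipped to 0; voxels outside the mask (or with non-positive
    signal, which are excluded with a warning) are 0.

    Returns
    -------
    adc, b0 : ndarray
        ADC map (mm^2/s) and the b = 0 volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.volumes.shape[:3]:
        raise ValueError("mask grid differs from series grid")
    b = series.bvalues
    design = np.column_stack([np.ones_like(b), -b])  # (nb, 2)
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("singular design matrix (need two distinct b-values)")

    sig = series.volumes[mask]  # (K, nb)
    valid = np.all(sig > 0, axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(f"{n_bad} in-mask voxels with non-positive DWI signal excluded")
    y = np.log(sig[valid])  # (Kv, nb)

    # ordinary LS: beta = pinv(X) y
    beta_lls = y @ np.linalg.pinv(design).T  # (Kv, 2)
    w = np.exp(2.0 * (beta_lls @ design.T))  # (Kv, nb)

    # per-voxel 2x2 weighted normal equations, vectorised
    xw = design[None, :, :] * w[:, :, None]  # (Kv, nb, 2)
    ata = np.einsum("kbi,bj->kij", xw, design)  # (Kv, 2, 2)
    atb = np.einsum("kbi,kb->ki", xw, y)  # (Kv, 2)
    beta = np.linalg.solve(ata, atb[..., None])[..., 0]

    adc = np.zeros(mask.shape, dtype=float)
    vals = np.zeros(sig.shape[0], dtype=float)
    vals[valid] = np.clip(beta[:, 1], 0.0, None)
    adc[mask] = vals

    i0 = int(np.argmin(b))
    if b[i0] != 0:
        warnings.warn("no b = 0 acquisition; returning the lowest-b volume as b0")
    b0 = series.volumes[..., i0].copy()
    return adc, b0


def relaxivity_curves(series: DSCSeries, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-voxel relaxivity change ``dR2*(t) = -ln(S(t)/S0) / TE``.

    ``S0`` is the mean of the pre-contrast baseline points.  Returns the
    ``(K, nt)`` curves for in-mask voxels together with a validity flag
    per voxel (False where the baseline or signal is non-positive).
    """
    mask = np.asarray(mask, dtype=bool)
    sig = series.volumes[mask]  # (K, nt)
    s0 = sig[:, : series.n_baseline].mean(axis=1)
    valid = (s0 > 0) & np.all(sig > 0, axis=1)
    curves = np.zeros_like(sig)
    ratio = sig[valid] / s0[valid, None]
    curves[valid] = -np.log(ratio) / series.echo_time
    return curves, valid


def average_relaxivity(series: DSCSeries, nonenh_mask: np.ndarray) -> np.ndarray:
    """Whole-brain average relaxivity curve over non-enhancing voxels."""
    nonenh_mask = np.asarray(nonenh_mask, dtype=bool)
    if not nonenh_mask.any():
        raise ValueError("non-enhancing mask is empty")
    curves, valid = relaxivity_curves(series, nonenh_mask)
    if not valid.any():
        raise ValueError("no valid relaxivity curves in the non-enhancing mask")
    return curves[valid].mean(axis=0)


def fit_leakage(
    series: DSCSeries, mask: np.ndarray, nonenh_mask: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the two-regressor leakage model per voxel.

    Each voxel curve is approximated as ``K1 * avg(t) - K2 * int_0^t avg``
    by linear least squares against the regressors
    ``[avg(t), -cumtrapz(avg)(t)]`` (1 s sampling).  Voxels with invalid
    baselines are excluded (maps stay 0 there).
    """
    mask = np.asarray(mask, dtype=bool)
    avg = average_relaxivity(series, nonenh_mask)
    if np.allclose(avg, 0.0):
        raise ValueError("average relaxivity curve is identically zero")
    integral = cumulative_trapezoid(avg, dx=1.0, initial=0.0)
    design = np.column_stack([avg, -integral])  # (nt, 2)

    curves, valid = relaxivity_curves(series, mask)
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(f"{n_bad} in-mask voxels with invalid DSC baseline excluded")
    coef = np.zeros((curves.shape[0], 2))
    coef[valid] = np.linalg.lstsq(design, curves[valid].T, rcond=None)[0].T

    k1 = np.zeros(mask.shape)
    k2 = np.zeros(mask.shape)
    k1[mask] = coef[:, 0]
    k2[mask] = coef[:, 1]
    return k1, k2


def compute_rcbv(
    series: DSCSeries,
    k1: np.ndarray,
    mask: np.ndarray,
    nonenh_mask: np.ndarray = None,
    avg_curve: np.ndarray = None,
) -> np.ndarray:
    """Leakage-corrected rCBV: time-integral of the K1 term only.

    The corrected curve of a voxel is ``K1 * avg(t)``; rCBV is its
    trapezoidal integral over the post-baseline window, clipped at 0.
    Either ``avg_curve`` (as returned by :func:`average_relaxivity`) or
    ``nonenh_mask`` must be given.
    """
    mask = np.asarray(mask, dtype=bool)
    if k1.shape != mask.shape or mask.shape != series.volumes.shape[:3]:
        raise ValueError("k1 / mask / series grids do not match")
    if avg_curve is None:
        if nonenh_mask is None:
            raise ValueError("provide avg_curve or nonenh_mask")
        avg_curve = average_relaxivity(series, nonenh_mask)
    post = np.asarray(avg_curve, dtype=float)[series.n_baseline :]
    area = float(np.trapezoid(post, dx=1.0))
    rcbv = np.zeros(mask.shape)
    rcbv[mask] = np.clip(k1[mask] * area, 0.0, None)
    return rcbv
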