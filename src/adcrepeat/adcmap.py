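"""Voxel-wise ADC estimation from multi-b-value magnitude DWI.

The decay model is mono-exponential, S(b) = S0 * exp(-b * ADC), fitted as
an ordinary least-squares line on log-signal versus b.  Magnitude images
carry a Rician noise floor that biases low-SNR (high-b) signal upward and
hence inflates the apparent decay; signals are first corrected by
first-moment-consistent quadrature subtraction, using E[M^2] = A^2 +
2*sigma^2 for single-coil Rician magnitude M with true amplitude A.

ADC values are reported in 10^-5 mm^2/s (so 1.09e-3 mm^2/s prints as 109),
matching the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .io import ROIMeasurement

#: slope scale: ADC_phys [mm^2/s] = ADC_reported * 1e-5
_UNIT = 1e5

#: default acquisition geometry: 1.5 x 1.5 mm pixels, 5 mm slices
DEFAULT_VOXEL_DIMS_MM = (1.5, 1.5, 5.0)

#: clamp for the noise-floor correction, as a fraction of noise_sigma
_FLOOR_FRACTION = 0.05


class EmptyROIError(ValueError):
    """An ROI mask contains no valid voxels."""


@dataclass
class BValueStack:
    """Multi-b-value magnitude data for a set of voxels.

    ``signals`` has shape (..., n_b): one magnitude value per b-value in
    the trailing axis.  ``noise_sigma`` is the magnitude-noise scale in
    signal units.
    """

    b_values: np.ndarray
    signals: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if len(np.unique(self.b_values)) < 2:
            raise ValueError("need >= 2 distinct b-values")
        if self.signals.shape[-1] != self.b_values.size:
            raise ValueError("signals trailing axis must match b_values")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class ADCMap:
    """Per-voxel ADC values (10^-5 mm^2/s) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")


def correct_noise_floor(signal, noise_sigma: float):
    """Remove the Rician noise floor from magnitude signal.

    Returns sqrt(max(signal^2 - 2*sigma^2, floor)) where the floor is a
    small positive clamp (a fixed fraction of sigma, itself capped by the
    signal so the output never exceeds the input; identity when
    sigma == 0).  Monotone non-decreasing in the signal.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0) or noise_sigma < 0:
        raise ValueError("signal and noise_sigma must be >= 0")
    floor = np.minimum((_FLOOR_FRACTION * noise_sigma) ** 2, signal**2)
    out = np.sqrt(np.maximum(signal**2 - 2.0 * noise_sigma**2, floor))
    return out if out.ndim else float(out)


def compute_adc_map(stack: BValueStack, *, correct: bool = True) -> ADCMap:
    """Fit every voxel of a stack; invalid voxels are masked, not raised.

    A voxel is invalid when fewer than 2 b-values have positive corrected
    signal or the fitted slope is non-finite.  The fit is unweighted OLS
    of ln(signal) on b; the negated slope, scaled to 10^-5 mm^2/s, is the
    ADC.
    """
    b = stack.b_values
    sig = stack.signals
    if correct and stack.noise_sigma > 0:
        sig = correct_noise_floor(sig, stack.noise_sigma)
    usable = sig > 0
    n_use = usable.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(usable, np.log(np.where(usable, sig, 1.0)), 0.0)
    # per-voxel masked OLS slope of y on b
    bsum = np.where(usable, b, 0.0).sum(axis=-1)
    bbar = np.divide(bsum, n_use, out=np.zeros_like(bsum), where=n_use > 0)
    ybar = np.divide(y.sum(axis=-1), n_use,
                     out=np.zeros(n_use.shape, dtype=float), where=n_use > 0)
    db = np.where(usable, b - bbar[..., None], 0.0)
    sxx = (db**2).sum(axis=-1)
    sxy = (db * (y - ybar[..., None])).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    adc = -slope * _UNIT
    valid = (n_use >= 2) & (sxx > 0) & np.isfinite(adc)
    adc = np.where(valid, adc, np.nan)
    return ADCMap(adc, valid)


def fit_monoexponential(stack: BValueStack, voxel) -> float:
    """ADC (10^-5 mm^2/s) for one voxel index; NaN if the fit is invalid."""
    amap = compute_adc_map(stack)
    return float(amap.values[voxel])


def summarise_roi(adc_map: ADCMap, mask, *, patient_id: str,
                  roi_kind: str, session: str,
                  motion_flag: bool = False) -> ROIMeasurement:
    """Collapse the masked, valid voxels of an ADC map to an ROI summary.

    N is the count of valid masked voxels, D their arithmetic mean and w
    the sample standard deviation (N-1 denominator; 0 for a single voxel).
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        sel = mask & adc_map.valid
        values = adc_map.values[sel]
    else:  # index array / tuple of index arrays
        values = adc_map.values[mask]
        values = values[np.isfinite(values)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyROIError("no valid voxels inside the ROI mask")
    n = int(values.size)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return ROIMeasurement(patient_id=patient_id, roi_kind=roi_kind,
                          session=session, n_voxels=n, mean_adc=mean,
                          adc_sd=sd, motion_flag=motion_flag)


def roi_histogram(adc_map: ADCMap, mask, bins: int = 50):
    """Histogram (counts, edges) of the valid masked ADC values."""
    mask = np.asarray(mask)
    values = adc_map.values[mask & adc_map.valid] if mask.dtype == bool \
        else adc_map.values[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyROIError("no valid voxels inside the ROI mask")
    return np.histogram(values, bins=bins)


class Volume(NamedTuple):
    mm3: float
    cm3: float


def voxels_to_volume(n_voxels: float,
                     voxel_dims_mm: Sequence[float] = DEFAULT_VOXEL_DIMS_MM
                     ) -> Volume:
    """Convert a voxel count to physical volume.

    The default geometry (1.5 x 1.5 x 5 mm) gives 11.25 mm^3 per voxel,
    so 2000 voxels correspond to 22.5 cm^3.
    """
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    mm3 = float(n_voxels) * float(np.prod(voxel_dims_mm))
    return Volume(mm3=mm3, cm3=mm3 / 1000.0)
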