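"""Power-spectral-density estimation and Nyquist/aliasing arithmetic.

Dynamic PET sampled at frame duration TR can only represent frequencies up
to the Nyquist limit 1/(2 TR); physiological oscillations above it (e.g.
respiration near 0.3 Hz at 3 s frames) fold back to |f - n fs| and appear as
spurious low-frequency peaks. These helpers quantify that arithmetic and
estimate Welch spectra of regional signals after baseline-uptake removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.signal

from .filters import compcor_residualize
from .nuisance import DesignMatrix
from .types import RegionTimeSeries, nyquist_frequency

__all__ = [
    "PSDEstimate",
    "nyquist_frequency",
    "alias_frequency",
    "remove_baseline_uptake",
    "welch_psd",
]


@dataclass
class PSDEstimate:
    """Welch power spectral density on [0, Nyquist]."""

    frequencies: np.ndarray
    power: np.ndarray
    segment_length: int
    overlap: int
    window: str

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must ascend from 0")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and non-negative")

    def peak_frequency(self, f_min: float = 0.0, f_max: Optional[float] = None) -> float:
        """Frequency of the maximum power within [f_min, f_max]."""
        sel = self.frequencies >= f_min
        if f_max is not None:
            sel &= self.frequencies <= f_max
        if not sel.any():
            raise ValueError("no frequency bins in the requested range")
        idx = np.flatnonzero(sel)
        return float(self.frequencies[idx[np.argmax(self.power[idx])]])


def alias_frequency(f: float, sampling_rate: float):
    """Apparent frequency of ``f`` Hz when sampled at ``sampling_rate`` Hz.

    The folding rule f_alias = min_n |f - n * fs| maps any frequency into
    [0, Nyquist]; e.g. a 0.3 Hz oscillation sampled at 3 s frames
    (fs = 1/3 Hz) appears at ~0.033 Hz. Idempotent for in-range inputs.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("f must be >= 0")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    m = np.mod(f, sampling_rate)
    out = np.minimum(m, sampling_rate - m)
    return float(out) if out.ndim == 0 else out


def remove_baseline_uptake(
    regions: RegionTimeSeries,
    method: str = "polynomial",
    order: int = 3,
    design: Optional[DesignMatrix] = None,
) -> RegionTimeSeries:
    """Remove the slow tracer-uptake trend from regional signals.

    ``method="polynomial"`` (default) regresses out a degree-``order``
    polynomial in time (cubic by default); ``method="design"`` removes a
    supplied nuisance design containing tissue components instead. Output
    time courses have zero mean.
    """
    if method == "polynomial":
        t = regions.n_frames
        if order >= t:
            raise ValueError(f"polynomial order {order} must be < n_frames {t}")
        # Legendre basis on [-1, 1] keeps the fit well-conditioned
        tau = np.linspace(-1.0, 1.0, t)
        basis = np.polynomial.legendre.legvander(tau, order)
        y = regions.values.T
        beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
        resid = (y - basis @ beta).T
        return regions.with_values(resid)
    if method == "design":
        if design is None:
            raise ValueError("method='design' requires a DesignMatrix")
        return compcor_residualize(regions, design)
    raise ValueError(f"method must be 'polynomial' or 'design', got {method!r}")


def welch_psd(
    data: Union[RegionTimeSeries, np.ndarray],
    frame_duration: Optional[float] = None,
    segment_fraction: float = 0.25,
    overlap: float = 0.5,
    window: str = "hann",
) -> PSDEstimate:
    """Welch PSD of a single signal, or the region-mean PSD of a set.

    Defaults: segments of T/4 samples, 50 % overlap, Hann window, constant
    detrend. For a RegionTimeSeries the spectra of all regions are averaged.
    """
    if isinstance(data, RegionTimeSeries):
        x = data.values
        fs = 1.0 / data.frame_duration
    else:
        x = np.atleast_2d(np.asarray(data, dtype=float))
        if frame_duration is None:
            raise ValueError("frame_duration required for raw array input")
        fs = 1.0 / frame_duration
    t = x.shape[1]
    nperseg = max(8, int(round(t * segment_fraction)))
    if nperseg > t:
        raise ValueError(f"segment length {nperseg} exceeds series length {t}")
    noverlap = int(round(nperseg * overlap))
    freqs, power = scipy.signal.welch(
        x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
        detrend="constant", axis=1, scaling="density",
    )
    return PSDEstimate(frequencies=freqs, power=power.mean(axis=0),
                       segment_length=nperseg, overlap=noverlap, window=window)
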