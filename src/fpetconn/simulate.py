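"""Synthetic constant-infusion fPET generator with known ground truth.

The generator emulates the signal composition of a bolus + constant-infusion
FDG acquisition at second-scale framing:

* a global tracer-uptake trend ``U(t)`` (early bolus hump followed by a
  saturating quasi-linear infusion ramp), scaled per tissue class;
* band-limited, correlated "spontaneous metabolic" fluctuations in gray
  matter, built from latent factors with a known loading matrix, so the
  ground-truth connectivity of every injected network is available exactly;
* physiological oscillations (~0.3 Hz respiratory, ~1.0 Hz cardiac) weighted
  by the CSF compartment — sampled at the frame grid, so at 3 s frames they
  alias exactly as the sampling theory predicts;
* motion-coupled artifacts (inner product of a random-walk rigid-body trace
  with a per-voxel gain vector);
* heteroscedastic pseudo-Poisson noise whose standard deviation scales with
  sqrt(instantaneous activity) and inversely with the square root of scanner
  sensitivity.

Two scanner profiles mirror the acquisition regimes of interest: a
high-sensitivity large-axial-field-of-view system (1500 frames of 1 s,
~176 kcps/MBq) and a standard hybrid system (400 frames of 3 s,
~15 kcps/MBq); at equal ``sigma0`` the standard profile's noise standard
deviation is sqrt(176/15) ~ 3.43x larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    ConnectivityMatrix,
    DynamicSeries,
    FrequencyBand,
    MotionTrace,
    ParcelMap,
    RegionTimeSeries,
    TissueProbabilityMap,
    make_connectivity,
    nyquist_frequency,
)

__all__ = [
    "UptakeParams",
    "NetworkSpec",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedSubject",
    "uptake_curve",
    "band_limited_latents",
    "random_loading",
    "simulate_subject",
    "simulate_region_series",
    "SCANNER_PROFILES",
]

#: NEMA count sensitivities (kcps/MBq) of the two emulated scanner regimes
SCANNER_PROFILES = {
    "high_sensitivity_1s": {"n_frames": 1500, "frame_duration": 1.0,
                            "sensitivity_kcps_per_mbq": 176.0},
    "standard_3s": {"n_frames": 400, "frame_duration": 3.0,
                    "sensitivity_kcps_per_mbq": 15.0},
}

_REFERENCE_SENSITIVITY = 176.0  # noise factor 1.0 for the high-sensitivity profile


@dataclass(frozen=True)
class UptakeParams:
    """Parameters of the bolus + constant-infusion uptake curve.

    U(t) = A_b (exp(-t/tau_bolus_decay) - exp(-t/tau_bolus_rise))
         + ramp_slope * t * (1 - exp(-t/tau_saturation))

    ``bolus_fraction`` (default 0.2, emulating a 20:80 bolus:infusion
    administration split) sets the bolus amplitude relative to the infusion
    term when ``bolus_amplitude`` is not given explicitly.
    """

    ramp_slope: float = 0.06          # activity units per second
    tau_saturation: float = 300.0     # s, approach to the linear ramp
    bolus_fraction: float = 0.2
    tau_bolus_rise: float = 15.0      # s, ~1 min bolus rise
    tau_bolus_decay: float = 60.0     # s, bolus washout into tissue
    bolus_amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tau_saturation", "tau_bolus_rise", "tau_bolus_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_bolus_rise >= self.tau_bolus_decay:
            raise ValueError("tau_bolus_rise must be shorter than tau_bolus_decay")
        if not 0.0 <= self.bolus_fraction < 1.0:
            raise ValueError("bolus_fraction must lie in [0, 1)")

    @property
    def effective_bolus_amplitude(self) -> float:
        if self.bolus_amplitude is not None:
            return float(self.bolus_amplitude)
        if self.bolus_fraction == 0.0:
            return 0.0
        # scale the bolus hump against the infusion term's equilibrium level
        return (self.bolus_fraction / (1.0 - self.bolus_fraction)
                * self.ramp_slope * self.tau_saturation)


def uptake_curve(t, params: UptakeParams = UptakeParams()) -> np.ndarray:
    """Evaluate the bolus + constant-infusion uptake trend at times ``t`` (s).

    U(0) = 0; with the default parameters the curve is non-decreasing once
    the bolus peak-trough transient has passed (~2 min).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t must be a 1D ascending array")
    a_b = params.effective_bolus_amplitude
    bolus = a_b * (np.exp(-t / params.tau_bolus_decay)
                   - np.exp(-t / params.tau_bolus_rise))
    infusion = params.ramp_slope * t * (1.0 - np.exp(-t / params.tau_saturation))
    return bolus + infusion


def band_limited_latents(
    n_frames: int,
    frame_duration: float,
    band: FrequencyBand,
    n_latents: int,
    rng,
    orthonormal: bool = True,
) -> np.ndarray:
    """Draw ``n_latents`` zero-mean signals with all spectral power inside ``band``.

    The signals are synthesized in the frequency domain: independent complex
    Gaussian coefficients on the Fourier-grid bins falling inside [low, high],
    zero elsewhere, inverse-transformed to the time domain. Their periodogram
    mass therefore lies entirely within the band. With ``orthonormal=True``
    (default) the latents are additionally orthogonalized, so their empirical
    covariance is exactly the identity — which makes the two routes to the
    ground-truth connectivity (empirical correlation of the components vs.
    the normalized loading Gram matrix) coincide.

    Returns an ``n_latents x n_frames`` array with unit-variance rows.
    """
    if n_latents < 1:
        raise ValueError("n_latents must be >= 1")
    band.validate_for(frame_duration)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.fft.rfftfreq(n_frames, d=frame_duration)
    in_band = (freqs > 0) & band.contains(freqs)
    n_bins = int(in_band.sum())
    if n_bins == 0:
        raise ValueError(
            f"band {band} contains no resolvable Fourier grid frequency "
            f"(T={n_frames}, dt={frame_duration})"
        )
    if orthonormal and n_latents > n_bins * 2:
        raise ValueError(
            f"cannot draw {n_latents} orthogonal latents from {n_bins} frequency bins"
        )
    coeffs = np.zeros((n_latents, freqs.size), dtype=complex)
    coeffs[:, in_band] = (rng.standard_normal((n_latents, n_bins))
                          + 1j * rng.standard_normal((n_latents, n_bins)))
    # the Nyquist bin (even T) must carry a real coefficient
    if n_frames % 2 == 0 and in_band[-1]:
        coeffs[:, -1] = coeffs[:, -1].real
    latents = np.fft.irfft(coeffs, n=n_frames, axis=1)
    if orthonormal:
        # QR over time: linear combinations of in-band sinusoids stay in-band
        q, r = np.linalg.qr(latents.T)
        sign = np.sign(np.diag(r))
        sign[sign == 0] = 1.0
        latents = (q * sign).T * np.sqrt(n_frames)  # unit variance, exact orthogonality
    else:
        sd = latents.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("degenerate latent draw (zero variance)")
        latents = latents / sd
    return latents


@dataclass(frozen=True)
class NetworkSpec:
    """A band-limited latent-factor network: regions x factors loading matrix."""

    band: FrequencyBand
    loading: np.ndarray  # R x C
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        loading = np.asarray(self.loading, dtype=float)
        if loading.ndim != 2 or loading.shape[1] < 1:
            raise ValueError("loading must be a 2D R x C array with C >= 1")
        if not np.any(np.abs(loading).sum(axis=1) > 0):
            raise ValueError("at least one row of the loading matrix must be nonzero")
        object.__setattr__(self, "loading", loading)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def n_regions(self) -> int:
        return self.loading.shape[0]

    def truth_connectivity(self) -> np.ndarray:
        """Normalized loading Gram matrix L L^T — the analytic ground truth."""
        gram = self.loading @ self.loading.T
        d = np.sqrt(np.diag(gram))
        if np.any(d == 0):
            raise ValueError("ground-truth correlation undefined for zero-loading rows")
        return gram / np.outer(d, d)


def random_loading(n_regions: int, n_factors: int, rng,
                   cross_scale: float = 0.35) -> np.ndarray:
    """Block-dominant loading matrix: each region loads 1 on its own factor
    plus smaller random cross-loadings, giving a non-trivial but structured
    ground-truth correlation pattern."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    loading = cross_scale * rng.standard_normal((n_regions, n_factors))
    # shuffle the region->factor assignment so independently drawn networks
    # do not share a common block structure
    own = rng.permutation(np.arange(n_regions) * n_factors // n_regions)
    loading[np.arange(n_regions), own] += 1.0
    return loading


@dataclass
class SimulationConfig:
    """Full configuration of one synthetic subject."""

    grid_shape: Tuple[int, int, int] = (24, 24, 16)
    n_frames: int = 1500
    frame_duration: float = 1.0
    scanner_profile: str = "high_sensitivity_1s"
    n_parcels: int = 20
    uptake: UptakeParams = field(default_factory=UptakeParams)
    networks: Optional[List[NetworkSpec]] = None  # default: one mid-band network
    uptake_tissue_weights: Tuple[float, float, float] = (1.0, 0.4, 0.1)  # GM, WM, CSF
    physio_amp_03hz: float = 1.0
    physio_amp_1hz: float = 0.5
    motion_step_mm: float = 0.002
    motion_step_rad: float = 5e-5
    motion_coupling: float = 0.5
    sigma0: float = 0.3
    seed: int = 0
    exclusion_s: float = 600.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 2 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 sizes >= 2, got {self.grid_shape}")
        if self.scanner_profile not in SCANNER_PROFILES:
            raise ValueError(
                f"unknown scanner_profile {self.scanner_profile!r}; "
                f"choose from {sorted(SCANNER_PROFILES)}"
            )
        if self.n_frames * self.frame_duration < 2 * self.exclusion_s:
            raise ValueError(
                "scan too short: n_frames * frame_duration must be >= "
                f"{2 * self.exclusion_s} s so an analyzable half remains after the "
                f"{self.exclusion_s} s uptake exclusion"
            )
        for name in ("physio_amp_03hz", "physio_amp_1hz", "motion_step_mm",
                     "motion_step_rad", "motion_coupling", "sigma0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "SimulationConfig":
        """Config with frame count/duration matching a scanner profile."""
        if profile not in SCANNER_PROFILES:
            raise ValueError(f"unknown scanner profile {profile!r}")
        spec = SCANNER_PROFILES[profile]
        params = dict(
            n_frames=spec["n_frames"],
            frame_duration=spec["frame_duration"],
            scanner_profile=profile,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def sensitivity_kcps_per_mbq(self) -> float:
        return SCANNER_PROFILES[self.scanner_profile]["sensitivity_kcps_per_mbq"]

    @property
    def noise_factor(self) -> float:
        """Noise sd multiplier relative to the high-sensitivity reference."""
        return float(np.sqrt(_REFERENCE_SENSITIVITY / self.sensitivity_kcps_per_mbq))

    def default_networks(self, rng) -> List[NetworkSpec]:
        band = FrequencyBand(0.01, 0.1)
        band.validate_for(self.frame_duration)
        loading = random_loading(self.n_parcels, 3, rng)
        return [NetworkSpec(band=band, loading=loading, amplitude=1.0)]


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated subject."""

    config: SimulationConfig
    components: List[np.ndarray]              # per network: R x T noiseless signals
    connectivity: List[ConnectivityMatrix]    # per network: truth correlation
    uptake: np.ndarray                        # U(t), length T
    motion: MotionTrace
    region_ids: np.ndarray


@dataclass
class SimulatedSubject:
    """Bundle returned by :func:`simulate_subject`."""

    series: DynamicSeries
    tissue_maps: dict        # {"GM": ..., "WM": ..., "CSF": ...}
    motion: MotionTrace
    parcels: ParcelMap
    truth: SimulationTruth


def _tissue_geometry(grid_shape):
    """Ribbon/core/ventricle tissue probabilities on a normalized ellipsoid.

    CSF fills the centre (the "ventricle"), WM a surrounding core, GM an
    outer ribbon. Radial trapezoid memberships give graded, mostly distinct
    probabilities so that top-fraction thresholding selects compartment cores.
    """
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    csf = np.clip((0.25 - r) / 0.25, 0.0, 1.0)
    wm = np.clip(1.0 - np.abs(r - 0.40) / 0.15, 0.0, 1.0)
    gm = np.clip(1.0 - np.abs(r - 0.70) / 0.15, 0.0, 1.0)
    return gm, wm, csf, r


def _build_parcels(gm_prob, n_parcels, grid_shape):
    """Split gray-matter voxels into n_parcels roughly contiguous sectors."""
    gm_mask = gm_prob >= 0.5
    idx = np.argwhere(gm_mask)
    if len(idx) < n_parcels:
        raise ValueError(
            f"grid too small: only {len(idx)} gray-matter voxels for "
            f"{n_parcels} parcels"
        )
    cx, cy = (grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0
    angle = np.arctan2(idx[:, 1] - cy, idx[:, 0] - cx)
    order = np.lexsort((angle, idx[:, 2]))
    idx = idx[order]
    labels = np.zeros(grid_shape, dtype=np.int32)
    bounds = np.linspace(0, len(idx), n_parcels + 1).astype(int)
    for k in range(n_parcels):
        sel = idx[bounds[k]:bounds[k + 1]]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = k + 1
    return labels, gm_mask


def simulate_subject(config: SimulationConfig) -> SimulatedSubject:
    """Generate one synthetic subject with full ground truth.

    The voxel signal is assembled additively:

    ``tissue-weighted U(t) + GM network components + CSF-weighted physio
    sinusoids + motion coupling + heteroscedastic noise``.

    A single master seed determines every random draw, so identical configs
    produce bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    # child streams in a fixed order keep outputs stable as code evolves
    rng_net, rng_motion, rng_gain, rng_phase, rng_noise = rng.spawn(5)

    t = np.arange(config.n_frames) * config.frame_duration
    uptake = uptake_curve(t, config.uptake)

    gm_prob, wm_prob, csf_prob, _ = _tissue_geometry(config.grid_shape)
    labels, gm_mask = _build_parcels(gm_prob, config.n_parcels, config.grid_shape)

    networks = config.networks
    if networks is None:
        networks = config.default_networks(rng_net.spawn(1)[0])
    for net in networks:
        if net.n_regions != config.n_parcels:
            raise ValueError(
                f"network loading has {net.n_regions} rows but the parcellation "
                f"has {config.n_parcels} regions"
            )

    components: List[np.ndarray] = []
    truth_mats: List[ConnectivityMatrix] = []
    region_ids = np.arange(1, config.n_parcels + 1)
    net_signal = np.zeros((config.n_parcels, config.n_frames))
    for net in networks:
        latents = band_limited_latents(
            config.n_frames, config.frame_duration, net.band,
            net.loading.shape[1], rng_net,
        )
        comp = net.amplitude * (net.loading @ latents)
        components.append(comp)
        truth_mats.append(
            make_connectivity(np.corrcoef(comp), region_ids,
                              method="pearson", band=net.band)
        )
        net_signal += comp

    # motion: slow random walk around zero
    steps = np.concatenate([
        rng_motion.normal(0.0, config.motion_step_mm, (config.n_frames, 3)),
        rng_motion.normal(0.0, config.motion_step_rad, (config.n_frames, 3)),
    ], axis=1)
    motion_params = np.cumsum(steps, axis=0)
    motion = MotionTrace(params=motion_params, frame_duration=config.frame_duration)

    data = np.empty(config.grid_shape + (config.n_frames,), dtype=float)
    w_gm, w_wm, w_csf = config.uptake_tissue_weights
    tissue_weight = w_gm * gm_prob + w_wm * wm_prob + w_csf * csf_prob
    np.multiply.outer(tissue_weight, uptake, out=data)

    # gray-matter network components, weighted by GM probability
    flat_labels = labels.reshape(-1)
    flat_gm = gm_prob.reshape(-1)
    voxels = np.flatnonzero(flat_labels > 0)
    data_flat = data.reshape(-1, config.n_frames)
    data_flat[voxels] += (flat_gm[voxels, None]
                          * net_signal[flat_labels[voxels] - 1])

    # physiological oscillations in CSF, sampled on the frame grid
    if config.physio_amp_03hz > 0 or config.physio_amp_1hz > 0:
        ph1, ph2 = rng_phase.uniform(0, 2 * np.pi, 2)
        physio = (config.physio_amp_03hz * np.sin(2 * np.pi * 0.3 * t + ph1)
                  + config.physio_amp_1hz * np.sin(2 * np.pi * 1.0 * t + ph2))
        data += np.multiply.outer(csf_prob, physio)

    # motion coupling: standardized params times a per-voxel gain vector
    if config.motion_coupling > 0:
        m_sd = motion_params.std(axis=0, ddof=0)
        m_sd[m_sd == 0] = 1.0
        m_std = (motion_params - motion_params.mean(axis=0)) / m_sd
        n_vox = int(np.prod(config.grid_shape))
        gains = rng_gain.normal(0.0, config.motion_coupling, (n_vox, 6))
        data_flat += gains @ m_std.T

    # pseudo-Poisson noise: sd ~ sqrt(activity), scaled by scanner sensitivity
    if config.sigma0 > 0:
        sd_t = config.sigma0 * np.sqrt(np.maximum(uptake, 1e-3)) * config.noise_factor
        noise = rng_noise.standard_normal(data.shape)
        noise *= sd_t  # broadcasts over the trailing frame axis
        data += noise

    series = DynamicSeries(data=data, frame_duration=config.frame_duration,
                           voxel_size=(2.0, 2.0, 2.0))
    tissue_maps = {
        name: TissueProbabilityMap(prob=prob, tissue_class=name,
                                   voxel_size=(2.0, 2.0, 2.0))
        for name, prob in (("GM", gm_prob), ("WM", wm_prob), ("CSF", csf_prob))
    }
    networks_per_region = 1 + (region_ids - 1) * 7 // config.n_parcels
    table = pd.DataFrame({
        "label": region_ids,
        "name": [f"GM-{i:03d}" for i in region_ids],
        "network": [f"Net{k}" for k in networks_per_region],
    })
    parcels = ParcelMap(labels=labels, region_table=table, voxel_size=(2.0, 2.0, 2.0))
    truth = SimulationTruth(
        config=config, components=components, connectivity=truth_mats,
        uptake=uptake, motion=motion, region_ids=region_ids,
    )
    return SimulatedSubject(series=series, tissue_maps=tissue_maps, motion=motion,
                            parcels=parcels, truth=truth)


def simulate_region_series(
    networks: Sequence[NetworkSpec],
    n_frames: int,
    frame_duration: float,
    noise_sd: float,
    rng,
    include_uptake: bool = False,
    uptake: UptakeParams = UptakeParams(),
) -> RegionTimeSeries:
    """Light-weight region-level simulation (no voxel grid).

    Useful for statistics that need many subjects, e.g. split-half
    reliability: region signals = sum of network components + white noise
    (+ optionally the uptake trend).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_regions = networks[0].n_regions
    values = np.zeros((n_regions, n_frames))
    for net in networks:
        latents = band_limited_latents(n_frames, frame_duration, net.band,
                                       net.loading.shape[1], rng)
        values += net.amplitude * (net.loading @ latents)
    if include_uptake:
        t = np.arange(n_frames) * frame_duration
        values += uptake_curve(t, uptake)[None, :]
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, values.shape)
    return RegionTimeSeries(values=values, region_ids=np.arange(1, n_regions + 1),
                            frame_duration=frame_duration)
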