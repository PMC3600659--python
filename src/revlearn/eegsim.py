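"""Synthetic feedback-locked EEG epochs and voxel current-density maps.

Epoch templates are compact-support Gaussian bumps: an early positive
peak (150-220 ms), a valence-dependent negativity confined to the
220-350 ms window, and a late slow wave.  The extra negativity added to
negative-feedback epochs is calibrated on the discrete sampling grid so
that the downstream differential FRN score at FCz equals the configured
value exactly when noise is zero.

Voxel maps are drawn from a bivariate model per anatomical area,
``density = baseline + scale * (rho * z_frn + sqrt(1 - rho^2) * eps)``,
so each area's population density-FRN correlation matches its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erp import EpochSet, ScoringConfig
from .sources import DEFAULT_SOURCE_WINDOW, CurrentDensityMap

__all__ = [
    "SynthEEGConfig",
    "AreaSpec",
    "SourceSynthConfig",
    "HC_AREA_TARGETS",
    "PG_AREA_TARGETS",
    "CDI_AREA_TARGETS",
    "default_source_config",
    "component_templates",
    "generate_epochs",
    "generate_source_maps",
]


def _bump(times: np.ndarray, center: float, sigma: float, support=None):
    """Gaussian bump, hard-truncated to ``support`` (ms) so it is exactly
    zero outside — keeps scoring windows analytically separable."""
    v = np.exp(-0.5 * ((times - center) / sigma) ** 2)
    if support is not None:
        lo, hi = support
        v = np.where((times >= lo) & (times <= hi), v, 0.0)
    return v


@dataclass(frozen=True)
class SynthEEGConfig:
    channels: tuple = ("Fz", "FCz", "Pz")
    sfreq: float = 250.0
    tmin_ms: float = -200.0
    n_samples: int = 138                       # -200 .. +348 ms at 4 ms
    # early positive peak (inside the 150-220 ms peak window)
    p1_center: float = 185.0
    p1_sigma: float = 18.0
    p1_amp: float = 6.0
    p1_weights: tuple = (0.8, 1.0, 0.6)
    # feedback negativity bump: support strictly inside (220, 350]
    frn_center: float = 285.0
    frn_sigma: float = 22.0
    frn_support: tuple = (224.0, 346.0)
    frn_pf_amp: float = -1.0                   # small negativity after PF
    frn_weights: tuple = (0.8, 1.0, 0.4)       # largest at FCz
    frn_differential: float = 3.0              # uV at FCz (default target)
    # late slow wave
    p3_center: float = 330.0
    p3_sigma: float = 35.0
    p3_amp: float = 4.0
    p3_weights: tuple = (0.6, 0.8, 1.0)
    # noise and artifacts
    noise_sd: float = 8.0                      # uV per sample
    pink_fraction: float = 0.6                 # share of 1/f power
    artifact_rate: float = 0.0
    artifact_amp: float = 150.0
    # epoch counts (used when no trial log is supplied)
    n_pf: int = 100
    n_nf: int = 60

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return self.tmin_ms + step * np.arange(self.n_samples)


def component_templates(config: SynthEEGConfig, frn_differential: float,
                        scoring: ScoringConfig = ScoringConfig()):
    """Noise-free per-condition templates (channels x samples).

    The NF template equals the PF template plus an extra negativity whose
    amplitude is solved on the discrete grid so the differential FRN
    score (PF - NF) at the maximally weighted channel equals
    ``frn_differential`` exactly.
    """
    t = config.times
    p1 = _bump(t, config.p1_center, config.p1_sigma)
    frn_shape = _bump(t, config.frn_center, config.frn_sigma, config.frn_support)
    p3 = _bump(t, config.p3_center, config.p3_sigma)

    lo, hi = scoring.frn_mean_window
    mean_mask = (t >= lo) & (t <= hi)
    m = frn_shape[mean_mask].mean()
    plo, phi = scoring.frn_peak_window
    if frn_shape[(t >= plo) & (t <= phi)].any():
        raise ValueError("FRN bump support leaks into the peak window")
    # differential = -w_max * extra * m  (w_max = 1 by convention)
    extra = -frn_differential / m

    pf = np.empty((len(config.channels), len(t)))
    nf = np.empty_like(pf)
    for i in range(len(config.channels)):
        base = (config.p1_weights[i] * config.p1_amp * p1
                + config.frn_weights[i] * config.frn_pf_amp * frn_shape
                + config.p3_weights[i] * config.p3_amp * p3)
        pf[i] = base
        nf[i] = base + config.frn_weights[i] * extra * frn_shape
    return {"PF": pf, "NF": nf}


def _noise(rng, shape, sfreq, sd, pink_fraction):
    """Mixture of 1/f-shaped and white noise, unit-sd scaled to ``sd``."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    pink = np.fft.irfft(spec * shaping, n=n, axis=-1)
    pink_sd = pink.std()
    if pink_sd > 0:
        pink = pink / pink_sd
    mix = np.sqrt(pink_fraction) * pink + np.sqrt(1 - pink_fraction) * white
    return sd * mix


def generate_epochs(profile, config: SynthEEGConfig = SynthEEGConfig(),
                    seed=None, n_pf=None, n_nf=None,
                    scoring: ScoringConfig = ScoringConfig()) -> EpochSet:
    """Draw feedback-locked epochs for one participant.

    ``profile`` may be ``None`` (use the config's default differential)
    or a :class:`~revlearn.cohort.ParticipantProfile`, whose
    ``erp_effect['frn_differential']`` calibrates the NF negativity.
    Artifact epochs (rate ``config.artifact_rate``) receive a spike
    exceeding the rejection threshold.
    """
    rng = np.random.default_rng(seed)
    d = config.frn_differential
    if profile is not None:
        d = profile.erp_effect.get("frn_differential", d)
    templates = component_templates(config, d, scoring)
    n_pf = config.n_pf if n_pf is None else int(n_pf)
    n_nf = config.n_nf if n_nf is None else int(n_nf)
    conditions = np.array(["PF"] * n_pf + ["NF"] * n_nf)
    n_ch = len(config.channels)
    data = np.empty((n_pf + n_nf, n_ch, config.n_samples))
    for i, cond in enumerate(conditions):
        data[i] = templates[cond]
    if config.noise_sd > 0:
        data += _noise(rng, data.shape, config.sfreq, config.noise_sd,
                       config.pink_fraction)
    if config.artifact_rate > 0:
        hit = rng.random(n_pf + n_nf) < config.artifact_rate
        for i in np.flatnonzero(hit):
            ch = rng.integers(n_ch)
            s = rng.integers(config.n_samples)
            data[i, ch, s] += float(rng.choice([-1, 1])) * config.artifact_amp
    return EpochSet(data=data, times=config.times,
                    channels=list(config.channels), conditions=conditions,
                    sfreq=config.sfreq)


# -- voxel current-density synthesis ----------------------------------

@dataclass(frozen=True)
class AreaSpec:
    n_voxels: int
    target_r: float

    def __post_init__(self):
        if self.n_voxels < 1:
            raise ValueError("each area needs at least one voxel")
        if not (-1.0 < self.target_r < 1.0):
            raise ValueError("target correlations must lie in (-1, 1)")


#: Reported density-FRN correlations in controls (calibration targets)
#: with the reported voxel-cluster sizes.
HC_AREA_TARGETS = {
    "BA9": (10, -0.70),
    "BA10": (16, -0.75),
    "BA13": (9, -0.71),
    "BA23": (4, -0.75),
    "BA46": (16, -0.74),
}
#: Clinical-group calibration targets for the same areas.
PG_AREA_TARGETS = {
    "BA9": (10, 0.35), "BA10": (16, 0.34), "BA13": (9, 0.72),
    "BA23": (4, 0.78), "BA46": (16, 0.07),
}
CDI_AREA_TARGETS = {
    "BA9": (10, -0.47), "BA10": (16, -0.43), "BA13": (9, -0.53),
    "BA23": (4, -0.42), "BA46": (16, -0.36),
}


@dataclass(frozen=True)
class SourceSynthConfig:
    areas: dict = field(default_factory=dict)   # name -> AreaSpec
    baseline: float = 10.0
    scale: float = 1.0
    noise_scale: float = 1.0                    # 0 => sample r -> +/-1
    window: tuple = DEFAULT_SOURCE_WINDOW

    def __post_init__(self):
        if not self.areas:
            object.__setattr__(self, "areas", _default_areas("HC"))
        for name, spec in self.areas.items():
            if not isinstance(spec, AreaSpec):
                raise TypeError(f"area {name} must be an AreaSpec")


def _default_areas(group: str) -> dict:
    targets = {"HC": HC_AREA_TARGETS, "PG": PG_AREA_TARGETS,
               "CDI": CDI_AREA_TARGETS}[group]
    areas = {name: AreaSpec(k, r) for name, (k, r) in targets.items()}
    areas["null_parietal"] = AreaSpec(20, 0.0)
    areas["null_occipital"] = AreaSpec(20, 0.0)
    return areas


def default_source_config(group: str = "HC") -> SourceSynthConfig:
    """Calibrated per-group source config: the five reported areas at
    their reported cluster sizes and correlations, plus two null areas."""
    return SourceSynthConfig(areas=_default_areas(group))


def generate_source_maps(frn_scores, config: SourceSynthConfig = None,
                         seed=None, participant_ids=None) -> CurrentDensityMap:
    """Participant x voxel densities whose per-area population
    correlation with the FRN scores equals each area's target.

    Densities are shifted to be non-negative (shifts do not change
    correlations).  Null-area voxels are independent of the FRN.
    """
    config = config or default_source_config("HC")
    frn = np.asarray(frn_scores, dtype=float)
    n = len(frn)
    if n < 4:
        raise ValueError("need at least 4 participants")
    sd = frn.std(ddof=1)
    if sd == 0:
        raise ValueError("FRN scores are constant")
    z = (frn - frn.mean()) / sd
    rng = np.random.default_rng(seed)
    cols = []
    areas = []
    for name, spec in config.areas.items():
        rho = spec.target_r
        eps = rng.standard_normal((n, spec.n_voxels))
        block = config.scale * (rho * z[:, None]
                                + config.noise_scale * np.sqrt(1 - rho**2) * eps)
        cols.append(block)
        areas.extend([name] * spec.n_voxels)
    dens = config.baseline + np.concatenate(cols, axis=1)
    mn = dens.min()
    if mn < 0:
        dens = dens - mn
    return CurrentDensityMap(densities=dens, areas=areas,
                             participant_ids=list(participant_ids or []),
                             window=tuple(config.window))
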