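"""Synthetic paired master/slave NIR-like datasets.

Real transfer experiments need the same samples measured on two
spectrometers. This module emulates that situation from first
principles so every algorithm in the package is testable without any
download: smooth, highly collinear absorbance spectra arise from
Beer-Lambert-like linear mixing of overlapping Gaussian peak spectra,
the property of interest is linear in one component's concentration,
and the slave instrument re-measures the same (noise-free) signal
through a parameterized chain of distortions — fractional wavelength
shift, multiplicative gain, additive and sloped baseline, Gaussian peak
broadening, and its own measurement noise.

Three ready scenarios mirror the dimensions of the public benchmark
datasets this field routinely uses (an 80-sample corn set at 700
channels, a 248-sample wheat set, a 655-tablet set), with the
inter-instrument difference smallest in the wheat-like scenario.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigError
from .pls import PLS1Model
from .spectra import SpectraSet

__all__ = [
    "InstrumentDistortion",
    "SimulationConfig",
    "generate_paired_spectra",
    "make_paper_like_scenario",
    "plant_untransferable_directions",
]


@dataclass
class InstrumentDistortion:
    """Parameterized master-to-slave instrument difference.

    All-default (zero/identity) settings reproduce the master signal
    bit-for-bit before noise.

    Parameters
    ----------
    wavelength_shift:
        Channel shift, may be fractional; applied by linear
        interpolation with edge clamping. Positive moves features to
        higher channels.
    gain:
        Multiplicative factor, scalar or a smooth length-p curve.
    baseline_offset, baseline_slope:
        Additive baseline ``offset + slope * t`` with ``t`` running 0..1
        across the axis.
    broadening_sigma:
        Gaussian convolution width in channels (0 = off).
    noise_sigma:
        Slave measurement noise, absorbance units; scalar or a length-p
        curve for heteroscedastic noise.
    """

    wavelength_shift: float = 0.0
    gain: float | np.ndarray = 1.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    broadening_sigma: float = 0.0
    noise_sigma: float | np.ndarray = 0.0

    def apply(self, signal: np.ndarray) -> np.ndarray:
        """Distort noise-free spectra (no noise added here)."""
        out = np.array(signal, dtype=float, copy=True)
        p = out.shape[1]
        if self.broadening_sigma > 0:
            out = gaussian_filter1d(out, self.broadening_sigma, axis=1, mode="nearest")
        if self.wavelength_shift != 0.0:
            idx = np.arange(p, dtype=float)
            src = idx - self.wavelength_shift
            out = np.stack([np.interp(src, idx, row) for row in out])
        out = out * np.asarray(self.gain, dtype=float)
        if self.baseline_offset != 0.0 or self.baseline_slope != 0.0:
            t = np.linspace(0.0, 1.0, p)
            out = out + self.baseline_offset + self.baseline_slope * t
        return out


@dataclass
class SimulationConfig:
    """Everything that determines one paired dataset, given the seed.

    The peak library (per-component Gaussian centers/widths/heights) is
    drawn from the seed unless given explicitly; widths default to
    30-90 channels, wide enough that spectra are smooth and strongly
    collinear across neighboring channels, as NIR absorbance is.
    Concentrations are Dirichlet compositions times a per-sample
    positive scale, so spectra stay non-negative and the concentration
    matrix keeps full column rank. The response is linear in one
    designated component's concentration.
    """

    n_samples: int = 80
    n_channels: int = 700
    n_components: int = 4
    wavelength_start: float = 1100.0
    wavelength_step: float = 2.0
    n_peaks_per_component: int = 3
    peak_width_range: tuple[float, float] = (30.0, 90.0)
    peak_height_range: tuple[float, float] = (0.3, 1.0)
    peak_centers: list[list[float]] | None = None
    peak_widths: list[list[float]] | None = None
    peak_heights: list[list[float]] | None = None
    concentration_alpha: float = 1.0
    concentration_scale_range: tuple[float, float] = (0.7, 1.3)
    y_component: int = 0
    y_coefficient: float = 4.0
    y_intercept: float = 9.0
    y_noise_sigma: float = 0.0
    master_noise_sigma: float | np.ndarray = 0.0
    distortion: InstrumentDistortion = field(default_factory=InstrumentDistortion)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_channels, self.n_components) < 1:
            raise ConfigError("n_samples, n_channels and n_components must be positive")
        if not (0 <= self.y_component < self.n_components):
            raise ConfigError(f"y_component={self.y_component} outside components")
        if self.wavelength_step <= 0:
            raise ConfigError("wavelength_step must be positive")

    def to_json(self, path: str | Path | None = None) -> dict:
        d = asdict(self)
        for key in ("gain", "noise_sigma"):
            if isinstance(d["distortion"][key], np.ndarray):
                d["distortion"][key] = d["distortion"][key].tolist()
        if isinstance(d["master_noise_sigma"], np.ndarray):
            d["master_noise_sigma"] = d["master_noise_sigma"].tolist()
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SimulationConfig":
        d = dict(source) if isinstance(source, dict) else json.loads(Path(source).read_text())
        dist = d.pop("distortion", {})
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) and k.endswith("_range") else v)
                     for k, v in d.items()},
                  distortion=InstrumentDistortion(**dist))
        return cfg


def _pure_spectra(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Component pure spectra: sums of Gaussian peaks over the channel axis."""
    p, nc, npk = cfg.n_channels, cfg.n_components, cfg.n_peaks_per_component
    if cfg.peak_centers is not None:
        centers = np.asarray(cfg.peak_centers, dtype=float)
        widths = np.asarray(cfg.peak_widths, dtype=float)
        heights = np.asarray(cfg.peak_heights, dtype=float)
    else:
        margin = 0.05 * p
        centers = rng.uniform(margin, p - margin, size=(nc, npk))
        widths = rng.uniform(*cfg.peak_width_range, size=(nc, npk))
        heights = rng.uniform(*cfg.peak_height_range, size=(nc, npk))
    idx = np.arange(p, dtype=float)
    S = np.zeros((centers.shape[0], p))
    for i in range(centers.shape[0]):
        for c, w, h in zip(centers[i], widths[i], heights[i]):
            S[i] += h * np.exp(-0.5 * ((idx - c) / w) ** 2)
    return S


def generate_paired_spectra(config: SimulationConfig) -> tuple[SpectraSet, SpectraSet]:
    """Draw one paired master/slave dataset.

    The master measures signal + its own noise; the slave measures the
    distorted noise-free signal + its own independent noise. Sample
    order and ids are identical across instruments, as they are the
    same physical samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S = _pure_spectra(config, rng)
    n, p = config.n_samples, config.n_channels
    conc = rng.dirichlet(np.full(config.n_components, config.concentration_alpha), size=n)
    conc *= rng.uniform(*config.concentration_scale_range, size=(n, 1))
    signal = conc @ S
    y = (
        config.y_intercept
        + config.y_coefficient * conc[:, config.y_component]
        + (rng.normal(0.0, config.y_noise_sigma, n) if config.y_noise_sigma else 0.0)
    )
    master_noise = np.asarray(config.master_noise_sigma, dtype=float)
    Xm = signal + (rng.normal(size=(n, p)) * master_noise if np.any(master_noise) else 0.0)
    slave_signal = config.distortion.apply(signal)
    slave_noise = np.asarray(config.distortion.noise_sigma, dtype=float)
    Xs = slave_signal + (rng.normal(size=(n, p)) * slave_noise if np.any(slave_noise) else 0.0)
    wl = config.wavelength_start + config.wavelength_step * np.arange(p)
    ids = [f"s{i:05d}" for i in range(n)]
    return (
        SpectraSet(X=Xm, wavelengths=wl, y=y.copy(), ids=list(ids)),
        SpectraSet(X=Xs, wavelengths=wl, y=y.copy(), ids=list(ids)),
    )


_SCENARIOS = {
    # distortion magnitudes ordered wheat_like < tablet_like < corn_like
    "corn_like": dict(
        n_samples=80, n_channels=700, n_components=4,
        wavelength_start=1100.0, wavelength_step=2.0,
        y_intercept=9.0, y_coefficient=4.0, y_noise_sigma=0.01,
        master_noise_sigma=0.0005,
        distortion=InstrumentDistortion(
            wavelength_shift=1.0, gain=1.05,
            baseline_offset=0.02, noise_sigma=0.001,
        ),
    ),
    "wheat_like": dict(
        n_samples=248, n_channels=741, n_components=4,
        wavelength_start=730.0, wavelength_step=0.5,
        y_intercept=11.0, y_coefficient=5.0, y_noise_sigma=0.02,
        master_noise_sigma=0.0005,
        distortion=InstrumentDistortion(
            wavelength_shift=0.3, gain=1.01,
            baseline_offset=0.005, noise_sigma=0.0005,
        ),
    ),
    "tablet_like": dict(
        n_samples=655, n_channels=650, n_components=5,
        wavelength_start=600.0, wavelength_step=2.0,
        y_intercept=200.0, y_coefficient=60.0, y_noise_sigma=0.5,
        master_noise_sigma=0.0005,
        distortion=InstrumentDistortion(
            wavelength_shift=0.5, gain=1.03, baseline_offset=0.01,
            baseline_slope=0.005, noise_sigma=0.001,
        ),
    ),
}


def make_paper_like_scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Ready-made config emulating a public benchmark dataset's shape."""
    if name not in _SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    return replace(SimulationConfig(seed=seed), **_SCENARIOS[name], seed=seed)


def plant_untransferable_directions(
    model: PLS1Model, X, k_star: int, magnitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Destroy the information in PLS score directions beyond ``k_star``.

    The score contributions after ``k_star`` are replaced by pure
    Gaussian noise through the loadings ``P[:, k_star:]``; because
    ``P' W (P' W)^{-1} = I``, exactly the score columns after ``k_star``
    are scrambled while the first ``k_star`` features survive intact —
    a planted ground truth for factor-count selection.
    """
    Xm = np.atleast_2d(np.asarray(X, dtype=float))
    n_extra = model.A - k_star
    if n_extra <= 0:
        return Xm.copy()
    scores = (Xm - model.x_mean) @ model.rotation()[:, k_star:]
    noise = rng.normal(0.0, magnitude, size=(Xm.shape[0], n_extra))
    return Xm + (noise - scores) @ model.P[:, k_star:].T
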