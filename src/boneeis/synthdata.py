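"""Seeded generator of labeled synthetic bone EIS datasets.

Stands in for the (unreleased) bench measurements: six mineral-content
classes (0..100 wt%), circuit parameters following the observed trends —
bulk resistance R_b rising log-linearly with mineral content, interfacial
R_Ct and CPE magnitude Q stepping between two plateaus at 80 wt%, constant
CPE exponent — plus lognormal inter-sample parameter variability and
multiplicative Gaussian measurement noise on the rectangular impedance
components.

The default class-mean scales were calibrated once so that the noiseless
intact-bone spectrum shows the characteristic ~60 deg phase magnitude at
1 Hz (the CPE dominates both R_b and R_Ct at the low-frequency end) while
class-mean |Z|(1 Hz) stays strictly ordered by mineral content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import (
    CircuitParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    circuit_impedance,
    make_grid,
)
from .exceptions import InvalidArgumentError

__all__ = [
    "GeneratorConfig",
    "Sample",
    "LabeledDataset",
    "class_mean_params",
    "sample_spectrum",
    "generate_dataset",
    "DEFAULT_CLASS_LABELS",
    "DEFAULT_N_PER_CLASS",
]

#: Mineral-content class labels, wt%.
DEFAULT_CLASS_LABELS = (0, 20, 40, 60, 80, 100)
#: Per-class sample counts; total 91 (train+test per class of the study design).
DEFAULT_N_PER_CLASS = (16, 16, 16, 15, 12, 16)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic dataset.

    ``r_b_log10_at_0/100`` define the log-linear bulk-resistance rule
    (10 kOhm at 0 wt% to 316 kOhm at 100 wt%); ``r_ct_*``/``q_*`` are the
    two plateau levels with the step at ``plateau_threshold`` wt%.
    """

    class_labels: tuple = DEFAULT_CLASS_LABELS
    n_per_class: tuple = DEFAULT_N_PER_CLASS
    param_cv: float = 0.10
    noise_sd: float = 0.02
    grid: FrequencyGrid = field(default_factory=make_grid)
    seed: int = 0
    r_b_log10_at_0: float = 4.0
    r_b_log10_at_100: float = 5.5
    r_ct_high: float = 5.0e8
    r_ct_low: float = 1.0e8
    q_high: float = 3.0e-8
    q_low: float = 4.5e-8
    plateau_threshold: float = 80.0
    alpha: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.n_per_class):
            raise InvalidArgumentError("class_labels and n_per_class lengths differ")
        if any(n < 1 for n in self.n_per_class):
            raise InvalidArgumentError("n_per_class entries must be >= 1")
        if self.param_cv < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("param_cv and noise_sd must be >= 0")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    label: float
    spectrum: ImpedanceSpectrum
    true_params: CircuitParams | None = None


@dataclass(frozen=True)
class LabeledDataset:
    """Collection of labeled spectra sharing one frequency grid."""

    samples: tuple

    def __post_init__(self) -> None:
        if self.samples:
            n0 = len(self.samples[0].spectrum.grid)
            f0 = self.samples[0].spectrum.grid.frequencies
            for s in self.samples:
                f = s.spectrum.grid.frequencies
                if len(f) != n0 or not np.allclose(f, f0):
                    raise InvalidArgumentError(
                        f"sample {s.sample_id!r} is on a different frequency grid"
                    )
        object.__setattr__(self, "samples", tuple(self.samples))

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=float)

    @property
    def grid(self) -> FrequencyGrid:
        return self.samples[0].spectrum.grid


def class_mean_params(
    wt_percent: float, config: GeneratorConfig | None = None
) -> CircuitParams:
    """Class-mean circuit parameters for a mineral content in [0, 100] wt%.

    R_b is log-linear in wt%; R_Ct and Q take their high plateau at and
    above ``plateau_threshold`` (default 80 wt%); alpha is constant.
    """
    cfg = config or GeneratorConfig()
    if not (0.0 <= wt_percent <= 100.0):
        raise InvalidArgumentError(f"wt_percent must be in [0, 100], got {wt_percent!r}")
    log_rb = cfg.r_b_log10_at_0 + (wt_percent / 100.0) * (
        cfg.r_b_log10_at_100 - cfg.r_b_log10_at_0
    )
    high = wt_percent >= cfg.plateau_threshold
    return CircuitParams(
        r_b=10.0 ** log_rb,
        r_ct=cfg.r_ct_high if high else cfg.r_ct_low,
        q=cfg.q_high if high else cfg.q_low,
        alpha=cfg.alpha,
    )


def _lognormal_around(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Draw lognormally with expectation ``mean`` and coefficient of
    variation ``cv`` (degenerate to ``mean`` when cv == 0)."""
    if cv == 0:
        return mean
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(mean * np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def sample_spectrum(
    config: GeneratorConfig, wt_percent: float, rng: np.random.Generator
) -> tuple[CircuitParams, ImpedanceSpectrum]:
    """Draw one sample's circuit parameters and noisy spectrum.

    R_b, R_Ct, Q are drawn lognormally around the class means with CV
    ``param_cv`` (alpha held fixed); multiplicative Gaussian noise
    ``(1 + eps)``, ``eps ~ N(0, noise_sd^2)``, is applied independently to
    the real and imaginary components per frequency; the imaginary part is
    clamped to <= 0 (capacitive circuit).
    """
    mean = class_mean_params(wt_percent, config)
    params = CircuitParams(
        r_b=_lognormal_around(mean.r_b, config.param_cv, rng),
        r_ct=_lognormal_around(mean.r_ct, config.param_cv, rng),
        q=_lognormal_around(mean.q, config.param_cv, rng),
        alpha=mean.alpha,
    )
    clean = circuit_impedance(params, config.grid)
    n = len(config.grid)
    z_real = clean.z_real * (1.0 + rng.normal(0.0, config.noise_sd, n)) \
        if config.noise_sd > 0 else clean.z_real.copy()
    z_imag = clean.z_imag * (1.0 + rng.normal(0.0, config.noise_sd, n)) \
        if config.noise_sd > 0 else clean.z_imag.copy()
    z_imag = np.minimum(z_imag, 0.0)
    return params, ImpedanceSpectrum(grid=config.grid, z_real=z_real, z_imag=z_imag)


def generate_dataset(config: GeneratorConfig | None = None) -> LabeledDataset:
    """Generate the full labeled dataset (default: 91 samples over 6 classes).

    Deterministic for a fixed config (including its seed); true parameters
    are retained on each sample for recovery testing.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for label, n in zip(cfg.class_labels, cfg.n_per_class):
        for i in range(n):
            params, spectrum = sample_spectrum(cfg, label, rng)
            samples.append(
                Sample(
                    sample_id=f"wt{int(label):03d}_{i:02d}",
                    label=float(label),
                    spectrum=spectrum,
                    true_params=params,
                )
            )
    return LabeledDataset(samples=tuple(samples))
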