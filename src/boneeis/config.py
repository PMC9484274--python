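"""Flat YAML run configuration.

Every key is optional and overrides a documented default; unknown keys are
rejected with a message listing the valid ones. The same file drives
``boneeis simulate`` and ``boneeis pipeline``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .circuit import make_grid
from .exceptions import FormatError
from .fitting import FitOptions
from .mlpipe import SplitSpec
from .pipeline import PipelineConfig
from .synthdata import GeneratorConfig

__all__ = ["load_run_config", "KNOWN_KEYS"]

KNOWN_KEYS = {
    # generator
    "seed": "master seed fanned out to every stage",
    "class_labels": "mineral-content class labels, wt%",
    "n_per_class": "samples per class",
    "param_cv": "inter-sample coefficient of variation",
    "noise_sd": "multiplicative spectral noise sd",
    "f_min_hz": "grid lower bound",
    "f_max_hz": "grid upper bound",
    "n_points": "grid size",
    "r_b_log10_at_0": "log10 bulk resistance at 0 wt%",
    "r_b_log10_at_100": "log10 bulk resistance at 100 wt%",
    "r_ct_high": "interfacial resistance plateau >= threshold, ohm",
    "r_ct_low": "interfacial resistance plateau below threshold, ohm",
    "q_high": "CPE magnitude plateau >= threshold, S.s^alpha",
    "q_low": "CPE magnitude plateau below threshold, S.s^alpha",
    "plateau_threshold": "wt% where R_Ct/Q step",
    "alpha": "CPE exponent",
    # fitting
    "n_restarts": "Nelder-Mead restarts",
    "max_iterations": "iterations per restart",
    "fit_tol": "relative objective tolerance",
    "weighting": "residual weighting: modulus or unit",
    # features / PCA
    "feature_modes": "impedance_only and/or combined",
    "variance_threshold": "cumulative explained-variance threshold",
    # split / classifiers
    "train_per_class": "per-class training counts",
    "test_per_class": "per-class test counts",
    "classifiers": "subset of logistic,v_svm,neural_network,random_forest",
}


def load_run_config(path) -> PipelineConfig:
    """Parse a flat YAML config into a PipelineConfig."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise FormatError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError("config must be a flat key: value mapping")
    unknown = set(raw) - set(KNOWN_KEYS)
    if unknown:
        raise FormatError(
            f"unknown config keys {sorted(unknown)}; valid keys: "
            f"{sorted(KNOWN_KEYS)}"
        )

    grid = make_grid(
        raw.get("f_min_hz", 1.0),
        raw.get("f_max_hz", 1.0e5),
        raw.get("n_points", 60),
    )
    gen_kwargs = {}
    for key in (
        "param_cv", "noise_sd", "r_b_log10_at_0", "r_b_log10_at_100",
        "r_ct_high", "r_ct_low", "q_high", "q_low", "plateau_threshold", "alpha",
    ):
        if key in raw:
            gen_kwargs[key] = raw[key]
    if "class_labels" in raw:
        gen_kwargs["class_labels"] = tuple(raw["class_labels"])
    if "n_per_class" in raw:
        gen_kwargs["n_per_class"] = tuple(raw["n_per_class"])
    generator = GeneratorConfig(grid=grid, **gen_kwargs)

    fit_kwargs = {}
    if "n_restarts" in raw:
        fit_kwargs["n_restarts"] = raw["n_restarts"]
    if "max_iterations" in raw:
        fit_kwargs["max_iterations"] = raw["max_iterations"]
    if "fit_tol" in raw:
        fit_kwargs["tol"] = raw["fit_tol"]
    if "weighting" in raw:
        fit_kwargs["weighting"] = raw["weighting"]
    fit_options = FitOptions(**fit_kwargs)

    split_kwargs = {"class_labels": generator.class_labels}
    if "train_per_class" in raw:
        split_kwargs["train_per_class"] = tuple(raw["train_per_class"])
    if "test_per_class" in raw:
        split_kwargs["test_per_class"] = tuple(raw["test_per_class"])
    split_spec = SplitSpec(**split_kwargs)

    return PipelineConfig(
        generator=generator,
        fit_options=fit_options,
        split_spec=split_spec,
        classifier_kinds=tuple(
            raw.get(
                "classifiers",
                ("logistic", "v_svm", "neural_network", "random_forest"),
            )
        ),
        feature_modes=tuple(raw.get("feature_modes", ("impedance_only", "combined"))),
        variance_threshold=raw.get("variance_threshold", 0.90),
        master_seed=raw.get("seed", 7),
    )
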