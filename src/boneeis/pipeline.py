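"""End-to-end orchestration: simulate -> fit -> featurize -> reduce ->
split -> train -> evaluate.

One master seed fans out deterministically (via ``numpy.random.SeedSequence``)
to the generator, the circuit-fit restarts, the split and the classifiers,
so a single integer reproduces a whole run.

Component-selection defaults per feature mode: the impedance-only matrix is
reduced to the leading principal component when it carries >= 90% of the
variance (it does under the default generator), matching the study's
reduction. The combined matrix retains at least two components: the circuit
contributes two physically independent class-informative directions — the
bulk-resistance trend and the interfacial Q/R_Ct plateau step — and a 1-D
projection would discard one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import (
    build_features,
    pca_fit,
    pca_transform,
    standardize_apply,
    standardize_fit,
)
from .fitting import FitOptions, FitResult, fit_spectrum
from .mlpipe import ClassifierSpec, SplitSpec, evaluate, predict, split, train
from .synthdata import GeneratorConfig, LabeledDataset, generate_dataset

__all__ = ["PipelineConfig", "ModeResult", "derive_seeds", "run_pipeline",
           "MIN_COMPONENTS_BY_MODE"]

#: Principal components retained at minimum, per feature mode.
MIN_COMPONENTS_BY_MODE = {"impedance_only": 1, "combined": 2}


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    fit_options: FitOptions = field(default_factory=FitOptions)
    split_spec: SplitSpec = field(default_factory=SplitSpec)
    classifier_kinds: tuple = ("logistic", "v_svm", "neural_network", "random_forest")
    feature_modes: tuple = ("impedance_only", "combined")
    variance_threshold: float = 0.90
    master_seed: int = 7


def derive_seeds(master_seed: int) -> dict:
    """Fan one master seed out to the stochastic stages (all < 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    gen, fit, spl, clf = ss.spawn(4)
    to_int = lambda s: int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
    return {
        "generator": to_int(gen),
        "fit": to_int(fit),
        "split": to_int(spl),
        "classifier": to_int(clf),
    }


@dataclass(frozen=True)
class ModeResult:
    """Per-feature-mode outputs: PCA diagnostics plus one evaluation
    report per classifier kind."""

    mode: str
    n_components: int
    explained_variance_ratios: np.ndarray
    reports: dict


def run_pipeline(config: PipelineConfig | None = None,
                 dataset: LabeledDataset | None = None,
                 fits: list[FitResult] | None = None) -> dict:
    """Run the full comparison for every feature mode and classifier kind.

    Returns ``{mode: ModeResult}``. A pre-generated ``dataset`` (and
    optionally pre-computed ``fits``) may be supplied to reuse expensive
    stages; otherwise they are produced from the seeded config.
    """
    cfg = config or PipelineConfig()
    seeds = derive_seeds(cfg.master_seed)
    if dataset is None:
        dataset = generate_dataset(replace(cfg.generator, seed=seeds["generator"]))
    if "combined" in cfg.feature_modes and fits is None:
        fit_opts = replace(cfg.fit_options, seed=seeds["fit"])
        fits = [fit_spectrum(s.spectrum, fit_opts) for s in dataset.samples]
    split_spec = replace(cfg.split_spec, seed=seeds["split"])
    train_idx, test_idx = split(dataset.labels, split_spec)

    results = {}
    for mode in cfg.feature_modes:
        fm = build_features(dataset, fits=fits if mode == "combined" else None,
                            mode=mode)
        stats = standardize_fit(fm.values[train_idx])
        x_tr = standardize_apply(fm.values[train_idx], stats)
        x_te = standardize_apply(fm.values[test_idx], stats)
        model = pca_fit(
            x_tr,
            variance_threshold=cfg.variance_threshold,
            min_components=MIN_COMPONENTS_BY_MODE.get(mode, 1),
        )
        s_tr = pca_transform(x_tr, model)
        s_te = pca_transform(x_te, model)
        reports = {}
        for kind in cfg.classifier_kinds:
            spec = ClassifierSpec(kind=kind, seed=seeds["classifier"])
            clf = train(spec, s_tr, fm.labels[train_idx])
            pred = predict(clf, s_te)
            reports[kind] = evaluate(
                pred, fm.labels[test_idx], split_spec.class_labels
            )
        results[mode] = ModeResult(
            mode=mode,
            n_components=model.n_selected,
            explained_variance_ratios=model.explained_variance_ratios,
            reports=reports,
        )
    return results
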