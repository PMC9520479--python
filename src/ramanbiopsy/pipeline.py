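"""End-to-end orchestration of the three analysis variants.

Variants (all sharing identical train/test splits for paired comparison):

* ``pca_only``      — PCA(2) on the full cropped range, then RBF-SVM;
* ``filtered_svm``  — Fisher-criterion mask, retained wavenumbers
                      (z-scored on the training rows) straight into the SVM;
* ``combined``      — Fisher mask first, PCA(2) on the retained wavenumbers,
                      then the SVM.

A single 30% split of ~50 spectra is high-variance, so reporting defaults
to repeated seeded splits with means and standard deviations; a single-split
mode remains available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .classify import (
    ClassificationReport,
    ClassifyError,
    PCAModel,
    RBFSVMConfig,
    RepeatedSummary,
    SplitPlan,
    evaluate,
    fit_pca,
    project,
    split_train_test,
    train_svm,
)
from .feature_filter import FeatureMask, GroupedMatrix, build_mask, filter_matrix
from .preprocess import PreprocessConfig, preprocess_pipeline
from .spectra_io import SpectrumSet
from .synthetic import GeneratorConfig, generate_dataset

VARIANTS = ("pca_only", "filtered_svm", "combined")


@dataclass(frozen=True)
class VariantConfig:
    alpha: float = 0.05
    n_components: int = 2
    svm: RBFSVMConfig = field(default_factory=RBFSVMConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    standardize_filtered: bool = True
    # where the Fisher mask is estimated: "all" applies the filter once to
    # the whole dataset before splitting (the original protocol); "train"
    # re-estimates it inside every split (leakage-free)
    mask_scope: str = "all"
    # fit PCA on training rows only (default) or on all rows (figure mode)
    pca_on_all: bool = False


def _zscore_train(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def run_variant(m: GroupedMatrix, variant: str, cfg: VariantConfig,
                split_seed: int, patients: Sequence[str] | None = None,
                mask: FeatureMask | None = None) -> ClassificationReport:
    """Run one variant on one seeded split of a preprocessed matrix."""
    if variant not in VARIANTS:
        raise ClassifyError(f"unknown variant {variant!r}; expected {VARIANTS}")
    plan = SplitPlan(train_fraction=cfg.split.train_fraction,
                     min_per_class=cfg.split.min_per_class,
                     group_by_patient=cfg.split.group_by_patient,
                     seed=split_seed)
    train_idx, test_idx = split_train_test(m.labels, plan, patients)

    if variant in ("filtered_svm", "combined"):
        if mask is None:
            if cfg.mask_scope == "train":
                sub = GroupedMatrix(m.X[train_idx], m.labels[train_idx],
                                    m.wavenumbers)
                mask = build_mask(sub, cfg.alpha)
            else:
                mask = build_mask(m, cfg.alpha)
        fm = filter_matrix(m, mask)
        X = fm.X
    else:
        X = m.X

    Xtr, Xte = X[train_idx], X[test_idx]
    if variant in ("pca_only", "combined"):
        pca_input = X if cfg.pca_on_all else Xtr
        model = fit_pca(pca_input, cfg.n_components)
        Xtr = project(model, Xtr)
        Xte = project(model, Xte)
    elif cfg.standardize_filtered:
        Xtr, Xte = _zscore_train(Xtr, Xte)

    clf = train_svm(Xtr, m.labels[train_idx], cfg.svm)
    return evaluate(clf, Xte, m.labels[test_idx], variant=variant,
                    split_seed=split_seed)


def repeated_evaluation(m: GroupedMatrix, variant: str, cfg: VariantConfig,
                        n_repeats: int = 50, base_seed: int = 0,
                        patients: Sequence[str] | None = None
                        ) -> RepeatedSummary:
    """Repeat split -> train -> evaluate over seeded splits.

    Split seeds are derived from ``base_seed`` alone, so different variants
    called with the same ``base_seed`` see identical splits (paired design).
    """
    if n_repeats < 1:
        raise ClassifyError("n_repeats must be >= 1")
    seeds = derive_split_seeds(base_seed, n_repeats)
    mask = None
    if variant in ("filtered_svm", "combined") and cfg.mask_scope == "all":
        mask = build_mask(m, cfg.alpha)   # shared across repeats
    reports = [run_variant(m, variant, cfg, int(s), patients, mask)
               for s in seeds]
    return RepeatedSummary(variant=variant, reports=reports)


def derive_split_seeds(base_seed: int, n_repeats: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n_repeats) % (2 ** 31)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    variant_cfg: VariantConfig = field(default_factory=VariantConfig)
    variants: tuple[str, ...] = VARIANTS
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants:
            raise ClassifyError("at least one variant required")
        for v in self.variants:
            if v not in VARIANTS:
                raise ClassifyError(f"unknown variant {v!r}")


def run_full(config: PipelineConfig,
             measurements: SpectrumSet | None = None,
             backgrounds: SpectrumSet | None = None) -> dict:
    """Simulate (unless data given) -> preprocess -> per-variant repeated
    evaluation -> comparison report dict."""
    if measurements is None:
        measurements, backgrounds, _ = generate_dataset(config.generator)
    if backgrounds is None:
        raise ClassifyError("background frames are required")
    processed = preprocess_pipeline(measurements, backgrounds, config.preprocess)
    m = GroupedMatrix.from_spectrum_set(processed)
    patients = [s.meta.patient_id for s in processed]

    mask = build_mask(m, config.variant_cfg.alpha)
    summaries = {}
    for variant in config.variants:
        summaries[variant] = repeated_evaluation(
            m, variant, config.variant_cfg, config.n_repeats,
            base_seed=config.seed, patients=patients)

    report = {
        "n_spectra": int(m.X.shape[0]),
        "n_wavenumbers": int(m.X.shape[1]),
        "class_counts": {c: int(np.sum(m.labels == c))
                         for c in sorted(set(m.labels))},
        "retained_features": int(mask.n_kept),
        "alpha": config.variant_cfg.alpha,
        "f_critical": mask.f_critical,
        "n_repeats": config.n_repeats,
        "seed": config.seed,
        "variants": {v: s.to_dict() for v, s in summaries.items()},
        "provenance": processed.provenance,
        "config_hash": config_hash(config),
    }
    return report


def paired_specificity_test(a: RepeatedSummary, b: RepeatedSummary
                            ) -> tuple[float, float]:
    """One-sided paired test that variant ``a`` has higher specificity than
    ``b`` over matched split seeds.  Returns (mean difference, p-value)."""
    da = np.array([r.specificity for r in a.reports])
    db = np.array([r.specificity for r in b.reports])
    diff = da - db
    if np.allclose(diff, 0):
        return 0.0, 1.0
    t, p_two = stats.ttest_rel(da, db)
    p = p_two / 2 if t > 0 else 1 - p_two / 2
    return float(diff.mean()), float(p)


def config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
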