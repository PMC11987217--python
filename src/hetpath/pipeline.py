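"""End-to-end orchestration: study -> features -> model -> report."""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import SplitSpec
from .features import FeatureTable, feature_set
from .model_eval import (
    ClassifierSpec,
    EvaluationReport,
    FittedModel,
    evaluate,
    tune_and_train,
)
from .synthetic import StudyBundle, SyntheticConfig, generate_study


@dataclass
class StudyResult:
    bundle: StudyBundle
    train_features: FeatureTable
    test_features: FeatureTable
    model: FittedModel
    report: EvaluationReport

    def summary(self) -> dict:
        return {
            "auc": self.report.auc,
            "f1": self.report.f1,
            "threshold": self.report.threshold,
            "n_train": len(self.train_features),
            "n_test": len(self.test_features),
            "best_params": self.model.best_params,
            "algorithm": self.model.algorithm,
            "seed": self.model.seed,
            "preset": self.train_features.feature_set_name,
        }


def compute_study_features(
    bundle: StudyBundle, preset: str = "Feature-II", mask_mode: str = "paper"
) -> tuple[FeatureTable, FeatureTable]:
    """Train/test feature tables on the leakage-controlled network."""
    strict = mask_mode == "strict"
    train_ft = feature_set(
        bundle.network, bundle.train.pairs(), preset, mask_pair_edge=strict
    )
    test_ft = feature_set(
        bundle.network, bundle.test.pairs(), preset, mask_pair_edge=strict
    )
    return train_ft, test_ft


def run_study(
    config: SyntheticConfig,
    preset: str = "Feature-II",
    classifier: ClassifierSpec | None = None,
    split: SplitSpec | None = None,
    n_positives: int | None = None,
    mask_mode: str = "paper",
    ablate_signal: bool = False,
    threshold: float = 0.5,
) -> StudyResult:
    """Generate a study, extract features, tune/train, and evaluate."""
    classifier = classifier or ClassifierSpec(seed=config.seed, grid={"n_estimators": [300], "max_depth": [5]})
    bundle = generate_study(
        config, n_positives=n_positives, split=split,
        mask_mode=mask_mode, ablate_signal=ablate_signal,
    )
    train_ft, test_ft = compute_study_features(bundle, preset, mask_mode)
    model = tune_and_train(train_ft, bundle.train.labels(), classifier)
    report = evaluate(model, test_ft, bundle.test.labels(), threshold)
    return StudyResult(bundle, train_ft, test_ft, model, report)
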