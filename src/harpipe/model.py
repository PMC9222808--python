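"""Model/Results surface tying the pipeline together.

:class:`HARModel` is built from data (per-window feature records, or raw
recordings via :meth:`HARModel.from_recordings`); :meth:`HARModel.fit` runs
an evaluation protocol and returns a :class:`HARResults` carrying the
accuracy estimate with its across-run uncertainty, per-class diagnostics,
the pooled confusion matrix, and a printable ``summary()`` table.  A final
classifier trained on all records backs ``results.predict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import (
    ClassifierConfig,
    EvaluationReport,
    evaluate,
    run_protocol,
    sensitivity_grid,
    train_classifier,
)
from .features import NormalizationParams, apply_minmax, fit_minmax
from .io_formats import FeatureRecord, Recording
from .pipeline import PipelineConfig, extract_features, pipeline_config

__all__ = ["HARModel", "HARResults"]


class HARModel:
    """An activity-recognition model over per-window feature records.

    Parameters
    ----------
    records : sequence of FeatureRecord
        Already-extracted (and scaled) per-window feature vectors.
    classifier : ClassifierConfig, optional
        Defaults to a 200-tree depth-25 Random Forest.
    pipeline : PipelineConfig, optional
        Recorded for provenance when the model was built from recordings.
    """

    def __init__(
        self,
        records: Sequence[FeatureRecord],
        classifier: ClassifierConfig | None = None,
        pipeline: PipelineConfig | None = None,
    ) -> None:
        self.records = list(records)
        if not self.records:
            raise ValueError("no feature records")
        dims = {r.dim for r in self.records}
        if len(dims) > 1:
            raise ValueError(f"mixed feature dimensions: {sorted(dims)}")
        self.classifier = classifier or ClassifierConfig()
        self.pipeline = pipeline
        self.classes_ = sorted({r.label for r in self.records})
        self.subjects_ = sorted({r.subject_id for r in self.records})

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[Recording],
        preset: str = "shoaib",
        classifier: ClassifierConfig | None = None,
        pipeline: PipelineConfig | None = None,
    ) -> "HARModel":
        """Run the preprocessing + feature pipeline, then build the model."""
        cfg = pipeline or pipeline_config(preset)
        records = extract_features(recordings, cfg)
        return cls(records, classifier=classifier, pipeline=cfg)

    @property
    def endog_names(self) -> list[str]:
        return self.classes_

    @property
    def exog_names(self) -> list[str] | None:
        return self.records[0].feature_names

    def fit(
        self,
        protocol: str = "subject_dependent_x10",
        seed: int = 0,
        n_runs: int = 10,
        k: int = 10,
    ) -> "HARResults":
        """Run an evaluation protocol and train the final classifier.

        protocol : {"subject_dependent_x10", "stratified_10fold",
        "leave_one_subject_out"}.
        """
        report = run_protocol(
            self.records,
            protocol=protocol,
            config=self.classifier,
            seed=seed,
            n_runs=n_runs,
            k=k,
        )
        norm = fit_minmax(self.records)
        final = train_classifier(
            apply_minmax(self.records, norm), self.classifier, seed=seed
        )
        return HARResults(
            model=self,
            protocol=protocol,
            seed=seed,
            report=report,
            normalization=norm,
            classifier_=final,
        )

    def sensitivity_grid(
        self,
        sizes: Sequence[int] = (50, 100, 200, 400),
        depths: Sequence[int] = (15, 20, 25, 30, 40),
        protocol: str = "subject_dependent_x10",
        seed: int = 0,
        n_runs: int = 3,
    ) -> np.ndarray:
        """Forest size x depth accuracy sweep over this model's records."""
        return sensitivity_grid(
            self.records, sizes=sizes, depths=depths,
            protocol=protocol, seed=seed, n_runs=n_runs,
        )


@dataclass
class HARResults:
    """Fitted results: protocol metrics, diagnostics, and a usable classifier."""

    model: HARModel
    protocol: str
    seed: int
    report: EvaluationReport
    normalization: NormalizationParams
    classifier_: object = field(repr=False, default=None)

    @property
    def accuracy(self) -> float:
        """Mean accuracy across runs/folds (the protocol's point estimate)."""
        if self.report.accuracy_mean is not None:
            return self.report.accuracy_mean
        return self.report.accuracy

    @property
    def accuracy_std(self) -> float | None:
        return self.report.accuracy_std

    @property
    def confusion(self) -> np.ndarray:
        """Confusion matrix pooled over all runs/folds."""
        return self.report.confusion

    def predict(self, records: Sequence[FeatureRecord]) -> np.ndarray:
        """Predict labels for new feature records (same pipeline settings)."""
        normalized = apply_minmax(records, self.normalization)
        X = np.vstack([r.vector for r in normalized])
        return self.classifier_.predict(X)

    def evaluate(self, records: Sequence[FeatureRecord]) -> EvaluationReport:
        """Score held-out records with the final classifier."""
        return evaluate(self.classifier_, apply_minmax(records, self.normalization))

    def summary(self) -> str:
        """Human-readable summary table of the fitted evaluation."""
        r = self.report
        lines = []
        lines.append("Human Activity Recognition Results")
        lines.append("=" * 62)
        lines.append(f"Protocol:            {self.protocol}")
        lines.append(f"Classifier:          {self.model.classifier.kind}")
        if self.model.classifier.kind == "rf":
            lines.append(
                f"Forest:              {self.model.classifier.n_estimators} trees, "
                f"max depth {self.model.classifier.max_depth}"
            )
        lines.append(f"Windows:             {len(self.model.records)}")
        lines.append(f"Feature dimension:   {self.model.records[0].dim}")
        lines.append(f"Classes:             {len(self.model.classes_)}")
        lines.append(f"Subjects:            {len(self.model.subjects_)}")
        lines.append(f"Seed:                {self.seed}")
        lines.append("-" * 62)
        if r.accuracy_mean is not None:
            lines.append(
                f"Accuracy:            {100 * r.accuracy_mean:.2f}% "
                f"(std {100 * r.accuracy_std:.2f} over {len(r.per_run)} runs)"
            )
            lines.append(
                f"Macro F1:            {100 * r.f1_mean:.2f}% "
                f"(std {100 * r.f1_std:.2f})"
            )
        else:
            lines.append(f"Accuracy:            {100 * r.accuracy:.2f}%")
            lines.append(f"Macro F1:            {100 * r.macro_f1:.2f}%")
        lines.append("-" * 62)
        lines.append(f"{'class':<16}{'precision':>10}{'recall':>10}"
                     f"{'F1':>10}{'support':>10}")
        for lab in r.labels:
            m = r.per_class[lab]
            lines.append(
                f"{lab:<16}{m['precision']:>10.3f}{m['recall']:>10.3f}"
                f"{m['f_measure']:>10.3f}{m['support']:>10d}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        """Heatmap of the pooled confusion matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.confusion, cmap="Blues")
        ax.set_xticks(range(len(self.report.labels)))
        ax.set_yticks(range(len(self.report.labels)))
        ax.set_xticklabels(self.report.labels, rotation=90)
        ax.set_yticklabels(self.report.labels)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax)
        return ax
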