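"""Model/Results interface for sequence-based multiple hypothesis testing.

:class:`SequenceMHT` bundles one labelled evidence sequence (the training
battery's W sequence or ordered p-values) with a classifier configuration;
``fit()`` trains the convolutional classifier and returns a
:class:`SequenceMHTResults` carrying per-test alternative probabilities,
the training history, diagnostics and a ``summary()`` table.  The results
object is also the transfer vehicle: ``predict`` / ``apply`` score new
evidence — of any length, from any test family that yields unscaled Bayes
factors or p-values — with the already-trained network.

Typical use::

    battery = simulate.make_training_battery(seed=1)
    res = SequenceMHT.from_battery(battery).fit()
    print(res.summary())
    new_p_hat = res.predict(df_with_log_bf_column)
    decision = res.apply(df_with_log_bf_column, q=0.05)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from .bf import (EvidenceSequence, TestBattery, build_w_sequence,
                 log_bf_lower_bound, ordered_pvalue_sequence,
                 unscaled_log_bf_battery)
from .classifier import ModelConfig, SequenceClassifier
from .decisions import MHTResult
from .evaluate import main_crossing
from .simulate import welch_pvalues

__all__ = ["SequenceMHT", "SequenceMHTResults"]


def _sequence_from_frame(df: pd.DataFrame, input_kind: str,
                         calibrate: str = "lower_bound") -> EvidenceSequence:
    labels = df["label"].to_numpy() if "label" in df.columns else None
    ids = df["id"].to_numpy()
    if "log_bf" in df.columns:
        if input_kind != "w":
            raise ValueError("log_bf evidence requires the W input pathway")
        return build_w_sequence(df["log_bf"].to_numpy(), ids=ids, labels=labels)
    if "pvalue" not in df.columns:
        raise ValueError("evidence frame needs a 'log_bf' or 'pvalue' column")
    pv = df["pvalue"].to_numpy()
    if input_kind == "ordered_pvalues":
        return ordered_pvalue_sequence(pv, ids=ids, labels=labels)
    if calibrate != "lower_bound":
        raise ValueError("p-values enter the W pathway only through the "
                         "Bayes-factor lower bound (calibrate='lower_bound')")
    return build_w_sequence(log_bf_lower_bound(pv), ids=ids, labels=labels)


class SequenceMHT:
    """Sequence classification model for a labelled evidence sequence."""

    def __init__(self, sequence, labels, ids=None,
                 config: ModelConfig | None = None):
        if config is None:
            config = ModelConfig()
        self.config = config
        if isinstance(sequence, EvidenceSequence):
            self.evidence = sequence
            if sequence.labels_sorted is None and labels is None:
                raise ValueError("training requires ground-truth labels")
        else:
            sequence = np.asarray(sequence, float)
            if labels is None:
                raise ValueError("training requires ground-truth labels")
            self.evidence = None
            self._raw_sequence = sequence
        self._labels = None if labels is None else np.asarray(labels, int)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_battery(cls, battery: TestBattery, config: ModelConfig | None = None,
                     evidence_spec=None) -> "SequenceMHT":
        """Build the model from raw two-sample data: compute unscaled BFs
        (or Welch p-values for the ordered-p pathway) and sort."""
        if battery.labels is None:
            raise ValueError("training battery must carry labels")
        if config is None:
            config = ModelConfig()
        if config.input_kind == "w":
            seq = build_w_sequence(unscaled_log_bf_battery(battery, evidence_spec),
                                   ids=battery.ids, labels=battery.labels)
        else:
            seq = ordered_pvalue_sequence(welch_pvalues(battery),
                                          ids=battery.ids, labels=battery.labels)
        obj = cls.__new__(cls)
        obj.config = config
        obj.evidence = seq
        obj._labels = None
        return obj

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ModelConfig | None = None,
                       calibrate: str = "lower_bound") -> "SequenceMHT":
        """Build from an evidence table with columns ``id``, ``label`` and
        one of ``log_bf`` / ``pvalue``."""
        if "label" not in df.columns:
            raise ValueError("training requires a 'label' column")
        if config is None:
            config = ModelConfig()
        seq = _sequence_from_frame(df, config.input_kind, calibrate)
        obj = cls.__new__(cls)
        obj.config = config
        obj.evidence = seq
        obj._labels = None
        return obj

    # -- fitting ------------------------------------------------------------
    def fit(self, epochs: int | None = None, seed: int | None = None) -> "SequenceMHTResults":
        model = clf.build_model(self.config)
        if self.evidence is not None:
            seq = self.evidence.w
            labels = self.evidence.labels_sorted
        else:
            seq = self._raw_sequence
            labels = self._labels
        clf.train(model, seq, labels, epochs=epochs, seed=seed)
        return SequenceMHTResults(self, model)


class SequenceMHTResults:
    """Trained classifier plus training-sequence diagnostics."""

    def __init__(self, model: SequenceMHT, classifier: SequenceClassifier):
        self.model = model
        self.classifier = classifier
        self.history = classifier.training_history
        if model.evidence is not None:
            self._train_seq = model.evidence.w
            self._train_labels = model.evidence.labels_sorted
        else:
            self._train_seq = model._raw_sequence
            self._train_labels = model._labels
        self.fittedvalues = classifier.predict_proba(self._train_seq)

    # -- diagnostics ---------------------------------------------------------
    @property
    def accuracy(self) -> float:
        """Per-position training accuracy at threshold 0.5."""
        return float(np.mean((self.fittedvalues > 0.5) == self._train_labels))

    @property
    def misclassification(self) -> float:
        return 1.0 - self.accuracy

    def crossing_report(self) -> dict:
        return main_crossing(self.fittedvalues)

    def summary(self) -> str:
        cfg = self.classifier.config
        cross = self.crossing_report()
        m = len(self._train_seq)
        m1 = int(np.sum(self._train_labels))
        lines = [
            "Sequence MHT classifier results",
            "=" * 47,
            f"{'input kind':<28}{cfg.input_kind}",
            f"{'training sequence length':<28}{m}",
            f"{'true alternatives':<28}{m1}",
            f"{'epochs':<28}{len(self.history)}",
            f"{'final training loss':<28}{self.history['loss'].iloc[-1]:.4f}",
            f"{'training accuracy':<28}{self.accuracy:.4f}",
            f"{'misclassified fraction':<28}{self.misclassification:.4f}",
            f"{'0.5-crossings':<28}{cross['n_crossings']}",
            f"{'main crossing position':<28}{cross['main']}",
            f"{'model fingerprint':<28}{self.classifier.fingerprint[:16]}",
        ]
        return "\n".join(lines)

    # -- transfer ------------------------------------------------------------
    def _coerce_sequence(self, evidence) -> EvidenceSequence:
        kind = self.classifier.config.input_kind
        if isinstance(evidence, EvidenceSequence):
            return evidence
        if isinstance(evidence, TestBattery):
            if kind == "w":
                return build_w_sequence(unscaled_log_bf_battery(evidence),
                                        ids=evidence.ids, labels=evidence.labels)
            return ordered_pvalue_sequence(welch_pvalues(evidence),
                                           ids=evidence.ids, labels=evidence.labels)
        if isinstance(evidence, pd.DataFrame):
            return _sequence_from_frame(evidence, kind)
        raise TypeError("evidence must be an EvidenceSequence, TestBattery or DataFrame")

    def predict(self, evidence) -> pd.Series:
        """P(alternative) per test id, in the evidence's original order."""
        seq = self._coerce_sequence(evidence)
        p_sorted = self.classifier.predict_proba(seq.w)
        inv = seq.inverse_order()
        return pd.Series(p_sorted[inv], index=pd.Index(seq.ids_sorted[inv], name="id"),
                         name="p_hat")

    def apply(self, evidence, q: float = 0.05) -> MHTResult:
        """Score new evidence and decide at FDR level q."""
        seq = self._coerce_sequence(evidence)
        p = self.predict(seq)
        result = MHTResult(ids=p.index.to_numpy(), p_hat=p.to_numpy(), q=q)
        if seq.labels_sorted is not None:
            result.attach_metrics(seq.labels_sorted[seq.inverse_order()])
        return result

    # -- persistence ----------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        clf.save_model(self.classifier, directory)
        np.savez(directory / "training_sequence.npz",
                 sequence=self._train_seq, labels=self._train_labels)

    @classmethod
    def load(cls, directory) -> "SequenceMHTResults":
        directory = Path(directory)
        classifier = clf.load_model(directory)
        with np.load(directory / "training_sequence.npz") as npz:
            seq, labels = npz["sequence"], npz["labels"]
        model = SequenceMHT(seq, labels, config=classifier.config)
        return cls(model, classifier)
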