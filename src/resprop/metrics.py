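"""Evaluation metrics for the six prediction tasks.

Classification metrics (Q3/Q8 accuracy; disorder MCC, FPR, FNR) are
computed over non-padded positions; regression metrics (RSA/ASA Pearson
correlation, phi/psi circular mean absolute error) are additionally
restricted to positions whose reference values are valid (not disordered,
not unknown residues).  Dihedral error uses the shorter arc on the 360°
circle, so a prediction of 170° against a target of -170° counts 20°.

A metric whose value is undefined on the given data — an empty mask, zero
variance for a correlation, a zero confusion-table margin for MCC — raises
:class:`UndefinedMetric` rather than silently reporting 0; dataset-level
evaluation records such metrics as absent.

By default dataset-level metrics pool residues across all proteins
(micro-average); per-protein macro-averaging is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ResidueAnnotations, ValidationError, max_asa_vector
from .network import PredictionBundle


class UndefinedMetric(ValueError):
    """The requested metric has no defined value on this data."""


def _as_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValidationError(f"mask shape {mask.shape} does not match length {n}")
    return mask


def class_accuracy(pred_classes, true_classes, mask=None) -> float:
    """Fraction of masked-in positions predicted correctly.

    ``pred_classes`` may be integer classes or an (L, C) probability/logit
    matrix, in which case the argmax is taken (ties break to the lowest
    class index, numpy convention).
    """
    pred = np.asarray(pred_classes)
    if pred.ndim == 2:
        pred = pred.argmax(axis=1)
    true = np.asarray(true_classes)
    if pred.shape != true.shape:
        raise ValidationError("prediction/target length mismatch")
    m = _as_mask(mask, len(true))
    if m.sum() == 0:
        raise UndefinedMetric("accuracy over an empty mask")
    return float((pred[m] == true[m]).mean())


def binary_confusion_metrics(pred_flags, true_flags, mask=None) -> tuple[float, float, float]:
    """(MCC, FPR, FNR) from the 2×2 confusion table.

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any
    factor of the denominator is zero the table is degenerate and MCC is
    reported as 0.0.  FPR = FP/(FP+TN), FNR = FN/(FN+TP); an empty margin
    raises :class:`UndefinedMetric`.
    """
    pred = np.asarray(pred_flags)
    true = np.asarray(true_flags)
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValidationError("confusion metrics require binary inputs")
    pred = pred.astype(bool)
    true = true.astype(bool)
    m = _as_mask(mask, len(true))
    if m.sum() == 0:
        raise UndefinedMetric("confusion metrics over an empty mask")
    pred, true = pred[m], true[m]
    tp = int((pred & true).sum())
    tn = int((~pred & ~true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    if fp + tn == 0:
        raise UndefinedMetric("FPR undefined: no true-negative-or-false-positive cases")
    if fn + tp == 0:
        raise UndefinedMetric("FNR undefined: no positive cases")
    return float(mcc), fp / (fp + tn), fn / (fn + tp)


def pearson(pred_values, true_values, mask=None) -> float:
    """Pearson product-moment correlation over masked-in positions."""
    pred = np.asarray(pred_values, dtype=np.float64)
    true = np.asarray(true_values, dtype=np.float64)
    m = _as_mask(mask, len(true))
    if m.sum() < 2:
        raise UndefinedMetric("Pearson correlation needs at least two positions")
    x, y = pred[m], true[m]
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0.0:
        raise UndefinedMetric("Pearson correlation undefined for zero variance")
    return float((xc * yc).sum() / denom)


def angular_mae(pred_deg, true_deg, mask=None) -> float:
    """Mean absolute circular error in degrees: min(|Δ|, 360 − |Δ|)."""
    pred = np.asarray(pred_deg, dtype=np.float64)
    true = np.asarray(true_deg, dtype=np.float64)
    m = _as_mask(mask, len(true))
    if m.sum() == 0:
        raise UndefinedMetric("angular MAE over an empty mask")
    delta = np.abs(pred[m] - true[m]) % 360.0
    return float(np.minimum(delta, 360.0 - delta).mean())


@dataclass
class MetricsReport:
    """Evaluation summary; metrics undefined on the data are ``None``."""

    q3_acc: float | None = None
    q8_acc: float | None = None
    disorder_mcc: float | None = None
    disorder_fpr: float | None = None
    disorder_fnr: float | None = None
    rsa_pcc: float | None = None
    asa_pcc: float | None = None
    phi_mae: float | None = None
    psi_mae: float | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "q3_acc": self.q3_acc, "q8_acc": self.q8_acc,
            "disorder_mcc": self.disorder_mcc,
            "disorder_fpr": self.disorder_fpr,
            "disorder_fnr": self.disorder_fnr,
            "rsa_pcc": self.rsa_pcc, "asa_pcc": self.asa_pcc,
            "phi_mae": self.phi_mae, "psi_mae": self.psi_mae,
            "counts": dict(self.counts),
        }

    def to_table(self) -> str:
        """Human-readable one-row table (columns RSA, ASA, Q8, Q3, Disorder,
        Phi, Psi)."""
        def fmt(v, nd=3):
            return "-" if v is None else f"{v:.{nd}f}"

        header = (f"{'RSA':>7} {'ASA':>7} {'Q8':>7} {'Q3':>7} "
                  f"{'Dis MCC':>8} {'Dis FPR':>8} {'Dis FNR':>8} "
                  f"{'Phi':>7} {'Psi':>7}")
        row = (f"{fmt(self.rsa_pcc):>7} {fmt(self.asa_pcc):>7} "
               f"{fmt(self.q8_acc):>7} {fmt(self.q3_acc):>7} "
               f"{fmt(self.disorder_mcc):>8} {fmt(self.disorder_fpr):>8} "
               f"{fmt(self.disorder_fnr):>8} "
               f"{fmt(self.phi_mae, 2):>7} {fmt(self.psi_mae, 2):>7}")
        return header + "\n" + row


def _pooled(bundles: Sequence[PredictionBundle],
            annotations: Sequence[ResidueAnnotations],
            sequences: Sequence[str], table, unknown_default):
    """Concatenate per-protein arrays for micro-averaged evaluation."""
    parts: dict[str, list[np.ndarray]] = {k: [] for k in (
        "q8p", "q3p", "disp", "rsa", "asa", "phid", "psid",
        "q8t", "q3t", "dist", "rsat", "asat", "phit", "psit", "reg")}
    for bundle, ann, seq in zip(bundles, annotations, sequences):
        if len(bundle) != len(ann):
            raise ValidationError("bundle/annotation length mismatch")
        parts["q8p"].append(bundle.q8_probs.argmax(axis=1))
        parts["q3p"].append(bundle.q3_probs.argmax(axis=1))
        parts["disp"].append(bundle.disorder_probs.argmax(axis=1))
        parts["rsa"].append(bundle.rsa)
        parts["asa"].append(bundle.asa)
        parts["phid"].append(bundle.phi_deg)
        parts["psid"].append(bundle.psi_deg)
        parts["q8t"].append(ann.q8)
        parts["q3t"].append(ann.q3)
        parts["dist"].append(ann.disorder.astype(int))
        parts["rsat"].append(ann.rsa)
        parts["asat"].append(ann.rsa * max_asa_vector(seq, table, unknown_default))
        parts["phit"].append(ann.phi)
        parts["psit"].append(ann.psi)
        parts["reg"].append(ann.valid_regression)
    return {k: np.concatenate(v) for k, v in parts.items()}


def evaluate_bundles(
    bundles: Sequence[PredictionBundle],
    annotations: Sequence[ResidueAnnotations],
    sequences: Sequence[str],
    table=None,
    unknown_default: float | None = None,
    macro: bool = False,
) -> MetricsReport:
    """Score predictions against reference annotations.

    With ``macro=True`` each metric is averaged over per-protein values
    (proteins where it is undefined are skipped); the default pools all
    residues first.
    """
    if len(bundles) == 0:
        raise ValidationError("no predictions to evaluate")
    if macro:
        reports = [
            evaluate_bundles([b], [a], [s], table, unknown_default)
            for b, a, s in zip(bundles, annotations, sequences)
        ]
        agg = MetricsReport(counts={"proteins": len(reports)})
        for name in ("q3_acc", "q8_acc", "disorder_mcc", "disorder_fpr",
                     "disorder_fnr", "rsa_pcc", "asa_pcc", "phi_mae", "psi_mae"):
            vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
            setattr(agg, name, float(np.mean(vals)) if vals else None)
        return agg

    p = _pooled(bundles, annotations, sequences, table, unknown_default)
    reg = p["reg"]
    report = MetricsReport(counts={
        "classification": int(len(p["q3t"])),
        "regression": int(reg.sum()),
    })

    def attempt(name, fn):
        try:
            setattr(report, name, fn())
        except UndefinedMetric:
            setattr(report, name, None)

    attempt("q3_acc", lambda: class_accuracy(p["q3p"], p["q3t"]))
    attempt("q8_acc", lambda: class_accuracy(p["q8p"], p["q8t"]))

    def confusion():
        return binary_confusion_metrics(p["disp"], p["dist"])

    try:
        mcc, fpr, fnr = confusion()
        report.disorder_mcc, report.disorder_fpr, report.disorder_fnr = mcc, fpr, fnr
    except UndefinedMetric:
        pass
    attempt("rsa_pcc", lambda: pearson(p["rsa"], p["rsat"], reg))
    attempt("asa_pcc", lambda: pearson(p["asa"], p["asat"], reg))
    attempt("phi_mae", lambda: angular_mae(p["phid"], p["phit"], reg))
    attempt("psi_mae", lambda: angular_mae(p["psid"], p["psit"], reg))
    return report


def evaluate_model(model, pairs, embeddings=None, macro: bool = False) -> MetricsReport:
    """Predict every sequence with ``model`` and score the results.

    ``pairs`` is a sequence of (ProteinRecord, ResidueAnnotations);
    ``embeddings`` optionally maps ids to precomputed matrices, else the
    one-hot encoding is used.
    """
    from .encode import one_hot_encode
    from .network import predict_bundle

    bundles = []
    for record, _ in pairs:
        emb = embeddings[record.id] if embeddings is not None else one_hot_encode(record)
        bundles.append(predict_bundle(model, emb, record.sequence))
    cfg = model.config
    return evaluate_bundles(
        bundles, [a for _, a in pairs], [r.sequence for r, _ in pairs],
        cfg.max_asa, cfg.max_asa_unknown, macro=macro,
    )
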