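"""Paired leave-one-subject-out (LOSO) evaluation.

Subjects are paired rank-wise across classes (one depressed + one control
per fold); every fold trains on all remaining subjects and scores every
2-s window of the two held-out subjects.  Confusion counts are window-level
with depression as the positive class.  The harness also runs the ablation
variants (no SE attention, no feature smoothing, time-domain input).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import MDD, Recording
from .model import SparNetClassifier, SparNetResults, TrainConfig
from .network import ArchitectureSpec
from .preprocess import bandpass, denoise_recording, segment
from .regions import RegionMap, load_region_map, slice_by_region
from .spectra import features_time_domain, smooth, to_spectrum

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "EvalReport",
    "make_folds",
    "metrics",
    "roc_auc",
    "subject_features",
    "run_experiment",
    "TrainConfig",
]


class ProtocolError(ValueError):
    """Raised when the evaluation protocol preconditions are violated."""


# ---------------------------------------------------------------------------
# Fold planning


@dataclass(frozen=True)
class Fold:
    test: tuple  # (mdd_subject, control_subject)
    train: tuple  # remaining subject ids


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(manifest: pd.DataFrame) -> FoldPlan:
    """Pair MDD and control subjects rank-wise by sorted subject id.

    One fold per pair; surplus subjects of the larger class stay in every
    training set and are never tested.
    """
    mdd = sorted(manifest.loc[manifest["label"] == MDD, "subject_id"].astype(str))
    ctl = sorted(manifest.loc[manifest["label"] != MDD, "subject_id"].astype(str))
    if not mdd or not ctl:
        raise ProtocolError("both classes must have at least one subject")
    n_folds = min(len(mdd), len(ctl))
    all_subjects = set(mdd) | set(ctl)
    folds = []
    for i in range(n_folds):
        test = (mdd[i], ctl[i])
        train = tuple(sorted(all_subjects - set(test)))
        if not train:
            raise ProtocolError("training set would be empty; need more subjects")
        folds.append(Fold(test=test, train=train))
    return FoldPlan(folds=tuple(folds))


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """Window-level counts with depression positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity (recall), precision, specificity and F1.

    F1 is the harmonic mean of precision and sensitivity.  Ratios with a
    zero denominator are reported as NaN, never as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": sens,
        "precision": prec,
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "f1": _ratio(2.0 * prec * sens, prec + sens),
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points from sweeping all distinct score thresholds, AUC by trapezoid.

    Equal scores are grouped into a single threshold step.  Returns
    ``(points, auc)`` with points as an (n, 2) array of (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ProtocolError("AUC undefined with a single class present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    distinct = np.nonzero(np.diff(s))[0]
    keep = np.r_[distinct, len(s) - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Feature pipeline


def subject_features(
    rec: Recording,
    region_map: RegionMap,
    denoise: bool = True,
    smoothing: bool = True,
    representation: str = "freq",
    time_decimate: int | None = 5,
    window_s: float = 2.0,
):
    """Preprocess one recording into its five region tensors.

    band-pass -> (optional) phase-space denoising -> 2-s segmentation ->
    FFT features (or raw/decimated windows) -> (optional) 3-sigma smoothing
    -> region slicing.  Returns ``(region_tensors, n_windows, n_replaced)``.
    """
    rec = bandpass(rec)
    if denoise:
        rec = denoise_recording(rec)
    ep = segment(rec, window_s=window_s)
    if representation == "freq":
        sf = to_spectrum(ep)
    elif representation == "time":
        sf = features_time_domain(ep, decimate=time_decimate)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    n_replaced = 0
    if smoothing:
        sf, report = smooth(sf)
        n_replaced = report.total_replaced
    tensors = slice_by_region(sf, region_map)
    return tensors, sf.n_windows, n_replaced


# ---------------------------------------------------------------------------
# The experiment


@dataclass
class EvalReport:
    """Per-fold and pooled LOSO results."""

    folds: list = field(default_factory=list)
    pooled: ConfusionMatrix | None = None
    pooled_metrics: dict = field(default_factory=dict)
    pooled_auc: float = float("nan")
    metric_mean: dict = field(default_factory=dict)
    metric_sd: dict = field(default_factory=dict)
    param_count: int = 0
    param_breakdown: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    **{k: v for k, v in f.items() if k not in ("cm", "roc")},
                    "confusion": asdict(f["cm"]),
                }
                for f in self.folds
            ],
            "pooled": {
                "confusion": asdict(self.pooled),
                "metrics": self.pooled_metrics,
                "auc": self.pooled_auc,
            },
            "metric_mean": self.metric_mean,
            "metric_sd": self.metric_sd,
            "param_count": self.param_count,
            "param_breakdown": self.param_breakdown,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            rows.append(
                {"fold": f["fold"], "test_mdd": f["test"][0], "test_control": f["test"][1],
                 "auc": f["auc"], **f["metrics"]}
            )
        return pd.DataFrame(rows)

    def roc_table(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            for fpr, tpr in f["roc"]:
                rows.append({"fold": f["fold"], "fpr": fpr, "tpr": tpr})
        return pd.DataFrame(rows)

    def plot_roc(self, ax=None):
        """Per-fold ROC curves (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f in self.folds:
            pts = np.asarray(f["roc"])
            ax.plot(pts[:, 0], pts[:, 1], alpha=0.6, label=f"fold {f['fold']}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize="small")
        return ax


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_experiment(
    recordings: list[Recording],
    region_map: RegionMap | str = "final",
    cfg: TrainConfig | None = None,
    denoise: bool = True,
    smoothing: bool = True,
    representation: str = "freq",
    use_senet: bool = True,
    n_folds: int | None = None,
    seed: int = 0,
    time_decimate: int | None = 5,
    progress: callable | None = None,
) -> EvalReport:
    """Full paired-LOSO experiment on a cohort of recordings.

    Features are computed once per subject and reused across folds (they do
    not depend on the split).  Per-fold randomness is keyed by
    ``seed + fold_index``.  ``n_folds`` limits the number of folds for
    scaled-down runs.
    """
    if isinstance(region_map, str):
        region_map = load_region_map(region_map)
    cfg = cfg or TrainConfig()

    manifest = pd.DataFrame(
        {"subject_id": [r.subject_id for r in recordings],
         "label": [r.label for r in recordings]}
    )
    plan = make_folds(manifest)
    folds = plan.folds[:n_folds] if n_folds else plan.folds

    features = {}
    total_replaced = 0
    for rec in recordings:
        tensors, n_win, n_rep = subject_features(
            rec, region_map, denoise=denoise, smoothing=smoothing,
            representation=representation, time_decimate=time_decimate,
        )
        features[rec.subject_id] = tensors
        total_replaced += n_rep
        if progress:
            progress(f"featurized {rec.subject_id}: {n_win} windows")
    labels = {r.subject_id: int(r.label == MDD) for r in recordings}

    def stack(subjects):
        regs = [np.concatenate([features[s][r] for s in subjects]) for r in range(5)]
        y = np.concatenate(
            [np.full(features[s][0].shape[0], labels[s]) for s in subjects]
        )
        groups = np.concatenate(
            [np.full(features[s][0].shape[0], s, dtype=object) for s in subjects]
        )
        return regs, y, groups

    report = EvalReport()
    pooled_cm = ConfusionMatrix(0, 0, 0, 0)
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    results: SparNetResults | None = None
    for i, fold in enumerate(folds):
        # structural leakage check: train and test subject sets are disjoint
        assert not (set(fold.train) & set(fold.test))
        Xtr, ytr, gtr = stack(fold.train)
        Xte, yte, _ = stack(fold.test)
        arch = ArchitectureSpec(
            region_channels=tuple(r.shape[1] for r in Xtr),
            feature_length=Xtr[0].shape[2],
            use_senet=use_senet,
        )
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": seed + i})
        clf = SparNetClassifier(Xtr, ytr, groups=gtr, arch=arch)
        results = clf.fit(fold_cfg)
        scores = results.predict_proba(Xte)[:, 1]
        pred = (scores >= 0.5).astype(int)
        cm = ConfusionMatrix(
            tp=int(np.sum((pred == 1) & (yte == 1))),
            fn=int(np.sum((pred == 0) & (yte == 1))),
            fp=int(np.sum((pred == 1) & (yte == 0))),
            tn=int(np.sum((pred == 0) & (yte == 0))),
        )
        roc, auc = roc_auc(scores, yte)
        pooled_cm = pooled_cm + cm
        all_scores.append(scores)
        all_labels.append(yte)
        report.folds.append(
            {"fold": i, "test": list(fold.test), "cm": cm, "metrics": metrics(cm),
             "auc": auc, "roc": roc.tolist(), "n_epochs": results.n_epochs_run,
             "val_loss": results.best_val_loss, "seed": seed + i}
        )
        if progress:
            progress(
                f"fold {i} ({fold.test[0]} vs {fold.test[1]}): "
                f"acc={metrics(cm)['accuracy']:.3f} auc={auc:.3f} "
                f"epochs={results.n_epochs_run}"
            )

    report.pooled = pooled_cm
    report.pooled_metrics = metrics(pooled_cm)
    _, report.pooled_auc = roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))
    fold_metric_rows = [f["metrics"] for f in report.folds]
    for key in fold_metric_rows[0]:
        vals = np.array([row[key] for row in fold_metric_rows], dtype=float)
        finite = vals[~np.isnan(vals)]
        report.metric_mean[key] = float(finite.mean()) if finite.size else float("nan")
        report.metric_sd[key] = float(finite.std()) if finite.size else float("nan")
    total, breakdown = results.network.count_params(breakdown=True)
    report.param_count = total
    report.param_breakdown = breakdown
    payload = {
        "cfg": asdict(cfg), "denoise": denoise, "smoothing": smoothing,
        "representation": representation, "use_senet": use_senet,
        "region_variant": region_map.variant, "seed": seed,
        "n_folds": len(folds),
    }
    report.provenance = {
        **payload,
        "config_hash": _config_hash(payload),
        "fold_seeds": [seed + i for i in range(len(folds))],
        "smoothing_replacements": total_replaced,
        "n_subjects": len(recordings),
    }
    return report
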