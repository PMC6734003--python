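"""SVM classification of 5-mer window feature vectors.

A site is classified as m6A-modified or unmodified from its window
feature vector.  Several feature sets are supported, mirroring the
single-feature / combined / context-extended comparisons of the method:

``single:q0``, ``single:mis0``, ``single:del0``
    one base-called feature at the central (modified) position;
``single:curr_mean``, ``single:curr_sd``
    one current-intensity window statistic;
``combined3``
    quality, mismatch and deletion frequency at position 0 (the default —
    current features are deliberately excluded, being poor predictors, and
    the 15-feature context model inflates false positives on control
    k-mers);
``extended15``
    quality, mismatch and deletion frequency at all five positions.

Training standardizes features with training-split statistics only,
compares linear / polynomial / RBF kernels on the held-out split and
retains the best (ties broken in that order).  Probabilities are the
SVM's Platt-calibrated outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .features import POSITION_TAGS

MODEL_FORMAT_VERSION = 1

FEATURE_SETS: dict[str, list[str]] = {
    "single:q0": ["q0"],
    "single:mis0": ["mis0"],
    "single:del0": ["del0"],
    "single:curr_mean": ["curr_mean"],
    "single:curr_sd": ["curr_sd"],
    "combined3": ["q0", "mis0", "del0"],
    "extended15": [f"{f}{t}" for f in ("q", "mis", "del") for t in POSITION_TAGS],
}

#: methylation ratios of the published mixture experiment
PAPER_MIXTURE_RATIOS = (0.0, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 1.00)

KERNEL_ORDER = ("linear", "poly", "rbf")


@dataclass(frozen=True)
class ModelSpec:
    feature_set: str = "combined3"
    kernels: tuple[str, ...] = KERNEL_ORDER
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature_set {self.feature_set!r}; "
                f"choose from {sorted(FEATURE_SETS)}"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        unknown = set(self.kernels) - set(KERNEL_ORDER)
        if unknown or not self.kernels:
            raise ValueError(f"kernels must be a non-empty subset of {KERNEL_ORDER}")

    @property
    def feature_names(self) -> list[str]:
        return FEATURE_SETS[self.feature_set]


@dataclass
class PerformanceReport:
    """Confusion counts and the derived rates.

    ``sensitivity`` doubles as the "recovery" of known modified sites
    (TP / all known); ``ppv`` is the positive predictive value.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    auc: float | None = None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float | None:
        n = self.tp + self.fn
        return self.tp / n if n else None

    recovery = sensitivity

    @property
    def specificity(self) -> float | None:
        n = self.tn + self.fp
        return self.tn / n if n else None

    @property
    def ppv(self) -> float | None:
        n = self.tp + self.fp
        return self.tp / n if n else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "auc": self.auc,
        }


@dataclass
class TrainedModel:
    spec: ModelSpec
    selected_kernel: str
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    svc: SVC
    metadata: dict = field(default_factory=dict)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "spec": self.spec,
                "selected_kernel": self.selected_kernel,
                "feature_names": self.feature_names,
                "scaler_mean": self.scaler_mean,
                "scaler_scale": self.scaler_scale,
                "svc": self.svc,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"incompatible model archive (format {version}, "
                f"expected {MODEL_FORMAT_VERSION})"
            )
        payload.pop("format_version")
        return cls(**payload)


def _labels_to_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(int)
    return (arr == "modified").astype(int)


def train_svm(windows: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> TrainedModel:
    """Train and select an SVM on labeled window features.

    Splits stratified by label at ``spec.train_fraction``; standardizes
    with training-split statistics; fits each candidate kernel with
    probability outputs enabled and retains the one with the highest
    held-out accuracy (ties: linear before poly before rbf).
    """
    names = spec.feature_names
    missing = [c for c in names if c not in windows.columns]
    if missing:
        raise ValueError(f"windows table lacks feature columns: {missing}")
    usable = windows.dropna(subset=names)
    X = usable[names].to_numpy(dtype=float)
    y = _labels_to_binary(usable["label"].to_numpy())
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both labels")
    caveats = []
    if counts.min() < 10:
        caveats.append(
            f"fewer than 10 windows in the smallest class (counts {dict(zip(classes.tolist(), counts.tolist()))})"
        )

    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=spec.train_fraction,
        stratify=y,
        random_state=spec.seed,
    )
    mean = X_tr.mean(axis=0)
    scale = X_tr.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z_tr = (X_tr - mean) / scale
    Z_te = (X_te - mean) / scale

    kernel_accuracy: dict[str, float] = {}
    fitted: dict[str, SVC] = {}
    for kernel in spec.kernels:
        svc = SVC(kernel=kernel, probability=True, random_state=spec.seed)
        with warnings.catch_warnings():
            # Platt-calibrated probability output of the SVM is exactly the
            # probability model used here; silence sklearn's migration nudge.
            warnings.filterwarnings("ignore", category=FutureWarning)
            svc.fit(Z_tr, y_tr)
        kernel_accuracy[kernel] = float((svc.predict(Z_te) == y_te).mean())
        fitted[kernel] = svc
    best = max(spec.kernels, key=lambda k: kernel_accuracy[k])  # first max wins ties

    return TrainedModel(
        spec=spec,
        selected_kernel=best,
        feature_names=list(names),
        scaler_mean=mean,
        scaler_scale=scale,
        svc=fitted[best],
        metadata={
            "n_train": int(len(y_tr)),
            "n_test": int(len(y_te)),
            "seed": spec.seed,
            "kernel_accuracy": kernel_accuracy,
            "heldout_accuracy": kernel_accuracy[best],
            "warnings": caveats,
            "svc_params": fitted[best].get_params(),
        },
    )


def predict_proba(
    model: TrainedModel, windows: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Probability of "modified" for each window.

    Returns (probabilities indexed like the scored ``windows`` rows,
    table of skipped rows with a ``reason`` column).  Windows missing any
    model feature are skipped, not scored.
    """
    names = model.feature_names
    missing = [c for c in names if c not in windows.columns]
    if missing:
        raise ValueError(f"windows table lacks feature columns: {missing}")
    if not len(windows):
        return pd.Series(dtype=float, name="prob"), pd.DataFrame(columns=["reason"])
    ok = windows[names].notna().all(axis=1)
    skipped = pd.DataFrame(
        {"reason": "missing features"}, index=windows.index[~ok]
    )
    kept = windows.loc[ok]
    if not len(kept):
        return pd.Series(dtype=float, name="prob"), skipped
    Z = model._standardize(kept[names].to_numpy(dtype=float))
    modified_col = int(np.where(model.svc.classes_ == 1)[0][0])
    probs = model.svc.predict_proba(Z)[:, modified_col]
    return pd.Series(probs, index=kept.index, name="prob"), skipped


def evaluate(
    probabilities: Sequence[float],
    labels: Sequence,
    threshold: float = 0.5,
) -> PerformanceReport:
    """Threshold probabilities (>= threshold -> modified) and count outcomes."""
    p = np.asarray(probabilities, dtype=float)
    y = _labels_to_binary(labels)
    if p.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if p.size != y.size:
        raise ValueError("probabilities and labels differ in length")
    pred = p >= threshold
    truth = y == 1
    report = PerformanceReport(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )
    if len(np.unique(y)) == 2:
        report.auc = float(roc_auc_score(y, p))
    return report


def roc_auc(
    probabilities: Sequence[float], labels: Sequence
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC (Mann-Whitney concordance; ties count 1/2)."""
    p = np.asarray(probabilities, dtype=float)
    y = _labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(y, p)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, float(roc_auc_score(y, p))


def mixture_curve(
    model: TrainedModel,
    modified_table: pd.DataFrame,
    unmodified_table: pd.DataFrame,
    reference: str,
    modified_positions: Sequence[int],
    ratios: Sequence[float] = PAPER_MIXTURE_RATIOS,
    n_reads: int = 100,
    seed: int = 0,
    candidate_positions: Sequence[int] | None = None,
    ref_name: str | None = None,
) -> pd.DataFrame:
    """Classification AUC as a function of the methylation ratio.

    For each ratio, mixes reads from the fully modified and unmodified
    per-base tables, recomputes site and window features, scores the
    candidate windows, and computes the AUC of the scores against the
    ground-truth site labels (centre in ``modified_positions``).  At ratio
    0 the mixture carries no signal and the AUC is expected near 0.5.
    """
    from .features import per_site_features, window_features
    from .simulate import mix_read_sets
    from ._util import stable_hash

    mod_set = set(int(p) for p in modified_positions)
    rows = []
    for ratio in ratios:
        mixed = mix_read_sets(
            modified_table,
            unmodified_table,
            ratio,
            n_reads,
            seed=stable_hash("mixture", seed, f"{ratio:.6f}"),
        )
        sites = per_site_features(mixed, reference=reference, ref_name=ref_name)
        windows = window_features(sites)
        if candidate_positions is not None:
            windows = windows[windows["center_pos"].isin(set(map(int, candidate_positions)))]
        else:
            center_a = windows["kmer"].str[2] == "A"
            single_a = windows["kmer"].str.count("A") == 1
            windows = windows[center_a & single_a & ~windows["has_missing"]]
        probs, _ = predict_proba(model, windows)
        labels = windows.loc[probs.index, "center_pos"].isin(mod_set).astype(int)
        _, auc = roc_auc(probs.to_numpy(), labels.to_numpy())
        rows.append({"ratio": float(ratio), "auc": auc, "n_sites": int(len(probs))})
    return pd.DataFrame(rows)


def youden_threshold(probabilities: Sequence[float], labels: Sequence) -> float:
    """Threshold maximizing Youden's J = TPR - FPR on the given data."""
    curve, _ = roc_auc(probabilities, labels)
    j = curve["tpr"] - curve["fpr"]
    return float(curve.loc[j.idxmax(), "threshold"])
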