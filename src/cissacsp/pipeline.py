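"""End-to-end pipeline: segmentation -> CiSSA sub-bands -> CSP -> fusion ->
linear-margin classification under stratified cross-validation.

The per-trial transform up to the feature table is label-free (windowing
and CiSSA band extraction are unsupervised and act on one trial at a
time), so band-limited tensors are computed once per dataset.  Everything
that looks at labels — CSP filter banks, MIBIF ranking, PCA axes, the
classifier — is refitted inside every training fold and only then applied
to the held-out trials, so no information leaks across the split.

The classifier is a linear-kernel soft-margin SVM (hinge loss) with cost
C = 1 by default.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import cissa
from .csp import SpatialFilterBank, class_covariances, fit_csp, log_variance_features
from .fusion import (
    FeatureMatrix,
    MibifRanking,
    PcaModel,
    mibif_scores,
    mibif_select,
    pca_fit,
    pca_transform,
)
from .segmentation import WindowSpec, plan_windows
from .trial_store import TrialSet

__all__ = [
    "PipelineConfig",
    "CVReport",
    "FeatureGridReport",
    "extract_features",
    "run_cv",
    "sweep_feature_count",
    "feature_grid_report",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place.

    Defaults follow the public-dataset protocol: 2 s windows at 0.5 s
    stride (T = 4 on a 3.5 s trial), 6-30 Hz in 4 Hz sub-bands (B = 6),
    M = 2 filter pairs (2M = 4 features per segment-band, 2MBT = 96
    total), 10 stratified folds, linear SVM with C = 1, PCA fusion.
    """

    window: WindowSpec = field(default_factory=lambda: WindowSpec.sliding(2.0, 0.5))
    f_min: float = 6.0
    f_max: float = 30.0
    fb: float = 4.0
    L: int | None = None
    M: int = 2
    fusion: str = "pca"  # "mibif" | "pca" | "none"
    k: int | None = 12
    folds: int = 10
    C: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.fusion not in ("mibif", "pca", "none"):
            raise ValueError(f"unknown fusion method {self.fusion!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.C <= 0:
            raise ValueError("classifier cost C must be positive")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    def to_dict(self) -> dict:
        return {
            "window": {
                "window_length": self.window.window_length,
                "stride": self.window.stride,
                "windows": self.window.windows,
            },
            "f_min": self.f_min,
            "f_max": self.f_max,
            "fb": self.fb,
            "L": self.L,
            "M": self.M,
            "fusion": self.fusion,
            "k": self.k,
            "folds": self.folds,
            "C": self.C,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        w = d.pop("window", None)
        if w is None:
            spec = WindowSpec.sliding(2.0, 0.5)
        elif isinstance(w, WindowSpec):
            spec = w
        elif w.get("windows"):
            spec = WindowSpec.explicit(w["windows"])
        else:
            spec = WindowSpec.sliding(w["window_length"], w["stride"])
        cfg = cls(window=spec, **d)
        cfg.validate()
        return cfg

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class CVReport:
    """Per-fold accuracies (%), their mean/std, and the run's provenance."""

    fold_accuracies: list[float]
    mean: float
    std: float
    d_before: int
    d_after: int
    fingerprint: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "mean": self.mean,
            "std": self.std,
            "d_before": self.d_before,
            "d_after": self.d_after,
            "fingerprint": self.fingerprint,
            "seed": self.seed,
        }


@dataclass
class FeatureGridReport:
    """Single-feature diagnostics over (window, band, filter-rank) cells.

    Row 0 of the window axis is the whole trial; rows 1.. are the T
    sub-windows.  ``accuracy`` holds cross-validated single-feature
    accuracies (%), ``mibif`` the mutual information of each feature with
    the label (bits), estimated on the full dataset.
    """

    accuracy: np.ndarray  # (T+1, B, 2M)
    mibif: np.ndarray  # (T+1, B, 2M)
    windows: list[tuple[float, float]]
    bands: list[tuple[float, float]]
    fingerprint: str
    seed: int

    def argmax_cell(self) -> tuple[int, int]:
        """(window, band) of the best single-feature accuracy (max over ranks)."""
        cell = self.accuracy.max(axis=2)
        w, b = np.unravel_index(np.argmax(cell), cell.shape)
        return int(w), int(b)


# ---------------------------------------------------------------------------
# plan resolution and label-free feature tensors
# ---------------------------------------------------------------------------

def _resolve_plan(cfg: PipelineConfig, fs: float) -> tuple[cissa.SubBandPlan, int]:
    L = cfg.L if cfg.L is not None else int(round(fs / cfg.fb))
    realized_fb = fs / L
    if abs(realized_fb - cfg.fb) <= 1e-9 * max(1.0, cfg.fb):
        return cissa.make_subband_plan(cfg.f_min, cfg.f_max, realized_fb, fs, L), L
    warnings.warn(
        f"fs/L = {realized_fb:.4g} Hz differs from the requested band width "
        f"{cfg.fb} Hz; using the realized width",
        stacklevel=2,
    )
    B = int(round((cfg.f_max - cfg.f_min) / cfg.fb))
    edges = cfg.f_min + realized_fb * np.arange(B + 1)
    plan = cissa.SubBandPlan(
        bands=[(float(edges[i]), float(edges[i + 1])) for i in range(B)],
        fb=realized_fb,
    )
    return plan, L


def _band_tensors(ts: TrialSet, cfg: PipelineConfig):
    """CiSSA band tensors for every (segment, band): list over segments of
    arrays (B, n_trials, C, P_seg), plus the window list and plan."""
    trial_length = ts.n_samples / ts.fs
    windows = plan_windows(trial_length, cfg.window)
    plan, L = _resolve_plan(cfg, ts.fs)
    tensors = []
    for start, end in windows:
        i0, i1 = int(round(start * ts.fs)), int(round(end * ts.fs))
        tensors.append(_chunked_band_filter(ts.data[:, :, i0:i1], plan, L, ts.fs))
    return windows, plan, L, tensors


def _chunked_band_filter(data: np.ndarray, plan, L: int, fs: float) -> np.ndarray:
    """Apply :func:`cissa.band_filter` in trial chunks to bound memory."""
    n = data.shape[0]
    P = data.shape[-1]
    K = P - L + 1
    # keep the complex projection tensor of each chunk under ~300 MB
    per_trial = data.shape[1] * K * L * 16
    chunk = max(1, int(3e8 // max(per_trial, 1)))
    out = np.empty((plan.B,) + data.shape)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[:, lo:hi] = cissa.band_filter(data[lo:hi], plan, L, fs)
    return out


def _segment_band_trialset(tensor_b: np.ndarray, ts: TrialSet, idx=None) -> TrialSet:
    data = tensor_b if idx is None else tensor_b[idx]
    labels = ts.labels if idx is None else ts.labels[idx]
    return TrialSet(
        data=data, labels=labels, fs=ts.fs, channel_names=list(ts.channel_names)
    )


def _fit_banks(tensors, ts: TrialSet, cfg: PipelineConfig, idx) -> dict:
    """CSP filter bank per (segment, band), fitted on rows ``idx`` only."""
    banks: dict[tuple[int, int], SpatialFilterBank] = {}
    for t, tensor in enumerate(tensors):
        for b in range(tensor.shape[0]):
            seg = _segment_band_trialset(tensor[b], ts, idx)
            banks[(t, b)] = fit_csp(class_covariances(seg), cfg.M)
    return banks


def _features_from_banks(tensors, ts: TrialSet, banks: dict, M: int, idx=None) -> FeatureMatrix:
    blocks, columns = [], []
    for t, tensor in enumerate(tensors):
        for b in range(tensor.shape[0]):
            seg = _segment_band_trialset(tensor[b], ts, idx)
            blocks.append(log_variance_features(seg, banks[(t, b)]).values)
            columns.extend((t, b, r) for r in range(2 * M))
    labels = ts.labels if idx is None else ts.labels[idx]
    return FeatureMatrix(values=np.hstack(blocks), labels=labels, columns=columns)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def extract_features(ts: TrialSet, cfg: PipelineConfig) -> FeatureMatrix:
    """Full 2MBT-column feature table, CSP banks fitted on all trials.

    This is the descriptive (non-cross-validated) view of the feature
    space; :func:`run_cv` refits the banks inside each training fold.
    """
    cfg.validate()
    ts.validate(require_both_classes=True)
    windows, plan, L, tensors = _band_tensors(ts, cfg)
    banks = _fit_banks(tensors, ts, cfg, idx=None)
    return _features_from_banks(tensors, ts, banks, cfg.M)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    return list(skf.split(np.zeros(labels.size), labels))


def _apply_fusion(cfg: PipelineConfig, F_train: FeatureMatrix, F_test: FeatureMatrix):
    d = F_train.d
    if cfg.fusion == "none":
        return F_train, F_test
    k = cfg.k if cfg.k is not None else d
    if cfg.fusion == "mibif":
        ranking = mibif_scores(F_train)
        return (
            mibif_select(ranking, k, F_train),
            mibif_select(ranking, k, F_test),
        )
    k = min(k, F_train.n - 1)
    model = pca_fit(F_train, k)
    return pca_transform(model, F_train), pca_transform(model, F_test)


def _classify_fold(cfg: PipelineConfig, F_train: FeatureMatrix, F_test: FeatureMatrix) -> float:
    clf = SVC(kernel="linear", C=cfg.C)
    clf.fit(F_train.values, F_train.labels)
    return float(np.mean(clf.predict(F_test.values) == F_test.labels) * 100.0)


def run_cv(ts: TrialSet, cfg: PipelineConfig) -> CVReport:
    """Stratified k-fold cross-validated accuracy of the full pipeline.

    CSP banks, the fusion stage and the SVM are all refitted on each
    training split; the held-out split is only ever transformed and
    scored.
    """
    cfg.validate()
    ts.validate(require_both_classes=True)
    for label in (1, 2):
        if len(ts.class_indices(label)) < cfg.folds:
            raise ValueError(
                f"class {label} has fewer trials than folds={cfg.folds}"
            )
    windows, plan, L, tensors = _band_tensors(ts, cfg)
    folds = _stratified_folds(ts.labels, cfg.folds, cfg.seed)
    accs = []
    d_before = d_after = 0
    for train_idx, test_idx in folds:
        banks = _fit_banks(tensors, ts, cfg, train_idx)
        F_train = _features_from_banks(tensors, ts, banks, cfg.M, train_idx)
        F_test = _features_from_banks(tensors, ts, banks, cfg.M, test_idx)
        d_before = F_train.d
        G_train, G_test = _apply_fusion(cfg, F_train, F_test)
        d_after = G_train.d
        accs.append(_classify_fold(cfg, G_train, G_test))
    return CVReport(
        fold_accuracies=accs,
        mean=float(np.mean(accs)),
        std=float(np.std(accs)),
        d_before=d_before,
        d_after=d_after,
        fingerprint=cfg.fingerprint(),
        seed=cfg.seed,
    )


def sweep_feature_count(
    ts: TrialSet, cfg: PipelineConfig, ks: list[int]
) -> tuple[list[CVReport], int]:
    """One cross-validated run per feature count k, sharing folds and banks.

    Returns the per-k reports and the k attaining the highest mean
    accuracy (first on ties).
    """
    cfg.validate()
    ts.validate(require_both_classes=True)
    windows, plan, L, tensors = _band_tensors(ts, cfg)
    folds = _stratified_folds(ts.labels, cfg.folds, cfg.seed)

    fold_state = []
    for train_idx, test_idx in folds:
        banks = _fit_banks(tensors, ts, cfg, train_idx)
        F_train = _features_from_banks(tensors, ts, banks, cfg.M, train_idx)
        F_test = _features_from_banks(tensors, ts, banks, cfg.M, test_idx)
        state: dict = {"train": F_train, "test": F_test}
        if cfg.fusion == "mibif":
            state["ranking"] = mibif_scores(F_train)
        elif cfg.fusion == "pca":
            state["pca"] = pca_fit(F_train, min(F_train.d, F_train.n - 1))
        fold_state.append(state)

    d = fold_state[0]["train"].d
    if any(not 1 <= k <= d for k in ks):
        raise ValueError(f"every k must lie in [1, {d}]")

    reports = []
    for k in ks:
        accs = []
        for state in fold_state:
            F_train, F_test = state["train"], state["test"]
            if cfg.fusion == "mibif":
                G_train = mibif_select(state["ranking"], k, F_train)
                G_test = mibif_select(state["ranking"], k, F_test)
            elif cfg.fusion == "pca":
                model = state["pca"]
                kk = min(k, model.k)
                sub = PcaModel(
                    mean=model.mean, W=model.W[:, :kk], variances=model.variances[:kk]
                )
                G_train = pca_transform(sub, F_train)
                G_test = pca_transform(sub, F_test)
            else:
                G_train, G_test = F_train, F_test
            accs.append(_classify_fold(cfg, G_train, G_test))
        reports.append(
            CVReport(
                fold_accuracies=accs,
                mean=float(np.mean(accs)),
                std=float(np.std(accs)),
                d_before=d,
                d_after=k if cfg.fusion != "none" else d,
                fingerprint=cfg.fingerprint(),
                seed=cfg.seed,
            )
        )
    best_k = ks[int(np.argmax([r.mean for r in reports]))]
    return reports, best_k


def feature_grid_report(ts: TrialSet, cfg: PipelineConfig) -> FeatureGridReport:
    """Single-feature diagnostics over the (window, band, rank) grid.

    The window axis prepends the whole trial to the T sub-windows.  Each
    cell's accuracy is the stratified-CV accuracy of an SVM on that single
    CSP feature (banks refitted per fold); each cell's MIBIF value is the
    feature's mutual information with the label on the full dataset (banks
    fitted on all trials) — the descriptive view used to map where the
    discriminative ERD/ERS activity lives.
    """
    cfg.validate()
    ts.validate(require_both_classes=True)
    trial_length = ts.n_samples / ts.fs
    sub_windows = plan_windows(trial_length, cfg.window)
    windows = [(0.0, trial_length)] + list(sub_windows)
    plan, L = _resolve_plan(cfg, ts.fs)
    folds = _stratified_folds(ts.labels, cfg.folds, cfg.seed)
    n = ts.n_trials
    n_ranks = 2 * cfg.M
    acc = np.zeros((len(windows), plan.B, n_ranks))
    mib = np.zeros((len(windows), plan.B, n_ranks))

    for w, (start, end) in enumerate(windows):
        i0, i1 = int(round(start * ts.fs)), int(round(end * ts.fs))
        tensor = _chunked_band_filter(ts.data[:, :, i0:i1], plan, L, ts.fs)
        for b in range(plan.B):
            correct = np.zeros(n_ranks)
            for train_idx, test_idx in folds:
                seg_train = _segment_band_trialset(tensor[b], ts, train_idx)
                bank = fit_csp(class_covariances(seg_train), cfg.M)
                Ftr = log_variance_features(seg_train, bank).values
                seg_test = _segment_band_trialset(tensor[b], ts, test_idx)
                Fte = log_variance_features(seg_test, bank).values
                for r in range(n_ranks):
                    clf = SVC(kernel="linear", C=cfg.C)
                    clf.fit(Ftr[:, [r]], ts.labels[train_idx])
                    correct[r] += np.sum(
                        clf.predict(Fte[:, [r]]) == ts.labels[test_idx]
                    )
            acc[w, b] = correct / n * 100.0
            seg_all = _segment_band_trialset(tensor[b], ts)
            bank_all = fit_csp(class_covariances(seg_all), cfg.M)
            F_all = FeatureMatrix(
                values=log_variance_features(seg_all, bank_all).values,
                labels=ts.labels,
                columns=[(w, b, r) for r in range(n_ranks)],
            )
            mib[w, b] = mibif_scores(F_all).mi
    return FeatureGridReport(
        accuracy=acc,
        mibif=mib,
        windows=windows,
        bands=list(plan.bands),
        fingerprint=cfg.fingerprint(),
        seed=cfg.seed,
    )
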