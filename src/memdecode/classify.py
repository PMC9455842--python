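"""Memory-outcome classification from sensor- or source-space signals.

Trials labeled remembered vs forgotten are classified per frequency
band and analysis window, in both feature spaces, with two models:
shrinkage-regularized LDA (pooled covariance shrunk toward a scaled
identity, Σ(γ) = (1−γ)Σ + γvI with v = trace(Σ)/d) and a compact CNN.
Evaluation uses seeded 5-fold cross-validation with SMOTE applied to
the training folds only; the fold assignment is computed once per
dataset and reused across every (feature space × band × model) cell so
cells are compared on identical splits.  AUC is the macro area under
the ROC curve (identical to the plain AUC for two classes, midrank tie
convention); "remembered" is the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.neighbors import NearestNeighbors

from ._cnn import CNNConfig, CompactCNN
from .io_formats import EpochSet
from .preprocess import bandpass_epochs
from .sourceloc import InverseOperator, apply_inverse, parcellate
from .synthgen import BANDS_HZ

__all__ = [
    "ShrinkageLDA",
    "CNNConfig",
    "CompactCNN",
    "CVReport",
    "ComparisonReport",
    "make_folds",
    "smote",
    "shrink_covariance",
    "evaluate",
    "cross_validate_cell",
    "run_comparison",
    "permutation_null_mean_auc",
]

POSITIVE_CLASS = "remembered"
NEGATIVE_CLASS = "forgotten"

ANALYSIS_WINDOWS = {"pre": (-300.0, 0.0), "ongoing": (400.0, 800.0)}


def make_folds(n_trials: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition into k near-equal folds; returns fold id per trial.

    With n = qk + r, the first r folds get q+1 trials.  Reproducible
    from the seed; the same assignment is reused for every feature
    space, band and model on one dataset.
    """
    if k < 2 or n_trials < k:
        raise ValueError("need k >= 2 and at least one trial per fold")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    assignment = np.empty(n_trials, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return assignment


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling in feature space.

    Each synthetic sample is ``x + u (x_nn − x)`` with ``u ~ U(0, 1)``
    and ``x_nn`` one of the k nearest minority neighbors of ``x``;
    the minority class is upsampled to the majority count.  Balanced
    input is returned unchanged.  Only ever apply this to training
    folds.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here is binary")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples")
    k = k_neighbors
    if n_min <= k:
        k = n_min - 1
        warnings.warn(
            f"minority count {n_min} <= k_neighbors {k_neighbors}; using k={k}",
            stacklevel=2,
        )
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    need = n_maj - n_min
    base = rng.integers(0, n_min, need)
    pick = neigh[base, rng.integers(1, k + 1, need)]
    u = rng.random((need, 1))
    synth = Xm[base] + u * (Xm[pick] - Xm[base])
    return np.vstack([X, synth]), np.concatenate([y, np.full(need, minority, dtype=y.dtype)])


def shrink_covariance(sigma: np.ndarray, gamma: float) -> np.ndarray:
    """Σ(γ) = (1−γ) Σ + γ v I with v = trace(Σ)/d."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    d = sigma.shape[0]
    v = np.trace(sigma) / d
    return (1.0 - gamma) * sigma + gamma * v * np.eye(d)


class ShrinkageLDA:
    """Binary LDA with identity-target covariance shrinkage.

    The discriminant is ``w = Σ(γ)⁻¹ (μ₁ − μ₀)`` with the pooled
    within-class covariance Σ (class covariances weighted by class
    priors, biased normalization).  For wide feature matrices
    (d ≫ n) the solve goes through the Woodbury identity on the n × n
    Gram matrix rather than the d × d covariance.
    """

    def __init__(self, gamma: float = 0.1):
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        self.gamma = gamma
        self.w: np.ndarray | None = None
        self.b: float | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("ShrinkageLDA is binary")
        self.classes_ = classes
        n, d = X.shape
        mu = np.stack([X[y == c].mean(axis=0) for c in classes])
        Xc = X.copy()
        for i, c in enumerate(classes):
            Xc[y == c] -= mu[i]
        delta = mu[1] - mu[0]
        gamma = self.gamma
        v = float(np.sum(Xc * Xc) / (n * d))  # trace(Σ)/d without forming Σ
        if gamma == 1.0:
            w = delta / v
        elif d <= 2 * n:
            sigma = Xc.T @ Xc / n
            w = np.linalg.solve(shrink_covariance(sigma, gamma), delta)
        else:
            # Woodbury: (αI + c XᵀX)⁻¹ = α⁻¹I − α⁻¹Xᵀ(c⁻¹I + α⁻¹XXᵀ)⁻¹Xα⁻¹
            alpha = gamma * v
            c = (1.0 - gamma) / n
            G = Xc @ Xc.T
            inner = np.linalg.solve(np.eye(n) / c + G / alpha, Xc @ delta)
            w = delta / alpha - (Xc.T @ inner) / alpha**2
        n1 = int(np.sum(y == classes[1]))
        self.w = w
        self.b = float(-0.5 * w @ (mu[0] + mu[1]) + np.log(n1 / (n - n1)))
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        if self.w is None:
            raise RuntimeError("fit before predict")
        return np.asarray(X, float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(X) > 0, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class CVReport:
    """Per-cell cross-validation result (one feature space × band × model).

    The cell's AUC is the mean of per-fold AUCs (folds whose test set
    contains a single class are skipped); per-fold AUC is invariant to
    fold-specific score offsets, which pooled scores are not.
    """

    fold_auc_pct: np.ndarray  # nan where a fold's test set is one-class
    auc_pct: float  # mean over valid folds
    pooled_auc_pct: float
    roc: tuple[np.ndarray, np.ndarray]
    confusion: np.ndarray  # rows = true class (forgotten, remembered), row-normalized
    fold_assignment: np.ndarray
    scores: np.ndarray  # held-out score per trial, original order
    seed: int


def evaluate(scores: np.ndarray, labels01: np.ndarray, threshold: float = 0.0) -> dict:
    """AUC (%), ROC points and row-normalized confusion at a threshold."""
    labels01 = np.asarray(labels01, int)
    scores = np.asarray(scores, float)
    if len(np.unique(labels01)) < 2:
        auc = np.nan
        roc = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    else:
        auc = roc_auc_score(labels01, scores) * 100.0
        fpr, tpr, _ = roc_curve(labels01, scores)
        roc = (fpr, tpr)
    pred = (scores > threshold).astype(int)
    cm = confusion_matrix(labels01, pred, labels=[0, 1]).astype(float)
    rows = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, rows, out=np.zeros_like(cm), where=rows > 0)
    return {"auc_pct": auc, "roc": roc, "confusion": cm}


def cross_validate_cell(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    fold_assignment: np.ndarray,
    seed: int = 0,
    gamma: float = 0.1,
    cnn_config: CNNConfig | None = None,
    use_smote: bool = True,
) -> CVReport:
    """Seeded k-fold CV of one classifier on (trials, channels, time) input.

    SMOTE balances each training set in flattened feature space; the
    test fold is never touched.  Scores are collected in original trial
    order; the cell's headline number is the mean of per-fold AUCs
    (results over the test sets averaged), skipping the rare fold whose
    random test split contains one class only.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    k = int(fold_assignment.max()) + 1
    scores = np.empty(len(y))
    fold_aucs = np.full(k, np.nan)
    threshold = 0.0 if model == "rlda" else 0.5
    for fold in range(k):
        test = fold_assignment == fold
        train = ~test
        Xtr_flat = X[train].reshape(train.sum(), -1)
        ytr = y[train]
        if use_smote and len(np.unique(ytr)) == 2 and np.unique(ytr, return_counts=True)[1].min() >= 2:
            Xtr_flat, ytr = smote(Xtr_flat, ytr, seed=seed * 1000 + fold)
        if model == "rlda":
            clf = ShrinkageLDA(gamma=gamma).fit(Xtr_flat, ytr)
            s = clf.decision_scores(X[test].reshape(test.sum(), -1))
        elif model == "cnn":
            cfg = cnn_config or CNNConfig()
            cfg = replace(cfg, seed=seed * 1000 + fold)
            Xtr = Xtr_flat.reshape(-1, X.shape[1], X.shape[2])
            clf = CompactCNN(cfg).fit(Xtr, ytr)
            s = clf.decision_scores(X[test])
        else:
            raise ValueError(f"unknown model {model!r}")
        scores[test] = s
        if len(np.unique(y[test])) == 2:
            fold_aucs[fold] = roc_auc_score(y[test], s) * 100.0
    ev = evaluate(scores, y, threshold=threshold)
    return CVReport(
        fold_auc_pct=fold_aucs,
        auc_pct=float(np.nanmean(fold_aucs)),
        pooled_auc_pct=ev["auc_pct"],
        roc=ev["roc"],
        confusion=ev["confusion"],
        fold_assignment=fold_assignment,
        scores=scores,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# the sensor-vs-source comparison


@dataclass
class ComparisonReport:
    """Full comparison output across subjects.

    ``table``: one row per (window, space, band, model, subject) with
    the pooled CV AUC.  ``summary``: mean ± sd over subjects per cell.
    ``anova``: two-way repeated-measures ANOVA (frequency × features)
    per window and model.  ``posthoc``: Bonferroni-corrected paired t
    sensor vs source per band.  ``null95``: 95th percentile of the
    permutation null of the subject-mean AUC per cell.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    anova: dict
    posthoc: dict
    null95: pd.DataFrame
    confusions: dict
    seed: int


def _cell_features(
    es_band: EpochSet,
    inverse: InverseOperator | None,
    space: str,
    window_ms: tuple[float, float],
    decimate: int,
) -> np.ndarray:
    if space == "source":
        if inverse is None:
            raise ValueError("source-space cells need an inverse operator")
        es_band = parcellate(apply_inverse(es_band, inverse), inverse.grid)
    cropped = es_band.crop(window_ms)
    data = cropped.data[:, :, ::decimate]
    return data


def _fold_mean_auc(scores: np.ndarray, y: np.ndarray, folds: np.ndarray) -> float:
    aucs = []
    for fold in np.unique(folds):
        sel = folds == fold
        if len(np.unique(y[sel])) == 2:
            aucs.append(roc_auc_score(y[sel], scores[sel]) * 100.0)
    return float(np.mean(aucs)) if aucs else np.nan


def permutation_null_mean_auc(
    scores_per_subject: list[np.ndarray],
    labels_per_subject: list[np.ndarray],
    folds_per_subject: list[np.ndarray],
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the subject-mean fold-mean AUC.

    Labels are permuted independently within each subject against that
    subject's held-out scores — the exact null of "no score–label
    association" — and the observed statistic (per-fold AUCs on the
    same fold assignment, averaged over folds then subjects) is
    recomputed per permutation, so observed value and null are
    structurally matched.  Since scores are fixed across permutations,
    per-fold AUCs reduce to rank sums over the permuted positive set
    (midrank tie convention, as in :func:`evaluate`).
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    # precompute per (subject, fold): trial indices and score midranks
    fold_cache = []
    for s, f in zip(scores_per_subject, folds_per_subject):
        per_fold = []
        for fold in np.unique(f):
            idx = np.where(f == fold)[0]
            per_fold.append((idx, rankdata(s[idx])))
        fold_cache.append(per_fold)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        aucs = []
        for y, per_fold in zip(labels_per_subject, fold_cache):
            yp = rng.permutation(y)
            fold_aucs = []
            for idx, ranks in per_fold:
                yf = yp[idx]
                n_pos = int(yf.sum())
                n_neg = len(idx) - n_pos
                if n_pos == 0 or n_neg == 0:
                    continue
                u = ranks[yf == 1].sum() - n_pos * (n_pos + 1) / 2.0
                fold_aucs.append(u / (n_pos * n_neg) * 100.0)
            if fold_aucs:
                aucs.append(np.mean(fold_aucs))
        null[i] = np.mean(aucs) if aucs else np.nan
    return null


def run_comparison(
    subjects: list[EpochSet],
    inverse: InverseOperator,
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma"),
    windows: dict | None = None,
    models: tuple[str, ...] = ("rlda", "cnn"),
    seed: int = 0,
    gamma: float = 0.1,
    cnn_config: CNNConfig | None = None,
    decimate: int = 2,
    filter_order: int = 4,
    n_permutations: int = 200,
) -> ComparisonReport:
    """Sensor vs source classification across subjects, bands, windows.

    For each subject the remembered/forgotten trials are selected once
    and one fold assignment is drawn; for each band the sensor epochs
    are zero-phase band-filtered, source features are obtained by
    applying the inverse to the band-filtered sensor data and averaging
    within parcels, both are cropped to the analysis window and
    decimated, then every model is cross-validated on identical folds
    with SMOTE-balanced training sets.
    """
    windows = windows or ANALYSIS_WINDOWS
    rows = []
    confusions: dict = {}
    cell_scores: dict = {}
    cell_labels: dict = {}
    subj_labels = []
    subj_folds = []
    subj_epochs = []
    for si, es in enumerate(subjects):
        keep = np.isin(es.labels, [POSITIVE_CLASS, NEGATIVE_CLASS])
        sel = es.select_trials(np.where(keep)[0])
        y = (sel.labels == POSITIVE_CLASS).astype(int)
        folds = make_folds(sel.n_trials, 5, seed=seed * 10007 + si)
        subj_epochs.append(sel)
        subj_labels.append(y)
        subj_folds.append(folds)

    for band in bands:
        lo, hi = BANDS_HZ[band]
        for si, sel in enumerate(subj_epochs):
            es_band = bandpass_epochs(sel, lo, hi, order=filter_order)
            for wname, wrange in windows.items():
                for space in ("sensor", "source"):
                    feats = _cell_features(es_band, inverse, space, wrange, decimate)
                    for model in models:
                        rep = cross_validate_cell(
                            feats,
                            subj_labels[si],
                            model,
                            subj_folds[si],
                            seed=seed * 10007 + si,
                            gamma=gamma,
                            cnn_config=cnn_config,
                        )
                        key = (wname, space, band, model)
                        cell_scores.setdefault(key, []).append(rep.scores)
                        cell_labels.setdefault(key, []).append(subj_labels[si])
                        confusions.setdefault(key, []).append(rep.confusion)
                        rows.append(
                            {
                                "window": wname,
                                "space": space,
                                "band": band,
                                "model": model,
                                "subject": si,
                                "auc_pct": rep.auc_pct,
                            }
                        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["window", "space", "band", "model"], sort=False)["auc_pct"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "auc_mean_pct", "std": "auc_sd_pct"})
    )

    from .stats import bonferroni, paired_t, rm_anova

    anova: dict = {}
    posthoc: dict = {}
    for wname in windows:
        for model in models:
            cube = np.empty((len(subjects), len(bands), 2))
            for bi, band in enumerate(bands):
                for fi, space in enumerate(("sensor", "source")):
                    sub = table[
                        (table.window == wname)
                        & (table.model == model)
                        & (table.band == band)
                        & (table.space == space)
                    ].sort_values("subject")
                    cube[:, bi, fi] = sub["auc_pct"].to_numpy()
            if len(bands) > 1:
                anova[(wname, model)] = rm_anova(cube, ("frequency", "features"))
            else:  # single band: frequency factor degenerate, one-way on features
                anova[(wname, model)] = {"features": rm_anova(cube[:, 0, :], ("features",))["features"]}
            praw, tstats = [], []
            for bi, band in enumerate(bands):
                t, p, _ = paired_t(cube[:, bi, 1], cube[:, bi, 0])  # source vs sensor
                tstats.append(t)
                praw.append(p)
            reject, padj = bonferroni(np.array(praw))
            posthoc[(wname, model)] = {
                band: {"t": tstats[bi], "p_raw": praw[bi], "p_adjusted": float(padj[bi]), "reject": bool(reject[bi])}
                for bi, band in enumerate(bands)
            }

    import zlib

    null_rows = []
    for key in cell_scores:
        key_hash = zlib.crc32("/".join(key).encode()) % 2**16  # stable across runs
        null = permutation_null_mean_auc(
            cell_scores[key], cell_labels[key], subj_folds, n_permutations,
            seed=seed * 31 + key_hash,
        )
        wname, space, band, model = key
        observed = table[
            (table.window == wname) & (table.space == space) & (table.band == band) & (table.model == model)
        ]["auc_pct"].mean()
        null_rows.append(
            {
                "window": wname,
                "space": space,
                "band": band,
                "model": model,
                "auc_mean_pct": observed,
                "null_p95_pct": float(np.nanpercentile(null, 95)),
                "null_p2_5_pct": float(np.nanpercentile(null, 2.5)),
                "null_p97_5_pct": float(np.nanpercentile(null, 97.5)),
                "null_min_pct": float(np.nanmin(null)),
                "null_max_pct": float(np.nanmax(null)),
            }
        )
    null95 = pd.DataFrame(null_rows)
    mean_conf = {k: np.mean(np.stack(v), axis=0) for k, v in confusions.items()}
    return ComparisonReport(
        table=table,
        summary=summary,
        anova=anova,
        posthoc=posthoc,
        null95=null95,
        confusions=mean_conf,
        seed=seed,
    )
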