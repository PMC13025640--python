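"""Multiparametric analysis: feature stability, selection, scoring, nested CV.

The classification target is a two-group label (responder-like pCR vs
non-pCR). The analysis chain, run strictly inside each training partition:

1. **ICC stability filter** — features whose intraclass correlation across
   small spatial perturbations of the region masks exceeds 0.90 are retained
   (two-way mixed, absolute agreement, single measurement: ICC(2,1)).
2. **SVM-RFE ranking** — a linear SVM is refit while the feature with the
   smallest squared weight is eliminated each round; elimination order gives
   the rank.
3. **Incremental combinations** — ranked features are added one at a time;
   each combination x hyperparameter cell is evaluated by inner k-fold CV
   with bootstrap-averaged score maps.
4. **3D score map** — z-score -> 3-component PCA -> SMOTE (k = 5) in PC
   space -> RBF-SVM; the signed distance from the decision surface, offset by
   a threshold recalibrated to maximize balanced accuracy on the
   SMOTE-balanced training scores, is the multiparametric score. Positive
   scores predict the responder group.
5. **Nested CV aggregation** — outer stratified partitions are repeated; for
   each patient only scores from models trained without that patient are
   kept, aggregated across folds and averaged across iterations into one
   cross-validated score per patient. Metrics (AUC, accuracy, sensitivity,
   specificity) are computed on those aggregated scores with patient-level
   bootstrap confidence intervals.

Everything is a pure function of (data, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class SelectionConfig:
    """Knobs of the multiparametric selection/validation pipeline."""

    icc_threshold: float = 0.90
    inner_folds: tuple = (3, 5, 10)
    inner_iterations: int = 3
    bootstrap_scoremaps: int = 5
    outer_partitions: int = 10
    outer_iterations: int = 10
    box_constraints: tuple = tuple(np.logspace(-4, 0, 5))
    kernel_scales: tuple = tuple(np.logspace(0, 1, 5))
    max_features: int = 15
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.icc_threshold < 1.0:
            raise ValueError("icc_threshold must lie in (0, 1)")
        for name in ("inner_iterations", "bootstrap_scoremaps", "outer_partitions",
                     "outer_iterations", "max_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# ICC stability filter
# ---------------------------------------------------------------------------

def icc_2_1(data: np.ndarray) -> float:
    """Two-way, absolute-agreement, single-measurement ICC of an n x k table.

    Rows are subjects, columns repeated measurements (perturbation
    replicates). Closed form from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 measurements")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ZeroDivisionError("ICC undefined: zero between-subject variance")
    return float((msr - mse) / denom)


def icc_filter(
    replicates: pd.DataFrame,
    threshold: float = 0.90,
    patients: list | None = None,
) -> list[str]:
    """Retain features whose perturbation ICC exceeds the threshold.

    ``replicates`` is indexed by (patient, replicate); ``patients`` restricts
    the computation to a training subset (leakage guard). Features with an
    undefined ICC (zero between-patient variance) are dropped with a warning.
    """
    if patients is not None:
        replicates = replicates.loc[list(patients)]
    retained = []
    for col in replicates.columns:
        mat = replicates[col].unstack(level="replicate").to_numpy()
        if np.isnan(mat).any():
            continue
        try:
            val = icc_2_1(mat)
        except ZeroDivisionError:
            warnings.warn(f"feature {col}: ICC undefined, dropped", stacklevel=2)
            continue
        if val > threshold:
            retained.append(col)
    return retained


# ---------------------------------------------------------------------------
# SVM-RFE ranking
# ---------------------------------------------------------------------------

def _zscore_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def rfe_rank(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, fine_below: int = 30
) -> list[int]:
    """Linear-SVM recursive feature elimination; best feature first.

    Each round fits a linear SVM on the z-scored surviving features and
    removes the smallest-squared-weight features. While more than
    ``fine_below`` features survive, 10% are shed per round (the usual RFE
    acceleration); after that, elimination is strictly one at a time, so the
    ranking of the features that can actually be selected downstream comes
    from single-feature elimination. Constant features are eliminated first
    by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("RFE needs both classes present")
    surviving = [j for j in range(X.shape[1]) if X[:, j].std() > 0]
    eliminated = [j for j in range(X.shape[1]) if X[:, j].std() == 0]
    order = []  # elimination order, first eliminated = worst
    while len(surviving) > 1:
        sub = X[:, surviving]
        mu, sd = _zscore_fit(sub)
        svm = SVC(kernel="linear", C=C)
        svm.fit((sub - mu) / sd, y)
        w2 = (svm.coef_[0]) ** 2
        n_drop = (
            max(1, int(0.1 * len(surviving)))
            if len(surviving) > fine_below
            else 1
        )
        n_drop = min(n_drop, len(surviving) - 1)
        batch = np.argsort(w2, kind="stable")[:n_drop]
        order.extend(surviving[int(k)] for k in batch)  # worst first
        for k in sorted((int(k) for k in batch), reverse=True):
            surviving.pop(k)
    order.extend(surviving)
    # rank: last eliminated = best
    return order[::-1] + eliminated[::-1]


# ---------------------------------------------------------------------------
# SMOTE and the 3D score map
# ---------------------------------------------------------------------------

def smote(X: np.ndarray, y: np.ndarray, k: int = 5, rng=None):
    """Synthetic minority oversampling: balance classes by k-NN interpolation."""
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE expects exactly two classes")
    n_needed = counts.max() - counts.min()
    if n_needed == 0:
        return X, y
    minority = classes[np.argmin(counts)]
    Xm = X[y == minority]
    if Xm.shape[0] < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k_eff = min(k, Xm.shape[0] - 1)
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k_eff]
    picks = rng.integers(0, Xm.shape[0], n_needed)
    neigh = nn[picks, rng.integers(0, k_eff, n_needed)]
    u = rng.uniform(size=(n_needed, 1))
    X_new = Xm[picks] + u * (Xm[neigh] - Xm[picks])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
    )


@dataclass
class ScoreMap3D:
    """Trained PC-space RBF-SVM with normalization and recalibrated threshold."""

    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray  # [n_pc x n_features]
    svm: SVC
    threshold: float
    features: list

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((np.asarray(X, float) - self.mean) / self.sd) @ self.components.T

    def score(self, X: np.ndarray) -> np.ndarray:
        """Signed distance from the decision surface minus the threshold."""
        return self.svm.decision_function(self.transform(X)) - self.threshold


def _pca_components(Xz: np.ndarray, n_pc: int) -> np.ndarray:
    _, _, vt = np.linalg.svd(Xz - Xz.mean(axis=0), full_matrices=False)
    comps = vt[:n_pc]
    # deterministic sign: largest-magnitude loading positive
    for c in comps:
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1
    return comps


def balanced_accuracy_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing balanced accuracy of `score > t => class 1`.

    Candidates include 0, so recalibration never loses to the raw cut; ties
    prefer the smallest |t|.
    """
    s = np.asarray(scores, float)
    y = np.asarray(y)
    uniq = np.unique(s)
    cand = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[0] - 1.0, uniq[-1] + 1.0]])
    best_t, best_ba = 0.0, -1.0
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    for t in cand:
        pred = s > t
        tpr = (pred & (y == 1)).sum() / n1
        tnr = (~pred & (y == 0)).sum() / n0
        ba = 0.5 * (tpr + tnr)
        if ba > best_ba + 1e-12 or (abs(ba - best_ba) <= 1e-12 and abs(t) < abs(best_t)):
            best_t, best_ba = float(t), ba
    return best_t


def train_scoremap(
    X: np.ndarray,
    y: np.ndarray,
    features: list | None = None,
    C: float = 1.0,
    kernel_scale: float = 1.0,
    smote_k: int = 5,
    rng=None,
) -> ScoreMap3D:
    """Fit the z-score -> PCA(3) -> SMOTE -> RBF-SVM score map on training rows.

    ``kernel_scale`` s enters the RBF as gamma = 1/s^2. Raises if either
    class has fewer than 3 training members (SMOTE infeasible).
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 3:
        raise ValueError("each class needs at least 3 training members")
    mu, sd = _zscore_fit(X)
    Xz = (X - mu) / sd
    n_pc = min(3, Xz.shape[1], Xz.shape[0])
    comps = _pca_components(Xz, n_pc)
    P = Xz @ comps.T
    Pb, yb = smote(P, y, k=smote_k, rng=rng)
    svm = SVC(kernel="rbf", C=C, gamma=1.0 / kernel_scale**2)
    svm.fit(Pb, yb)
    raw = svm.decision_function(Pb)
    thr = balanced_accuracy_threshold(raw, yb)
    return ScoreMap3D(
        mean=mu, sd=sd, components=comps, svm=svm, threshold=thr,
        features=list(features) if features is not None else list(range(X.shape[1])),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic with mid-ranked ties."""
    s = np.asarray(scores, float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classification_metrics(
    scores: np.ndarray,
    y: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """AUC/accuracy/sensitivity/specificity at score threshold 0, with
    percentile bootstrap 95% CIs over patients."""
    s = np.asarray(scores, float)
    y = np.asarray(y)

    def _all(sv, yv):
        pred = sv > 0
        sens = (pred & (yv == 1)).sum() / max(1, (yv == 1).sum())
        spec = (~pred & (yv == 0)).sum() / max(1, (yv == 0).sum())
        acc = (pred == (yv == 1)).mean()
        return auc_rank(sv, yv), acc, sens, spec

    auc, acc, sens, spec = _all(s, y)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(s)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        boots.append(_all(s[idx], y[idx]))
    boots = np.array(boots) if boots else np.full((1, 4), np.nan)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    names = ("auc", "accuracy", "sensitivity", "specificity")
    point = (auc, acc, sens, spec)
    return {
        name: {"value": float(v), "ci95": (float(l), float(h))}
        for name, v, l, h in zip(names, point, lo, hi)
    }


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    scores: pd.Series  # aggregated held-out score per patient
    predictions: pd.Series
    metrics: dict
    selection_counts: pd.Series
    fold_log: pd.DataFrame


def _stratified_partition(patients, y, n_parts, rng):
    """Disjoint label-stratified partition of patients into n_parts folds."""
    folds = [[] for _ in range(n_parts)]
    for cls in np.unique(y):
        idx = [p for p, lab in zip(patients, y) if lab == cls]
        idx = list(np.array(idx)[rng.permutation(len(idx))])
        for i, p in enumerate(idx):
            folds[i % n_parts].append(p)
    return folds


def _inner_score(X, y, combo_idx, C, ks, folds_k, n_iter, n_boot, smote_k, rng):
    """Pooled held-out AUC of one (combination, hyperparameter) cell."""
    aucs = []
    for k in folds_k:
        for _ in range(n_iter):
            skf = StratifiedKFold(
                n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
            )
            pooled_s, pooled_y = [], []
            for tr, va in skf.split(X, y):
                Xtr, ytr = X[tr][:, combo_idx], y[tr]
                Xva = X[va][:, combo_idx]
                sv = np.zeros(len(va))
                n_ok = 0
                for _b in range(n_boot):
                    bidx = rng.integers(0, len(tr), len(tr))
                    if np.unique(ytr[bidx], return_counts=True)[1].min() < 3 or len(
                        np.unique(ytr[bidx])
                    ) < 2:
                        bidx = np.arange(len(tr))  # fall back to the full fold
                    try:
                        sm = train_scoremap(
                            Xtr[bidx], ytr[bidx], C=C, kernel_scale=ks,
                            smote_k=smote_k, rng=rng,
                        )
                    except ValueError:
                        continue
                    sv += sm.score(Xva)
                    n_ok += 1
                if n_ok == 0:
                    continue
                pooled_s.extend(sv / n_ok)
                pooled_y.extend(y[va])
            pooled_y = np.asarray(pooled_y)
            if len(np.unique(pooled_y)) == 2:
                aucs.append(auc_rank(np.asarray(pooled_s), pooled_y))
    return float(np.mean(aucs)) if aucs else 0.5


def nested_cv(
    X: pd.DataFrame,
    y: pd.Series,
    config: SelectionConfig | None = None,
    replicates: pd.DataFrame | None = None,
) -> CVResult:
    """Nested cross-validated multiparametric scoring.

    ``X`` is the patient-indexed feature table (no label column), ``y`` the
    binary labels (1 = responder-like), ``replicates`` optional perturbation
    replicates for the ICC stage. Every selection/normalization/PCA/SMOTE
    step is refit inside each outer training partition; a held-out patient
    never influences the model that scores it.
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(config.seed)
    patients = list(X.index)
    y_arr = y.loc[patients].to_numpy()
    all_cols = list(X.columns)

    score_sum = pd.Series(0.0, index=patients)
    score_n = pd.Series(0, index=patients)
    sel_counts = pd.Series(0, index=all_cols, dtype=int)
    log_rows = []

    for it in range(config.outer_iterations):
        folds = _stratified_partition(patients, y_arr, config.outer_partitions, rng)
        for fi, test_pat in enumerate(folds):
            if not test_pat:
                continue
            train_pat = [p for p in patients if p not in set(test_pat)]
            ytr = y.loc[train_pat].to_numpy()
            if len(np.unique(ytr)) < 2:
                continue
            if replicates is not None:
                cols = icc_filter(replicates[all_cols], config.icc_threshold,
                                  patients=train_pat)
                if not cols:
                    cols = all_cols
            else:
                cols = all_cols
            Xtr = X.loc[train_pat, cols].to_numpy()
            rank = rfe_rank(Xtr, ytr)
            n_max = min(config.max_features, len(cols))
            best = None  # (auc, -n_feat, -C_index...) tie-breaks
            for n_feat in range(1, n_max + 1):
                combo = rank[:n_feat]
                for C in config.box_constraints:
                    for ks in config.kernel_scales:
                        a = _inner_score(
                            Xtr, ytr, combo, C, ks,
                            config.inner_folds, config.inner_iterations,
                            config.bootstrap_scoremaps, config.smote_k, rng,
                        )
                        key = (a, -n_feat, -C, -ks)
                        if best is None or key > best[0]:
                            best = (key, combo, C, ks)
            _, combo, C, ks = best
            sm = train_scoremap(
                Xtr[:, combo], ytr, features=[cols[j] for j in combo],
                C=C, kernel_scale=ks, smote_k=config.smote_k, rng=rng,
            )
            Xte = X.loc[test_pat, cols].to_numpy()[:, combo]
            s_te = sm.score(Xte)
            for p, sv in zip(test_pat, s_te):
                score_sum[p] += sv
                score_n[p] += 1
            for f in sm.features:
                sel_counts[f] += 1
            log_rows.append(
                {
                    "iteration": it,
                    "fold": fi,
                    "n_features": len(combo),
                    "C": C,
                    "kernel_scale": ks,
                    "features": ";".join(sm.features),
                    "test_patients": ";".join(map(str, test_pat)),
                    "test_scores": ";".join(f"{v:.17g}" for v in s_te),
                }
            )

    agg = score_sum / score_n.replace(0, np.nan)
    mets = classification_metrics(
        agg.to_numpy(), y_arr, seed=int(rng.integers(2**31))
    )
    return CVResult(
        scores=agg,
        predictions=(agg > 0).astype(int),
        metrics=mets,
        selection_counts=sel_counts.sort_values(ascending=False),
        fold_log=pd.DataFrame(log_rows),
    )


def feature_frequency(result: CVResult, top: int = 16) -> pd.DataFrame:
    """Top-k selection-frequency histogram with region/domain tags."""
    from .features import feature_schema

    tags = {c.name: (c.region, c.domain) for c in feature_schema()}
    rows = []
    for name, count in result.selection_counts.head(top).items():
        region, domain = tags.get(name, ("", ""))
        rows.append({"feature": name, "count": int(count),
                     "region": region, "domain": domain})
    return pd.DataFrame(rows)


def group_stats(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Normality check plus two-sample t-test on per-group scores."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    g1, g0 = s[y == 1], s[y == 0]
    if len(g1) < 3 or len(g0) < 3:
        raise ValueError("need at least 3 patients per group")
    out = {
        "shapiro_p": {
            "group1": float(stats.shapiro(g1).pvalue),
            "group0": float(stats.shapiro(g0).pvalue),
        }
    }
    if g1.std() == 0 and g0.std() == 0:
        out["t"] = 0.0 if g1.mean() == g0.mean() else np.inf
        out["p"] = 1.0 if g1.mean() == g0.mean() else 0.0
        out["degenerate_variance"] = True
    else:
        t, p = stats.ttest_ind(g1, g0)
        out["t"], out["p"] = float(t), float(p)
        out["degenerate_variance"] = False
    return out


def pearson(x, y):
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y):
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)
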