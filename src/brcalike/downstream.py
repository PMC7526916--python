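"""Distance-to-reference profiling, indicator correlations and classification.

Each patient is summarized by the median Euclidean distance (in the
signature embedding) to the members of the BRCA-like reference group, a
reference member excluding itself.  Binary indicators (low-expression flags,
clinical variables, drug response) are screened against these distances with
a two-sided Pearson (point-biserial) correlation test.  Aberration status is
additionally predicted from the two embedding coordinates by a logistic
model under stratified cross-validation, weighting minority-class samples by
the majority/minority frequency ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .embedding import Embedding
from .errors import InvalidInputError, StratificationError, ValidationError


def distance_to_reference(
    embedding: Embedding, reference: set[str] | list[str]
) -> pd.Series:
    """Median distance from every embedded patient to the reference members."""
    ref_ids = sorted(set(map(str, reference)))
    if len(ref_ids) < 2:
        raise InvalidInputError("reference group must have at least 2 members")
    ref_idx = embedding.index_of(ref_ids)
    coords = embedding.coords
    diffs = coords[:, None, :] - coords[ref_idx][None, :, :]
    d = np.sqrt((diffs**2).sum(axis=-1))  # (n, n_ref)
    ref_set = set(ref_idx.tolist())
    out = np.empty(embedding.n)
    for i in range(embedding.n):
        row = d[i]
        if i in ref_set:
            row = np.delete(row, np.where(ref_idx == i)[0])
        out[i] = np.median(row)
    return pd.Series(out, index=pd.Index(embedding.sample_ids, name="patient"), name="median_distance_to_reference")


def indicator_correlation(
    distances: pd.Series, indicator: pd.Series
) -> tuple[float, float, int]:
    """Two-sided Pearson test between distances and a 0/1 indicator.

    Missing values are dropped pairwise.  Returns ``(rho, p, n)``.
    """
    df = pd.concat([distances, indicator], axis=1, join="inner").dropna()
    if len(df) < 4:
        raise InvalidInputError("need at least 4 paired observations")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("indicator must be binary 0/1")
    if np.unique(y).size < 2:
        raise InvalidInputError("indicator is constant; correlation undefined")
    rho, p = stats.pearsonr(x, y)
    return float(rho), float(p), len(df)


def correlation_screen(
    distances: pd.Series,
    indicators: pd.DataFrame,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Pearson screen of every indicator column against the distance profile.

    Indicators that are constant or nearly unobserved are skipped.  Raw
    p-values are reported; ``add_bh`` appends a Benjamini-Hochberg column as
    a labeled extension.
    """
    rows = []
    for col in indicators.columns:
        try:
            rho, p, n = indicator_correlation(distances, indicators[col])
        except (InvalidInputError, ValidationError):
            continue
        rows.append({"variable": col, "n": n, "rho": rho, "p": p})
    out = pd.DataFrame(rows, columns=["variable", "n", "rho", "p"])
    if add_bh and len(out):
        out["bh_fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


@dataclass
class ClassifierReport:
    target: str
    seed: int
    folds: int
    sensitivity: float
    specificity: float
    auroc: float
    class_weights: list[float]  # minority-class sample weight per fold


def crossval_logistic(
    embedding: Embedding | np.ndarray,
    labels: pd.Series | np.ndarray,
    folds: int = 2,
    seed: int = 0,
    target: str = "aberration",
) -> ClassifierReport:
    """Stratified cross-validated logistic prediction from embedding coordinates.

    Minority-class samples are weighted by the majority/minority frequency
    ratio in each training fold; out-of-fold probabilities are pooled and
    thresholded at 0.5 for sensitivity/specificity, with AUROC reported
    threshold-free.
    """
    X = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    y = np.asarray(labels, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise ValidationError("labels must align with embedded samples")
    if not set(np.unique(y)) <= {0, 1} or np.unique(y).size < 2:
        raise ValidationError("labels must be binary with both classes present")
    n_minority = min(np.sum(y == 0), np.sum(y == 1))
    if n_minority < folds:
        raise StratificationError(
            f"minority class has {n_minority} samples; cannot stratify {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = np.empty(y.size)
    weights_per_fold: list[float] = []
    for train, test in skf.split(X, y):
        y_tr = y[train]
        n_pos, n_neg = int(np.sum(y_tr == 1)), int(np.sum(y_tr == 0))
        if n_pos == 0 or n_neg == 0:
            raise StratificationError("a training fold contains a single class")
        minority = 1 if n_pos <= n_neg else 0
        ratio = max(n_pos, n_neg) / min(n_pos, n_neg)
        weights_per_fold.append(float(ratio))
        w = np.where(y_tr == minority, ratio, 1.0)
        model = LogisticRegression(solver="lbfgs", max_iter=1000)
        model.fit(X[train], y_tr, sample_weight=w)
        proba[test] = model.predict_proba(X[test])[:, 1]
    pred = (proba >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    sens = tp / int(np.sum(y == 1))
    spec = tn / int(np.sum(y == 0))
    auroc = float(roc_auc_score(y, proba))
    return ClassifierReport(
        target=target,
        seed=seed,
        folds=folds,
        sensitivity=float(sens),
        specificity=float(spec),
        auroc=auroc,
        class_weights=weights_per_fold,
    )
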