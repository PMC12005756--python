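"""Statistical layer over the trait tables.

Implements the study-style comparisons across the four IgG fractions
(total/ACPA x plasma/synovial fluid): PCA with minimum-positive-value
imputation (0.01), within-patient paired t-tests, Šídák-adjusted
predefined comparisons, and Spearman correlations against clinical
parameters with pairwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "FRACTIONS",
    "PREDEFINED_FRACTION_COMPARISONS",
    "impute_min_positive",
    "PCAResult",
    "pca_fractions",
    "paired_test",
    "paired_tests",
    "sidak_adjust",
    "sidak_comparisons",
    "spearman_matrix",
    "fraction_silhouette",
]

FRACTIONS = ("total_plasma", "total_SF", "ACPA_plasma", "ACPA_SF")

# the study's predefined fraction contrasts (k = 4 per trait)
PREDEFINED_FRACTION_COMPARISONS = (
    ("total_plasma", "total_SF"),
    ("total_plasma", "ACPA_plasma"),
    ("total_SF", "ACPA_SF"),
    ("ACPA_plasma", "ACPA_SF"),
)


def impute_min_positive(df: pd.DataFrame, value: float = 0.01) -> pd.DataFrame:
    """Replace missing values by the minimum positive number (default 0.01)."""
    return df.fillna(value)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_fractions(
    features: pd.DataFrame,
    mode: str = "per_patient_centered",
    impute_value: float = 0.01,
    n_components: int = 2,
) -> PCAResult:
    """PCA of IgG features across the four fractions.

    ``features`` is indexed by (patient, fraction) with one column per
    feature.  Missing values are imputed with ``impute_value``, columns
    are standardised, and in ``per_patient_centered`` mode each
    patient's mean feature vector is subtracted first so that the
    scores express within-patient differences between fractions.  In
    ``concatenated`` mode the rows are used as given (e.g. one row per
    patient with features concatenated over fractions).
    """
    if mode not in ("per_patient_centered", "concatenated"):
        raise ValueError(f"unknown PCA mode: {mode!r}")
    x = impute_min_positive(features.astype(float), impute_value)
    if len(x) < 3:
        raise ValueError("PCA requires at least 3 rows")
    if mode == "per_patient_centered":
        if not isinstance(x.index, pd.MultiIndex):
            raise ValueError("per_patient_centered mode needs a (patient, fraction) index")
        x = x - x.groupby(level=0).transform("mean")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0).replace(0.0, 1.0)
    xs = (x - mu) / sd
    n_components = min(n_components, len(x) - 1, xs.shape[1])
    model = PCA(n_components=n_components)
    scores = model.fit_transform(xs.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=x.index, columns=cols),
        loadings=pd.DataFrame(model.components_.T, index=x.columns, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def paired_test(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Two-sided paired t-test on complete pairs.

    Identical pairs (all differences zero) give t=0, p=1; a constant
    non-zero shift with zero variance of differences is degenerate and
    flagged (p = NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        return {"t": math.nan, "p": math.nan, "n": n, "degenerate": True}
    if np.all(d == 0):
        return {"t": 0.0, "p": 1.0, "n": n, "degenerate": False}
    if np.std(d, ddof=1) == 0:
        return {"t": math.inf, "p": math.nan, "n": n, "degenerate": True}
    t, p = sps.ttest_rel(x[keep], y[keep])
    return {"t": float(t), "p": float(p), "n": n, "degenerate": False}


def paired_tests(
    table: pd.DataFrame,
    pair: Tuple[str, str],
    patient_col: str = "patient",
    fraction_col: str = "fraction",
    value_col: str = "value",
    feature_col: str = "trait",
) -> pd.DataFrame:
    """Per-feature paired t-tests between two fractions of a tidy trait table."""
    a, b = pair
    rows = []
    for feat, grp in table.groupby(feature_col):
        wide = grp.pivot_table(
            index=patient_col, columns=fraction_col, values=value_col, aggfunc="mean"
        )
        if a not in wide.columns or b not in wide.columns:
            continue
        res = paired_test(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append({feature_col: feat, "fraction_a": a, "fraction_b": b, **res})
    return pd.DataFrame(rows)


def sidak_adjust(p: float, k: int) -> float:
    """Šídák adjustment for k predefined comparisons: 1 - (1-p)^k."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - p) ** k


def sidak_comparisons(
    table: pd.DataFrame,
    comparisons: Sequence[Tuple[str, str]] = PREDEFINED_FRACTION_COMPARISONS,
    **kwargs,
) -> pd.DataFrame:
    """Paired t-tests for each predefined comparison, Šídák-adjusted.

    The adjustment counts the k predefined comparisons per feature.
    """
    k = len(comparisons)
    frames = [paired_tests(table, pair, **kwargs) for pair in comparisons]
    out = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    if out.empty:
        return out
    out["p_adj"] = [
        sidak_adjust(p, k) if not math.isnan(p) else math.nan for p in out["p"]
    ]
    return out


def spearman_matrix(
    traits: pd.DataFrame,
    clinical: pd.DataFrame,
    min_pairs: int = 4,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p per (trait, clinical) pair with pairwise deletion.

    Both inputs are indexed by patient; columns are features.  Cells
    supported by fewer than ``min_pairs`` complete pairs are NaN and
    marked unavailable in the returned mask.
    """
    idx = traits.index.intersection(clinical.index)
    t = traits.loc[idx].astype(float)
    c = clinical.loc[idx].astype(float)
    rho = pd.DataFrame(index=t.columns, columns=c.columns, dtype=float)
    pval = pd.DataFrame(index=t.columns, columns=c.columns, dtype=float)
    avail = pd.DataFrame(False, index=t.columns, columns=c.columns)
    for tc in t.columns:
        for cc in c.columns:
            x, y = t[tc].to_numpy(), c[cc].to_numpy()
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < min_pairs:
                continue
            r, p = sps.spearmanr(x[keep], y[keep])
            rho.loc[tc, cc] = float(r)
            pval.loc[tc, cc] = float(p)
            avail.loc[tc, cc] = True
    return rho, pval, avail


def fraction_silhouette(scores: pd.DataFrame, labels: Sequence[str]) -> float:
    """Silhouette coefficient of score rows grouped by fraction labels."""
    return float(silhouette_score(scores.to_numpy(), np.asarray(labels)))
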