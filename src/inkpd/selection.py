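"""Feature selection and univariate screening.

Because the per-channel catalogue produces far more features than there
are recordings, each feature family (kinematic, pressure, angle, moment)
is reduced to its top-30 features by random-forest impurity importance,
fitted strictly on training rows. Univariate screening reports, per
feature, a Mann-Whitney U p-value (two classes) or Kruskal-Wallis p-value
(three or more) together with the absolute Spearman correlation against
the integer-coded class label, mirroring how such feature tables are
usually reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTable

__all__ = ["SelectionResult", "ScreenRow", "rf_select", "stat_screen", "LABEL_ORDER"]

#: integer coding of class labels (affects only the sign of Spearman rho)
LABEL_ORDER = {"HC": 0, "ET": 1, "PD": 2}


@dataclasses.dataclass
class SelectionResult:
    """Retained features of one family, ordered by importance."""

    family: str
    features: list[str]
    importances: np.ndarray
    train_index: pd.Index

    def __post_init__(self) -> None:
        if np.any(self.importances < 0):
            raise ValueError("importances must be non-negative")
        if np.any(np.diff(self.importances) > 1e-12):
            raise ValueError("importances must be sorted non-increasing")

    def transform(self, table: FeatureTable) -> pd.DataFrame:
        """Apply the stored column subset; never refits."""
        return table.data[self.features]


@dataclasses.dataclass
class ScreenRow:
    feature: str
    channel: str
    family: str
    test: str
    p_value: float
    abs_spearman: float


def encode_labels(labels: pd.Series | np.ndarray) -> np.ndarray:
    lab = np.asarray(labels)
    return np.array([LABEL_ORDER.get(v, v) for v in lab])


def rf_select(
    table: FeatureTable,
    labels: pd.Series | np.ndarray,
    family: str,
    k: int = 30,
    seed: int = 0,
    n_trees: int = 500,
    train_index: pd.Index | None = None,
) -> SelectionResult:
    """Top-k features of one family by random-forest impurity importance.

    The forest is fitted only on ``train_index`` rows (all rows when not
    given). Ties in importance break by feature name so the retained set
    is deterministic for a fixed seed.
    """
    cols = table.family_columns(family)
    if not cols:
        raise ValueError(f"family {family!r} has no features")
    y = np.asarray(labels)
    idx = table.data.index if train_index is None else train_index
    pos = table.data.index.get_indexer(idx)
    X = table.data.loc[idx, cols].to_numpy()
    y_tr = y[pos]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("need at least two classes to fit the selector")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y_tr)
    imp = rf.feature_importances_
    order = sorted(range(len(cols)), key=lambda j: (-imp[j], cols[j]))
    keep = order[: min(k, len(cols))]
    return SelectionResult(
        family=family,
        features=[cols[j] for j in keep],
        importances=imp[keep],
        train_index=pd.Index(idx),
    )


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact enumeration for small tie-free groups."""
    method = "exact" if (len(a) <= 10 and len(b) <= 10
                         and len(np.unique(np.concatenate([a, b])))
                         == len(a) + len(b)) else "asymptotic"
    return float(scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method=method).pvalue)


def stat_screen(
    table: FeatureTable, labels: pd.Series | np.ndarray
) -> list[ScreenRow]:
    """Univariate screening of every feature against the class label.

    Constant features get p = 1 and |rho| = 0 by convention. Rows come back
    sorted by |rho| descending within family.
    """
    y = encode_labels(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    test = "mannwhitneyu" if len(classes) == 2 else "kruskal"
    rows: list[ScreenRow] = []
    for col in table.data.columns:
        x = table.data[col].to_numpy()
        channel = col.split("__")[0]
        family = table.families[col]
        if np.ptp(x) == 0:
            rows.append(ScreenRow(col, channel, family, test, 1.0, 0.0))
            continue
        groups = [x[y == c] for c in classes]
        if test == "mannwhitneyu":
            p = _mannwhitney_p(groups[0], groups[1])
        else:
            p = float(scipy.stats.kruskal(*groups).pvalue)
        rho = scipy.stats.spearmanr(x, y).statistic
        rho = 0.0 if np.isnan(rho) else float(abs(rho))
        rows.append(ScreenRow(col, channel, family, test, p, rho))
    rows.sort(key=lambda r: (r.family, -r.abs_spearman, r.feature))
    return rows


def screen_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
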