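"""Sequential categorical synthesizer for decoy records.

Decoy (synthetic) records are sampled from the estimated empirical joint
distribution of the linkage variables of a file.  The joint is factorized
sequentially: the first column is drawn from its marginal frequency table,
each later column from a conditional frequency table given all earlier
columns.  Conditional tables receive a small Dirichlet-style pseudo-count
mass spread proportionally to the column marginal, so sparse parent
combinations shrink toward the marginal and unseen parent combinations back
off to it entirely.

Synthesis quality is certified by the cross-validated AUC of a classifier
trained to tell real records from synthetic ones: an AUC near 0.5 means the
decoys are statistically indistinguishable from the real file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import OneHotEncoder

from .records import SOURCE_SYNTH, RecordTable

BY_CARDINALITY_DESC = "by_cardinality_desc"
AS_GIVEN = "as_given"


@dataclass
class _ColumnModel:
    name: str
    categories: np.ndarray          # observed categories, fixed order
    marginal: np.ndarray            # smoothed marginal over `categories`
    # parent tuple -> probability vector over `categories`; empty for col 0
    conditionals: dict = field(default_factory=dict)


@dataclass
class SynthModel:
    """Fitted sequential model of the joint linkage-variable distribution."""

    column_order: list[str]
    columns: list[_ColumnModel]
    smoothing: float
    declared_order: list[str] | None = None

    def marginal_of(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        for col in self.columns:
            if col.name == name:
                return col.categories, col.marginal
        raise KeyError(name)


def _smoothed(counts: np.ndarray, weights: np.ndarray, mass: float) -> np.ndarray:
    """Counts plus total pseudo-count `mass` spread as `weights` (sums to 1)."""
    total = counts.sum() + mass
    return (counts + mass * weights) / total


def fit_synthesizer(
    table: RecordTable,
    column_order_rule: str = BY_CARDINALITY_DESC,
    smoothing: float = 0.5,
) -> SynthModel:
    """Fit the sequential empirical model of a file's linkage variables.

    The first modelled column is the highest-cardinality variable under the
    default ordering rule (ties broken by declaration order); each subsequent
    column is modelled conditionally on all earlier ones.  Missing values are
    dropped per column when estimating that column's distribution.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if table.n == 0 or not table.variables:
        raise ValueError("no records to fit")
    df = table.values
    for v in table.variables:
        if df[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values")

    if column_order_rule == BY_CARDINALITY_DESC:
        # stable sort keeps declaration order among ties
        order = sorted(table.variables, key=lambda v: -df[v].nunique())
    elif column_order_rule == AS_GIVEN:
        order = list(table.variables)
    else:
        raise ValueError(f"unknown column_order_rule {column_order_rule!r}")

    columns: list[_ColumnModel] = []
    for t, name in enumerate(order):
        obs = df[df[name].notna()]
        vc = obs[name].value_counts(sort=False)
        cats = vc.index.to_numpy()
        pos = {c: k for k, c in enumerate(cats)}
        counts = vc.to_numpy(dtype=float)
        # add-`smoothing` per category on the marginal itself
        prior_mass = smoothing * len(cats)
        marg = _smoothed(counts, np.full(len(cats), 1.0 / len(cats)), prior_mass)
        col = _ColumnModel(name=name, categories=cats, marginal=marg)
        if t > 0:
            parents = order[:t]
            complete = obs.dropna(subset=parents)
            grouped = complete.groupby(parents, observed=True, sort=False)[name]
            tables: dict[tuple, np.ndarray] = {}
            ll_cond = ll_marg = 0.0
            n_groups = 0
            n_complete = len(complete)
            emp_marg = counts / counts.sum()
            for parent_key, child in grouped:
                if not isinstance(parent_key, tuple):
                    parent_key = (parent_key,)
                cnt = np.zeros(len(cats))
                for c, k in child.value_counts(sort=False).items():
                    cnt[pos[c]] = k
                n_groups += 1
                nz = cnt > 0
                ll_cond += float(cnt[nz] @ np.log(cnt[nz] / cnt.sum()))
                ll_marg += float(cnt[nz] @ np.log(emp_marg[nz]))
                # Dirichlet prior centred at the column marginal: sparse parent
                # combinations generalise toward the marginal instead of
                # memorising individual source rows
                tables[parent_key] = _smoothed(cnt, marg, prior_mass)
            # keep the conditional model only when it beats the marginal by
            # BIC; otherwise the column is synthesized from its marginal,
            # mirroring tree-based synthesizers that only split on real signal
            extra_params = (n_groups - 1) * (len(cats) - 1)
            penalty = 0.5 * extra_params * math.log(max(n_complete, 2))
            if ll_cond - ll_marg > penalty:
                col.conditionals = tables
        columns.append(col)
    return SynthModel(
        column_order=order,
        columns=columns,
        smoothing=smoothing,
        declared_order=list(table.variables),
    )


def sample_synthetic(model: SynthModel, n: int, seed: int) -> RecordTable:
    """Draw ``n`` decoy records column-by-column from a fitted model.

    Deterministic given ``(model, n, seed)``.  Decoys carry ``source =
    "SYNTH"`` and no entity identifier; missing values are never generated.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    drawn = np.empty((n, len(model.columns)), dtype=object)
    cdf_cache: dict[tuple, np.ndarray] = {}
    for t, col in enumerate(model.columns):
        u = rng.random(n)
        if t == 0:
            idx = np.searchsorted(np.cumsum(col.marginal), u, side="right")
            idx = np.minimum(idx, len(col.categories) - 1)
        else:
            idx = np.empty(n, dtype=int)
            marg_cdf = np.cumsum(col.marginal)
            for r in range(n):
                key = tuple(drawn[r, :t])
                cdf = cdf_cache.get((t,) + key)
                if cdf is None:
                    probs = col.conditionals.get(key)
                    cdf = marg_cdf if probs is None else np.cumsum(probs)
                    cdf_cache[(t,) + key] = cdf
                k = np.searchsorted(cdf, u[r], side="right")
                idx[r] = min(k, len(col.categories) - 1)
        drawn[:, t] = col.categories[idx]
        out[col.name] = drawn[:, t].copy()
    df = pd.DataFrame(out)
    df["record_id"] = [f"SYN{r}" for r in range(n)]
    df["source"] = SOURCE_SYNTH
    variables = model.declared_order or model.column_order
    return RecordTable(df[variables + ["record_id", "source"]], variables)


def _one_hot_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.astype(str)


def classifier_auc(
    X: pd.DataFrame, y: np.ndarray, folds: int = 5, seed: int = 0
) -> float:
    """Cross-validated ROC AUC of a regularized linear classifier on
    one-hot-encoded categorical features."""
    y = np.asarray(y).astype(int)
    if len(X) < folds:
        raise ValueError("fewer records than cross-validation folds")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = make_pipeline(
        OneHotEncoder(handle_unknown="ignore"),
        LogisticRegression(max_iter=1000),
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, _one_hot_frame(X), y, cv=cv, method="predict_proba")[:, 1]
    return float(roc_auc_score(y, proba))


def synth_quality_auc(
    real: RecordTable, synthetic: RecordTable, folds: int = 5, seed: int = 0
) -> float:
    """AUC of a real-vs-synthetic classifier; ~0.5 certifies fidelity."""
    if real.n == 0 or synthetic.n == 0:
        raise ValueError("both tables must be non-empty")
    if list(real.variables) != list(synthetic.variables):
        raise ValueError("tables must share the same declared variables")
    X = pd.concat([real.values, synthetic.values], ignore_index=True)
    y = np.r_[np.zeros(real.n), np.ones(synthetic.n)]
    return classifier_auc(X, y, folds=folds, seed=seed)
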