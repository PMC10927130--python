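"""Feature selection and Mahalanobis leave-one-out kNN classification.

Features (keypress metrics and brain volumes) are screened for group
differences with the Kruskal-Wallis test and Dunn's pairwise post-hoc z
test (Benjamini-Hochberg corrected across the three group pairs within a
feature); a feature is selected when any pairwise q < .05.

Pairwise classification then uses leave-one-out k-nearest-neighbors
(k = 5): within each fold the continuous features are whitened by the
inverse principal square root of the pooled within-group covariance (the
Mahalanobis transform, so Euclidean distance in the transformed space is
the Mahalanobis distance), one-hot demographic indicators are appended
unwhitened, the k nearest training points vote, and the votes are weighted
by class priors (training-fold class proportions by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .labels import GROUPS

__all__ = [
    "FeatureSelectionRow",
    "KNNConfig",
    "kruskal_dunn",
    "select_features",
    "mahalanobis_transform",
    "knn_loo",
    "run_combinations",
    "COMBINATIONS",
]

#: The six feature-set combinations evaluated per group pair.
COMBINATIONS: tuple[str, ...] = (
    "metrics",
    "metrics+demographics",
    "volumes",
    "volumes+metrics",
    "volumes+demographics",
    "metrics+volumes+demographics",
)


@dataclass
class FeatureSelectionRow:
    """Groupwise difference tests for one candidate feature."""

    feature: str
    kw_p: float = np.nan
    pairwise_p: dict = field(default_factory=dict)
    pairwise_q: dict = field(default_factory=dict)
    selected: bool = False


@dataclass
class KNNConfig:
    """kNN hyperparameters.

    ``priors=None`` uses training-fold class proportions.  ``transform``
    is "mahalanobis" (pooled within-group whitening) or "none".
    ``refit_transform`` controls whether the whitening is re-estimated
    inside every leave-one-out fold (no leakage) or once on the full
    sample.
    """

    k: int = 5
    transform: str = "mahalanobis"
    priors: dict[str, float] | None = None
    ridge: float = 1e-8
    refit_transform: bool = True

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.transform not in ("mahalanobis", "none"):
            raise ValueError("transform must be 'mahalanobis' or 'none'")
        if self.priors is not None:
            tot = sum(self.priors.values())
            if not np.isclose(tot, 1.0):
                raise ValueError("priors must sum to 1")


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> dict:
    """Dunn's z tests on pooled mean ranks with tie correction."""
    ranks = stats.rankdata(values)
    N = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term
    out = {}
    groups = sorted(set(labels))
    for a, b in itertools.combinations(groups, 2):
        ra = ranks[labels == a]
        rb = ranks[labels == b]
        se = np.sqrt(var_base * (1.0 / ra.size + 1.0 / rb.size))
        z = (ra.mean() - rb.mean()) / se if se > 0 else np.nan
        p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        out[(a, b)] = {"z": float(z), "p": p}
    return out


def kruskal_dunn(
    values: np.ndarray,
    labels: np.ndarray,
    *,
    feature: str = "",
    alpha: float = 0.05,
) -> FeatureSelectionRow:
    """Kruskal-Wallis across groups plus Dunn's pairwise post-hoc tests.

    Pairwise p-values are Benjamini-Hochberg corrected across the group
    pairs within this feature; the feature is selected when any pairwise
    q < alpha.  A constant feature is left unselected with NaN statistics.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    row = FeatureSelectionRow(feature=feature)
    groups = sorted(set(labels))
    samples = [values[labels == g] for g in groups]
    if any(s.size < 2 for s in samples) or np.all(values == values[0]):
        return row
    row.kw_p = float(stats.kruskal(*samples).pvalue)
    pw = _dunn_pairwise(values, labels)
    row.pairwise_p = {k: v["p"] for k, v in pw.items()}
    pairs = list(row.pairwise_p)
    qs = bh_adjust([row.pairwise_p[k] for k in pairs])
    row.pairwise_q = dict(zip(pairs, (float(q) for q in qs)))
    row.selected = any(q < alpha for q in row.pairwise_q.values())
    return row


def select_features(
    cohort: pd.DataFrame,
    features,
    *,
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`kruskal_dunn` over a feature list; tidy result table."""
    labels = cohort[group_col].to_numpy()
    rows = []
    for f in features:
        r = kruskal_dunn(
            cohort[f].to_numpy(dtype=float), labels, feature=f, alpha=alpha
        )
        rec = {"feature": f, "kw_p": r.kw_p, "selected": r.selected}
        for pair, p in r.pairwise_p.items():
            rec[f"p_{pair[0]}_vs_{pair[1]}"] = p
            rec[f"q_{pair[0]}_vs_{pair[1]}"] = r.pairwise_q[pair]
        rows.append(rec)
    return pd.DataFrame(rows)


def mahalanobis_transform(
    X: np.ndarray,
    labels: np.ndarray,
    *,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Whitening matrix from the pooled within-group covariance.

    Returns W = S_w^{-1/2} (inverse principal square root) so that the
    transformed pooled within-group covariance of ``X @ W`` is the
    identity.  A small ridge is added to the covariance diagonal when it is
    numerically singular; a singular covariance with ``ridge=0`` raises.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, d = X.shape
    S = np.zeros((d, d))
    dof = 0
    for g in np.unique(labels):
        xg = X[labels == g]
        if xg.shape[0] < 2:
            continue
        xc = xg - xg.mean(axis=0)
        S += xc.T @ xc
        dof += xg.shape[0] - 1
    if dof == 0:
        raise ValueError("no group has >= 2 members")
    S /= dof
    evals, evecs = np.linalg.eigh(S)
    if np.min(evals) <= 0 or np.min(evals) / max(np.max(evals), 1e-300) < 1e-12:
        if ridge <= 0:
            raise np.linalg.LinAlgError(
                "pooled within-group covariance is singular; set ridge > 0"
            )
        evals = evals + ridge * max(np.max(evals), 1.0)
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def _classify_one(
    dists: np.ndarray,
    train_labels: np.ndarray,
    k: int,
    priors: dict[str, float],
) -> str:
    order = np.argsort(dists, kind="stable")
    votes = train_labels[order[:k]]
    classes = sorted(priors)
    scores = {
        g: priors[g] * float((votes == g).sum()) / k for g in classes
    }
    best = max(scores.values())
    tied = [g for g in classes if scores[g] == best]
    if len(tied) > 1:
        # tie: larger prior wins, then lexicographic order
        tied.sort(key=lambda g: (-priors[g], g))
    return tied[0]


def knn_loo(
    X: np.ndarray,
    labels: np.ndarray,
    config: KNNConfig,
    *,
    continuous: np.ndarray | None = None,
) -> pd.DataFrame:
    """Leave-one-out kNN over a two-class sample.

    ``continuous`` is a boolean column mask marking which features enter
    the Mahalanobis covariance (default all); the remaining columns (e.g.
    one-hot demographic indicators) are appended untransformed.  Returns
    one row per class with correct/incorrect counts and percentages.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    classes = sorted(set(labels))
    counts = {g: int((labels == g).sum()) for g in classes}
    if any(c < config.k + 1 for c in counts.values()):
        raise ValueError(f"every class needs >= k+1 = {config.k + 1} members")
    if continuous is None:
        continuous = np.ones(X.shape[1], dtype=bool)
    cont, rest = X[:, continuous], X[:, ~continuous]

    def _coords(train_idx):
        if config.transform == "none" or cont.shape[1] == 0:
            return np.column_stack([cont, rest])
        W = mahalanobis_transform(
            cont[train_idx], labels[train_idx], ridge=config.ridge
        )
        return np.column_stack([cont @ W, rest])

    full_coords = None
    if not config.refit_transform:
        full_coords = _coords(np.arange(n))

    predicted = np.empty(n, dtype=object)
    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        coords = full_coords if full_coords is not None else _coords(train)
        d = np.linalg.norm(coords[train] - coords[i], axis=1)
        if config.priors is not None:
            priors = config.priors
        else:
            priors = {g: (labels[train] == g).sum() / train.size for g in classes}
        predicted[i] = _classify_one(d, labels[train], config.k, priors)

    rows = []
    for g in classes:
        mask = labels == g
        correct = int((predicted[mask] == g).sum())
        rows.append(
            {
                "class": g,
                "n": counts[g],
                "n_correct": correct,
                "n_misclassified": counts[g] - correct,
                "pct_correct": 100.0 * correct / counts[g],
                "pct_misclassified": 100.0 * (counts[g] - correct) / counts[g],
            }
        )
    return pd.DataFrame(rows)


def _encode_demographics(demo: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Continuous demographics as floats plus one-hot categoricals.

    Returns the design block and a boolean mask marking its continuous
    columns (these join the Mahalanobis covariance; indicators do not).
    """
    num = demo.select_dtypes(include=[np.number])
    cat = demo.select_dtypes(exclude=[np.number])
    blocks, cont_mask = [], []
    if num.shape[1]:
        blocks.append(num.to_numpy(dtype=float))
        cont_mask += [True] * num.shape[1]
    if cat.shape[1]:
        dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
        if dummies.shape[1]:
            blocks.append(dummies.to_numpy())
            cont_mask += [False] * dummies.shape[1]
    if not blocks:
        return np.empty((len(demo), 0)), np.array([], dtype=bool)
    return np.column_stack(blocks), np.array(cont_mask, dtype=bool)


def run_combinations(
    cohort: pd.DataFrame,
    selected_metrics,
    selected_volumes,
    *,
    demographics=("gender", "age", "ethnicity", "education"),
    config: KNNConfig | None = None,
    groups=GROUPS,
) -> pd.DataFrame:
    """Pairwise LOO-kNN over the six feature combinations.

    For each of the three group pairs and each combination in
    :data:`COMBINATIONS`, runs :func:`knn_loo` on the selected keypress
    metrics, selected brain volumes and/or demographics.  Rows with any
    missing feature value are dropped listwise per model.  Returns the
    tidy classification report (one row per pair x combination x class).
    """
    config = config or KNNConfig()
    sets = {
        "metrics": (list(selected_metrics), False),
        "metrics+demographics": (list(selected_metrics), True),
        "volumes": (list(selected_volumes), False),
        "volumes+metrics": (list(selected_volumes) + list(selected_metrics), False),
        "volumes+demographics": (list(selected_volumes), True),
        "metrics+volumes+demographics": (
            list(selected_metrics) + list(selected_volumes), True),
    }
    out = []
    for a, b in itertools.combinations(groups, 2):
        sub = cohort[cohort["group"].isin([a, b])]
        if "valid" in sub.columns:
            sub = sub[sub["valid"].astype(bool)]
        for combo in COMBINATIONS:
            feats, with_demo = sets[combo]
            if not feats and not with_demo:
                out.append({"pair": f"{a}_vs_{b}", "combination": combo,
                            "class": None, "not_run": True})
                continue
            cols = feats + ([c for c in demographics] if with_demo else [])
            use = sub.dropna(subset=cols)
            Xc = use[feats].to_numpy(dtype=float) if feats else np.empty((len(use), 0))
            cont_mask = np.ones(Xc.shape[1], dtype=bool)
            if with_demo:
                demo_block, demo_mask = _encode_demographics(use[list(demographics)])
                Xc = np.column_stack([Xc, demo_block])
                cont_mask = np.concatenate([cont_mask, demo_mask])
            labels = use["group"].to_numpy()
            try:
                rep = knn_loo(Xc, labels, config, continuous=cont_mask)
            except ValueError as exc:
                out.append({"pair": f"{a}_vs_{b}", "combination": combo,
                            "class": None, "not_run": True, "reason": str(exc)})
                continue
            rep = rep.assign(
                pair=f"{a}_vs_{b}", combination=combo, N=len(use), not_run=False
            )
            out.extend(rep.to_dict("records"))
    return pd.DataFrame(out)
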