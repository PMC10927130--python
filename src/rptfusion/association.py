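"""Per-group structure-behavior regression grid.

For each diagnostic group, each of the 29 normalized brain volumes is
regressed against each of the 15 keypress metrics (metric as dependent
variable), giving a 435-cell grid of standardized slopes.  The stages are:

1. covariate screening — per (group, volume), ethnicity (two-sample rank
   sum between the two largest strata, Asian participants dropped), age and
   years of education (Spearman) are tested against the volume; a
   demographic enters the model only when its screening p < .05;
2. influence filtering — iterative Cook's-distance outlier removal
   (single worst point at a time while max D_i exceeds the cutoff,
   capped at 20% of n; Cook-Weisberg F-median cutoff by default,
   4/n optional);
3. OLS on within-group z-scored variables -> standardized beta, t-based
   95% CI, two-sided p;
4. Benjamini-Hochberg q-values over the 15-metric family sharing one
   (group, volume);
5. cross-group overlap accounting: cells significant in two groups, and
   whether their slopes agree in sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .labels import METRICS, VOLUMES

__all__ = [
    "RegressionResult",
    "OverlapSummary",
    "screen_covariates",
    "cooks_filter",
    "fit_bivariate",
    "bh_adjust",
    "run_grid",
    "overlap_analysis",
]

MIN_N = 10            # minimum observations per regression
COOKS_CAP = 0.20      # at most this fraction of points removed
ALPHA = 0.05


@dataclass
class RegressionResult:
    """One cell of the regression grid (metric ~ volume [+ covariates])."""

    group: str
    metric: str
    volume: str
    covariates: tuple[str, ...] = ()
    std_beta: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    q: float = np.nan
    n_outliers_removed: int = 0
    n_used: int = 0
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class OverlapSummary:
    """Cross-group overlap of significant grid cells.

    ``fraction`` is reported in the "a of b" convention: twice the number of
    sign-consistent common pairs over the total number of significant
    regressions entering the comparison.
    """

    pairs: dict = field(default_factory=dict)
    n_significant: dict = field(default_factory=dict)
    common_pairs: int = 0
    consistent_pairs: int = 0
    total_significant: int = 0
    fraction: float = np.nan
    shared_volumes: dict = field(default_factory=dict)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd


def screen_covariates(
    cohort: pd.DataFrame,
    group: str,
    *,
    volumes=VOLUMES,
    alpha: float = ALPHA,
) -> dict[str, list[tuple[str, float]]]:
    """Screen demographics against each volume within one group.

    Ethnicity is compared with a two-sample Wilcoxon rank-sum test between
    the two largest ethnicity strata (participants identifying as Asian are
    dropped; a single usable stratum skips the test).  Age and education
    use the Spearman correlation.  Returns, per volume, the list of
    ``(covariate, p)`` pairs with p < alpha.
    """
    sub = cohort[cohort["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 members")
    out: dict[str, list[tuple[str, float]]] = {}

    eth = sub[sub["ethnicity"] != "Asian"]
    strata = eth["ethnicity"].value_counts()
    top2 = list(strata.index[:2]) if len(strata) >= 2 else None

    for vol in volumes:
        hits: list[tuple[str, float]] = []
        v = sub[vol].to_numpy(dtype=float)
        if np.nanstd(v) > 0:
            if top2 is not None:
                a = eth.loc[eth["ethnicity"] == top2[0], vol].to_numpy(dtype=float)
                b = eth.loc[eth["ethnicity"] == top2[1], vol].to_numpy(dtype=float)
                if a.size >= 2 and b.size >= 2 and (a.std() > 0 or b.std() > 0):
                    p = stats.ranksums(a, b).pvalue
                    if p < alpha:
                        hits.append(("ethnicity", float(p)))
            for cov in ("age", "education"):
                c = sub[cov].to_numpy(dtype=float)
                if np.nanstd(c) > 0:
                    rho, p = stats.spearmanr(c, v)
                    if np.isfinite(p) and p < alpha:
                        hits.append((cov, float(p)))
        out[vol] = hits
    return out


def cooks_filter(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    rule: str = "classical",
    cap: float = COOKS_CAP,
) -> tuple[np.ndarray, int]:
    """Iteratively drop the single most influential observation.

    Refits OLS of y on (x, covariates) and removes the observation with
    the largest Cook's distance while that maximum exceeds the cutoff,
    stopping once at most ``cap`` of the original points have been
    removed.  Returns the retained index set (into the original arrays)
    and the number removed.

    ``rule="classical"`` (default) is the Cook-Weisberg cutoff: remove
    while max D_i exceeds the median of the F(p, n-p) distribution
    (p = model parameters), i.e. roughly D > 0.7 for a bivariate fit.
    Only genuinely gross outliers reach that bound, which keeps the null
    significance rate of the downstream grid calibrated.  ``rule="4/n"``
    uses the common 4/n flagging threshold as a removal cutoff; iterated
    to convergence it is aggressive (on clean Gaussian data it typically
    removes several ordinary points per regression and inflates the
    false-positive rate several-fold), so it is provided for sensitivity
    analysis only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rule not in ("classical", "4/n"):
        raise ValueError("rule must be 'classical' or '4/n'")
    n0 = x.size
    idx = np.arange(n0)
    max_remove = int(np.floor(cap * n0))
    removed = 0
    while True:
        n = idx.size
        X = x[idx, None]
        if covariates is not None and covariates.size:
            X = np.column_stack([X, covariates[idx]])
        X = sm.add_constant(X, has_constant="add")
        if n <= X.shape[1] + 1:
            break
        fit = sm.OLS(y[idx], X).fit()
        d = fit.get_influence().cooks_distance[0]
        d = np.where(np.isfinite(d), d, 0.0)
        worst = int(np.argmax(d))
        if rule == "classical":
            cutoff = float(stats.f.ppf(0.5, X.shape[1], n - X.shape[1]))
        else:
            cutoff = 4.0 / n
        if d[worst] <= cutoff or removed >= max_remove:
            break
        idx = np.delete(idx, worst)
        removed += 1
    return idx, removed


def fit_bivariate(
    y: np.ndarray,
    x: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    group: str = "",
    metric: str = "",
    volume: str = "",
    cooks: bool = True,
    cooks_rule: str = "classical",
    alpha: float = ALPHA,
) -> RegressionResult:
    """OLS of a keypress metric on a brain volume, standardized.

    Continuous variables (y, x, and continuous covariates) are z-scored
    over the retained observations after Cook's filtering; categorical
    covariates enter as unscaled indicator contrasts.  ``std_beta`` is the
    coefficient of x; with no covariates it equals the Pearson correlation
    of the retained points.  The 95% CI uses the t distribution on the
    residual degrees of freedom.
    """
    res = RegressionResult(
        group=group, metric=metric, volume=volume,
        covariates=tuple(covariates.columns) if covariates is not None else (),
    )
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)

    mask = np.isfinite(y) & np.isfinite(x)
    cov_num = None
    cov_cat_codes = None
    if covariates is not None and covariates.shape[1]:
        num = covariates.select_dtypes(include=[np.number])
        cat = covariates.select_dtypes(exclude=[np.number])
        if num.shape[1]:
            cov_num = num.to_numpy(dtype=float)
            mask &= np.all(np.isfinite(cov_num), axis=1)
        if cat.shape[1]:
            cov_cat_codes = cat
            mask &= cat.notna().all(axis=1).to_numpy()

    y, x = y[mask], x[mask]
    cov_arr = None
    parts = []
    if cov_num is not None:
        parts.append(cov_num[mask])
    if cov_cat_codes is not None:
        dummies = pd.get_dummies(
            cov_cat_codes.loc[mask], drop_first=True, dtype=float
        )
        if dummies.shape[1]:
            parts.append(dummies.to_numpy())
    if parts:
        cov_arr = np.column_stack(parts)

    if y.size < MIN_N:
        res.skipped, res.skip_reason = True, f"n={y.size} < {MIN_N}"
        return res
    if y.std() == 0 or x.std() == 0:
        res.skipped, res.skip_reason = True, "zero variance"
        return res

    if cooks:
        idx, removed = cooks_filter(x, y, cov_arr, rule=cooks_rule)
    else:
        idx, removed = np.arange(y.size), 0
    res.n_outliers_removed = removed
    res.n_used = int(idx.size)
    if idx.size < MIN_N:
        res.skipped, res.skip_reason = True, f"n={idx.size} < {MIN_N} after filtering"
        return res

    yr, xr = y[idx], x[idx]
    if yr.std() == 0 or xr.std() == 0:
        res.skipped, res.skip_reason = True, "zero variance after filtering"
        return res
    cols = [_zscore(xr)]
    if cov_arr is not None:
        cr = cov_arr[idx]
        # z-score the continuous covariates only; indicator columns stay 0/1
        n_cont = cov_num[mask].shape[1] if cov_num is not None else 0
        for j in range(cr.shape[1]):
            col = cr[:, j]
            if j < n_cont and col.std() > 0:
                col = _zscore(col)
            cols.append(col)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    fit = sm.OLS(_zscore(yr), X).fit()
    ci = fit.conf_int(alpha=alpha)
    res.std_beta = float(fit.params[1])
    res.ci_low = float(ci[1, 0])
    res.ci_high = float(ci[1, 1])
    res.p = float(fit.pvalues[1])
    return res


def bh_adjust(pvalues, *, method: str = "bh") -> np.ndarray:
    """Multiplicity-adjusted q-values for one test family.

    ``method="bh"`` is the Benjamini-Hochberg step-up with monotonicity
    enforcement (the default throughout the pipeline); ``method="holm"``
    gives Holm's step-down bound, which reproduces the q = p * (m - rank + 1)
    arithmetic seen in some published report tables.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm"}[method]
    return multipletests(p, method=key)[1]


def run_grid(
    cohort: pd.DataFrame,
    group: str,
    *,
    with_covariates: bool = True,
    volumes=VOLUMES,
    metrics=METRICS,
    alpha: float = ALPHA,
    cooks: bool = True,
    cooks_rule: str = "classical",
    bh_method: str = "bh",
) -> pd.DataFrame:
    """Fit the full volumes-by-metrics grid for one group.

    ``cohort`` is the merged participant x {group, demographics, volumes,
    metrics, valid} table; invalid profiles are excluded first.  Returns a
    tidy frame with one row per grid cell including q-values computed per
    (volume) family across the metrics, plus skip bookkeeping.
    """
    sub = cohort[(cohort["group"] == group)]
    if "valid" in sub.columns:
        sub = sub[sub["valid"].astype(bool)]
    sub = sub.reset_index(drop=True)

    covmap = (
        screen_covariates(sub.assign(group=group), group,
                          volumes=volumes, alpha=alpha)
        if with_covariates and len(sub) >= 3
        else {v: [] for v in volumes}
    )

    rows = []
    for vol in volumes:
        fam: list[RegressionResult] = []
        covs = [c for c, _ in covmap.get(vol, [])]
        use = sub
        cov_df = None
        if covs:
            use = sub
            if "ethnicity" in covs:
                # the rank-sum screen compares the two largest non-Asian
                # strata; the model keeps those participants only
                eth = use[use["ethnicity"] != "Asian"]
                top2 = eth["ethnicity"].value_counts().index[:2]
                use = eth[eth["ethnicity"].isin(top2)].reset_index(drop=True)
            cov_df = use[covs]
        for met in metrics:
            fam.append(
                fit_bivariate(
                    use[met].to_numpy(dtype=float),
                    use[vol].to_numpy(dtype=float),
                    cov_df,
                    group=group, metric=met, volume=vol,
                    cooks=cooks, cooks_rule=cooks_rule, alpha=alpha,
                )
            )
        ok = [r for r in fam if not r.skipped]
        if ok:
            qs = bh_adjust([r.p for r in ok], method=bh_method)
            for r, q in zip(ok, qs):
                r.q = float(q)
        rows.extend(fam)

    df = pd.DataFrame([vars(r) for r in rows])
    df["covariates"] = df["covariates"].map(lambda t: ",".join(t))
    return df


def grid_summary(grid: pd.DataFrame, *, alpha: float = ALPHA) -> dict:
    """Counts of significant cells in one grid."""
    ok = grid[~grid["skipped"]]
    return {
        "n_cells": int(len(grid)),
        "n_fit": int(len(ok)),
        "n_p_significant": int((ok["p"] < alpha).sum()),
        "n_q_significant": int((ok["q"] < alpha).sum()),
    }


def overlap_analysis(
    grids: dict[str, pd.DataFrame],
    *,
    rule: str = "p",
    alpha: float = ALPHA,
) -> OverlapSummary:
    """Cross-group consistency of significant structure-behavior cells.

    For every pair of groups, a *common* cell is one significant (by
    ``rule`` in {"p", "q"} at ``alpha``) in both grids; a *consistent* cell
    additionally has standardized slopes of the same sign ("beta
    agreeance").  ``fraction`` = 2 * consistent pairs / total significant
    regressions across all supplied grids.  Also lists, per pair, the
    volumes involved in both groups' significant cells outside the common
    cells.
    """
    universes = {g: set(zip(df["volume"], df["metric"])) for g, df in grids.items()}
    first = next(iter(universes.values()))
    if any(u != first for u in universes.values()):
        raise ValueError("grids do not share the same cell universe")

    sig: dict[str, pd.DataFrame] = {}
    for g, df in grids.items():
        ok = df[~df["skipped"]]
        sig[g] = ok[ok[rule] < alpha]

    out = OverlapSummary()
    out.n_significant = {g: int(len(s)) for g, s in sig.items()}
    out.total_significant = sum(out.n_significant.values())

    for a, b in itertools.combinations(grids.keys(), 2):
        sa = sig[a].set_index(["metric", "volume"])["std_beta"]
        sb = sig[b].set_index(["metric", "volume"])["std_beta"]
        common = sorted(set(sa.index) & set(sb.index))
        cells = []
        n_consistent = 0
        for cell in common:
            agree = bool(np.sign(sa[cell]) == np.sign(sb[cell]))
            n_consistent += agree
            cells.append(
                {"metric": cell[0], "volume": cell[1],
                 "beta_a": float(sa[cell]), "beta_b": float(sb[cell]),
                 "beta_agreeance": agree}
            )
        vols_a = set(sig[a]["volume"]) - {c[1] for c in common}
        vols_b = set(sig[b]["volume"]) - {c[1] for c in common}
        out.shared_volumes[(a, b)] = sorted(vols_a & vols_b)
        out.pairs[(a, b)] = {
            "common": cells,
            "n_common": len(common),
            "n_consistent": n_consistent,
        }
        out.common_pairs += len(common)
        out.consistent_pairs += n_consistent

    if out.total_significant:
        out.fraction = 2.0 * out.consistent_pairs / out.total_significant
    return out
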