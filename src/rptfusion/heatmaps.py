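"""Beta-matrix heatmaps and group-difference tests.

The covariate-free standardized slopes from the regression grid form, per
group, a volumes x metrics "beta matrix".  Group pairs are compared cell by
cell through three derived matrices and one summary test each:

* valence  |beta_A| - |beta_B|  (range -1..1) — one-sample t test vs 0;
* intensity |beta_A - beta_B|   (range 0..2)  — sample median plus a
  one-sample Wilcoxon signed-rank test vs 0 (a two-sample rank-sum variant
  against another pair's intensities is available);
* sign agreement (+1 same direction, -1 opposite) — one-sample proportion
  test of the success (same-direction) rate against 0.5.

Cells where either grid could not be fit are dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .association import run_grid
from .labels import METRICS, VOLUMES

__all__ = [
    "BetaMatrix",
    "MatrixComparison",
    "beta_matrix",
    "compare",
    "valence_ttest",
    "intensity_test",
    "sign_proportion_test",
    "render_heatmaps",
]


@dataclass
class BetaMatrix:
    """Per-group matrix of covariate-free standardized slopes.

    ``beta`` and ``p`` are volumes x metrics frames; unfit cells are NaN.
    """

    group: str
    beta: pd.DataFrame
    p: pd.DataFrame


@dataclass
class MatrixComparison:
    """Cellwise comparison of two beta matrices plus summary tests."""

    pair: tuple[str, str]
    valence: pd.DataFrame
    intensity: pd.DataFrame
    agreement: pd.DataFrame
    t_stat: float = np.nan
    t_p: float = np.nan
    wilcoxon_p: float = np.nan
    wilcoxon_median: float = np.nan
    proportion_p: float = np.nan
    agree_fraction: float = np.nan
    n_cells: int = 0


def beta_matrix(
    cohort: pd.DataFrame,
    group: str,
    *,
    volumes=VOLUMES,
    metrics=METRICS,
    grid: pd.DataFrame | None = None,
) -> BetaMatrix:
    """Build the covariate-free beta matrix for one group.

    Runs the regression grid without covariates (Cook's filtering still
    applies) unless a precomputed covariate-free grid is supplied.
    """
    if grid is None:
        grid = run_grid(
            cohort, group, with_covariates=False, volumes=volumes, metrics=metrics
        )
    beta = pd.DataFrame(np.nan, index=list(volumes), columns=list(metrics))
    pmat = beta.copy()
    for row in grid.itertuples():
        if not row.skipped:
            beta.at[row.volume, row.metric] = row.std_beta
            pmat.at[row.volume, row.metric] = row.p
    return BetaMatrix(group=group, beta=beta, p=pmat)


def valence_ttest(values: np.ndarray) -> dict:
    """One-sample two-sided t test of the valence cells against mean 0.

    A degenerate all-equal-to-zero input is reported as "no difference"
    (t = 0, p = 1) rather than an undefined statistic.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    if np.all(v == 0):
        return {"t": 0.0, "p": 1.0, "n": int(v.size)}
    t, p = stats.ttest_1samp(v, 0.0)
    return {"t": float(t), "p": float(p), "n": int(v.size)}


def intensity_test(
    values: np.ndarray,
    other: np.ndarray | None = None,
) -> dict:
    """Median intensity plus a Wilcoxon test.

    Default: one-sample Wilcoxon signed-rank of the intensities against a
    zero median (zeros dropped by the standard convention).  When ``other``
    is given, a two-sample rank-sum test between two pairs' intensity
    distributions is used instead.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty intensity vector")
    med = float(np.median(v))
    if other is not None:
        o = np.asarray(other, dtype=float)
        o = o[np.isfinite(o)]
        p = float(stats.ranksums(v, o).pvalue)
        return {"p": p, "median": med, "n": int(v.size)}
    nz = v[v != 0]
    if nz.size == 0:
        return {"p": 1.0, "median": med, "n": int(v.size)}
    p = float(stats.wilcoxon(nz, zero_method="wilcox").pvalue)
    return {"p": p, "median": med, "n": int(v.size)}


def sign_proportion_test(
    agreement: np.ndarray, *, exact: bool = False
) -> dict:
    """Test the same-direction rate against chance (0.5).

    ``agreement`` holds +1 (same sign) / -1 (opposite).  Default is the
    two-sided normal-approximation z test without continuity correction;
    ``exact=True`` switches to the exact binomial test.
    """
    a = np.asarray(agreement, dtype=float)
    a = a[np.isfinite(a)]
    n = a.size
    if n == 0:
        raise ValueError("empty agreement vector")
    succ = int((a > 0).sum())
    frac = succ / n
    if exact:
        p = float(stats.binomtest(succ, n, 0.5).pvalue)
        z = np.nan
    else:
        z = (frac - 0.5) / np.sqrt(0.25 / n)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"agree_fraction": float(frac), "p": p, "z": float(z) if z == z else np.nan,
            "n": int(n)}


def compare(
    A: BetaMatrix, B: BetaMatrix, *, exact_proportion: bool = False
) -> MatrixComparison:
    """Compare two groups' beta matrices cell by cell.

    Builds the valence, intensity and sign-agreement matrices and runs the
    three summary tests over the cells defined in both groups.
    """
    if not A.beta.index.equals(B.beta.index) or not A.beta.columns.equals(
        B.beta.columns
    ):
        raise ValueError("beta matrices have mismatched labels")
    a, b = A.beta, B.beta
    valence = a.abs() - b.abs()
    intensity = (a - b).abs()
    agreement = np.sign(a) * np.sign(b)
    agreement = agreement.where((a != 0) & (b != 0))

    mc = MatrixComparison(
        pair=(A.group, B.group),
        valence=valence,
        intensity=intensity,
        agreement=agreement,
    )
    val = valence.to_numpy().ravel()
    val = val[np.isfinite(val)]
    mc.n_cells = int(val.size)
    if val.size >= 2:
        t = valence_ttest(val)
        mc.t_stat, mc.t_p = t["t"], t["p"]
    inten = intensity.to_numpy().ravel()
    inten = inten[np.isfinite(inten)]
    if inten.size:
        w = intensity_test(inten)
        mc.wilcoxon_p, mc.wilcoxon_median = w["p"], w["median"]
    agr = agreement.to_numpy().ravel()
    agr = agr[np.isfinite(agr)]
    if agr.size:
        pr = sign_proportion_test(agr, exact=exact_proportion)
        mc.proportion_p, mc.agree_fraction = pr["p"], pr["agree_fraction"]
    return mc


def render_heatmaps(
    matrices: dict[str, pd.DataFrame],
    outdir: str | Path,
    *,
    limits: dict[str, tuple[float, float]] | None = None,
    formats: tuple[str, ...] = ("png", "svg"),
) -> list[Path]:
    """Render each named matrix as a diverging-scale heatmap.

    Volumes label the y axis and metrics the x axis.  Color limits default
    to (-1, 1) (slope scale) unless given per matrix, with red at the
    negative end and blue at the positive end.  Output is deterministic
    for fixed inputs (no timestamps embedded).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, mat in matrices.items():
        lim = (limits or {}).get(name, (-1.0, 1.0))
        fig, ax = plt.subplots(
            figsize=(max(4, 0.45 * mat.shape[1] + 3), max(3, 0.25 * mat.shape[0] + 2))
        )
        im = ax.imshow(
            mat.to_numpy(dtype=float),
            cmap="RdBu",
            vmin=lim[0],
            vmax=lim[1],
            aspect="auto",
            interpolation="nearest",
        )
        ax.set_xticks(range(mat.shape[1]), labels=list(mat.columns),
                      rotation=90, fontsize=7)
        ax.set_yticks(range(mat.shape[0]), labels=list(mat.index), fontsize=7)
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        for ext in formats:
            path = outdir / f"{name}.{ext}"
            meta = {"Date": None} if ext == "svg" else None
            fig.savefig(path, dpi=150, metadata=meta)
            written.append(path)
        plt.close(fig)
    return written
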