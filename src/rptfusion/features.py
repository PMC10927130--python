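"""Relative-preference-theory (RPT) keypress metrics.

An operant keypress task lets a participant trade keypresses to lengthen
("inc", approach) or shorten ("dec", avoidance) the viewing time of pictures
drawn from a small number of categories.  Per participant, this module turns
the raw per-picture keypress counts into 15 "keypress metrics":

six base variables
    K+/K- mean keypresses per responded picture, H+/H- Shannon entropy of
    the count distribution over pictures (bits), sigma+/sigma- standard
    deviation of counts, each averaged across categories;

nine RPT graph features
    from three per-participant curves fit over the per-category points:

    * value function  H = b * ln(K - x0) on the avoidance limb ->
      loss resilience (curvature b) and negative offset (x0);
    * limit function  sigma = a*K^2 + b*K + c on the avoidance limb ->
      negative apex (vertex height), negative turning point (vertex K),
      negative area (area bounded by the K axis);
    * trade-off function over per-category (H+, H-) points ->
      polar angle theta and radial distance r = sqrt(H+^2 + H-^2) with
      their across-category dispersions.

Participants whose avoidance value fit, avoidance limit fit, or trade-off
construction cannot be produced are flagged invalid (``valid=False`` with a
reason code) and are excluded from downstream regressions, mirroring the
cohort-exclusion rule of the study design this package supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .labels import METRICS

__all__ = [
    "CategoryStats",
    "RPTProfile",
    "shannon_entropy",
    "category_stats",
    "fit_value_function",
    "fit_limit_function",
    "tradeoff_features",
    "assemble_profile",
    "profiles_from_responses",
]

# Reason codes for participant-level exclusion.
REASON_VALUE_FIT = "value_fit_failure"        # avoidance K-H fit failed
REASON_LIMIT_FIT = "limit_fit_failure"        # avoidance K-sigma fit failed
REASON_TRADEOFF = "tradeoff_failure"          # H+H- construction failed

_FIT_TOL = 1e-8


@dataclass
class CategoryStats:
    """Per-category, per-valence summary of one participant's keypressing.

    K and sigma are computed over the pictures with a nonzero count of the
    given valence (work actually traded); H is the Shannon entropy of the
    normalized count distribution over those pictures, in bits.  All three
    are NaN when no picture was responded to (``n_active == 0``).
    """

    participant_id: str
    category: str
    valence: str
    K: float
    sigma: float
    H: float
    n_active: int


@dataclass
class RPTProfile:
    """The 15 keypress metrics for one participant, with a validity flag."""

    participant_id: str
    loss_resilience: float = np.nan
    negative_offset: float = np.nan
    negative_apex: float = np.nan
    negative_turning_point: float = np.nan
    negative_area: float = np.nan
    polar_angle: float = np.nan
    polar_dispersion: float = np.nan
    radial_distance: float = np.nan
    radial_dispersion: float = np.nan
    mean_k_inc: float = np.nan
    mean_k_dec: float = np.nan
    mean_h_inc: float = np.nan
    mean_h_dec: float = np.nan
    mean_std_inc: float = np.nan
    mean_std_dec: float = np.nan
    valid: bool = True
    exclusion_reason: str = ""

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def shannon_entropy(counts) -> float:
    """Shannon entropy, in bits, of the distribution p_i = k_i / sum(k).

    Zero counts contribute nothing (0*log 0 := 0).  An all-zero or empty
    input is undefined and returns NaN rather than 0: a participant who
    never pressed carries no information, which is not the same as a
    perfectly concentrated one.
    """
    k = np.asarray(counts, dtype=float)
    if k.size == 0 or np.any(k < 0):
        return float("nan")
    total = k.sum()
    if total <= 0:
        return float("nan")
    p = k[k > 0] / total
    return float(-(p * np.log2(p)).sum())


def category_stats(
    responses: pd.DataFrame, *, include_zeros: bool = False
) -> list[CategoryStats]:
    """Summarize one participant's responses into per-category statistics.

    Parameters
    ----------
    responses
        Rows for a single participant with columns ``participant_id``,
        ``category``, ``picture``, ``valence`` (``inc``/``dec``) and
        ``keypresses``.  A picture absent for a valence counts as zero.
    include_zeros
        When True, K and sigma average over all pictures of the category
        including zero counts (entropy is unaffected: zero counts never
        carry probability mass).
    """
    if responses.empty:
        raise ValueError("no responses supplied")
    pid = str(responses["participant_id"].iloc[0])
    out: list[CategoryStats] = []
    # Emit a record for both valences of every category present, so an
    # entirely un-keypressed side is an explicit n_active=0 record rather
    # than a silent absence.
    for cat in sorted(responses["category"].astype(str).unique()):
        cat_rows = responses[responses["category"].astype(str) == cat]
        for val in ("inc", "dec"):
            grp = cat_rows[cat_rows["valence"] == val]
            counts = grp["keypresses"].to_numpy(dtype=float)
            out.append(_one_stat(pid, cat, val, counts, include_zeros))
    return out


def _one_stat(
    pid: str, cat: str, val: str, counts: np.ndarray, include_zeros: bool
) -> CategoryStats:
    active = counts[counts > 0]
    n_active = int(active.size)
    H = shannon_entropy(counts)
    basis = counts if include_zeros else active
    if basis.size == 0:
        K = sigma = float("nan")
    else:
        K = float(basis.mean())
        sigma = float(basis.std(ddof=1)) if basis.size > 1 else 0.0
    if n_active == 1:
        H = 0.0
    return CategoryStats(
        participant_id=pid,
        category=str(cat),
        valence=str(val),
        K=K,
        sigma=sigma,
        H=H,
        n_active=n_active,
    )


def _log_sse(x0: float, K: np.ndarray, H: np.ndarray) -> tuple[float, float]:
    """SSE and closed-form slope of H = b*ln(K - x0) at a fixed offset."""
    u = np.log(K - x0)
    denom = float(u @ u)
    if denom < _FIT_TOL:
        return float("inf"), 0.0
    b = float(u @ H) / denom
    resid = H - b * u
    return float(resid @ resid), b


def fit_value_function(points, valence: str = "dec", *, form: str = "log") -> dict:
    """Fit the value function through the per-category (K, H) points.

    The primary form is logarithmic with a free x-axis offset,
    ``H = b * ln(K - x0)``; individual keypress data fit this form readily.
    A power law ``H = a * K**b`` is the fallback when the log fit cannot be
    produced (and may be requested directly with ``form="power"``).

    Returns a dict with ``offset`` (x0; NaN for the power form),
    ``curvature`` (b), ``form`` actually used, and ``fit_ok``.  On the
    avoidance limb, curvature is the loss-resilience feature and the offset
    is the negative offset.  Requires >= 3 points with distinct K.
    """
    pts = np.asarray(points, dtype=float)
    res = {"offset": np.nan, "curvature": np.nan, "form": form, "fit_ok": False,
           "valence": valence}
    if pts.ndim != 2 or pts.shape[0] < 3:
        return res
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] < 3 or np.unique(pts[:, 0]).size < 3:
        return res
    K, H = pts[:, 0], pts[:, 1]

    if form == "log":
        # Offset must keep every K - x0 positive; profile the SSE over x0
        # with b solved in closed form, seed from a coarse grid, then polish.
        hi = K.min() - 1e-9
        span = max(K.max() - K.min(), 1.0)
        lo = K.min() - 10.0 * span
        grid = np.linspace(lo, hi - 1e-12, 400)
        sses = np.array([_log_sse(x, K, H)[0] for x in grid])
        if not np.any(np.isfinite(sses)):
            return fit_value_function(points, valence, form="power")
        x_best = float(grid[int(np.argmin(sses))])
        w = (hi - lo) / 399.0
        opt = minimize_scalar(
            lambda x: _log_sse(x, K, H)[0],
            bounds=(max(lo, x_best - 2 * w), min(hi, x_best + 2 * w)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        x0 = float(opt.x) if opt.success else x_best
        sse, b = _log_sse(x0, K, H)
        if not math.isfinite(sse):
            return fit_value_function(points, valence, form="power")
        res.update(offset=x0, curvature=b, fit_ok=True)
        return res

    if form == "power":
        ok = (K > 0) & (H > 0)
        if ok.sum() < 3:
            return res
        lx, ly = np.log(K[ok]), np.log(H[ok])
        b, la = np.polyfit(lx, ly, 1)
        res.update(offset=np.nan, curvature=float(b), fit_ok=True,
                   amplitude=float(np.exp(la)))
        return res

    raise ValueError(f"unknown value-function form: {form!r}")


def fit_limit_function(points, valence: str = "dec") -> dict:
    """Fit the quadratic limit function sigma = a*K^2 + b*K + c.

    Returns vertex location (``turning_point`` = -b/2a), vertex height
    (``apex`` = c - b^2/4a), and the area bounded by the K axis
    (``quad_area`` = (b^2-4ac)^(3/2) / (6 a^2)), defined only when the
    parabola crosses the axis (positive discriminant).  ``fit_ok`` is False
    when the fit is under-determined, the quadratic term vanishes, or the
    discriminant is non-positive — the limit features then cannot be
    produced for this participant.
    """
    pts = np.asarray(points, dtype=float)
    res = {"apex": np.nan, "turning_point": np.nan, "quad_area": np.nan,
           "coeffs": None, "fit_ok": False, "valence": valence}
    if pts.ndim != 2 or pts.shape[0] < 3:
        return res
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.shape[0] < 3 or np.unique(pts[:, 0]).size < 3:
        return res
    a, b, c = np.polyfit(pts[:, 0], pts[:, 1], 2)
    res["coeffs"] = (float(a), float(b), float(c))
    if abs(a) < _FIT_TOL:
        return res
    tp = -b / (2.0 * a)
    apex = c - b * b / (4.0 * a)
    disc = b * b - 4.0 * a * c
    res.update(turning_point=float(tp), apex=float(apex))
    if disc <= 0:
        return res
    res.update(quad_area=float(disc ** 1.5 / (6.0 * a * a)), fit_ok=True)
    return res


def tradeoff_features(points) -> dict:
    """Polar summary of the per-category (H+, H-) trade-off points.

    Each category contributes r = sqrt(H+^2 + H-^2) (bits) and
    theta = arctan(H-/H+) measured from the H+ axis in degrees (90 deg when
    H+ = 0; a category with both entropies zero is undefined and skipped).
    Returns the across-category arithmetic means and sample (n-1) standard
    deviations; the dispersions are 0 when a single category is usable and
    everything is NaN with ``fit_ok=False`` when none is.
    """
    pts = np.asarray(points, dtype=float)
    res = {"theta": np.nan, "sigma_theta": np.nan, "r": np.nan,
           "sigma_r": np.nan, "fit_ok": False}
    if pts.ndim != 2 or pts.shape[0] == 0:
        return res
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    pts = pts[~np.all(pts == 0, axis=1)]
    if pts.shape[0] == 0:
        return res
    hp, hm = pts[:, 0], pts[:, 1]
    r = np.hypot(hp, hm)
    theta = np.degrees(np.arctan2(hm, hp))
    res.update(
        theta=float(theta.mean()),
        r=float(r.mean()),
        sigma_theta=float(theta.std(ddof=1)) if theta.size > 1 else 0.0,
        sigma_r=float(r.std(ddof=1)) if r.size > 1 else 0.0,
        fit_ok=True,
    )
    return res


def assemble_profile(
    responses: pd.DataFrame,
    *,
    include_zeros: bool = False,
    value_form: str = "log",
) -> RPTProfile:
    """Compute the full 15-metric profile for one participant.

    The six base variables are across-category means of the per-category
    statistics.  The five negative-limb features come from the avoidance
    value and limit fits; the four trade-off features from the per-category
    (H+, H-) points.  A profile is flagged invalid, with a reason code, as
    soon as a required fit cannot be produced; its computable metrics are
    still reported.
    """
    stats = category_stats(responses, include_zeros=include_zeros)
    pid = stats[0].participant_id
    prof = RPTProfile(participant_id=pid)

    by_val: dict[str, list[CategoryStats]] = {"inc": [], "dec": []}
    for s in stats:
        by_val.setdefault(s.valence, []).append(s)

    def _mean(vals):
        vals = [v for v in vals if math.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    prof.mean_k_inc = _mean([s.K for s in by_val["inc"]])
    prof.mean_k_dec = _mean([s.K for s in by_val["dec"]])
    prof.mean_h_inc = _mean([s.H for s in by_val["inc"]])
    prof.mean_h_dec = _mean([s.H for s in by_val["dec"]])
    prof.mean_std_inc = _mean([s.sigma for s in by_val["inc"]])
    prof.mean_std_dec = _mean([s.sigma for s in by_val["dec"]])

    dec = [s for s in by_val["dec"] if math.isfinite(s.K)]
    kh = [(s.K, s.H) for s in dec if math.isfinite(s.H)]
    ks = [(s.K, s.sigma) for s in dec if math.isfinite(s.sigma)]

    vfit = fit_value_function(kh, "dec", form=value_form)
    if vfit["fit_ok"]:
        prof.loss_resilience = vfit["curvature"]
        prof.negative_offset = vfit["offset"]
    else:
        prof.valid = False
        prof.exclusion_reason = REASON_VALUE_FIT

    lfit = fit_limit_function(ks, "dec")
    prof.negative_apex = lfit["apex"]
    prof.negative_turning_point = lfit["turning_point"]
    prof.negative_area = lfit["quad_area"]
    if not lfit["fit_ok"] and prof.valid:
        prof.valid = False
        prof.exclusion_reason = REASON_LIMIT_FIT

    inc_h = {s.category: s.H for s in by_val["inc"]}
    dec_h = {s.category: s.H for s in by_val["dec"]}
    cats = sorted(set(inc_h) | set(dec_h))
    hh = [(inc_h.get(c, np.nan), dec_h.get(c, np.nan)) for c in cats]
    tfit = tradeoff_features(hh)
    prof.polar_angle = tfit["theta"]
    prof.polar_dispersion = tfit["sigma_theta"]
    prof.radial_distance = tfit["r"]
    prof.radial_dispersion = tfit["sigma_r"]
    if not tfit["fit_ok"] and prof.valid:
        prof.valid = False
        prof.exclusion_reason = REASON_TRADEOFF

    return prof


def profiles_from_responses(
    responses: pd.DataFrame,
    *,
    include_zeros: bool = False,
    value_form: str = "log",
) -> pd.DataFrame:
    """Profile every participant in a response table.

    Returns one row per participant with the 15 metric columns (named as in
    :data:`rptfusion.labels.METRICS`), plus ``valid`` and
    ``exclusion_reason``.
    """
    rows = []
    for _, grp in responses.groupby("participant_id", sort=True):
        prof = assemble_profile(
            grp, include_zeros=include_zeros, value_form=value_form
        )
        rows.append(prof.as_dict())
    df = pd.DataFrame(rows)
    cols = ["participant_id", *METRICS, "valid", "exclusion_reason"]
    return df[cols]
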