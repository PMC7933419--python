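"""Normalization, ROI summaries, and moderated differential expression.

The statistical unit is the biological sample: per-pixel intensities are
MSTUS-normalized and log2-transformed, then averaged over a region of
interest (ROI) to give one value per (sample, feature).  Group
comparisons (control vs ischemic, per timepoint) use an empirical-Bayes
moderated t-statistic: per-feature residual variances are shrunk toward
a prior estimated by matching the moments of their log to a scaled-F
distribution, which stabilizes inference at five samples per group.
P-values are adjusted by the Benjamini-Hochberg step-up procedure within
each timepoint's feature family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .iodata import StudyDesign
from .peakflow import FeatureMatrix

logger = logging.getLogger(__name__)

#: Prior degrees of freedom are capped here; beyond this the moderated
#: statistic is numerically indistinguishable from a shared-variance z.
D0_CAP = 1e6


@dataclass
class ROI:
    """A named set of pixels, applied identically to each sample's grid."""

    name: str
    pixels: set[tuple[int, int]]  # (x, y)

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError(f"ROI {self.name!r} is empty")


@dataclass
class DEResult:
    """Per-feature moderated-t differential expression, one contrast."""

    table: pd.DataFrame  # mz, mean_log2_control, mean_log2_ischemic, log2FC,
    #                      s2, s2_post, t_mod, df_total, p, q
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance
    n_control: int
    n_ischemic: int


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def mstus_normalize(
    matrix: FeatureMatrix, shared: Optional[np.ndarray] = None
) -> FeatureMatrix:
    """MS "total useful signal" normalization of one sample's matrix.

    Each tissue pixel's row is rescaled so that its summed intensity over
    the shared feature set equals the tissue-wide mean of those sums;
    off-tissue pixels are left untouched.  ``shared`` is a boolean mask
    over features (default: all features — in the pipeline the shared set
    is the post-filter feature list).
    """
    values = matrix.values.copy()
    tissue = matrix.tissue_rows()
    if shared is None:
        shared = np.ones(len(matrix.features), dtype=bool)
    sums = values[:, shared].sum(axis=1)
    if not tissue.any():
        return replace(matrix, values=values)
    target = sums[tissue].mean()
    ok = tissue & (sums > 0)
    skipped = int(tissue.sum() - ok.sum())
    if skipped:
        logger.warning("mstus_normalize: %d tissue pixels with zero shared signal left unscaled", skipped)
    values[ok] *= (target / sums[ok])[:, None]
    return replace(matrix, values=values)


def impute_zeros(matrix: FeatureMatrix, factor: float = 0.2) -> FeatureMatrix:
    """Replace zero intensities on tissue pixels by a per-feature floor.

    Zeros in centroided imaging data are detection failures, not true
    absences; left in place they become extreme outliers after a log
    transform and dominate distance-based analyses such as clustering.
    Each zero on a tissue pixel is replaced by ``factor`` times the
    smallest positive intensity observed for that feature on tissue
    (``factor=0.2``, i.e. one fifth of the per-feature minimum, the
    convention popularized by MetaboAnalyst).  Features never detected on
    tissue, and all off-tissue pixels, are left unchanged.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    values = matrix.values.copy()
    tissue = matrix.tissue_rows()
    if not tissue.any():
        return replace(matrix, values=values)
    sub = values[tissue]
    pos = np.where(sub > 0, sub, np.inf)
    floor = pos.min(axis=0)  # per-feature minimum positive intensity
    detected = np.isfinite(floor)
    fill = np.where(detected, factor * np.where(detected, floor, 0.0), 0.0)
    sub = np.where(sub == 0, fill[None, :], sub)
    values[tissue] = sub
    return replace(matrix, values=values)


def log2_transform(matrix: FeatureMatrix, offset: float = 1.0) -> FeatureMatrix:
    """Elementwise ``log2(value + offset)``; offset 1 maps zeros to zero."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if np.any(matrix.values < 0):
        raise ValueError("negative intensities cannot be log-transformed")
    return replace(matrix, values=np.log2(matrix.values + offset))


# ---------------------------------------------------------------------------
# ROI summaries
# ---------------------------------------------------------------------------

def extract_roi_means(
    matrices: Sequence[FeatureMatrix], roi: ROI
) -> pd.DataFrame:
    """Per-sample mean over ROI pixels for each feature.

    Returns a samples x features DataFrame (index sample_id, columns the
    feature m/z values).  Input matrices are expected to be normalized
    and log2-transformed already.
    """
    out = {}
    for m in matrices:
        rows, cols = m.grid_shape
        for x, y in roi.pixels:
            if not (0 <= x < cols and 0 <= y < rows):
                raise ValueError(
                    f"ROI {roi.name!r} pixel ({x},{y}) outside grid {cols}x{rows}"
                )
        index = {pix: i for i, pix in enumerate(m.pixels)}
        try:
            sel = [index[pix] for pix in sorted(roi.pixels)]
        except KeyError as exc:
            raise ValueError(f"ROI pixel {exc} absent from sample {m.sample_id}") from exc
        out[m.sample_id] = m.values[sel].mean(axis=0)
    df = pd.DataFrame.from_dict(out, orient="index")
    df.columns = matrices[0].features.mz
    return df


def summarize_by_condition(
    roi_means: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Mean and SD across samples per (group, timepoint, feature)."""
    meta = design.to_frame().set_index("sample_id")
    df = roi_means.join(meta[["group", "timepoint"]])
    grouped = df.groupby(["group", "timepoint"], observed=True)
    mean = grouped.mean(numeric_only=True)
    sd = grouped.std(numeric_only=True, ddof=1)
    n = grouped.size()
    long = pd.concat(
        {"mean": mean.stack(), "sd": sd.stack()}, axis=1
    ).reset_index()
    long.columns = ["group", "timepoint", "mz", "mean", "sd"]
    long["n"] = long.apply(lambda r: n[(r.group, r.timepoint)], axis=1)
    return long


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by monotone bisection/Newton."""
    if x <= 0:
        return np.inf
    # trigamma is strictly decreasing from +inf to 0 on (0, inf)
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, hi) > x:
        return hi
    if special.polygamma(1, lo) < x:
        return lo
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    return float(np.sqrt(lo * hi))


def estimate_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for per-feature variances.

    Assuming s2_g ~ s0^2 * F(df, d0), the mean and variance of log s2_g
    determine (d0, s0^2) through digamma/trigamma identities; the excess
    of the observed variance of log s2 over trigamma(df/2) identifies d0,
    and the mean identifies s0^2.  Zero variances are excluded from the
    moment fit.  d0 is capped at 1e6 (effectively infinite shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return D0_CAP, float(pos.mean()) if pos.size else 1.0
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        d0 = D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(resid), D0_CAP)
    s0_sq = float(np.exp(
        e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )) if d0 < D0_CAP else float(np.exp(e_mean))
    return float(d0), s0_sq


def fit_moderated_de(
    roi_means: pd.DataFrame,
    design: StudyDesign,
    prior_df: Optional[float] = None,
    prior_var: Optional[float] = None,
) -> DEResult:
    """Two-group moderated-t differential expression on ROI sample means.

    ``roi_means`` is samples x features (log2 scale).  The contrast is
    ischemic minus control.  Per-feature pooled variances ``s2`` with
    ``n1+n2-2`` degrees of freedom are moderated toward the empirical
    prior: ``s2_post = (d0*s0^2 + dg*s2) / (d0 + dg)``; the moderated t
    is ``log2FC / sqrt(s2_post * (1/n1 + 1/n2))`` on ``d0 + dg`` degrees
    of freedom.  Pass ``prior_df``/``prior_var`` to override the fit
    (e.g. ``prior_df -> 0`` recovers the ordinary pooled t).
    """
    meta = design.to_frame().set_index("sample_id")
    samples = [s for s in roi_means.index if s in meta.index]
    groups = meta.loc[samples, "group"].to_numpy()
    X = roi_means.loc[samples].to_numpy(dtype=float)
    ctrl, isch = X[groups == "control"], X[groups == "ischemic"]
    n1, n2 = ctrl.shape[0], isch.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} control / {n2} ischemic")

    mean_c, mean_i = ctrl.mean(axis=0), isch.mean(axis=0)
    log2fc = mean_i - mean_c
    dg = n1 + n2 - 2
    s2 = (ctrl.var(axis=0, ddof=1) * (n1 - 1) + isch.var(axis=0, ddof=1) * (n2 - 1)) / dg

    if prior_df is None or prior_var is None:
        d0, s0_sq = estimate_f_prior(s2, dg)
        if prior_df is not None:
            d0 = prior_df
        if prior_var is not None:
            s0_sq = prior_var
    else:
        d0, s0_sq = prior_df, prior_var
    d0 = min(max(d0, 0.0), D0_CAP)

    s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    df_total = d0 + dg
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = bh_adjust(p)

    table = pd.DataFrame({
        "mz": np.asarray(roi_means.columns, dtype=float),
        "mean_log2_control": mean_c,
        "mean_log2_ischemic": mean_i,
        "log2FC": log2fc,
        "s2": s2,
        "s2_post": s2_post,
        "t_mod": t_mod,
        "df_total": df_total,
        "p": p,
        "q": q,
    })
    return DEResult(table=table, d0=float(d0), s0_sq=float(s0_sq), n_control=n1, n_ischemic=n2)


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped
    at 1; monotone non-decreasing in p.
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def volcano_table(de: DEResult, fdr: float = 0.05, fc: float = 1.5) -> pd.DataFrame:
    """Classify features for a volcano plot: up / down / ns.

    A feature is "up" iff q < ``fdr`` and log2FC >= log2(``fc``); "down"
    iff q < ``fdr`` and log2FC <= -log2(``fc``); otherwise "ns".
    """
    gate = np.log2(fc)
    t = de.table
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(t["p"].to_numpy())
    status = np.where(
        (t["q"] < fdr) & (t["log2FC"] >= gate), "up",
        np.where((t["q"] < fdr) & (t["log2FC"] <= -gate), "down", "ns"),
    )
    return pd.DataFrame({
        "mz": t["mz"],
        "log2FC": t["log2FC"],
        "neg_log10_p": neglogp,
        "q": t["q"],
        "status": status,
    })


#: Significance-star thresholds on the adjusted p-value (q).
STAR_THRESHOLDS = ((0.0005, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(q: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if q < thr:
            return stars
    return ""


def temporal_profile(
    summaries: Mapping[str, pd.DataFrame],
    de_results: Mapping[str, DEResult],
    mz: float,
    timepoints: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-timepoint mean +/- SD of one feature with significance stars.

    ``summaries`` maps timepoint -> output of :func:`summarize_by_condition`;
    ``de_results`` maps timepoint -> :class:`DEResult`.  Missing timepoints
    are left as gaps (omitted rows), never interpolated.
    """
    tps = list(timepoints) if timepoints is not None else list(summaries)
    rows = []
    for tp in tps:
        if tp not in summaries or tp not in de_results:
            continue
        summ = summaries[tp]
        det = de_results[tp].table
        idx = (det["mz"] - mz).abs().idxmin()
        if abs(det.loc[idx, "mz"] - mz) / mz > 1e-6:
            raise KeyError(f"feature m/z {mz} not present at timepoint {tp}")
        qv = float(det.loc[idx, "q"])
        for grp in ("control", "ischemic"):
            sel = summ[
                (summ["group"] == grp)
                & (summ["timepoint"] == tp)
                & (np.isclose(summ["mz"].astype(float), det.loc[idx, "mz"]))
            ]
            if sel.empty:
                continue
            rows.append({
                "timepoint": tp,
                "group": grp,
                "mean": float(sel["mean"].iloc[0]),
                "sd": float(sel["sd"].iloc[0]),
                "q": qv,
                "stars": significance_stars(qv),
            })
    return pd.DataFrame(rows)
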