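"""Synthetic imaging-MS phantoms with a planted ischemic region.

The phantom emulates a transverse ventricular heart section: an annulus
of tissue (the myocardial wall around the lumen) on a rectangular pixel
grid, with a contiguous angular wedge of the annulus designated as the
ischemic sector.  Each pixel carries a centroid spectrum over a fixed set
of feature m/z values; intensities follow a log-normal model with

* per-feature baseline log-mean and log-sd,
* a per-(sample, feature) biological replicate effect shared by all of a
  sample's pixels,
* a per-pixel multiplicative total-ion-current drift factor,
* per-cell multiplicative log-scale noise,
* a planted fold change ``2**(log2fc * effect(timepoint))`` applied to
  differential features inside the ischemic sector of ischemic samples,
  with the effect multiplier growing monotonically with nominal ischemia
  duration,
* ppm-scale mass jitter per observed peak and random feature dropout,
* off-tissue pixels carrying only low-level matrix (background) noise.

Every random quantity derives deterministically from the spec seed; the
per-sample stream is seeded from (spec seed, sample id) so cohorts are
reproducible sample by sample.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .iodata import ImagingDataset, PixelSpectrum, StudyDesign
from .peakflow import FeatureList, FeatureMatrix

#: Effect multipliers by nominal ischemia duration.  Chosen monotone so a
#: 15-minute occlusion already shows roughly half the asymptotic change.
DEFAULT_TIMEPOINT_EFFECTS = {
    "15min": 0.5,
    "30min": 0.65,
    "1h": 0.8,
    "2h": 0.9,
    "4h": 1.0,
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic heart-section phantom.

    Geometry is an annulus (outer/inner radius as fractions of the short
    grid side) with an angular ischemic wedge; ``radial_fraction`` < 1
    restricts the wedge to the outer part of the wall.
    """

    grid: tuple[int, int] = (60, 60)  # (rows, cols)
    outer_radius_frac: float = 0.42
    inner_radius_frac: float = 0.15
    sector_deg: tuple[float, float] = (-60.0, 60.0)
    radial_fraction: float = 1.0
    n_features: int = 800
    timepoints: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINT_EFFECTS)
    )
    n_de_up: int = 40
    n_de_down: int = 40
    log2fc_range: tuple[float, float] = (1.0, 2.0)
    baseline_log_mean_loc: float = 11.5  # natural-log scale; exp(11.5) ~ 1e5 counts
    baseline_log_mean_scale: float = 1.0
    baseline_log_sd: float = 0.2
    sample_effect_sd: float = 0.2  # between-replicate biological variation (log scale)
    pixel_noise_sd: float = 0.5
    tic_drift_sd: float = 0.3
    mass_jitter_ppm: float = 3.0
    dropout_rate: float = 0.05
    matrix_feature_frac: float = 0.1  # fraction of channels that are matrix ions
    matrix_log_mean: float = 6.0  # matrix-ion background level, exp(6) ~ 400 counts
    matrix_log_sd: float = 0.5
    mz_range: tuple[float, float] = (100.0, 2000.0)
    min_mz_gap: float = 0.2
    metabolite_mz: Optional[Sequence[float]] = None
    prioritize_pinned_de: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_log_sd",
            "sample_effect_sd",
            "pixel_noise_sd",
            "tic_drift_sd",
            "mass_jitter_ppm",
            "matrix_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.matrix_feature_frac <= 1:
            raise ValueError("matrix_feature_frac must be in [0, 1]")
        if not 0 < self.inner_radius_frac < self.outer_radius_frac <= 0.5:
            raise ValueError("need 0 < inner_radius_frac < outer_radius_frac <= 0.5")
        if not 0 < self.radial_fraction <= 1:
            raise ValueError("radial_fraction must be in (0, 1]")
        effects = list(self.timepoints.values())
        if any(b < a for a, b in zip(effects, effects[1:])):
            raise ValueError("timepoint effect multipliers must be non-decreasing")
        if self.n_de_up + self.n_de_down > self.n_features:
            raise ValueError("more planted DE features than features")


@dataclass
class GroundTruth:
    """What was planted: masks and the per-feature effect table."""

    tissue_mask: np.ndarray  # [rows, cols] bool
    ischemic_mask: np.ndarray  # [rows, cols] bool
    de_table: pd.DataFrame  # feature, mz, direction, log2fc, log2fc_<tp>...


@dataclass
class PhantomModel:
    """Cohort-invariant quantities derived deterministically from the spec."""

    mz: np.ndarray
    baseline_log_mean: np.ndarray
    de_index: np.ndarray  # indices of planted DE features
    de_log2fc: np.ndarray  # signed log2 fold changes, aligned with de_index
    pinned_index: np.ndarray  # features pinned at metabolite m/z values
    matrix_index: np.ndarray  # channels carrying matrix (background) ions


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _polar(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = spec.grid
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.hypot(xx - cx, yy - cy)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))
    return r, theta


def tissue_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean annulus mask of on-tissue pixels."""
    r, _ = _polar(spec)
    short = min(spec.grid)
    return (r >= spec.inner_radius_frac * short) & (r <= spec.outer_radius_frac * short)


def ischemic_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the planted ischemic wedge (subset of tissue)."""
    r, theta = _polar(spec)
    short = min(spec.grid)
    outer = spec.outer_radius_frac * short
    inner = spec.inner_radius_frac * short
    wedge_inner = inner + (1.0 - spec.radial_fraction) * (outer - inner)
    a0, a1 = spec.sector_deg
    span = (a1 - a0) % 360.0
    in_angle = ((theta - a0) % 360.0) <= span
    return tissue_mask(spec) & in_angle & (r >= wedge_inner)


def sector_area_fraction(spec: PhantomSpec) -> float:
    """Analytic area of the ischemic wedge as a fraction of the grid."""
    short = min(spec.grid)
    outer = spec.outer_radius_frac * short
    inner = spec.inner_radius_frac * short
    wedge_inner = inner + (1.0 - spec.radial_fraction) * (outer - inner)
    span = np.radians((spec.sector_deg[1] - spec.sector_deg[0]) % 360.0)
    area = 0.5 * span * (outer**2 - wedge_inner**2)
    return float(area / (spec.grid[0] * spec.grid[1]))


def default_rois(spec: PhantomSpec) -> dict[str, set[tuple[int, int]]]:
    """Two regions of interest on the phantom geometry.

    ``ROI1_ischemic`` is the planted wedge; ``ROI2_remote`` is the
    diametrically opposite wedge of the wall (the septum analogue,
    presumed non-ischemic).
    """
    isch = ischemic_mask(spec)
    r, theta = _polar(spec)
    short = min(spec.grid)
    outer = spec.outer_radius_frac * short
    inner = spec.inner_radius_frac * short
    wedge_inner = inner + (1.0 - spec.radial_fraction) * (outer - inner)
    a0, a1 = spec.sector_deg[0] + 180.0, spec.sector_deg[1] + 180.0
    span = (a1 - a0) % 360.0
    remote = (
        tissue_mask(spec)
        & (((theta - a0) % 360.0) <= span)
        & (r >= wedge_inner)
    )
    to_set = lambda m: {(int(x), int(y)) for y, x in zip(*np.nonzero(m))}
    return {"ROI1_ischemic": to_set(isch), "ROI2_remote": to_set(remote)}


# ---------------------------------------------------------------------------
# Cohort-invariant model
# ---------------------------------------------------------------------------

def _sample_seed(spec_seed: int, sample_id: str) -> int:
    digest = hashlib.blake2b(
        f"{spec_seed}:{sample_id}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big")


def build_model(spec: PhantomSpec) -> PhantomModel:
    """Derive the cohort-invariant feature model from the spec seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 101]))
    lo, hi = spec.mz_range
    gap = spec.min_mz_gap

    pinned = np.sort(np.asarray(
        [m for m in (spec.metabolite_mz or []) if lo < m < hi], dtype=float
    ))
    n_random = spec.n_features - pinned.size
    if n_random < 0:
        raise ValueError("more pinned metabolite m/z values than features")
    # sorted uniforms with a guaranteed minimum gap
    raw = np.sort(rng.uniform(lo, hi - n_random * gap, n_random))
    raw = raw + np.arange(n_random) * gap
    if pinned.size:
        # discard random positions colliding with pinned metabolite masses
        idx = np.searchsorted(pinned, raw)
        near = np.minimum(
            np.abs(raw - pinned[np.clip(idx - 1, 0, pinned.size - 1)]),
            np.abs(raw - pinned[np.clip(idx, 0, pinned.size - 1)]),
        )
        raw = raw[near > gap]
    mz = np.sort(np.concatenate([raw, pinned]))
    n = mz.size
    pinned_index = np.searchsorted(mz, pinned)

    baseline = rng.normal(spec.baseline_log_mean_loc, spec.baseline_log_mean_scale, n)

    n_up, n_down = spec.n_de_up, spec.n_de_down
    up: list[int] = []
    down: list[int] = []
    if spec.prioritize_pinned_de and pinned_index.size:
        # alternate pinned features into the up/down sets so that planted
        # differential features overlap the annotatable metabolites
        half = pinned_index.size // 2
        up = list(pinned_index[:half][: n_up])
        down = list(pinned_index[half:][: n_down])
    pool = np.setdiff1d(np.arange(n), np.asarray(up + down, dtype=int))
    need_up, need_down = n_up - len(up), n_down - len(down)
    extra = rng.choice(pool, size=need_up + need_down, replace=False)
    up = np.asarray(up + list(extra[:need_up]), dtype=int)
    down = np.asarray(down + list(extra[need_up:]), dtype=int)

    mag_lo, mag_hi = spec.log2fc_range
    fc = np.concatenate([
        rng.uniform(mag_lo, mag_hi, up.size),
        -rng.uniform(mag_lo, mag_hi, down.size),
    ])
    de_index = np.concatenate([up, down])

    # matrix (MALDI chemical background) ions live in a fixed subset of
    # channels, disjoint from pinned metabolites and planted effects
    n_matrix = int(round(spec.matrix_feature_frac * n))
    matrix_pool = np.setdiff1d(
        np.arange(n), np.concatenate([de_index, pinned_index]).astype(int)
    )
    n_matrix = min(n_matrix, matrix_pool.size)
    matrix_index = np.sort(rng.choice(matrix_pool, size=n_matrix, replace=False))

    return PhantomModel(
        mz=mz,
        baseline_log_mean=baseline,
        de_index=de_index,
        de_log2fc=fc,
        pinned_index=pinned_index,
        matrix_index=matrix_index,
    )


def ground_truth(spec: PhantomSpec, model: Optional[PhantomModel] = None) -> GroundTruth:
    model = model or build_model(spec)
    rows = {
        "feature": model.de_index,
        "mz": model.mz[model.de_index],
        "direction": np.where(model.de_log2fc > 0, "up", "down"),
        "log2fc": model.de_log2fc,
    }
    df = pd.DataFrame(rows).sort_values("feature").reset_index(drop=True)
    for tp, eff in spec.timepoints.items():
        df[f"log2fc_{tp}"] = df["log2fc"] * eff
    return GroundTruth(
        tissue_mask=tissue_mask(spec), ischemic_mask=ischemic_mask(spec), de_table=df
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _resolve_effect(
    spec: PhantomSpec, group: str, timepoint: str, effect: Optional[float]
) -> float:
    if group == "control":
        if effect is not None and effect != 0:
            warnings.warn("control group: requested nonzero effect ignored")
        return 0.0
    if effect is not None:
        return effect
    if timepoint not in spec.timepoints:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; spec defines {list(spec.timepoints)}"
        )
    return spec.timepoints[timepoint]


def _intensity_matrix(
    spec: PhantomSpec,
    model: PhantomModel,
    rng: np.random.Generator,
    group: str,
    eff: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel feature intensities; returns (values, tissue_flat, isch_flat)."""
    rows, cols = spec.grid
    npix, nf = rows * cols, model.mz.size
    tmask = tissue_mask(spec).ravel()
    imask = ischemic_mask(spec).ravel()

    # biological replicate effect: one multiplicative factor per feature for
    # the whole sample, shared by all of its pixels
    sample_shift = (
        rng.normal(0.0, spec.sample_effect_sd, nf)
        if spec.sample_effect_sd > 0
        else np.zeros(nf)
    )
    log_int = rng.normal(
        model.baseline_log_mean[None, :] + sample_shift[None, :],
        spec.baseline_log_sd,
        size=(npix, nf),
    )
    values = np.exp(log_int)
    tic = np.exp(rng.normal(0.0, spec.tic_drift_sd, npix))
    values *= tic[:, None]
    if group == "ischemic" and eff != 0.0:
        fold = np.ones(nf)
        fold[model.de_index] = 2.0 ** (model.de_log2fc * eff)
        values[imask] *= fold[None, :]
    if spec.pixel_noise_sd > 0:
        values *= np.exp(rng.normal(0.0, spec.pixel_noise_sd, size=(npix, nf)))
    if spec.dropout_rate > 0:
        values[rng.random((npix, nf)) < spec.dropout_rate] = 0.0

    # matrix is sprayed over the whole slide: matrix-ion channels carry a
    # stable background layer everywhere; all other channels are zero off
    # tissue ("only low-level matrix noise" outside the section)
    off = ~tmask
    values[off] = 0.0
    mi = model.matrix_index
    if mi.size:
        mat = np.exp(
            rng.normal(spec.matrix_log_mean, spec.matrix_log_sd, (npix, mi.size))
        )
        if spec.dropout_rate > 0:
            mat[rng.random(mat.shape) < spec.dropout_rate] = 0.0
        values[:, mi] += mat
    return values, tmask, imask


def generate_phantom_matrix(
    spec: PhantomSpec,
    sample_id: str,
    group: str = "control",
    timepoint: str = "none",
    effect: Optional[float] = None,
    model: Optional[PhantomModel] = None,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Generate one sample directly as a pixels x features matrix.

    This skips the per-pixel spectrum representation (and hence mass
    jitter), which makes large simulation studies of the statistical
    stages cheap; :func:`generate_phantom` is the full spectrum-level
    generator.
    """
    model = model or build_model(spec)
    eff = _resolve_effect(spec, group, timepoint, effect)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, _sample_seed(spec.seed, sample_id)])
    )
    values, tmask, _ = _intensity_matrix(spec, model, rng, group, eff)
    rows, cols = spec.grid
    pixels = [(x, y) for y in range(rows) for x in range(cols)]
    fm = FeatureMatrix(
        sample_id=sample_id,
        pixels=pixels,
        features=FeatureList(model.mz, np.ones(model.mz.size)),
        values=values,
        tissue=tmask,
        group=group,
        timepoint=timepoint,
    )
    return fm, ground_truth(spec, model)


def generate_phantom(
    spec: PhantomSpec,
    sample_id: str,
    group: str = "control",
    timepoint: str = "none",
    effect: Optional[float] = None,
    model: Optional[PhantomModel] = None,
) -> tuple[ImagingDataset, GroundTruth]:
    """Generate one sample as a full imaging dataset of centroid spectra.

    Observed peak m/z values carry per-pixel Gaussian mass jitter of scale
    ``mass_jitter_ppm``; dropped-out features are absent from the pixel's
    spectrum entirely.
    """
    model = model or build_model(spec)
    eff = _resolve_effect(spec, group, timepoint, effect)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, _sample_seed(spec.seed, sample_id)])
    )
    values, tmask, _ = _intensity_matrix(spec, model, rng, group, eff)
    rows, cols = spec.grid
    npix, nf = values.shape
    if spec.mass_jitter_ppm > 0:
        jitter = rng.normal(0.0, spec.mass_jitter_ppm * 1e-6, size=(npix, nf))
        mz_obs = model.mz[None, :] * (1.0 + jitter)
    else:
        mz_obs = np.broadcast_to(model.mz, (npix, nf))
    lo, hi = spec.mz_range
    mz_obs = np.clip(mz_obs, lo, hi)

    pixels: list[PixelSpectrum] = []
    i = 0
    for y in range(rows):
        for x in range(cols):
            keep = values[i] > 0
            m, v = mz_obs[i, keep], values[i, keep]
            order = np.argsort(m, kind="stable")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # clipped boundary duplicates
                pixels.append(PixelSpectrum(x=x, y=y, mz=m[order], intensity=v[order]))
            i += 1
    ds = ImagingDataset(
        sample_id=sample_id,
        group=group,
        timepoint=timepoint,
        pixels=pixels,
        tissue_mask=tissue_mask(spec),
        mz_range=spec.mz_range,
    )
    return ds, ground_truth(spec, model)


def generate_cohort(
    spec: PhantomSpec,
    design: StudyDesign,
    as_matrix: bool = False,
) -> list[tuple[object, GroundTruth]]:
    """Generate one dataset per design row, deterministically per sample."""
    model = build_model(spec)
    out = []
    gen = generate_phantom_matrix if as_matrix else generate_phantom
    for sample_id, group, tp, _rep in design.samples:
        if group == "ischemic" and tp not in spec.timepoints:
            raise ValueError(f"design references unknown timepoint {tp!r}")
        out.append(gen(spec, sample_id, group, tp, model=model))
    return out


def make_design(
    timepoints: Sequence[str], n_per_cell: int = 5
) -> StudyDesign:
    """Standard cohort layout: n controls + n ischemic samples per timepoint."""
    rows = []
    for tp in timepoints:
        for i in range(1, n_per_cell + 1):
            rows.append((f"ctrl_{tp}_{i}", "control", tp, i))
        for i in range(1, n_per_cell + 1):
            rows.append((f"isch_{tp}_{i}", "ischemic", tp, i))
    return StudyDesign(samples=rows, n_per_cell=n_per_cell)
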