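"""Consensus feature-list construction and the feature-filter cascade.

Per-pixel centroid spectra are reduced to a single study-wide list of
consensus m/z features in four steps:

1. :func:`pick_peaks` — per-pixel local-maximum picking with an SNR gate,
   where noise is estimated as 1.4826 x the median absolute deviation of
   the spectrum's intensities.
2. :func:`build_consensus_mzlist` — single-linkage grouping of all picked
   peaks within a fixed Da tolerance; groups seen in at least a minimum
   fraction of pixels are kept, at their intensity-weighted mean m/z.
3. :func:`merge_duplicate_mz` — neighbouring consensus m/z within a ppm
   window are averaged to absorb residual mass shifts.
4. :func:`extract_feature_matrix` / :func:`filter_features` — per-pixel
   intensity extraction in a ppm window around each feature, then the
   three-criterion retention filter (pixel prevalence, per-group sample
   support, minimum abundance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .iodata import ImagingDataset, PixelSpectrum, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class PeakList:
    """Peaks picked from one pixel's spectrum."""

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class FeatureList:
    """Consensus m/z values with per-feature peak-count provenance."""

    mz: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("FeatureList m/z must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size

    def subset(self, mask: np.ndarray) -> "FeatureList":
        return FeatureList(self.mz[mask], self.provenance[mask])


@dataclass
class FeatureMatrix:
    """Pixels x features intensity matrix for one sample.

    ``tissue`` flags, when present, mark which rows are on-tissue pixels;
    prevalence filtering and MSTUS normalization are restricted to those.
    """

    sample_id: str
    pixels: list[tuple[int, int]]  # (x, y)
    features: FeatureList
    values: np.ndarray  # shape (n_pixels, n_features), >= 0
    tissue: Optional[np.ndarray] = None  # bool per pixel
    group: str = "control"
    timepoint: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pixels), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.pixels)} pixels x {len(self.features)} features"
            )
        if np.any(self.values < 0):
            raise ValueError("FeatureMatrix values must be non-negative")
        if self.tissue is not None:
            self.tissue = np.asarray(self.tissue, dtype=bool)
            if self.tissue.shape != (len(self.pixels),):
                raise ValueError("tissue mask length mismatch")

    @property
    def grid_shape(self) -> tuple[int, int]:
        rows = max(y for _x, y in self.pixels) + 1
        cols = max(x for x, _y in self.pixels) + 1
        return rows, cols

    def tissue_rows(self) -> np.ndarray:
        if self.tissue is None:
            return np.ones(len(self.pixels), dtype=bool)
        return self.tissue

    def subset_features(self, mask: np.ndarray) -> "FeatureMatrix":
        return replace(
            self, features=self.features.subset(mask), values=self.values[:, mask]
        )


# ---------------------------------------------------------------------------
# Peak picking
# ---------------------------------------------------------------------------

def mad_noise(intensity: np.ndarray) -> float:
    """Robust noise level: 1.4826 x median absolute deviation."""
    intensity = np.asarray(intensity, dtype=float)
    med = np.median(intensity)
    return float(1.4826 * np.median(np.abs(intensity - med)))


def pick_peaks(
    spectrum: PixelSpectrum, snr_min: float = 3.0, halfwindow: int = 2
) -> PeakList:
    """Pick local maxima with SNR >= ``snr_min`` from one spectrum.

    A point is a peak if its intensity strictly exceeds every other point
    within ``halfwindow`` index positions and its signal-to-noise ratio
    (intensity / MAD-based noise) reaches ``snr_min``.  With
    ``halfwindow=0`` every point passes the locality test, which is the
    right behaviour for already-centroided data where each point is a
    peak in its own right; for such data ``snr_min=0`` disables the SNR
    gate entirely, because the MAD of a centroid list reflects the spread
    of genuine peak heights rather than an instrument noise floor.
    """
    if snr_min < 0:
        raise ValueError("snr_min must be >= 0")
    if halfwindow < 0:
        raise ValueError("halfwindow must be >= 0")
    inten = spectrum.intensity
    n = inten.size
    empty = PeakList(spectrum.x, spectrum.y, np.empty(0), np.empty(0), np.empty(0))
    if n == 0 or not np.any(inten > 0):
        return empty

    noise = mad_noise(inten)
    if noise <= 0:
        # flat-baseline spectra: any positive point is formally infinite SNR
        noise = np.finfo(float).tiny

    if halfwindow == 0:
        is_max = inten > 0
    else:
        is_max = inten > 0
        for off in range(1, halfwindow + 1):
            left = np.empty(n, dtype=bool)
            left[:off] = True
            left[off:] = inten[off:] > inten[:-off]
            right = np.empty(n, dtype=bool)
            right[-off:] = True
            right[:-off] = inten[:-off] > inten[off:]
            is_max &= left & right
    with np.errstate(over="ignore"):
        # flat-baseline spectra give formally infinite SNR; inf is fine here
        snr = inten / noise
    keep = is_max & (snr >= snr_min)
    return PeakList(
        spectrum.x, spectrum.y, spectrum.mz[keep], inten[keep], snr[keep]
    )


# ---------------------------------------------------------------------------
# Consensus list
# ---------------------------------------------------------------------------

def build_consensus_mzlist(
    peaklists: Sequence[PeakList],
    tolerance_da: float = 0.001,
    min_frequency: float = 0.5,
) -> FeatureList:
    """Group peaks across pixels into consensus m/z features.

    Peaks from all pixels are pooled, sorted, and chained by single
    linkage: consecutive peaks closer than ``tolerance_da`` belong to the
    same group.  A group is retained if it contains peaks from at least
    ``min_frequency`` of the non-empty peak lists; its consensus m/z is
    the intensity-weighted mean of its members.  Provenance records the
    number of member peaks.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be > 0")
    if not (0 < min_frequency <= 1):
        raise ValueError("min_frequency must be in (0, 1]")

    nonempty = [pl for pl in peaklists if len(pl) > 0]
    if not nonempty:
        return FeatureList(np.empty(0), np.empty(0))
    n_lists = len(nonempty)

    mz = np.concatenate([pl.mz for pl in nonempty])
    inten = np.concatenate([pl.intensity for pl in nonempty])
    src = np.concatenate(
        [np.full(len(pl), i, dtype=int) for i, pl in enumerate(nonempty)]
    )
    order = np.argsort(mz, kind="stable")
    mz, inten, src = mz[order], inten[order], src[order]

    # single-linkage: a new group starts wherever the gap exceeds tolerance
    breaks = np.flatnonzero(np.diff(mz) > tolerance_da) + 1
    bounds = np.concatenate([[0], breaks, [mz.size]])

    out_mz, out_prov = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        members = src[lo:hi]
        if np.unique(members).size / n_lists >= min_frequency:
            w = inten[lo:hi]
            if w.sum() > 0:
                center = float(np.average(mz[lo:hi], weights=w))
            else:
                center = float(np.mean(mz[lo:hi]))
            out_mz.append(center)
            out_prov.append(hi - lo)
    if not out_mz:
        return FeatureList(np.empty(0), np.empty(0))
    order = np.argsort(out_mz)
    return FeatureList(np.asarray(out_mz)[order], np.asarray(out_prov, float)[order])


def merge_duplicate_mz(fl: FeatureList, merge_ppm: float = 20.0) -> FeatureList:
    """Merge neighbouring features within a ppm window (mass-shift repair).

    Greedy left-to-right: whenever the relative gap from the current
    (running) feature to the next is at most ``merge_ppm`` x 1e-6, the two
    are replaced by their provenance-weighted mean.  Passes repeat until a
    fixed point, so the result has all pairwise gaps strictly above the
    window — applying the operation twice equals applying it once.
    """
    if merge_ppm < 0:
        raise ValueError("merge_ppm must be >= 0")
    mz = fl.mz.copy()
    prov = fl.provenance.copy()
    tol = merge_ppm * 1e-6
    while mz.size > 1:
        new_mz, new_prov = [mz[0]], [prov[0]]
        changed = False
        for m, p in zip(mz[1:], prov[1:]):
            cur = new_mz[-1]
            if (m - cur) / cur <= tol:
                w = new_prov[-1] + p
                new_mz[-1] = (cur * new_prov[-1] + m * p) / w if w > 0 else 0.5 * (cur + m)
                new_prov[-1] = w
                changed = True
            else:
                new_mz.append(m)
                new_prov.append(p)
        mz = np.asarray(new_mz)
        prov = np.asarray(new_prov)
        if not changed:
            break
    return FeatureList(mz, prov)


# ---------------------------------------------------------------------------
# Intensity extraction
# ---------------------------------------------------------------------------

def extract_feature_matrix(
    ds: ImagingDataset, fl: FeatureList, extract_ppm: float = 20.0
) -> FeatureMatrix:
    """Extract per-pixel feature intensities in a +/- ppm window.

    Each spectrum point is assigned to at most one feature: the nearest in
    ppm, provided it lies within the window (ties go to the lower m/z);
    assigned intensities are summed per (pixel, feature) cell.  Cells with
    no point in the window are 0.
    """
    if len(fl) == 0:
        raise ValueError("feature list is empty")
    feat = fl.mz
    tol = extract_ppm * 1e-6
    n_pix = len(ds.pixels)
    values = np.zeros((n_pix, feat.size))

    for i, p in enumerate(ds.pixels):
        if p.mz.size == 0:
            continue
        right = np.searchsorted(feat, p.mz)
        left = np.clip(right - 1, 0, feat.size - 1)
        right = np.clip(right, 0, feat.size - 1)
        ppm_left = np.abs(p.mz - feat[left]) / feat[left]
        ppm_right = np.abs(p.mz - feat[right]) / feat[right]
        # nearest feature in ppm; ties resolved to the lower m/z (left)
        use_left = ppm_left <= ppm_right
        nearest = np.where(use_left, left, right)
        ppm = np.where(use_left, ppm_left, ppm_right)
        ok = ppm <= tol
        np.add.at(values[i], nearest[ok], p.intensity[ok])

    tissue = None
    if ds.tissue_mask is not None:
        tissue = np.array([ds.is_tissue(p.x, p.y) for p in ds.pixels])
    return FeatureMatrix(
        sample_id=ds.sample_id,
        pixels=[(p.x, p.y) for p in ds.pixels],
        features=fl,
        values=values,
        tissue=tissue,
        group=ds.group,
        timepoint=ds.timepoint,
    )


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def filter_features(
    matrices: Sequence[FeatureMatrix],
    design: StudyDesign,
    pixel_frac_min: float = 0.10,
    min_samples_per_group: int = 3,
    min_abundance: float = 20000.0,
) -> tuple[np.ndarray, dict]:
    """Apply the three-criterion feature retention filter.

    A feature is kept iff all of:

    a) in at least one sample, the fraction of tissue pixels with a
       nonzero value exceeds ``pixel_frac_min``;
    b) the number of samples satisfying (a) reaches
       ``min_samples_per_group`` within at least one design group;
    c) its maximum single-pixel value across all samples reaches
       ``min_abundance``.

    Returns a boolean keep-mask over features plus per-criterion counts.
    """
    if not matrices:
        raise ValueError("no matrices given")
    n_feat = len(matrices[0].features)
    for m in matrices[1:]:
        if len(m.features) != n_feat or not np.allclose(
            m.features.mz, matrices[0].features.mz
        ):
            raise ValueError("matrices must share one FeatureList")

    groups = sorted({s[1] for s in design.samples})
    present = np.zeros((len(matrices), n_feat), dtype=bool)  # criterion (a)
    max_val = np.zeros(n_feat)
    sample_group = []
    for i, m in enumerate(matrices):
        t = m.tissue_rows()
        if t.sum() == 0:
            t = np.ones(len(m.pixels), dtype=bool)
        frac = (m.values[t] > 0).mean(axis=0)
        present[i] = frac > pixel_frac_min
        max_val = np.maximum(max_val, m.values.max(axis=0))
        sample_group.append(design.group_of(m.sample_id))
    sample_group = np.asarray(sample_group)

    crit_a = present.any(axis=0)
    crit_b = np.zeros(n_feat, dtype=bool)
    usable_groups = [g for g in groups if (sample_group == g).any()]
    if len(usable_groups) < len(groups):
        warnings.warn("empty design group; criterion (b) uses remaining groups")
    for g in usable_groups:
        crit_b |= present[sample_group == g].sum(axis=0) >= min_samples_per_group
    crit_c = max_val >= min_abundance

    keep = crit_a & crit_b & crit_c
    stats = {
        "n_input": int(n_feat),
        "pass_pixel_fraction": int(crit_a.sum()),
        "pass_group_support": int(crit_b.sum()),
        "pass_abundance": int(crit_c.sum()),
        "retained": int(keep.sum()),
    }
    logger.info("filter_features: %s", stats)
    return keep, stats
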