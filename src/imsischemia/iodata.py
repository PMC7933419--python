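"""Data model and I/O for imaging mass-spectrometry datasets.

An imaging-MS acquisition rasters a laser over a tissue section and
records one mass spectrum per position ("pixel").  The central container
here is :class:`ImagingDataset`: a collection of :class:`PixelSpectrum`
objects on an integer grid, together with sample-level metadata (group,
nominal ischemia duration) and an optional tissue mask.

Coordinates are 0-based and row-major internally; imzML files store them
1-based, and the readers/writers convert at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "ischemic")
TIMEPOINTS = ("15min", "30min", "1h", "2h", "4h", "none")

#: Default acquisition mass range (Th); ions below/above are not recorded.
DEFAULT_MZ_RANGE = (100.0, 2000.0)


class SchemaError(ValueError):
    """A tabular input is missing required columns or violates its schema."""


class ImzmlParseError(ValueError):
    """An imzML file (or its companion binary) could not be parsed."""


@dataclass
class PixelSpectrum:
    """A centroided mass spectrum at one raster position.

    Parameters
    ----------
    x, y
        0-based column / row index of the pixel.
    mz
        Strictly increasing m/z values (Th).
    intensity
        Non-negative abundances, same length as ``mz``.
    """

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            # non-monotone axes are repaired by sorting, with a warning;
            # anything else is rejected outright
            warnings.warn(
                f"pixel ({self.x},{self.y}): m/z axis not strictly increasing; sorting",
                stacklevel=2,
            )
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                keep = np.concatenate([[True], np.diff(self.mz) > 0])
                self.mz, self.intensity = self.mz[keep], self.intensity[keep]
        if np.any(self.intensity < 0):
            raise ValueError(f"pixel ({self.x},{self.y}): negative intensity")

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities in the spectrum."""
        return float(self.intensity.sum())


@dataclass
class ImagingDataset:
    """One sample's imaging-MS acquisition plus its study metadata."""

    sample_id: str
    group: str = "control"
    timepoint: str = "none"
    pixels: list[PixelSpectrum] = field(default_factory=list)
    tissue_mask: Optional[np.ndarray] = None  # [rows, cols] bool
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        coords = [(p.x, p.y) for p in self.pixels]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate pixel coordinates in dataset")
        lo, hi = self.mz_range
        for p in self.pixels:
            if p.mz.size and (p.mz[0] < lo or p.mz[-1] > hi):
                raise ValueError(
                    f"pixel ({p.x},{p.y}) has m/z outside range [{lo}, {hi}]"
                )

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) inferred from the maximal pixel coordinates."""
        if not self.pixels:
            return (0, 0)
        return (
            max(p.y for p in self.pixels) + 1,
            max(p.x for p in self.pixels) + 1,
        )

    def is_tissue(self, x: int, y: int) -> bool:
        if self.tissue_mask is None:
            return True
        return bool(self.tissue_mask[y, x])


@dataclass
class StudyDesign:
    """The sample sheet: which samples exist in which group/timepoint cell.

    ``samples`` rows are (sample_id, group, timepoint, replicate).  The
    default cohort layout uses five biological replicates per cell.
    """

    samples: list[tuple[str, str, str, int]]
    n_per_cell: int = 5

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate sample_id in study design")
        for sid, group, tp, _rep in self.samples:
            if group not in GROUPS:
                raise SchemaError(f"sample {sid}: unknown group {group!r}")
            if tp not in TIMEPOINTS:
                raise SchemaError(f"sample {sid}: unknown timepoint {tp!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s[0] for s in self.samples]

    def group_of(self, sample_id: str) -> str:
        for sid, group, _tp, _rep in self.samples:
            if sid == sample_id:
                return group
        raise KeyError(sample_id)

    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for _sid, _g, tp, _r in self.samples:
            if tp not in seen:
                seen.append(tp)
        return seen

    def subset(self, timepoint: str) -> "StudyDesign":
        rows = [s for s in self.samples if s[2] == timepoint]
        return StudyDesign(samples=rows, n_per_cell=self.n_per_cell)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.samples, columns=["sample_id", "group", "timepoint", "replicate"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_per_cell: int = 5) -> "StudyDesign":
        rows = [
            (str(r.sample_id), str(r.group), str(r.timepoint), int(r.replicate))
            for r in df.itertuples()
        ]
        return cls(samples=rows, n_per_cell=n_per_cell)


@dataclass
class Config:
    """All pipeline parameters with their standard defaults.

    The defaults reflect a typical negative-mode MALDI metabolomics
    workflow: a 0.001 Da consensus tolerance and 50% minimum frequency for
    peak-list alignment, 20 ppm windows for duplicate merging and intensity
    extraction, the three-criterion feature filter (present in >10% of
    pixels; in at least 3 samples of one group; max abundance at least
    20,000 counts), FDR 0.05 with a 1.5 fold-change gate for the volcano
    classification, a 10 ppm annotation window, and spatially-aware
    k-means with k=6 clusters and neighborhood radius r=1.
    """

    consensus_tolerance_da: float = 0.001
    min_frequency: float = 0.5
    snr_nb: int = 100  # legacy noise-block size; the picker uses MAD-based SNR
    snr_min: float = 0.0  # 0 disables the SNR gate (centroided input); use ~3 for profile data
    pick_halfwindow: int = 0  # 0 = centroid data, every point is a candidate peak
    merge_ppm: float = 20.0
    extract_ppm: float = 20.0
    pixel_frac_min: float = 0.10
    min_samples_per_group: int = 3
    min_abundance: float = 20000.0
    de_fdr: float = 0.05
    volcano_fc: float = 1.5
    annotate_ppm: float = 10.0
    k: int = 6
    r: int = 1
    enrich_min_hits: int = 2
    enrich_q: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def _imzml_spectrum_count(path: Path) -> Optional[int]:
    """Number of <spectrum> elements, or None if the XML is unreadable."""
    try:
        from lxml import etree

        tree = etree.parse(str(path))
        return len(tree.findall(".//{*}spectrum"))
    except Exception:
        return None


def read_imzml(
    path: str | Path,
    sample_id: Optional[str] = None,
    group: str = "control",
    timepoint: str = "none",
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
) -> ImagingDataset:
    """Read an imzML file (continuous or processed dialect) into a dataset.

    imzML coordinates are 1-based; they are shifted to the internal 0-based
    convention.  Spectra with a non-monotone m/z axis are repaired by
    sorting, with a warning.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # lxml / struct errors from malformed input
        if _imzml_spectrum_count(path) == 0:
            # a valid file with zero spectra; pyimzml cannot represent it
            return ImagingDataset(
                sample_id=sample_id, group=group, timepoint=timepoint,
                pixels=[], mz_range=mz_range,
            )
        raise ImzmlParseError(f"cannot parse {path}: {exc}") from exc

    pixels: list[PixelSpectrum] = []
    for i, (cx, cy, *_z) in enumerate(parser.coordinates):
        try:
            mz, inten = parser.getspectrum(i)
            declared = parser.mzLengths[i]
        except Exception as exc:
            raise ImzmlParseError(
                f"cannot read spectrum index {i} at imzML coordinate ({cx},{cy}): {exc}"
            ) from exc
        if len(mz) != declared or len(inten) != declared:
            # a truncated .ibd silently yields short arrays; refuse the file
            raise ImzmlParseError(
                f"spectrum index {i} at imzML coordinate ({cx},{cy}): binary data "
                f"truncated ({len(mz)} of {declared} declared points)"
            )
        pixels.append(
            PixelSpectrum(x=int(cx) - 1, y=int(cy) - 1, mz=mz, intensity=inten)
        )
    return ImagingDataset(
        sample_id=sample_id,
        group=group,
        timepoint=timepoint,
        pixels=pixels,
        mz_range=mz_range,
    )


_EMPTY_IMZML = """<?xml version="1.0" encoding="UTF-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="2">
    <cv id="MS" fullName="Mass Spectrometry Ontology" URI="http://psidev.info/ms/mzML/psi-ms.obo"/>
    <cv id="IMS" fullName="Imaging MS Ontology" URI="http://www.maldi-msi.org/download/imzml/imagingMS.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="IMS" accession="IMS:1000031" name="processed" value=""/>
    </fileContent>
  </fileDescription>
  <referenceableParamGroupList count="2">
    <referenceableParamGroup id="mzArray">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000101" name="external data" value="true"/>
    </referenceableParamGroup>
    <referenceableParamGroup id="intensityArray">
      <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000101" name="external data" value="true"/>
    </referenceableParamGroup>
  </referenceableParamGroupList>
  <scanSettingsList count="1">
    <scanSettings id="scanSettings0">
      <cvParam cvRef="IMS" accession="IMS:1000042" name="max count of pixels x" value="0"/>
      <cvParam cvRef="IMS" accession="IMS:1000043" name="max count of pixels y" value="0"/>
    </scanSettings>
  </scanSettingsList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC0">
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp0">
      <processingMethod order="1" softwareRef="sw0">
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run0" defaultInstrumentConfigurationRef="IC0">
    <spectrumList count="0" defaultDataProcessingRef="dp0">
    </spectrumList>
  </run>
</mzML>
"""


def write_imzml(ds: ImagingDataset, path: str | Path, mode: str = "processed") -> Path:
    """Write a dataset to imzML (+ companion .ibd), 1-based coordinates.

    ``mode`` is the imzML dialect: "processed" stores one m/z axis per
    pixel, "continuous" a shared axis (only valid if all pixels share one).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    if not ds.pixels:
        # the pyimzml writer cannot emit a spectrum-free file; write a
        # minimal but valid imzML skeleton with an empty binary companion
        path.write_text(_EMPTY_IMZML)
        path.with_suffix(".ibd").write_bytes(b"")
        return path
    if mode == "continuous":
        first = ds.pixels[0].mz
        for p in ds.pixels[1:]:
            if p.mz.shape != first.shape or not np.array_equal(p.mz, first):
                raise ValueError(
                    "continuous imzML requires one shared m/z axis across all "
                    "pixels; use mode='processed' for per-pixel axes"
                )
    with ImzMLWriter(str(path), mode=mode) as writer:
        for p in ds.pixels:
            writer.addSpectrum(p.mz, p.intensity, (p.x + 1, p.y + 1))
    return path


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "feature_matrix": ["sample_id", "x", "y"],
    "metabolite_db": ["name"],
    "pathway_sets": ["pathway", "metabolite"],
    "design": ["sample_id", "group", "timepoint", "replicate"],
}


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a CSV/TSV table of a known kind.

    Kinds: ``feature_matrix`` (sample_id, x, y, one column per m/z),
    ``metabolite_db`` (name, formula and/or monoisotopic_mass, optional
    pathways), ``pathway_sets`` (pathway, metabolite), ``design``
    (sample_id, group, timepoint, replicate).
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    df = _read_delimited(path)
    missing = [c for c in _REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} ({kind}): missing columns {missing}")

    if kind == "design":
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise SchemaError(f"design: duplicate sample_id {dupes}")
    elif kind == "feature_matrix":
        value_cols = [c for c in df.columns if c not in ("sample_id", "x", "y")]
        if not value_cols:
            raise SchemaError("feature_matrix: no m/z columns")
        vals = df[value_cols].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise SchemaError("feature_matrix: negative intensity value")
    elif kind == "metabolite_db":
        has_formula = "formula" in df.columns
        has_mass = "monoisotopic_mass" in df.columns
        if not has_formula and not has_mass:
            raise SchemaError(
                "metabolite_db: need a 'formula' or 'monoisotopic_mass' column"
            )
        # rows may omit the formula as long as a precomputed mass is given
        if has_formula and has_mass:
            bad = df["formula"].isna() & df["monoisotopic_mass"].isna()
            if bad.any():
                raise SchemaError(
                    f"metabolite_db: rows without formula or mass: "
                    f"{df.loc[bad, 'name'].tolist()}"
                )
    return df
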