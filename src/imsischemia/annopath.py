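"""Metabolite annotation and pathway over-representation analysis.

Features are annotated in negative-ion mode: a feature m/z matches a
metabolite when it lies within a ppm window of the metabolite's
deprotonated monoisotopic mass, m/z([M-H]-) = M - m(H+).  Only the
[M-H]- adduct is considered (the acquisition is negative polarity);
other negative adducts are a natural extension point.

Pathway enrichment uses the one-sided Fisher exact test (hypergeometric
tail) on 2x2 tables of (in-pathway x differentially-expressed) counts
over the annotated background, with BH adjustment across tested pathways
and a minimum-hits rule: pathways with fewer than two differential
metabolites are excluded before testing.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import MONOISOTOPIC_MASS, PROTON_MASS
from .iodata import SchemaError, read_table

logger = logging.getLogger(__name__)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class MetaboliteRecord:
    """A reference metabolite: name, elemental formula, monoisotopic mass."""

    name: str
    formula: Optional[dict[str, int]] = None
    monoisotopic_mass: Optional[float] = None
    pathways: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.formula is not None and self.monoisotopic_mass is None:
            self.monoisotopic_mass = monoisotopic_mass(self.formula)
        if self.monoisotopic_mass is None:
            raise ValueError(f"{self.name}: need a formula or a mass")
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if self.formula is not None:
            computed = monoisotopic_mass(self.formula)
            if abs(computed - self.monoisotopic_mass) / computed > 1e-6:
                raise ValueError(
                    f"{self.name}: stated mass {self.monoisotopic_mass} deviates "
                    f"from formula mass {computed:.6f} by more than 1 ppm"
                )


@dataclass
class AnnotationHit:
    """One feature-to-metabolite match through the [M-H]- adduct."""

    feature_mz: float
    metabolite: MetaboliteRecord
    ppm_error: float
    ambiguous: bool = False
    adduct: str = "[M-H]-"


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def parse_formula(s: str) -> dict[str, int]:
    """Parse an elemental formula like ``C10H16N5O13P3`` into counts."""
    s = s.strip()
    if not s:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        if not m.group(0):
            break
        elem = m.group(1)
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {elem!r} in formula {s!r}")
        counts[elem] = counts.get(elem, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"cannot parse formula {s!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a formula from the frozen atomic masses."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for elem, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for {elem}")
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"no tabulated mass for element {elem!r}")
        total += MONOISOTOPIC_MASS[elem] * count
    return total


def deprotonated_mz(formula_or_mass: str | Mapping[str, int] | float) -> float:
    """m/z of the [M-H]- ion: neutral mass minus the proton mass.

    The electron stays with the anion, so only a proton's mass is lost.
    """
    if isinstance(formula_or_mass, (int, float)):
        mass = float(formula_or_mass)
    else:
        mass = monoisotopic_mass(formula_or_mass)
    if mass <= PROTON_MASS:
        raise ValueError(f"neutral mass {mass} not above the proton mass")
    return mass - PROTON_MASS


def ppm_deviation(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def load_metabolite_db(path) -> list[MetaboliteRecord]:
    """Load a metabolite reference TSV (name, formula, mass?, pathways?)."""
    df = read_table(path, "metabolite_db")
    records = []
    for row in df.itertuples():
        formula = None
        if "formula" in df.columns and isinstance(row.formula, str) and row.formula:
            formula = parse_formula(row.formula)
        mass = None
        if "monoisotopic_mass" in df.columns and pd.notna(
            getattr(row, "monoisotopic_mass", None)
        ):
            mass = float(row.monoisotopic_mass)
        pathways: set[str] = set()
        if "pathways" in df.columns and isinstance(getattr(row, "pathways", None), str):
            pathways = {p.strip() for p in row.pathways.split(";") if p.strip()}
        records.append(
            MetaboliteRecord(
                name=str(row.name_ if hasattr(row, "name_") else row.name),
                formula=formula,
                monoisotopic_mass=mass,
                pathways=pathways,
            )
        )
    return records


def bundled_metabolite_db() -> list[MetaboliteRecord]:
    """The small curated metabolite list shipped with the package."""
    with resources.as_file(
        resources.files("imsischemia").joinpath("data/metabolites.tsv")
    ) as p:
        return load_metabolite_db(p)


def bundled_pathways() -> dict[str, set[str]]:
    """Pathway membership sets shipped with the package."""
    with resources.as_file(
        resources.files("imsischemia").joinpath("data/pathways.tsv")
    ) as p:
        return load_pathways(p)


def load_pathways(path) -> dict[str, set[str]]:
    df = read_table(path, "pathway_sets")
    out: dict[str, set[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.pathway), set()).add(str(row.metabolite))
    return out


def annotate_features(
    feature_mz: Sequence[float] | np.ndarray,
    db: Sequence[MetaboliteRecord],
    annotate_ppm: float = 10.0,
) -> list[AnnotationHit]:
    """Match feature m/z values to metabolites through the [M-H]- adduct.

    Every metabolite whose deprotonated mass lies within the ppm window
    of a feature is reported; features matching several metabolites (for
    example isomers with identical formulas) have all hits flagged
    ambiguous.  Features with no match simply produce no hit.
    """
    if annotate_ppm <= 0:
        raise ValueError("annotate_ppm must be > 0")
    if not db:
        warnings.warn("empty metabolite database: nothing can be annotated")
        return []
    theo = np.array([deprotonated_mz(m.monoisotopic_mass) for m in db])
    order = np.argsort(theo)
    theo_sorted = theo[order]

    hits: list[AnnotationHit] = []
    for fmz in np.asarray(feature_mz, dtype=float):
        tol = fmz * annotate_ppm * 1e-6
        a = np.searchsorted(theo_sorted, fmz - tol, side="left")
        b = np.searchsorted(theo_sorted, fmz + tol, side="right")
        cand = order[a:b]
        feature_hits = [
            AnnotationHit(
                feature_mz=float(fmz),
                metabolite=db[j],
                ppm_error=ppm_deviation(fmz, theo[j]),
            )
            for j in cand
            if abs(ppm_deviation(fmz, theo[j])) <= annotate_ppm
        ]
        if len(feature_hits) > 1:
            for h in feature_hits:
                h.ambiguous = True
        hits.extend(feature_hits)
    return hits


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_mz": [h.feature_mz for h in hits],
            "metabolite": [h.metabolite.name for h in hits],
            "adduct": [h.adduct for h in hits],
            "ppm_error": [h.ppm_error for h in hits],
            "ambiguous": [h.ambiguous for h in hits],
        }
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(
    de_hits: Iterable[str],
    background: Iterable[str],
    pathways: Mapping[str, set[str]],
    min_hits: int = 2,
    q_threshold: float = 0.05,
    directions: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Pathway over-representation among differential metabolites.

    For each pathway, the 2x2 table (in-pathway x differential) over the
    annotated ``background`` is tested with the one-sided Fisher exact
    test (hypergeometric upper tail); p-values are BH-adjusted across
    the pathways actually tested.  Pathways with fewer than ``min_hits``
    differential metabolites are excluded before testing, and pathways
    with no background overlap are skipped.  Coverage is the percentage
    of the pathway's metabolites present in the background; the optional
    ``directions`` map (metabolite -> "up"/"down") yields the fraction
    of up-regulated hits per pathway.
    """
    from .normstats import bh_adjust

    de = set(de_hits)
    bg = set(background)
    if not de <= bg:
        raise ValueError("de_hits must be a subset of the background")
    n_bg, n_de = len(bg), len(de)

    rows = []
    for name, members in pathways.items():
        overlap = members & bg
        if not overlap:
            logger.info("pathway %r has no background overlap; skipped", name)
            continue
        hits = overlap & de
        if len(hits) < min_hits:
            continue
        k, K = len(hits), len(overlap)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=K, n=n_de)
        p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_de))
        frac_up = np.nan
        if directions is not None:
            ups = sum(1 for m in hits if directions.get(m) == "up")
            frac_up = ups / k
        rows.append(
            {
                "pathway": name,
                "hits": k,
                "pathway_size": K,
                "p": p,
                "coverage": 100.0 * K / len(members),
                "fraction_up": frac_up,
                "hit_metabolites": ";".join(sorted(hits)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pathway", "hits", "pathway_size", "p", "coverage",
            "fraction_up", "hit_metabolites",
        ],
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values(["q", "p"]).reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
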