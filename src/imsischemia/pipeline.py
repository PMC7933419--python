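"""End-to-end orchestration: simulate -> features -> normalize -> segment
-> differential expression -> annotate -> enrich, with a run manifest.

Also houses the simulation-study helpers used to validate the pipeline
against phantom ground truth: empirical-FDR calibration on null cohorts,
segmentation recovery of the planted ischemic sector, and planted
fold-change recovery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annopath, normstats, peakflow, spatialseg, synthgen
from .constants import CONSTANTS_VERSION
from .iodata import Config, StudyDesign
from .normstats import ROI
from .peakflow import FeatureMatrix
from .synthgen import PhantomSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

def validate_config(config: Config) -> list[str]:
    """Check all configuration invariants; empty list means valid."""
    v: list[str] = []
    for name in ("consensus_tolerance_da", "merge_ppm", "extract_ppm",
                 "annotate_ppm"):
        if getattr(config, name) <= 0:
            v.append(f"{name} must be > 0")
    if config.snr_min < 0:
        v.append("snr_min must be >= 0")
    if not (0 < config.min_frequency <= 1):
        v.append("min_frequency must be in (0, 1]")
    if not (0 <= config.pixel_frac_min < 1):
        v.append("pixel_frac_min must be in [0, 1)")
    if config.min_samples_per_group < 1:
        v.append("min_samples_per_group must be >= 1")
    if config.min_abundance < 0:
        v.append("min_abundance must be >= 0")
    if not (0 < config.de_fdr < 1):
        v.append("de_fdr must be in (0, 1)")
    if config.volcano_fc < 1:
        v.append("volcano_fc must be >= 1")
    if config.k < 2:
        v.append("k must be >= 2")
    if config.r < 0:
        v.append("r must be >= 0")
    if config.enrich_min_hits < 1:
        v.append("enrich_min_hits must be >= 1")
    if not (0 < config.enrich_q < 1):
        v.append("enrich_q must be in (0, 1)")
    return v


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: Config) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(
    config: Config,
    design: StudyDesign,
    out_dir: str | Path,
    spec: Optional[PhantomSpec] = None,
    db: Optional[Sequence[annopath.MetaboliteRecord]] = None,
    pathways: Optional[dict[str, set[str]]] = None,
    ion_mz: Optional[Sequence[float]] = None,
) -> dict:
    """Run the whole analysis on a simulated cohort and write artifacts.

    Stages: phantom simulation, peak picking + consensus feature list +
    duplicate merge, intensity extraction, three-criterion filtering,
    MSTUS + log2 normalization, per-sample spatially-aware segmentation,
    per-timepoint moderated differential expression and volcano tables,
    [M-H]- annotation of significant features, and pathway enrichment.
    Returns the run manifest (also written as ``manifest.json``).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if db is None:
        db = annopath.bundled_metabolite_db()
    if pathways is None:
        pathways = annopath.bundled_pathways()
    if spec is None:
        spec = PhantomSpec(
            seed=config.seed,
            metabolite_mz=[annopath.deprotonated_mz(m.monoisotopic_mass) for m in db],
            timepoints={tp: synthgen.DEFAULT_TIMEPOINT_EFFECTS[tp]
                        for tp in design.timepoints()},
        )

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "constants_version": CONSTANTS_VERSION,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts
            }
            logger.info("stage %s done: %s", name, manifest["stages"][name])

        return done

    # --- simulate -----------------------------------------------------
    end = stage("simulate")
    cohort = synthgen.generate_cohort(spec, design)
    datasets = [ds for ds, _gt in cohort]
    truth = cohort[0][1]
    end(samples=len(datasets))

    # --- consensus features -------------------------------------------
    end = stage("features")
    peaklists = []
    for ds in datasets:
        for px in ds.pixels:
            if ds.is_tissue(px.x, px.y):
                peaklists.append(
                    peakflow.pick_peaks(px, config.snr_min, config.pick_halfwindow)
                )
    fl = peakflow.build_consensus_mzlist(
        peaklists, config.consensus_tolerance_da, config.min_frequency
    )
    fl = peakflow.merge_duplicate_mz(fl, config.merge_ppm)
    end(features=len(fl))

    # --- extraction + filter ------------------------------------------
    end = stage("filter")
    matrices = [
        peakflow.extract_feature_matrix(ds, fl, config.extract_ppm) for ds in datasets
    ]
    keep, filter_stats = peakflow.filter_features(
        matrices, design, config.pixel_frac_min,
        config.min_samples_per_group, config.min_abundance,
    )
    matrices = [m.subset_features(keep) for m in matrices]
    features_df = pd.DataFrame({
        "mz": matrices[0].features.mz,
        "provenance": matrices[0].features.provenance,
    })
    features_path = out_dir / "features.csv"
    features_df.to_csv(features_path, index=False)
    end(**filter_stats)

    # --- normalization -------------------------------------------------
    end = stage("normalize")
    norm = [
        normstats.log2_transform(normstats.mstus_normalize(m)) for m in matrices
    ]
    end(samples=len(norm))

    # --- segmentation (per sample) ------------------------------------
    end = stage("segment")
    seg_rows = []
    seg_input = [
        normstats.log2_transform(normstats.impute_zeros(normstats.mstus_normalize(m)))
        for m in matrices
    ]
    for m in seg_input:
        seg = spatialseg.spatial_kmeans(
            m, k=config.k, r=config.r, seed=config.seed
        )
        _ari, jac = spatialseg.segmentation_quality(
            seg, truth.ischemic_mask, truth.tissue_mask
        )
        labels_path = out_dir / f"labels_{m.sample_id}.csv"
        pd.DataFrame({
            "x": [x for x, _y in seg.pixels],
            "y": [y for _x, y in seg.pixels],
            "cluster": seg.labels,
        }).to_csv(labels_path, index=False)
        seg_rows.append({"sample_id": m.sample_id, "best_jaccard": jac})
    end(samples=len(seg_rows))

    # --- differential expression per timepoint ------------------------
    end = stage("de")
    rois = synthgen.default_rois(spec)
    roi1 = ROI("ROI1_ischemic", rois["ROI1_ischemic"])
    de_counts = {}
    de_tables = {}
    for tp in design.timepoints():
        sub = design.subset(tp)
        sub_norm = [m for m in norm if m.sample_id in sub.sample_ids]
        means = normstats.extract_roi_means(sub_norm, roi1)
        de = normstats.fit_moderated_de(means, sub)
        de_tables[tp] = de
        volcano = normstats.volcano_table(de, config.de_fdr, config.volcano_fc)
        de_out = de.table.copy()
        de_out["status"] = volcano["status"]
        de_out.to_csv(out_dir / f"de_{tp}.csv", index=False)
        volcano.to_csv(out_dir / f"volcano_{tp}.csv", index=False)
        de_counts[tp] = int((de.table["q"] < config.de_fdr).sum())
    end(**{f"de_{tp}": n for tp, n in de_counts.items()})

    # --- annotation + enrichment (first timepoint's DE set) -----------
    end = stage("annotate")
    first_tp = design.timepoints()[0]
    de = de_tables[first_tp]
    sig = de.table[de.table["q"] < config.de_fdr]
    all_hits = annopath.annotate_features(
        de.table["mz"].to_numpy(), db, config.annotate_ppm
    )
    sig_mz = set(np.round(sig["mz"].to_numpy(), 6))
    de_hits = [h for h in all_hits if round(h.feature_mz, 6) in sig_mz]
    annopath.hits_to_frame(de_hits).to_csv(out_dir / "hits.csv", index=False)
    directions = {}
    for h in de_hits:
        row = sig[np.isclose(sig["mz"], h.feature_mz)]
        if len(row):
            directions[h.metabolite.name] = (
                "up" if float(row["log2FC"].iloc[0]) > 0 else "down"
            )
    enrich = annopath.fisher_enrichment(
        de_hits={h.metabolite.name for h in de_hits},
        background={h.metabolite.name for h in all_hits},
        pathways=pathways,
        min_hits=config.enrich_min_hits,
        q_threshold=config.enrich_q,
        directions=directions,
    )
    enrich.to_csv(out_dir / "enrich.csv", index=False)
    end(annotated_background=len({h.metabolite.name for h in all_hits}),
        annotated_de=len({h.metabolite.name for h in de_hits}),
        pathways_tested=len(enrich))

    # --- ion images ----------------------------------------------------
    if ion_mz:
        end = stage("ion_images")
        for mz in ion_mz:
            img = spatialseg.reconstruct_ion_image(datasets[0], mz, config.extract_ppm)
            np.savetxt(out_dir / f"ion_{mz:.4f}.csv", img.image, delimiter=",")
        end(images=len(ion_mz))

    for path in sorted(out_dir.glob("*.csv")):
        manifest["outputs"][path.name] = _digest(path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------

def null_fdr_simulation(
    n_reps: int = 200,
    seed: int = 0,
    n_features: int = 500,
    grid: tuple[int, int] = (20, 20),
    n_per_group: int = 5,
    q_threshold: float = 0.05,
) -> dict:
    """Empirical FDR of the DE stage on null cohorts (no planted effect).

    Each replicate simulates ``n_per_group`` control and ischemic samples
    with no differential features, runs MSTUS + log2 + ROI means +
    moderated t + BH, and records the false-discovery proportion at the
    q threshold (0 when nothing is called).  Returns the mean FDP, the
    per-replicate discovery counts, and the replicate count.
    """
    fdps, n_disc = [], []
    for rep in range(n_reps):
        spec = PhantomSpec(
            grid=grid,
            n_features=n_features,
            n_de_up=0,
            n_de_down=0,
            seed=(seed * 100003 + rep) % (2**31 - 1),
            timepoints={"15min": 0.0},
        )
        design = synthgen.make_design(["15min"], n_per_group)
        cohort = synthgen.generate_cohort(spec, design, as_matrix=True)
        norm = [
            normstats.log2_transform(normstats.mstus_normalize(fm))
            for fm, _gt in cohort
        ]
        roi = ROI("ROI1_ischemic", synthgen.default_rois(spec)["ROI1_ischemic"])
        means = normstats.extract_roi_means(norm, roi)
        de = normstats.fit_moderated_de(means, design)
        d = int((de.table["q"] < q_threshold).sum())
        n_disc.append(d)
        fdps.append(1.0 if d > 0 else 0.0)  # all discoveries on a null are false
    return {
        "empirical_fdr": float(np.mean(fdps)),
        "mean_discoveries": float(np.mean(n_disc)),
        "n_reps": n_reps,
    }


def roi2_discovery_simulation(
    n_reps: int = 20,
    seed: int = 0,
    grid: tuple[int, int] = (40, 40),
    n_features: int = 300,
    timepoint: str = "15min",
    q_threshold: float = 0.05,
) -> dict:
    """Discoveries in the remote (non-ischemic) ROI of effect-bearing phantoms.

    The planted effect is confined to the ischemic sector, so the remote
    septum-analogue ROI is a true null even though the cohort carries
    differential features; discoveries there should be ~0.
    """
    counts = []
    for rep in range(n_reps):
        spec = PhantomSpec(
            grid=grid, n_features=n_features,
            n_de_up=max(4, n_features // 20),
            n_de_down=max(4, n_features // 20),
            seed=(seed * 99991 + rep) % (2**31 - 1),
        )
        design = synthgen.make_design([timepoint], 5)
        cohort = synthgen.generate_cohort(spec, design, as_matrix=True)
        norm = [
            normstats.log2_transform(normstats.mstus_normalize(fm))
            for fm, _gt in cohort
        ]
        roi2 = ROI("ROI2_remote", synthgen.default_rois(spec)["ROI2_remote"])
        means = normstats.extract_roi_means(norm, roi2)
        de = normstats.fit_moderated_de(means, design)
        counts.append(int((de.table["q"] < q_threshold).sum()))
    return {"mean_discoveries": float(np.mean(counts)), "counts": counts}


def segmentation_recovery_simulation(
    n_seeds: int = 10,
    seed: int = 0,
    timepoints: Optional[Sequence[str]] = None,
    k: int = 6,
    r: int = 1,
    jaccard_threshold: float = 0.7,
) -> dict:
    """Fraction of seeded phantoms whose ischemic sector is isolated.

    For each seed and each nominal ischemia duration, one ischemic sample
    is simulated with the default phantom conditions, normalized, and
    segmented with spatially-aware k-means; success means some cluster
    overlaps the planted ischemic mask with Jaccard at least
    ``jaccard_threshold``.
    """
    if timepoints is None:
        timepoints = list(synthgen.DEFAULT_TIMEPOINT_EFFECTS)
    jaccards = {tp: [] for tp in timepoints}
    for rep in range(n_seeds):
        spec = PhantomSpec(seed=(seed * 7919 + rep) % (2**31 - 1))
        for tp in timepoints:
            fm, gt = synthgen.generate_phantom_matrix(
                spec, f"isch_{tp}_{rep}", "ischemic", tp
            )
            norm = normstats.log2_transform(
                normstats.impute_zeros(normstats.mstus_normalize(fm))
            )
            seg = spatialseg.spatial_kmeans(norm, k=k, r=r, seed=rep)
            _ari, jac = spatialseg.segmentation_quality(
                seg, gt.ischemic_mask, gt.tissue_mask
            )
            jaccards[tp].append(jac)
    success = {
        tp: float(np.mean([j >= jaccard_threshold for j in js]))
        for tp, js in jaccards.items()
    }
    return {
        "success_rate": success,
        "min_success_rate": float(min(success.values())),
        "jaccards": {tp: [float(j) for j in js] for tp, js in jaccards.items()},
    }


def fc_recovery_slope(
    seed: int = 0,
    grid: tuple[int, int] = (40, 40),
    n_features: int = 300,
    timepoint: str = "4h",
    n_per_group: int = 5,
) -> dict:
    """Slope of estimated vs planted log2FC across features.

    At the 4 h timepoint the effect multiplier is 1, so the estimated
    ischemic-ROI log2 fold change should track the planted value with
    unit slope; the regression is over the planted differential features.
    """
    spec = PhantomSpec(
        grid=grid, n_features=n_features,
        n_de_up=max(20, n_features // 10),
        n_de_down=max(20, n_features // 10),
        seed=seed % (2**31 - 1),
    )
    design = synthgen.make_design([timepoint], n_per_group)
    cohort = synthgen.generate_cohort(spec, design, as_matrix=True)
    gt = cohort[0][1]
    norm = [
        normstats.log2_transform(normstats.mstus_normalize(fm)) for fm, _ in cohort
    ]
    roi = ROI("ROI1_ischemic", synthgen.default_rois(spec)["ROI1_ischemic"])
    means = normstats.extract_roi_means(norm, roi)
    de = normstats.fit_moderated_de(means, design)
    eff = spec.timepoints[timepoint]
    planted = gt.de_table.set_index("feature")["log2fc"] * eff
    est = de.table["log2FC"].to_numpy()[planted.index.to_numpy()]
    slope, intercept = np.polyfit(planted.to_numpy(), est, 1)
    return {"slope": float(slope), "intercept": float(intercept),
            "n_de": int(len(planted))}
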