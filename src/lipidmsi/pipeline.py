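"""End-to-end orchestration: simulate -> preprocess -> segment -> validate ->
enrich -> annotate -> report.

Every stage writes its artifacts (TSV tables, label CSVs, imzML) into a run
directory together with a manifest of all parameters and seeds, so a rerun
with the same config is bit-identical.  All randomness flows from the
config seed; nothing is seeded from the wall clock.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import enrichment as enr
from . import phantom as ph
from . import preprocess as pp
from . import segmentation as seg
from . import stats as vs
from .io import MSIDataset, write_imzml, write_mask, write_tsv

__all__ = ["PipelineConfig", "run_pipeline", "render_ion_image"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults mirror the per-stage choices."""

    seed: int = 1
    width: int = 64
    height: int = 32
    n_replicates: int = 3
    noise_cv: float = 0.15
    isotope_satellites: bool = True
    write_imzml_files: bool = False

    baseline_window_da: float = 5.0
    min_rel_intensity: float = 0.01
    top_n: int = 200
    align_tol_da: float = 0.02
    deisotope_tol_da: float = 0.01

    n_leaves: int = 8
    n_restarts: int = 10

    alpha: float = 0.05
    auc_threshold: float = 0.7
    replicate_fraction: float = 0.5

    annotation_tol_da: float = 0.05
    ms2_tol_ppm: float = 5.0

    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha"),
            (0 <= self.auc_threshold <= 1, "auc_threshold"),
            (0 < self.replicate_fraction <= 1, "replicate_fraction"),
            (self.annotation_tol_da > 0, "annotation_tol_da"),
            (self.n_leaves >= 2, "n_leaves"),
            (0 < self.noise_cv < 1, "noise_cv"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"config parameter {name} out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.validate()
        return cfg


def render_ion_image(
    dataset: MSIDataset,
    feature_mz: float,
    tol_da: float = 0.05,
    floor_percent: float = 20.0,
) -> np.ndarray:
    """Per-pixel intensity map of one feature, scaled to percent of maximum.

    Pixels below ``floor_percent`` of the maximum are masked (NaN), matching
    the way reconstructed ion images are thresholded for overlay display.
    """
    mz = dataset.mz_axis
    if not (mz[0] - tol_da <= feature_mz <= mz[-1] + tol_da):
        raise ValueError(f"feature {feature_mz} outside the m/z axis")
    sel = np.abs(mz - feature_mz) <= tol_da
    img = dataset.intensities[:, sel].sum(axis=1).reshape(
        dataset.height, dataset.width).astype(float)
    peak = img.max()
    if peak <= 0:
        return np.full_like(img, np.nan)
    pct = 100.0 * img / peak
    pct[pct < floor_percent] = np.nan
    return pct


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and return a summary dict (also written as JSON).

    Raises with the failing stage's name if any stage errors.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    summary: dict = {}

    stage = "simulate"
    try:
        spec = ph.PhantomSpec(
            seed=config.seed, width=config.width, height=config.height,
            n_replicates=config.n_replicates, noise_cv=config.noise_cv,
            isotope_satellites=config.isotope_satellites)
        datasets, truth = ph.simulate_dataset(spec)
        write_mask(truth.mask, out / "mask.csv")
        gt = pd.DataFrame({
            "mz": truth.feature_mz,
            "lipid": [p.lipid.species_name for p in truth.panel],
            "adduct": [p.adduct_name for p in truth.panel],
            "role": [p.role for p in truth.panel],
            "adipose_fold": [p.adipose_fold for p in truth.panel],
        })
        write_tsv(gt, out / "ground_truth.tsv")
        if config.write_imzml_files:
            for ds in datasets:
                write_imzml(ds, out / f"{ds.replicate_id}.imzML")
        manifest["stages"][stage] = {
            "n_replicates": len(datasets),
            "n_planted_features": len(truth.feature_mz),
            "n_tissue_pixels": int(len(truth.mask.tissue_pixels())),
            "replicate_scales": list(truth.replicate_scales),
        }

        stage = "preprocess"
        tables = []
        for ds in datasets:
            norm = pp.tic_normalize(pp.baseline_correct(
                ds, window_da=config.baseline_window_da))
            t = pp.pick_features(norm, min_rel_intensity=config.min_rel_intensity,
                                 top_n=config.top_n)
            t = pp.deisotope(t, tol_da=config.deisotope_tol_da)
            tables.append(t)
        aligned = pp.align_features(tables, tol_da=config.align_tol_da)
        write_tsv(aligned.to_dataframe(), out / "aligned_features.tsv")
        consensus = aligned.covered_by_all()
        matrices = [
            np.stack([tables[r].matrix[f.members[tables[r].replicate_id]]
                      for f in consensus])
            for r in range(len(tables))
        ]
        cons_mz = np.array([f.avg_mz for f in consensus])
        manifest["stages"][stage] = {
            "features_per_replicate": [t.n_features for t in tables],
            "removed_isotopologues": [len(t.removed_isotopologues) for t in tables],
            "consensus_features": len(consensus),
        }

        stage = "segment"
        clusters = seg.bisecting_kmeans(
            tables[0], n_leaves=config.n_leaves, seed=config.seed,
            n_restarts=config.n_restarts)
        overlap = seg.score_overlap(clusters, truth.mask)
        adipose_leaf, nonadipose_px = seg.select_adipose_cluster(
            clusters, truth.mask)
        adipose_px = np.nonzero(clusters.labels == adipose_leaf)[0]
        np.savetxt(out / "cluster_map.csv",
                   clusters.as_image(), fmt="%d", delimiter=",")
        write_tsv(pd.DataFrame(
            [(leaf, lab, dice, jac)
             for leaf, (lab, dice, jac) in overlap.per_leaf.items()],
            columns=["leaf", "best_label", "dice", "jaccard"]),
            out / "cluster_overlap.tsv")
        adipose_dice = overlap.per_leaf[adipose_leaf][1]
        manifest["stages"][stage] = {
            "n_leaves": clusters.n_leaves,
            "ari": overlap.ari,
            "adipose_leaf": int(adipose_leaf),
            "adipose_dice": adipose_dice,
        }

        stage = "validate"
        cv_rows = []
        roi_tissues = ("muscle", "liver", "brain")
        tic_groups = []
        for tissue in roi_tissues:
            rois = vs.select_rois(truth.mask, tissue, n_rois=3, seed=config.seed)
            cv = vs.cv_summary(tables[0], rois)
            cv_rows.append({
                "tissue": tissue,
                "frac_cv_below_20": cv.frac_below_20,
                "frac_cv_below_25": cv.frac_below_25,
            })
            raw_tic = tables[0].pixel_tic
            tic_groups.append([
                float(np.mean(raw_tic[list(r.pixels)])) for r in rois])
        f_stat, p_tic = vs.one_way_anova(tic_groups)
        write_tsv(pd.DataFrame(cv_rows), out / "cv_summary.tsv")
        manifest["stages"][stage] = {
            "tic_anova_F": f_stat, "tic_anova_p": p_tic,
            "cv": cv_rows,
        }

        stage = "enrich"
        n_rep = len(matrices)
        results = enr.run_enrichment(
            matrices,
            adipose_idx=[adipose_px] * n_rep,
            nonadipose_idx=[nonadipose_px] * n_rep,
            mz=cons_mz,
            polarity=datasets[0].polarity,
            alpha=config.alpha,
            auc_threshold=config.auc_threshold,
            replicate_fraction=config.replicate_fraction,
        )
        table1_style = enr.summarize_enrichment(results)
        write_tsv(table1_style, out / "enrichment_summary.tsv")
        enriched = [r for r in results if r.enriched]
        called = {r.mz for r in enriched}
        truth_pos = {round(m, 4) for m in truth.enriched_mz}
        truth_neg = {round(m, 4) for m in truth.null_mz}
        called_r = {round(m, 4) for m in called}
        scored = {round(float(m), 4) for m in cons_mz}
        tp = len(called_r & truth_pos)
        fp = len(called_r & truth_neg)
        fn = len((truth_pos & scored) - called_r)
        tn = len((truth_neg & scored) - called_r)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec_ = tn / (tn + fp) if tn + fp else float("nan")
        manifest["stages"][stage] = {
            "tier1_candidates": int(np.sum([r.pass_tier1 for r in results])),
            "enriched": len(enriched),
            "sensitivity": sens,
            "specificity": spec_,
        }
        summary.update({"sensitivity": sens, "specificity": spec_,
                        "adipose_dice": adipose_dice, "ari": overlap.ari,
                        "n_enriched": len(enriched)})

        stage = "annotate"
        db = ann.default_database()
        truth_by_mz = {round(p.mz, 4): p for p in truth.panel}
        desi_hits = []
        lesa_ids = []
        for r in enriched:
            hits = ann.accurate_mass_search(
                r.mz, datasets[0].polarity, db, tol_da=config.annotation_tol_da)
            for h in hits:
                desi_hits.append((round(r.mz, 4), h))
            planted = truth_by_mz.get(round(r.mz, 4))
            if planted is None:
                continue
            try:
                spectrum = ph.simulate_ms2(
                    planted.lipid, planted.adduct_name, seed=config.seed)
            except (ValueError, ann.UnsupportedClassError):
                continue
            best = ann.match_ms2(spectrum, hits, tol_ppm=config.ms2_tol_ppm)
            if best is not None:
                lesa_ids.append((best.hit.lipid, best.hit.adduct.name, best))
        level2 = ann.level2_crossmatch(desi_hits, lesa_ids)
        write_tsv(pd.DataFrame(
            [(rec.feature_id, rec.lipid_name, rec.adduct_name)
             for rec in level2],
            columns=["feature_mz", "lipid", "adduct"]),
            out / "level2_identifications.tsv")
        manifest["stages"][stage] = {
            "desi_hits": len(desi_hits),
            "lesa_identifications": len(lesa_ids),
            "level2_records": len(level2),
        }
        summary["n_level2"] = len(level2)

        stage = "report"
        if enriched:
            top = max(enriched, key=lambda r: r.avg_fold_change)
            img = render_ion_image(datasets[0], top.mz,
                                   tol_da=config.annotation_tol_da)
            np.savetxt(out / "top_ion_image.csv", img, delimiter=",", fmt="%.3f")
            manifest["stages"][stage] = {"top_feature_mz": top.mz}
        checks = {
            p.name: _file_checksum(p)
            for p in sorted(out.glob("*.tsv"))
        }
        manifest["artifact_checksums"] = checks
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    summary["manifest"] = manifest
    return summary
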