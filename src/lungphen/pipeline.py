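"""End-to-end phenotyping pipeline.

Runs the full analysis from a single configuration: cohort simulation
(or NIfTI ingestion) → lung segmentation → lattice feature extraction
per window size and kernel → outlier screening + ComBat harmonization →
per-kernel hierarchical clustering with consensus K selection →
entanglement between the kernels' dendrograms → optional centroid
mapping to an independent cohort → association tables.

Stages communicate through files in the run directory, every stage
reads its inputs back from disk, and a provenance manifest records the
seed, a configuration hash and the SHA-256 of every artifact — so a run
with identical config and seed is bit-identical and deleting downstream
artifacts re-derives them unchanged from cached upstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .associations import build_association_table
from .clustering import (
    consensus_select_k,
    cut_clusters,
    entanglement,
    fit_centroids,
    hierarchical_cluster,
    map_clusters,
)
from .features import FEATURE_NAMES, LatticeFeatureExtractor
from .harmonization import (
    HarmonizationConfig,
    build_protected_design,
    combat_apply,
    combat_fit,
    flag_outliers,
    ks_batch_assessment,
)
from .segmentation import SegmentationParams, segment_lung
from .volume import load_mask, load_volume, save_mask, save_volume


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, scan_id: str | None = None, code: str = "stage_failure"):
        self.stage = stage
        self.scan_id = scan_id
        self.code = code
        where = f" (scan {scan_id})" if scan_id else ""
        super().__init__(f"[{code}] stage {stage!r}{where}: {message}")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" or "nifti"
    out_dir: str = "run"
    seed: int = 0
    window_mm: tuple[float, ...] = (4.0, 8.0, 20.0)
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    segmentation: dict = field(default_factory=dict)  # SegmentationParams overrides
    lattice: dict = field(default_factory=dict)  # LatticeFeatureExtractor overrides
    harmonization: dict = field(default_factory=dict)  # HarmonizationConfig overrides
    k: str | int = "auto"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_resamples: int = 250
    subsample_frac: float = 0.8
    entanglement_L: float = 1.5
    entanglement_untangle: str = "step2side"
    independent_n_scans: int | None = None
    save_volumes: bool = False
    # nifti mode inputs
    scans: list[dict] = field(default_factory=list)  # {path, mask_path?, scan_id, kernel}
    covariates_csv: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _extract_features_stage(cfg: PipelineConfig, out: Path) -> tuple[dict[float, Path], Path]:
    """Segment and extract per-scan features; cached via the CSV files."""
    feat_paths = {w: out / f"features_w{w:g}.csv" for w in cfg.window_mm}
    cov_path = out / "covariates.csv"
    if cov_path.exists() and all(p.exists() for p in feat_paths.values()):
        return feat_paths, cov_path

    if cfg.mode == "synthetic":
        cohort_cfg = synthetic.CohortConfig(seed=cfg.seed, **cfg.cohort)
        scans, covariates = synthetic.generate_cohort(cohort_cfg)
        masks = {}
        seg_params = SegmentationParams(**cfg.segmentation)
        for s in scans:
            try:
                masks[(s.scan_id, s.kernel_label)] = segment_lung(s.volume, seg_params)
            except ValueError as e:
                raise PipelineError("segment", str(e), scan_id=s.scan_id, code="segmentation_failed")
        if cfg.save_volumes:
            vol_dir = out / "volumes"
            vol_dir.mkdir(parents=True, exist_ok=True)
            for s in scans:
                save_volume(s.volume, str(vol_dir / f"{s.scan_id}_{s.kernel_label}.nii.gz"))
                save_mask(
                    masks[(s.scan_id, s.kernel_label)],
                    s.volume.spacing,
                    str(vol_dir / f"{s.scan_id}_{s.kernel_label}_mask.nii.gz"),
                )
        scan_list = [(s.volume, masks[(s.scan_id, s.kernel_label)], s.scan_id, s.kernel_label) for s in scans]
    elif cfg.mode == "nifti":
        if not cfg.scans or cfg.covariates_csv is None:
            raise PipelineError("ingest", "nifti mode requires scans and covariates_csv", code="bad_config")
        covariates = pd.read_csv(cfg.covariates_csv)
        seg_params = SegmentationParams(**cfg.segmentation)
        scan_list = []
        for entry in cfg.scans:
            vol = load_volume(entry["path"], scan_id=entry["scan_id"])
            if entry.get("mask_path"):
                mask = load_mask(entry["mask_path"], scan_id=entry["scan_id"])
            else:
                mask = segment_lung(vol, seg_params)
            scan_list.append((vol, mask, entry["scan_id"], entry["kernel"]))
    else:
        raise PipelineError("config", f"unknown mode {cfg.mode!r}", code="bad_config")

    for w in cfg.window_mm:
        extractor = LatticeFeatureExtractor(window_mm=w, **cfg.lattice)
        rows = []
        for vol, mask, scan_id, kernel in scan_list:
            try:
                fv = extractor.extract_scan(vol, mask, kernel_label=kernel)
            except ValueError as e:
                raise PipelineError("extract", str(e), scan_id=scan_id, code="extraction_failed")
            row = {"scan_id": scan_id, "kernel": kernel, "window_mm": w,
                   "n_windows_used": fv.n_windows_used}
            row.update(fv.values)
            rows.append(row)
        _write_csv(pd.DataFrame(rows), feat_paths[w])
    _write_csv(covariates, cov_path)
    return feat_paths, cov_path


def _fit_combat(cfg: PipelineConfig, feat_path: Path, cov_path: Path):
    """Deterministically (re)fit ComBat from the stage files.

    Returns (model, protected design DataFrame, screened working table,
    outlier flags).  Cheap relative to feature extraction, so the
    mapping stage refits from disk instead of carrying state across
    stage boundaries.
    """
    features = pd.read_csv(feat_path)
    covariates = pd.read_csv(cov_path)
    merged = features.merge(covariates, on=["scan_id", "kernel"], how="left", validate="one_to_one")
    hcfg = HarmonizationConfig(**cfg.harmonization)
    flags = flag_outliers(merged, merged, hcfg)
    work = merged.loc[~flags.flagged.to_numpy()].reset_index(drop=True) if hcfg.drop_outliers else merged
    model, design = combat_fit(work.rename(columns={"kernel": "batch"}), covariates=work, config=hcfg)
    return model, design, work, flags


def _harmonize_stage(cfg: PipelineConfig, out: Path, feat_path: Path, cov_path: Path, w: float) -> Path:
    harm_path = out / f"harmonized_w{w:g}.csv"
    ks_path = out / f"ks_report_w{w:g}.csv"
    if harm_path.exists() and ks_path.exists():
        return harm_path
    hcfg = HarmonizationConfig(**cfg.harmonization)
    model, design, work, flags = _fit_combat(cfg, feat_path, cov_path)
    ks_before = ks_batch_assessment(work.rename(columns={"kernel": "batch"}), config=hcfg)
    harmonized = combat_apply(model, work.rename(columns={"kernel": "batch"}), design=design)
    harmonized = harmonized.rename(columns={"batch": "kernel"})
    ks_after = ks_batch_assessment(harmonized.rename(columns={"kernel": "batch"}), config=hcfg)
    ks = ks_before.merge(ks_after, on="feature", suffixes=("_before", "_after"))
    harmonized["outlier_dropped_n"] = flags.n_flagged
    _write_csv(harmonized, harm_path)
    _write_csv(ks, ks_path)
    return harm_path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    feat_paths, cov_path = _extract_features_stage(config, out)
    artifacts.extend(feat_paths.values())
    artifacts.append(cov_path)

    entanglements: dict[str, float] = {}
    for w in config.window_mm:
        harm_path = _harmonize_stage(config, out, feat_paths[w], cov_path, w)
        artifacts.append(harm_path)
        artifacts.append(out / f"ks_report_w{w:g}.csv")
        harmonized = pd.read_csv(harm_path)
        dendrograms = {}
        models = {}
        for kernel in sorted(harmonized["kernel"].unique()):
            sub = harmonized[harmonized["kernel"] == kernel].reset_index(drop=True)
            if config.k == "auto":
                kernel_tag = sum(ord(c) for c in kernel) % 97  # stable across processes
                seed_k = (config.seed * 1009 + int(w * 8) + kernel_tag) % (2**31 - 1)
                # small cohorts cannot support the full scanned range
                k_range = tuple(k for k in config.k_range if k <= len(sub) - 1)
                if not k_range:
                    raise PipelineError(
                        "cluster", f"cohort too small to scan K at W={w:g}", code="too_few_scans"
                    )
                res = consensus_select_k(
                    sub,
                    k_range=k_range,
                    n_resamples=config.n_resamples,
                    subsample_frac=config.subsample_frac,
                    seed=seed_k,
                )
                k = res.selected_k
                cons_path = out / f"consensus_w{w:g}_{kernel}.json"
                cons_path.write_text(
                    json.dumps(
                        {
                            "selected_k": res.selected_k,
                            "areas": {str(kk): res.areas[kk] for kk in res.areas},
                            "deltas": {str(kk): res.deltas[kk] for kk in res.deltas},
                            "n_resamples": res.n_resamples,
                            "subsample_frac": res.subsample_frac,
                            "seed": res.seed,
                        },
                        indent=2,
                        sort_keys=True,
                    )
                )
                artifacts.append(cons_path)
            else:
                k = int(config.k)
            dend = hierarchical_cluster(sub)
            assignments = cut_clusters(dend, k)
            dendrograms[kernel] = dend
            models[kernel] = fit_centroids(sub, assignments)
            assign_df = pd.DataFrame({"scan_id": sub["scan_id"], "cluster": assignments})
            assign_path = out / f"assignments_w{w:g}_{kernel}.csv"
            _write_csv(assign_df, assign_path)
            artifacts.append(assign_path)
            cov_k = sub  # harmonized frame still carries the covariates
            table = build_association_table(assignments, cov_k)
            tab_path = out / f"associations_w{w:g}_{kernel}.csv"
            _write_csv(table, tab_path)
            artifacts.append(tab_path)
        kernels = sorted(dendrograms)
        if len(kernels) == 2:
            a, b = kernels
            common = set(dendrograms[a].labels) & set(dendrograms[b].labels)
            if common != set(dendrograms[a].labels) or common != set(dendrograms[b].labels):
                # outlier dropping can remove a scan from one kernel only;
                # entanglement needs identical leaf sets, so re-cluster on
                # the intersection
                dd = {}
                for kk in kernels:
                    sub = harmonized[
                        (harmonized["kernel"] == kk) & (harmonized["scan_id"].isin(common))
                    ].reset_index(drop=True)
                    dd[kk] = hierarchical_cluster(sub)
                dendrograms = dd
            ent = entanglement(
                dendrograms[a],
                dendrograms[b],
                L=config.entanglement_L,
                untangle=config.entanglement_untangle,
            )
            entanglements[f"w{w:g}"] = ent.coefficient

        if config.independent_n_scans:
            mapped_path = out / f"mapped_w{w:g}.csv"
            if not mapped_path.exists():
                ind_cfg_kwargs = dict(config.cohort)
                ind_cfg_kwargs["n_scans"] = config.independent_n_scans
                ind_cfg_kwargs["include_obstruction"] = True
                ind_cfg = synthetic.CohortConfig(seed=(config.seed + 7919) % (2**31 - 1), **ind_cfg_kwargs)
                ind_scans, ind_cov = synthetic.generate_cohort(ind_cfg)
                seg_params = SegmentationParams(**config.segmentation)
                extractor = LatticeFeatureExtractor(window_mm=w, **config.lattice)
                rows = []
                for s in ind_scans:
                    if s.kernel_label != "medium":
                        continue
                    fv = extractor.extract_scan(s.volume, segment_lung(s.volume, seg_params), s.kernel_label)
                    row = {"scan_id": s.scan_id}
                    row.update(fv.values)
                    rows.append(row)
                ind_feat = pd.DataFrame(rows)
                ind_cov_m = ind_cov[ind_cov["kernel"] == "medium"].reset_index(drop=True)
                # harmonize the independent cohort with the training-fit
                # ComBat model before mapping, as the centroids live in
                # harmonized feature space
                model, design, _, _ = _fit_combat(config, feat_paths[w], cov_path)
                hcfg = HarmonizationConfig(**config.harmonization)
                ind_design = build_protected_design(ind_cov_m, hcfg.protected_variables)
                ind_design = ind_design.reindex(columns=design.columns, fill_value=0.0)
                ind_harm = ind_feat.copy()
                ind_harm["batch"] = "medium"
                ind_harm = combat_apply(model, ind_harm, design=ind_design)
                mapped = map_clusters(models["medium"], ind_harm)
                mapped_df = pd.DataFrame({"scan_id": ind_feat["scan_id"], "cluster": mapped})
                _write_csv(mapped_df, mapped_path)
                if len(np.unique(mapped)) >= 2:
                    tab = build_association_table(mapped, ind_cov_m)
                else:
                    warnings.warn(
                        f"all mapped scans fell in one cluster at W={w:g}; association table is empty"
                    )
                    tab = pd.DataFrame()
                _write_csv(tab, out / f"associations_mapped_w{w:g}.csv")
            artifacts.append(mapped_path)
            artifacts.append(out / f"associations_mapped_w{w:g}.csv")

    ent_path = out / "entanglement.json"
    ent_path.write_text(json.dumps(entanglements, indent=2, sort_keys=True))
    artifacts.append(ent_path)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts)) if p.exists()
        },
        "entanglement": entanglements,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
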