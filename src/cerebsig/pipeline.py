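"""End-to-end orchestration: simulate → load → adjust → embed → classify →
symptom-map, with a deterministic run manifest.

The manifest records, per stage, the parameters, input and output files and
their SHA-256 checksums.  It contains no timestamps, so two runs of the same
config and seed produce bit-identical manifests; wall times go to the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adjustment as adj
from . import classification as clf
from . import embedding as emb
from . import io as cio
from . import symptom as sym
from . import synthetic as syn
from .config import CONTROL_GROUP, SimulationConfig
from .errors import ConfigurationError, PipelineError

log = logging.getLogger("cerebsig")


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-serializable."""

    out_dir: str = "cerebsig_run"
    # either simulate a cohort ...
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # ... or point at existing files
    map_paths: list[str] = field(default_factory=list)
    table_path: str | None = None
    atlas_path: str | None = None

    mask_source: str = "atlas-cortical"
    mask_threshold: float = 0.1
    apply_brain_correction: bool = True
    controls_only_regression: bool = False
    severity_floor_frac: float = 1e-3
    classifier_mode: str = "shrinkage"
    alpha: float = 0.05
    sphere_radius_mm: float = 6.0
    n_maxima: int = 10
    focus_group: str | None = None          # default: 2nd subtype (SCA3 analog)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.sphere_radius_mm <= 0:
            raise ConfigurationError("sphere_radius_mm must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def validate_paths(self) -> None:
        if self.simulate:
            return
        missing = [p for p in [*self.map_paths, self.table_path] if p is None
                   or not Path(p).exists()]
        if self.mask_source == "atlas-cortical":
            if self.atlas_path is None or not Path(self.atlas_path).exists():
                raise ConfigurationError(
                    "atlas-cortical mask requires an existing atlas_path")
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "stages": {}}
    written: dict[str, list[str]] = {}

    def record(stage: str, **params):
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        return t0

    def finish(stage: str, t0: float, outputs: list[Path], params: dict | None = None):
        manifest["stages"][stage] = {
            "parameters": params or {},
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
        }
        written[stage] = [str(p) for p in outputs]
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    try:
        # ---- simulate / load ------------------------------------------------
        if config.simulate:
            t0 = record("simulate")
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                sim_cfg = SimulationConfig.from_dict(
                    {**sim_cfg.to_dict(), "seed": config.seed})
            cohort_sim = syn.simulate(sim_cfg)
            sim_dir = out / "simulated"
            paths = syn.write_cohort(cohort_sim, sim_dir)
            outputs = [Path(p) for p in paths["maps"]]
            outputs += [Path(paths["atlas"]), Path(paths["table"]), Path(paths["truth"])]
            outputs.append(sim_dir / "atlas_regions.tsv")
            finish("simulate", t0, outputs,
                   {"n_clipped_voxels": paths["n_clipped_voxels"]})
            map_paths = paths["maps"]
            table_path, atlas_path = paths["table"], paths["atlas"]
        else:
            map_paths = config.map_paths
            table_path, atlas_path = config.table_path, config.atlas_path

        t0 = record("load")
        maps, table, atlas = cio.load_cohort(map_paths, table_path, atlas_path)
        mask = cio.gm_mask(maps=maps, atlas=atlas, source=config.mask_source,
                           threshold=config.mask_threshold,
                           control_ids=table.loc[table.group == CONTROL_GROUP,
                                                 "subject_id"])
        finish("load", t0, [], {"n_subjects": len(maps),
                                "mask_voxels": mask.n_voxels,
                                "mask_source": mask.source})

        # ---- adjust ---------------------------------------------------------
        t0 = record("adjust")
        result = adj.run_adjustment(
            maps, table, mask,
            apply_brain_correction=config.apply_brain_correction,
            controls_only_regression=config.controls_only_regression,
            severity_floor_frac=config.severity_floor_frac)
        sev_path = out / "severity.tsv"
        result.severity_table.to_csv(sev_path, sep="\t", index=False)
        finish("adjust", t0, [sev_path],
               {"n_flagged": int(result.severity_table.near_zero_flag.sum())})

        # ---- embed ----------------------------------------------------------
        t0 = record("embed")
        ids = table.subject_id.tolist()
        X_unc = np.array([result.degeneration[s].values for s in ids])
        emb_unc = emb.embed_mds(X_unc, dims=2, correction_state="uncorrected")
        pat_ids = [s for s in ids if s in result.pattern]
        emb_paths = []
        coords = pd.DataFrame(emb_unc.coordinates, columns=["dim1", "dim2"])
        coords.insert(0, "subject_id", ids)
        coords["state"] = "uncorrected"
        frames = [coords]
        emb_cor = None
        if len(pat_ids) >= 3:
            X_cor = np.array([result.pattern[s].values for s in pat_ids])
            emb_cor = emb.embed_mds(X_cor, dims=2, correction_state="corrected")
            c2 = pd.DataFrame(emb_cor.coordinates, columns=["dim1", "dim2"])
            c2.insert(0, "subject_id", pat_ids)
            c2["state"] = "corrected"
            frames.append(c2)
        emb_path = out / "embedding.tsv"
        pd.concat(frames, ignore_index=True).to_csv(emb_path, sep="\t", index=False)
        emb_paths.append(emb_path)
        finish("embed", t0, emb_paths, {
            "uncorrected_variance_fractions": emb_unc.variance_fractions.tolist(),
            "corrected_variance_fractions":
                emb_cor.variance_fractions.tolist() if emb_cor else None})

        # ---- classify -------------------------------------------------------
        t0 = record("classify")
        report = clf.run_classification_suite(
            result, table, clf.ClassifierConfig(mode=config.classifier_mode))
        rep_path = out / "classification.tsv"
        report.to_frame().to_csv(rep_path, sep="\t", index=False)
        per_path = out / "classification_per_subject.tsv"
        report.per_subject_frame().to_csv(per_path, sep="\t", index=False)
        finish("classify", t0, [rep_path, per_path],
               {"mode": config.classifier_mode})

        # ---- symptom-map ----------------------------------------------------
        t0 = record("symptom_map")
        patients = table[table.group != CONTROL_GROUP]
        sev_by_id = {s: result.severity[s].severity for s in table.subject_id}
        stats_ = sym.severity_group_stats(sev_by_id, table)
        pat_maps = [m for m in maps if m.subject_id in set(patients.subject_id)]
        # correlation maps use the brain-size-scaled (not severity-corrected) maps
        scaled_maps = [cio.GrayMatterMap(
            m.subject_id, _unmask(result.scaled[m.subject_id], mask), m.affine)
            for m in pat_maps]
        sara = dict(zip(table.subject_id, table.sara))
        cmap = sym.correlation_map(scaled_maps, sara, mask, alpha=config.alpha)
        peaks = sym.find_local_maxima(cmap, k=config.n_maxima, atlas=atlas,
                                      radius_mm=config.sphere_radius_mm)
        focus = config.focus_group
        if focus is None:
            subs = [g for g in table.group.unique() if g != CONTROL_GROUP]
            focus = subs[min(1, len(subs) - 1)]
        outputs = []
        deg = {s: result.degeneration[s].values for s in patients.subject_id}
        if len(peaks.peaks):
            contrast = sym.sphere_contrast(peaks, deg, mask, maps[0].affine,
                                           table, focus,
                                           radius_mm=config.sphere_radius_mm)
            cpath = out / "sphere_contrasts.tsv"
            contrast.table.to_csv(cpath, sep="\t", index=False)
            outputs.append(cpath)
        pk_path = out / "correlation_peaks.tsv"
        peaks.peaks.to_csv(pk_path, sep="\t", index=False)
        outputs.append(pk_path)
        roi_df = None
        if atlas is not None:
            cf = dict(zip(result.severity_table.subject_id,
                          result.severity_table.correction_factor))
            roi_df = sym.nucleus_roi_volumes(maps, table, atlas, cf)
            roi_path = out / "nucleus_rois.tsv"
            roi_df.to_csv(roi_path, sep="\t", index=False)
            outputs.append(roi_path)
        stats_path = out / "cohort_stats.json"
        with open(stats_path, "w") as fh:
            json.dump({
                "anova_F": stats_.anova_F, "anova_df": list(stats_.anova_df),
                "anova_p": stats_.anova_p,
                "severity_sara_r": stats_.severity_sara_r,
                "severity_sara_p": stats_.severity_sara_p,
                "ancova_F": stats_.ancova_F, "ancova_df": list(stats_.ancova_df),
                "ancova_p": stats_.ancova_p,
                "n_significant_voxels": int(cmap.significant.sum()),
                "n_peaks": len(peaks.peaks)}, fh, indent=2, sort_keys=True)
        outputs.append(stats_path)
        finish("symptom_map", t0, outputs,
               {"alpha": config.alpha, "focus_group": focus,
                "sphere_radius_mm": config.sphere_radius_mm})
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "startup"
        raise PipelineError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _unmask(values: np.ndarray, mask) -> np.ndarray:
    vol = np.zeros(mask.mask.shape)
    vol[mask.mask] = values
    return vol
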