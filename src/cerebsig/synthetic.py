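"""Synthetic cohorts of modulated gray-matter maps with known ground truth.

The generator emulates the statistical structure a severity-vs-pattern
analysis assumes: each subtype has a fixed unit-mean spatial degeneration
signature, each patient a scalar severity drawn from the group's distribution,
cerebellar size is multiplicatively coupled to cerebrum volume, voxel noise is
additive Gaussian, and the ataxia score is linearly coupled to true
degeneration in motor-flagged regions.  Because the generative model is the
same decomposition the analysis performs (template minus severity times
unit-mean pattern), the factorization is exactly recoverable in the noiseless,
unit-brain-factor limit — the key round-trip property the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import CONTROL_GROUP, SimulationConfig
from .errors import ConfigurationError

NUCLEUS_NAMES = ("dentate", "pontine", "inferior_olive")


@dataclass
class SyntheticAtlas:
    """Integer parcellation of a blob-shaped foreground.

    ``label_volume`` holds region ids (0 = background).  ``region_table`` maps
    each id to a name, a class (``cortical`` or ``nucleus``) and a motor flag.
    The cortical regions stand in for cerebellar lobules; the three nucleus
    regions stand in for the dentate, pontine and inferior-olive ROIs.
    """

    label_volume: np.ndarray
    region_table: pd.DataFrame          # columns: region_id, name, region_class, motor
    affine: np.ndarray

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_volume)) - {0}
        known = set(self.region_table["region_id"])
        if not labels <= known:
            raise ConfigurationError(f"labels {labels - known} missing from region table")
        classes = self.region_table.groupby("region_class")["region_id"].apply(set)
        cort = classes.get("cortical", set())
        nuc = classes.get("nucleus", set())
        if cort & nuc:
            raise ConfigurationError("cortical and nucleus labels overlap")
        if not self.region_table["motor"].any():
            raise ConfigurationError("at least one region must be motor-flagged")

    @property
    def cortical_ids(self) -> np.ndarray:
        t = self.region_table
        return t.loc[t.region_class == "cortical", "region_id"].to_numpy()

    @property
    def nucleus_ids(self) -> np.ndarray:
        t = self.region_table
        return t.loc[t.region_class == "nucleus", "region_id"].to_numpy()

    @property
    def motor_ids(self) -> np.ndarray:
        t = self.region_table
        return t.loc[t.motor, "region_id"].to_numpy()

    def cortical_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, self.cortical_ids)

    def motor_mask(self) -> np.ndarray:
        return np.isin(self.label_volume, self.motor_ids)

    def foreground(self) -> np.ndarray:
        return self.label_volume > 0


@dataclass
class SubtypeSignature:
    """A subtype's spatial degeneration weight map, unit mean over cortex."""

    subtype: str
    pattern: np.ndarray                 # nonnegative; defined on the foreground

    def cortical_mean(self, atlas: SyntheticAtlas) -> float:
        return float(self.pattern[atlas.cortical_mask()].mean())


@dataclass
class SimulatedCohort:
    """Generated maps plus the clinical table and the hidden ground truth."""

    maps: list                          # list[GrayMatterMap]
    table: pd.DataFrame                 # subject_id, group, sara, cerebrum_volume
    truth: pd.DataFrame                 # subject_id, group, severity, brain_factor
    template: np.ndarray                # noise-free control anatomy
    atlas: SyntheticAtlas
    signatures: dict[str, SubtypeSignature]
    n_clipped_voxels: int = 0


def _affine(config: SimulationConfig) -> np.ndarray:
    aff = np.diag([config.voxel_size_mm] * 3 + [1.0])
    return aff


def make_atlas(config: SimulationConfig) -> SyntheticAtlas:
    """Build a connected blob foreground partitioned into labeled regions.

    The foreground is an ellipsoid; three small spheres near its inferior pole
    become the nucleus regions, and the remaining voxels are split into
    cortical regions by a Voronoi partition of seed voxels.  The first
    ``n_motor_regions`` cortical regions are motor-flagged.
    """
    rng = np.random.default_rng(config.seed)
    nx, ny, nz = config.grid_shape
    n_cortical = config.n_regions - 3
    ii, jj, kk = np.indices(config.grid_shape)
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    radii = np.array([nx, ny, nz]) * 0.38
    blob = (((ii - center[0]) / radii[0]) ** 2
            + ((jj - center[1]) / radii[1]) ** 2
            + ((kk - center[2]) / radii[2]) ** 2) <= 1.0
    if blob.sum() < config.n_regions:
        raise ConfigurationError(
            f"{config.n_regions} regions do not fit in a foreground of "
            f"{int(blob.sum())} voxels")

    labels = np.zeros(config.grid_shape, dtype=np.int32)

    # Nucleus stand-ins: small spheres along the inferior (low-k) pole.
    nuc_rad = max(1.0, min(nx, ny, nz) * 0.08)
    offsets = [(-radii[0] * 0.4, 0.0), (0.0, 0.0), (radii[0] * 0.4, 0.0)]
    for idx, (dx, dy) in enumerate(offsets):
        c = np.array([center[0] + dx, center[1] + dy, center[2] - radii[2] * 0.6])
        sph = ((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2) <= nuc_rad ** 2
        sph &= blob
        labels[sph] = n_cortical + 1 + idx
    cortex = blob & (labels == 0)
    if cortex.sum() < n_cortical:
        raise ConfigurationError("cortical foreground too small for requested regions")

    # Voronoi partition of the cortex into lobule stand-ins.
    cvox = np.argwhere(cortex)
    seed_idx = rng.choice(len(cvox), size=n_cortical, replace=False)
    seeds = cvox[seed_idx].astype(float)
    d2 = ((cvox[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    labels[tuple(cvox.T)] = assign + 1

    rows = []
    for r in range(1, n_cortical + 1):
        rows.append({"region_id": r, "name": f"lobule_{r:02d}",
                     "region_class": "cortical",
                     "motor": r <= config.n_motor_regions})
    for idx, name in enumerate(NUCLEUS_NAMES):
        rows.append({"region_id": n_cortical + 1 + idx, "name": name,
                     "region_class": "nucleus", "motor": False})
    table = pd.DataFrame(rows)
    # Drop any cortical region that ended up empty (possible when a nucleus
    # sphere swallowed a seed's whole cell); guaranteed non-empty by seeding
    # from cortex voxels, but keep the invariant explicit.
    present = set(np.unique(labels)) - {0}
    table = table[table.region_id.isin(present)].reset_index(drop=True)
    if not (table.region_class == "nucleus").sum() == 3:
        raise ConfigurationError("nucleus regions collapsed; enlarge the grid")
    if not table.motor.any():
        raise ConfigurationError("all motor regions empty; enlarge the grid")
    return SyntheticAtlas(labels, table, _affine(config))


def make_signatures(atlas: SyntheticAtlas, subtypes: list[str],
                    config: SimulationConfig) -> list[SubtypeSignature]:
    """Draw one unit-mean degeneration signature per subtype.

    Each signature is region-wise constant (log-normal weights) with each
    subtype's "own" cortical regions elevated and motor regions multiplied by
    the subtype's motor emphasis, optionally smoothed, then normalized to unit
    mean over the cortical mask.  Distinct elevated-region sets keep pairwise
    signatures non-proportional.
    """
    if len(subtypes) < 2:
        raise ConfigurationError("need at least 2 subtypes for distinct signatures")
    rng = np.random.default_rng(config.seed + 1)
    cort_ids = atlas.cortical_ids
    nuc_ids = atlas.nucleus_ids
    motor_ids = set(atlas.motor_ids)
    cmask = atlas.cortical_mask()
    fg = atlas.foreground()

    # Partition non-motor cortical regions round-robin into subtype-specific
    # "own" sets so elevated regions are disjoint across subtypes.
    nonmotor = [r for r in cort_ids if r not in motor_ids]
    own: dict[str, set[int]] = {s: set() for s in subtypes}
    for i, r in enumerate(nonmotor):
        own[subtypes[i % len(subtypes)]].add(r)

    sigs = []
    for s in subtypes:
        weights = {}
        for r in cort_ids:
            w = float(rng.lognormal(mean=0.0, sigma=config.signature_region_sd))
            if r in own[s]:
                w += config.signature_boost
            if r in motor_ids:
                w *= config.motor_emphasis.get(s, 1.0)
            weights[r] = w
        nscale = config.nucleus_scale.get(s, 1.0)
        for r in nuc_ids:
            weights[r] = nscale * float(rng.lognormal(0.0, config.signature_region_sd))
        pat = np.zeros(atlas.label_volume.shape)
        for r, w in weights.items():
            pat[atlas.label_volume == r] = w
        if config.signature_smooth_sigma > 0:
            sm = ndimage.gaussian_filter(pat, config.signature_smooth_sigma)
            norm = ndimage.gaussian_filter(fg.astype(float), config.signature_smooth_sigma)
            pat = np.where(fg, sm / np.maximum(norm, 1e-12), 0.0)
        pat = np.clip(pat, 0.0, None)
        pat /= pat[cmask].mean()
        sigs.append(SubtypeSignature(s, pat))
    return sigs


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Severity draw truncated to [0, 1)."""
    if sd == 0:
        return np.full(size, np.clip(mean, 0.0, np.nextafter(1.0, 0.0)))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def make_template(atlas: SyntheticAtlas, config: SimulationConfig) -> np.ndarray:
    """Noise-free control anatomy: flat baseline plus an optional smooth field."""
    fg = atlas.foreground()
    tpl = np.where(fg, config.template_baseline, 0.0)
    if config.template_variation > 0:
        rng = np.random.default_rng(config.seed + 2)
        field_ = ndimage.gaussian_filter(rng.standard_normal(fg.shape), 3.0)
        field_ /= max(np.abs(field_[fg]).max(), 1e-12)
        tpl = np.where(fg, tpl * (1.0 + config.template_variation * field_), 0.0)
    return tpl


def simulate_cohort(atlas: SyntheticAtlas, signatures: list[SubtypeSignature],
                    config: SimulationConfig) -> SimulatedCohort:
    """Generate gray-matter maps and the clinical table for a full cohort.

    Returns a :class:`SimulatedCohort`; ``cohort.maps`` and ``cohort.table``
    are the analysis inputs, ``cohort.truth`` the hidden per-subject severity
    and brain factor used by round-trip tests.
    """
    from .io import GrayMatterMap  # deferred to avoid an import cycle

    sig_by_name = {s.subtype: s for s in signatures}
    for g in config.subtypes:
        if g not in sig_by_name:
            raise ConfigurationError(f"no signature for subtype {g!r}")
    if CONTROL_GROUP not in config.group_sizes:
        raise ConfigurationError("group_sizes must include the control group")

    rng = np.random.default_rng(config.seed + 3)
    tpl = make_template(atlas, config)
    fg = atlas.foreground()
    motor = atlas.motor_mask()

    maps, rows, truth_rows = [], [], []
    n_clipped = 0
    for group, n in config.group_sizes.items():
        if group == CONTROL_GROUP:
            sev = np.zeros(n)
        else:
            sev = _truncated_normal(rng, config.severity_mean[group],
                                    config.severity_sd[group], n)
        cereb = rng.normal(config.brain_size_mean, config.brain_size_sd, size=n)
        for i in range(n):
            sid = f"{group}_{i + 1:03d}"
            factor = 1.0 + config.brain_coupling * (cereb[i] - config.brain_size_mean) / config.brain_size_mean
            if group == CONTROL_GROUP:
                clean = tpl
                motor_deg = 0.0
            else:
                pat = sig_by_name[group].pattern
                if config.pattern_jitter_sd > 0:
                    # subject-specific deviation from the group signature:
                    # smooth, zero mean over cortex, scales with severity
                    eta = ndimage.gaussian_filter(
                        rng.standard_normal(fg.shape),
                        config.pattern_jitter_smooth_sigma)
                    cmask_ = np.isin(atlas.label_volume, atlas.cortical_ids)
                    eta = eta - eta[cmask_].mean()
                    eta *= config.pattern_jitter_sd / eta[cmask_].std()
                    pat = pat + np.where(fg, eta, 0.0)
                clean = tpl - sev[i] * pat
                motor_deg = float(sev[i] * pat[motor].mean())
            data = factor * clean
            if config.noise_sd > 0:
                noise = rng.standard_normal(fg.shape)
                if config.noise_smooth_sigma > 0:
                    noise = ndimage.gaussian_filter(noise, config.noise_smooth_sigma)
                    noise /= noise[fg].std()
                data = data + np.where(fg, config.noise_sd * noise, 0.0)
            n_clipped += int((data < 0).sum())
            data = np.clip(data, 0.0, None)
            data = np.where(fg, data, 0.0)
            sara = config.sara_intercept + config.sara_slope * motor_deg
            if config.sara_noise_sd > 0:
                sara += rng.normal(0.0, config.sara_noise_sd)
            sara = float(np.clip(sara, 0.0, 40.0))
            maps.append(GrayMatterMap(sid, data, atlas.affine.copy()))
            rows.append({"subject_id": sid, "group": group, "sara": sara,
                         "cerebrum_volume": float(cereb[i])})
            truth_rows.append({"subject_id": sid, "group": group,
                               "severity": float(sev[i]),
                               "brain_factor": float(factor),
                               "motor_degeneration": motor_deg})
    return SimulatedCohort(maps, pd.DataFrame(rows), pd.DataFrame(truth_rows),
                           tpl, atlas, sig_by_name, n_clipped)


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Convenience one-call generator: atlas → signatures → cohort."""
    atlas = make_atlas(config)
    sigs = make_signatures(atlas, config.subtypes, config)
    return simulate_cohort(atlas, sigs, config)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path,
                 compress: bool = True) -> dict[str, object]:
    """Write maps + atlas as NIfTI and the clinical table as TSV.

    Returns a manifest-style dict of written paths.
    """
    from .io import save_map, save_atlas, save_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    map_paths = []
    for m in cohort.maps:
        p = out / f"{m.subject_id}{ext}"
        save_map(m, p)
        map_paths.append(str(p))
    atlas_path = out / f"atlas{ext}"
    save_atlas(cohort.atlas, atlas_path)
    table_path = out / "cohort.tsv"
    save_table(cohort.table, table_path)
    truth_path = out / "truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    return {"maps": map_paths, "atlas": str(atlas_path),
            "table": str(table_path), "truth": str(truth_path),
            "n_clipped_voxels": cohort.n_clipped_voxels}
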