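"""Cohort statistics, nucleus ROI volumetry, and symptom-correlation mapping.

Covers: one-way ANOVA of severity across subtypes; severity-SARA Pearson
correlation; ANCOVA of severity by group with SARA as covariate; per-nucleus
ROI degeneration; the voxelwise SARA-intensity Pearson correlation map with
its significance mask; local maxima of |r|; and sphere-ROI contrasts of one
focus subtype against the pooled remaining patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import CONTROL_GROUP
from .errors import CerebsigError, ROIError
from .io import GrayMatterMap, MaskDefinition
from .synthetic import SyntheticAtlas


# --------------------------------------------------------------------------
# cohort-level statistics

@dataclass
class CohortStats:
    anova_F: float
    anova_df: tuple[int, int]
    anova_p: float
    severity_sara_r: float
    severity_sara_p: float
    ancova_F: float
    ancova_df: tuple[int, int]
    ancova_p: float
    degenerate: bool = False


def severity_group_stats(severities: Mapping[str, float], cohort: pd.DataFrame,
                         ) -> CohortStats:
    """ANOVA of severity across subtypes, severity-SARA r, and the ANCOVA
    of severity by group with the SARA score as covariate (patients only)."""
    df = cohort[cohort.group != CONTROL_GROUP].copy()
    df["severity"] = df.subject_id.map(severities)
    if df.severity.isna().any():
        raise CerebsigError("severity missing for some patients")
    groups = [g.severity.to_numpy(float) for _, g in df.groupby("group")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise CerebsigError("need >= 2 subtype groups with >= 2 members")
    if np.ptp(df.severity.to_numpy()) == 0:
        return CohortStats(0.0, (len(groups) - 1, len(df) - len(groups)), 1.0,
                           np.nan, np.nan, 0.0,
                           (len(groups) - 1, len(df) - len(groups) - 1), 1.0,
                           degenerate=True)

    F, p = stats.f_oneway(*groups)
    df1, df2 = len(groups) - 1, len(df) - len(groups)
    r, rp = stats.pearsonr(df.severity, df.sara)

    model = smf.ols("severity ~ C(group) + sara", data=df).fit()
    an = sm.stats.anova_lm(model, typ=2)
    row = an.loc["C(group)"]
    adf = (int(row.df), int(an.loc["Residual", "df"]))
    return CohortStats(float(F), (df1, df2), float(p), float(r), float(rp),
                       float(row.F), adf, float(row["PR(>F)"]))


# --------------------------------------------------------------------------
# nucleus ROI volumetry

def nucleus_roi_volumes(maps: Sequence[GrayMatterMap], cohort: pd.DataFrame,
                        atlas: SyntheticAtlas,
                        correction_factors: Mapping[str, float] | None = None,
                        ) -> pd.DataFrame:
    """Per-subject, per-nucleus-ROI brain-size-scaled mean intensity and
    degeneration (control mean minus subject), with per-ROI group F tests.

    Returns a long-format frame with columns: subject_id, group, roi,
    scaled_mean, degeneration; group-contrast F/p are attached in ``attrs``.
    """
    nuc = atlas.region_table[atlas.region_table.region_class == "nucleus"]
    if not len(nuc):
        raise ROIError("atlas has no nucleus regions")
    factors = correction_factors or {}
    group_of = dict(zip(cohort.subject_id, cohort.group))

    rows = []
    for m in maps:
        f = factors.get(m.subject_id, 1.0)
        for _, r in nuc.iterrows():
            roi = atlas.label_volume == r.region_id
            if not roi.any():
                raise ROIError(f"empty nucleus ROI {r['name']}")
            rows.append({"subject_id": m.subject_id,
                         "group": group_of[m.subject_id], "roi": r["name"],
                         "scaled_mean": float(m.data[roi].mean() * f)})
    df = pd.DataFrame(rows)
    ctrl = (df[df.group == CONTROL_GROUP].groupby("roi")["scaled_mean"].mean())
    df["degeneration"] = df.apply(lambda x: ctrl[x.roi] - x.scaled_mean, axis=1)

    contrasts = {}
    pat = df[df.group != CONTROL_GROUP]
    for roi, sub in pat.groupby("roi"):
        samples = [g.degeneration.to_numpy() for _, g in sub.groupby("group")]
        if len(samples) >= 2:
            F, p = stats.f_oneway(*samples)
            contrasts[roi] = {"F": float(F), "p": float(p)}
    df.attrs["group_contrasts"] = contrasts
    return df


# --------------------------------------------------------------------------
# SARA-voxel correlation map

@dataclass
class CorrelationMap:
    """Voxelwise Pearson r/p between the ataxia score and intensity."""

    r: np.ndarray                     # 3-D, NaN outside mask / dropped voxels
    p: np.ndarray
    significant: np.ndarray           # boolean 3-D, p < alpha within mask
    alpha: float
    n_subjects: int
    n_dropped_constant: int
    affine: np.ndarray


def correlation_map(maps: Sequence[GrayMatterMap], sara: Mapping[str, float],
                    mask: MaskDefinition, alpha: float = 0.05,
                    fdr: bool = False) -> CorrelationMap:
    """Vectorized voxelwise Pearson correlation with a t-transform p-value.

    Constant voxels (zero variance across subjects) have undefined r; they
    are dropped from the map and counted.  The significance mask is
    uncorrected at ``alpha`` by default; ``fdr`` switches to Benjamini-
    Hochberg.
    """
    n = len(maps)
    if n < 4:
        raise CerebsigError(f"correlation map needs >= 4 patients, got {n}")
    y = np.array([sara[m.subject_id] for m in maps], dtype=float)
    if np.ptp(y) == 0:
        raise CerebsigError("ataxia score has zero variance")
    X = np.array([m.data[mask.mask] for m in maps])        # subjects x voxels

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    const = X.max(axis=0) == X.min(axis=0)     # exactly constant across subjects
    sx[const] = 1.0                            # avoid 0/0; overwritten below
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Xc) / (sx * sy)
    r[const] = np.nan
    r = np.clip(r, -1.0, 1.0)
    dfree = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dfree / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), dfree)
    p[np.isclose(np.abs(r), 1.0)] = np.finfo(float).tiny
    p[const] = np.nan

    if fdr:
        ok = ~const
        rej = np.zeros_like(p, dtype=bool)
        if ok.any():
            rej[ok] = sm.stats.multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
        sig_flat = rej
    else:
        with np.errstate(invalid="ignore"):
            sig_flat = p < alpha
        sig_flat &= ~const

    shape = mask.mask.shape
    r_vol = np.full(shape, np.nan)
    p_vol = np.full(shape, np.nan)
    sig_vol = np.zeros(shape, dtype=bool)
    r_vol[mask.mask] = r
    p_vol[mask.mask] = p
    sig_vol[mask.mask] = sig_flat
    return CorrelationMap(r_vol, p_vol, sig_vol, alpha, n,
                          int(const.sum()), maps[0].affine.copy())


# --------------------------------------------------------------------------
# local maxima and sphere-ROI contrasts

@dataclass
class LocalMaximaSet:
    peaks: pd.DataFrame               # voxel i,j,k; world x,y,z; r; region
    k_requested: int
    min_separation_mm: float

    def __len__(self) -> int:
        return len(self.peaks)


def find_local_maxima(cmap: CorrelationMap, k: int = 10,
                      min_separation_mm: float | None = None,
                      atlas: SyntheticAtlas | None = None,
                      radius_mm: float = 6.0) -> LocalMaximaSet:
    """Greedy selection of 26-neighborhood maxima of |r| in the significant
    mask, in descending |r|, subject to a minimum pairwise separation
    (default twice the sphere radius)."""
    if min_separation_mm is None:
        min_separation_mm = 2.0 * radius_mm
    absr = np.where(cmap.significant, np.abs(np.nan_to_num(cmap.r)), -np.inf)
    cols = ["i", "j", "k", "x", "y", "z", "r", "region"]
    if k == 0 or not cmap.significant.any():
        return LocalMaximaSet(pd.DataFrame(columns=cols), k, min_separation_mm)
    localmax = (ndimage.maximum_filter(absr, size=3, mode="constant",
                                       cval=-np.inf) == absr)
    cand = np.argwhere(localmax & cmap.significant)
    vals = absr[tuple(cand.T)]
    order = np.argsort(vals)[::-1]
    cand = cand[order]

    world = (cmap.affine[:3, :3] @ cand.T).T + cmap.affine[:3, 3]
    chosen: list[int] = []
    for idx in range(len(cand)):
        if len(chosen) >= k:
            break
        if all(np.linalg.norm(world[idx] - world[c]) >= min_separation_mm
               for c in chosen):
            chosen.append(idx)
    rows = []
    for c in chosen:
        i, j, kk = cand[c]
        region = ""
        if atlas is not None:
            lab = int(atlas.label_volume[i, j, kk])
            t = atlas.region_table
            hit = t[t.region_id == lab]
            region = hit.iloc[0]["name"] if len(hit) else ""
        rows.append({"i": int(i), "j": int(j), "k": int(kk),
                     "x": world[c][0], "y": world[c][1], "z": world[c][2],
                     "r": float(cmap.r[i, j, kk]), "region": region})
    return LocalMaximaSet(pd.DataFrame(rows, columns=cols), k, min_separation_mm)


@dataclass
class SphereROIContrast:
    table: pd.DataFrame               # per peak: mean degeneration + t, p
    df: int
    radius_mm: float
    focus_group: str
    subject_means: pd.DataFrame = field(default_factory=pd.DataFrame)


def sphere_contrast(peaks: LocalMaximaSet,
                    degeneration: Mapping[str, np.ndarray],
                    mask: MaskDefinition, affine: np.ndarray,
                    cohort: pd.DataFrame, focus_group: str,
                    radius_mm: float = 6.0,
                    per_pair: bool = False) -> SphereROIContrast:
    """Mean degeneration in a sphere around each peak, per subject, and a
    pooled-variance two-sample t of the focus subtype against the remaining
    patients pooled (df = n_patients - 2).  ``per_pair`` adds a separate t
    against each other subtype instead of pooling them."""
    if not len(peaks.peaks):
        raise CerebsigError("no peaks to contrast")
    pat = cohort[cohort.group != CONTROL_GROUP]
    if focus_group not in set(pat.group):
        raise CerebsigError(f"focus group {focus_group!r} not in cohort")
    vox = np.argwhere(mask.mask)
    world = (affine[:3, :3] @ vox.T).T + affine[:3, 3]

    rows, mean_rows = [], []
    dfree = len(pat) - 2
    for p_idx, pk in peaks.peaks.iterrows():
        center = np.array([pk.x, pk.y, pk.z])
        inside = np.linalg.norm(world - center, axis=1) <= radius_mm
        if not inside.any():
            continue
        idx = np.flatnonzero(inside)
        focus_vals, other_vals = [], []
        for _, srow in pat.iterrows():
            v = float(degeneration[srow.subject_id][idx].mean())
            mean_rows.append({"peak": p_idx, "subject_id": srow.subject_id,
                              "group": srow.group, "mean_degeneration": v})
            (focus_vals if srow.group == focus_group else other_vals).append(v)
        t, pval = stats.ttest_ind(focus_vals, other_vals, equal_var=True)
        row = {"peak": p_idx, "x": pk.x, "y": pk.y, "z": pk.z,
               "region": pk.region, "r": pk.r,
               "n_voxels": int(inside.sum()),
               "t": float(t), "p": float(pval)}
        if per_pair:
            sub = pd.DataFrame(mean_rows)
            sub = sub[sub.peak == p_idx]
            fv = sub.loc[sub.group == focus_group, "mean_degeneration"]
            for g in sorted(set(pat.group) - {focus_group}):
                gv = sub.loc[sub.group == g, "mean_degeneration"]
                tg, pg = stats.ttest_ind(fv, gv, equal_var=True)
                row[f"t_vs_{g}"] = float(tg)
                row[f"p_vs_{g}"] = float(pg)
        rows.append(row)
    return SphereROIContrast(pd.DataFrame(rows), dfree, radius_mm, focus_group,
                             pd.DataFrame(mean_rows))
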