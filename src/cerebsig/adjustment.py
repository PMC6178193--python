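"""Brain-size scaling and the severity/pattern factorization of degeneration.

The pipeline stage this module implements:

1. Regress per-subject cerebellar gray-matter volume (sum of masked
   intensities times voxel volume) on cerebrum volume, across the cohort.
2. Scale each subject's map by (group-average cerebellar volume) / (predicted
   cerebellar volume), which zeroes the fitted brain-size dependence.
3. Average the scaled control maps into a control template.
4. Degeneration map = template - scaled subject map (masked; positive = loss).
5. Severity = mean degeneration over the mask; corrected pattern map =
   degeneration / severity, which has unit mean over the mask by construction.

Patients whose severity is indistinguishable from zero get no stable pattern;
they are flagged and excluded from pattern-space analyses rather than divided
by a near-zero number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CONTROL_GROUP
from .errors import RegressionError, ScalingError, TemplateError
from .io import GrayMatterMap, MaskDefinition


@dataclass
class BrainSizeModel:
    """OLS of cerebellar volume on cerebrum volume, plus the cohort average."""

    intercept: float
    slope: float
    mean_cerebellar_volume: float
    n_subjects: int

    def predict(self, cerebrum_volume: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(cerebrum_volume, dtype=float)

    def correction_factor(self, cerebrum_volume: float) -> float:
        """Factor the subject's map is multiplied by: average / predicted."""
        pred = float(self.predict(cerebrum_volume))
        if pred <= 0:
            raise ScalingError(f"non-positive predicted cerebellar volume {pred:g}")
        return self.mean_cerebellar_volume / pred


@dataclass
class DegenerationMap:
    """Control-mean-referenced loss map; defined on the mask only."""

    subject_id: str
    values: np.ndarray               # 1-D, one entry per masked voxel


@dataclass
class SeverityScore:
    subject_id: str
    severity: float                  # mean masked degeneration intensity
    flagged_near_zero: bool = False


@dataclass
class CorrectedPatternMap:
    """Degeneration divided by severity; unit mean over the mask."""

    subject_id: str
    values: np.ndarray


@dataclass
class AdjustmentResult:
    """Everything downstream stages need, keyed by table order."""

    model: BrainSizeModel | None
    template: np.ndarray                         # masked 1-D template values
    scaled: dict[str, np.ndarray]                # subject -> masked scaled map
    degeneration: dict[str, DegenerationMap]
    severity: dict[str, SeverityScore]
    pattern: dict[str, CorrectedPatternMap]      # flagged subjects absent
    severity_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def cerebellar_volume(gm: GrayMatterMap, mask: MaskDefinition) -> float:
    """Masked intensity integral in mm^3 (modulated VBM volume estimate)."""
    return float(gm.data[mask.mask].sum() * gm.voxel_volume_mm3())


def fit_brain_size_model(maps: Sequence[GrayMatterMap], cohort: pd.DataFrame,
                         mask: MaskDefinition, min_subjects: int = 3,
                         controls_only: bool = False) -> BrainSizeModel:
    """OLS fit of cerebellar volume on cerebrum volume.

    By default the regression uses all subjects; ``controls_only`` restricts
    it to the control group.
    """
    vols = {m.subject_id: cerebellar_volume(m, mask) for m in maps}
    df = cohort.copy()
    df["cereb_vol"] = df.subject_id.map(vols)
    fit_df = df[df.group == CONTROL_GROUP] if controls_only else df
    if len(fit_df) < min_subjects:
        raise RegressionError(
            f"brain-size regression needs >= {min_subjects} subjects, got {len(fit_df)}")
    if (df.cerebrum_volume <= 0).any():
        raise RegressionError("non-positive cerebrum volume in cohort")
    x = fit_df.cerebrum_volume.to_numpy(dtype=float)
    y = fit_df.cereb_vol.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in cerebrum volume")
    slope, intercept = np.polyfit(x, y, 1)
    return BrainSizeModel(float(intercept), float(slope),
                          float(np.mean(list(vols.values()))), len(fit_df))


def scale_map(gm: GrayMatterMap, model: BrainSizeModel,
              cerebrum_volume_mm3: float) -> GrayMatterMap:
    """Multiply a subject's map by the brain-size correction factor."""
    f = model.correction_factor(cerebrum_volume_mm3)
    return GrayMatterMap(gm.subject_id, gm.data * f, gm.affine.copy())


def control_template(scaled_controls: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise mean of the scaled control maps (masked 1-D vectors)."""
    if len(scaled_controls) < 1:
        raise TemplateError("no control subjects to form a template")
    return np.mean(scaled_controls, axis=0)


def degeneration_map(subject_id: str, scaled_values: np.ndarray,
                     template: np.ndarray) -> DegenerationMap:
    """template - subject, on the mask; positive values mean tissue loss."""
    if scaled_values.shape != template.shape:
        raise TemplateError("subject and template are on different masks")
    return DegenerationMap(subject_id, template - scaled_values)


def severity_and_pattern(dmap: DegenerationMap, template_mean: float,
                         severity_floor_frac: float = 1e-3,
                         ) -> tuple[SeverityScore, CorrectedPatternMap | None]:
    """Factor a degeneration map into scalar severity and unit-mean pattern.

    Severity below ``severity_floor_frac`` times the template mean is flagged:
    such subjects (typically controls or barely-affected patients) have no
    stable pattern and are excluded from pattern-space analyses.
    """
    sev = float(dmap.values.mean())
    floor = abs(severity_floor_frac * template_mean)
    if abs(sev) < floor:
        return SeverityScore(dmap.subject_id, sev, flagged_near_zero=True), None
    return (SeverityScore(dmap.subject_id, sev),
            CorrectedPatternMap(dmap.subject_id, dmap.values / sev))


def run_adjustment(maps: Sequence[GrayMatterMap], cohort: pd.DataFrame,
                   mask: MaskDefinition, apply_brain_correction: bool = True,
                   controls_only_regression: bool = False,
                   severity_floor_frac: float = 1e-3) -> AdjustmentResult:
    """Run the full stage on a cohort; see the module docstring for the steps."""
    m = mask.mask
    model = None
    factors = {sid: 1.0 for sid in cohort.subject_id}
    if apply_brain_correction:
        model = fit_brain_size_model(maps, cohort, mask,
                                     controls_only=controls_only_regression)
        cereb = dict(zip(cohort.subject_id, cohort.cerebrum_volume))
        factors = {sid: model.correction_factor(cereb[sid]) for sid in cohort.subject_id}

    scaled = {g.subject_id: g.data[m] * factors[g.subject_id] for g in maps}
    ctrl_ids = cohort.loc[cohort.group == CONTROL_GROUP, "subject_id"].tolist()
    if not ctrl_ids:
        raise TemplateError("cohort has no control subjects")
    template = control_template([scaled[s] for s in ctrl_ids])
    tmean = float(template.mean())

    degeneration, severity, pattern = {}, {}, {}
    rows = []
    for sid in cohort.subject_id:
        d = degeneration_map(sid, scaled[sid], template)
        sev, pat = severity_and_pattern(d, tmean, severity_floor_frac)
        degeneration[sid] = d
        severity[sid] = sev
        if pat is not None:
            pattern[sid] = pat
        rows.append({"subject_id": sid, "severity": sev.severity,
                     "relative_severity": sev.severity / tmean,
                     "correction_factor": factors[sid],
                     "near_zero_flag": sev.flagged_near_zero})
    return AdjustmentResult(model, template, scaled, degeneration, severity,
                            pattern, pd.DataFrame(rows))
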