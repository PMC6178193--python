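"""Pairwise linear-discriminant classification with paired leave-one-out CV.

The cross-validation scheme holds out one subject from *each* of the two
groups per fold, trains on the rest, and tests on the held-out pair, over all
|A|x|B| pairs (so 2|A||B| test evaluations).  Mean accuracy averages over test
evaluations; per-subject accuracy is the fraction of folds containing that
subject in which it was labeled correctly.

With ~10^3-10^5 voxel features and tens of subjects plain LDA is singular, so
the default classifier is LDA with Ledoit-Wolf shrinkage of the pooled
covariance (sklearn lsqr solver); an alternative mode reduces the training
fold with PCA (components explaining 95% of training variance only — no test
leakage) before plain LDA.  Features are standardized with training-fold
statistics.  Exact ties at the decision boundary go to the first-listed
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .adjustment import AdjustmentResult
from .config import CONTROL_GROUP
from .errors import CerebsigError, PipelineError


@dataclass
class ClassifierConfig:
    mode: str = "shrinkage"            # "shrinkage" | "pca"
    standardize: bool = True
    pca_variance: float = 0.95


@dataclass
class PairResult:
    """One group pair in one correction state."""

    pair: tuple[str, str]
    correction_state: str
    accuracy: float
    per_subject_accuracy: dict[str, float]
    n_folds: int
    n_evaluations: int


@dataclass
class PairwiseClassificationReport:
    entries: list[PairResult] = field(default_factory=list)

    def get(self, pair: tuple[str, str], state: str) -> PairResult:
        for e in self.entries:
            if set(e.pair) == set(pair) and e.correction_state == state:
                return e
        raise KeyError((pair, state))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"group_a": e.pair[0], "group_b": e.pair[1],
              "state": e.correction_state, "accuracy": e.accuracy,
              "n_folds": e.n_folds} for e in self.entries])

    def per_subject_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for sid, acc in e.per_subject_accuracy.items():
                rows.append({"subject_id": sid, "group_a": e.pair[0],
                             "group_b": e.pair[1], "state": e.correction_state,
                             "accuracy": acc})
        return pd.DataFrame(rows)


def shrinkage_lda_decision(train_X: np.ndarray, train_y: np.ndarray,
                           test_X: np.ndarray) -> np.ndarray:
    """Binary LDA with per-class Ledoit-Wolf shrinkage, solved via Woodbury.

    Numerically equivalent to sklearn's
    ``LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")`` decision
    function (same per-class standardize/shrink/rescale covariance and
    empirical priors), but the pooled shrunk covariance ``S = D + B'B`` with
    diagonal ``D`` is inverted with the Woodbury identity, costing
    O(n^2 p) instead of O(p^3) per fit — the fold loops would otherwise
    dominate the pipeline at voxel dimensionality.
    """
    n, p = train_X.shape
    classes = np.array([0, 1])
    priors = np.array([(train_y == c).mean() for c in classes])
    means = np.array([train_X[train_y == c].mean(axis=0) for c in classes])

    D = np.zeros(p)
    blocks = []
    for c, prior in zip(classes, priors):
        Xc = train_X[train_y == c] - means[c]
        sd = Xc.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        alpha = float(ledoit_wolf_shrinkage(Xc / sd))
        mu = float((Xc / sd).var(axis=0).mean())   # trace(cov of standardized)/p
        D += prior * alpha * mu * sd ** 2
        blocks.append(np.sqrt(prior * (1.0 - alpha) / len(Xc)) * Xc)
    B = np.vstack(blocks)

    if np.any(D <= 0):
        # shrinkage degenerated to zero; fall back to the dense solve
        S = B.T @ B + np.diag(D)
        solve = lambda v: np.linalg.lstsq(S, v, rcond=None)[0]
    else:
        Dinv = 1.0 / D
        core = np.linalg.inv(np.eye(len(B)) + (B * Dinv) @ B.T)

        def solve(v):
            dv = Dinv * v
            return dv - Dinv * (B.T @ (core @ (B @ dv)))

    w = solve(means[1] - means[0])
    b = (-0.5 * (means[1] @ solve(means[1]) - means[0] @ solve(means[0]))
         + np.log(priors[1] / priors[0]))
    return test_X @ w + b


def _fit_predict(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                 config: ClassifierConfig) -> np.ndarray:
    """Train LDA on one fold and label the test rows (0 = first group)."""
    if config.standardize:
        mu = train_X.mean(axis=0)
        sd = train_X.std(axis=0)
        sd[sd == 0] = 1.0
        train_X = (train_X - mu) / sd
        test_X = (test_X - mu) / sd
    if config.mode == "pca":
        k = min(len(train_X) - 1, train_X.shape[1])
        p = PCA(n_components=k).fit(train_X)
        cum = np.cumsum(p.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, config.pca_variance) + 1)
        train_X = p.transform(train_X)[:, :keep]
        test_X = p.transform(test_X)[:, :keep]
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(train_X, train_y)
        score = clf.decision_function(test_X)
    elif config.mode == "shrinkage":
        score = shrinkage_lda_decision(train_X, train_y, test_X)
    else:
        raise CerebsigError(f"unknown classifier mode {config.mode!r}")
    # score > 0 means the second group; exact ties go to the first-listed group
    return (score > 0).astype(int)


def count_folds(n_a: int, n_b: int) -> tuple[int, int]:
    """(folds, test evaluations) of the paired leave-one-out scheme."""
    return n_a * n_b, 2 * n_a * n_b


def loo_pairwise_classify(features_a: np.ndarray, features_b: np.ndarray,
                          ids_a: Sequence[str], ids_b: Sequence[str],
                          pair: tuple[str, str],
                          config: ClassifierConfig | None = None,
                          correction_state: str = "uncorrected") -> PairResult:
    """Paired leave-one-out LDA between two groups of feature vectors."""
    config = config or ClassifierConfig()
    Xa = np.asarray(features_a, dtype=float)
    Xb = np.asarray(features_b, dtype=float)
    na, nb = len(Xa), len(Xb)
    if na < 3 or nb < 3:
        raise CerebsigError(f"each group needs >= 3 members, got {na} and {nb}")
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(Xb))):
        raise CerebsigError("non-finite features")

    correct = {sid: 0 for sid in list(ids_a) + list(ids_b)}
    tested = {sid: 0 for sid in correct}
    n_correct_total = 0
    for i in range(na):
        train_a = np.delete(Xa, i, axis=0)
        for j in range(nb):
            train_b = np.delete(Xb, j, axis=0)
            train_X = np.vstack([train_a, train_b])
            train_y = np.concatenate([np.zeros(na - 1, int), np.ones(nb - 1, int)])
            test_X = np.vstack([Xa[i], Xb[j]])
            pred = _fit_predict(train_X, train_y, test_X, config)
            for sid, truth, p in ((ids_a[i], 0, pred[0]), (ids_b[j], 1, pred[1])):
                tested[sid] += 1
                if p == truth:
                    correct[sid] += 1
                    n_correct_total += 1
    n_folds, n_eval = count_folds(na, nb)
    per_subject = {sid: correct[sid] / tested[sid] for sid in correct}
    return PairResult(pair, correction_state, n_correct_total / n_eval,
                      per_subject, n_folds, n_eval)


def run_classification_suite(adjustment: AdjustmentResult, cohort: pd.DataFrame,
                             config: ClassifierConfig | None = None,
                             ) -> PairwiseClassificationReport:
    """Full pairwise suite mirroring the published comparisons.

    Controls vs each subtype use the scaled-but-uncorrected degeneration maps
    (the pure amount of degeneration is the signal there); subtype-vs-subtype
    comparisons run twice, on uncorrected degeneration maps and on
    severity-corrected pattern maps.  Subjects flagged near-zero severity are
    excluded from the corrected analyses only.
    """
    config = config or ClassifierConfig()
    groups = [g for g in cohort.group.unique() if g != CONTROL_GROUP]
    ids_by_group = {g: cohort.loc[cohort.group == g, "subject_id"].tolist()
                    for g in cohort.group.unique()}

    def unc(ids):
        return np.array([adjustment.degeneration[s].values for s in ids])

    def cor(ids):
        kept = [s for s in ids if s in adjustment.pattern]
        return kept, np.array([adjustment.pattern[s].values for s in kept])

    report = PairwiseClassificationReport()
    if CONTROL_GROUP in ids_by_group:
        for g in groups:
            ia, ib = ids_by_group[CONTROL_GROUP], ids_by_group[g]
            report.entries.append(loo_pairwise_classify(
                unc(ia), unc(ib), ia, ib, (CONTROL_GROUP, g), config,
                "uncorrected"))
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            ia, ib = ids_by_group[a], ids_by_group[b]
            report.entries.append(loo_pairwise_classify(
                unc(ia), unc(ib), ia, ib, (a, b), config, "uncorrected"))
            ka, Xa = cor(ia)
            kb, Xb = cor(ib)
            if len(ka) < 3 or len(kb) < 3:
                raise PipelineError(
                    f"too few unflagged patients for corrected {a} vs {b}")
            report.entries.append(loo_pairwise_classify(
                Xa, Xb, ka, kb, (a, b), config, "corrected"))
    return report


@dataclass
class AccuracyCurveFit:
    """2-parameter logistic fit of per-patient accuracy vs a covariate."""

    covariate: str
    location: float
    scale: float
    flat: bool = False                 # all accuracies equal; scale meaningless
    per_patient: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.flat:
            return np.full(np.shape(x), float(self.per_patient.accuracy.mean()))
        return expit((np.asarray(x, float) - self.location) / self.scale)


def patient_mean_accuracy(report: PairwiseClassificationReport,
                          cohort: pd.DataFrame,
                          state: str = "corrected") -> pd.DataFrame:
    """Average each patient's accuracy over the pairwise-subtype tasks
    involving their own group (controls excluded), with fold counts."""
    per = report.per_subject_frame()
    per = per[per.state == state]
    groups = dict(zip(cohort.subject_id, cohort.group))
    rows = []
    for sid, sub in per.groupby("subject_id"):
        if groups.get(sid) == CONTROL_GROUP:
            continue
        sub = sub[(sub.group_a != CONTROL_GROUP) & (sub.group_b != CONTROL_GROUP)]
        if not len(sub):
            continue
        rows.append({"subject_id": sid, "group": groups[sid],
                     "accuracy": float(sub.accuracy.mean()),
                     "n_tasks": len(sub)})
    return pd.DataFrame(rows)


def accuracy_vs_covariate(report: PairwiseClassificationReport,
                          cohort: pd.DataFrame, covariate_values: Mapping[str, float],
                          covariate_name: str = "severity",
                          state: str = "corrected",
                          n_trials: int = 40) -> AccuracyCurveFit:
    """Maximum-likelihood logistic fit of per-patient accuracy vs a covariate.

    Each patient's mean accuracy is treated as a binomial proportion with
    ``n_trials`` pseudo-trials; floor and ceiling are fixed at 0 and 1.  The
    fitted curve is monotone in the covariate by construction (logistic in
    (x - location)/scale).  If all accuracies are equal the fit is flagged
    flat and the scale reported as infinite.
    """
    acc = patient_mean_accuracy(report, cohort, state)
    if not len(acc):
        raise CerebsigError("no per-patient accuracies available")
    acc["covariate"] = acc.subject_id.map(covariate_values)
    if acc.covariate.isna().any():
        raise CerebsigError("covariate missing for some patients")
    x = acc.covariate.to_numpy(float)
    p = np.clip(acc.accuracy.to_numpy(float), 0.0, 1.0)
    if np.ptp(p) == 0:
        return AccuracyCurveFit(covariate_name, float(np.median(x)), np.inf,
                                flat=True, per_patient=acc)
    k = p * n_trials

    def nll(theta):
        loc, log_scale = theta
        q = expit((x - loc) / np.exp(log_scale))
        q = np.clip(q, 1e-9, 1 - 1e-9)
        return -(k * np.log(q) + (n_trials - k) * np.log(1 - q)).sum()

    x0 = np.array([float(np.median(x)), np.log(max(np.ptp(x) / 4, 1e-3))])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    loc, log_scale = res.x
    return AccuracyCurveFit(covariate_name, float(loc), float(np.exp(log_scale)),
                            flat=False, per_patient=acc)
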