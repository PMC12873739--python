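"""Discrimination and calibration assessment for case-control risk models.

Covers the rank-based (Mann-Whitney) AUC, Harrell-style bootstrap optimism
correction, the calibration slope (logistic refit of outcomes on a model's
linear predictor) and the Hosmer-Lemeshow goodness-of-fit test.  All
resampling is driven by an explicit seed recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from alcprs.association_stats import logistic_ml_fit

#: A model specification for bootstrap validation: fit(scores_X, y) on a
#: resample, returning a score function applied to any scores_X.
FitFunction = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class ValidationReport:
    apparent_auc: float
    optimism: float
    corrected_auc: float
    auc_ci95: tuple[float, float]
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0
    calibration_slope: float | None = None
    hl_chi2: float | None = None
    hl_df: int | None = None
    hl_p: float | None = None


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank estimator (ties get 0.5 credit)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def bootstrap_optimism(
    scores_X: np.ndarray,
    y: np.ndarray,
    fit_fn: FitFunction | None = None,
    B: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """Harrell bootstrap optimism correction of the AUC.

    Per resample: refit via ``fit_fn`` on the bootstrap sample (or keep the
    fixed score when ``fit_fn`` is None, e.g. a fixed-weight PRS), evaluate
    AUC on the resample (AUC_boot) and on the original data (AUC_test);
    optimism is the mean of AUC_boot - AUC_test and the corrected AUC is
    apparent - optimism.  The 95% CI is the percentile interval of the
    bootstrap AUCs.  Single-class resamples are redrawn and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(scores_X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("scores/X and y lengths differ")
    flat_score = X.ndim == 1
    if flat_score and fit_fn is not None:
        X = X[:, None]
        flat_score = False

    def apparent_scores() -> np.ndarray:
        return X if X.ndim == 1 else X[:, 0]

    if fit_fn is None:
        base = X if flat_score else X[:, 0]
        apparent = roc_auc(base, y)
    else:
        predict = fit_fn(X, y)
        apparent = roc_auc(predict(X), y)

    rng = np.random.default_rng(seed)
    optimisms = np.empty(B)
    boot_aucs = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            n_redrawn += 1
        yb = y[idx]
        if fit_fn is None:
            sb = (X if flat_score else X[:, 0])[idx]
            auc_boot = roc_auc(sb, yb)
            auc_test = apparent
        else:
            predict_b = fit_fn(X[idx], yb)
            auc_boot = roc_auc(predict_b(X[idx]), yb)
            auc_test = roc_auc(predict_b(X), y)
        boot_aucs[b] = auc_boot
        optimisms[b] = auc_boot - auc_test
    optimism = float(optimisms.mean())
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    return ValidationReport(
        apparent_auc=apparent,
        optimism=optimism,
        corrected_auc=apparent - optimism,
        auc_ci95=(float(lo), float(hi)),
        n_bootstrap=B,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def logistic_fit_fn(X: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """A ready-made ``fit_fn``: ML logistic regression on the given columns."""
    design = np.column_stack([np.ones(len(y)), X])
    fit = logistic_ml_fit(design, np.asarray(y, dtype=float))

    def predict(Xnew: np.ndarray) -> np.ndarray:
        eta = np.column_stack([np.ones(len(Xnew)), Xnew]) @ fit.params
        return 1.0 / (1.0 + np.exp(-eta))

    return predict


def calibration_slope(linear_predictor: Sequence[float], outcomes: Sequence[int]) -> float:
    """Slope b of the logistic refit P(y=1) = expit(a + b * LP).

    A slope of 1 indicates ideal calibration; above 1 suggests underfitting,
    below 1 overfitting.  A constant linear predictor is rejected.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError("linear predictor must be finite")
    if np.ptp(lp) == 0:
        raise ValueError("constant linear predictor: calibration slope undefined")
    X = np.column_stack([np.ones_like(lp), lp])
    fit = logistic_ml_fit(X, y, names=("intercept", "slope"))
    return float(fit.params[1])


def hosmer_lemeshow(
    predicted_probabilities: Sequence[float],
    outcomes: Sequence[int],
    groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square over risk-ranked bins; df = bins - 2.

    Subjects are split into ``groups`` near-equal bins by predicted
    probability with tied probabilities kept in a single bin (so the
    realized number of bins may be smaller, e.g. for a few-level PRS);
    bins whose expected event or non-event count is zero are merged with
    a neighbour.
    """
    p = np.asarray(predicted_probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if groups < 3:
        raise ValueError("need at least 3 groups")
    if len(p) < groups:
        raise ValueError("need at least as many subjects as groups")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    # quantile bin edges; ties collapse duplicate edges into one bin
    edges = np.quantile(p_sorted, np.linspace(0, 1, groups + 1)[1:-1])
    bin_idx = np.searchsorted(np.unique(edges), p_sorted, side="right")
    bins = []
    for b in np.unique(bin_idx):
        mask = bin_idx == b
        bins.append((float(p_sorted[mask].sum()), float(y_sorted[mask].sum()),
                     int(mask.sum())))
    # merge bins with a degenerate expected count into the previous bin
    merged: list[tuple[float, float, int]] = []
    for exp_e, obs_e, n_b in bins:
        if merged and (exp_e == 0 or exp_e == n_b):
            pe, po, pn = merged[-1]
            merged[-1] = (pe + exp_e, po + obs_e, pn + n_b)
        else:
            merged.append((exp_e, obs_e, n_b))
    if len(merged) > 1 and (merged[0][0] == 0 or merged[0][0] == merged[0][2]):
        first, second = merged[0], merged[1]
        merged = [(first[0] + second[0], first[1] + second[1],
                   first[2] + second[2])] + merged[2:]
    chi2 = 0.0
    for exp_e, obs_e, n_b in merged:
        exp_ne = n_b - exp_e
        obs_ne = n_b - obs_e
        if exp_e > 0:
            chi2 += (obs_e - exp_e) ** 2 / exp_e
        if exp_ne > 0:
            chi2 += (obs_ne - exp_ne) ** 2 / exp_ne
    df = max(len(merged) - 2, 1)
    return float(chi2), df, float(stats.chi2.sf(chi2, df))
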