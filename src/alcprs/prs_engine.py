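"""Beta-normalized polygenic risk score, risk stratification and comparison.

The score is a weighted mean of per-variant genotype points:

    f_b(x) = sum_i(b_i * g(x_i)) / sum_i(b_i)

where g maps risk-allele counts 0/1/2 to points 0/0.5/1 and b_i is the
variant's log-odds effect weight.  With positive weights the score is
bounded in [0, 1]: 0 means wild type at every scored variant, 1 means
homozygous for every risk allele.  Risk strata follow the published
convention: low is exactly score 0, moderate is (0, c], high is above c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from alcprs.genotype_io import GenotypeTable, VariantDef


@dataclass
class PRSModel:
    """A set of weighted variants; the normalizer is the weight sum."""

    variants: list[VariantDef]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("a PRS model needs at least one variant")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsIDs in PRS model")
        if self.normalizer <= 0:
            raise ValueError("sum of effect weights must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.effect_weight for v in self.variants])

    @property
    def normalizer(self) -> float:
        return float(sum(v.effect_weight for v in self.variants))

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]


@dataclass
class PRSResult:
    subject_id: str
    points: tuple[float, ...]
    score: float
    stratum: str | None = None


@dataclass
class RiskStrata:
    """Partition of scored subjects into low / moderate / high risk groups."""

    cutpoint: float
    labels: pd.Series  # subject id -> "low" | "moderate" | "high"

    @property
    def sizes(self) -> dict[str, int]:
        return {k: int((self.labels == k).sum()) for k in ("low", "moderate", "high")}


def genotype_points(g: int) -> float:
    """Points for a risk-allele count: 0 -> 0, 1 -> 0.5, 2 -> 1 (i.e. g/2)."""
    if g not in (0, 1, 2):
        raise ValueError(f"risk-allele count must be 0, 1 or 2, got {g!r}")
    return g / 2.0


def compute_prs(points: Sequence[float], model: PRSModel) -> float:
    """Weight-normalized score for one subject's per-variant points."""
    if len(points) != len(model.variants):
        raise ValueError(
            f"{len(points)} point values for {len(model.variants)} model variants"
        )
    pts = np.asarray(points, dtype=float)
    if ((pts < 0) | (pts > 1)).any():
        raise ValueError("points must lie in [0, 1]")
    return float(model.weights @ pts / model.normalizer)


def score_table(table: GenotypeTable, model: PRSModel) -> pd.Series:
    """Per-subject scores for every complete case in the table."""
    complete = table.complete_cases()
    dosages = complete.data[model.rsids].astype(float).to_numpy()
    scores = (dosages / 2.0) @ model.weights / model.normalizer
    return pd.Series(scores, index=complete.subject_ids, name="prs")


def enumerate_score_levels(model: PRSModel) -> list[float]:
    """All distinct scores over the full genotype grid (3^n combinations)."""
    levels = {0.0}
    grid = np.array(np.meshgrid(*[[0, 0.5, 1]] * len(model.variants))).T.reshape(
        -1, len(model.variants)
    )
    for row in grid:
        levels.add(compute_prs(row, model))
    return sorted(levels)


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class PRSSummary:
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    statistic: float
    p_value: float
    method: str  # "exact" | "normal"


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating rank assignments.

    Handles ties through mid-ranks; feasible for small groups only.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    dev_obs = abs(u_obs - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        u = float(ranks[list(idx)].sum()) - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return u_obs, hits / comb(n, n1)


def cohort_prs_summary(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> PRSSummary:
    """Per-group mean/SD and a two-sided Wilcoxon rank-sum comparison.

    Uses exact enumeration of rank assignments when both groups have at most
    10 subjects; otherwise the normal approximation with mid-ranks,
    tie-corrected variance and 0.5 continuity correction.  SDs use the n-1
    denominator.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if x.size <= 10 and y.size <= 10:
        u, p = _exact_rank_sum_p(x, y)
        method = "exact"
    else:
        u, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(u), float(p)
        method = "normal"
    return PRSSummary(
        case_mean=float(x.mean()),
        case_sd=float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        control_mean=float(y.mean()),
        control_sd=float(y.std(ddof=1)) if y.size > 1 else float("nan"),
        statistic=u,
        p_value=min(1.0, p),
        method=method,
    )


# ---------------------------------------------------------------------------
# stratification


def stratify_prs(scores: pd.Series, cutpoint: float = 0.26) -> RiskStrata:
    """Assign low (score 0), moderate (0 < score <= c) and high (> c) strata."""
    if not 0 < cutpoint < 1:
        raise ValueError("cutpoint must lie in (0, 1)")
    s = pd.Series(scores, dtype=float)
    labels = pd.Series("moderate", index=s.index, dtype=object)
    labels[s == 0] = "low"
    labels[s > cutpoint] = "high"
    labels.name = "stratum"
    return RiskStrata(cutpoint=cutpoint, labels=labels)


def empirical_tertile_cutpoints(scores: pd.Series) -> tuple[float, float]:
    """Tertile boundaries of the empirical score distribution (alternative
    stratification mode; the default uses the fixed published cutpoint)."""
    s = pd.Series(scores, dtype=float)
    q1, q2 = s.quantile([1 / 3, 2 / 3])
    return float(q1), float(q2)


def strata_association(
    strata: RiskStrata,
    table: GenotypeTable,
    adjust: Sequence[str] = ("age", "sex"),
):
    """Logistic ORs of case status for moderate/high strata versus low.

    ML estimation with Firth fallback on separation.  An empty stratum's
    contrast is omitted with a warning on the result list.
    """
    import warnings

    from alcprs.association_stats import (
        AssociationResult,
        firth_fit,
        logistic_ml_fit,
    )

    data = table.data.loc[strata.labels.index]
    if (strata.labels == "low").sum() == 0:
        raise ValueError("low (reference) stratum is empty")
    y = (data["phenotype"] == "case").to_numpy(dtype=float)
    cols = [np.ones_like(y)]
    names = ["intercept"]
    terms: list[int] = []
    for level in ("moderate", "high"):
        ind = (strata.labels == level).to_numpy(dtype=float)
        if ind.sum() == 0:
            warnings.warn(f"empty {level} stratum: contrast omitted")
            continue
        cols.append(ind)
        terms.append(len(names))
        names.append(level)
    used: list[str] = []
    for cov in adjust:
        if cov == "age" and not data["age"].isna().any():
            cols.append(data["age"].to_numpy(dtype=float))
        elif cov == "sex" and not data["sex"].isna().any():
            cols.append((data["sex"] == "male").to_numpy(dtype=float))
        else:
            continue
        names.append(cov)
        used.append(cov)
    X = np.column_stack(cols)
    fit = logistic_ml_fit(X, y, names=names)
    if fit.separation or not fit.converged:
        fit = firth_fit(X, y, names=names)
    results = [
        AssociationResult(
            model="prs-strata", term="low", estimate=1.0, ci95=(1.0, 1.0),
            p_value=float("nan"), method="reference", covariates=tuple(used),
        )
    ]
    for j in terms:
        results.append(
            AssociationResult(
                model="prs-strata",
                term=names[j],
                estimate=float(np.exp(fit.params[j])),
                ci95=fit.wald_ci(j),
                p_value=fit.wald_p(j),
                method=fit.method,
                covariates=tuple(used),
            )
        )
    return results
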