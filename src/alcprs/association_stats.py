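"""Frequencies, Hardy-Weinberg testing, contingency tests and logistic models.

The regression core is a Newton-Raphson solver with step-halving shared by
maximum-likelihood and Firth-penalized logistic regression.  The Firth fit
maximizes the Jeffreys-prior penalized likelihood l(b) + 1/2 log det I(b),
which keeps estimates finite under separation and shrinks the bias from
sparse genotype cells; on a single binary covariate it coincides with the
Haldane-corrected (add 1/2 to every cell) cross-product odds ratio, a
closed form used as an oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))

GeneticModel = Literal["allelic", "additive", "dominant", "recessive", "genotypic"]


class SeparationError(RuntimeError):
    """Monotone likelihood: the ML estimate does not exist (use Firth)."""


@dataclass
class HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions."""

    chi_square: float
    df: int
    p_value: float
    testable: bool = True


@dataclass
class ContingencyResult:
    statistic: float | None
    p_value: float
    method: str
    dof: int | None = None


@dataclass
class AssociationResult:
    """One odds-ratio contrast from a genetic-model analysis."""

    model: str
    term: str
    estimate: float  # odds ratio
    ci95: tuple[float, float] | None
    p_value: float
    method: str  # crude | ml | firth
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ci95 is not None and np.isfinite(self.estimate):
            lo, hi = self.ci95
            if not (lo <= self.estimate <= hi):
                raise ValueError(f"{self.term}: OR {self.estimate} outside CI {self.ci95}")


@dataclass
class FdrDecision:
    """Benjamini-Hochberg step-up decision for one family of p-values."""

    q: float
    threshold: float  # (k/m)q for the largest rejected rank k (0 if none)
    largest_rejected_p: float | None
    rejected: list[bool] = field(default_factory=list)


@dataclass
class LogisticFit:
    """Coefficients and Wald inference from a (penalized) logistic fit."""

    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation: bool
    method: str  # "ml" | "firth"
    names: tuple[str, ...] = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_ci(self, j: int) -> tuple[float, float]:
        b, s = self.params[j], self.se[j]
        return (float(np.exp(b - Z975 * s)), float(np.exp(b + Z975 * s)))

    def wald_p(self, j: int) -> float:
        z = self.params[j] / self.se[j]
        return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# frequencies and Hardy-Weinberg


def allele_frequencies(counts: tuple[int, int, int]) -> tuple[int, float]:
    """Effect-allele count and frequency from (n_homref, n_het, n_homalt)."""
    n_homref, n_het, n_homalt = counts
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("empty cohort: cannot compute allele frequency")
    if min(counts) < 0:
        raise ValueError("negative genotype count")
    count = 2 * n_homalt + n_het
    return count, count / (2 * n)


def hwe_chi_square(counts: tuple[int, int, int]) -> HWEResult:
    """Pearson 1-df chi-square test against Hardy-Weinberg proportions.

    Expected counts are n(1-p)^2, 2np(1-p), np^2 at the observed effect-allele
    frequency p.  A monomorphic sample is returned untestable with chi2=0, p=1.
    """
    n = sum(counts)
    _, p = allele_frequencies(counts)
    if p in (0.0, 1.0):
        return HWEResult(chi_square=0.0, df=1, p_value=1.0, testable=False)
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    chi2 = float(np.sum((np.asarray(counts) - expected) ** 2 / expected))
    return HWEResult(chi_square=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# contingency tests


def contingency_test(
    table: Sequence[Sequence[int]], method: Literal["chi2", "fisher", "auto"] = "auto"
) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) or two-sided Fisher exact.

    ``auto`` uses Fisher for 2x2 tables with any expected cell below 5,
    matching common small-sample practice, and chi-square otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a nonnegative 2-D array")
    if t.sum() == 0:
        raise ValueError("table has no observations")
    if method == "auto":
        expected = stats.contingency.expected_freq(t)
        method = "fisher" if t.shape == (2, 2) and (expected < 5).any() else "chi2"
    if method == "fisher":
        if t.shape != (2, 2):
            raise ValueError("Fisher exact test supports 2x2 tables only")
        _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return ContingencyResult(statistic=None, p_value=float(p), method="fisher")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(statistic=float(chi2), p_value=float(p),
                             method="chi2", dof=int(dof))


def crude_odds_ratio(
    table: Sequence[Sequence[int]],
    haldane: bool | Literal["auto"] = "auto",
) -> AssociationResult:
    """Cross-product odds ratio ad/bc with Woolf 95% CI for a 2x2 table.

    Rows are case/control, columns exposed/unexposed.  With ``haldane=True``
    (or ``"auto"`` and a zero cell) 0.5 is added to every cell; with
    ``haldane=False`` a zero cell yields an infinite/zero OR and no CI.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be nonnegative 2x2")
    a, b = t[0]
    c, d = t[1]
    corrected = haldane is True or (haldane == "auto" and (t == 0).any())
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(b, c) == 0:
        return AssociationResult("2x2", "exposure", float("inf"), None, float("nan"),
                                 method="crude")
    if min(a, d) == 0:
        return AssociationResult("2x2", "exposure", 0.0, None, float("nan"),
                                 method="crude")
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(orr * np.exp(-1.96 * se)), float(orr * np.exp(1.96 * se)))
    z = np.log(orr) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult("2x2", "exposure", float(orr), ci, p, method="crude")


# ---------------------------------------------------------------------------
# genetic-model coding


def encode_genetic_model(g: int, model: GeneticModel):
    """Map a risk-allele count to the covariate(s) of a genetic model.

    additive: dosage; dominant: carrier indicator; recessive: homozygote
    indicator; genotypic: (het, homalt) indicator pair.  The allelic model
    operates on allele-count tables, not per-subject covariates.
    """
    if g not in (0, 1, 2):
        raise ValueError(f"risk-allele count must be 0, 1 or 2, got {g!r}")
    if model == "additive":
        return g
    if model == "dominant":
        return int(g >= 1)
    if model == "recessive":
        return int(g == 2)
    if model == "genotypic":
        return (int(g == 1), int(g == 2))
    raise ValueError(f"no per-subject coding for model {model!r}")


# ---------------------------------------------------------------------------
# logistic regression (shared Newton core)

_MAX_ITER = 50
_TOL = 1e-8
_MAX_HALVINGS = 10
_SEPARATION_BOUND = 30.0  # |log-odds| beyond any plausible finite MLE


def _check_design(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p and y length n")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or (w < 0).any():
            raise ValueError("weights must be nonnegative, length n")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if len(np.unique(y[w > 0])) < 2:
        raise ValueError("outcome has a single class")
    return X, y, w


def _loglik(X, y, w, beta, firth: bool) -> float:
    eta = X @ beta
    # log-likelihood via logaddexp for numerical stability
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    if firth:
        p = _expit(eta)
        W = w * p * (1 - p)
        _, logdet = np.linalg.slogdet(X.T * W @ X)
        ll += 0.5 * logdet
    return ll


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def _newton_logistic(X, y, w, firth: bool, names: tuple[str, ...]) -> LogisticFit:
    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, w, beta, firth)
    converged = False
    separation = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        pi = _expit(X @ beta)
        W = w * pi * (1 - pi)
        info = X.T * W @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            separation = True
            break
        if firth:
            # leverage of each covariate pattern under the weighted fit
            h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
            score = X.T @ (w * (y - pi) + h * (0.5 - pi))
        else:
            score = X.T @ (w * (y - pi))
        step = info_inv @ score
        # step-halving: insist the (penalized) log-likelihood does not decrease
        scale = 1.0
        improved = False
        for _ in range(_MAX_HALVINGS + 1):
            candidate = beta + scale * step
            ll_new = _loglik(X, y, w, candidate, firth)
            if ll_new >= ll - 1e-12:
                improved = True
                break
            scale /= 2.0
        if not improved:
            # no step-halving improves the objective: numerically at an optimum
            converged = True
            break
        beta = candidate
        delta_ll = ll_new - ll
        ll = max(ll_new, ll)
        if np.max(np.abs(scale * step)) < _TOL:
            converged = True
            break
        # secondary criterion: at machine precision the step can cycle just
        # above _TOL while the objective is flat — accept as converged
        if abs(delta_ll) < 1e-13 and np.max(np.abs(scale * step)) < 1e-7:
            converged = True
            break
        if not firth and np.max(np.abs(beta)) > _SEPARATION_BOUND:
            separation = True
            break
    pi = _expit(X @ beta)
    W = w * pi * (1 - pi)
    info = X.T * W @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if not firth and not separation and not converged:
        # ran out of iterations while the likelihood kept improving
        separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND / 2)
    return LogisticFit(
        params=beta, cov=cov, loglik=ll, n_iter=it, converged=converged,
        separation=separation, method="firth" if firth else "ml", names=names,
    )


def logistic_ml_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    names: Sequence[str] = (),
) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    `X` must include the intercept column.  Separation (monotone likelihood)
    is detected and flagged on the returned fit; the recommended remedy is
    :func:`firth_fit`.  Rank-deficient designs raise ``LinAlgError``.
    """
    X, y, w = _check_design(X, y, weights)
    return _newton_logistic(X, y, w, firth=False, names=tuple(names))


def firth_fit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    names: Sequence[str] = (),
) -> LogisticFit:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    The score is corrected with hat values h_i: each residual becomes
    y_i - pi_i + h_i(1/2 - pi_i); estimates stay finite under separation.
    Wald CIs come from the inverse penalized information.
    """
    X, y, w = _check_design(X, y, weights)
    fit = _newton_logistic(X, y, w, firth=True, names=tuple(names))
    if not fit.converged:
        raise RuntimeError(
            f"Firth fit did not converge in {fit.n_iter} iterations "
            f"(last penalized log-likelihood {fit.loglik:.6g})"
        )
    return fit


# ---------------------------------------------------------------------------
# high-level genetic-model association


def genotype_association(
    table,
    rsid: str,
    model: GeneticModel,
    method: Literal["ml", "firth", "auto"] = "auto",
    adjust: Sequence[str] = ("age", "sex"),
) -> list[AssociationResult]:
    """Odds ratios for one variant under a genetic model.

    ``allelic`` builds the per-allele 2x2 table (two alleles per subject) and
    reports the crude cross-product OR; the regression models fit case status
    on the encoded genotype plus covariates.  ``auto`` fits ML and falls back
    to Firth when separation or non-convergence is flagged.
    """
    from alcprs.genotype_io import GenotypeTable

    if not isinstance(table, GenotypeTable):
        raise TypeError("table must be a GenotypeTable")
    if model == "allelic":
        case = table.subset("case").genotype_counts(rsid)
        ctrl = table.subset("control").genotype_counts(rsid)
        t = [
            [2 * case[2] + case[1], 2 * case[0] + case[1]],
            [2 * ctrl[2] + ctrl[1], 2 * ctrl[0] + ctrl[1]],
        ]
        res = crude_odds_ratio(t)
        res.model, res.term = "allelic", f"{rsid} per-allele"
        return [res]

    data = table.data.dropna(subset=[rsid])
    g = data[rsid].astype(int).to_numpy()
    y = (data["phenotype"] == "case").to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones_like(y)]
    names: list[str] = ["intercept"]
    if model == "genotypic":
        cols += [(g == 1).astype(float), (g == 2).astype(float)]
        names += [f"{rsid} het", f"{rsid} homalt"]
        terms = [1, 2]
    else:
        enc = np.array([encode_genetic_model(int(v), model) for v in g], dtype=float)
        cols.append(enc)
        names.append(f"{rsid} {model}")
        terms = [1]
    used_covs: list[str] = []
    for cov in adjust:
        if cov == "age":
            age = data["age"].to_numpy(dtype=float)
            if np.isnan(age).any():
                continue
            cols.append(age)
        elif cov == "sex":
            if data["sex"].isna().any():
                continue
            cols.append((data["sex"] == "male").to_numpy(dtype=float))
        else:
            raise ValueError(f"unsupported covariate {cov!r}")
        names.append(cov)
        used_covs.append(cov)
    X = np.column_stack(cols)

    if method == "firth":
        fit = firth_fit(X, y, names=names)
    else:
        fit = logistic_ml_fit(X, y, names=names)
        if method == "auto" and (fit.separation or not fit.converged):
            fit = firth_fit(X, y, names=names)
    out = []
    for j in terms:
        out.append(
            AssociationResult(
                model=model,
                term=names[j],
                estimate=float(np.exp(fit.params[j])),
                ci95=fit.wald_ci(j),
                p_value=fit.wald_p(j),
                method=fit.method,
                covariates=tuple(used_covs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> FdrDecision:
    """Benjamini-Hochberg step-up procedure at FDR level q.

    Rejects the k smallest p-values where k is the largest rank with
    p_(k) <= (k/m) q; the reported threshold is (k/m) q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, m + 1)
    passing = sorted_p <= ranks / m * q
    if not passing.any():
        return FdrDecision(q=q, threshold=0.0, largest_rejected_p=None,
                           rejected=[False] * m)
    k = int(np.max(ranks[passing]))
    p_k = float(sorted_p[k - 1])
    return FdrDecision(
        q=q,
        threshold=k / m * q,
        largest_rejected_p=p_k,
        rejected=(p <= p_k).tolist(),
    )
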