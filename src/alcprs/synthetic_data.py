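"""Synthetic case-control cohorts with the structure the analysis assumes.

Three generation modes:

``hwe_cohort``
    Genotypes drawn per cohort from Hardy-Weinberg proportions at given
    allele frequencies, with an optional dosage-level odds-ratio coupling
    between the two loci (joint table from iterative proportional fitting).
``disease_model``
    Population genotypes under HWE plus a logistic disease model with known
    per-allele log-odds effects; sampling continues until the case and
    control quotas are filled, so the truth is available for
    parameter-recovery testing.
``reconstruct``
    Exact expansion of published per-cohort genotype count tables into
    subject-level records: an IPF target with the chosen coupling is rounded
    to integers by a largest-remainder scheme that preserves both margins
    exactly.

Ages are Normal(58.5, 10^2) years truncated at 18 and sex is Bernoulli(0.87
male), matching the study demographics; both are covariate plumbing, not
risk factors, unless the disease model says otherwise.  All randomness flows
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from alcprs.genotype_io import GenotypeTable, MarginalCounts

DOSAGES = np.array([0, 1, 2])

#: Study-cohort demographic defaults.
AGE_MEAN, AGE_SD, AGE_MIN, MALE_FRACTION = 58.5, 10.0, 18.0, 0.87


@dataclass
class SimSpec:
    """Parameters for one synthetic-cohort generation run."""

    mode: Literal["hwe_cohort", "disease_model", "reconstruct"]
    variants: list[str] = field(default_factory=list)
    n_cases: int = 0
    n_controls: int = 0
    #: per-cohort allele frequencies for hwe_cohort mode
    case_freqs: dict[str, float] = field(default_factory=dict)
    control_freqs: dict[str, float] = field(default_factory=dict)
    #: population frequencies + logistic truth for disease_model mode
    pop_freqs: dict[str, float] = field(default_factory=dict)
    theta: dict[str, float] = field(default_factory=dict)  # per-allele log-OR
    alpha: float = 0.0  # intercept of the disease model
    gamma_age: float = 0.0
    gamma_sex: float = 0.0
    #: dosage-level odds-ratio coupling between two loci (1 = independence)
    coupling_or: float = 1.0
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    male_fraction: float = MALE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        for freqs in (self.case_freqs, self.control_freqs, self.pop_freqs):
            for rsid, f in freqs.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"{rsid}: allele frequency {f} outside [0, 1]")
        if self.coupling_or <= 0:
            raise ValueError("coupling odds ratio must be positive")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# joint genotype distributions


def hwe_proportions(freq: float) -> np.ndarray:
    """Hardy-Weinberg genotype proportions ((1-p)^2, 2p(1-p), p^2)."""
    return np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])


def ipf_joint(
    row_p: np.ndarray, col_p: np.ndarray, coupling_or: float = 1.0,
    tol: float = 1e-12, max_iter: int = 10_000,
) -> np.ndarray:
    """3x3 joint distribution with given margins and dosage association.

    Starts from the seed matrix theta^(i*j) (theta the coupling odds ratio
    applied at the dosage level) and rakes rows and columns until both
    margins match; theta=1 returns the independence product.
    """
    row_p = np.asarray(row_p, dtype=float)
    col_p = np.asarray(col_p, dtype=float)
    i = np.arange(len(row_p))[:, None]
    j = np.arange(len(col_p))[None, :]
    with np.errstate(over="ignore"):
        m = np.power(float(coupling_or), i * j).astype(float)
    m = np.clip(m, 1e-300, 1e300)
    for _ in range(max_iter):
        rs = m.sum(axis=1)
        m = np.where(rs[:, None] > 0, m * (row_p / np.where(rs > 0, rs, 1))[:, None], 0)
        cs = m.sum(axis=0)
        m = np.where(cs[None, :] > 0, m * (col_p / np.where(cs > 0, cs, 1))[None, :], 0)
        if np.abs(m.sum(axis=1) - row_p).max() < tol and np.abs(
            m.sum(axis=0) - col_p
        ).max() < tol:
            break
    return m


def controlled_round(target: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray) -> np.ndarray:
    """Round a nonnegative real matrix to integers with exact given margins.

    Largest-remainder allocation restricted to cells whose row and column
    still have a deficit; ties break on cell order, so the result is
    deterministic.  Requires sum(row_sums) == sum(col_sums).
    """
    row_sums = np.asarray(row_sums, dtype=int)
    col_sums = np.asarray(col_sums, dtype=int)
    if row_sums.sum() != col_sums.sum():
        raise ValueError("row and column totals disagree")
    base = np.floor(target).astype(int)
    # never exceed a margin with the floors alone
    while (base.sum(axis=1) > row_sums).any() or (base.sum(axis=0) > col_sums).any():
        rows_over = np.where(base.sum(axis=1) > row_sums)[0]
        cols_over = np.where(base.sum(axis=0) > col_sums)[0]
        if len(rows_over):
            r = rows_over[0]
            overshoot = np.where(base[r] > 0, base[r] - target[r], -np.inf)
            c = int(np.argmax(overshoot))
        else:
            c = cols_over[0]
            overshoot = np.where(base[:, c] > 0, base[:, c] - target[:, c], -np.inf)
            r = int(np.argmax(overshoot))
        base[r, c] -= 1
    remainder = target - base
    while True:
        row_def = row_sums - base.sum(axis=1)
        col_def = col_sums - base.sum(axis=0)
        if row_def.sum() == 0:
            break
        eligible = (row_def[:, None] > 0) & (col_def[None, :] > 0)
        if not eligible.any():
            raise RuntimeError("controlled rounding failed to honor margins")
        masked = np.where(eligible, remainder, -np.inf)
        r, c = np.unravel_index(int(np.argmax(masked)), masked.shape)
        base[r, c] += 1
        remainder[r, c] -= 1.0
    return base


# ---------------------------------------------------------------------------
# covariates


def _draw_covariates(n: int, spec_like, rng: np.random.Generator):
    a = (AGE_MIN - spec_like.age_mean) / spec_like.age_sd
    ages = stats.truncnorm.rvs(
        a, np.inf, loc=spec_like.age_mean, scale=spec_like.age_sd,
        size=n, random_state=rng,
    )
    sexes = np.where(rng.random(n) < spec_like.male_fraction, "male", "female")
    return np.round(ages, 1), sexes


def _assemble_table(
    rows: list[dict], variants: Sequence[str]
) -> GenotypeTable:
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["subject_id", "phenotype", "age", "sex", *variants])
    df = df.set_index("subject_id")
    return GenotypeTable(df, list(variants))


# ---------------------------------------------------------------------------
# generation modes


def _draw_joint_genotypes(
    n: int, freqs: dict[str, float], variants: Sequence[str],
    coupling_or: float, rng: np.random.Generator,
) -> np.ndarray:
    """n x len(variants) dosage matrix under HWE marginals and coupling."""
    if len(variants) == 2:
        joint = ipf_joint(
            hwe_proportions(freqs[variants[0]]),
            hwe_proportions(freqs[variants[1]]),
            coupling_or,
        )
        cells = rng.multinomial(n, joint.ravel() / joint.sum())
        out = np.repeat(np.indices((3, 3)).reshape(2, -1).T, cells, axis=0)
        return rng.permutation(out, axis=0)
    if coupling_or != 1.0:
        raise ValueError("coupling applies to exactly two loci")
    cols = [
        rng.choice(DOSAGES, size=n, p=hwe_proportions(freqs[v])) for v in variants
    ]
    return np.column_stack(cols)


def simulate_hwe_cohort(spec: SimSpec) -> GenotypeTable:
    """Case and control cohorts drawn from per-cohort HWE genotype models."""
    if spec.mode != "hwe_cohort":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'hwe_cohort'")
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for phenotype, n, freqs in (
        ("case", spec.n_cases, spec.case_freqs),
        ("control", spec.n_controls, spec.control_freqs),
    ):
        if n == 0:
            continue
        missing = [v for v in spec.variants if v not in freqs]
        if missing:
            raise ValueError(f"no {phenotype} allele frequency for {missing}")
        dosages = _draw_joint_genotypes(n, freqs, spec.variants, spec.coupling_or, rng)
        ages, sexes = _draw_covariates(n, spec, rng)
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"{phenotype}_{k:05d}",
                    "phenotype": phenotype,
                    "age": ages[k],
                    "sex": sexes[k],
                    **{v: int(dosages[k, i]) for i, v in enumerate(spec.variants)},
                }
            )
    return _assemble_table(rows, spec.variants)


def simulate_disease_model(spec: SimSpec) -> tuple[GenotypeTable, dict]:
    """Cohorts sampled from a logistic disease model with known effects.

    Returns the genotype table and the ground-truth parameter dictionary
    (intercept, per-allele log-ORs, covariate effects).
    """
    if spec.mode != "disease_model":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'disease_model'")
    if spec.n_cases < 1 or spec.n_controls < 1:
        raise ValueError("disease_model needs positive case and control quotas")
    missing = [v for v in spec.variants if v not in spec.pop_freqs]
    if missing:
        raise ValueError(f"no population frequency for {missing}")
    rng = np.random.default_rng(spec.seed)
    theta = np.array([spec.theta.get(v, 0.0) for v in spec.variants])
    cases: list[dict] = []
    controls: list[dict] = []
    batch = max(4 * (spec.n_cases + spec.n_controls), 1000)
    total_drawn = 0
    while len(cases) < spec.n_cases or len(controls) < spec.n_controls:
        dosages = _draw_joint_genotypes(
            batch, spec.pop_freqs, spec.variants, spec.coupling_or, rng
        )
        ages, sexes = _draw_covariates(batch, spec, rng)
        eta = (
            spec.alpha
            + dosages @ theta
            + spec.gamma_age * ages
            + spec.gamma_sex * (sexes == "male")
        )
        pi = 1.0 / (1.0 + np.exp(-eta))
        is_case = rng.random(batch) < pi
        total_drawn += batch
        if total_drawn >= batch and (pi.mean() < 1e-6 or pi.mean() > 1 - 1e-6):
            short = "case" if pi.mean() < 1e-6 else "control"
            raise RuntimeError(
                f"unattainable {short} quota: mean case probability {pi.mean():.3g}"
            )
        for k in range(batch):
            bucket, quota = (
                (cases, spec.n_cases) if is_case[k] else (controls, spec.n_controls)
            )
            if len(bucket) >= quota:
                continue
            phenotype = "case" if is_case[k] else "control"
            bucket.append(
                {
                    "subject_id": f"{phenotype}_{len(bucket):05d}",
                    "phenotype": phenotype,
                    "age": ages[k],
                    "sex": sexes[k],
                    **{v: int(dosages[k, i]) for i, v in enumerate(spec.variants)},
                }
            )
            if len(cases) >= spec.n_cases and len(controls) >= spec.n_controls:
                break
    truth = {
        "alpha": spec.alpha,
        "theta": dict(zip(spec.variants, theta.tolist())),
        "gamma_age": spec.gamma_age,
        "gamma_sex": spec.gamma_sex,
    }
    return _assemble_table(cases + controls, spec.variants), truth


def reconstruct_from_counts(
    marginals: Sequence[MarginalCounts] | MarginalCounts,
    coupling_or: float = 1.0,
    seed: int = 0,
    age_mean: float = AGE_MEAN,
    age_sd: float = AGE_SD,
    male_fraction: float = MALE_FRACTION,
) -> GenotypeTable:
    """Expand per-cohort genotype count tables into subject-level records.

    Each cohort's 3x3 joint genotype table is the IPF fit of the chosen
    coupling to the printed marginals, rounded to integers with both margins
    preserved exactly; any per-variant count recomputed from the output
    therefore matches the input regardless of coupling or seed.  Covariates
    are drawn from the demographic defaults.
    """
    if isinstance(marginals, MarginalCounts):
        marginals = [marginals]
    if coupling_or <= 0:
        raise ValueError("coupling odds ratio must be positive")
    rng = np.random.default_rng(seed)
    spec_like = SimSpec(mode="reconstruct", age_mean=age_mean, age_sd=age_sd,
                        male_fraction=male_fraction, seed=seed)
    variants: list[str] | None = None
    rows: list[dict] = []
    for m in marginals:
        if m.cohort not in ("case", "control"):
            raise ValueError(f"cohort label must be case/control, got {m.cohort!r}")
        vlist = list(m.counts)
        if variants is None:
            variants = vlist
        elif set(vlist) != set(variants):
            raise ValueError("cohorts list different variants")
        n = m.n
        if n == 0:
            continue
        if len(vlist) == 2:
            r = np.asarray(m.counts[variants[0]])
            c = np.asarray(m.counts[variants[1]])
            target = ipf_joint(r / n, c / n, coupling_or) * n
            joint = controlled_round(target, r, c)
            dosages = np.repeat(
                np.indices((3, 3)).reshape(2, -1).T, joint.ravel(), axis=0
            )
        elif len(vlist) == 1:
            dosages = np.repeat(DOSAGES, m.counts[vlist[0]])[:, None]
        else:
            raise ValueError("reconstruction supports one or two variants")
        ages, sexes = _draw_covariates(n, spec_like, rng)
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"{m.cohort}_{k:04d}",
                    "phenotype": m.cohort,
                    "age": ages[k],
                    "sex": sexes[k],
                    **{v: int(dosages[k, i]) for i, v in enumerate(variants)},
                }
            )
    assert variants is not None
    return _assemble_table(rows, variants)
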