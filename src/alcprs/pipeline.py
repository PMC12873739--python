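"""Config-driven end-to-end orchestration of the case-control analysis.

Stage order: load or simulate the cohort, complete-case filtering,
frequencies and Hardy-Weinberg testing, genetic-model association (crude
and covariate-adjusted, ML with Firth fallback), PRS scoring with risk
stratification and rank-sum comparison, internal validation (AUC with
bootstrap optimism correction, calibration slope, Hosmer-Lemeshow), and
Benjamini-Hochberg FDR annotation.  Every output is stamped with the seed,
a config hash and the package version; a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import alcprs
from alcprs import reference
from alcprs.association_stats import (
    allele_frequencies,
    bh_fdr,
    contingency_test,
    genotype_association,
    hwe_chi_square,
)
from alcprs.genotype_io import (
    GenotypeTable,
    ReportBundle,
    read_genotype_table,
    read_marginal_counts,
    read_weight_file,
    write_report_tables,
)
from alcprs.model_validation import (
    bootstrap_optimism,
    calibration_slope,
    hosmer_lemeshow,
    logistic_fit_fn,
)
from alcprs.prs_engine import (
    PRSModel,
    cohort_prs_summary,
    score_table,
    strata_association,
    stratify_prs,
)
from alcprs.synthetic_data import SimSpec, reconstruct_from_counts, simulate_hwe_cohort

log = logging.getLogger("alcprs")

REGRESSION_MODELS = ("genotypic", "dominant", "recessive", "additive")


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source plus analysis switches."""

    genotypes: str | None = None  # subject-level genotype TSV
    counts: str | None = None  # marginal-counts TSV to reconstruct from
    sim: SimSpec | None = None  # synthetic-cohort specification
    weights: str | None = None  # scoring file; None = bundled PGS000704 weights
    models: tuple[str, ...] = ("allelic",) + REGRESSION_MODELS
    adjust: tuple[str, ...] = ("age", "sex")
    cutpoint: float = reference.PRS_CUTPOINT
    coupling_or: float = 1.0
    bootstrap_B: int = 1000
    hl_groups: int = 10
    fdr_q: tuple[float, ...] = (0.05, 0.1)
    seed: int = 0
    out_dir: str = "alcprs_out"

    def __post_init__(self) -> None:
        sources = [s for s in (self.genotypes, self.counts, self.sim) if s is not None]
        if len(sources) != 1:
            raise ValueError(
                f"exactly one input source required (genotypes/counts/sim), got "
                f"{len(sources)}"
            )
        if not all(0 < q < 1 for q in self.fdr_q):
            raise ValueError("FDR q levels must lie in (0, 1)")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimSpec(**raw["sim"])
        for key in ("models", "adjust", "fdr_q"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (output path excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        if self.sim is not None:
            payload["sim"] = asdict(self.sim)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stages


def _load_cohort(config: RunConfig, variants) -> GenotypeTable:
    if config.genotypes is not None:
        table = read_genotype_table(config.genotypes, variants)
    elif config.counts is not None:
        marginals = read_marginal_counts(config.counts)
        table = reconstruct_from_counts(
            marginals, coupling_or=config.coupling_or, seed=config.seed
        )
    else:
        assert config.sim is not None
        table = simulate_hwe_cohort(config.sim)
    n_before = len(table)
    table = table.complete_cases()
    log.info("load: %d subjects, %d complete cases", n_before, len(table))
    return table


def _frequencies_stage(table: GenotypeTable, variants) -> tuple[pd.DataFrame, dict]:
    rows = []
    metrics: dict = {}
    case, ctrl = table.subset("case"), table.subset("control")
    for v in variants:
        cc, kc = case.genotype_counts(v.rsid), ctrl.genotype_counts(v.rsid)
        ca_n, ca_f = allele_frequencies(cc)
        ko_n, ko_f = allele_frequencies(kc)
        n_case, n_ctrl = sum(cc), sum(kc)
        allele_table = [[ca_n, 2 * n_case - ca_n], [ko_n, 2 * n_ctrl - ko_n]]
        allele_p = contingency_test(allele_table, method="chi2").p_value
        rows.append(
            {
                "variant": v.rsid, "level_type": "allele", "level": v.ref_allele,
                "case_n": 2 * n_case - ca_n,
                "case_pct": round((1 - ca_f) * 100, 1),
                "control_n": 2 * n_ctrl - ko_n,
                "control_pct": round((1 - ko_f) * 100, 1),
                "p_value": round(allele_p, 3),
            }
        )
        rows.append(
            {
                "variant": v.rsid, "level_type": "allele", "level": v.effect_allele,
                "case_n": ca_n, "case_pct": round(ca_f * 100, 1),
                "control_n": ko_n, "control_pct": round(ko_f * 100, 1),
                "p_value": round(allele_p, 3),
            }
        )
        genos = (
            v.ref_allele * 2,
            v.ref_allele + v.effect_allele,
            v.effect_allele * 2,
        )
        geno_ps = []
        for gi, glabel in enumerate(genos):
            t = [[cc[gi], n_case - cc[gi]], [kc[gi], n_ctrl - kc[gi]]]
            p = contingency_test(t, method="auto").p_value
            geno_ps.append(p)
            rows.append(
                {
                    "variant": v.rsid, "level_type": "genotype", "level": glabel,
                    "case_n": cc[gi], "case_pct": round(cc[gi] / n_case * 100, 1),
                    "control_n": kc[gi], "control_pct": round(kc[gi] / n_ctrl * 100, 1),
                    "p_value": round(p, 3),
                }
            )
        hwe_case, hwe_ctrl = hwe_chi_square(cc), hwe_chi_square(kc)
        rows.append(
            {
                "variant": v.rsid, "level_type": "hwe_p", "level": "",
                "case_n": "", "case_pct": round(hwe_case.p_value, 3),
                "control_n": "", "control_pct": round(hwe_ctrl.p_value, 3),
                "p_value": "",
            }
        )
        metrics[v.rsid] = {
            "case_effect_allele_freq": ca_f,
            "control_effect_allele_freq": ko_f,
            "allele_test_p": allele_p,
            "genotype_test_p": geno_ps,
            "hwe_p_case": hwe_case.p_value,
            "hwe_p_control": hwe_ctrl.p_value,
        }
    log.info("frequencies: %d variants", len(variants))
    return pd.DataFrame(rows), metrics


def _association_stage(
    table: GenotypeTable, variants, models: Sequence[str], adjust: Sequence[str]
) -> tuple[pd.DataFrame, dict]:
    rows = []
    metrics: dict = {}
    for v in variants:
        metrics[v.rsid] = {}
        for model in models:
            variants_adjusts = (
                [("crude", ())] if model == "allelic" else [("crude", ()), ("adjusted", tuple(adjust))]
            )
            for label, adj in variants_adjusts:
                results = genotype_association(
                    table, v.rsid, model, method="auto", adjust=adj
                )
                for res in results:
                    lo, hi = res.ci95 if res.ci95 else (float("nan"), float("nan"))
                    rows.append(
                        {
                            "variant": v.rsid, "model": model, "term": res.term,
                            "estimation": label, "method": res.method,
                            "or": round(res.estimate, 2),
                            "ci_low": round(lo, 2), "ci_high": round(hi, 2),
                            "p_value": round(res.p_value, 3),
                        }
                    )
                    metrics[v.rsid][f"{model}:{res.term}:{label}"] = {
                        "or": res.estimate, "ci": [lo, hi], "p": res.p_value,
                        "method": res.method,
                    }
    log.info("association: %d contrasts", len(rows))
    return pd.DataFrame(rows), metrics


def _prs_stage(table: GenotypeTable, model: PRSModel, cutpoint: float, adjust):
    scores = score_table(table, model)
    phen = table.data.loc[scores.index, "phenotype"]
    summary = cohort_prs_summary(scores[phen == "case"], scores[phen == "control"])
    strata = stratify_prs(scores, cutpoint)
    strata_results = strata_association(strata, table, adjust=adjust)
    scores_df = pd.DataFrame(
        {
            "subject_id": scores.index,
            "phenotype": phen.to_numpy(),
            "prs": np.round(scores.to_numpy(), 6),
            "stratum": strata.labels.to_numpy(),
        }
    )
    strata_rows = []
    for res in strata_results:
        mask = strata.labels == res.term if res.term in ("low", "moderate", "high") else None
        strata_rows.append(
            {
                "stratum": res.term,
                "n": int(mask.sum()) if mask is not None else "",
                "or": round(res.estimate, 2),
                "ci_low": round(res.ci95[0], 2) if res.ci95 else "",
                "ci_high": round(res.ci95[1], 2) if res.ci95 else "",
                "p_value": "" if np.isnan(res.p_value) else round(res.p_value, 3),
                "method": res.method,
            }
        )
    metrics = {
        "case_mean": summary.case_mean, "case_sd": summary.case_sd,
        "control_mean": summary.control_mean, "control_sd": summary.control_sd,
        "wilcoxon_p": summary.p_value, "wilcoxon_method": summary.method,
        "strata_sizes": strata.sizes,
        "strata_or": {
            r.term: {"or": r.estimate, "ci": list(r.ci95 or ()), "p": r.p_value}
            for r in strata_results
        },
    }
    log.info(
        "prs: mean case %.3f control %.3f, strata %s",
        summary.case_mean, summary.control_mean, strata.sizes,
    )
    return scores, pd.DataFrame(strata_rows), scores_df, metrics


def _validation_stage(table, scores, config: RunConfig) -> dict:
    y = (table.data.loc[scores.index, "phenotype"] == "case").to_numpy(dtype=int)
    s = scores.to_numpy()
    fixed = bootstrap_optimism(s, y, fit_fn=None, B=config.bootstrap_B,
                               seed=config.seed)
    refit = bootstrap_optimism(
        s[:, None], y, fit_fn=logistic_fit_fn, B=config.bootstrap_B,
        seed=config.seed,
    )
    from alcprs.association_stats import logistic_ml_fit

    X = np.column_stack([np.ones_like(s), s])
    fit = logistic_ml_fit(X, y.astype(float), names=("intercept", "prs"))
    lp = X @ fit.params
    slope = calibration_slope(lp, y)
    probs = 1.0 / (1.0 + np.exp(-lp))
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(probs, y, groups=config.hl_groups)
    metrics = {
        "fixed_score": {
            "apparent_auc": fixed.apparent_auc, "optimism": fixed.optimism,
            "corrected_auc": fixed.corrected_auc, "auc_ci95": list(fixed.auc_ci95),
        },
        "refit_logistic": {
            "apparent_auc": refit.apparent_auc, "optimism": refit.optimism,
            "corrected_auc": refit.corrected_auc, "auc_ci95": list(refit.auc_ci95),
        },
        "calibration_slope": slope,
        "hosmer_lemeshow": {"chi2": hl_chi2, "df": hl_df, "p": hl_p},
        "bootstrap_B": config.bootstrap_B,
        "seed": config.seed,
    }
    log.info(
        "validation: apparent AUC %.3f, corrected %.3f, slope %.3f, HL p %.3f",
        fixed.apparent_auc, fixed.corrected_auc, slope, hl_p,
    )
    return metrics


def _fdr_stage(freq_metrics: dict, assoc_metrics: dict, q_levels) -> dict:
    chi2_family = [m["allele_test_p"] for m in freq_metrics.values()]
    chi2_family += [p for m in freq_metrics.values() for p in m["genotype_test_p"]]
    regression_family = [
        entry["p"]
        for per_variant in assoc_metrics.values()
        for entry in per_variant.values()
        if np.isfinite(entry["p"])
    ]
    out: dict = {}
    for q in q_levels:
        out[f"q={q}"] = {}
        for name, family in (
            ("chi2_tests", chi2_family),
            ("regression_models", regression_family),
        ):
            if not family:
                continue
            d = bh_fdr(family, q)
            out[f"q={q}"][name] = {
                "threshold": d.threshold,
                "largest_rejected_p": d.largest_rejected_p,
                "n_rejected": int(sum(d.rejected)),
                "n_tests": len(family),
            }
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to disk."""
    out_dir = Path(config.out_dir)
    try:
        if config.weights is not None:
            variants = read_weight_file(config.weights)
        else:
            variants = list(reference.VARIANTS)
        stage = "load"
        table = _load_cohort(config, variants)
        variants = [v for v in variants if v.rsid in table.variants]
        stage = "frequencies"
        freq_df, freq_metrics = _frequencies_stage(table, variants)
        stage = "association"
        assoc_df, assoc_metrics = _association_stage(
            table, variants, config.models, config.adjust
        )
        stage = "prs"
        prs_model = PRSModel(variants)
        scores, strata_df, scores_df, prs_metrics = _prs_stage(
            table, prs_model, config.cutpoint, config.adjust
        )
        stage = "validation"
        val_metrics = _validation_stage(table, scores, config)
        stage = "fdr"
        fdr_metrics = _fdr_stage(freq_metrics, assoc_metrics, config.fdr_q)
    except Exception as exc:
        # remove partial outputs so a failed run leaves no half-written bundle
        if out_dir.exists():
            for f in out_dir.glob("*"):
                f.unlink()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    bundle = ReportBundle(
        frequencies=freq_df,
        association=assoc_df,
        strata=strata_df,
        scores=scores_df,
        metrics={
            "meta": {
                "seed": config.seed,
                "config_hash": config.hash(),
                "version": alcprs.__version__,
                "n_subjects": len(table),
            },
            "frequencies": freq_metrics,
            "association": assoc_metrics,
            "prs": prs_metrics,
            "validation": val_metrics,
            "fdr": fdr_metrics,
        },
    )
    write_report_tables(bundle, out_dir)
    log.info("report bundle written to %s", out_dir)
    return bundle
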