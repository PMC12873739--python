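"""Data model and I/O for genotypes, phenotypes, variant weights and count tables.

Genotypes are stored internally as risk-allele counts (dosages) in {0, 1, 2},
the representation every downstream formula consumes.  Readers accept both
allele-pair cells ("C/G", order-insensitive, "/" or "|" separators) and
integer counts.  Variant weights follow the PGS-Catalog scoring-file dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Cell values treated as a missing genotype call.
MISSING_TOKENS = {"", ".", "na", "nan", "./.", ".|."}

#: Phenotype column levels.
CASE, CONTROL = "case", "control"


class GenotypeParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


class GenotypeValidationError(ValueError):
    """Input parsed but violates a data-model invariant."""


@dataclass(frozen=True)
class VariantDef:
    """A scored variant: identity, alleles and its log-odds effect weight."""

    rsid: str
    gene: str
    ref_allele: str
    effect_allele: str
    effect_weight: float

    def __post_init__(self) -> None:
        if not self.rsid:
            raise GenotypeValidationError("rsid must be nonempty")
        if self.ref_allele == self.effect_allele:
            raise GenotypeValidationError(
                f"{self.rsid}: ref and effect allele are both {self.ref_allele!r}"
            )
        if not np.isfinite(self.effect_weight):
            raise GenotypeValidationError(f"{self.rsid}: non-finite effect weight")


@dataclass(frozen=True)
class Subject:
    """One study participant with phenotype and optional covariates."""

    id: str
    phenotype: str  # "case" | "control"
    age: float | None = None
    sex: str | None = None  # "male" | "female"

    def __post_init__(self) -> None:
        if self.phenotype not in (CASE, CONTROL):
            raise GenotypeValidationError(
                f"subject {self.id}: phenotype must be {CASE!r} or {CONTROL!r}, "
                f"got {self.phenotype!r}"
            )
        if self.sex is not None and self.sex not in ("male", "female"):
            raise GenotypeValidationError(f"subject {self.id}: bad sex {self.sex!r}")
        if self.age is not None and not self.age > 0:
            raise GenotypeValidationError(f"subject {self.id}: bad age {self.age!r}")


class GenotypeTable:
    """Subjects x variants risk-allele counts plus phenotype/covariates.

    Wraps a DataFrame indexed by subject id with columns ``phenotype``,
    ``age``, ``sex`` and one nullable-integer dosage column per rsid.
    """

    META_COLS = ("phenotype", "age", "sex")

    def __init__(self, data: pd.DataFrame, variants: Sequence[str]):
        variants = list(variants)
        missing = [c for c in self.META_COLS if c not in data.columns]
        if missing:
            raise GenotypeValidationError(f"missing metadata columns: {missing}")
        for rsid in variants:
            if rsid not in data.columns:
                raise GenotypeValidationError(f"missing dosage column for {rsid}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].tolist()
            raise GenotypeValidationError(f"duplicate subject ids: {dups}")
        data = data.copy()
        for rsid in variants:
            col = pd.array(data[rsid], dtype="Int64")
            bad = col.dropna()
            if len(bad) and not bad.isin([0, 1, 2]).all():
                raise GenotypeValidationError(f"{rsid}: dosages outside {{0,1,2}}")
            data[rsid] = col
        ph = data["phenotype"].dropna()
        if len(ph) and not ph.isin([CASE, CONTROL]).all():
            raise GenotypeValidationError("phenotype values must be case/control")
        self.data = data
        self.variants = variants

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    def dosages(self, rsid: str | None = None):
        """Dosage column for one variant, or the subjects x variants frame."""
        if rsid is not None:
            return self.data[rsid]
        return self.data[self.variants]

    @property
    def is_case(self) -> pd.Series:
        return (self.data["phenotype"] == CASE).astype(int)

    @property
    def sex_male(self) -> pd.Series:
        """Regression coding: male=1, female=0."""
        return (self.data["sex"] == "male").astype(int)

    def complete_cases(self) -> "GenotypeTable":
        """Drop subjects with any missing genotype call (idempotent)."""
        keep = self.data[self.variants].notna().all(axis=1)
        return GenotypeTable(self.data.loc[keep], self.variants)

    def subset(self, phenotype: str) -> "GenotypeTable":
        return GenotypeTable(
            self.data[self.data["phenotype"] == phenotype], self.variants
        )

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(n_homref, n_het, n_homalt) over non-missing calls."""
        d = self.data[rsid].dropna()
        return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return self.variants == other.variants and self.data[
            list(self.META_COLS) + self.variants
        ].equals(other.data[list(other.META_COLS) + other.variants])


@dataclass
class MarginalCounts:
    """Per-cohort genotype counts (n_homref, n_het, n_homalt) per variant."""

    cohort: str
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = set()
        for rsid, (a, b, c) in self.counts.items():
            if min(a, b, c) < 0:
                raise GenotypeValidationError(f"{rsid}: negative genotype count")
            sizes.add(a + b + c)
        if len(sizes) > 1:
            raise GenotypeValidationError(
                f"cohort {self.cohort}: variant totals differ ({sorted(sizes)})"
            )

    @property
    def n(self) -> int:
        if not self.counts:
            return 0
        return sum(next(iter(self.counts.values())))


# ---------------------------------------------------------------------------
# genotype table TSV


def _parse_cell(cell: str, variant: VariantDef, lineno: int) -> int | None:
    cell = cell.strip()
    if cell.lower() in MISSING_TOKENS:
        return None
    if cell.lstrip("-").isdigit():
        g = int(cell)
        if g not in (0, 1, 2):
            raise GenotypeValidationError(
                f"line {lineno}: count {g} for {variant.rsid} not in {{0,1,2}}"
            )
        return g
    sep = "/" if "/" in cell else ("|" if "|" in cell else None)
    if sep is None:
        raise GenotypeParseError(
            f"line {lineno}: cannot parse genotype cell {cell!r} for {variant.rsid}"
        )
    alleles = cell.upper().split(sep)
    if len(alleles) != 2:
        raise GenotypeParseError(
            f"line {lineno}: expected two alleles in {cell!r} for {variant.rsid}"
        )
    count = 0
    for a in alleles:
        if a == variant.effect_allele:
            count += 1
        elif a != variant.ref_allele:
            raise GenotypeValidationError(
                f"line {lineno}: allele {a!r} not in "
                f"{{{variant.ref_allele},{variant.effect_allele}}} for {variant.rsid}"
            )
    return count


def read_genotype_table(
    path: str | Path, variants: Sequence[VariantDef] | None = None
) -> GenotypeTable:
    """Read a tab-separated genotype table.

    Expected header: ``subject_id  age  sex  phenotype  <rsid> ...``.
    Genotype cells may be allele pairs (resolved against each variant's
    effect allele, requiring `variants`) or integer risk-allele counts.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    try:
        idx = {c: header.index(c) for c in ("subject_id", "phenotype")}
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: header must name subject_id and phenotype") from exc
    age_i = header.index("age") if "age" in header else None
    sex_i = header.index("sex") if "sex" in header else None
    meta_cols = {"subject_id", "age", "sex", "phenotype"}
    rsids = [c for c in header if c not in meta_cols]
    vmap: dict[str, VariantDef] = {}
    if variants is not None:
        vmap = {v.rsid: v for v in variants}
    else:
        # counts-only dialect: a placeholder def per column suffices
        vmap = {
            r: VariantDef(rsid=r, gene="", ref_allele="N", effect_allele="X",
                          effect_weight=0.0)
            for r in rsids
        }
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise GenotypeParseError(
                f"{path}: line {lineno}: {len(cells)} fields, expected {len(header)}"
            )
        rec: dict[str, object] = {
            "subject_id": cells[idx["subject_id"]].strip(),
            "phenotype": cells[idx["phenotype"]].strip().lower(),
            "age": np.nan,
            "sex": None,
        }
        if age_i is not None and cells[age_i].strip().lower() not in MISSING_TOKENS:
            try:
                rec["age"] = float(cells[age_i])
            except ValueError as exc:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: bad age {cells[age_i]!r}"
                ) from exc
        if sex_i is not None and cells[sex_i].strip().lower() not in MISSING_TOKENS:
            rec["sex"] = cells[sex_i].strip().lower()
        for rsid in rsids:
            if rsid not in vmap:
                raise GenotypeValidationError(f"{path}: unknown variant column {rsid}")
            rec[rsid] = _parse_cell(cells[header.index(rsid)], vmap[rsid], lineno)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    if df.empty:
        df = pd.DataFrame(columns=["subject_id", "age", "sex", "phenotype", *rsids])
    df = df.set_index("subject_id")
    return GenotypeTable(df, rsids)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write the counts dialect of the genotype TSV (round-trips with the reader)."""
    df = table.data[["age", "sex", "phenotype", *table.variants]].copy()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# PGS-Catalog-style scoring file

_WEIGHT_SYNONYMS = {
    "rsid": "rsID",
    "rsID": "rsID",
    "hm_rsID": "rsID",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "hm_inferOtherAllele": "other_allele",
    "effect_weight": "effect_weight",
    "gene": "gene",
    "locus_name": "gene",
}


def read_weight_file(path: str | Path) -> list[VariantDef]:
    """Read a PGS-Catalog-style scoring file (TSV; '#' header lines ignored).

    Required columns: rsID, effect_allele, effect_weight (harmonized synonyms
    accepted).  other_allele/gene are optional.
    """
    path = Path(path)
    rows = [
        line.split("\t")
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not rows:
        raise GenotypeParseError(f"{path}: no variants (no data rows)")
    header = [_WEIGHT_SYNONYMS.get(c.strip(), c.strip()) for c in rows[0]]
    for col in ("rsID", "effect_allele", "effect_weight"):
        if col not in header:
            raise GenotypeParseError(f"{path}: missing required column {col}")
    out: list[VariantDef] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        rec = dict(zip(header, (c.strip() for c in row)))
        rsid = rec["rsID"]
        if rsid in seen:
            raise GenotypeValidationError(f"{path}: duplicate rsID {rsid}")
        seen.add(rsid)
        try:
            weight = float(rec["effect_weight"])
        except ValueError as exc:
            raise GenotypeParseError(
                f"{path}: line {lineno}: non-numeric weight {rec['effect_weight']!r}"
            ) from exc
        out.append(
            VariantDef(
                rsid=rsid,
                gene=rec.get("gene", ""),
                ref_allele=rec.get("other_allele", "N"),
                effect_allele=rec["effect_allele"],
                effect_weight=weight,
            )
        )
    if not out:
        raise GenotypeParseError(f"{path}: no variants")
    return out


# ---------------------------------------------------------------------------
# VCF


def read_vcf_genotypes(path: str | Path, variants: Sequence[VariantDef]) -> GenotypeTable:
    """Extract risk-allele counts for `variants` from a VCF's GT fields.

    Variants are matched by ID, with CHROM:POS REF/ALT as no-ID fallback via
    allele comparison.  Phased and unphased GTs are accepted; half-missing
    genotypes (e.g. ``./1``) become missing calls.  Phenotype/covariates are
    absent from VCF and left missing (attach them separately).
    """
    import pysam

    wanted = {v.rsid: v for v in variants}
    found: dict[str, pd.Series] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            variant = None
            if rec.id in wanted:
                variant = wanted[rec.id]
            else:
                for v in wanted.values():
                    alts = rec.alts or ()
                    if {rec.ref, *alts} == {v.ref_allele, v.effect_allele}:
                        variant = v
                        break
            if variant is None or variant.rsid in found:
                continue
            alleles = [rec.ref, *(rec.alts or ())]
            dosage: list[float] = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosage.append(np.nan)
                    continue
                dosage.append(
                    sum(1 for a in gt if alleles[a] == variant.effect_allele)
                )
            found[variant.rsid] = pd.Series(dosage, index=samples)
    missing_ids = sorted(set(wanted) - set(found))
    if missing_ids:
        raise GenotypeValidationError(f"variants absent from VCF: {missing_ids}")
    df = pd.DataFrame(found)
    df["phenotype"] = None
    df["age"] = np.nan
    df["sex"] = None
    df.index.name = "subject_id"
    return GenotypeTable(df, list(wanted))


# ---------------------------------------------------------------------------
# marginal count tables


def read_marginal_counts(path: str | Path) -> list[MarginalCounts]:
    """Read a marginal-counts TSV: cohort, rsid, n_homref, n_het, n_homalt."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"cohort", "rsid", "n_homref", "n_het", "n_homalt"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"{path}: header must contain {sorted(required)}"
        )
    out = []
    for cohort, grp in df.groupby("cohort", sort=False):
        counts = {
            str(r.rsid): (int(r.n_homref), int(r.n_het), int(r.n_homalt))
            for r in grp.itertuples()
        }
        out.append(MarginalCounts(cohort=str(cohort), counts=counts))
    return out


def write_marginal_counts(marginals: Iterable[MarginalCounts], path: str | Path) -> None:
    rows = [
        {"cohort": m.cohort, "rsid": rsid, "n_homref": a, "n_het": b, "n_homalt": c}
        for m in marginals
        for rsid, (a, b, c) in m.counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report bundle


@dataclass
class ReportBundle:
    """Completed analysis tables plus machine-readable metrics.

    Tables are presentation-ready DataFrames; ``metrics`` carries every
    quantity at full precision.
    """

    frequencies: pd.DataFrame | None = None
    association: pd.DataFrame | None = None
    strata: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    metrics: dict = field(default_factory=dict)


def write_report_tables(results: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write the report bundle as TSV tables plus a metrics JSON file.

    Output is deterministic: identical results produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "frequencies_hwe.tsv": results.frequencies,
        "association.tsv": results.association,
        "prs_strata.tsv": results.strata,
        "prs_scores.tsv": results.scores,
    }
    for name, df in tables.items():
        target = out_dir / name
        if df is None:
            df = pd.DataFrame()
        df.to_csv(target, sep="\t", index=False)
        written.append(target)
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(
        json.dumps(_jsonify(results.metrics), indent=2, sort_keys=True) + "\n"
    )
    written.append(metrics_path)
    return written


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj
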