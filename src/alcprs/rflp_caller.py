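"""In-silico PCR-RFLP genotype calling from restriction fragment patterns.

A biallelic RFLP assay produces one fragment pattern per allele; a
heterozygote shows the union of both alleles' bands (co-dominant banding,
with shared lengths collapsing to a single band).  Calling compares an
observed band set to the three expected genotype patterns with a per-band
size tolerance, after discarding fragments too small to resolve on the gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

Genotype = Literal["homref", "het", "homalt", "no_call"]

#: Fragments below this size are assumed invisible on a 3% agarose gel.
DEFAULT_MIN_DETECTABLE_BP = 50
#: Per-band sizing tolerance for gel-estimated fragment lengths.
DEFAULT_TOL_BP = 5


@dataclass(frozen=True)
class AllelePattern:
    """Expected digest fragments (bp) for one allele of one variant."""

    rsid: str
    allele: str
    fragments: tuple[int, ...]
    product_length: int

    def __post_init__(self) -> None:
        if not self.fragments or any(f <= 0 for f in self.fragments):
            raise ValueError(f"{self.rsid} {self.allele}: fragment lengths must be positive")
        if self.product_length <= 0:
            raise ValueError(f"{self.rsid}: product length must be positive")

    @property
    def is_consistent(self) -> bool:
        """Whether the fragments sum to the PCR product length."""
        return sum(self.fragments) == self.product_length


@dataclass
class RflpCall:
    """Result of matching an observed band set against a variant's patterns."""

    genotype: Genotype
    matched_pattern: tuple[int, ...] | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotype == "no_call" and not self.diagnostics:
            raise ValueError("no_call requires at least one diagnostic message")


def expected_pattern(
    patterns: tuple[AllelePattern, AllelePattern],
    genotype: Literal["homref", "het", "homalt"],
) -> tuple[int, ...]:
    """Expected band lengths for a genotype (sorted, duplicates collapsed).

    Homozygotes show that allele's fragments; heterozygotes show every
    distinct length from either allele.
    """
    ref, alt = patterns
    if ref.rsid != alt.rsid:
        raise ValueError(f"pattern pair mixes variants {ref.rsid}/{alt.rsid}")
    if genotype == "homref":
        bands = set(ref.fragments)
    elif genotype == "homalt":
        bands = set(alt.fragments)
    elif genotype == "het":
        bands = set(ref.fragments) | set(alt.fragments)
    else:
        raise ValueError(f"unknown genotype {genotype!r}")
    return tuple(sorted(bands, reverse=True))


def _match_bands(
    observed: Sequence[int], expected: Sequence[int], tol_bp: int
) -> tuple[bool, list[int], list[int]]:
    """Greedy one-to-one matching of observed to expected bands within +/-tol.

    Returns (full_match, unexplained_observed, undetected_expected).  Bands
    are matched nearest-first so a tighter pairing is preferred.
    """
    remaining = list(expected)
    unexplained: list[int] = []
    for band in sorted(observed, reverse=True):
        best, best_d = None, tol_bp + 1
        for exp in remaining:
            d = abs(band - exp)
            if d < best_d:
                best, best_d = exp, d
        if best is None:
            unexplained.append(band)
        else:
            remaining.remove(best)
    return (not unexplained and not remaining, unexplained, remaining)


def call_genotype_from_fragments(
    observed: Iterable[int],
    patterns: tuple[AllelePattern, AllelePattern],
    tol_bp: int = DEFAULT_TOL_BP,
    min_detectable_bp: int = DEFAULT_MIN_DETECTABLE_BP,
) -> RflpCall:
    """Call a genotype from observed gel band sizes.

    Fragments below `min_detectable_bp` are removed from both the observed
    and expected sets before matching, keeping the comparison symmetric.
    The call is the unique genotype whose expected pattern matches every
    observed band (and vice versa) within ``tol_bp``; anything else is a
    no-call with diagnostics.
    """
    if tol_bp < 0:
        raise ValueError("tol_bp must be >= 0")
    obs = sorted({int(b) for b in observed if b >= min_detectable_bp}, reverse=True)
    if not obs:
        return RflpCall("no_call", diagnostics=["no detectable bands"])
    results: dict[str, tuple[bool, list[int], list[int], tuple[int, ...]]] = {}
    for g in ("homref", "het", "homalt"):
        exp_full = expected_pattern(patterns, g)  # type: ignore[arg-type]
        exp = [b for b in exp_full if b >= min_detectable_bp]
        ok, unexplained, undetected = _match_bands(obs, exp, tol_bp)
        results[g] = (ok, unexplained, undetected, exp_full)
    matches = [g for g, (ok, *_rest) in results.items() if ok]
    if len(matches) == 1:
        g = matches[0]
        return RflpCall(g, matched_pattern=results[g][3])  # type: ignore[arg-type]
    diagnostics: list[str] = []
    if len(matches) > 1:
        diagnostics.append(f"ambiguous match: {sorted(matches)}")
    else:
        # report against the closest pattern (fewest mismatched bands)
        g_best = min(results, key=lambda g: len(results[g][1]) + len(results[g][2]))
        _, unexplained, undetected, _ = results[g_best]
        diagnostics.extend(f"unexplained band {b}" for b in unexplained)
        diagnostics.extend(f"undetected band {b}" for b in undetected)
        if not diagnostics:
            diagnostics.append("no pattern matched")
    return RflpCall("no_call", diagnostics=diagnostics)


def validate_patterns(patterns: tuple[AllelePattern, AllelePattern]) -> list[str]:
    """Warnings for allele patterns whose fragments do not sum to the amplicon.

    Published patterns occasionally contain typos or omit fragments; the
    check surfaces them without rejecting the pattern.
    """
    warnings: list[str] = []
    for p in patterns:
        total = sum(p.fragments)
        if total != p.product_length:
            warnings.append(
                f"{p.rsid} allele {p.allele}: pattern sum {total} != product "
                f"{p.product_length}"
            )
    ref, alt = patterns
    if expected_pattern(patterns, "homref") == expected_pattern(patterns, "homalt"):
        warnings.append(f"{ref.rsid}: alleles {ref.allele}/{alt.allele} indistinguishable")
    return warnings


# ---------------------------------------------------------------------------
# file dialects


def read_patterns_file(path: str | Path) -> dict[str, tuple[AllelePattern, AllelePattern]]:
    """Patterns TSV: rsid, allele, product_length, fragments ('+'-separated bp)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"rsid", "allele", "product_length", "fragments"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    out: dict[str, tuple[AllelePattern, AllelePattern]] = {}
    for rsid, grp in df.groupby("rsid", sort=False):
        if len(grp) != 2:
            raise ValueError(f"{path}: {rsid}: expected exactly 2 allele patterns")
        pair = tuple(
            AllelePattern(
                rsid=str(rsid),
                allele=row.allele,
                fragments=tuple(int(x) for x in row.fragments.split("+")),
                product_length=int(row.product_length),
            )
            for row in grp.itertuples()
        )
        out[str(rsid)] = pair  # (ref, alt) in file order
    return out


def call_fragments_file(
    fragments_path: str | Path,
    patterns: dict[str, tuple[AllelePattern, AllelePattern]],
    tol_bp: int = DEFAULT_TOL_BP,
    min_detectable_bp: int = DEFAULT_MIN_DETECTABLE_BP,
):
    """Call genotypes for a gel-observation TSV: sample_id, rsid, bands.

    Returns a DataFrame with one row per (sample, variant) and columns
    genotype, dosage (0/1/2 or missing) and diagnostics.
    """
    import numpy as np
    import pandas as pd

    df = pd.read_csv(fragments_path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "rsid", "bands"}
    if not required.issubset(df.columns):
        raise ValueError(f"{fragments_path}: header must contain {sorted(required)}")
    dosage_of = {"homref": 0, "het": 1, "homalt": 2}
    rows = []
    for row in df.itertuples():
        if row.rsid not in patterns:
            raise ValueError(f"{fragments_path}: no patterns for {row.rsid}")
        observed = [int(x) for x in str(row.bands).split("+")]
        call = call_genotype_from_fragments(
            observed, patterns[row.rsid], tol_bp=tol_bp,
            min_detectable_bp=min_detectable_bp,
        )
        rows.append(
            {
                "sample_id": row.sample_id,
                "rsid": row.rsid,
                "genotype": call.genotype,
                "dosage": dosage_of.get(call.genotype, np.nan),
                "diagnostics": "; ".join(call.diagnostics),
            }
        )
    return pd.DataFrame(rows)
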