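import numpy as np
import pytest

from alcprs import reference
from alcprs.genotype_io import MarginalCounts
from alcprs.prs_engine import PRSModel
from alcprs.synthetic_data import reconstruct_from_counts


@pytest.fixture(scope="session")
def variants():
    return list(reference.VARIANTS)


@pytest.fixture(scope="session")
def prs_model(variants):
    return PRSModel(variants)


@pytest.fixture(scope="session")
def study_marginals():
    return [reference.CASE_COUNTS, reference.CONTROL_COUNTS]


@pytest.fixture(scope="session")
def study_table(study_marginals):
    """Subject-level cohort reconstructed from the published genotype counts."""
    return reconstruct_from_counts(study_marginals, coupling_or=1.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def genotype_tsv(tmp_path):
    """Write a small allele-pair genotype TSV and return its path."""

    def _write(rows, header=("subject_id", "age", "sex", "phenotype",
                             "rs738409", "rs58542926")):
        path = tmp_path / "genotypes.tsv"
        lines = ["\t".join(header)]
        lines += ["\t".join(str(c) for c in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def make_marginals(case_counts, control_counts, rsids=("rs738409", "rs58542926")):
    """Build case/control MarginalCounts; a single (homref, het, homalt)
    triple is applied to every variant."""

    def per_variant(counts):
        if isinstance(counts[0], int):
            counts = [tuple(counts)] * len(rsids)
        return dict(zip(rsids, counts))

    return [
        MarginalCounts("case", per_variant(case_counts)),
        MarginalCounts("control", per_variant(control_counts)),
    ]
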