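import numpy as np
import pandas as pd
import pytest

from xburden import (
    Consequence,
    FilterConfig,
    Subject,
    SyntheticConfig,
    VariantRecord,
    build_boolean_matrix,
    generate_cohort,
)
from xburden.io import subjects_from_frame


@pytest.fixture
def filter_cfg() -> FilterConfig:
    return FilterConfig()


@pytest.fixture
def two_subjects() -> list[Subject]:
    return [
        Subject(id="S1", sex="M", age=45, clinical_category=3),
        Subject(id="S2", sex="M", age=40, clinical_category=0),
    ]


def make_variant(**kwargs) -> VariantRecord:
    defaults = dict(
        chrom="X",
        pos=1000,
        ref="G",
        alt="A",
        gene="GENE_A",
        consequence=Consequence.MISSENSE,
        nfe_af=0.0002,
        cadd=20.0,
        carriers=frozenset({"S1"}),
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


@pytest.fixture
def small_cohort():
    """A reproducible small synthetic cohort with its burden matrix and labels."""
    cfg = SyntheticConfig(
        n_cases=30, n_controls=30, n_genes=40, seed=11,
        carrier_freq_cases=0.3, background_burden_rate=0.05,
    )
    variants, subjects = generate_cohort(cfg)
    matrix = build_boolean_matrix(variants, subjects_from_frame(subjects))
    labels = (
        subjects.set_index("subject_id").loc[matrix.index, "clinical_category"] >= 3
    ).astype(int)
    return cfg, variants, subjects, matrix, labels
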