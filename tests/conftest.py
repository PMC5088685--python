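import numpy as np
import pandas as pd
import pytest

from oncocase.synthetic import (
    ExpressionSimConfig,
    GenomeLayout,
    VariantSimConfig,
    simulate_expression_compendium,
    simulate_tumor_normal_variants,
)
from oncocase.variants import VariantRecord, records_from_frame


def make_variant(**kwargs) -> VariantRecord:
    base = dict(chrom="chr1", pos=100, ref="A", alt="T", gene="GENE1",
                consequence="missense", normal_af=0.5, tumor_af=0.5,
                normal_depth=100, tumor_depth=100, genotype_normal="het",
                quality=50.0)
    base.update(kwargs)
    return VariantRecord(**base)


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    return GenomeLayout(
        chromosomes=(("chr1", 50_000_000), ("chr17", 30_000_000)),
        bin_size=100_000,
        loh_segments=(("chr17", 5_000_000, 25_000_000, "deletion"),),
    )


@pytest.fixture(scope="session")
def variant_case(small_layout):
    """A modest paired tumor/normal simulation with one deletion-LOH arm."""
    cfg = VariantSimConfig(n_germline_het=400, n_germline_hom=50, n_somatic=15,
                           seed=1)
    normal, tumor, truth = simulate_tumor_normal_variants(cfg, small_layout)
    return cfg, normal, tumor, truth


@pytest.fixture(scope="session")
def paired_records(variant_case):
    _, normal, tumor, _ = variant_case
    return records_from_frame(normal, "normal"), records_from_frame(tumor, "tumor")


@pytest.fixture(scope="session")
def small_compendium():
    cfg = ExpressionSimConfig(n_genes=600, n_housekeeping=60, n_tissues=3,
                              samples_per_tissue=20, seed=7)
    reference, test, truth = simulate_expression_compendium(cfg, test_tissue=1)
    return cfg, reference, test, truth
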