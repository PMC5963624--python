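import numpy as np
import pytest

from gbmcontrast.cohort import CohortManifest, VariantRecord, infer_variant_class
from gbmcontrast.synthetic import generate_cohort, paper_scale_config, small_config


def make_record(
    sample_id="s1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    gene="GENE1",
    zygosity="heterozygous",
    consequence="missense",
    is_coding=True,
    is_deleterious=False,
    aaf=None,
):
    return VariantRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        variant_class=infer_variant_class(ref, alt),
        zygosity=zygosity,
        consequence=consequence,
        is_coding=is_coding or is_deleterious,
        is_deleterious=is_deleterious,
        alt_allele_fraction=aaf,
    )


def random_mini_cohort(rng, n_s=3, n_l=3, n_genes=8, n_keys=20, density=0.25):
    """Random small cohort over a bounded key space, for oracle checks."""
    samples = [f"S{i}" for i in range(n_s)] + [f"L{i}" for i in range(n_l)]
    manifest = CohortManifest(
        [(f"S{i}", "S", 2 + i % 4) for i in range(n_s)]
        + [(f"L{i}", "L", 26 + i) for i in range(n_l)]
    )
    keys = [
        (f"chr{k % 2 + 1}", 100 + k, "A", "G", f"G{k % n_genes}")
        for k in range(n_keys)
    ]
    records = []
    for sid in samples:
        for chrom, pos, ref, alt, gene in keys:
            if rng.random() < density:
                records.append(
                    make_record(
                        sample_id=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                        gene=gene, is_coding=bool(rng.random() < 0.7),
                        is_deleterious=False,
                    )
                )
    return records, manifest


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=7))


@pytest.fixture(scope="session")
def paper_cohort():
    """Paper-scale preset; session-scoped because generation plus the
    full contrast takes a few seconds."""
    return generate_cohort(paper_scale_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
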