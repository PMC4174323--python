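import numpy as np
import pytest

import peachpop as pp


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One-contig default-design cohort with an edible-only sweep and a
    wild-only sweep, plus some missing genotypes."""
    spec = pp.default_cohort_spec(seed=42)
    spec.contigs = [("chr1", 80_000)]
    spec.missing_rate = 0.02
    spec.sweeps = [
        pp.SweepSpec("chr1", 2, ("C", "D", "E", "F"), "intermediate_excess", 0.35),
        pp.SweepSpec("chr1", 5, ("W",), "low_freq_excess", 0.3),
    ]
    out = tmp_path_factory.mktemp("cohort")
    paths = pp.simulate_cohort(spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, paths = small_cohort
    matrix, groups = pp.read_cohort(paths["vcf"], paths["groups"])
    return matrix, groups


@pytest.fixture(scope="session")
def small_annotation(small_cohort):
    _, paths = small_cohort
    return pp.GenomeAnnotation.from_files(paths["fasta"], paths["gff3"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(codes, contig="chr1", start_pos=100, spacing=50):
    """Wrap a plain code array (samples x sites) as a GenotypeMatrix."""
    import pandas as pd

    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    sites = pd.DataFrame(
        {
            "contig": [contig] * m,
            "pos": start_pos + spacing * np.arange(m),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return pp.GenotypeMatrix([f"s{i}" for i in range(n)], sites, codes)
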