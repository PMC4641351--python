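import numpy as np
import pytest

from xpr1popgen.fixtures import make_survey_fixture
from xpr1popgen.haplotypes import phase_homozygote_anchored


@pytest.fixture(scope="session")
def bundle():
    """The deterministic survey reconstruction (seed 1)."""
    return make_survey_fixture(1)


@pytest.fixture(scope="session")
def phased(bundle):
    """Phased catalogue and assignment for the survey reconstruction."""
    return phase_homozygote_anchored(bundle.genotypes, bundle.panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


def make_vcf(tmp_path, hap, positions, samples, chrom="chr1", contig_length=None):
    from xpr1popgen.io import write_vcf

    path = tmp_path / "fixture.vcf"
    write_vcf(path, hap, positions, samples, chrom=chrom, contig_length=contig_length)
    return str(path)
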