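import numpy as np
import pytest

from nipthap.phasing import TrioSite


def make_site(pos, father, mother, child, ref="A", alt="G", chrom="6"):
    """Build a TrioSite from 'A/G'-style genotype strings."""
    def gt(s):
        a, b = s.split("/")
        return (a, b)

    return TrioSite(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                    father_gt=gt(father), mother_gt=gt(mother), child_gt=gt(child))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
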