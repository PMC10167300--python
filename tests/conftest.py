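import pytest

from hlacomposite.hla_model import LocusGenotype, parse_allele


@pytest.fixture
def gt():
    """Genotype constructor from allele name strings."""

    def _gt(locus, *names, ranked=False):
        return LocusGenotype(
            locus=locus,
            alleles=tuple(parse_allele(n) for n in names),
            ranked=ranked,
        )

    return _gt
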