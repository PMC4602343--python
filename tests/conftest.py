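import pytest

from dcjmoments import augment, build_genome


@pytest.fixture
def three_gene_pair():
    """Three genes in one linear chromosome, ordered 1 2 3 in the red
    genome and 3 2 1 in the blue one: two breakpoints, observed DCJ
    distance 2, and a telomere correspondence under which the true
    scenario needs three DCJs."""
    red = build_genome([[1, 2, 3]])
    blue = build_genome([[3, 2, 1]])
    return red, blue


@pytest.fixture
def three_gene_pair_augmented(three_gene_pair):
    red, blue = three_gene_pair
    return augment(red), augment(blue)
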