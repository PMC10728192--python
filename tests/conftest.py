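import numpy as np
import pytest

from wormforge.cassette_design import design_gene
from wormforge.synthetic_data import build_toy_genome, make_gene_family


@pytest.fixture(scope="session")
def toy_study():
    """A small simulated study: 5 gene families of 3 (ancestor + 2 at 60%
    identity), one chromosome, plus one full design per gene."""
    rng = np.random.default_rng(11)
    families = {}
    for i in range(5):
        proteins, _ = make_gene_family(220, 3, 0.6, rng)
        families[f"fam{i + 1:02d}"] = proteins
    genome, models, gff_text = build_toy_genome(families, 400, rng)
    designs = {m.gene_id: design_gene(m, genome) for m in models}
    return dict(genome=genome, models=models, gff_text=gff_text, designs=designs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
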