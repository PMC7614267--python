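import pytest

from glycanpipe import (
    SimulationConfig,
    n_glycan_grammar,
    o_glycan_grammar,
    parse_structure,
    sample_structures,
)


@pytest.fixture(scope="session")
def n_grammar():
    return n_glycan_grammar()


@pytest.fixture(scope="session")
def o_grammar():
    return o_glycan_grammar()


@pytest.fixture(scope="session")
def noise_free_cfg():
    return SimulationConfig(
        seed=3, n_structures=120, mz_sigma=0.0, dropout=0.0, spurious_rate=0.0
    )


@pytest.fixture(scope="session")
def sampled_panel(noise_free_cfg):
    """A modest shared panel of ground-truth N-glycans (seeded)."""
    return sample_structures(noise_free_cfg)


@pytest.fixture
def galfuc_structure():
    """Hex5HexNAc2Fuc1 isoform with the GalFuc epitope on the proximal
    GlcNAc (label 1459; beta-galactosidase converts it to 1297)."""
    return parse_structure(
        "PA:GlcNAc(Fuc@a6(Gal@b4),GlcNAc@b4(Man@b4(Man@a3,Man@a6(Man@a3))))"
    )


@pytest.fixture
def lacdinac_structure():
    """Hex3HexNAc4Fuc1 with a terminal LacdiNAc antenna (label 1541;
    HEX-4 converts it to 1338)."""
    return parse_structure(
        "PA:GlcNAc(Fuc@a6,GlcNAc@b4(Man@b4(Man@a3(GlcNAc@b2(GalNAc@b4)),Man@a6)))"
    )
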