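import pytest

from trfscope.reference import TRNAReference, TRNASpecies
from trfscope.synthdata import make_trna_reference


@pytest.fixture
def toy_species() -> TRNASpecies:
    """Handcrafted 76-nt Cys-like species: 5 leading G, annotated variable-loop G."""
    seq = list("ACGU" * 19)  # 76 nt
    seq[:5] = "GGGGG"
    seq[44:49] = "ACGCA"  # variable loop
    seq[45] = "G"         # the annotated guanosine
    seq[73:76] = "CCA"
    seq = "".join(seq)
    return TRNASpecies(
        id="Cys-GCA-toy",
        amino_acid="Cys",
        anticodon="GCA",
        sequence=seq,
        m7g_pos=45,
        var_loop=(44, 49),
    )


@pytest.fixture
def toy_reference(toy_species) -> TRNAReference:
    other = TRNASpecies(
        id="Lys-CUU-toy",
        amino_acid="Lys",
        anticodon="CUU",
        sequence="GCCCGGCUAGCUCAGUCGGUAGAGCAUGGGACUCUUAAUCCCAGGGUCGUGGGUUCGAGCCCCACGUUGGGCGCCA",
        m7g_pos=None,
        var_loop=(44, 48),
    )
    return TRNAReference([toy_species, other])


@pytest.fixture
def sim_reference() -> TRNAReference:
    """4 random species, 2 annotated, first two are 5'TOG sources."""
    return make_trna_reference(4, 2, length=76, seed=42)
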