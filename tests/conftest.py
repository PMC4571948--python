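import pytest

from armotif import ProteinRecord, bundled_definitions


@pytest.fixture(scope="session")
def general_defs():
    return bundled_definitions("general")


@pytest.fixture(scope="session")
def submotif_defs():
    return bundled_definitions("submotifs")


@pytest.fixture(scope="session")
def all_defs():
    return bundled_definitions("all")


@pytest.fixture
def snap25_peptide():
    """The ten-residue SNAP25b peptide, numbered 111-120."""
    return ProteinRecord(
        id="SNAP25b_111_120", sequence="GVVASQPARV", numbering_offset=111
    )


@pytest.fixture
def htt_region():
    """The nine-residue mutated HTT region, numbered 494-502.

    The printed hexamer signature is anchored at 494 with Arg at 500; the
    two trailing residues are neutral filler (synthetic).
    """
    return ProteinRecord(id="HTT_494_502", sequence="IITEQPRAS", numbering_offset=494)
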