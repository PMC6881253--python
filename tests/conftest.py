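import pytest

from pipflank.io import load_reference_motif_table
from pipflank.motifs import MotifEntry


@pytest.fixture(scope="session")
def reference_entries():
    """The packaged synthetic stand-in for the curated 83-motif table."""
    return load_reference_motif_table()


@pytest.fixture
def p21_entry():
    """p21 PIP-degron in its peptide context, motif span covering QTSMTDFY."""
    return MotifEntry(
        protein_id="p21", species="H. sapiens",
        context_seq="RQTSMTDFYHSKRRL", motif_start=2, motif_end=9,
        declared_class="pip_degron", evidence_code="B",
        kd_molar=8.0e-8, measure_ph=7.4, measure_temp_K=298.15,
    )


@pytest.fixture
def apim_entry():
    """Synthetic APIM peptide; the 5-residue core RWLVK spans indices 3-7."""
    return MotifEntry(
        protein_id="APIM_peptide", species="H. sapiens",
        context_seq="MDRWLVKW", motif_start=3, motif_end=7,
        declared_class="apim", evidence_code="B",
    )
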