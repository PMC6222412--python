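import pytest

from scarkit.seqs import Alignment, SeqRecord, SpeciesPanel
from scarkit.simulate import PanelSpec, generate_panel


@pytest.fixture
def toy_panel() -> SpeciesPanel:
    """Three species, hand-built so the diagnostic columns are known.

    Columns (0-based):
      5: A is T, others C      -> substitution diagnostic for A
      9: A is '-', others G    -> indel diagnostic for A
      14: B is G, others A     -> substitution diagnostic for B
      20: C is C, others T     -> substitution diagnostic for C
    """
    base = "ACGTACGTAGGCTAACGTACTTACGTACGT"  # 30 columns
    a = list(base)
    b = list(base)
    c = list(base)
    a[5], b[5], c[5] = "T", "C", "C"
    a[9], b[9], c[9] = "-", "G", "G"
    a[14], b[14], c[14] = "A", "G", "A"
    a[20], b[20], c[20] = "T", "T", "C"
    records = [
        SeqRecord(id="a1", bases="".join(a), species="spA"),
        SeqRecord(id="a2", bases="".join(a), species="spA"),
        SeqRecord(id="b1", bases="".join(b), species="spB"),
        SeqRecord(id="b2", bases="".join(b), species="spB"),
        SeqRecord(id="c1", bases="".join(c), species="spC"),
    ]
    return SpeciesPanel(Alignment(records))


@pytest.fixture(scope="session")
def synthetic_panel():
    """Default synthetic reference panel with ground truth (seed 11)."""
    return generate_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def small_panel():
    """Quick 3-species panel for pipeline tests."""
    return generate_panel(PanelSpec(seed=7, n_species=3, n_per_species=2, length=400))
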