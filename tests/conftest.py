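import pytest

from glycopipe import PeptideSpectrumMatch, ProteinRecord


@pytest.fixture
def toy_proteome() -> list[ProteinRecord]:
    """Three hand-checkable proteins.

    P1 'MKLNGSAKR'     - one sequon at position 4 (NGS)
    P2 'AAANVTAAKLLLK' - one sequon at position 4 (NVT)
    P3 'GGGGKLLLLK'    - no sequons
    """
    return [
        ProteinRecord("P1", "MKLNGSAKR"),
        ProteinRecord("P2", "AAANVTAAKLLLK"),
        ProteinRecord("P3", "GGGGKLLLLK"),
    ]


@pytest.fixture
def toy_psms() -> list[PeptideSpectrumMatch]:
    return [
        PeptideSpectrumMatch("LDGSAK", ("P1",), 3, 0.95),   # deamidated site P1:4
        PeptideSpectrumMatch("LDGSAK", ("P1",), 2, 0.99),   # second run, same site
        PeptideSpectrumMatch("AAADVTAAK", ("P2",), 4, 0.98),  # deamidated site P2:4
        PeptideSpectrumMatch("GGGGK", ("P3",), 2, 0.97),    # sequon-free -> dropped
        PeptideSpectrumMatch("LDGSAK", ("P1",), 6, 0.50),   # below probability 0.9
    ]
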