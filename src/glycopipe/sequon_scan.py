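"""Enumerate putative N-glycosylation sequons (N-X-S/T, X != P) in proteins."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_model import ProteinRecord


@dataclass(frozen=True)
class SequonSite:
    """A putative N-glycosylation site: 1-based position of the N plus motif."""

    accession: str
    position: int
    motif: str

    def __post_init__(self) -> None:
        if not (self.motif[0] == "N" and self.motif[1] != "P" and self.motif[2] in "ST"):
            raise ValueError(f"{self.motif!r} is not a valid sequon motif")


def scan_sequons(sequence: str, accession: str = "") -> list[SequonSite]:
    """Return every sequon in ``sequence`` in ascending position order.

    The consensus is N-X-S/T with X any residue except proline.  Overlapping
    sequons are all reported; windows running past the C-terminus are not.
    Case-insensitive; 'X' (unknown residue) never satisfies the N or S/T
    positions but is accepted as the middle residue.
    """
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    seq = sequence.upper()
    sites = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            sites.append(SequonSite(accession, i + 1, seq[i:i + 3]))
    return sites


def scan_proteome(proteome: Iterable[ProteinRecord]) -> dict[str, list[SequonSite]]:
    """Scan every protein; returns accession → list of sequon sites."""
    return {rec.accession: scan_sequons(rec.sequence, rec.accession) for rec in proteome}


def count_sequons(proteome: Iterable[ProteinRecord] | Mapping[str, str]) -> dict[str, int]:
    """Per-protein sequon counts; proteins with zero sequons are retained.

    Accepts either ProteinRecords or a plain accession → sequence mapping.
    """
    if isinstance(proteome, Mapping):
        items = [(acc, seq) for acc, seq in proteome.items()]
    else:
        items = [(rec.accession, rec.sequence) for rec in proteome]
    if not items:
        raise ValueError("cannot count sequons of an empty proteome")
    return {acc: len(scan_sequons(seq, acc)) for acc, seq in items}
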