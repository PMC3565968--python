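"""Loader for the bundled glycoenzyme reference panel.

The panel lists, per glycosyl transferase / hydrolase, the predicted TM
count, the stoichiometry-normalized protein spectra, and the detected vs
putative glycosite counts.  It serves as a small real-world input for the
occupancy statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class GlycoenzymeRow:
    gene_id: str
    symbol: str
    family: str  # 'transferase' | 'hydrolase'
    tm_count: int
    protein_spectra: float
    detected_glycosites: int
    putative_sequons: int


def load_glycoenzyme_panel() -> list[GlycoenzymeRow]:
    text = (resources.files("glycopipe") / "data" / "glycoenzyme_panel.tsv").read_text()
    rows: list[GlycoenzymeRow] = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        rows.append(GlycoenzymeRow(
            gene_id=rec["gene_id"],
            symbol=rec["symbol"],
            family=rec["family"],
            tm_count=int(rec["tm_count"]),
            protein_spectra=float(rec["protein_spectra"]),
            detected_glycosites=int(rec["detected_glycosites"]),
            putative_sequons=int(rec["putative_sequons"]),
        ))
    return rows
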