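"""Domain types and readers/writers for the external formats the pipeline touches.

Coordinates are 1-based and inclusive on the protein sequence throughout;
every TSV written by this package states that in its ``#`` header block.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: letters accepted in a normalized protein sequence ('X' = unknown residue)
PROTEIN_ALPHABET = STANDARD_AA + "X"

FUNCTIONAL_CLASSES = ("receptor", "transporter", "enzyme", "miscellaneous", "unclassified")

TIERS = ("low", "medium", "high")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_sequence(raw: str) -> str:
    """Upper-case a protein sequence and map non-standard letters to 'X'.

    A single terminal '*' (stop) is stripped; any other non-alphabetic
    character is rejected.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FormatError("empty protein sequence")
    out = []
    for ch in seq:
        if ch in PROTEIN_ALPHABET:
            out.append(ch)
        elif ch.isalpha():
            out.append("X")
        else:
            raise FormatError(f"illegal character {ch!r} in protein sequence")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not self.accession:
            raise FormatError("protein accession must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    """One deglycosylated peptide identification.

    The peptide is written as searched: 'D' where a formerly glycosylated
    'N' was converted by PNGase F.
    """

    peptide: str
    protein_accessions: tuple[str, ...]
    spectra_count: float
    probability: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", self.peptide.strip().upper())
        object.__setattr__(self, "protein_accessions", tuple(self.protein_accessions))
        if len(self.peptide) < 5:
            raise FormatError(f"peptide {self.peptide!r} shorter than 5 residues")
        if any(ch not in PROTEIN_ALPHABET for ch in self.peptide):
            raise FormatError(f"peptide {self.peptide!r} contains non-residue characters")
        if not self.protein_accessions:
            raise FormatError("PSM must list at least one protein accession")
        if self.spectra_count <= 0:
            raise FormatError(f"spectra_count must be > 0, got {self.spectra_count}")
        if not 0.0 <= self.probability <= 1.0:
            raise FormatError(f"probability must be in [0,1], got {self.probability}")


@dataclass(frozen=True)
class GlycositeAssignment:
    """A called N-glycosylation site on a protein.

    ``position`` is the 1-based index of the asparagine.  ``ambiguous`` is
    set when the source peptide spans two or more sequons, in which case
    every candidate site is emitted carrying the flag.  ``spectra_count``
    follows the configured crediting rule (fractional by default) and
    ``site_credit`` is the detection weight the site receives (1 for an
    unambiguous call, 1/k for a k-fold ambiguous one).
    """

    accession: str
    position: int
    motif: str
    peptide: str
    spectra_count: float
    ambiguous: bool = False
    shared: bool = False
    site_credit: float = 1.0
    deamidated: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError("glycosite position must be >= 1 (1-based)")
        if len(self.motif) != 3 or self.motif[0] != "N":
            raise FormatError(f"glycosite motif must be a 3-letter N.. string, got {self.motif!r}")


@dataclass
class GlycoproteinProfile:
    """Per-protein rollup used by quantification and the statistics stages."""

    accession: str
    total_peptide_spectra: float
    stoichiometry: float
    protein_spectra: float
    sequon_count: int
    tier: str = ""
    occupancy: float = 0.0
    tm_count: int | None = None
    functional_class: str = "unclassified"

    def __post_init__(self) -> None:
        if self.stoichiometry <= 0:
            raise FormatError("glycoprotein stoichiometry must be >= 1 site credit")
        if self.protein_spectra <= 0:
            raise FormatError("protein_spectra must be > 0")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise FormatError(f"unknown functional class {self.functional_class!r}")


@dataclass(frozen=True)
class OrthologSet:
    """One ortholog group: entries are (species label, accession) pairs."""

    group_id: str
    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        species = {sp for sp, _ in self.entries}
        if len(species) < 2:
            raise FormatError(f"ortholog group {self.group_id} spans fewer than 2 species")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into ProteinRecords.

    The accession is the first whitespace-delimited token after '>'.
    Duplicate accessions and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise FormatError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(acc, str(rec.seq), desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def proteome_index(records: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    index: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.accession in index:
            raise FormatError(f"duplicate accession {rec.accession!r} in proteome")
        index[rec.accession] = rec
    return index


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

PSM_COLUMNS = ("peptide", "proteins", "spectra", "probability")


def read_psm_table(path: str | Path) -> list[PeptideSpectrumMatch]:
    """Read a PSM TSV (columns: peptide, proteins, spectra[, probability]).

    ``proteins`` is a semicolon-separated, order-preserving accession list.
    The probability column is optional and defaults to 1.0.  Rows violating
    the PSM invariants raise a line-numbered error.
    """
    psms: list[PeptideSpectrumMatch] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                for col in ("peptide", "proteins", "spectra"):
                    if col not in header:
                        raise FormatError(f"{path}: missing mandatory column {col!r}")
                continue
            row = dict(zip(header, fields))
            try:
                psm = PeptideSpectrumMatch(
                    peptide=row["peptide"],
                    protein_accessions=tuple(
                        a.strip() for a in row["proteins"].split(";") if a.strip()
                    ),
                    spectra_count=float(row["spectra"]),
                    probability=float(row.get("probability", 1.0) or 1.0),
                )
            except (FormatError, ValueError, KeyError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            psms.append(psm)
    if header is None:
        raise FormatError(f"{path}: empty PSM table")
    return psms


def write_psm_table(psms: Iterable[PeptideSpectrumMatch], path: str | Path,
                    header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for p in psms:
            fh.write(
                f"{p.peptide}\t{';'.join(p.protein_accessions)}\t"
                f"{fmt_num(p.spectra_count)}\t{fmt_num(p.probability)}\n"
            )


# ---------------------------------------------------------------------------
# TM annotations, class maps, ortholog tables
# ---------------------------------------------------------------------------

def read_tm_annotations(path: str | Path, dialect: str = "plain") -> dict[str, int]:
    """Read per-protein TM counts.

    dialect='plain': two-column TSV (accession, tm_count).
    dialect='tmhmm_short': TMHMM short-format output; the count is taken
    from the ``PredHel=`` field.
    """
    if dialect not in ("plain", "tmhmm_short"):
        raise ValueError(f"unknown TM annotation dialect {dialect!r}")
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "plain":
                fields = line.split("\t")
                if len(fields) < 2:
                    raise FormatError(f"{path}: line {lineno}: expected 2 columns")
                acc = fields[0].strip()
                low = fields[1].strip().lower()
                if low == "tm_count":  # tolerated header row
                    continue
                try:
                    counts[acc] = int(fields[1])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: bad tm_count {fields[1]!r}") from exc
            else:
                fields = line.split()
                acc = fields[0]
                pred = [f for f in fields if f.startswith("PredHel=")]
                if not pred:
                    raise FormatError(f"{path}: line {lineno}: no PredHel= field")
                try:
                    counts[acc] = int(pred[0].split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: bad PredHel value") from exc
    return counts


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read an accession → functional-class TSV; classes are mutually exclusive."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            acc, cls = fields[0].strip(), fields[1].strip().lower()
            if cls == "class":
                continue
            if cls not in FUNCTIONAL_CLASSES:
                raise FormatError(f"{path}: line {lineno}: unknown class {cls!r}")
            if acc in mapping and mapping[acc] != cls:
                raise FormatError(f"{path}: line {lineno}: conflicting class for {acc!r}")
            mapping[acc] = cls
    return mapping


def read_ortholog_table(path: str | Path) -> list[OrthologSet]:
    """Read ortholog groups from a TSV (group_id, species, accession)."""
    groups: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            gid, sp, acc = (f.strip() for f in fields[:3])
            if gid == "group_id":
                continue
            if gid not in groups:
                groups[gid] = []
                order.append(gid)
            groups[gid].append((sp, acc))
    return [OrthologSet(gid, tuple(groups[gid])) for gid in order]


# ---------------------------------------------------------------------------
# Generic TSV output with provenance header
# ---------------------------------------------------------------------------

def fmt_num(x: float) -> str:
    """Render a number compactly: integers without a decimal point."""
    if isinstance(x, bool):
        return str(x)
    f = float(x)
    if f.is_integer():
        return str(int(f))
    return format(f, ".6g")


def write_tsv(path: str | Path | TextIO, columns: Sequence[str],
              rows: Iterable[Sequence[object]],
              header_comments: Sequence[str] = ()) -> None:
    """Write a TSV with '#'-prefixed provenance comments above the header."""
    from . import __version__

    own = path if hasattr(path, "write") else open(path, "w")
    try:
        own.write(f"# glycopipe {__version__}; coordinates 1-based inclusive\n")
        for comment in header_comments:
            own.write(f"# {comment}\n")
        own.write("\t".join(columns) + "\n")
        for row in rows:
            own.write("\t".join(
                fmt_num(v) if isinstance(v, (int, float)) else str(v) for v in row
            ) + "\n")
    finally:
        if own is not path:
            own.close()


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read back a TSV written by :func:`write_tsv` (comments skipped)."""
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise FormatError(f"{path}: no header row")
    return header, rows


def warn(msg: str) -> None:
    print(f"glycopipe: warning: {msg}", file=sys.stderr)
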