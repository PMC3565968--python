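"""Map deglycosylated PSMs onto proteins and call N-glycosites.

Matching tolerates 'D' in the peptide where the protein has 'N', but only
at sequon asparagines — the signature left by PNGase F deglycosylation.
Peptides spanning two or more sequons cannot be localized confidently and
are flagged ambiguous; all candidate sites are emitted with the flag and,
under the default crediting rule, each receives 1/k of the evidence so that
spectra and site counts are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_model import (
    FormatError,
    GlycositeAssignment,
    PeptideSpectrumMatch,
    ProteinRecord,
    proteome_index,
)
from .sequon_scan import scan_sequons

CREDITING_RULES = ("fractional", "first", "all")


def tryptic_digest(sequence: str, max_missed: int = 2,
                   min_length: int = 1) -> list[tuple[str, int, int]]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Returns every peptide with at most ``max_missed`` internal missed
    cleavage sites and length >= ``min_length``, as (peptide, start, end)
    with 1-based inclusive coordinates, ordered by start then end.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = sequence.upper()
    # fully cleaved fragment boundaries
    cuts = [0]
    for i in range(len(seq) - 1):
        if seq[i] in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    fragments = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    peptides: list[tuple[str, int, int]] = []
    for i in range(len(fragments)):
        for j in range(i, min(i + max_missed + 1, len(fragments))):
            start, end = fragments[i][0], fragments[j][1]
            if end - start >= min_length:
                peptides.append((seq[start:end], start + 1, end))
    return peptides


def _match_at(peptide: str, sequence: str, start0: int,
              sequon_positions: frozenset[int]) -> tuple[int, ...] | None:
    """Try to align ``peptide`` at 0-based ``start0``; return the 1-based
    positions where a peptide 'D' sits on a sequon 'N', or None on mismatch."""
    deamidated = []
    for j, pch in enumerate(peptide):
        sch = sequence[start0 + j]
        if pch == sch:
            continue
        if pch == "D" and sch == "N" and (start0 + j + 1) in sequon_positions:
            deamidated.append(start0 + j + 1)
            continue
        return None
    return tuple(deamidated)


def locate_peptide(peptide: str, proteome: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
                   sequon_index: Mapping[str, frozenset[int] | set[int]],
                   ) -> list[tuple[str, int, tuple[int, ...]]]:
    """Find every protein location where ``peptide`` matches.

    Peptide 'D' may stand for protein 'N' only at sequon asparagines (from
    ``sequon_index``: accession → set of 1-based N positions).  Returns
    (accession, 1-based start, deamidated sequon positions) triples; an
    unmatched peptide yields an empty list.
    """
    if not isinstance(proteome, Mapping):
        proteome = proteome_index(proteome)
    peptide = peptide.upper()
    hits: list[tuple[str, int, tuple[int, ...]]] = []
    for acc, rec in proteome.items():
        seq = rec.sequence
        positions = frozenset(sequon_index.get(acc, frozenset()))
        for start0 in range(len(seq) - len(peptide) + 1):
            matched = _match_at(peptide, seq, start0, positions)
            if matched is not None:
                hits.append((acc, start0 + 1, matched))
    return hits


@dataclass
class AssignmentStats:
    """Bookkeeping for the sequon-free filter and ambiguity accounting."""

    psms_in: int = 0
    spectra_in: float = 0.0
    psms_assigned: int = 0
    spectra_assigned: float = 0.0
    psms_dropped_no_sequon: int = 0
    spectra_dropped_no_sequon: float = 0.0
    psms_dropped_no_match: int = 0
    spectra_dropped_no_match: float = 0.0
    peptides_total: int = 0
    peptides_ambiguous: int = 0
    psms_ambiguous: int = 0

    @property
    def ambiguity_rate_peptides(self) -> float:
        if self.peptides_total == 0:
            raise ValueError("no identified peptides")
        return self.peptides_ambiguous / self.peptides_total

    @property
    def ambiguity_rate_psms(self) -> float:
        if self.psms_in == 0:
            raise ValueError("no PSMs")
        return self.psms_ambiguous / self.psms_in


def assign_glycosites(psms: Iterable[PeptideSpectrumMatch],
                      proteome: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
                      crediting: str = "fractional",
                      ) -> tuple[list[GlycositeAssignment], AssignmentStats]:
    """Call glycosites from deglycosylated PSMs.

    Each PSM is matched against the proteins it lists.  Candidate sites are
    the sequon asparagines covered by the matched span; a span covering >= 2
    sequons is ambiguous and all candidates are emitted flagged.  PSMs whose
    peptides cover no sequon anywhere are dropped and tallied (the paper's
    "non-N-glycoprotein" filter).  ``crediting`` controls how an ambiguous
    peptide's evidence is split: 'fractional' (1/k per site, conserving),
    'first' (all to the N-terminal-most site) or 'all' (full to every site).
    """
    if crediting not in CREDITING_RULES:
        raise ValueError(f"crediting must be one of {CREDITING_RULES}")
    if not isinstance(proteome, Mapping):
        proteome = proteome_index(proteome)
    sequon_index = {
        acc: frozenset(s.position for s in scan_sequons(rec.sequence, acc))
        for acc, rec in proteome.items()
    }

    assignments: list[GlycositeAssignment] = []
    stats = AssignmentStats()
    peptide_flags: dict[str, bool] = {}  # peptide -> ambiguous anywhere

    for psm in psms:
        stats.psms_in += 1
        stats.spectra_in += psm.spectra_count
        missing = [a for a in psm.protein_accessions if a not in proteome]
        if missing:
            raise FormatError(
                "PSM references accessions absent from the proteome: " + ", ".join(missing)
            )
        per_protein: dict[str, dict[int, bool]] = {}  # acc -> {site: deamidated}
        matched_anywhere = False
        for acc in psm.protein_accessions:
            rec = proteome[acc]
            positions = sequon_index[acc]
            sites: dict[int, bool] = {}
            for start0 in range(len(rec.sequence) - len(psm.peptide) + 1):
                deam = _match_at(psm.peptide, rec.sequence, start0, positions)
                if deam is None:
                    continue
                matched_anywhere = True
                end = start0 + len(psm.peptide)  # 1-based inclusive end
                for pos in positions:
                    if start0 + 1 <= pos <= end:
                        sites[pos] = sites.get(pos, False) or (pos in deam)
            if sites:
                per_protein[acc] = sites

        if not matched_anywhere:
            stats.psms_dropped_no_match += 1
            stats.spectra_dropped_no_match += psm.spectra_count
            continue
        if not per_protein:
            stats.psms_dropped_no_sequon += 1
            stats.spectra_dropped_no_sequon += psm.spectra_count
            peptide_flags.setdefault(psm.peptide, False)
            continue

        stats.psms_assigned += 1
        stats.spectra_assigned += psm.spectra_count
        shared = len(per_protein) > 1
        psm_ambiguous = False
        for acc, sites in per_protein.items():
            ordered = sorted(sites)
            k = len(ordered)
            ambiguous = k >= 2
            psm_ambiguous = psm_ambiguous or ambiguous
            if crediting == "first" and ambiguous:
                chosen = {ordered[0]: sites[ordered[0]]}
                credit, spectra = 1.0, psm.spectra_count
            elif crediting == "fractional":
                chosen = sites
                credit, spectra = 1.0 / k, psm.spectra_count / k
            else:  # 'all', or unambiguous 'first'
                chosen = sites
                credit, spectra = 1.0, psm.spectra_count
            seq = proteome[acc].sequence
            for pos, deam in sorted(chosen.items()):
                assignments.append(GlycositeAssignment(
                    accession=acc,
                    position=pos,
                    motif=seq[pos - 1:pos + 2],
                    peptide=psm.peptide,
                    spectra_count=spectra,
                    ambiguous=ambiguous,
                    shared=shared,
                    site_credit=credit,
                    deamidated=deam,
                ))
        if psm_ambiguous:
            stats.psms_ambiguous += 1
        peptide_flags[psm.peptide] = peptide_flags.get(psm.peptide, False) or psm_ambiguous

    stats.peptides_total = len(peptide_flags)
    stats.peptides_ambiguous = sum(peptide_flags.values())
    return assignments, stats


def ambiguity_rate(assignments_or_stats, denominator: str = "peptides") -> float:
    """Fraction of identified peptides (or PSMs) flagged ambiguous."""
    if isinstance(assignments_or_stats, AssignmentStats):
        if denominator == "peptides":
            return assignments_or_stats.ambiguity_rate_peptides
        return assignments_or_stats.ambiguity_rate_psms
    assignments = list(assignments_or_stats)
    if not assignments:
        raise ValueError("no assignments")
    flags: dict[str, bool] = {}
    for a in assignments:
        flags[a.peptide] = flags.get(a.peptide, False) or a.ambiguous
    return sum(flags.values()) / len(flags)


@dataclass
class ProteinGroup:
    """Degenerate proteins identified by one peptide set; first accession leads."""

    representative: str
    members: tuple[str, ...]
    peptides: frozenset[str]
    total_spectra: float


@dataclass
class FilterResult:
    psms: list[PeptideSpectrumMatch]
    groups: list[ProteinGroup]
    psms_below_probability: int = 0
    spectra_below_probability: float = 0.0
    single_hit_groups_removed: int = 0
    psms_orphaned: int = 0
    proteins_merged: int = 0


def filter_identifications(psms: Sequence[PeptideSpectrumMatch],
                           min_probability: float = 0.9,
                           remove_single_hits: bool = True) -> FilterResult:
    """Apply the identification filters ahead of site assignment.

    PSMs below ``min_probability`` are removed.  Proteins identified by an
    identical peptide set are merged into one group represented by the first
    accession in input order.  Groups whose total spectra count is 1 are
    removed when ``remove_single_hits``.  Accession lists of surviving PSMs
    are rewritten to group representatives; PSMs left with no protein are
    dropped (orphaned tally).
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError(f"min_probability must be in [0,1], got {min_probability}")
    result = FilterResult(psms=[], groups=[])
    kept: list[PeptideSpectrumMatch] = []
    for psm in psms:
        if psm.probability < min_probability:
            result.psms_below_probability += 1
            result.spectra_below_probability += psm.spectra_count
        else:
            kept.append(psm)

    # per-protein peptide sets and spectra, in first-seen accession order
    peptide_sets: dict[str, set[str]] = {}
    spectra: dict[str, float] = {}
    order: list[str] = []
    for psm in kept:
        for acc in psm.protein_accessions:
            if acc not in peptide_sets:
                peptide_sets[acc] = set()
                spectra[acc] = 0.0
                order.append(acc)
            peptide_sets[acc].add(psm.peptide)
            spectra[acc] += psm.spectra_count

    by_set: dict[frozenset[str], list[str]] = {}
    group_order: list[frozenset[str]] = []
    for acc in order:
        key = frozenset(peptide_sets[acc])
        if key not in by_set:
            by_set[key] = []
            group_order.append(key)
        by_set[key].append(acc)

    representative: dict[str, str] = {}
    groups: list[ProteinGroup] = []
    for key in group_order:
        members = by_set[key]
        rep = members[0]
        total = spectra[rep]
        group = ProteinGroup(rep, tuple(members), key, total)
        if remove_single_hits and total <= 1:
            result.single_hit_groups_removed += 1
            continue
        groups.append(group)
        result.proteins_merged += len(members) - 1
        for acc in members:
            representative[acc] = rep

    for psm in kept:
        reps: list[str] = []
        for acc in psm.protein_accessions:
            rep = representative.get(acc)
            if rep is not None and rep not in reps:
                reps.append(rep)
        if not reps:
            result.psms_orphaned += 1
            continue
        if reps == list(psm.protein_accessions):
            result.psms.append(psm)
        else:
            result.psms.append(PeptideSpectrumMatch(
                psm.peptide, tuple(reps), psm.spectra_count, psm.probability))
    result.groups = groups
    return result
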