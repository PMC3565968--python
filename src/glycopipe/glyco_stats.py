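"""Occupancy and glycosylation-rate statistics, stoichiometry grouping,
hydropathy-based TM prediction, class summaries and cross-species profiles.

The TM predictor is a Kyte-Doolittle sliding-window surrogate for a full
membrane-topology HMM; every TM-dependent statistic also accepts
precomputed per-protein TM counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_model import GlycoproteinProfile, ProteinRecord, warn
from .sequon_scan import scan_sequons

#: Kyte-Doolittle hydropathy index; 'X' (unknown) scored hydrophilic.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": -4.5,
}


def occupancy(detected: float, sequons: int) -> float:
    """Per-protein sequon occupancy: detected glycosites / putative sequons."""
    if sequons < 1:
        raise ValueError("occupancy undefined for a protein without sequons")
    if detected < 0 or detected > sequons:
        raise ValueError(
            f"detected glycosites ({detected}) must lie in [0, sequons={sequons}]")
    return detected / sequons


def _occupancies(items: Iterable) -> list[float]:
    vals: list[float] = []
    for item in items:
        if isinstance(item, GlycoproteinProfile):
            vals.append(item.occupancy)
        elif isinstance(item, (tuple, list)) and len(item) == 2:
            vals.append(occupancy(item[0], item[1]))
        else:
            vals.append(float(item))
    return vals


def set_glycosylation_rate(profiles: Iterable) -> float:
    """Unweighted mean of per-protein occupancies.

    Accepts GlycoproteinProfiles, (detected, sequons) pairs, or bare
    occupancy fractions.
    """
    vals = _occupancies(profiles)
    if not vals:
        raise ValueError("cannot average an empty set of proteins")
    return float(np.mean(vals))


@dataclass
class StoichiometryGroup:
    """Proteins binned by glycans-per-protein k (k >= cap pooled into cap)."""

    k: int
    accessions: tuple[str, ...]
    mean_protein_spectra: float
    pct_low_tm: float | None  # percent of TM-annotated members with <= split TMs
    pct_high_tm: float | None

    @property
    def n(self) -> int:
        return len(self.accessions)


def stoichiometry_groups(profiles: Sequence[GlycoproteinProfile],
                         max_k: int = 8, tm_split: int = 2) -> list[StoichiometryGroup]:
    """Group the glycoproteome by glycosylation stoichiometry.

    Fractional stoichiometries (ambiguity crediting) are rounded to the
    nearest integer, floored at 1; k >= ``max_k`` pools into the top group.
    The low/high TM split is <= ``tm_split`` vs > ``tm_split`` over members
    with a TM annotation (percentages sum to 100 there).
    """
    bins: dict[int, list[GlycoproteinProfile]] = {}
    for p in profiles:
        k = min(max_k, max(1, int(round(p.stoichiometry))))
        bins.setdefault(k, []).append(p)
    groups: list[StoichiometryGroup] = []
    for k in sorted(bins):
        members = bins[k]
        annotated = [p for p in members if p.tm_count is not None]
        if annotated:
            low = sum(1 for p in annotated if p.tm_count <= tm_split)
            pct_low = 100.0 * low / len(annotated)
            pct_high = 100.0 - pct_low
        else:
            pct_low = pct_high = None
        groups.append(StoichiometryGroup(
            k=k,
            accessions=tuple(p.accession for p in members),
            mean_protein_spectra=float(np.mean([p.protein_spectra for p in members])),
            pct_low_tm=pct_low,
            pct_high_tm=pct_high,
        ))
    return groups


def predict_tm(sequence: str, window: int = 19, threshold: float = 1.6,
               min_gap: int = 5) -> tuple[int, list[tuple[int, int]]]:
    """Count membrane-spanning segments by mean Kyte-Doolittle hydropathy.

    Windows of length ``window`` whose mean hydropathy exceeds ``threshold``
    are merged into segments (1-based inclusive residue spans); segments
    separated by fewer than ``min_gap`` residues are fused.  Sequences
    shorter than one window yield zero segments.  Deterministic and
    position-covariant.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return 0, []
    scores = np.array([KYTE_DOOLITTLE.get(ch, -4.5) for ch in seq], dtype=float)
    means = np.convolve(scores, np.ones(window) / window, mode="valid")
    hot = means > threshold
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            segments.append((i + 1, j + window))  # residue span of the window run
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for start, end in segments:
        if merged and start - merged[-1][1] - 1 < min_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return len(merged), merged


@dataclass
class ClassSummary:
    """Per-functional-class means over the profiled glycoproteome."""

    functional_class: str
    n: int
    mean_glycans: float
    mean_sequons: float
    mean_tms: float | None
    glycosylation_rate: float
    mean_protein_spectra: float


def class_summary(profiles: Sequence[GlycoproteinProfile],
                  class_map: Mapping[str, str] | None = None) -> list[ClassSummary]:
    """Summarize profiles per functional class; absent classes are omitted.

    ``class_map`` (accession → class) overrides the class stored on each
    profile; unmapped accessions fall back to the profile's own class.
    """
    by_class: dict[str, list[GlycoproteinProfile]] = {}
    for p in profiles:
        cls = (class_map or {}).get(p.accession, p.functional_class)
        by_class.setdefault(cls, []).append(p)
    out: list[ClassSummary] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        tms = [p.tm_count for p in members if p.tm_count is not None]
        out.append(ClassSummary(
            functional_class=cls,
            n=len(members),
            mean_glycans=float(np.mean([p.stoichiometry for p in members])),
            mean_sequons=float(np.mean([p.sequon_count for p in members])),
            mean_tms=float(np.mean(tms)) if tms else None,
            glycosylation_rate=set_glycosylation_rate(members),
            mean_protein_spectra=float(np.mean([p.protein_spectra for p in members])),
        ))
    return out


@dataclass
class SpeciesClassProfile:
    species: str
    functional_class: str
    n: int
    mean_sequons: float
    mean_tms: float


def cross_species_profile(ortholog_sets: Sequence,
                          proteomes: Mapping[str, Mapping[str, ProteinRecord]],
                          class_map: Mapping[str, str] | None = None,
                          tm_counts: Mapping[str, int] | None = None,
                          ) -> tuple[list[SpeciesClassProfile], int]:
    """Mean sequon and TM counts per species x functional class.

    Each ortholog group inherits the class of its first member present in
    ``class_map`` (default 'unclassified').  Sequon counts come from the
    scanner; TM counts from ``tm_counts`` when supplied, else from
    :func:`predict_tm`.  Unresolvable accessions are warned about, excluded
    and counted; the count is returned alongside the profiles.
    """
    per: dict[tuple[str, str], list[tuple[int, int]]] = {}
    excluded = 0
    for group in ortholog_sets:
        cls = "unclassified"
        if class_map:
            for _, acc in group.entries:
                if acc in class_map:
                    cls = class_map[acc]
                    break
        for species, acc in group.entries:
            rec = proteomes.get(species, {}).get(acc)
            if rec is None:
                warn(f"ortholog {acc!r} not found in proteome of {species!r}; excluded")
                excluded += 1
                continue
            n_seq = len(scan_sequons(rec.sequence, acc))
            if tm_counts is not None and acc in tm_counts:
                n_tm = tm_counts[acc]
            else:
                n_tm, _ = predict_tm(rec.sequence)
            per.setdefault((species, cls), []).append((n_seq, n_tm))
    profiles = [
        SpeciesClassProfile(
            species=sp, functional_class=cls, n=len(vals),
            mean_sequons=float(np.mean([v[0] for v in vals])),
            mean_tms=float(np.mean([v[1] for v in vals])),
        )
        for (sp, cls), vals in sorted(per.items())
    ]
    return profiles, excluded
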