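"""Stoichiometry-normalized spectral-count quantification.

Protein quantity = summed peptide spectra counts divided by the number of
distinct detected glycosites (the N-glycan stoichiometry).  Quantities fall
into three empirical tiers (<5 low, 5-12 medium, >12 high) and can be put
on an absolute copies-per-cell scale through a single reference protein.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .io_model import GlycositeAssignment, GlycoproteinProfile, warn


def protein_spectra(assignments: Iterable[GlycositeAssignment],
                    ) -> dict[str, tuple[float, float, float]]:
    """Roll assignments up per protein.

    Returns accession → (total_peptide_spectra, stoichiometry,
    protein_spectra).  Stoichiometry is the summed detection credit over
    distinct sites (an unambiguous site counts 1; sites seen only through
    k-fold ambiguous peptides count their best credit, 1/k).  Proteins whose
    stoichiometry rounds to zero are excluded with a warning.
    """
    spectra: dict[str, float] = {}
    site_credit: dict[str, dict[int, float]] = {}
    for a in assignments:
        spectra[a.accession] = spectra.get(a.accession, 0.0) + a.spectra_count
        credits = site_credit.setdefault(a.accession, {})
        credits[a.position] = max(credits.get(a.position, 0.0), a.site_credit)
    out: dict[str, tuple[float, float, float]] = {}
    for acc, total in spectra.items():
        stoich = sum(site_credit[acc].values())
        if stoich <= 0:
            warn(f"{acc}: zero glycan stoichiometry; excluded as non-glycoprotein")
            continue
        out[acc] = (total, stoich, total / stoich)
    return out


def abundance_tier(spectra: float) -> str:
    """Empirical quantity tier: <5 low, 5-12 (inclusive) medium, >12 high."""
    if spectra <= 0:
        raise ValueError(f"protein spectra must be positive, got {spectra}")
    if spectra < 5:
        return "low"
    if spectra <= 12:
        return "medium"
    return "high"


def calibrate_copies(spectra: float, ref_spectra: float, ref_copies: float) -> float:
    """Copies/cell via a linear-through-origin single-reference calibration."""
    if ref_spectra <= 0 or ref_copies <= 0:
        raise ValueError("reference spectra and copies must be positive")
    if spectra < 0:
        raise ValueError("protein spectra must be non-negative")
    return spectra * ref_copies / ref_spectra


def build_profiles(assignments: Iterable[GlycositeAssignment],
                   sequon_counts: Mapping[str, int],
                   tm_counts: Mapping[str, int] | None = None,
                   class_map: Mapping[str, str] | None = None,
                   ) -> list[GlycoproteinProfile]:
    """Assemble per-protein profiles from assignments plus annotations.

    ``sequon_counts`` must cover every assigned protein (from sequon_scan).
    Occupancy = stoichiometry / sequon_count, clipped into (0, 1].
    """
    quant = protein_spectra(assignments)
    profiles: list[GlycoproteinProfile] = []
    for acc in sorted(quant):
        total, stoich, prot_spec = quant[acc]
        if acc not in sequon_counts:
            raise KeyError(f"no sequon count for assigned protein {acc!r}")
        n_sequons = sequon_counts[acc]
        if n_sequons < 1:
            warn(f"{acc}: assignments but no sequons; skipped")
            continue
        occ = min(stoich / n_sequons, 1.0)
        profiles.append(GlycoproteinProfile(
            accession=acc,
            total_peptide_spectra=total,
            stoichiometry=stoich,
            protein_spectra=prot_spec,
            sequon_count=n_sequons,
            tier=abundance_tier(prot_spec),
            occupancy=occ,
            tm_count=None if tm_counts is None else tm_counts.get(acc),
            functional_class=(class_map or {}).get(acc, "unclassified"),
        ))
    return profiles
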