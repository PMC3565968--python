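"""Deterministic synthetic proteomes and PSM tables with known ground truth.

Sequences are drawn from a configurable background residue distribution;
transmembrane segments are planted as hydrophobic stretches and sequons are
planted outside them (membrane-spanning stretches need flanking space before
a glycosylation site, so a margin is kept by default).  PSM simulation
digests tryptically, draws per-sequon occupancy, converts occupied N to D,
and emits Poisson spectra counts proportional to protein abundance.  All
randomness flows through one integer-seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_model import PeptideSpectrumMatch, ProteinRecord, STANDARD_AA
from .glycosite_map import tryptic_digest
from .sequon_scan import scan_sequons

HYDROPHOBIC = "LIVFMA"
#: middle-residue choices that can never seed or feed a second sequon
SEQUON_X_CHOICES = sorted(set(STANDARD_AA) - set("PKRST"))

DEFAULT_CLASS_MIX = {
    "receptor": 0.42, "transporter": 0.17, "enzyme": 0.15, "miscellaneous": 0.26,
}

#: per-class probability vectors over TM counts 0,1,2,...
DEFAULT_TM_MODEL: dict[str, tuple[float, ...]] = {
    "receptor": (0.15, 0.60, 0.25),
    "transporter": (0.0, 0.05, 0.10, 0.15, 0.20, 0.20, 0.15, 0.10, 0.05),
    "enzyme": (0.45, 0.45, 0.10),
    "miscellaneous": (0.60, 0.30, 0.10),
    "unclassified": (0.60, 0.30, 0.10),
}


@dataclass
class SyntheticProtein:
    """Ground truth for one generated protein."""

    accession: str
    functional_class: str
    sequence: str
    tm_segments: tuple[tuple[int, int], ...]      # 1-based inclusive
    planted_sequons: tuple[int, ...]              # 1-based N positions
    abundance: float = 0.0                        # filled by simulate_psms
    sequon_occupied: dict[int, bool] = field(default_factory=dict)
    fully_covered: bool = True

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)


@dataclass
class SyntheticTruth:
    """Everything planted, keyed by accession, plus the seed used."""

    seed: int
    proteins: dict[str, SyntheticProtein] = field(default_factory=dict)

    def class_map(self) -> dict[str, str]:
        return {acc: p.functional_class for acc, p in self.proteins.items()}

    def tm_counts(self) -> dict[str, int]:
        return {acc: p.tm_count for acc, p in self.proteins.items()}


def _sample_length(length_distribution, rng: np.random.Generator) -> int:
    if callable(length_distribution):
        return int(length_distribution(rng))
    if isinstance(length_distribution, (tuple, list)):
        lo, hi = length_distribution
        return int(rng.integers(lo, hi + 1))
    return int(length_distribution)


def _background_letters(freqs: Mapping[str, float] | None,
                        exclude: str = "") -> tuple[list[str], np.ndarray]:
    if freqs is None:
        letters = [aa for aa in STANDARD_AA if aa not in exclude]
        probs = np.full(len(letters), 1.0 / len(letters))
    else:
        letters = [aa for aa in freqs if aa not in exclude]
        probs = np.array([freqs[aa] for aa in letters], dtype=float)
        probs = probs / probs.sum()
    return letters, probs


def _build_protein(rng: np.random.Generator, length: int, tm_count: int,
                   n_sequons: int, *, background_freqs=None,
                   regular_cleavage: bool, suppress_background_sequons: bool,
                   tm_length: int = 21, tm_margin: int = 12, block: int = 12,
                   sequon_pairing: float = 0.0, clip_to_capacity: bool = False,
                   ) -> tuple[str, list[tuple[int, int]], list[int]]:
    """Generate one sequence with planted TMs and sequons.

    Returns (sequence, tm segments 1-based inclusive, planted N positions).
    In ``regular_cleavage`` mode the backbone is built from fixed-size
    tryptic blocks terminated by K/R so every planted sequon falls into a
    short fully-cleaved peptide.
    """
    if length < 3:
        raise ValueError("protein length must be >= 3")
    if regular_cleavage:
        n_blocks = max(1, length // block)
        length = n_blocks * block
        letters, probs = _background_letters(background_freqs, exclude="KRP")
        seq = list(rng.choice(letters, size=length, p=probs))
        for b in range(n_blocks):
            seq[(b + 1) * block - 1] = "K" if rng.random() < 0.5 else "R"

        tm_blocks_needed = 2  # one TM spans two blocks (23 hydrophobic residues)
        # candidate starting blocks for TMs, keeping one spacer block between
        placed_tm_blocks: set[int] = set()
        tm_segments: list[tuple[int, int]] = []
        candidates = list(range(n_blocks - tm_blocks_needed + 1))
        rng.shuffle(candidates)
        for start_b in candidates:
            if len(tm_segments) == tm_count:
                break
            span = set(range(start_b - 1, start_b + tm_blocks_needed + 1))
            if span & placed_tm_blocks:
                continue
            placed_tm_blocks.update(range(start_b, start_b + tm_blocks_needed))
            s0 = start_b * block
            e0 = s0 + tm_blocks_needed * block - 1  # keep final K/R
            for i in range(s0, e0):
                seq[i] = rng.choice(list(HYDROPHOBIC))
            tm_segments.append((s0 + 1, e0))
        if len(tm_segments) < tm_count:
            raise ValueError(
                f"cannot place {tm_count} TM segments in a {length}-residue protein")

        forbidden_blocks = set(placed_tm_blocks)
        for b in list(placed_tm_blocks):  # margin: no sequon right next to a TM
            forbidden_blocks.update({b - 1, b + 1})
        host_candidates = [b for b in range(n_blocks) if b not in forbidden_blocks]
        rng.shuffle(host_candidates)
        planted: list[int] = []
        remaining = n_sequons
        for b in host_candidates:
            if remaining <= 0:
                break
            want_pair = remaining >= 2 and rng.random() < sequon_pairing
            s0 = b * block
            if want_pair:
                p1 = s0 + int(rng.integers(0, 3))
                p2 = p1 + 3 + int(rng.integers(0, max(1, s0 + block - 4 - (p1 + 3))))
                p2 = min(p2, s0 + block - 4)
                positions = [p1, p2]
            else:
                positions = [s0 + int(rng.integers(0, block - 4))]
            for p in positions:
                seq[p] = "N"
                seq[p + 1] = rng.choice(SEQUON_X_CHOICES)
                seq[p + 2] = "S" if rng.random() < 0.5 else "T"
                planted.append(p + 1)
                remaining -= 1
        if remaining > 0 and not clip_to_capacity:
            raise ValueError(
                f"cannot place {n_sequons} sequons in a {length}-residue protein "
                f"with {tm_count} TM segments")
    else:
        letters, probs = _background_letters(background_freqs)
        seq = list(rng.choice(letters, size=length, p=probs))
        tm_segments = []
        occupied: list[tuple[int, int]] = []  # 0-based inclusive keep-out spans
        for _ in range(tm_count):
            placed = False
            for _attempt in range(200):
                s0 = int(rng.integers(0, max(1, length - tm_length + 1)))
                e0 = s0 + tm_length - 1
                if e0 >= length:
                    continue
                if any(s0 <= oe + 4 and e0 >= os - 4 for os, oe in occupied):
                    continue
                for i in range(s0, e0 + 1):
                    seq[i] = rng.choice(list(HYDROPHOBIC))
                occupied.append((s0, e0))
                tm_segments.append((s0 + 1, e0 + 1))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"cannot place {tm_count} TM segments in a {length}-residue protein")
        keepout = [(max(0, s - tm_margin), min(length - 1, e + tm_margin))
                   for s, e in occupied]
        planted = []
        taken: list[int] = []
        for _ in range(n_sequons):
            placed = False
            for _attempt in range(500):
                p = int(rng.integers(0, length - 2))
                if any(ks <= p + 2 and p <= ke for ks, ke in keepout):
                    continue
                if any(abs(p - q) < 3 for q in taken):
                    continue
                seq[p] = "N"
                seq[p + 1] = rng.choice(SEQUON_X_CHOICES)
                seq[p + 2] = "S" if rng.random() < 0.5 else "T"
                taken.append(p)
                planted.append(p + 1)
                placed = True
                break
            if not placed:
                if clip_to_capacity:
                    break
                raise ValueError(
                    f"cannot place {n_sequons} sequons outside TM margins "
                    f"(length {length}, {tm_count} TMs)")

    if suppress_background_sequons:
        motif_positions = set()
        for p1 in planted:
            motif_positions.update({p1 - 1, p1, p1 + 1})  # 0-based p..p+2
        sequence = "".join(seq)
        for site in scan_sequons(sequence) if sequence else []:
            if site.position in planted:
                continue
            target = site.position + 1  # 0-based index of the S/T residue
            if target in motif_positions:
                continue  # cannot happen with the restricted X alphabet
            seq[target] = "A"

    return "".join(seq), tm_segments, sorted(planted)


def generate_proteome(n_proteins: int,
                      length_distribution=(240, 480),
                      class_mix: Mapping[str, float] | None = None,
                      sequon_density: float = 0.02,
                      tm_model: Mapping[str, Sequence[float]] | None = None,
                      seed: int = 0,
                      *,
                      background_freqs: Mapping[str, float] | None = None,
                      regular_cleavage: bool = False,
                      suppress_background_sequons: bool = False,
                      sequons_per_protein: int | None = None,
                      sequon_pairing: float = 0.0,
                      tm_margin: int = 12,
                      ) -> tuple[list[ProteinRecord], SyntheticTruth, dict[str, str]]:
    """Generate ``n_proteins`` sequences with planted TMs and sequons.

    Per protein: a functional class is drawn from ``class_mix``, a TM count
    from the class's distribution in ``tm_model``, and either an exact
    ``sequons_per_protein`` or a Poisson(sequon_density * length) number of
    sequons is planted outside TM segments.  Returns (records, truth,
    class map).  Bit-identical across runs for a fixed seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    classes = sorted(mix)
    weights = np.array([mix[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    tm_model = {**DEFAULT_TM_MODEL, **(tm_model or {})}

    records: list[ProteinRecord] = []
    truth = SyntheticTruth(seed=seed)
    class_map: dict[str, str] = {}
    for i in range(n_proteins):
        acc = f"SYN{i + 1:05d}"
        cls = classes[int(rng.choice(len(classes), p=weights))]
        length = _sample_length(length_distribution, rng)
        probs = np.asarray(tm_model[cls], dtype=float)
        tm_count = int(rng.choice(len(probs), p=probs / probs.sum()))
        # many-pass membrane proteins are simply longer; guarantee room
        length = max(length, tm_count * 48 + 96)
        if sequons_per_protein is not None:
            n_seq = sequons_per_protein
            clip = False  # an explicit request that does not fit is an error
        else:
            n_seq = int(rng.poisson(sequon_density * length))
            clip = True  # density draws are clipped to placement capacity
        sequence, tms, planted = _build_protein(
            rng, length, tm_count, n_seq,
            background_freqs=background_freqs,
            regular_cleavage=regular_cleavage,
            suppress_background_sequons=suppress_background_sequons,
            sequon_pairing=sequon_pairing,
            tm_margin=tm_margin,
            clip_to_capacity=clip,
        )
        records.append(ProteinRecord(acc, sequence, f"synthetic {cls}"))
        truth.proteins[acc] = SyntheticProtein(
            accession=acc, functional_class=cls, sequence=sequence,
            tm_segments=tuple(tms), planted_sequons=tuple(planted))
        class_map[acc] = cls
    return records, truth, class_map


@dataclass
class AbundanceModel:
    """Log-normal copies-per-protein; ``fixed`` overrides by accession."""

    median: float = 50.0
    sigma: float = 1.0
    fixed: Mapping[str, float] | None = None

    def sample(self, rng: np.random.Generator, accession: str) -> float:
        if self.fixed is not None and accession in self.fixed:
            return float(self.fixed[accession])
        return float(rng.lognormal(np.log(self.median), self.sigma))


@dataclass
class OccupancyModel:
    """Per-sequon Bernoulli occupancy; rate scalar or per functional class."""

    rate: float | Mapping[str, float] = 0.5

    def rate_for(self, functional_class: str) -> float:
        if isinstance(self.rate, Mapping):
            return float(self.rate.get(functional_class, 0.5))
        return float(self.rate)


@dataclass
class DetectionModel:
    """Peptide-level detection and spectra generation."""

    peptide_prob: float = 1.0          # Bernoulli detectability per peptide
    spectra_per_copy: float = 0.05     # Poisson rate = abundance * this
    min_peptide_length: int = 5        # shorter tryptic peptides are unobservable
    psm_probability: float = 0.99      # identification probability written out


def simulate_psms(proteome: Sequence[ProteinRecord], truth: SyntheticTruth,
                  abundance_model: AbundanceModel | None = None,
                  occupancy_model: OccupancyModel | None = None,
                  detection_model: DetectionModel | None = None,
                  seed: int = 0,
                  ) -> tuple[list[PeptideSpectrumMatch], SyntheticTruth]:
    """Simulate deglycosylated PSMs from a generated proteome.

    Occupancy is drawn Bernoulli per *scanned* sequon (planted and
    incidental alike).  Each fully-cleaved tryptic peptide containing at
    least one occupied sequon is a candidate identification: detected with
    ``peptide_prob``, carrying Poisson spectra proportional to the protein's
    abundance (zero spectra means unobserved).  Occupied asparagines are
    written as 'D'; unoccupied sequons never are.  The truth object is
    updated in place with abundances, occupancy indicators and a
    ``fully_covered`` flag (every sequon sits in an observable peptide).
    """
    abundance_model = abundance_model or AbundanceModel()
    occupancy_model = occupancy_model or OccupancyModel()
    detection_model = detection_model or DetectionModel()
    rng = np.random.default_rng(seed)

    psms: list[PeptideSpectrumMatch] = []
    for rec in proteome:
        info = truth.proteins[rec.accession]
        abundance = abundance_model.sample(rng, rec.accession)
        info.abundance = abundance
        rate = occupancy_model.rate_for(info.functional_class)
        sequons = [s.position for s in scan_sequons(rec.sequence, rec.accession)]
        info.sequon_occupied = {pos: bool(rng.random() < rate) for pos in sequons}

        fragments = tryptic_digest(rec.sequence, max_missed=0, min_length=1)
        min_len = detection_model.min_peptide_length
        info.fully_covered = all(
            any(start <= pos <= end and end - start + 1 >= min_len
                for _, start, end in fragments)
            for pos in sequons
        )
        lam = abundance * detection_model.spectra_per_copy
        for peptide, start, end in fragments:
            occupied_here = [pos for pos in sequons
                             if start <= pos <= end and info.sequon_occupied[pos]]
            if not occupied_here or end - start + 1 < min_len:
                continue
            if rng.random() >= detection_model.peptide_prob:
                continue
            spectra = int(rng.poisson(lam))
            if spectra < 1:
                continue
            chars = list(peptide)
            for pos in occupied_here:
                chars[pos - start] = "D"
            psms.append(PeptideSpectrumMatch(
                peptide="".join(chars),
                protein_accessions=(rec.accession,),
                spectra_count=spectra,
                probability=detection_model.psm_probability,
            ))
    if not psms:
        raise ValueError(
            "simulation produced no detected peptides; increase abundance, "
            "spectra_per_copy, occupancy rate or detection probability")
    return psms, truth


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_complementarity_cohort(n: int, slope: float, seed: int = 0,
                                    max_k: int = 8,
                                    ) -> tuple[list[ProteinRecord], SyntheticTruth, dict[str, int]]:
    """Cohort with a planted association between sequon count and TM count.

    Per protein, the sequon count k is uniform on 1..max_k and the chance of
    a high TM count (>= 3) is sigmoid(slope * (k - (max_k+1)/2)): negative
    ``slope`` plants the membrane-complementarity pattern, slope 0 plants
    none.  Sequences use regular tryptic blocks with background sequons
    suppressed so the pipeline recovers k exactly under full detection.
    Returns (records, truth, per-protein TM counts).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth = SyntheticTruth(seed=seed)
    tm_counts: dict[str, int] = {}
    mid = (max_k + 1) / 2.0
    ks = rng.integers(1, max_k + 1, size=n)
    # quota sampling: each k group gets exactly round(p_high * n_k) high-TM
    # members, so the planted association is the sigmoid itself and not
    # additionally blurred by per-protein Bernoulli noise
    high_flags = np.zeros(n, dtype=bool)
    for k in range(1, max_k + 1):
        idx = np.flatnonzero(ks == k)
        rng.shuffle(idx)
        p_high = sigmoid(slope * (k - mid))
        n_high = int(np.floor(p_high * len(idx) + 0.5))
        high_flags[idx[:n_high]] = True
    for i in range(n):
        acc = f"CPL{i + 1:05d}"
        k = int(ks[i])
        if high_flags[i]:
            tm = 3 + int(rng.poisson(2.0))
        else:
            tm = int(rng.integers(0, 3))
        length = max(240, tm * 36 + k * 24 + 72)
        sequence, tms, planted = _build_protein(
            rng, length, tm, k,
            background_freqs=None,
            regular_cleavage=True,
            suppress_background_sequons=True,
        )
        records.append(ProteinRecord(acc, sequence, "synthetic complementarity"))
        truth.proteins[acc] = SyntheticProtein(
            accession=acc, functional_class="miscellaneous", sequence=sequence,
            tm_segments=tuple(tms), planted_sequons=tuple(planted))
        tm_counts[acc] = tm
    return records, truth, tm_counts
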