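"""End-to-end orchestration: scan -> filter -> map -> quantify -> stats.

The pipeline is driven by a flat INI-style config (section.key), every value
of which can be overridden by a CLI flag.  Each output TSV carries a '#'
provenance header; a run-summary TSV records the exact filter tallies so
that PSMs_in = PSMs_used + dropped categories is checkable after the fact.
"""

from __future__ import annotations

import configparser
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .io_model import (
    read_class_map,
    read_fasta,
    read_psm_table,
    read_tm_annotations,
    write_fasta,
    write_psm_table,
    write_tsv,
)
from .sequon_scan import count_sequons
from .glycosite_map import assign_glycosites, filter_identifications
from .quantify import build_profiles
from .glyco_stats import class_summary, predict_tm, stoichiometry_groups
from . import synthetic_data

log = logging.getLogger("glycopipe")


@dataclass
class PipelineConfig:
    fasta: str | None = None
    psms: str | None = None
    classes: str | None = None
    tm: str | None = None
    tm_dialect: str = "plain"
    predict_tm_fallback: bool = True
    min_probability: float = 0.9
    drop_single_hits: bool = True
    crediting: str = "fractional"
    ref_accession: str | None = None
    ref_copies: float = 100.0
    out_dir: str = "glyco_out"
    # simulation block (used when no fasta/psms given)
    simulate: bool = False
    sim_n_proteins: int = 50
    sim_seed: int = 0
    sim_occupancy: float = 0.5
    sim_regular_cleavage: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.min_probability <= 1.0:
            raise ValueError(
                f"min_probability must be in [0,1], got {self.min_probability}")
        if not self.simulate and (self.fasta is None or self.psms is None):
            raise ValueError("config must name a FASTA and a PSM table, "
                             "or enable the simulate block")


_BOOL = {"1": True, "true": True, "yes": True, "on": True,
         "0": False, "false": False, "no": False, "off": False}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key-value config with [input]/[filter]/[map]/[quantify]/
    [simulate]/[output] sections."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    cfg = PipelineConfig()

    def get(section: str, key: str, default):
        if parser.has_option(section, key):
            raw = parser.get(section, key)
            if isinstance(default, bool):
                return _BOOL[raw.strip().lower()]
            if isinstance(default, float):
                return float(raw)
            if isinstance(default, int):
                return int(raw)
            return raw
        return default

    cfg.fasta = get("input", "fasta", cfg.fasta)
    cfg.psms = get("input", "psms", cfg.psms)
    cfg.classes = get("input", "classes", cfg.classes)
    cfg.tm = get("input", "tm", cfg.tm)
    cfg.tm_dialect = get("input", "tm_dialect", cfg.tm_dialect)
    cfg.min_probability = get("filter", "min_probability", cfg.min_probability)
    cfg.drop_single_hits = get("filter", "drop_single_hits", cfg.drop_single_hits)
    cfg.crediting = get("map", "crediting", cfg.crediting)
    cfg.ref_accession = get("quantify", "ref_accession", cfg.ref_accession)
    cfg.ref_copies = get("quantify", "ref_copies", cfg.ref_copies)
    cfg.out_dir = get("output", "dir", cfg.out_dir)
    cfg.simulate = get("simulate", "enabled", cfg.simulate)
    cfg.sim_n_proteins = get("simulate", "n_proteins", cfg.sim_n_proteins)
    cfg.sim_seed = get("simulate", "seed", cfg.sim_seed)
    cfg.sim_occupancy = get("simulate", "occupancy", cfg.sim_occupancy)
    cfg.sim_regular_cleavage = get("simulate", "regular_cleavage",
                                   cfg.sim_regular_cleavage)
    return cfg


def run_pipeline(config: PipelineConfig | Mapping | str | Path) -> Path:
    """Run the full analysis; returns the output directory.

    Stage order: (simulate) -> scan -> filter -> map -> quantify -> stats.
    Any stage failure is re-raised annotated with the stage name.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, Mapping):
        config = PipelineConfig(**config)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.simulate:
            stage = "simulate"
            records, truth, sim_classes = synthetic_data.generate_proteome(
                config.sim_n_proteins, seed=config.sim_seed,
                regular_cleavage=config.sim_regular_cleavage)
            psms, truth = synthetic_data.simulate_psms(
                records, truth,
                occupancy_model=synthetic_data.OccupancyModel(config.sim_occupancy),
                seed=config.sim_seed)
            write_fasta(records, out / "proteome.fasta")
            write_psm_table(psms, out / "psms.tsv",
                            header_comments=[f"simulated; seed={config.sim_seed}"])
            class_map: dict[str, str] | None = sim_classes
            tm_counts: dict[str, int] | None = truth.tm_counts()
        else:
            records = read_fasta(config.fasta)
            psms = read_psm_table(config.psms)
            class_map = read_class_map(config.classes) if config.classes else None
            tm_counts = (read_tm_annotations(config.tm, config.tm_dialect)
                         if config.tm else None)
        n_psms_in = len(psms)
        spectra_in = sum(p.spectra_count for p in psms)
        log.info("input: %d proteins, %d PSMs (%.0f spectra)",
                 len(records), n_psms_in, spectra_in)

        stage = "scan"
        sequon_counts = count_sequons(records)

        stage = "filter"
        filt = filter_identifications(psms, config.min_probability,
                                      config.drop_single_hits)
        log.info("filter: %d below probability, %d single-hit groups removed, "
                 "%d orphaned, %d degenerate proteins merged",
                 filt.psms_below_probability, filt.single_hit_groups_removed,
                 filt.psms_orphaned, filt.proteins_merged)

        stage = "map"
        assignments, astats = assign_glycosites(filt.psms, records,
                                                crediting=config.crediting)
        log.info("map: %d assignments, %d PSMs sequon-free, ambiguity %.1f%% "
                 "of peptides", len(assignments), astats.psms_dropped_no_sequon,
                 100 * astats.ambiguity_rate_peptides
                 if astats.peptides_total else 0.0)

        stage = "quantify"
        if tm_counts is None and config.predict_tm_fallback:
            tm_counts = {r.accession: predict_tm(r.sequence)[0] for r in records}
        profiles = build_profiles(assignments, sequon_counts, tm_counts, class_map)

        stage = "stats"
        groups = stoichiometry_groups(profiles)
        classes = class_summary(profiles)

        stage = "write"
        params = (f"min_probability={config.min_probability} "
                  f"drop_single_hits={config.drop_single_hits} "
                  f"crediting={config.crediting}")
        write_tsv(out / "sites.tsv",
                  ["accession", "position", "motif", "peptide", "spectra",
                   "ambiguous", "shared", "site_credit"],
                  [[a.accession, a.position, a.motif, a.peptide, a.spectra_count,
                    a.ambiguous, a.shared, a.site_credit]
                   for a in sorted(assignments,
                                   key=lambda a: (a.accession, a.position))],
                  header_comments=[params])
        write_tsv(out / "profiles.tsv",
                  ["accession", "total_peptide_spectra", "stoichiometry",
                   "protein_spectra", "tier", "sequon_count", "occupancy",
                   "tm_count", "functional_class"],
                  [[p.accession, p.total_peptide_spectra, p.stoichiometry,
                    p.protein_spectra, p.tier, p.sequon_count, p.occupancy,
                    "" if p.tm_count is None else p.tm_count, p.functional_class]
                   for p in profiles],
                  header_comments=[params])
        write_tsv(out / "stoichiometry_groups.tsv",
                  ["k", "n", "mean_protein_spectra", "pct_low_tm", "pct_high_tm"],
                  [[g.k, g.n, g.mean_protein_spectra,
                    "" if g.pct_low_tm is None else g.pct_low_tm,
                    "" if g.pct_high_tm is None else g.pct_high_tm]
                   for g in groups])
        write_tsv(out / "class_summary.tsv",
                  ["functional_class", "n", "mean_glycans", "mean_sequons",
                   "mean_tms", "glycosylation_rate", "mean_protein_spectra"],
                  [[c.functional_class, c.n, c.mean_glycans, c.mean_sequons,
                    "" if c.mean_tms is None else c.mean_tms,
                    c.glycosylation_rate, c.mean_protein_spectra]
                   for c in classes])
        tallies = [
            ["psms_in", n_psms_in],
            ["spectra_in", spectra_in],
            ["psms_below_probability", filt.psms_below_probability],
            ["psms_orphaned", filt.psms_orphaned],
            ["single_hit_groups_removed", filt.single_hit_groups_removed],
            ["proteins_merged", filt.proteins_merged],
            ["psms_no_sequon", astats.psms_dropped_no_sequon],
            ["psms_no_match", astats.psms_dropped_no_match],
            ["psms_assigned", astats.psms_assigned],
            ["peptides_total", astats.peptides_total],
            ["peptides_ambiguous", astats.peptides_ambiguous],
            ["glycoproteins", len(profiles)],
        ]
        write_tsv(out / "run_summary.tsv", ["key", "value"], tallies,
                  header_comments=[f"version={__version__}", params])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def configure_logging(verbosity: int = 1) -> None:
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(name)s %(levelname)s %(message)s")
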