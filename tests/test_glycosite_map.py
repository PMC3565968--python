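import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopipe import (
    FormatError,
    PeptideSpectrumMatch,
    ProteinRecord,
    ambiguity_rate,
    assign_glycosites,
    filter_identifications,
    locate_peptide,
    tryptic_digest,
)
from glycopipe.io_model import proteome_index
from glycopipe.sequon_scan import scan_sequons

AA = "ACDEFGHIKLMNPQRSTVWY"


def digest_oracle(seq, max_missed, min_length):
    """Exhaustive enumeration over all substrings with tryptic boundaries."""
    seq = seq.upper()
    n = len(seq)

    def cut_after(c):  # cleavage site after 0-based index c
        return seq[c] in "KR" and (c + 1 >= n or seq[c + 1] != "P")

    out = []
    for i in range(n):
        if not (i == 0 or cut_after(i - 1)):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or cut_after(j - 1)):
                continue
            internal = sum(1 for c in range(i, j - 1) if cut_after(c))
            if internal <= max_missed and j - i >= min_length:
                out.append((seq[i:j], i + 1, j))
    return sorted(out)


class TestTrypticDigest:
    def test_kr_before_p_suppressed(self):
        assert tryptic_digest("AKRPGKR", 0) == [
            ("AK", 1, 2), ("RPGK", 3, 6), ("R", 7, 7)]

    def test_no_cleavage_site(self):
        assert tryptic_digest("GGGG", 2) == [("GGGG", 1, 4)]

    def test_missed_cleavage_adds_joined_peptide(self):
        zero = set(tryptic_digest("AKGK", 0))
        one = set(tryptic_digest("AKGK", 1))
        assert one - zero == {("AKGK", 1, 4)}

    def test_min_length_filter(self):
        peps = tryptic_digest("AKRPGKR", 0, min_length=3)
        assert peps == [("RPGK", 3, 6)]

    def test_negative_missed_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("AK", -1)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=60),
           st.integers(0, 3), st.integers(1, 6))
    def test_matches_enumeration_oracle(self, seq, max_missed, min_length):
        got = sorted(tryptic_digest(seq, max_missed, min_length))
        assert got == digest_oracle(seq, max_missed, min_length)


class TestLocatePeptide:
    @pytest.fixture
    def proteome(self):
        recs = [ProteinRecord("P1", "MKLNGSAK")]
        index = proteome_index(recs)
        sequons = {"P1": {s.position for s in scan_sequons(recs[0].sequence)}}
        return index, sequons

    def test_deamidated_match(self, proteome):
        index, sequons = proteome
        assert locate_peptide("LDGSAK", index, sequons) == [("P1", 3, (4,))]

    def test_exact_match_without_deamidation(self, proteome):
        index, sequons = proteome
        assert locate_peptide("LNGSAK", index, sequons) == [("P1", 3, ())]

    def test_d_at_non_sequon_n_rejected(self):
        # protein N at 2 is not a sequon ('NKA'); D must not match there
        recs = [ProteinRecord("P1", "MNKAAAA")]
        sequons = {"P1": set()}
        assert locate_peptide("MDKAAAA", proteome_index(recs), sequons) == []

    def test_unmatched_peptide_empty(self, proteome):
        index, sequons = proteome
        assert locate_peptide("WWWWW", index, sequons) == []


class TestAssignGlycosites:
    def test_unambiguous_assignment(self):
        recs = [ProteinRecord("P1", "MKLNGSAK")]
        psms = [PeptideSpectrumMatch("LDGSAK", ("P1",), 3)]
        assignments, stats = assign_glycosites(psms, recs)
        assert len(assignments) == 1
        a = assignments[0]
        assert (a.accession, a.position, a.motif) == ("P1", 4, "NGS")
        assert a.spectra_count == 3
        assert not a.ambiguous
        assert a.site_credit == 1.0

    def test_two_sequon_peptide_flagged_ambiguous(self):
        # sequons at 2 (NGS) and 6 (NVT); peptide spans both
        recs = [ProteinRecord("P1", "ANGSANVTAK")]
        psms = [PeptideSpectrumMatch("DGSADVTAK", ("P1",), 4)]
        assignments, stats = assign_glycosites(psms, recs)
        assert len(assignments) == 2
        assert all(a.ambiguous for a in assignments)
        assert sorted(a.position for a in assignments) == [2, 6]
        # fractional crediting conserves spectra and site credit
        assert sum(a.spectra_count for a in assignments) == pytest.approx(4)
        assert sum(a.site_credit for a in assignments) == pytest.approx(1)

    def test_crediting_first(self):
        recs = [ProteinRecord("P1", "ANGSANVTAK")]
        psms = [PeptideSpectrumMatch("DGSADVTAK", ("P1",), 4)]
        assignments, _ = assign_glycosites(psms, recs, crediting="first")
        assert [(a.position, a.spectra_count) for a in assignments] == [(2, 4)]

    def test_sequon_free_peptide_dropped_and_tallied(self, toy_proteome):
        psms = [PeptideSpectrumMatch("GGGGK", ("P3",), 2)]
        assignments, stats = assign_glycosites(psms, toy_proteome)
        assert assignments == []
        assert stats.psms_dropped_no_sequon == 1
        assert stats.spectra_dropped_no_sequon == 2

    def test_missing_accession_error(self, toy_proteome):
        psms = [PeptideSpectrumMatch("LDGSAK", ("NOPE",), 3)]
        with pytest.raises(FormatError, match="NOPE"):
            assign_glycosites(psms, toy_proteome)

    def test_every_site_satisfies_sequon_rule(self, toy_proteome, toy_psms):
        assignments, _ = assign_glycosites(toy_psms, toy_proteome)
        index = proteome_index(toy_proteome)
        for a in assignments:
            positions = {s.position for s in scan_sequons(index[a.accession].sequence)}
            assert a.position in positions
            assert index[a.accession].sequence[a.position - 1] == "N"

    def test_spectra_conservation(self, toy_proteome, toy_psms):
        assignments, stats = assign_glycosites(toy_psms, toy_proteome)
        total_in = sum(p.spectra_count for p in toy_psms)
        accounted = (stats.spectra_assigned + stats.spectra_dropped_no_sequon
                     + stats.spectra_dropped_no_match)
        assert accounted == pytest.approx(total_in)
        assert sum(a.spectra_count for a in assignments) == pytest.approx(
            stats.spectra_assigned)


class TestAmbiguityRate:
    def test_arithmetic(self):
        recs2 = [ProteinRecord("P1", "ANGSANVTAK"), ProteinRecord("P2", "MKLNGSAK")]
        psms2 = [PeptideSpectrumMatch("DGSADVTAK", ("P1",), 1),
                 PeptideSpectrumMatch("LDGSAK", ("P2",), 1)]
        _, stats = assign_glycosites(psms2, recs2)
        assert stats.ambiguity_rate_peptides == pytest.approx(0.5)

    def test_all_unambiguous_is_zero(self, toy_proteome, toy_psms):
        _, stats = assign_glycosites(toy_psms, toy_proteome)
        assert stats.ambiguity_rate_peptides == 0.0

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            ambiguity_rate([])

    def test_simulated_pairing_frequency_recovered(self):
        # plant two-sequon tryptic windows at a known frequency and compare
        # the recovered peptide-level rate against the generator truth
        from glycopipe import synthetic_data as syn

        recs, truth, _ = syn.generate_proteome(
            200, seed=11, regular_cleavage=True, suppress_background_sequons=True,
            sequon_density=0.03, sequon_pairing=0.3)
        psms, truth = syn.simulate_psms(
            recs, truth,
            abundance_model=syn.AbundanceModel(median=100, sigma=0.0),
            occupancy_model=syn.OccupancyModel(1.0),
            detection_model=syn.DetectionModel(1.0, 0.1), seed=11)
        _, stats = assign_glycosites(psms, recs)
        # truth: fraction of emitted peptides spanning 2 planted sequons
        from glycopipe.glycosite_map import tryptic_digest
        pair = tot = 0
        for rec in recs:
            planted = set(truth.proteins[rec.accession].planted_sequons)
            for pep, s, e in tryptic_digest(rec.sequence, 0, 1):
                inside = [p for p in planted if s <= p <= e]
                if inside:
                    tot += 1
                    pair += len(inside) >= 2
        assert stats.ambiguity_rate_peptides == pytest.approx(pair / tot, abs=0.02)


class TestFilterIdentifications:
    def test_probability_threshold(self, toy_psms):
        result = filter_identifications(toy_psms, 0.9, remove_single_hits=False)
        assert result.psms_below_probability == 1
        assert all(p.probability >= 0.9 for p in result.psms)

    def test_degenerate_proteins_merged_first_representative(self):
        psms = [
            PeptideSpectrumMatch("LDGSAK", ("P1", "P2"), 3),
            PeptideSpectrumMatch("AAADVTAAK", ("P1", "P2"), 2),
        ]
        result = filter_identifications(psms, 0.0, remove_single_hits=False)
        assert len(result.groups) == 1
        g = result.groups[0]
        assert g.representative == "P1"
        assert g.members == ("P1", "P2")
        assert result.proteins_merged == 1
        assert all(p.protein_accessions == ("P1",) for p in result.psms)

    def test_single_hit_removed(self):
        psms = [
            PeptideSpectrumMatch("LDGSAK", ("P1",), 1),
            PeptideSpectrumMatch("AAADVTAAK", ("P2",), 5),
        ]
        result = filter_identifications(psms, 0.0, remove_single_hits=True)
        assert result.single_hit_groups_removed == 1
        assert [g.representative for g in result.groups] == ["P2"]
        assert result.psms_orphaned == 1

    def test_single_hit_kept_when_disabled(self):
        psms = [PeptideSpectrumMatch("LDGSAK", ("P1",), 1)]
        result = filter_identifications(psms, 0.0, remove_single_hits=False)
        assert [g.representative for g in result.groups] == ["P1"]

    def test_invalid_threshold(self, toy_psms):
        with pytest.raises(ValueError):
            filter_identifications(toy_psms, 1.1)

    def test_tally_conservation(self, toy_psms):
        result = filter_identifications(toy_psms, 0.9, remove_single_hits=True)
        assert (len(result.psms) + result.psms_below_probability
                + result.psms_orphaned) == len(toy_psms)
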