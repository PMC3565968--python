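import numpy as np
import pytest

from glycopipe import (
    GlycoproteinProfile,
    OrthologSet,
    ProteinRecord,
    class_summary,
    cross_species_profile,
    occupancy,
    predict_tm,
    set_glycosylation_rate,
    stoichiometry_groups,
)
from glycopipe.glyco_stats import KYTE_DOOLITTLE


def profile(acc, stoich, sequons, spectra=10.0, tm=None, cls="unclassified"):
    return GlycoproteinProfile(
        accession=acc, total_peptide_spectra=spectra * stoich,
        stoichiometry=stoich, protein_spectra=spectra, sequon_count=sequons,
        tier="medium", occupancy=stoich / sequons, tm_count=tm,
        functional_class=cls)


class TestOccupancy:
    def test_quarter(self):
        assert occupancy(1, 4) == 0.25

    def test_full(self):
        assert occupancy(4, 4) == 1.0

    def test_zero(self):
        assert occupancy(0, 5) == 0.0

    def test_impossible_state(self):
        with pytest.raises(ValueError):
            occupancy(5, 4)

    def test_no_sequons(self):
        with pytest.raises(ValueError):
            occupancy(1, 0)


class TestSetGlycosylationRate:
    def test_single_protein_is_own_occupancy(self):
        assert set_glycosylation_rate([(1, 4)]) == 0.25

    def test_unweighted_mean_of_pairs(self):
        # oracle: mean of ratios, not ratio of sums
        pairs = [(1, 2), (1, 4)]
        assert set_glycosylation_rate(pairs) == pytest.approx((0.5 + 0.25) / 2)

    def test_accepts_profiles(self):
        profs = [profile("A", 1, 2), profile("B", 1, 4)]
        assert set_glycosylation_rate(profs) == pytest.approx(0.375)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            set_glycosylation_rate([])


class TestStoichiometryGroups:
    def test_single_group(self):
        profs = [profile(f"P{i}", 1, 4) for i in range(5)]
        groups = stoichiometry_groups(profs)
        assert len(groups) == 1
        assert groups[0].k == 1 and groups[0].n == 5

    def test_pooling_above_cap(self):
        profs = [profile("A", 12, 20), profile("B", 8, 10), profile("C", 2, 4)]
        groups = stoichiometry_groups(profs, max_k=8)
        assert [g.k for g in groups] == [2, 8]
        assert groups[1].n == 2  # 12 pooled into 8

    def test_tm_split_percentages(self):
        profs = [profile("A", 1, 2, tm=1), profile("B", 1, 2, tm=2),
                 profile("C", 1, 2, tm=3), profile("D", 1, 2)]
        g = stoichiometry_groups(profs, tm_split=2)[0]
        assert g.pct_low_tm == pytest.approx(200 / 3)
        assert g.pct_high_tm == pytest.approx(100 / 3)
        assert g.pct_low_tm + g.pct_high_tm == pytest.approx(100)

    def test_no_tm_annotation_gives_none(self):
        g = stoichiometry_groups([profile("A", 1, 2)])[0]
        assert g.pct_low_tm is None and g.pct_high_tm is None

    def test_mean_spectra(self):
        profs = [profile("A", 1, 2, spectra=4), profile("B", 1, 2, spectra=8)]
        assert stoichiometry_groups(profs)[0].mean_protein_spectra == 6


class TestPredictTm:
    def test_single_hydrophobic_stretch(self):
        count, segments = predict_tm("S" * 10 + "L" * 30 + "S" * 10)
        assert count == 1
        start, end = segments[0]
        assert start <= 11 <= 40 <= end  # segment covers the leucine core

    def test_polyglycine_none(self):
        assert predict_tm("G" * 100)[0] == 0

    def test_two_separated_stretches(self):
        seq = "L" * 25 + "S" * 40 + "L" * 25
        assert predict_tm(seq)[0] == 2

    def test_close_stretches_merged(self):
        seq = "L" * 25 + "SS" + "L" * 25
        assert predict_tm(seq)[0] == 1

    def test_short_sequence_zero(self):
        assert predict_tm("L" * 18) == (0, [])

    def test_position_covariance(self):
        # padding wider than the window so every L-overlapping window exists
        # in both sequences and the prefix cannot seed new hot windows
        core = "S" * 25 + "L" * 30 + "S" * 25
        shift = 17
        count0, seg0 = predict_tm(core)
        count1, seg1 = predict_tm("G" * shift + core)
        assert count0 == count1 == 1
        assert seg1[0][0] == seg0[0][0] + shift
        assert seg1[0][1] == seg0[0][1] + shift

    def test_oracle_window_means(self):
        # independent check of the windowed mean against a direct loop
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(KYTE_DOOLITTLE), size=80))
        scores = [KYTE_DOOLITTLE[c] for c in seq]
        hot_oracle = [np.mean(scores[i:i + 19]) > 1.6 for i in range(80 - 18)]
        count, segments = predict_tm(seq)
        covered = set()
        for s, e in segments:
            covered.update(range(s, e + 1))
        for i, hot in enumerate(hot_oracle):
            if hot:
                assert set(range(i + 1, i + 20)) <= covered


class TestClassSummary:
    def test_means_per_class(self):
        profs = [
            profile("A", 1, 4, spectra=2, tm=1, cls="enzyme"),
            profile("B", 1, 2, spectra=6, tm=0, cls="enzyme"),
            profile("C", 4, 8, spectra=10, tm=1, cls="receptor"),
        ]
        summaries = {c.functional_class: c for c in class_summary(profs)}
        enz = summaries["enzyme"]
        assert enz.n == 2
        assert enz.mean_sequons == 3
        assert enz.mean_tms == 0.5
        assert enz.glycosylation_rate == pytest.approx((0.25 + 0.5) / 2)
        assert enz.mean_protein_spectra == 4

    def test_absent_class_omitted(self):
        profs = [profile("A", 1, 4, cls="enzyme")]
        assert [c.functional_class for c in class_summary(profs)] == ["enzyme"]

    def test_class_map_overrides(self):
        profs = [profile("A", 1, 4, cls="enzyme")]
        out = class_summary(profs, {"A": "receptor"})
        assert out[0].functional_class == "receptor"

    def test_pooled_consistency_with_whole_cohort(self):
        rng = np.random.default_rng(3)
        profs = []
        for i in range(60):
            seqn = int(rng.integers(2, 9))
            st = int(rng.integers(1, seqn + 1))
            cls = ["receptor", "transporter", "enzyme"][i % 3]
            profs.append(profile(f"P{i}", st, seqn, cls=cls))
        summaries = class_summary(profs)
        pooled = sum(c.glycosylation_rate * c.n for c in summaries) / sum(
            c.n for c in summaries)
        assert pooled == pytest.approx(set_glycosylation_rate(profs))


class TestCrossSpecies:
    def _proteomes(self, seq_by_species):
        return {sp: {acc: ProteinRecord(acc, seq) for acc, seq in accs.items()}
                for sp, accs in seq_by_species.items()}

    def test_identical_sequences_identical_profiles(self):
        seq = "S" * 5 + "NAT" + "L" * 30 + "GGKAA"
        proteomes = self._proteomes({
            "mouse": {"M1": seq}, "human": {"H1": seq}})
        groups = [OrthologSet("g1", (("mouse", "M1"), ("human", "H1")))]
        rows, excluded = cross_species_profile(groups, proteomes)
        assert excluded == 0
        assert len(rows) == 2
        assert rows[0].mean_sequons == rows[1].mean_sequons
        assert rows[0].mean_tms == rows[1].mean_tms

    def test_unresolvable_excluded_and_counted(self):
        proteomes = self._proteomes({"mouse": {"M1": "NATAAKAAAA"}, "human": {}})
        groups = [OrthologSet("g1", (("mouse", "M1"), ("human", "H1")))]
        rows, excluded = cross_species_profile(groups, proteomes)
        assert excluded == 1
        assert [r.species for r in rows] == ["mouse"]

    def test_class_inherited_from_first_classified_member(self):
        seq = "NATAAKAAAA"
        proteomes = self._proteomes({"mouse": {"M1": seq}, "human": {"H1": seq}})
        groups = [OrthologSet("g1", (("mouse", "M1"), ("human", "H1")))]
        rows, _ = cross_species_profile(groups, proteomes, {"M1": "receptor"})
        assert {r.functional_class for r in rows} == {"receptor"}

    def test_planted_pattern_recovered_in_every_species(self):
        # receptors: many sequons few TMs; transporters: few sequons many TMs
        from glycopipe import synthetic_data as syn

        species = ["mouse", "human", "fish"]
        proteomes = {sp: {} for sp in species}
        groups = []
        class_map = {}
        tm_counts = {}
        rng = np.random.default_rng(21)
        for i in range(30):
            cls = "receptor" if i % 2 == 0 else "transporter"
            n_seq, n_tm = (8, 1) if cls == "receptor" else (3, 6)
            entries = []
            for sp in species:
                acc = f"{sp}{i}"
                seq, tms, _planted = syn._build_protein(
                    rng, 600, n_tm, n_seq, regular_cleavage=True,
                    suppress_background_sequons=True)
                proteomes[sp][acc] = ProteinRecord(acc, seq)
                tm_counts[acc] = len(tms)
                entries.append((sp, acc))
            class_map[entries[0][1]] = cls
            groups.append(OrthologSet(f"g{i}", tuple(entries)))
        rows, _ = cross_species_profile(groups, proteomes, class_map, tm_counts)
        by = {(r.species, r.functional_class): r for r in rows}
        for sp in species:
            rec, tra = by[(sp, "receptor")], by[(sp, "transporter")]
            assert rec.mean_sequons > tra.mean_sequons
            assert tra.mean_tms > rec.mean_tms
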