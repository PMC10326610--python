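"""Guild composition, family composition, checklist and OTU sharing."""

import numpy as np
import pandas as pd
import pytest

from ednadiv import (
    Checklist,
    CommunityMatrix,
    SampleInfo,
    TaxonRecord,
    checklist_metrics,
    dominance_summary,
    family_composition,
    guild_composition,
    mcnaughton,
    shared_otu_fraction,
)
from ednadiv.otu import AnnotatedOtuTable, OtuRow


def _rec(tid, species="sp", family="Fam", vel="F", lay="B", egg="A", flags=()):
    return TaxonRecord(tid, "Ord", family, "Gen", species, vel, lay, egg,
                       frozenset(flags))


class TestGuildComposition:
    def test_single_guild_everywhere(self):
        m = CommunityMatrix(pd.DataFrame({"s1": [3, 4], "s2": [1, 2]},
                                         index=["a", "b"]))
        recs = [_rec("a", vel="F"), _rec("b", vel="F")]
        table = guild_composition(m, recs, "velocity", "species_count")
        assert (table["proportion"] == 1.0).all()
        assert set(table["guild"]) == {"F"}

    def test_two_taxa_hand_example(self):
        m = CommunityMatrix(pd.DataFrame({"s1": [90, 10]}, index=["a", "b"]))
        recs = [_rec("a", vel="F"), _rec("b", vel="E")]
        by_abund = guild_composition(m, recs, "velocity", "sequence_abundance")
        props = dict(zip(by_abund["guild"], by_abund["proportion"]))
        assert props == {"F": pytest.approx(0.9), "E": pytest.approx(0.1)}
        by_species = guild_composition(m, recs, "velocity", "species_count")
        props = dict(zip(by_species["guild"], by_species["proportion"]))
        assert props == {"F": pytest.approx(0.5), "E": pytest.approx(0.5)}

    @pytest.mark.parametrize("axis", ["velocity", "layer", "egg"])
    @pytest.mark.parametrize("basis", ["species_count", "sequence_abundance"])
    def test_fixture_proportions_sum_to_one(self, survey, axis, basis):
        matrix, records = survey
        table = guild_composition(matrix, records, axis, basis)
        sums = table.groupby("section")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_species_basis_scale_invariant_abundance_not(self):
        m1 = CommunityMatrix(pd.DataFrame({"s1": [90, 10], "s2": [10, 10]},
                                          index=["a", "b"]))
        m2 = CommunityMatrix(pd.DataFrame({"s1": [900, 100], "s2": [10, 10]},
                                          index=["a", "b"]))
        recs = [_rec("a", vel="F"), _rec("b", vel="E")]
        sp1 = guild_composition(m1, recs, "velocity", "species_count")
        sp2 = guild_composition(m2, recs, "velocity", "species_count")
        pd.testing.assert_frame_equal(sp1, sp2)
        ab1 = guild_composition(m1, recs, "velocity", "sequence_abundance")
        ab2 = guild_composition(m2, recs, "velocity", "sequence_abundance")
        pd.testing.assert_frame_equal(ab1, ab2)  # proportions ARE ratio-scale
        # ...but change the mix (not just the scale) and they differ
        m3 = CommunityMatrix(pd.DataFrame({"s1": [90, 100], "s2": [10, 10]},
                                          index=["a", "b"]))
        ab3 = guild_composition(m3, recs, "velocity", "sequence_abundance")
        assert not ab3["proportion"].equals(ab1["proportion"])

    def test_missing_guild_code_names_taxon(self):
        m = CommunityMatrix(pd.DataFrame({"s1": [1, 1]}, index=["a", "b"]))
        recs = [_rec("a"), TaxonRecord("b", "O", "F", "G", "sp", "", "B", "A")]
        with pytest.raises(ValueError, match="b"):
            guild_composition(m, recs, "velocity", "species_count")


class TestFamilyComposition:
    def test_fixture_top_families(self, survey_records):
        fam = family_composition(survey_records)
        assert fam["Cyprinidae"] == (54, pytest.approx(54 / 97))
        assert fam["Bagridae"] == (9, pytest.approx(9 / 97))
        assert fam["Cobitidae"] == (8, pytest.approx(8 / 97))
        assert list(fam)[0] == "Cyprinidae"  # sorted by count

    def test_percent_values_match_survey_report(self, survey_records):
        fam = family_composition(survey_records)
        assert fam["Cyprinidae"][1] * 100 == pytest.approx(55.67, abs=0.005)
        assert fam["Bagridae"][1] * 100 == pytest.approx(9.28, abs=0.005)
        assert fam["Cobitidae"][1] * 100 == pytest.approx(8.25, abs=0.005)

    def test_single_record(self):
        fam = family_composition([_rec("a", family="Solo")])
        assert fam == {"Solo": (1, 1.0)}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            family_composition([])


class TestChecklistMetrics:
    def test_fixture_against_historical_summary(self, survey_records,
                                                historical_checklist):
        rep = checklist_metrics(survey_records, historical_checklist)
        assert rep.n_edna_species == 97
        assert rep.n_checklist_species == 193
        assert rep.detection_rate * 100 == pytest.approx(50.26, abs=0.005)
        assert (rep.n_alien, rep.n_indigenous, rep.n_endemic) == (12, 85, 13)
        assert rep.pct_alien * 100 == pytest.approx(12.37, abs=0.005)
        assert rep.pct_indigenous * 100 == pytest.approx(87.63, abs=0.005)
        assert rep.pct_endemic * 100 == pytest.approx(13.40, abs=0.005)
        assert rep.n_shared == 72  # shared-with-history flags
        assert rep.n_alien + rep.n_indigenous == rep.n_edna_species

    def test_identity_checklist_full_detection(self):
        recs = [_rec(f"t{i}", species=f"sp{i}") for i in range(5)]
        cl = Checklist(entries=[(r.species, r.genus, r.family, r.order)
                                for r in recs])
        rep = checklist_metrics(recs, cl)
        assert rep.detection_rate == pytest.approx(1.0)
        assert rep.n_shared == rep.n_edna_species == 5

    def test_name_match_and_flag_conventions_agree(self):
        recs = [
            _rec("t1", species="shared sp", flags=["shared_historical"]),
            _rec("t2", species="new sp", flags=["alien"]),
        ]
        with_entries = checklist_metrics(
            recs,
            Checklist(entries=[("shared sp", "g", "f", "o"),
                               ("absent sp", "g2", "f", "o")]),
        )
        with_flags = checklist_metrics(
            recs, Checklist(summary_counts={"species": 2, "genus": 2,
                                            "family": 1, "order": 1})
        )
        assert with_entries.n_shared == with_flags.n_shared == 1

    def test_empty_records_rejected(self, historical_checklist):
        with pytest.raises(ValueError):
            checklist_metrics([], historical_checklist)


class TestSharedOtuFraction:
    @staticmethod
    def _table(n_shared, n_total, n_sections=12, seed=0):
        """Synthetic OTU table with exact shared/total margins."""
        rng = np.random.default_rng(seed)
        samples = [SampleInfo(f"S{j}", f"S{j}") for j in range(n_sections)]
        rows = []
        for i in range(n_total):
            if i < n_shared:
                counts = rng.integers(1, 50, n_sections)  # everywhere
            else:
                counts = rng.integers(0, 50, n_sections)
                counts[rng.integers(n_sections)] = 0  # absent somewhere
            rows.append(OtuRow(f"o{i}", tuple(int(c) for c in counts),
                               f"t{i % 40}", 0.99, 1e-9, True))
        return AnnotatedOtuTable(rows, samples)

    def test_survey_margins(self):
        table = self._table(533, 2299)
        n, frac = shared_otu_fraction(table)
        assert n == 533
        assert frac * 100 == pytest.approx(23.18, abs=0.005)

    def test_all_everywhere(self):
        table = self._table(10, 10, n_sections=3)
        assert shared_otu_fraction(table) == (10, 1.0)

    def test_none_everywhere(self):
        table = self._table(0, 7, n_sections=4)
        assert shared_otu_fraction(table) == (0, 0.0)

    def test_replicates_pool_into_sections(self):
        # OTU present in only one replicate of each section still counts
        # as present in the section
        samples = [SampleInfo(f"S{j}_r{r}", f"S{j}", r)
                   for j in range(2) for r in (1, 2)]
        rows = [OtuRow("o1", (5, 0, 0, 5), "t1", 0.99, 1e-9, True),
                OtuRow("o2", (5, 0, 0, 0), "t2", 0.99, 1e-9, True)]
        n, frac = shared_otu_fraction(AnnotatedOtuTable(rows, samples))
        assert (n, frac) == (1, 0.5)


class TestDominanceSummary:
    def test_fixture_whole_mainstream(self, survey):
        matrix, records = survey
        doms = mcnaughton(matrix)
        summary = dominance_summary(doms, records, "whole")[0]
        assert len(summary.dominant) == 6
        assert summary.n_rheophilic == 1
        rheophilic = [
            s for s, t in zip(summary.dominant_species, summary.dominant)
            if next(r for r in records if r.taxon_id == t).velocity_guild == "F"
        ]
        assert rheophilic == ["O. bidens"]
        assert summary.rheophilic_share == pytest.approx(1 / 6)

    def test_no_dominant_taxa_empty(self):
        m = CommunityMatrix(
            pd.DataFrame({"s1": np.ones(60, dtype=int)},
                         index=[f"t{i}" for i in range(60)])
        )
        recs = [_rec(f"t{i}") for i in range(60)]
        summary = dominance_summary(mcnaughton(m), recs, "whole")[0]
        assert summary.dominant == []
        assert summary.rheophilic_share == 0.0

    def test_all_rheophilic_share_one(self):
        m = CommunityMatrix(pd.DataFrame({"s1": [50, 50]}, index=["a", "b"]))
        recs = [_rec("a", vel="F"), _rec("b", vel="F")]
        summary = dominance_summary(mcnaughton(m), recs, "whole")[0]
        assert summary.rheophilic_share == 1.0

    def test_per_section_scopes(self, survey):
        matrix, records = survey
        doms = mcnaughton(matrix)
        per_section = dominance_summary(
            doms, records, "section", matrix=matrix
        )
        assert [s.scope for s in per_section] == matrix.sample_ids
        for s in per_section:
            assert 0.0 <= s.rheophilic_share <= 1.0
            assert len(s.dominant) >= 1  # every section has a dominant fish
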