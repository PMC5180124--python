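"""Domain types: kin classification, age bins, table validation."""

import numpy as np
import pandas as pd
import pytest

from kinbias.datamodel import (
    DataError,
    Individual,
    Pedigree,
    Roster,
    age_bin_of,
    bin_window,
    classify_kin,
    KinCategory,
    MIPair,
    pair_present_in_window,
)
from kinbias.io import read_tables, write_tables

from conftest import follows_frame, make_individual, samples_frame, simple_bundle


class TestKinClassification:
    @pytest.mark.parametrize(
        "male,expected",
        [
            ("DAD", KinCategory.FATHER),
            ("BRO", KinCategory.MATERNAL_KIN),  # maternal brother
            ("UNC", KinCategory.MATERNAL_KIN),  # maternal uncle
            ("COUS", KinCategory.MATERNAL_KIN),  # maternal cousin
            ("NK", KinCategory.NON_KIN),
        ],
    )
    def test_named_relations(self, kin_community, male, expected):
        roster, pedigree = kin_community
        assert classify_kin(male, "INF", pedigree, roster) is expected

    def test_unknown_paternity(self, kin_community):
        roster, pedigree = kin_community
        # UNKI has no father assigned and NK has no maternal link to it
        assert classify_kin("NK", "UNKI", pedigree, roster) is KinCategory.UNKNOWN
        # but an established maternal relation still wins over UNKNOWN:
        # COUS is AUNT's son and UNKI is AUNT's daughter -> maternal brother
        assert classify_kin("COUS", "UNKI", pedigree, roster) is KinCategory.MATERNAL_KIN

    def test_father_precedence_over_maternal_relation(self):
        # a male who is both the sire and a matrilineal relative is FATHER
        roster = Roster(
            [
                make_individual("G", "F", "1950-01-01"),
                make_individual("M", "F", "1975-01-01"),
                make_individual("U", "M", "1978-01-01"),
                make_individual("I", "F", "2010-01-01"),
            ]
        )
        ped = Pedigree(
            mother_of={"M": "G", "U": "G", "I": "M"}, father_of={"I": "U"}, roster=roster
        )
        assert classify_kin("U", "I", ped, roster) is KinCategory.FATHER

    def test_unknown_id_raises(self, kin_community):
        roster, pedigree = kin_community
        with pytest.raises(DataError, match="GHOST"):
            classify_kin("GHOST", "INF", pedigree, roster)
        with pytest.raises(DataError, match="not male"):
            classify_kin("MOM", "INF", pedigree, roster)

    def test_per_infant_classification_is_independent(self, kin_community):
        # a father is FATHER only toward his own infant
        roster, pedigree = kin_community
        assert classify_kin("DAD", "UNKI", pedigree, roster) is KinCategory.UNKNOWN

    def test_wide_matriline_switch(self):
        # great-grand relation: NON_KIN by default, kin when widened
        roster = Roster(
            [
                make_individual("GG", "F", "1940-01-01"),
                make_individual("G1", "F", "1955-01-01"),
                make_individual("G2", "F", "1957-01-01"),
                make_individual("M", "F", "1975-01-01"),
                make_individual("X", "M", "1980-01-01"),
                make_individual("D", "M", "1980-06-01"),
                make_individual("I", "F", "2010-01-01"),
            ]
        )
        ped = Pedigree(
            mother_of={"G1": "GG", "G2": "GG", "M": "G1", "X": "G2", "I": "M"},
            father_of={"I": "D"},
            roster=roster,
        )
        assert classify_kin("X", "I", ped, roster) is KinCategory.NON_KIN
        assert classify_kin("X", "I", ped, roster, wide_matriline=True) is (
            KinCategory.MATERNAL_KIN
        )

    def test_agrees_with_exhaustive_enumeration_on_random_pedigrees(self):
        """Brute-force oracle built from forward (children) links."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 30
            sexes = ["F" if rng.random() < 0.5 else "M" for _ in range(n)]
            ids = [f"P{k}" for k in range(n)]
            inds = [
                make_individual(ids[k], sexes[k], f"{1950 + 2 * k}-01-01")
                for k in range(n)
            ]
            roster = Roster(inds)
            mother_of, father_of = {}, {}
            for k in range(n):
                elig_m = [j for j in range(k) if sexes[j] == "F"]
                if elig_m and rng.random() < 0.8:
                    mother_of[ids[k]] = ids[int(rng.choice(elig_m))]
                elig_f = [j for j in range(k) if sexes[j] == "M"]
                if elig_f and rng.random() < 0.5:
                    father_of[ids[k]] = ids[int(rng.choice(elig_f))]
            ped = Pedigree(mother_of, father_of, roster=roster)

            children = {}
            for c, m in mother_of.items():
                children.setdefault(m, []).append(c)

            def oracle(male, infant):
                if father_of.get(infant) == male:
                    return KinCategory.FATHER
                mom = mother_of.get(infant)
                kin = False
                if mom is not None:
                    # brothers: other sons of the mother
                    kin |= male in children.get(mom, [])
                    gm = mother_of.get(mom)
                    if gm is not None:
                        # uncles: sons of the grandmother
                        kin |= male in children.get(gm, [])
                        # cousins: sons of the mother's sisters
                        for aunt in children.get(gm, []):
                            if aunt != mom:
                                kin |= male in children.get(aunt, [])
                if kin:
                    return KinCategory.MATERNAL_KIN
                return (
                    KinCategory.UNKNOWN
                    if infant not in father_of
                    else KinCategory.NON_KIN
                )

            for male in [i for i in ids if sexes[ids.index(i)] == "M"][:10]:
                for infant in ids[-10:]:
                    if infant == male:
                        continue
                    assert classify_kin(male, infant, ped, roster) is oracle(male, infant)

    def test_category_counts_partition_all_males(self, kin_community):
        roster, pedigree = kin_community
        males = [i.id for i in roster if i.sex == "M" and i.id != "INF"]
        cats = [classify_kin(m, "INF", pedigree, roster) for m in males]
        assert len(cats) == len(males)  # exactly one category each


class TestAgeBins:
    def test_boundaries(self):
        assert age_bin_of("2010-01-01", "2010-01-01") == 0
        # exactly six calendar months later starts bin 1 (half-open)
        assert age_bin_of("2010-01-01", "2010-06-30") == 0
        assert age_bin_of("2010-01-01", "2010-07-01") == 1
        assert age_bin_of("2010-01-01", "2013-06-30") == 6  # 41 months 29 days
        assert age_bin_of("2010-01-01", "2013-07-01") is None  # 42 months

    def test_day_count_oracle(self):
        # every day of the first 42 months falls in exactly the bin whose
        # calendar window contains it
        birth = pd.Timestamp("2011-03-17")
        for day in pd.date_range(birth, periods=1290, freq="7D"):
            b = age_bin_of(birth, day)
            if day >= birth + pd.DateOffset(months=42):
                assert b is None
            else:
                lo, hi = bin_window(birth, b)
                assert lo <= day < hi

    def test_windows_partition_infancy(self):
        birth = pd.Timestamp("2010-01-01")
        for b in range(6):
            assert bin_window(birth, b)[1] == bin_window(birth, b + 1)[0]

    def test_date_before_birth_raises(self):
        with pytest.raises(DataError):
            age_bin_of("2010-01-01", "2009-12-31")


class TestIndividualInvariants:
    def test_death_before_birth_rejected(self):
        with pytest.raises(DataError):
            Individual(id="x", sex="F", birth_date="2000-01-01", death_date="1999-01-01")

    def test_default_adulthood_is_twelve_years(self):
        ind = make_individual("x", "M", "2000-03-05")
        assert ind.adult_from == pd.Timestamp("2012-03-05")
        assert not ind.adult_on("2012-03-04")
        assert ind.adult_on("2012-03-05")

    def test_explicit_adult_from_overrides(self):
        ind = make_individual("x", "M", "2000-03-05", adult_from="2013-01-01")
        assert ind.adult_from == pd.Timestamp("2013-01-01")

    def test_pair_presence_respects_death_and_age(self):
        roster = Roster(
            [
                make_individual("F", "F", "1990-01-01"),
                make_individual("I", "F", "2010-01-01", death="2011-02-10"),
            ]
        )
        pair = MIPair("F", "I", "2010-01-01")
        assert pair_present_in_window(pair, ("2011-01-01", "2011-07-01"), roster)
        assert not pair_present_in_window(pair, ("2011-02-11", "2011-08-01"), roster)
        # age limit: gone after 42 months even when alive
        roster2 = Roster(
            [make_individual("F", "F", "1990-01-01"), make_individual("I", "F", "2010-01-01")]
        )
        assert not pair_present_in_window(pair, ("2013-07-01", "2014-01-01"), roster2)


class TestTablesIO:
    def test_round_trip_identity(self, tmp_path, kin_community):
        roster, pedigree = kin_community
        bundle = simple_bundle(
            roster,
            pedigree,
            follows=follows_frame(
                [("DAD", "2010-02-01", 0, 60, "DAD;MOM;INF"),
                 ("DAD", "2010-02-01", 60, 120, "DAD")]
            ),
            point_samples=samples_frame(
                [("INF", "2010-08-01", 0, "GROOM", "DAD", "INF;MOM;DAD"),
                 ("INF", "2010-08-01", 1, "NONE", "", "INF;MOM")]
            ),
        )
        write_tables(bundle, tmp_path, {"seed": 1})
        back = read_tables(tmp_path)
        assert back.follows.equals(bundle.follows)
        assert back.point_samples.equals(bundle.point_samples)
        assert back.roster.to_frame().equals(bundle.roster.to_frame())
        assert sorted(back.pedigree.mother_of.items()) == sorted(pedigree.mother_of.items())

    def test_overlapping_intervals_rejected_naming_date(self, tmp_path, kin_community):
        roster, pedigree = kin_community
        bundle = simple_bundle(
            roster,
            pedigree,
            follows=follows_frame(
                [("DAD", "2010-02-01", 0, 100, "DAD"), ("DAD", "2010-02-01", 50, 150, "DAD")]
            ),
        )
        write_tables(bundle, tmp_path, {})
        with pytest.raises(DataError, match="2010-02-01"):
            read_tables(tmp_path)

    def test_groom_without_partner_rejected(self, tmp_path, kin_community):
        roster, pedigree = kin_community
        bundle = simple_bundle(
            roster,
            pedigree,
            point_samples=samples_frame(
                [("INF", "2010-08-01", 0, "GROOM", "", "INF;MOM;DAD")]
            ),
        )
        write_tables(bundle, tmp_path, {})
        with pytest.raises(DataError, match="partner"):
            read_tables(tmp_path)

    def test_focal_missing_from_party_rejected(self, tmp_path, kin_community):
        roster, pedigree = kin_community
        bundle = simple_bundle(
            roster, pedigree, follows=follows_frame([("DAD", "2010-02-01", 0, 30, "MOM;INF")])
        )
        write_tables(bundle, tmp_path, {})
        with pytest.raises(DataError, match="focal"):
            read_tables(tmp_path)

    def test_matriline_cycle_rejected(self):
        with pytest.raises(DataError, match="cycle"):
            Pedigree(mother_of={"A": "B", "B": "A"})
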