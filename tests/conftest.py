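"""Shared builders for hand-constructed observation fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinbias.datamodel import FollowBundle, Individual, Pedigree, Roster


def make_individual(id_, sex, birth, death=None, adult_from=None):
    return Individual(id=id_, sex=sex, birth_date=birth, death_date=death, adult_from=adult_from)


@pytest.fixture
def kin_community():
    """A 10-individual toy community covering every kin relation.

    GM (dead founder) is mother of MOM, AUNT and UNC; BRO is MOM's son,
    COUS is AUNT's son; INF is MOM's infant sired by DAD; NK is an
    unrelated male; UNKI is an infant of unassigned paternity.
    """
    roster = Roster(
        [
            make_individual("GM", "F", "1950-01-01", death="1995-01-01"),
            make_individual("MOM", "F", "1975-01-01"),
            make_individual("AUNT", "F", "1977-01-01"),
            make_individual("UNC", "M", "1979-01-01"),
            make_individual("BRO", "M", "1992-01-01"),
            make_individual("COUS", "M", "1994-01-01"),
            make_individual("DAD", "M", "1985-01-01"),
            make_individual("NK", "M", "1986-01-01"),
            make_individual("INF", "M", "2010-01-01"),
            make_individual("UNKI", "F", "2010-06-01"),
        ]
    )
    pedigree = Pedigree(
        mother_of={
            "MOM": "GM", "AUNT": "GM", "UNC": "GM",
            "BRO": "MOM", "COUS": "AUNT", "INF": "MOM", "UNKI": "AUNT",
        },
        father_of={"INF": "DAD"},
        roster=roster,
    )
    return roster, pedigree


def follows_frame(rows):
    """Rows of (focal, date, start, end, 'id1;id2;...')."""
    return pd.DataFrame(
        [
            dict(focal_id=f, date=d, start_min=s, end_min=e, member_ids=m)
            for f, d, s, e, m in rows
        ],
        columns=["focal_id", "date", "start_min", "end_min", "member_ids"],
    )


def samples_frame(rows):
    """Rows of (infant, date, minute, behavior, partner, members)."""
    return pd.DataFrame(
        [
            dict(infant_id=i, date=d, minute=m, behavior=b, partner_id=p, member_ids=mm)
            for i, d, m, b, p, mm in rows
        ],
        columns=["infant_id", "date", "minute", "behavior", "partner_id", "member_ids"],
    )


def simple_bundle(roster, pedigree, follows=None, point_samples=None,
                  dominance=None, conceptions=None):
    empty_follow = follows_frame([])
    empty_samples = samples_frame([])
    return FollowBundle(
        roster=roster,
        pedigree=pedigree,
        follows=follows if follows is not None else empty_follow,
        point_samples=point_samples if point_samples is not None else empty_samples,
        dominance=dominance
        if dominance is not None
        else pd.DataFrame(columns=["date", "winner_id", "loser_id"]),
        conceptions=conceptions
        if conceptions is not None
        else pd.DataFrame(
            columns=["mother_id", "prior_infant_id", "conception_date",
                     "next_infant_id", "sire_id"]
        ),
    )


def random_follow_fixture(seed: int):
    """A small random follow fixture plus its roster/pedigree.

    Three adult males, three MI pairs; segments have random bounds and
    random party membership (sometimes mother without infant), so
    per-minute enumeration is a meaningful oracle.
    """
    rng = np.random.default_rng(seed)
    males = ["M1", "M2", "M3"]
    pairs = [("F1", "I1"), ("F2", "I2"), ("F3", "I3")]
    inds = [make_individual(m, "M", "1985-03-01") for m in males]
    inds += [make_individual(f, "F", "1984-07-01") for f, _ in pairs]
    inds += [make_individual(i, "F", "2010-01-01") for _, i in pairs]
    roster = Roster(inds)
    pedigree = Pedigree(
        mother_of={i: f for f, i in pairs},
        father_of={"I1": "M1", "I2": "M2"},  # I3 unassigned
        roster=roster,
    )
    rows = []
    for m in males:
        for day in rng.choice(pd.date_range("2010-01-05", "2010-05-20", freq="D"), size=3,
                              replace=False):
            t = 0
            for _ in range(int(rng.integers(1, 5))):
                start = t + int(rng.integers(0, 60))
                end = start + int(rng.integers(10, 200))
                if end > 720:
                    break
                members = [m]
                for f, i in pairs:
                    r = rng.random()
                    if r < 0.35:
                        members += [f, i]
                    elif r < 0.45:
                        members.append(f)  # infant out of sight
                rows.append((m, str(pd.Timestamp(day).date()), start, end, ";".join(members)))
                t = end
    return simple_bundle(roster, pedigree, follows=follows_frame(rows))


def minute_oracle_proportion(follows: pd.DataFrame, male, mother, infant, window):
    """Brute-force per-minute enumeration of the association index."""
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    total = 0
    co = 0
    for row in follows.itertuples(index=False):
        if row.focal_id != male:
            continue
        d = pd.Timestamp(row.date)
        if not (start <= d < end):
            continue
        for minute in range(int(row.start_min), int(row.end_min)):
            total += 1
            ids = str(row.member_ids).split(";")
            if mother in ids and infant in ids:
                co += 1
    return co, total
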