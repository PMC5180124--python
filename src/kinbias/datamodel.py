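"""Core domain types for fission-fusion association analysis.

The analytic units are adult males, mother-infant (MI) pairs, and the
kin category linking a male to an infant (father, maternal kin, non-kin,
or unknown paternity).  Infancy is divided into seven half-open
six-month age bins covering [0, 42) months; "six months" always means
calendar-month addition, so an infant born 2010-01-01 occupies bin 0
through 2010-06-30 and bin 1 starts on 2010-07-01.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

#: Number of six-month age bins spanning infancy ([0, 42) months).
N_AGE_BINS = 7

#: Age (months) at which an individual stops being an "infant" for analysis.
INFANCY_END_MONTHS = 6 * N_AGE_BINS

#: Default age (years) of adulthood.
ADULT_AGE_YEARS = 12


class KinCategory(enum.Enum):
    """Relationship of an adult male to a focal infant."""

    FATHER = "FATHER"
    MATERNAL_KIN = "MATERNAL_KIN"
    NON_KIN = "NON_KIN"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DataError(ValueError):
    """Raised when input tables violate a structural invariant."""


def _ts(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        raise DataError(f"invalid date: {value!r}")
    return ts.normalize()


def add_months(date, months: int) -> pd.Timestamp:
    """Calendar-month addition (the convention used for all windows)."""
    return _ts(date) + pd.DateOffset(months=months)


@dataclass(frozen=True)
class Individual:
    """One community member with its demographic dates.

    ``adult_from`` defaults to ``birth_date + 12 years``; an explicit
    value overrides (used for individuals of estimated age).
    """

    id: str
    sex: str
    birth_date: pd.Timestamp
    death_date: Optional[pd.Timestamp] = None
    adult_from: Optional[pd.Timestamp] = None

    def __post_init__(self):
        object.__setattr__(self, "birth_date", _ts(self.birth_date))
        if self.death_date is not None:
            object.__setattr__(self, "death_date", _ts(self.death_date))
        if self.adult_from is None:
            object.__setattr__(
                self, "adult_from", self.birth_date + pd.DateOffset(years=ADULT_AGE_YEARS)
            )
        else:
            object.__setattr__(self, "adult_from", _ts(self.adult_from))
        if self.sex not in ("M", "F"):
            raise DataError(f"individual {self.id}: sex must be M or F, got {self.sex!r}")
        if self.adult_from <= self.birth_date:
            raise DataError(f"individual {self.id}: adult_from must be after birth_date")
        if self.death_date is not None and self.death_date < self.birth_date:
            raise DataError(f"individual {self.id}: death_date before birth_date")

    def alive_on(self, date) -> bool:
        date = _ts(date)
        if date < self.birth_date:
            return False
        return self.death_date is None or date <= self.death_date

    def adult_on(self, date) -> bool:
        return self.alive_on(date) and _ts(date) >= self.adult_from


class Roster:
    """The community: a lookup of :class:`Individual` by id."""

    def __init__(self, individuals: Iterable[Individual]):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise DataError(f"duplicate roster id {ind.id}")
            self._by_id[ind.id] = ind

    def __contains__(self, id_: str) -> bool:
        return id_ in self._by_id

    def __getitem__(self, id_: str) -> Individual:
        try:
            return self._by_id[id_]
        except KeyError:
            raise DataError(f"unknown individual id {id_!r}") from None

    def __iter__(self):
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def adult_males_on(self, date) -> list[str]:
        """Ids of males alive and adult on ``date`` (roster order)."""
        return [i.id for i in self if i.sex == "M" and i.adult_on(date)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": i.id,
                "sex": i.sex,
                "birth_date": i.birth_date.date().isoformat(),
                "death_date": "" if i.death_date is None else i.death_date.date().isoformat(),
                "adult_from": i.adult_from.date().isoformat(),
            }
            for i in self
        ]
        return pd.DataFrame(rows, columns=["id", "sex", "birth_date", "death_date", "adult_from"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Roster":
        inds = []
        for row in df.itertuples(index=False):
            death = getattr(row, "death_date", None)
            adult = getattr(row, "adult_from", None)
            inds.append(
                Individual(
                    id=str(row.id),
                    sex=str(row.sex),
                    birth_date=row.birth_date,
                    death_date=None if _blank(death) else death,
                    adult_from=None if _blank(adult) else adult,
                )
            )
        return cls(inds)


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""


class Pedigree:
    """Mother links (required) and father links (optional) per child.

    Matriline membership is derived by following mother links.  Kin
    classification is a pure function of (male, infant, pedigree):
    FATHER takes precedence, maternal kin covers the infant's adult
    maternal brothers, maternal uncles and maternal cousins (males whose
    matriline chain meets the infant's at the mother, the maternal
    grandmother, or through a maternal aunt respectively).
    """

    def __init__(
        self,
        mother_of: dict[str, str],
        father_of: Optional[dict[str, Optional[str]]] = None,
        roster: Optional[Roster] = None,
    ):
        self.mother_of = dict(mother_of)
        self.father_of = {k: v for k, v in (father_of or {}).items() if v is not None}
        if roster is not None:
            for child, mother in self.mother_of.items():
                if mother not in roster:
                    raise DataError(f"pedigree: mother {mother!r} of {child!r} not in roster")
        # cycle check: walking mother links must terminate without revisits
        for start in self.mother_of:
            seen = {start}
            cur = self.mother_of.get(start)
            while cur is not None:
                if cur in seen:
                    raise DataError(f"pedigree: matriline cycle involving {start!r}")
                seen.add(cur)
                cur = self.mother_of.get(cur)

    def mother(self, id_: str) -> Optional[str]:
        return self.mother_of.get(id_)

    def father(self, id_: str) -> Optional[str]:
        return self.father_of.get(id_)

    def matriline_chain(self, id_: str) -> list[str]:
        """Ancestors through mother links, nearest first (excludes self)."""
        chain = []
        cur = self.mother_of.get(id_)
        while cur is not None:
            chain.append(cur)
            cur = self.mother_of.get(cur)
        return chain

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"child_id": c, "mother_id": m, "father_id": self.father_of.get(c, "")}
            for c, m in self.mother_of.items()
        ]
        return pd.DataFrame(rows, columns=["child_id", "mother_id", "father_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, roster: Optional[Roster] = None) -> "Pedigree":
        mother_of, father_of = {}, {}
        for row in df.itertuples(index=False):
            child = str(row.child_id)
            mother_of[child] = str(row.mother_id)
            f = getattr(row, "father_id", None)
            if not _blank(f):
                father_of[child] = str(f)
        return cls(mother_of, father_of, roster=roster)


def classify_kin(
    male_id: str,
    infant_id: str,
    pedigree: Pedigree,
    roster: Optional[Roster] = None,
    wide_matriline: bool = False,
) -> KinCategory:
    """Kin category of an adult male relative to an infant.

    FATHER requires a father-link match and takes precedence over any
    coincidental maternal relation.  MATERNAL_KIN covers maternal
    brothers (same mother), maternal uncles (male's mother is the
    infant's maternal grandmother) and maternal cousins (male's mother
    and the infant's mother share a mother); ``wide_matriline=True``
    widens this to any shared matrilineal ancestor.  UNKNOWN is returned
    when the infant's paternity is unassigned and no maternal relation
    holds.
    """
    if roster is not None:
        if male_id not in roster:
            raise DataError(f"unknown male id {male_id!r}")
        if infant_id not in roster:
            raise DataError(f"unknown infant id {infant_id!r}")
        if roster[male_id].sex != "M":
            raise DataError(f"{male_id!r} is not male")

    infant_father = pedigree.father(infant_id)
    if infant_father is not None and infant_father == male_id:
        return KinCategory.FATHER

    if _is_maternal_kin(male_id, infant_id, pedigree, wide_matriline):
        return KinCategory.MATERNAL_KIN

    if infant_father is None:
        return KinCategory.UNKNOWN
    return KinCategory.NON_KIN


def _is_maternal_kin(
    male_id: str, infant_id: str, pedigree: Pedigree, wide: bool
) -> bool:
    infant_mother = pedigree.mother(infant_id)
    if infant_mother is None:
        return False
    male_mother = pedigree.mother(male_id)
    if wide:
        infant_line = set(pedigree.matriline_chain(infant_id))
        male_line = set(pedigree.matriline_chain(male_id))
        return bool(infant_line & male_line) or male_id in infant_line
    if male_mother is None:
        return False
    # maternal brother: same mother as the infant
    if male_mother == infant_mother:
        return True
    grandmother = pedigree.mother(infant_mother)
    if grandmother is None:
        return False
    # maternal uncle: male is the mother's (maternal) brother
    if male_mother == grandmother:
        return True
    # maternal cousin: male's mother is a maternal sister of the mother
    male_grandmother = pedigree.mother(male_mother)
    return male_grandmother is not None and male_grandmother == grandmother


@dataclass(frozen=True)
class MIPair:
    """A mother and her dependent infant, the unit of association."""

    mother_id: str
    infant_id: str
    infant_birth_date: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "infant_birth_date", _ts(self.infant_birth_date))


def mi_pairs(roster: Roster, pedigree: Pedigree) -> list[MIPair]:
    """All mother-infant pairs derivable from the pedigree.

    Every individual with a mother link is an "infant" for the 42-month
    span starting at its own birth; presence in a given window is
    decided by :func:`pair_present_in_window`.
    """
    pairs = []
    for ind in roster:
        mom = pedigree.mother(ind.id)
        if mom is not None and mom in roster:
            pairs.append(MIPair(mom, ind.id, ind.birth_date))
    return pairs


def age_bin_of(infant_birth_date, date) -> Optional[int]:
    """Six-month age-bin index (0-6) of ``date``, or None once >= 42 months.

    Bins are half-open [start, next-start) with calendar-month bounds.
    """
    birth = _ts(infant_birth_date)
    date = _ts(date)
    if date < birth:
        raise DataError(f"date {date.date()} precedes birth {birth.date()}")
    if date >= add_months(birth, INFANCY_END_MONTHS):
        return None
    for b in range(N_AGE_BINS):
        if date < add_months(birth, 6 * (b + 1)):
            return b
    raise AssertionError("unreachable")  # pragma: no cover


def bin_window(infant_birth_date, bin_index: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open calendar window [start, end) of one age bin."""
    if not 0 <= bin_index < N_AGE_BINS:
        raise DataError(f"age bin index must be 0-{N_AGE_BINS - 1}, got {bin_index}")
    birth = _ts(infant_birth_date)
    return add_months(birth, 6 * bin_index), add_months(birth, 6 * (bin_index + 1))


def pair_present_in_window(pair: MIPair, window, roster: Roster) -> bool:
    """True if the MI pair is analytically present on >= 1 day of the window.

    Present means: infant alive and younger than 42 months, and the
    mother alive, on at least one day of the half-open window.
    """
    start, end = _ts(window[0]), _ts(window[1])
    infant = roster[pair.infant_id]
    mother = roster[pair.mother_id]
    lo = max(start, infant.birth_date, mother.birth_date)
    hi = min(end, add_months(infant.birth_date, INFANCY_END_MONTHS))
    if infant.death_date is not None:
        hi = min(hi, infant.death_date + pd.Timedelta(days=1))
    if mother.death_date is not None:
        hi = min(hi, mother.death_date + pd.Timedelta(days=1))
    return lo < hi


@dataclass
class FollowBundle:
    """Validated long-format observation tables.

    Attributes mirror the on-disk CSVs: ``follows`` (party-composition
    segments of focal follows), ``point_samples`` (1-min family-follow
    samples), ``dominance`` (decided dyadic contests) and
    ``conceptions`` (mother, prior infant, conception, next infant,
    sire).  ``roster`` and ``pedigree`` are parsed into domain objects.
    """

    roster: Roster
    pedigree: Pedigree
    follows: pd.DataFrame = field(default_factory=pd.DataFrame)
    point_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    dominance: pd.DataFrame = field(default_factory=pd.DataFrame)
    conceptions: pd.DataFrame = field(default_factory=pd.DataFrame)
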