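"""Dyadic male x mother-infant association indices.

The association index of a male with a mother-infant (MI) pair over a
window is::

    minutes the MI pair was in the male's party  /  minutes the male was followed

A minute counts toward the numerator only when the mother AND the
infant are both recorded in the focal male's party segment; the MI pair
is the analytic unit.  Within each (male, window) the proportions
across all MI pairs present in the community are z-standardized, which
controls for temporal changes in demography and in community-level
gregariousness.  Windows are anchored to each focal infant's birth date
and advance in calendar six-month steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .datamodel import (
    INFANCY_END_MONTHS,
    N_AGE_BINS,
    FollowBundle,
    KinCategory,
    add_months,
    bin_window,
    classify_kin,
    mi_pairs,
)
from .io import split_members

logger = logging.getLogger(__name__)

#: Default minimum observed follow time (hours) per six-month window.
MIN_HOURS_ASSOCIATION = 30.0
#: Default minimum follow time (hours) over the 18-month paternity window.
MIN_HOURS_PATERNITY = 90.0


class Proportion(NamedTuple):
    co_minutes: float
    follow_minutes: float
    proportion: float
    defined: bool  # False when the male has no follow time in the window


def _day(value) -> np.datetime64:
    return np.datetime64(pd.Timestamp(value).date(), "D")


def association_proportion(male_id: str, pair, window, follows: pd.DataFrame) -> Proportion:
    """Direct (row-scan) association proportion of one male with one MI pair.

    ``window`` is a half-open (start, end) date pair.  The denominator
    is every follow minute of the male inside the window; a segment
    counts as co-presence only if both pair members are in its party.
    An undefined proportion (zero follow minutes) is flagged.
    """
    start, end = _day(window[0]), _day(window[1])
    mask = follows["focal_id"].values == male_id
    sub = follows.loc[mask]
    dates = sub["date"].values.astype("datetime64[D]")
    inwin = (dates >= start) & (dates < end)
    sub = sub.loc[inwin]
    seglen = (sub["end_min"].values - sub["start_min"].values).astype(float)
    follow_min = float(seglen.sum())
    if follow_min == 0:
        return Proportion(0.0, 0.0, float("nan"), False)
    co = 0.0
    for length, members in zip(seglen, sub["member_ids"]):
        ids = split_members(members)
        if pair.mother_id in ids and pair.infant_id in ids:
            co += length
    return Proportion(co, follow_min, co / follow_min, True)


def ztransform(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """z-scores with the n-1 denominator; degenerate sets map to zeros.

    Returns ``(z, degenerate)``: when fewer than two values or zero
    spread, every z is 0 and the degeneracy flag is set.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return np.zeros_like(values), True
    sd = values.std(ddof=1)
    # guard against zero spread up to floating-point noise
    if sd <= 1e-12 * max(1.0, float(np.abs(values).max())):
        return np.zeros_like(values), True
    return (values - values.mean()) / sd, False


class AssociationIndex:
    """Pre-indexed follow data for fast window queries.

    Builds, once per dataset, per-male daily follow minutes and daily
    co-presence minutes with every MI pair, so that any calendar-window
    proportion is a prefix-sum difference.
    """

    def __init__(self, bundle: FollowBundle):
        self.roster = bundle.roster
        self.pedigree = bundle.pedigree
        self.pairs = sorted(
            mi_pairs(bundle.roster, bundle.pedigree), key=lambda p: p.infant_id
        )
        self._pair_idx = {p.infant_id: j for j, p in enumerate(self.pairs)}
        self._kin_cache: dict[tuple[str, str], KinCategory] = {}
        self._build_presence()
        self._build_followsums(bundle.follows)

    # -- construction -------------------------------------------------
    def _build_presence(self):
        lo, hi = [], []
        for p in self.pairs:
            infant = self.roster[p.infant_id]
            mother = self.roster[p.mother_id]
            start = max(infant.birth_date, mother.birth_date)
            end = add_months(infant.birth_date, INFANCY_END_MONTHS)
            for person in (infant, mother):
                if person.death_date is not None:
                    end = min(end, person.death_date + pd.Timedelta(days=1))
            lo.append(_day(start))
            hi.append(_day(end))
        self._pres_lo = np.array(lo, dtype="datetime64[D]")
        self._pres_hi = np.array(hi, dtype="datetime64[D]")

    def _build_followsums(self, follows: pd.DataFrame):
        self._per_male: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if follows.empty:
            return
        codes, uniq = pd.factorize(follows["member_ids"].values)
        memsets = [frozenset(split_members(u)) for u in uniq]
        n_pairs = len(self.pairs)
        inparty = np.zeros((len(uniq), n_pairs), dtype=bool)
        for k, s in enumerate(memsets):
            for j, p in enumerate(self.pairs):
                if p.mother_id in s and p.infant_id in s:
                    inparty[k, j] = True
        dates = follows["date"].values.astype("datetime64[D]")
        seglen = (follows["end_min"].values - follows["start_min"].values).astype(float)
        focal = follows["focal_id"].values
        for male in pd.unique(focal):
            m = focal == male
            udates, dayidx = np.unique(dates[m], return_inverse=True)
            fday = np.bincount(dayidx, weights=seglen[m], minlength=udates.size)
            coday = np.zeros((udates.size, n_pairs))
            w = seglen[m] * inparty[codes[m], :].T  # (n_pairs, n_rows)
            for j in range(n_pairs):
                coday[:, j] = np.bincount(dayidx, weights=w[j], minlength=udates.size)
            cumf = np.concatenate([[0.0], np.cumsum(fday)])
            cumco = np.vstack([np.zeros(n_pairs), np.cumsum(coday, axis=0)])
            self._per_male[male] = (udates, cumf, cumco)

    # -- queries ------------------------------------------------------
    def males(self) -> list[str]:
        return sorted(self._per_male)

    def _locate(self, male: str, window):
        if male not in self._per_male:
            return None
        udates, cumf, cumco = self._per_male[male]
        lo = np.searchsorted(udates, _day(window[0]), side="left")
        hi = np.searchsorted(udates, _day(window[1]), side="left")
        return udates, cumf, cumco, lo, hi

    def follow_minutes(self, male: str, window) -> float:
        loc = self._locate(male, window)
        if loc is None:
            return 0.0
        _, cumf, _, lo, hi = loc
        return float(cumf[hi] - cumf[lo])

    def co_minutes(self, male: str, window) -> np.ndarray:
        """Co-presence minutes with every MI pair (pair order)."""
        loc = self._locate(male, window)
        if loc is None:
            return np.zeros(len(self.pairs))
        _, _, cumco, lo, hi = loc
        return cumco[hi] - cumco[lo]

    def pairs_present(self, window) -> np.ndarray:
        """Boolean mask over pairs analytically present in the window."""
        ws, we = _day(window[0]), _day(window[1])
        return (self._pres_lo < we) & (self._pres_hi > ws)

    def kin(self, male: str, infant: str) -> KinCategory:
        key = (male, infant)
        if key not in self._kin_cache:
            self._kin_cache[key] = classify_kin(male, infant, self.pedigree)
        return self._kin_cache[key]

    def kin_array(self, male: str) -> np.ndarray:
        """Kin-category values of ``male`` toward every pair (pair order)."""
        if not hasattr(self, "_kin_arrays"):
            self._kin_arrays: dict[str, np.ndarray] = {}
        if male not in self._kin_arrays:
            self._kin_arrays[male] = np.array(
                [self.kin(male, p.infant_id).value for p in self.pairs]
            )
        return self._kin_arrays[male]

    def z_values(self, male: str, window):
        """Array form of :meth:`standardized`.

        Returns ``(present_idx, proportions, z, degenerate, exposure)``
        where ``present_idx`` indexes into :attr:`pairs`; empty when the
        male has no follow time in the window.

        Each pair's denominator is exposure-corrected: the male's follow
        minutes on days the pair was analytically present.  For pairs
        present throughout the window this equals the male's total
        follow time; for partially present pairs it removes the
        mechanical deflation their proportion would otherwise suffer,
        so partial-window pairs can be included in the standardization
        set without biasing the father/non-kin contrast.
        """
        empty = (np.array([], dtype=int), np.array([]), np.array([]), True, np.array([]))
        loc = self._locate(male, window)
        if loc is None:
            return empty
        udates, cumf, cumco, _, _ = loc
        present = self.pairs_present(window)
        if not present.any():
            return empty
        pres_idx = np.nonzero(present)[0]
        ws, we = _day(window[0]), _day(window[1])
        lo_days = np.maximum(self._pres_lo[pres_idx], ws)
        hi_days = np.minimum(self._pres_hi[pres_idx], we)
        ilo = np.searchsorted(udates, lo_days, side="left")
        ihi = np.searchsorted(udates, hi_days, side="left")
        exposure = cumf[ihi] - cumf[ilo]
        co = cumco[ihi, pres_idx] - cumco[ilo, pres_idx]
        observed = exposure > 0
        pres_idx, exposure, co = pres_idx[observed], exposure[observed], co[observed]
        if pres_idx.size == 0:
            return empty
        props = co / exposure
        z, degenerate = ztransform(props)
        return pres_idx, props, z, degenerate, exposure

    def standardized(self, male: str, window) -> pd.DataFrame:
        """Per-pair proportions and z-scores for one (male, window).

        The standardization set is every MI pair present in the window
        regardless of kin category (maternal kin, unknown paternity and
        other-age father dyads all contribute), which is what makes the
        father vs non-kin contrast comparable across windows.
        """
        pres_idx, props, z, degenerate, exposure = self.z_values(male, window)
        if pres_idx.size == 0:
            return pd.DataFrame(
                columns=["male_id", "mother_id", "infant_id", "co_minutes",
                         "follow_minutes", "proportion", "z", "degenerate", "kin"]
            )
        sel = [self.pairs[j] for j in pres_idx]
        return pd.DataFrame(
            {
                "male_id": male,
                "mother_id": [p.mother_id for p in sel],
                "infant_id": [p.infant_id for p in sel],
                "co_minutes": props * exposure,
                "follow_minutes": exposure,
                "proportion": props,
                "z": z,
                "degenerate": degenerate,
                "kin": self.kin_array(male)[pres_idx],
            }
        )


@dataclass
class FilterLog:
    """Bookkeeping of how many candidate rows each filter removed."""

    windows_considered: int = 0
    windows_below_min_hours: int = 0
    windows_no_father_row: int = 0
    windows_no_nonkin_row: int = 0
    windows_degenerate: int = 0
    windows_kept: int = 0


def _father_children(pedigree) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for child, father in pedigree.father_of.items():
        out.setdefault(father, []).append(child)
    for v in out.values():
        v.sort()
    return out


_DATASET_COLUMNS = [
    "male_id", "mother_id", "infant_id", "infant_sex", "focal_infant_id",
    "age_bin", "kin", "proportion", "z", "window_start", "window_end",
]


class _RowAccumulator:
    """Bulk collector of analysis-table rows (avoids per-window frames)."""

    def __init__(self, idx: "AssociationIndex"):
        self.idx = idx
        self.cols: dict[str, list] = {c: [] for c in _DATASET_COLUMNS}

    def add(self, male, pair_indices, props, z, kin, focal_infant, age_bin, window):
        ws, we = str(_day(window[0])), str(_day(window[1]))
        for j, p, zz, k in zip(pair_indices, props, z, kin):
            pair = self.idx.pairs[j]
            c = self.cols
            c["male_id"].append(male)
            c["mother_id"].append(pair.mother_id)
            c["infant_id"].append(pair.infant_id)
            c["infant_sex"].append(self.idx.roster[pair.infant_id].sex)
            c["focal_infant_id"].append(focal_infant)
            c["age_bin"].append(age_bin)
            c["kin"].append(k)
            c["proportion"].append(p)
            c["z"].append(zz)
            c["window_start"].append(ws)
            c["window_end"].append(we)

    @property
    def empty(self) -> bool:
        return not self.cols["male_id"]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cols, columns=_DATASET_COLUMNS)


def build_within_period_dataset(
    bundle: FollowBundle,
    min_hours: float = MIN_HOURS_ASSOCIATION,
    index: Optional[AssociationIndex] = None,
    drop_degenerate: bool = False,
) -> tuple[pd.DataFrame, FilterLog]:
    """Father vs non-kin rows compared inside the same calendar window.

    For each father and each six-month bin of each of his offspring,
    the offspring-anchored window contributes the father's z with that
    offspring's MI pair (kin FATHER) and with every non-kin MI pair
    present in the same window (kin NON_KIN) — provided the father was
    followed at least ``min_hours`` in the window (boundary inclusive)
    and both kinds of rows exist.  Degenerate standardization sets
    (zero spread, z pinned at 0) are kept by default; the
    ``drop_degenerate`` sensitivity switch removes those windows.
    """
    idx = index if index is not None else AssociationIndex(bundle)
    log = FilterLog()
    acc = _RowAccumulator(idx)
    for father, children in sorted(_father_children(bundle.pedigree).items()):
        for child in children:
            if child not in idx._pair_idx:
                continue
            birth = bundle.roster[child].birth_date
            for b in range(N_AGE_BINS):
                w = bin_window(birth, b)
                log.windows_considered += 1
                if idx.follow_minutes(father, w) < min_hours * 60.0:
                    log.windows_below_min_hours += 1
                    continue
                pres_idx, props, z, deg, _exp = idx.z_values(father, w)
                if drop_degenerate and deg:
                    log.windows_degenerate += 1
                    continue
                own_pos = np.nonzero(pres_idx == idx._pair_idx[child])[0]
                if own_pos.size == 0:
                    log.windows_no_father_row += 1
                    continue
                kin = idx.kin_array(father)[pres_idx]
                nonkin_pos = np.nonzero(kin == KinCategory.NON_KIN.value)[0]
                if nonkin_pos.size == 0:
                    log.windows_no_nonkin_row += 1
                    continue
                log.windows_kept += 1
                take = np.concatenate([own_pos, nonkin_pos])
                acc.add(father, pres_idx[take], props[take], z[take], kin[take], child, b, w)
    if acc.empty:
        logger.info("within-period dataset is empty after filtering")
    return acc.frame(), log


def build_between_period_dataset(
    bundle: FollowBundle,
    min_hours: float = MIN_HOURS_ASSOCIATION,
    index: Optional[AssociationIndex] = None,
    drop_degenerate: bool = False,
) -> tuple[pd.DataFrame, FilterLog]:
    """Father vs non-kin rows compared at the same infant age bin.

    Every MI pair anchors its own six-month windows; a male's z with a
    pair in that pair's bin-``b`` window yields one candidate row, no
    matter the calendar period.  A male enters bin ``b`` only if he has
    both a FATHER row and at least one NON_KIN row in that bin.
    """
    idx = index if index is not None else AssociationIndex(bundle)
    log = FilterLog()
    acc = _RowAccumulator(idx)
    for pair in idx.pairs:
        birth = bundle.roster[pair.infant_id].birth_date
        j0 = idx._pair_idx[pair.infant_id]
        for b in range(N_AGE_BINS):
            w = bin_window(birth, b)
            for male in idx.males():
                log.windows_considered += 1
                if idx.follow_minutes(male, w) < min_hours * 60.0:
                    log.windows_below_min_hours += 1
                    continue
                pres_idx, props, z, deg, _exp = idx.z_values(male, w)
                if drop_degenerate and deg:
                    log.windows_degenerate += 1
                    continue
                pos = np.nonzero(pres_idx == j0)[0]
                if pos.size == 0:
                    continue
                kin = idx.kin_array(male)[pres_idx[pos]]
                acc.add(male, pres_idx[pos], props[pos], z[pos], kin,
                        pair.infant_id, b, w)
    if acc.empty:
        return pd.DataFrame(columns=_DATASET_COLUMNS), log
    cand = acc.frame()
    # retain (male, bin) cells having both a FATHER and a NON_KIN row
    kept = []
    for (male, b), grp in cand.groupby(["male_id", "age_bin"], sort=True):
        kinds = set(grp["kin"])
        if KinCategory.FATHER.value in kinds and KinCategory.NON_KIN.value in kinds:
            sel = grp[grp["kin"].isin([KinCategory.FATHER.value, KinCategory.NON_KIN.value])]
            kept.append(sel)
            log.windows_kept += len(sel)
    if not kept:
        return pd.DataFrame(columns=_DATASET_COLUMNS), log
    return pd.concat(kept, ignore_index=True), log


_CASE_COLUMNS = [
    "mother_id", "father_id", "prior_infant_id", "next_infant_id",
    "conception_date", "z", "same_sire", "follow_minutes", "passes_filter",
]


def build_paternity_cases(
    bundle: FollowBundle,
    min_hours: float = MIN_HOURS_PATERNITY,
    window_months: int = 18,
    index: Optional[AssociationIndex] = None,
) -> pd.DataFrame:
    """One row per (mother, prior infant) conception case.

    ``z`` is the father's standardized association with the mother's MI
    pair over the prior infant's first ``window_months`` months;
    ``same_sire`` records whether the same male sired the next
    offspring.  Cases whose prior paternity or next sire is unassigned
    are omitted (they cannot enter the model); the observation-time
    filter is reported per row, not applied.
    """
    idx = index if index is not None else AssociationIndex(bundle)
    rows = []
    for rec in bundle.conceptions.itertuples(index=False):
        father = bundle.pedigree.father(str(rec.prior_infant_id))
        sire = str(rec.sire_id).strip()
        if father is None or not sire:
            continue
        birth = bundle.roster[str(rec.prior_infant_id)].birth_date
        w = (birth, add_months(birth, window_months))
        fmin = idx.follow_minutes(father, w)
        recs = idx.standardized(father, w)
        own = recs[recs["infant_id"] == str(rec.prior_infant_id)]
        z = float(own["z"].iloc[0]) if not own.empty else 0.0
        rows.append(
            dict(
                mother_id=str(rec.mother_id),
                father_id=father,
                prior_infant_id=str(rec.prior_infant_id),
                next_infant_id=str(rec.next_infant_id),
                conception_date=str(rec.conception_date),
                z=z,
                same_sire=bool(sire == father),
                follow_minutes=fmin,
                passes_filter=bool(fmin >= min_hours * 60.0),
            )
        )
    return pd.DataFrame(rows, columns=_CASE_COLUMNS)
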