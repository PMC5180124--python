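"""Infant-adult male interaction rates and observed-vs-expected tests.

From 1-minute family-follow point samples, the dyadic interaction rate
of an infant with an adult male is::

    minutes grooming or playing with the male / minutes observed in the same party as the male

Rates are summed over males into the infant's *total strength* per
infancy period (EARLY = [0, 6) months, LATE = [6, 42) months).  The
observed proportion of a kin category is that category's rate-sum over
the total strength; the expected proportion is the fraction of adult
males in the community belonging to the category at a reference date.
Per-infant observed-minus-expected differences are tested against zero
with a one-sample sign-flip permutation test (two-sided).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from .datamodel import (
    DataError,
    FollowBundle,
    KinCategory,
    Pedigree,
    Roster,
    add_months,
    classify_kin,
)
from .io import split_members

logger = logging.getLogger(__name__)

#: Observation-time filters (hours of family-follow samples).
MIN_HOURS_EARLY = 10.0
MIN_HOURS_LATE = 60.0

EARLY_END_MONTHS = 6
LATE_END_MONTHS = 42


class Period(enum.Enum):
    EARLY = "EARLY"
    LATE = "LATE"

    def __str__(self):  # pragma: no cover - cosmetic
        return self.value


def period_of_age_months(age_months: float) -> Optional[Period]:
    if age_months < 0:
        raise DataError("negative infant age")
    if age_months < EARLY_END_MONTHS:
        return Period.EARLY
    if age_months < LATE_END_MONTHS:
        return Period.LATE
    return None


def reference_date(birth_date, period: Period, anchor: str = "period_start"):
    """Demography reference date for expected proportions.

    ``period_start`` (default): the infant's birthday for EARLY and the
    six-month anniversary for LATE.  ``midpoint``: the middle of the
    period instead.
    """
    if anchor == "period_start":
        months = 0 if period is Period.EARLY else EARLY_END_MONTHS
    elif anchor == "midpoint":
        months = 3 if period is Period.EARLY else (EARLY_END_MONTHS + LATE_END_MONTHS) // 2
    else:
        raise ValueError(f"unknown reference anchor {anchor!r}")
    return add_months(birth_date, months)


def interaction_rate(
    infant_id: str, male_id: str, period: Period, point_samples: pd.DataFrame, roster: Roster
) -> tuple[float, bool]:
    """Direct (row-scan) dyadic interaction rate; flagged when undefined.

    Returns ``(rate, defined)`` where ``defined`` is False (and rate 0)
    when the pair was never co-present in the period's samples.
    """
    birth = roster[infant_id].birth_date
    lo = birth if period is Period.EARLY else add_months(birth, EARLY_END_MONTHS)
    hi = add_months(birth, EARLY_END_MONTHS if period is Period.EARLY else LATE_END_MONTHS)
    sub = point_samples[point_samples["infant_id"] == infant_id]
    dates = pd.to_datetime(sub["date"])
    sub = sub[(dates >= lo) & (dates < hi)]
    denom = num = 0
    for row in sub.itertuples(index=False):
        if male_id in split_members(row.member_ids):
            denom += 1
            if row.behavior in ("GROOM", "PLAY") and str(row.partner_id) == male_id:
                num += 1
    if denom == 0:
        return 0.0, False
    return num / denom, True


def observed_proportions(rates: dict[str, float], kin_of) -> Optional[dict[KinCategory, float]]:
    """Share of total interaction strength per kin category.

    ``rates`` maps male id to dyadic rate; ``kin_of`` maps male id to
    :class:`KinCategory`.  Every male (any category) contributes to the
    total-strength denominator.  Returns None when total strength is 0
    (the infant is excluded from the contrast).
    """
    total = float(sum(rates.values()))
    if total <= 0:
        return None
    out = {cat: 0.0 for cat in KinCategory}
    for male, r in rates.items():
        out[kin_of(male)] += r / total
    return out


def expected_proportions(
    infant_id: str, roster: Roster, pedigree: Pedigree, ref_date
) -> dict[KinCategory, float]:
    """Kin-category composition of the adult-male community at a date."""
    males = roster.adult_males_on(ref_date)
    if not males:
        raise DataError(f"no adult males alive on {ref_date}")
    out = {cat: 0.0 for cat in KinCategory}
    for m in males:
        out[classify_kin(m, infant_id, pedigree, roster)] += 1.0
    return {cat: v / len(males) for cat, v in out.items()}


class PermutationResult(NamedTuple):
    n: int
    mean_diff: float
    p_value: float
    iterations: int
    method: str  # "exhaustive" or "montecarlo"


def permutation_test(
    differences: Iterable[float],
    iterations: int = 10_000,
    seed: Optional[int] = None,
    method: str = "auto",
) -> PermutationResult:
    """One-sample sign-flip permutation test of mean difference = 0.

    The null resamples each difference's sign independently; the
    statistic is the mean and the two-sided p-value is the fraction of
    resampled |mean| at least the observed |mean|.  ``method='auto'``
    enumerates all 2^n sign patterns exactly whenever that is no more
    work than ``iterations`` draws; Monte-Carlo sampling is
    seed-reproducible.
    """
    d = np.asarray(list(differences), dtype=float)
    n = d.size
    if n < 2:
        raise DataError(f"permutation test requires >= 2 differences, got {n}")
    obs = d.mean()
    tol = 1e-12 * max(1.0, abs(obs))
    if method == "auto":
        method = "exhaustive" if (n <= 20 and 2**n <= iterations) else "montecarlo"
    if method == "exhaustive":
        if n > 20:
            raise DataError("exhaustive enumeration limited to n <= 20")
        patterns = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        signs = np.where(patterns & 1, -1.0, 1.0)
        means = signs @ d / n
        p = float(np.mean(np.abs(means) >= abs(obs) - tol))
        return PermutationResult(n, float(obs), p, 2**n, "exhaustive")
    if method != "montecarlo":
        raise ValueError(f"unknown permutation method {method!r}")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(iterations, n)) * 2.0 - 1.0
    means = signs @ d / n
    p = float(np.mean(np.abs(means) >= abs(obs) - tol))
    return PermutationResult(n, float(obs), p, iterations, "montecarlo")


@dataclass
class InteractionResults:
    """Per-dyad rates, per-infant summaries, and category-level tests."""

    rates: pd.DataFrame  # infant, period, male, co/interaction minutes, rate, kin
    summaries: pd.DataFrame  # infant, period, observed minutes, strength, obs/exp props
    tests: pd.DataFrame  # period, category, n, mean_diff, p, iterations, seed


def _candidate_males(roster: Roster) -> list[str]:
    return sorted(i.id for i in roster if i.sex == "M")


def compute_rates(bundle: FollowBundle) -> pd.DataFrame:
    """Vectorized dyadic rates for every (infant, period, adult male).

    Only sample minutes on which a male is alive and adult count toward
    his co-presence denominator.
    """
    samples = bundle.point_samples
    roster = bundle.roster
    males = _candidate_males(roster)
    cols = ["infant_id", "period", "male_id", "interaction_minutes",
            "co_minutes", "rate", "defined", "observed_minutes"]
    if samples.empty:
        return pd.DataFrame(columns=cols)

    dates = samples["date"].values.astype("datetime64[D]")
    infants = samples["infant_id"].values
    # period by calendar six-month boundary (exact, per infant)
    early = np.zeros(len(samples), dtype=bool)
    valid = np.ones(len(samples), dtype=bool)
    for inf in pd.unique(infants):
        m = infants == inf
        b = roster[inf].birth_date
        lo6 = np.datetime64(add_months(b, EARLY_END_MONTHS).date(), "D")
        hi42 = np.datetime64(add_months(b, LATE_END_MONTHS).date(), "D")
        early[m] = dates[m] < lo6
        valid[m] = dates[m] < hi42

    icodes, iuniq = pd.factorize(infants)
    raw = icodes * 2 + np.where(early, 0, 1)  # (infant, period) compound key
    gcodes, gu = pd.factorize(raw[valid])
    guniq = [
        (iuniq[g // 2], Period.EARLY.value if g % 2 == 0 else Period.LATE.value)
        for g in gu
    ]
    n_groups = len(guniq)
    observed = np.bincount(gcodes, minlength=n_groups).astype(float)

    codes, uniq = pd.factorize(samples["member_ids"].values)
    codes = codes[valid]
    msets = [frozenset(split_members(u)) for u in uniq]
    inparty = np.zeros((len(uniq), len(males)), dtype=bool)
    for k, s in enumerate(msets):
        for j, m in enumerate(males):
            if m in s:
                inparty[k, j] = True

    dts = dates[valid]
    denom = np.zeros((n_groups, len(males)))
    for j, m in enumerate(males):
        ind = roster[m]
        ok = inparty[codes, j] & (dts >= np.datetime64(ind.adult_from.date(), "D"))
        if ind.death_date is not None:
            ok &= dts <= np.datetime64(ind.death_date.date(), "D")
        denom[:, j] = np.bincount(gcodes, weights=ok.astype(float), minlength=n_groups)

    num = np.zeros((n_groups, len(males)))
    social_v = samples["behavior"].isin(("GROOM", "PLAY")).values[valid]
    partners_v = samples["partner_id"].values[valid]
    midx = {m: j for j, m in enumerate(males)}
    for g, pid in zip(np.asarray(gcodes)[social_v], partners_v[social_v]):
        j = midx.get(str(pid))
        if j is not None:
            num[g, j] += 1.0

    rows = []
    for g, (inf, per) in enumerate(guniq):
        for j, m in enumerate(males):
            d, nmin = denom[g, j], num[g, j]
            rows.append(
                dict(
                    infant_id=inf, period=per, male_id=m,
                    interaction_minutes=nmin, co_minutes=d,
                    rate=(nmin / d if d > 0 else 0.0),
                    defined=bool(d > 0),
                    observed_minutes=observed[g],
                )
            )
    return pd.DataFrame(rows, columns=cols)


def run_interaction_analysis(
    bundle: FollowBundle,
    iterations: int = 10_000,
    seed: int = 0,
    early_min_hours: float = MIN_HOURS_EARLY,
    late_min_hours: float = MIN_HOURS_LATE,
    reference_anchor: str = "period_start",
    permutation_method: str = "auto",
) -> InteractionResults:
    """Observed-vs-expected kin-category analysis for both periods.

    Infants enter a period only with enough observation time (>= 10 h
    of samples in EARLY, >= 60 h in LATE, boundary inclusive), known
    paternity, and positive total interaction strength.  One
    permutation test is run per (period, kin category present).
    """
    roster, pedigree = bundle.roster, bundle.pedigree
    rates = compute_rates(bundle)
    min_minutes = {Period.EARLY: early_min_hours * 60.0, Period.LATE: late_min_hours * 60.0}

    summary_rows = []
    kin_col = []
    for row in rates.itertuples(index=False):
        kin_col.append(classify_kin(row.male_id, row.infant_id, pedigree, roster).value)
    rates = rates.assign(kin=kin_col)

    for (inf, per), grp in rates.groupby(["infant_id", "period"], sort=True):
        period = Period(per)
        observed_min = float(grp["observed_minutes"].iloc[0])
        if observed_min < min_minutes[period]:
            continue
        if pedigree.father(inf) is None:
            logger.info("infant %s skipped: unassigned paternity", inf)
            continue
        ref = reference_date(roster[inf].birth_date, period, reference_anchor)
        # drop males not yet adult / not alive at the reference date from
        # the contrast only if they also never co-occurred
        rdict = dict(zip(grp["male_id"], grp["rate"]))
        obs = observed_proportions(
            rdict, lambda m: classify_kin(m, inf, pedigree, roster)
        )
        exp = expected_proportions(inf, roster, pedigree, ref)
        total = float(grp["rate"].sum())
        rec = dict(
            infant_id=inf, period=per, observed_minutes=observed_min,
            total_strength=total, reference_date=str(ref.date()),
        )
        for cat in KinCategory:
            rec[f"observed_{cat.value}"] = (obs[cat] if obs else np.nan)
            rec[f"expected_{cat.value}"] = exp[cat]
        rec["included"] = obs is not None
        summary_rows.append(rec)

    summaries = pd.DataFrame(summary_rows)
    test_rows = []
    if not summaries.empty:
        for per in (Period.EARLY.value, Period.LATE.value):
            sub = summaries[(summaries["period"] == per) & summaries["included"]]
            for cat in (KinCategory.FATHER, KinCategory.NON_KIN, KinCategory.MATERNAL_KIN):
                obs_c = sub[f"observed_{cat.value}"].values
                exp_c = sub[f"expected_{cat.value}"].values
                # an infant enters a category contrast only when the
                # category exists for it demographically (father alive,
                # at least one maternal-kin male, ...)
                mask = exp_c > 0
                diffs = obs_c[mask] - exp_c[mask]
                if diffs.size < 2:
                    continue
                res = permutation_test(
                    diffs, iterations=iterations, seed=seed, method=permutation_method
                )
                test_rows.append(
                    dict(
                        period=per, category=cat.value, n=res.n,
                        mean_diff=res.mean_diff, p_value=res.p_value,
                        iterations=res.iterations, method=res.method, seed=seed,
                    )
                )
    tests = pd.DataFrame(
        test_rows,
        columns=["period", "category", "n", "mean_diff", "p_value",
                 "iterations", "method", "seed"],
    )
    return InteractionResults(rates=rates, summaries=summaries, tests=tests)
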