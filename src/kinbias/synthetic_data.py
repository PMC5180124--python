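"""Synthetic fission-fusion community and follow-protocol generator.

Emulates a long-term chimpanzee study community: roughly a dozen adult
males and one-to-two dozen adult females under continuous observation,
with two protocols — all-day focal follows of adult males recording
party composition in segments, and monthly family follows of each
mother-infant (MI) pair recording behaviour and partner at 1-minute
point samples.

The generative model, per 30-minute party segment:

* each MI pair joins a given male's party with probability derived from
  the mother's gregariousness odds ``g/(1-g)``;
* when the male is the infant's father those odds are multiplied by
  ``father_bias ** (2 ** (-age_months / bias_decay_halflife_months))``,
  i.e. the bias equals ``father_bias`` at birth and decays toward 1
  with the configured half-life;
* while co-present, an infant grooms/plays with a male at a small
  per-minute rate — near zero for everyone in early infancy, and
  multiplied by ``father_interaction_bias`` for the father afterwards;
* dominance contests are drawn monthly from a fixed latent hierarchy
  plus logistic noise, and sires are drawn by a rank-skewed lottery
  whose log-odds of a repeat sire shift by ``paternity_link`` times the
  father's latent standardized association with the mother (0 disables
  the link, the null).

Identical seeds give byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .datamodel import (
    INFANCY_END_MONTHS,
    FollowBundle,
    Pedigree,
    Roster,
    add_months,
)
from .io import join_members

DAYS_PER_MONTH = 30.4375  # mean Gregorian month, used for fractional ages


class SimConfig(BaseModel):
    """Parameters of the synthetic community and observation protocols.

    Defaults describe the emulated study system: a community with 12
    adult males and 16 mothers observed for 7 years, father-biased
    co-party odds (x3 at birth, 6-month half-life), and rare
    infant-male interactions concentrated on fathers in late infancy.
    ``father_bias = father_interaction_bias = 1`` and
    ``paternity_link = 0`` give the null model.
    """

    n_adult_males: int = Field(default=12, ge=1)
    n_mothers: int = Field(default=16, ge=1)
    years: float = Field(default=7.0, gt=0)
    start_date: str = "2000-01-01"

    # gregariousness: per-male baseline co-presence probability of a
    # mother, drawn per mother from this range (so that time fully
    # alone spans roughly 25-60% of observation)
    g_low: float = Field(default=0.04, ge=0.0, le=1.0)
    g_high: float = Field(default=0.12, ge=0.0, le=1.0)

    father_bias: float = Field(default=3.0, ge=1.0)  # odds multiplier at birth
    bias_decay_halflife_months: float = Field(default=6.0, gt=0)

    interaction_rate: float = Field(default=0.004, ge=0.0, le=1.0)  # late infancy
    father_interaction_bias: float = Field(default=4.0, ge=1.0)
    early_interaction_rate: float = Field(default=5e-5, ge=0.0, le=1.0)
    other_behavior_rate: float = Field(default=0.05, ge=0.0, le=1.0)

    paternity_link: float = 0.0  # log-odds coefficient on latent z
    # lottery weight decays by this factor per rank step; 0.65 with 12
    # males implies a ~21% chance the same male sires consecutive
    # offspring (and a ~35% top-male paternity share), matching the
    # repeat-paternity level reported for east-African communities
    sire_skew: float = Field(default=0.65, gt=0.0, le=1.0)

    kin_rate: float = Field(default=0.5, ge=0.0, le=1.0)  # P(mother has an adult maternal brother)
    unknown_paternity_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    infant_out_rate: float = Field(default=0.04, ge=0.0, le=1.0)

    follow_days_per_month: int = Field(default=3, ge=0)
    family_follows_per_month: int = Field(default=1, ge=0)
    follow_minutes: int = Field(default=720, ge=30)
    family_minutes: int = Field(default=360, ge=30)
    segment_minutes: int = 30

    dominance_per_month: int = Field(default=10, ge=0)
    elo_noise: float = Field(default=1.5, gt=0)

    first_birth_window_months: float = Field(default=36.0, ge=0)
    ibi_mean_months: float = Field(default=40.0, gt=0)
    ibi_sd_months: float = Field(default=4.0, ge=0)
    gestation_months: float = Field(default=8.0, gt=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.g_high < self.g_low:
            raise ValueError("g_high must be >= g_low")
        if self.follow_minutes % self.segment_minutes or self.family_minutes % self.segment_minutes:
            raise ValueError("follow durations must be whole segments")
        return self

    @property
    def n_months(self) -> int:
        return int(round(self.years * 12))


def replicate_config(config: SimConfig, replicate: int) -> SimConfig:
    """Same conditions, an independently reproducible seed stream."""
    sub = int(np.random.SeedSequence([config.seed, replicate]).generate_state(1)[0] % (2**31))
    return config.model_copy(update={"seed": sub})


def lottery_probabilities(config: SimConfig) -> np.ndarray:
    """Closed-form sire-lottery probabilities by rank (rank 0 = top)."""
    w = config.sire_skew ** np.arange(config.n_adult_males)
    return w / w.sum()


@dataclass
class SimCommunity:
    """A simulated community plus the generator's ground truth."""

    config: SimConfig
    roster: Roster
    pedigree: Pedigree
    conceptions: pd.DataFrame
    males: list[str] = field(default_factory=list)  # ordered by latent rank
    mothers: list[str] = field(default_factory=list)
    gregariousness: dict[str, float] = field(default_factory=dict)  # per mother
    true_father: dict[str, str] = field(default_factory=dict)  # infant -> sire (incl. hidden)
    latent_score: dict[str, float] = field(default_factory=dict)  # dominance
    births: dict[str, np.datetime64] = field(default_factory=dict)  # infant -> birth day
    start: np.datetime64 = np.datetime64("2000-01-01")
    end: np.datetime64 = np.datetime64("2007-01-01")


def _bias_multiplier(age_months, beta: float, halflife: float):
    return beta ** (2.0 ** (-np.asarray(age_months, dtype=float) / halflife))


def _co_prob(g: float, mult=1.0):
    odds = g / (1.0 - g) * mult
    return odds / (1.0 + odds)


def _month_starts(config: SimConfig) -> np.ndarray:
    start = pd.Timestamp(config.start_date)
    idx = pd.date_range(start, periods=config.n_months + 1, freq=pd.DateOffset(months=1))
    return idx.values.astype("datetime64[D]")


def simulate_community(config: SimConfig) -> SimCommunity:
    """Build roster, pedigree and conception/paternity table.

    Mothers give birth 1-3 times across the span; sires are drawn by a
    rank-skewed lottery, except that a mother's *next* sire repeats her
    previous infant's father with log-odds shifted by
    ``paternity_link`` x the father's latent standardized association
    (computed from the same odds model the follow simulator uses, over
    the previous infant's first 18 months).  A configurable fraction of
    paternities is masked as unassigned in the emitted pedigree and
    conception table while still driving behaviour internally.
    """
    rng = np.random.default_rng(config.seed)
    t0 = pd.Timestamp(config.start_date)
    start_d = np.datetime64(t0.date(), "D")
    end_d = np.datetime64(add_months(t0, config.n_months).date(), "D")

    males = [f"M{i + 1:02d}" for i in range(config.n_adult_males)]
    mothers = [f"F{i + 1:02d}" for i in range(config.n_mothers)]

    roster_rows = []
    for i, m in enumerate(males):
        roster_rows.append(
            dict(id=m, sex="M", birth=add_months(t0, -12 * (15 + i)), death=None)
        )
    for i, f in enumerate(mothers):
        roster_rows.append(
            dict(id=f, sex="F", birth=add_months(t0, -12 * (18 + i % 14)), death=None)
        )

    # maternal-kin structure: some mothers share a (dead) founder mother
    # with one adult male, making him a maternal uncle of her infants
    mother_of: dict[str, str] = {}
    father_of: dict[str, str] = {}
    unassigned = list(males)
    n_founders = 0
    for f in mothers:
        if unassigned and rng.random() < config.kin_rate:
            brother = unassigned.pop(int(rng.integers(len(unassigned))))
            n_founders += 1
            g = f"G{n_founders:02d}"
            roster_rows.append(
                dict(id=g, sex="F", birth=add_months(t0, -12 * 45), death=add_months(t0, -12))
            )
            mother_of[f] = g
            mother_of[brother] = g

    gregariousness = {f: float(rng.uniform(config.g_low, config.g_high)) for f in mothers}
    latent = {m: -float(i) for i, m in enumerate(males)}
    p_lottery = lottery_probabilities(config)

    # births first (they fix demography), sires second (chronological)
    births: dict[str, np.datetime64] = {}
    birth_list: list[tuple[np.datetime64, str, str, int]] = []  # (day, infant, mother, parity)
    span_days = (end_d - start_d).astype(int)
    for f in mothers:
        day = start_d + int(rng.uniform(0, config.first_birth_window_months * DAYS_PER_MONTH))
        parity = 0
        while True:
            infant = f"{f}i{parity + 1}"
            births[infant] = day
            birth_list.append((day, infant, f, parity))
            ibi = max(20.0, rng.normal(config.ibi_mean_months, config.ibi_sd_months))
            nxt = day + int(ibi * DAYS_PER_MONTH)
            conception = nxt - int(config.gestation_months * DAYS_PER_MONTH)
            if (conception - start_d).astype(int) > span_days:
                break
            day = nxt
            parity += 1

    true_father: dict[str, str] = {}
    male_index = {m: i for i, m in enumerate(males)}

    def draw_lottery(exclude: str | None = None) -> str:
        w = p_lottery.copy()
        if exclude is not None:
            w[male_index[exclude]] = 0.0
            w = w / w.sum()
        return males[int(rng.choice(config.n_adult_males, p=w))]

    def latent_z(father: str, mother: str, prior_birth: np.datetime64) -> float:
        """Deterministic expected z of (father, mother's pair) over the
        18 months after ``prior_birth`` under the co-presence model."""
        w_start, w_end = prior_birth, prior_birth + int(18 * DAYS_PER_MONTH)
        grid = w_start + ((np.arange(18) + 0.5) * DAYS_PER_MONTH).astype(int)
        vals, target = [], None
        for inf, b in births.items():
            b_end = b + int(INFANCY_END_MONTHS * DAYS_PER_MONTH)
            if b >= w_end or b_end <= w_start:
                continue
            mom = inf.split("i")[0]
            g = gregariousness[mom]
            ages = (grid - b).astype(float) / DAYS_PER_MONTH
            alive = (ages >= 0) & (ages < INFANCY_END_MONTHS)
            if true_father.get(inf) == father:
                mult = _bias_multiplier(np.clip(ages, 0, None), config.father_bias,
                                        config.bias_decay_halflife_months)
            else:
                mult = np.ones_like(ages)
            p = np.where(alive, _co_prob(g, mult), 0.0)
            v = float(p.mean())
            vals.append(v)
            if mom == mother:
                target = v
        vals = np.array(vals)
        if target is None or len(vals) < 2 or vals.std(ddof=1) == 0:
            return 0.0
        return float((target - vals.mean()) / vals.std(ddof=1))

    conc_rows = []
    for day, infant, mother, parity in sorted(birth_list, key=lambda r: (r[0], r[1])):
        if parity == 0:
            true_father[infant] = draw_lottery()
        else:
            prior = f"{mother}i{parity}"
            f_prior = true_father[prior]
            z = latent_z(f_prior, mother, births[prior])
            p_f = p_lottery[male_index[f_prior]]
            p_same = float(expit(logit(p_f) + config.paternity_link * z))
            if rng.random() < p_same:
                sire = f_prior
            else:
                sire = draw_lottery(exclude=f_prior)
            true_father[infant] = sire
            conception = day - int(config.gestation_months * DAYS_PER_MONTH)
            conc_rows.append(
                dict(
                    mother_id=mother,
                    prior_infant_id=prior,
                    conception_date=str(conception),
                    next_infant_id=infant,
                    sire_id=sire,
                )
            )

    # mask a fraction of paternities as unassigned in the outputs
    hidden = {inf for inf in sorted(births) if rng.random() < config.unknown_paternity_rate}
    for row in conc_rows:
        if row["next_infant_id"] in hidden:
            row["sire_id"] = ""

    infant_sexes = {inf: ("M" if rng.random() < 0.5 else "F") for inf in sorted(births)}
    for inf, b in births.items():
        roster_rows.append(dict(id=inf, sex=infant_sexes[inf], birth=pd.Timestamp(str(b)), death=None))
        mother_of[inf] = inf.split("i")[0]
        if inf not in hidden:
            father_of[inf] = true_father[inf]

    from .datamodel import Individual

    roster = Roster(
        Individual(id=r["id"], sex=r["sex"], birth_date=r["birth"], death_date=r["death"])
        for r in roster_rows
    )
    pedigree = Pedigree(mother_of, father_of, roster=roster)
    conceptions = pd.DataFrame(
        conc_rows,
        columns=["mother_id", "prior_infant_id", "conception_date", "next_infant_id", "sire_id"],
    )
    return SimCommunity(
        config=config,
        roster=roster,
        pedigree=pedigree,
        conceptions=conceptions,
        males=males,
        mothers=mothers,
        gregariousness=gregariousness,
        true_father=true_father,
        latent_score=latent,
        births=births,
        start=start_d,
        end=end_d,
    )


def _choose_days(rng, month_starts: np.ndarray, k: int, n_per_month: int) -> np.ndarray:
    """``n_per_month`` distinct sorted days within month ``k``."""
    n_days = int((month_starts[k + 1] - month_starts[k]).astype(int))
    take = min(n_per_month, n_days)
    offs = np.sort(rng.choice(n_days, size=take, replace=False))
    return month_starts[k] + offs


def _simulate_male_follows(com: SimCommunity, rng) -> pd.DataFrame:
    cfg = com.config
    month_starts = _month_starts(cfg)
    seg = cfg.segment_minutes
    n_seg = cfg.follow_minutes // seg
    pair_infants = sorted(com.births)
    pair_mothers = [i.split("i")[0] for i in pair_infants]
    birth_days = np.array([com.births[i] for i in pair_infants])
    base_p = np.array([_co_prob(com.gregariousness[m]) for m in pair_mothers])
    pair_str = [f"{m};{i}" for m, i in zip(pair_mothers, pair_infants)]
    mom_str = [f"{m}" for m in pair_mothers]

    out_focal, out_date, out_seg, out_members = [], [], [], []
    for male in com.males:
        days = np.concatenate(
            [_choose_days(rng, month_starts, k, cfg.follow_days_per_month)
             for k in range(cfg.n_months)]
        ) if cfg.follow_days_per_month else np.array([], dtype="datetime64[D]")
        if days.size == 0:
            continue
        ages = (days[:, None] - birth_days[None, :]).astype(float) / DAYS_PER_MONTH
        present = (ages >= 0) & (ages < INFANCY_END_MONTHS)
        p = np.broadcast_to(base_p, ages.shape).copy()
        own = np.array([com.true_father[i] == male for i in pair_infants])
        if own.any() and cfg.father_bias > 1.0:
            mult = _bias_multiplier(
                np.clip(ages[:, own], 0, None), cfg.father_bias, cfg.bias_decay_halflife_months
            )
            g = base_p[own]
            odds = g / (1 - g) * mult
            p[:, own] = odds / (1 + odds)
        p *= present
        co = rng.random((days.size, n_seg, len(pair_infants))) < p[:, None, :]
        out = rng.random(co.shape) < cfg.infant_out_rate
        date_str = np.datetime_as_string(days, unit="D")
        for d in range(days.size):
            for s in range(n_seg):
                idx = np.nonzero(co[d, s])[0]
                members = [male]
                for j in idx:
                    members.append(mom_str[j] if out[d, s, j] else pair_str[j])
                out_focal.append(male)
                out_date.append(date_str[d])
                out_seg.append(s)
                out_members.append(join_members(members))
    segs = np.array(out_seg, dtype=int) if out_seg else np.array([], dtype=int)
    return pd.DataFrame(
        {
            "focal_id": out_focal,
            "date": out_date,
            "start_min": segs * seg,
            "end_min": (segs + 1) * seg,
            "member_ids": out_members,
        }
    )


def _simulate_family_follows(com: SimCommunity, rng) -> pd.DataFrame:
    cfg = com.config
    month_starts = _month_starts(cfg)
    seg = cfg.segment_minutes
    n_seg = cfg.family_minutes // seg
    males = com.males
    n_males = len(males)
    male_arr = np.array(males)

    frames = []
    for infant in sorted(com.births):
        birth = com.births[infant]
        mother = infant.split("i")[0]
        g = com.gregariousness[mother]
        father = com.true_father[infant]
        f_idx = males.index(father)
        days = []
        for k in range(cfg.n_months):
            lo = max(month_starts[k], birth)
            hi = min(month_starts[k + 1], birth + int(INFANCY_END_MONTHS * DAYS_PER_MONTH))
            if lo >= hi or cfg.family_follows_per_month == 0:
                continue
            span = int((hi - lo).astype(int))
            days.append(lo + int(rng.integers(span)))
        if not days:
            continue
        days = np.array(days, dtype="datetime64[D]")
        ages = (days - birth).astype(float) / DAYS_PER_MONTH

        p = np.full((days.size, n_males), _co_prob(g))
        if cfg.father_bias > 1.0:
            p[:, f_idx] = _co_prob(
                g, _bias_multiplier(ages, cfg.father_bias, cfg.bias_decay_halflife_months)
            )
        co_seg = rng.random((days.size, n_seg, n_males)) < p[:, None, :]
        co_min = np.repeat(co_seg, seg, axis=1)  # (n_days, minutes, n_males)

        rate = np.full((days.size, n_males), cfg.interaction_rate)
        rate[:, f_idx] *= cfg.father_interaction_bias
        rate[ages < 6.0, :] = cfg.early_interaction_rate
        trig = (rng.random(co_min.shape) < rate[:, None, :]) & co_min
        any_t = trig.any(axis=2)
        partner_idx = trig.argmax(axis=2)
        is_groom = rng.random(any_t.shape) < 0.5
        other = (~any_t) & (rng.random(any_t.shape) < cfg.other_behavior_rate)

        behavior = np.where(any_t, np.where(is_groom, "GROOM", "PLAY"),
                            np.where(other, "OTHER", "NONE"))
        partner = np.where(any_t, male_arr[partner_idx], "")

        base = f"{infant};{mother}"
        member_seg = np.empty((days.size, n_seg), dtype=object)
        for d in range(days.size):
            for s in range(n_seg):
                idx = np.nonzero(co_seg[d, s])[0]
                member_seg[d, s] = base if idx.size == 0 else base + ";" + ";".join(male_arr[idx])
        member_min = np.repeat(member_seg, seg, axis=1)

        n_min = cfg.family_minutes
        frames.append(
            pd.DataFrame(
                {
                    "infant_id": np.repeat(infant, days.size * n_min),
                    "date": np.repeat(np.datetime_as_string(days, unit="D"), n_min),
                    "minute": np.tile(np.arange(n_min), days.size),
                    "behavior": behavior.ravel(),
                    "partner_id": partner.ravel(),
                    "member_ids": member_min.ravel(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["infant_id", "date", "minute", "behavior", "partner_id", "member_ids"]
        )
    return pd.concat(frames, ignore_index=True)


def _simulate_dominance(com: SimCommunity, rng) -> pd.DataFrame:
    cfg = com.config
    month_starts = _month_starts(cfg)
    scores = np.array([com.latent_score[m] for m in com.males])
    rows = []
    for k in range(cfg.n_months):
        n_days = int((month_starts[k + 1] - month_starts[k]).astype(int))
        for _ in range(cfg.dominance_per_month):
            i, j = rng.choice(len(com.males), size=2, replace=False)
            p_i = expit((scores[i] - scores[j]) / cfg.elo_noise)
            w, l = (i, j) if rng.random() < p_i else (j, i)
            date = month_starts[k] + int(rng.integers(n_days))
            rows.append(dict(date=str(date), winner_id=com.males[w], loser_id=com.males[l]))
    rows.sort(key=lambda r: r["date"])
    return pd.DataFrame(rows, columns=["date", "winner_id", "loser_id"])


def simulate_follows(
    com: SimCommunity,
    include_male_follows: bool = True,
    include_family_follows: bool = True,
    include_dominance: bool = True,
) -> FollowBundle:
    """Simulate the observation protocols for an existing community.

    Uses a seed stream derived from (but distinct from) the community
    seed so that community and follows are jointly reproducible.
    The include flags let callers generate only the tables a given
    analysis consumes.
    """
    cfg = com.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    follows = (
        _simulate_male_follows(com, rng)
        if include_male_follows
        else pd.DataFrame(columns=["focal_id", "date", "start_min", "end_min", "member_ids"])
    )
    samples = (
        _simulate_family_follows(com, rng)
        if include_family_follows
        else pd.DataFrame(
            columns=["infant_id", "date", "minute", "behavior", "partner_id", "member_ids"]
        )
    )
    dominance = (
        _simulate_dominance(com, rng)
        if include_dominance
        else pd.DataFrame(columns=["date", "winner_id", "loser_id"])
    )
    return FollowBundle(
        roster=com.roster,
        pedigree=com.pedigree,
        follows=follows,
        point_samples=samples,
        dominance=dominance,
        conceptions=com.conceptions,
    )


def simulate(config: SimConfig, **flags) -> tuple[FollowBundle, SimCommunity]:
    """One-call simulation: community demography plus follow data."""
    com = simulate_community(config)
    return simulate_follows(com, **flags), com
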