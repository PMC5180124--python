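"""Elo-rating dominance hierarchy from a log of decided contests.

The rating update after a contest is the standard logistic form: the
winner's expected score is ``E_w = 1 / (1 + 10**((R_l - R_w) / 400))``
and the winner gains ``k * (1 - E_w)`` while the loser loses exactly
the same amount, so the rating sum is conserved.  Higher rating means
higher position; ordinal rank 1 is the top male.  The start rating
(1000) and k-factor (100) follow common animal-dominance convention
and are configurable; they are reported in output metadata because no
single canonical choice exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import DataError, Roster

DEFAULT_START_RATING = 1000.0
DEFAULT_K = 100.0


def elo_update(rating_winner: float, rating_loser: float, k: float = DEFAULT_K):
    """New (winner, loser) ratings after one decided contest."""
    if not k > 0:
        raise DataError("k-factor must be positive")
    expected_w = 1.0 / (1.0 + 10.0 ** ((rating_loser - rating_winner) / 400.0))
    delta = k * (1.0 - expected_w)
    return rating_winner + delta, rating_loser - delta


@dataclass
class EloHistory:
    """Replayed Elo ratings for every male in a dominance log.

    ``events`` rows are (date, winner, loser, new ratings); contests on
    the same date are applied in log order.  Unseen males hold the
    start rating.
    """

    start_rating: float = DEFAULT_START_RATING
    k: float = DEFAULT_K
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    _first_seen: dict[str, pd.Timestamp] = field(default_factory=dict)

    @classmethod
    def from_log(
        cls,
        dominance: pd.DataFrame,
        start_rating: float = DEFAULT_START_RATING,
        k: float = DEFAULT_K,
    ) -> "EloHistory":
        hist = cls(start_rating=start_rating, k=k)
        ratings: dict[str, float] = {}
        rows = []
        if not dominance.empty:
            log = dominance.copy()
            log["ts"] = pd.to_datetime(log["date"])
            log = log.sort_values("ts", kind="stable")
            for rec in log.itertuples(index=False):
                w, l = str(rec.winner_id), str(rec.loser_id)
                if w == l:
                    raise DataError(f"dominance log: {w} beats itself on {rec.date}")
                for who in (w, l):
                    ratings.setdefault(who, start_rating)
                    hist._first_seen.setdefault(who, rec.ts)
                ratings[w], ratings[l] = elo_update(ratings[w], ratings[l], k)
                rows.append(
                    dict(date=rec.ts, male_id=w, rating=ratings[w], role="winner")
                )
                rows.append(
                    dict(date=rec.ts, male_id=l, rating=ratings[l], role="loser")
                )
        hist.events = pd.DataFrame(rows, columns=["date", "male_id", "rating", "role"])
        return hist

    def ratings_at(self, date) -> dict[str, float]:
        """Latest rating per male from contests on or before ``date``."""
        if self.events.empty:
            return {}
        date = pd.Timestamp(date)
        upto = self.events[self.events["date"] <= date]
        out: dict[str, float] = {}
        for rec in upto.itertuples(index=False):
            out[rec.male_id] = rec.rating
        return out

    def ordinal_rank_at(self, date, roster: Roster) -> dict[str, int]:
        """Ordinal ranks (1 = highest rating) of adult males alive at date.

        Males without any contest yet hold the start rating.  Ties are
        broken by earlier first contest date, then id order, so the
        ranking is deterministic.
        """
        date = pd.Timestamp(date)
        males = roster.adult_males_on(date)
        if not males:
            raise DataError(f"no adult males alive on {date.date()}")
        ratings = self.ratings_at(date)
        far_future = pd.Timestamp.max

        def sort_key(m: str):
            return (
                -ratings.get(m, self.start_rating),
                self._first_seen.get(m, far_future),
                m,
            )

        ordered = sorted(males, key=sort_key)
        return {m: i + 1 for i, m in enumerate(ordered)}

    def ranks_frame(self, date, roster: Roster) -> pd.DataFrame:
        ranks = self.ordinal_rank_at(date, roster)
        ratings = self.ratings_at(date)
        return pd.DataFrame(
            [
                dict(
                    male_id=m,
                    rank=r,
                    rating=ratings.get(m, self.start_rating),
                    date=str(pd.Timestamp(date).date()),
                )
                for m, r in sorted(ranks.items(), key=lambda kv: kv[1])
            ]
        )
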