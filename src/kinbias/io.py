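"""Readers/writers for the long-format observation tables.

All tables are plain CSV.  Files written by this package carry a single
leading comment line recording the package version and a hash of the
configuration that produced them; readers skip ``#`` comment lines, so
read ∘ write is the identity on validated bundles.

``member_ids`` columns are semicolon-joined id lists.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .datamodel import DataError, FollowBundle, Pedigree, Roster

BEHAVIORS = ("GROOM", "PLAY", "OTHER", "NONE")

FILES = {
    "roster": "roster.csv",
    "pedigree": "pedigree.csv",
    "follows": "follows.csv",
    "point_samples": "point_samples.csv",
    "dominance": "dominance.csv",
    "conceptions": "conceptions.csv",
}

_COLUMNS = {
    "roster": ["id", "sex", "birth_date", "death_date", "adult_from"],
    "pedigree": ["child_id", "mother_id", "father_id"],
    "follows": ["focal_id", "date", "start_min", "end_min", "member_ids"],
    "point_samples": ["infant_id", "date", "minute", "behavior", "partner_id", "member_ids"],
    "dominance": ["date", "winner_id", "loser_id"],
    "conceptions": ["mother_id", "prior_infant_id", "conception_date", "next_infant_id", "sire_id"],
}


def config_hash(config) -> str:
    """Short stable hash of a (JSON-serializable) configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing input file {path}")
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[name] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    return df


def split_members(joined: str) -> list[str]:
    return [m for m in str(joined).split(";") if m]


def join_members(ids) -> str:
    return ";".join(ids)


def validate_follows(follows: pd.DataFrame, roster: Roster) -> None:
    """Check segment invariants: ordering, non-overlap, focal membership."""
    if follows.empty:
        return
    for (focal, date), grp in follows.groupby(["focal_id", "date"], sort=False):
        if focal not in roster:
            raise DataError(f"follows.csv: unknown focal_id {focal!r} on {date}")
        prev_end = None
        for row in grp.sort_values("start_min").itertuples(index=False):
            s, e = int(row.start_min), int(row.end_min)
            if e <= s:
                raise DataError(f"follows.csv: empty/negative segment for {focal} on {date}")
            if prev_end is not None and s < prev_end:
                raise DataError(f"follows.csv: overlapping intervals for {focal} on {date}")
            prev_end = e
            members = split_members(row.member_ids)
            if focal not in members:
                raise DataError(f"follows.csv: focal {focal} missing from its party on {date}")


def validate_point_samples(samples: pd.DataFrame, roster: Roster) -> None:
    if samples.empty:
        return
    bad_beh = ~samples["behavior"].isin(BEHAVIORS)
    if bad_beh.any():
        i = samples.index[bad_beh][0]
        raise DataError(
            f"point_samples.csv row {i}: behavior {samples.loc[i, 'behavior']!r} "
            f"not one of {BEHAVIORS}"
        )
    social = samples["behavior"].isin(("GROOM", "PLAY"))
    for i, row in samples.loc[social].iterrows():
        partner = str(row["partner_id"]).strip()
        if not partner:
            raise DataError(
                f"point_samples.csv row {i}: {row['behavior']} sample for "
                f"{row['infant_id']} on {row['date']} has no partner_id"
            )
        if partner not in split_members(row["member_ids"]):
            raise DataError(
                f"point_samples.csv row {i}: partner {partner!r} not in the recorded party"
            )


def _to_int(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        df[c] = df[c].astype(int)
    return df


def read_tables(data_dir, validate: bool = True) -> FollowBundle:
    """Load and validate a data directory of the six input CSVs.

    ``dominance.csv`` and ``conceptions.csv`` are optional (empty tables
    are substituted).  Raises :class:`DataError` naming the file and the
    offending row on any invariant violation.
    """
    data_dir = Path(data_dir)
    roster = Roster.from_frame(_read_csv(data_dir / FILES["roster"], "roster"))
    pedigree = Pedigree.from_frame(
        _read_csv(data_dir / FILES["pedigree"], "pedigree"), roster=roster
    )

    follows = _read_csv(data_dir / FILES["follows"], "follows")
    follows = _to_int(follows, ["start_min", "end_min"])

    samples = _read_csv(data_dir / FILES["point_samples"], "point_samples")
    samples = _to_int(samples, ["minute"])

    dom_path = data_dir / FILES["dominance"]
    dominance = (
        _read_csv(dom_path, "dominance")
        if dom_path.exists()
        else pd.DataFrame(columns=_COLUMNS["dominance"])
    )
    con_path = data_dir / FILES["conceptions"]
    conceptions = (
        _read_csv(con_path, "conceptions")
        if con_path.exists()
        else pd.DataFrame(columns=_COLUMNS["conceptions"])
    )

    if validate:
        validate_follows(follows, roster)
        validate_point_samples(samples, roster)
        for row in dominance.itertuples(index=False):
            for who in (row.winner_id, row.loser_id):
                if who not in roster:
                    raise DataError(f"dominance.csv: unknown id {who!r} on {row.date}")

    return FollowBundle(
        roster=roster,
        pedigree=pedigree,
        follows=follows,
        point_samples=samples,
        dominance=dominance,
        conceptions=conceptions,
    )


def write_frame(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    """Write a tidy CSV with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# kinbias={__version__} config_hash={config_hash(config or {})}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_tables(bundle: FollowBundle, data_dir, config: Optional[dict] = None) -> None:
    """Write a bundle back to the six-CSV directory layout."""
    data_dir = Path(data_dir)
    write_frame(bundle.roster.to_frame(), data_dir / FILES["roster"], config)
    write_frame(bundle.pedigree.to_frame(), data_dir / FILES["pedigree"], config)
    write_frame(bundle.follows, data_dir / FILES["follows"], config)
    write_frame(bundle.point_samples, data_dir / FILES["point_samples"], config)
    write_frame(bundle.dominance, data_dir / FILES["dominance"], config)
    write_frame(bundle.conceptions, data_dir / FILES["conceptions"], config)
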