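"""Social triangulation: user geolocation from followed community assets.

A user's region is inferred from the geocoded community organizations
(media, government, emergency services, ...) they follow: a declared
profile location wins outright; otherwise the majority region among the
user's resolvable followed communities is assigned, with confidence equal
to the majority share. Users are typed by how many organizations they
follow (embeddedness), and local/external follow ties are summarised by
the standard E-I homophily index (E - I)/(E + I).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .stream import COMMUNITY_CATEGORIES

__all__ = [
    "Community",
    "Gazetteer",
    "UserProfile",
    "EIScore",
    "LocationUnknownError",
    "UndefinedScoreError",
    "categorize_user",
    "infer_location",
    "ei_index",
    "evaluate_st",
    "geolocate_users",
]


class LocationUnknownError(ValueError):
    """No declared region and no resolvable followed community."""


class UndefinedScoreError(ValueError):
    """E-I index requested for a user with zero resolved community ties."""


@dataclass(frozen=True)
class Community:
    """A geocoded community asset (local organization account)."""

    name: str
    category: str
    lat: float
    lon: float
    region: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")


@dataclass
class UserProfile:
    user_id: str
    followed_communities: List[str]
    declared_region: Optional[str] = None


@dataclass(frozen=True)
class EIScore:
    """E-I homophily score over a user's community-follow ties.

    ``E`` counts followed communities outside the assigned region, ``I``
    inside; value = (E - I)/(E + I), so -1 is fully local and +1 fully
    external.
    """

    E: int
    I: int

    @property
    def value(self) -> float:
        if self.E + self.I == 0:
            raise UndefinedScoreError("E + I = 0: score undefined")
        return (self.E - self.I) / (self.E + self.I)


class Gazetteer:
    """Offline community-name -> location lookup (case-folded exact match).

    Replaces online geocoding with a reproducible table; unresolved names
    are collected in :attr:`unresolved` rather than raising.
    """

    def __init__(self, communities: Iterable[Community]):
        self._by_name: Dict[str, Community] = {}
        for c in communities:
            self._by_name[c.name.casefold()] = c
        self.unresolved: List[str] = []

    @classmethod
    def from_tsv(cls, path) -> "Gazetteer":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Gazetteer":
        return cls(
            Community(str(r.name), str(r.category), float(r.lat),
                      float(r.lon), str(r.region))
            for r in df.itertuples(index=False)
        )

    def resolve(self, name: str) -> Optional[Community]:
        c = self._by_name.get(name.casefold())
        if c is None:
            self.unresolved.append(name)
        return c

    def resolve_all(self, names: Sequence[str]) -> List[Community]:
        out = []
        for n in names:
            c = self.resolve(n)
            if c is not None:
                out.append(c)
        return out


def categorize_user(n_orgs: int) -> str:
    """Type a user by the number of local organizations followed.

    1 -> Unique (the single organization is the unique recipient of local
    information), 2 -> Low, 3-9 -> Moderate, 10-49 -> High, >=50 -> Extreme.
    """
    if n_orgs < 1:
        raise ValueError("untypeable: user follows no organizations")
    if n_orgs == 1:
        return "Unique"
    if n_orgs == 2:
        return "Low"
    if n_orgs <= 9:
        return "Moderate"
    if n_orgs <= 49:
        return "High"
    return "Extreme"


_CATEGORY_RANK = {c: i for i, c in enumerate(COMMUNITY_CATEGORIES)}


def infer_location(user: UserProfile, gazetteer: Gazetteer
                   ) -> Tuple[str, float]:
    """Assign a region to a user; returns ``(region, confidence)``.

    A declared region is returned with confidence 1. Otherwise the
    majority region among the user's resolved followed communities is
    assigned, with confidence equal to the majority share (Unique users
    inherit their single community's region at confidence 1). Region ties
    are broken by the most specific community-asset category present in
    the tied regions, then lexicographically.
    """
    if user.declared_region is not None:
        return user.declared_region, 1.0
    resolved = gazetteer.resolve_all(user.followed_communities)
    if not resolved:
        raise LocationUnknownError(
            f"user {user.user_id}: no declared region and no resolvable "
            "followed communities"
        )
    votes: Dict[str, int] = {}
    best_rank: Dict[str, int] = {}
    for c in resolved:
        votes[c.region] = votes.get(c.region, 0) + 1
        rank = _CATEGORY_RANK.get(c.category, len(_CATEGORY_RANK))
        best_rank[c.region] = min(best_rank.get(c.region, rank), rank)
    top = max(votes.values())
    tied = sorted(
        (r for r, v in votes.items() if v == top),
        key=lambda r: (best_rank[r], r),
    )
    region = tied[0]
    return region, votes[region] / len(resolved)


def ei_index(user: UserProfile, assigned_region: str,
             gazetteer: Gazetteer) -> EIScore:
    """E-I index of a user's follow ties relative to an assigned region."""
    resolved = gazetteer.resolve_all(user.followed_communities)
    if not resolved:
        raise UndefinedScoreError(
            f"user {user.user_id}: zero resolved communities"
        )
    internal = sum(1 for c in resolved if c.region == assigned_region)
    return EIScore(E=len(resolved) - internal, I=internal)


def _profiles(users: pd.DataFrame, with_declared: bool) -> List[UserProfile]:
    out = []
    for r in users.itertuples(index=False):
        declared = getattr(r, "declared_region", None)
        if isinstance(declared, float):  # NaN from tabular round-trips
            declared = None
        out.append(UserProfile(
            user_id=r.user_id,
            followed_communities=list(r.followed_communities),
            declared_region=declared if with_declared else None,
        ))
    return out


def evaluate_st(users: pd.DataFrame, gazetteer: Gazetteer) -> float:
    """Accuracy of social triangulation against declared locations.

    For every user with both a declared region and at least one resolvable
    community, the declared region is hidden, the location is inferred
    from follow ties alone, and the match rate is returned.
    """
    profiles = [
        p for p in _profiles(users, with_declared=True)
        if p.declared_region is not None and p.followed_communities
    ]
    if not profiles:
        raise ValueError("no users with declared region and followed communities")
    correct = total = 0
    for p in profiles:
        declared = p.declared_region
        p.declared_region = None
        try:
            region, _ = infer_location(p, gazetteer)
        except LocationUnknownError:
            continue
        total += 1
        correct += int(region == declared)
    if total == 0:
        raise ValueError("no user resolvable against the gazetteer")
    return correct / total


def geolocate_users(users: pd.DataFrame, gazetteer: Gazetteer
                    ) -> pd.DataFrame:
    """Full geolocation table: inferred region, confidence, user type and
    E-I value per user (the `geolocate` CLI output)."""
    rows = []
    for p in _profiles(users, with_declared=True):
        try:
            region, conf = infer_location(p, gazetteer)
        except LocationUnknownError:
            continue
        n = len(gazetteer.resolve_all(p.followed_communities))
        row = {
            "user_id": p.user_id,
            "inferred_region": region,
            "confidence": conf,
            "user_type": categorize_user(n) if n >= 1 else None,
        }
        try:
            row["ei_value"] = ei_index(p, region, gazetteer).value
        except UndefinedScoreError:
            row["ei_value"] = None
        rows.append(row)
    return pd.DataFrame(rows)
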