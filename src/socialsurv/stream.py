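"""Seeded synthetic OSN message streams with injectable events.

Emulates a multi-region, multi-topic social-media message stream: users
follow geocoded community accounts (mostly in their home region), post a
Poisson number of messages per day drawn from topic/subtopic vocabularies,
and carry an emotion-marker token sampled from a per-topic emotion mixture.
Events are injected as count bursts with an emergent subtopic and a shifted
emotion mixture, giving every downstream stage a ground-truthed input.

Randomness is organised as a single global seed feeding per-purpose and
per-user/per-day substreams (``numpy.random.SeedSequence`` spawn keys), so
regenerating any user-day slice is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TOPICS",
    "EMOTIONS",
    "EventInjection",
    "StreamSpec",
    "InvalidSpecError",
    "default_vocabulary",
    "default_emotion_mixture",
    "generate_users",
    "generate_stream",
    "write_messages_jsonl",
    "read_messages_jsonl",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_gazetteer_tsv",
]

#: The ten coarse message topics monitored by the system.
DEFAULT_TOPICS = [
    "family", "love", "religion", "study", "work",
    "friendship", "politics", "nature", "entertainment", "health",
]

#: Ekman's six basic emotions, the affect analyzer's label set.
EMOTIONS = ["anger", "disgust", "fear", "joy", "sadness", "surprise"]

#: Community-asset categories, ordered most- to least-specific for
#: deterministic tie-breaking in geolocation majority votes.
COMMUNITY_CATEGORIES = [
    "emergency", "government", "health", "media", "education",
    "business", "religious", "sports", "culture", "nonprofit",
]

#: Five marker tokens per emotion; one is appended to every message.
EMOTION_MARKERS: Dict[str, List[str]] = {
    e: [f"{e}mark{j}" for j in range(5)] for e in EMOTIONS
}

#: User types by number of followed organizations, with the share of users
#: in each type (90% follow a single local organization).
FOLLOW_TYPES = ["Unique", "Low", "Moderate", "High", "Extreme"]
# printed shares (90%, 9.2%, 0.3%, 0.1%, 0.3%) sum to 99.9% after rounding;
# normalized here so the vector is a proper distribution
_PRINTED_FOLLOW_SHARES = (0.90, 0.092, 0.003, 0.001, 0.003)
DEFAULT_FOLLOW_DISTRIBUTION = tuple(
    p / sum(_PRINTED_FOLLOW_SHARES) for p in _PRINTED_FOLLOW_SHARES
)
_FOLLOW_COUNT_RANGES = {
    "Unique": (1, 1),
    "Low": (2, 2),
    "Moderate": (3, 9),
    "High": (10, 49),
    "Extreme": (50, 80),
}

_EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)

_NAMED_SUBTOPICS = {
    "health": ["flu", "vaccine", "hospital"],
    "politics": ["election", "protest", "policy"],
    "entertainment": ["music", "sport", "cinema"],
}


class InvalidSpecError(ValueError):
    """The stream specification violates an invariant."""


def default_vocabulary(
    topics: Sequence[str] = tuple(DEFAULT_TOPICS),
    tokens_per_topic: int = 25,
    subtopics_per_topic: int = 3,
    tokens_per_subtopic: int = 12,
    shared_tokens: int = 40,
) -> "Vocabulary":
    """Pseudo-language vocabulary: exclusive topic and subtopic token sets
    plus a shared pool, so class separability is controlled, not assumed."""
    topic_tokens = {
        t: [f"{t}w{j:02d}" for j in range(tokens_per_topic)] for t in topics
    }
    subtopic_tokens: Dict[str, Dict[str, List[str]]] = {}
    for t in topics:
        names = _NAMED_SUBTOPICS.get(
            t, [f"{t}sub{k}" for k in range(subtopics_per_topic)]
        )[:subtopics_per_topic]
        subtopic_tokens[t] = {
            s: [f"{s}tok{j:02d}" for j in range(tokens_per_subtopic)]
            for s in names
        }
    shared = [f"common{j:02d}" for j in range(shared_tokens)]
    return Vocabulary(topic_tokens, subtopic_tokens, shared)


@dataclass
class Vocabulary:
    """Token inventories: per-topic, per-subtopic (nested by topic), shared."""

    topic_tokens: Dict[str, List[str]]
    subtopic_tokens: Dict[str, Dict[str, List[str]]]
    shared_tokens: List[str] = field(default_factory=list)

    def subtopics_of(self, topic: str) -> List[str]:
        return list(self.subtopic_tokens.get(topic, {}))

    def all_words(self) -> List[str]:
        words: List[str] = []
        for toks in self.topic_tokens.values():
            words.extend(toks)
        for subs in self.subtopic_tokens.values():
            for toks in subs.values():
                words.extend(toks)
        words.extend(self.shared_tokens)
        return words


def default_emotion_mixture(
    topics: Sequence[str] = tuple(DEFAULT_TOPICS),
) -> Dict[str, Dict[str, float]]:
    """Per-topic emotion mixtures. Joy-leaning baseline; health skews
    toward fear/sadness, politics toward anger, mirroring the qualitative
    shape of observed pre-event emotion profiles."""
    base = {"anger": 0.12, "disgust": 0.08, "fear": 0.12,
            "joy": 0.38, "sadness": 0.15, "surprise": 0.15}
    mixtures = {}
    for t in topics:
        m = dict(base)
        if t == "health":
            m = {"anger": 0.10, "disgust": 0.08, "fear": 0.25,
                 "joy": 0.22, "sadness": 0.22, "surprise": 0.13}
        elif t == "politics":
            m = {"anger": 0.30, "disgust": 0.15, "fear": 0.12,
                 "joy": 0.18, "sadness": 0.13, "surprise": 0.12}
        mixtures[t] = m
    return mixtures


@dataclass
class EventInjection:
    """Ground-truth event: a count burst in one (region, topic) with an
    emergent subtopic and optionally shifted emotion mixture."""

    region: str
    topic: str
    subtopic: str
    start_day: int
    duration_days: int
    rate_multiplier: float
    emotion_shift: Optional[Dict[str, float]] = None
    #: probability an in-event message of the topic uses the event subtopic
    p_event_subtopic: float = 0.8

    def active(self, region: str, day: int) -> bool:
        return (region == self.region
                and self.start_day <= day < self.start_day + self.duration_days)


@dataclass
class StreamSpec:
    """Full description of a synthetic stream's statistical conditions."""

    regions: List[str]
    users_per_region: int = 100
    topics: List[str] = field(default_factory=lambda: list(DEFAULT_TOPICS))
    vocab: Optional[Vocabulary] = None
    base_rate: float = 2.0
    n_days: int = 30
    follow_distribution: Tuple[float, ...] = DEFAULT_FOLLOW_DISTRIBUTION
    p_home_community: float = 0.92
    p_declared_location: float = 0.18
    topic_shares: Optional[Dict[str, float]] = None
    emotion_mixture: Optional[Dict[str, Dict[str, float]]] = None
    events: List[EventInjection] = field(default_factory=list)
    communities_per_region: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab is None:
            self.vocab = default_vocabulary(self.topics)
        if self.topic_shares is None:
            self.topic_shares = {t: 1.0 / len(self.topics) for t in self.topics}
        if self.emotion_mixture is None:
            self.emotion_mixture = default_emotion_mixture(self.topics)

    def validate(self) -> None:
        if not self.regions:
            raise InvalidSpecError("at least one region is required")
        if self.users_per_region <= 0:
            raise InvalidSpecError("users_per_region must be positive")
        if self.base_rate <= 0:
            raise InvalidSpecError("base_rate must be > 0")
        if self.n_days < 1:
            raise InvalidSpecError("n_days must be >= 1")
        if len(self.follow_distribution) != 5:
            raise InvalidSpecError("follow_distribution needs exactly 5 entries")
        for name, vec in [
            ("follow_distribution", list(self.follow_distribution)),
            ("topic_shares", list(self.topic_shares.values())),
        ]:
            if abs(sum(vec) - 1.0) > 1e-9:
                raise InvalidSpecError(f"{name} must sum to 1")
        for t, mix in self.emotion_mixture.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise InvalidSpecError(f"emotion mixture for {t} must sum to 1")
        for ev in self.events:
            if ev.rate_multiplier <= 0:
                raise InvalidSpecError("rate_multiplier must be > 0")
            if ev.start_day + ev.duration_days > self.n_days:
                raise InvalidSpecError("event extends past n_days")
            if ev.topic not in self.topics:
                raise InvalidSpecError(f"event topic {ev.topic!r} not in topics")
        for t in self.topics:
            if t not in self.vocab.topic_tokens:
                raise InvalidSpecError(f"no vocabulary for topic {t!r}")


def _rng(spec: StreamSpec, *key: int) -> np.random.Generator:
    """Substream generator keyed under the global seed (counter-based)."""
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


# spawn-key namespaces for the substreams
_NS_COMMUNITIES, _NS_USERS, _NS_MESSAGES = 1, 2, 3


def _region_center(region: str) -> Tuple[float, float]:
    # stable across processes (str hash is salted); display coords only
    h = int.from_bytes(region.encode("utf-8"), "little") % (120 * 300)
    return (h % 120) - 60.0, (h // 120 % 300) - 150.0


def generate_communities(spec: StreamSpec) -> pd.DataFrame:
    """Gazetteer of community assets: per region, a fixed roster of local
    organization accounts cycling through the asset categories."""
    rng = _rng(spec, _NS_COMMUNITIES)
    rows = []
    for region in spec.regions:
        lat0, lon0 = _region_center(region)
        for i in range(spec.communities_per_region):
            cat = COMMUNITY_CATEGORIES[i % len(COMMUNITY_CATEGORIES)]
            rows.append({
                "name": f"{region} {cat} {i:02d}",
                "category": cat,
                "lat": round(lat0 + rng.uniform(-0.5, 0.5), 6),
                "lon": round(lon0 + rng.uniform(-0.5, 0.5), 6),
                "region": region,
            })
    return pd.DataFrame(rows)


def generate_users(spec: StreamSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the user population and its community-follow edges.

    Each user gets a home region, a declared-location flag (18% by
    default), a follow count drawn from the five-type distribution (90%
    follow exactly one organization), and followed communities placed in
    the home region with probability ``p_home_community`` (0.92 default),
    else a uniformly random other region.

    Returns ``(users, communities)`` data frames; deterministic given
    ``spec.seed``.
    """
    spec.validate()
    communities = generate_communities(spec)
    by_region = {
        r: communities.loc[communities.region == r, "name"].to_numpy()
        for r in spec.regions
    }
    rng = _rng(spec, _NS_USERS)
    probs = np.asarray(spec.follow_distribution, dtype=float)
    rows = []
    uid = 0
    for region in spec.regions:
        others = [r for r in spec.regions if r != region]
        for _ in range(spec.users_per_region):
            ftype = FOLLOW_TYPES[rng.choice(5, p=probs)]
            lo, hi = _FOLLOW_COUNT_RANGES[ftype]
            n_follow = int(rng.integers(lo, hi + 1))
            followed = []
            for _ in range(n_follow):
                if len(others) == 0 or rng.random() < spec.p_home_community:
                    pool = by_region[region]
                else:
                    pool = by_region[others[rng.integers(len(others))]]
                followed.append(str(pool[rng.integers(len(pool))]))
            declared = bool(rng.random() < spec.p_declared_location)
            rows.append({
                "user_id": f"u{uid:05d}",
                "home_region": region,
                "declared_region": region if declared else None,
                "user_type": ftype,
                "n_followed": n_follow,
                "followed_communities": followed,
            })
            uid += 1
    return pd.DataFrame(rows), communities


def _active_multiplier(spec: StreamSpec, region: str, topic: str,
                       day: int) -> float:
    m = 1.0
    for ev in spec.events:
        if ev.topic == topic and ev.active(region, day):
            m *= ev.rate_multiplier
    return m


def _event_for(spec: StreamSpec, region: str, topic: str,
               day: int) -> Optional[EventInjection]:
    for ev in spec.events:
        if ev.topic == topic and ev.active(region, day):
            return ev
    return None


def generate_stream(
    spec: StreamSpec, users: pd.DataFrame
) -> Tuple[List[dict], pd.DataFrame]:
    """Generate the message stream for a user table drawn from ``spec``.

    Per user per day, the per-topic message count is
    Poisson(base_rate x topic share x active event multipliers). Each
    message's text is a bag of 5-15 tokens from its subtopic/topic/shared
    vocabularies plus one emotion-marker token; 0-2 hashtags are formed by
    concatenating vocabulary words. Ground-truth topic/subtopic/emotion
    labels are returned in a sidecar table keyed by message id.
    """
    spec.validate()
    vocab = spec.vocab
    emotions = EMOTIONS
    messages: List[dict] = []
    truth_rows: List[tuple] = []
    topics = spec.topics
    shares = np.array([spec.topic_shares[t] for t in topics])

    for uidx, user in enumerate(users.itertuples(index=False)):
        region = user.home_region
        followed = list(user.followed_communities)
        for day in range(spec.n_days):
            rng = _rng(spec, _NS_MESSAGES, uidx, day)
            mult = np.array(
                [_active_multiplier(spec, region, t, day) for t in topics]
            )
            counts = rng.poisson(spec.base_rate * shares * mult)
            k = 0
            for t_idx, topic in enumerate(topics):
                subs = vocab.subtopics_of(topic)
                for _ in range(int(counts[t_idx])):
                    ev = _event_for(spec, region, topic, day)
                    if ev is not None and rng.random() < ev.p_event_subtopic \
                            and ev.subtopic in subs:
                        subtopic = ev.subtopic
                    else:
                        subtopic = subs[rng.integers(len(subs))] if subs else ""
                    mix = spec.emotion_mixture[topic]
                    if ev is not None and ev.emotion_shift is not None:
                        mix = ev.emotion_shift
                    pvec = np.array([mix.get(e, 0.0) for e in emotions])
                    emotion = emotions[rng.choice(len(emotions),
                                                  p=pvec / pvec.sum())]
                    tokens = _sample_tokens(rng, vocab, topic, subtopic)
                    tokens.append(
                        EMOTION_MARKERS[emotion][rng.integers(5)])
                    hashtags = _sample_hashtags(rng, vocab, topic, subtopic)
                    ts = _EPOCH + timedelta(days=day,
                                            seconds=int(rng.integers(86400)))
                    mid = f"m{uidx:05d}d{day:03d}k{k:03d}"
                    k += 1
                    messages.append({
                        "id": mid,
                        "text": " ".join(tokens),
                        "username": user.user_id,
                        "created_at": ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
                        "hashtags": hashtags,
                        "geo": None,
                        "mentions": [],
                        "favorites": int(rng.poisson(1.5)),
                        "communities": followed,
                        "iso_language_code": "en",
                        "town": region,
                    })
                    truth_rows.append((mid, topic, subtopic, emotion))
    truth = pd.DataFrame(
        truth_rows, columns=["message_id", "topic", "subtopic", "emotion"]
    )
    return messages, truth


def _sample_tokens(rng: np.random.Generator, vocab: Vocabulary,
                   topic: str, subtopic: str) -> List[str]:
    n = int(rng.integers(5, 16))
    sub_toks = vocab.subtopic_tokens.get(topic, {}).get(subtopic, [])
    top_toks = vocab.topic_tokens[topic]
    shared = vocab.shared_tokens
    out = []
    for _ in range(n):
        u = rng.random()
        if sub_toks and u < 0.55:
            pool = sub_toks
        elif u < 0.80 or not shared:
            pool = top_toks
        else:
            pool = shared
        out.append(pool[rng.integers(len(pool))])
    return out


def _sample_hashtags(rng: np.random.Generator, vocab: Vocabulary,
                     topic: str, subtopic: str) -> List[str]:
    n = int(rng.integers(0, 3))
    pool = vocab.topic_tokens[topic] + \
        vocab.subtopic_tokens.get(topic, {}).get(subtopic, [])
    tags = []
    for _ in range(n):
        k = int(rng.integers(1, 3))
        words = [pool[rng.integers(len(pool))] for _ in range(k)]
        tags.append("#" + "".join(words))
    return tags


# ---------------------------------------------------------------------------
# serialization

def write_messages_jsonl(messages: List[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in messages:
            fh.write(json.dumps(m, ensure_ascii=False) + "\n")


def read_messages_jsonl(path) -> List[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_gazetteer_tsv(communities: pd.DataFrame, path) -> None:
    communities[["name", "category", "lat", "lon", "region"]].to_csv(
        path, sep="\t", index=False
    )
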