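"""Message text preprocessing chain.

Fixed stage order: noise removal (spam / ads / bot-rate) on whole
messages, then per-message token normalization (case folding, synonym
unification, conservative spelling correction), hashtag segmentation,
stopword removal and table-driven lemmatization. All lexicons are plain
UTF-8 text files, one entry per line (``word`` or ``word<TAB>canonical``),
so the chain is language-pluggable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

__all__ = [
    "Lexicons",
    "NoiseRules",
    "CleanMessage",
    "filter_noise",
    "segment_hashtag",
    "normalize",
    "lemmatize",
    "preprocess_messages",
]

_URL_RE = re.compile(r"^(https?://|www\.)\S+$", re.IGNORECASE)
_TOKEN_RE = re.compile(r"\S+")


@dataclass
class Lexicons:
    """Lexical resources for normalization; all optional, empty = no-op."""

    stopwords: Set[str] = field(default_factory=set)
    synonyms: Dict[str, str] = field(default_factory=dict)
    lemmas: Dict[str, str] = field(default_factory=dict)
    segment_vocab: Set[str] = field(default_factory=set)
    spell_lexicon: Set[str] = field(default_factory=set)

    @classmethod
    def from_dir(cls, directory) -> "Lexicons":
        d = Path(directory)
        return cls(
            stopwords=_read_words(d / "stopwords.txt"),
            synonyms=_read_map(d / "synonyms.tsv"),
            lemmas=_read_map(d / "lemmas.tsv"),
            segment_vocab=_read_words(d / "segment_vocab.txt"),
            spell_lexicon=_read_words(d / "spell_lexicon.txt"),
        )

    @classmethod
    def bundled(cls) -> "Lexicons":
        """The small illustrative English lexicons shipped with the package."""
        root = resources.files("socialsurv").joinpath("data")
        lex = cls(
            stopwords=_read_lines(root / "stopwords.txt"),
            synonyms=_read_map_lines(root / "synonyms.tsv"),
            lemmas=_read_map_lines(root / "lemmas.tsv"),
            segment_vocab=_read_lines(root / "segment_vocab.txt"),
        )
        lex.spell_lexicon = (
            set(lex.segment_vocab)
            | set(lex.lemmas)
            | set(lex.lemmas.values())
            | set(lex.synonyms.values())
        )
        return lex


def _read_lines(res) -> Set[str]:
    return {
        ln.strip().casefold()
        for ln in res.read_text(encoding="utf-8").splitlines()
        if ln.strip()
    }


def _read_map_lines(res) -> Dict[str, str]:
    out = {}
    for ln in res.read_text(encoding="utf-8").splitlines():
        if ln.strip():
            k, _, v = ln.partition("\t")
            out[k.strip().casefold()] = v.strip().casefold()
    return out


def _read_words(path: Path) -> Set[str]:
    return _read_lines(path) if path.exists() else set()


def _read_map(path: Path) -> Dict[str, str]:
    return _read_map_lines(path) if path.exists() else {}


@dataclass
class NoiseRules:
    """Spam/ad/bot filters. A duplicate run is spam once the same user
    posts the same text more than ``duplicate_threshold`` times within
    ``duplicate_window_hours``; only the first copy is kept."""

    duplicate_threshold: int = 3
    duplicate_window_hours: float = 1.0
    max_url_density: float = 0.5
    max_daily_rate: int = 100


@dataclass
class CleanMessage:
    message_id: str
    tokens: List[str]
    dropped: bool = False
    drop_reason: Optional[str] = None


def filter_noise(messages: Sequence[dict], rules: NoiseRules
                 ) -> Tuple[List[dict], pd.DataFrame]:
    """Partition messages into kept and removed, with an audit log.

    Rules: ``spam-duplicate`` (near-simultaneous identical reposts),
    ``ad-url-density`` (mostly-URL text), ``bot-daily-rate`` (per-user
    daily flood). Every removal is logged with its rule id;
    kept + removed partition the input.
    """
    removed: Dict[str, str] = {}

    # ad rule: URL-dominated text
    for m in messages:
        toks = _TOKEN_RE.findall(m["text"])
        if toks:
            density = sum(1 for t in toks if _URL_RE.match(t)) / len(toks)
            if density > rules.max_url_density:
                removed[m["id"]] = "ad-url-density"

    # spam rule: identical text repeated by one user within the window
    window = pd.Timedelta(hours=rules.duplicate_window_hours)
    by_key: Dict[tuple, List[dict]] = {}
    for m in messages:
        if m["id"] in removed:
            continue
        by_key.setdefault((m["username"], m["text"]), []).append(m)
    for group in by_key.values():
        if len(group) <= rules.duplicate_threshold:
            continue
        group.sort(key=lambda m: m["created_at"])
        times = pd.to_datetime([g["created_at"] for g in group])
        if times[-1] - times[0] <= window:
            for m in group[1:]:
                removed[m["id"]] = "spam-duplicate"

    # bot rule: per-user daily flood; keep the earliest max_daily_rate
    by_user_day: Dict[tuple, List[dict]] = {}
    for m in messages:
        if m["id"] in removed:
            continue
        day = str(m["created_at"])[:10]
        by_user_day.setdefault((m["username"], day), []).append(m)
    for group in by_user_day.values():
        if len(group) > rules.max_daily_rate:
            group.sort(key=lambda m: m["created_at"])
            for m in group[rules.max_daily_rate:]:
                removed[m["id"]] = "bot-daily-rate"

    kept = [m for m in messages if m["id"] not in removed]
    audit = pd.DataFrame(
        [{"message_id": mid, "rule": rule} for mid, rule in removed.items()],
        columns=["message_id", "rule"],
    )
    return kept, audit


def segment_hashtag(tag: str, vocabulary: Iterable[str]) -> List[str]:
    """Greedy longest-match segmentation of a hashtag into known words.

    ``#prayformyMother`` with {pray, for, my, mother} in the vocabulary
    segments to ``["pray", "for", "my", "mother"]``. Any unsegmentable
    remainder is kept as a single lowercased token.
    """
    if not tag.startswith("#"):
        raise ValueError(f"not a hashtag: {tag!r}")
    body = tag[1:].casefold()
    if not body:
        return []
    vocab = set(vocabulary)
    max_len = max((len(w) for w in vocab), default=0)
    out: List[str] = []
    i = 0
    while i < len(body):
        match = None
        for j in range(min(len(body), i + max_len), i, -1):
            if body[i:j] in vocab:
                match = body[i:j]
                break
        if match is None:
            out.append(body[i:])
            break
        out.append(match)
        i += len(match)
    return out


def _edit1_unique(word: str, lexicon: Set[str]) -> Optional[str]:
    """The unique lexicon word at Levenshtein distance 1, else None."""
    hits = [w for w in lexicon
            if abs(len(w) - len(word)) <= 1 and _dist_le1(word, w)]
    return hits[0] if len(hits) == 1 else None


def _dist_le1(a: str, b: str) -> bool:
    if a == b:
        return False
    la, lb = len(a), len(b)
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: deleting one char of b must give a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def normalize(tokens: Sequence[str], synonym_map: Dict[str, str],
              spell_lexicon: Set[str], stopwords: Set[str]) -> List[str]:
    """Case-fold, unify synonyms, correct unambiguous misspellings, and
    drop stopwords, preserving the order of surviving tokens.

    Spelling correction is deliberately conservative: an out-of-lexicon
    token is replaced only when exactly one lexicon word sits at edit
    distance 1, otherwise it passes through unchanged.
    """
    out = []
    for tok in tokens:
        t = tok.casefold()
        t = synonym_map.get(t, t)
        if spell_lexicon and t not in spell_lexicon and t.isalpha():
            fix = _edit1_unique(t, spell_lexicon)
            if fix is not None:
                t = fix
        if t and t not in stopwords:
            out.append(t)
    return out


def lemmatize(tokens: Sequence[str], lemma_table: Dict[str, str]
              ) -> List[str]:
    """Table-driven lemmatization; unknown words pass through."""
    return [lemma_table.get(t, t) for t in tokens]


def preprocess_messages(messages: Sequence[dict],
                        lexicons: Optional[Lexicons] = None,
                        rules: Optional[NoiseRules] = None
                        ) -> Tuple[List[CleanMessage], pd.DataFrame]:
    """Run the full chain over raw messages.

    Returns one :class:`CleanMessage` per input (dropped ones flagged with
    their single removal reason) and the noise-audit table.
    """
    lex = lexicons if lexicons is not None else Lexicons.bundled()
    rules = rules if rules is not None else NoiseRules()
    kept, audit = filter_noise(messages, rules)
    reasons = dict(zip(audit["message_id"], audit["rule"])) if len(audit) else {}
    kept_ids = {m["id"] for m in kept}
    clean: List[CleanMessage] = []
    for m in messages:
        if m["id"] not in kept_ids:
            clean.append(CleanMessage(m["id"], [], dropped=True,
                                      drop_reason=reasons[m["id"]]))
            continue
        tokens = _TOKEN_RE.findall(m["text"])
        tokens = [t for t in tokens if not _URL_RE.match(t)]
        hashtag_words: List[str] = []
        for tag in list(m.get("hashtags", [])) + [t for t in tokens
                                                  if t.startswith("#")]:
            hashtag_words.extend(segment_hashtag(tag, lex.segment_vocab))
        tokens = [t for t in tokens if not t.startswith("#")] + hashtag_words
        tokens = normalize(tokens, lex.synonyms, lex.spell_lexicon,
                           lex.stopwords)
        tokens = lemmatize(tokens, lex.lemmas)
        clean.append(CleanMessage(m["id"], tokens))
    return clean, audit
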