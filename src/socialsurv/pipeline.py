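"""Pipeline orchestration: config, stage ordering, logging, artifacts.

Stage order is fixed: geolocation -> preprocessing -> topic
classification -> subtopic modelling -> change detection -> affective
analysis. The pipeline either simulates its input stream (synthetic
mode) or consumes an external JSONL stream plus gazetteer. Every stage
appends a structured JSON-lines log record (stage, seed, input hash);
the event report itself contains no wall-clock timestamps so re-running
with the same config reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .affect import TreeCNNEmotionClassifier
from .changes import (DetectorConfig, aggregate_daily, attribute_event,
                      detect_events, emotion_window)
from .geolocate import Gazetteer, geolocate_users
from .preprocess import Lexicons, NoiseRules, preprocess_messages
from .stream import (EventInjection, StreamSpec, generate_stream,
                     generate_users, read_messages_jsonl,
                     write_gazetteer_tsv, write_messages_jsonl,
                     write_truth_tsv)
from .subtopics import SubtopicModel
from .topics import TopicClassifier

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "schema_version", "seed", "out_dir", "regions", "users_per_region",
    "n_days", "base_rate", "topics", "events", "messages_path",
    "gazetteer_path",
    "truth_path", "detector", "topic_model", "subtopic_model",
    "affect_model", "noise_rules", "min_topic_train",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One structured document holding every module's tunables."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # synthetic mode
    regions: List[str] = field(default_factory=lambda: ["Sao Paulo", "Lima"])
    users_per_region: int = 60
    n_days: int = 30
    base_rate: float = 2.0
    topics: Optional[List[str]] = None  # None = the default ten
    events: List[dict] = field(default_factory=list)
    # external-input mode
    messages_path: Optional[str] = None
    gazetteer_path: Optional[str] = None
    truth_path: Optional[str] = None
    # stage tunables
    detector: dict = field(default_factory=dict)
    topic_model: dict = field(default_factory=dict)
    subtopic_model: dict = field(default_factory=dict)
    affect_model: dict = field(default_factory=dict)
    noise_rules: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValueError("unsupported config schema version")
        return cls(**raw)


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        path.write_text("")

    def log(self, stage: str, **extra) -> None:
        rec = {"stage": stage, "time": time.time(), **extra}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> Dict[str, str]:
    """Execute all stages; returns a map of artifact names to paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Logger(out / "log.jsonl")
    artifacts: Dict[str, str] = {"log": str(out / "log.jsonl")}

    # --- input: simulate or load -----------------------------------------
    if cfg.messages_path is None:
        kwargs = {} if cfg.topics is None else {"topics": list(cfg.topics)}
        spec = StreamSpec(
            regions=list(cfg.regions),
            users_per_region=cfg.users_per_region,
            n_days=cfg.n_days, base_rate=cfg.base_rate,
            events=[EventInjection(**e) for e in cfg.events],
            seed=cfg.seed, **kwargs,
        )
        users, communities = generate_users(spec)
        messages, truth = generate_stream(spec, users)
        write_messages_jsonl(messages, out / "messages.jsonl")
        write_truth_tsv(truth, out / "truth.tsv")
        write_gazetteer_tsv(communities, out / "gazetteer.tsv")
        gaz = Gazetteer.from_frame(communities)
        artifacts.update(messages=str(out / "messages.jsonl"),
                         truth=str(out / "truth.tsv"),
                         gazetteer=str(out / "gazetteer.tsv"))
        log.log("simulate", seed=cfg.seed, n_messages=len(messages),
                input_hash=_hash(asdict(cfg)))
    else:
        if cfg.gazetteer_path is None or not Path(cfg.gazetteer_path).exists():
            raise StageError(
                "geolocation",
                f"gazetteer not found at {cfg.gazetteer_path!r}; set "
                "gazetteer_path to a TSV with columns "
                "name/category/lat/lon/region")
        messages = read_messages_jsonl(cfg.messages_path)
        gaz = Gazetteer.from_tsv(cfg.gazetteer_path)
        users = _users_from_messages(messages)
        truth = (pd.read_csv(cfg.truth_path, sep="\t")
                 if cfg.truth_path else None)
        log.log("load", n_messages=len(messages))

    # --- geolocation ------------------------------------------------------
    try:
        geo = geolocate_users(users, gaz)
    except Exception as e:  # noqa: BLE001 - rewrap with stage context
        raise StageError("geolocation", str(e)) from e
    geo.to_csv(out / "geolocated.tsv", sep="\t", index=False)
    artifacts["geolocated"] = str(out / "geolocated.tsv")
    region_of_user = dict(zip(geo["user_id"], geo["inferred_region"]))
    log.log("geolocation", n_users=len(geo))

    # --- preprocessing ----------------------------------------------------
    try:
        lex = Lexicons.bundled()
        if cfg.messages_path is None:
            # synthetic hashtags concatenate generator vocabulary words
            lex.segment_vocab = set(lex.segment_vocab) | set(
                spec.vocab.all_words())
        clean, audit = preprocess_messages(
            messages, lex, NoiseRules(**cfg.noise_rules))
    except Exception as e:
        raise StageError("preprocess", str(e)) from e
    audit.to_csv(out / "noise_audit.tsv", sep="\t", index=False)
    kept = [c for c in clean if not c.dropped and c.tokens]
    log.log("preprocess", kept=len(kept), dropped=len(clean) - len(kept))

    by_id = {m["id"]: m for m in messages}
    token_lists = [c.tokens for c in kept]
    ids = [c.message_id for c in kept]

    # --- topic classification --------------------------------------------
    if truth is None:
        raise StageError("topic", "no labeled data: provide truth_path")
    try:
        label_of = dict(zip(truth["message_id"], truth["topic"]))
        y = [label_of[i] for i in ids]
        clf = TopicClassifier(seed=cfg.seed, **cfg.topic_model)
        clf.fit(token_lists, y)
        topic_pred = clf.predict(token_lists)
    except Exception as e:
        raise StageError("topic", str(e)) from e
    log.log("topic", n_classes=len(clf.classes_))

    # --- daily counts + change detection ---------------------------------
    try:
        frame = pd.DataFrame({
            "message_id": ids,
            "region": [region_of_user.get(by_id[i]["username"],
                                          by_id[i]["town"]) for i in ids],
            "topic": topic_pred,
            "created_at": [by_id[i]["created_at"] for i in ids],
        })
        series = aggregate_daily(frame)
        counts = pd.concat([
            pd.DataFrame({"region": s.region, "topic": s.topic,
                          "date": s.counts.index.strftime("%Y-%m-%d"),
                          "count": s.counts.values})
            for s in series
        ]) if series else pd.DataFrame(
            columns=["region", "topic", "date", "count"])
        counts.to_csv(out / "counts.csv", index=False)
        artifacts["counts"] = str(out / "counts.csv")
        events = detect_events(series, DetectorConfig(**cfg.detector))
    except Exception as e:
        raise StageError("change_detection", str(e)) from e
    log.log("change_detection", n_events=len(events))

    # --- subtopics + affect per event ------------------------------------
    emo_label = dict(zip(truth["message_id"], truth["emotion"]))
    try:
        affect = TreeCNNEmotionClassifier(seed=cfg.seed, **cfg.affect_model)
        affect.fit(token_lists, [emo_label[i] for i in ids])
        emo_pred = affect.predict(token_lists)
    except Exception as e:
        raise StageError("affect", str(e)) from e
    pd.DataFrame({"message_id": ids, "emotion": emo_pred}).to_csv(
        out / "emotions.tsv", sep="\t", index=False)
    artifacts["emotions"] = str(out / "emotions.tsv")
    log.log("affect", n_classes=len(affect.classes_))

    frame = frame.assign(tokens=token_lists, emotion=emo_pred)
    try:
        for ev in events:
            sub_frame = frame.loc[(frame["topic"] == ev.topic)
                                  & (frame["region"] == ev.region)]
            if len(sub_frame) >= 4:
                sub_model = SubtopicModel(
                    seed=cfg.seed,
                    **{"k": 6, "layer_sizes": (32, 16), "epochs": 5,
                       **cfg.subtopic_model})
                toks = list(sub_frame["tokens"])
                sub_model.fit(toks)
                sub_frame = sub_frame.assign(
                    subtopic=sub_model.predict(toks))
                attribute_event(ev, sub_frame, stopwords=lex.stopwords)
            emotion_window(ev, frame.loc[frame["region"] == ev.region])
    except Exception as e:
        raise StageError("subtopic", str(e)) from e

    report = {
        "software_version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items() if k != "out_dir"},
        "events": [ev.to_dict() for ev in events],
    }
    (out / "events.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    artifacts["events"] = str(out / "events.json")
    log.log("report", n_events=len(events))
    return artifacts


def _users_from_messages(messages: List[dict]) -> pd.DataFrame:
    rows = {}
    for m in messages:
        u = m["username"]
        if u not in rows:
            rows[u] = {"user_id": u, "home_region": m.get("town"),
                       "declared_region": None,
                       "followed_communities": list(m.get("communities", []))}
    return pd.DataFrame(list(rows.values()))
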