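"""Training and applying the chemical-mention recognizer.

The pipeline per passage is: sentence split -> full tokenization ->
sub-tokenization -> feature extraction -> CRF labelling -> SOBIE decoding
back to character-offset mentions. Title and abstract are processed as
independent offset spaces.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from nerchem.corpus_io import Document, Mention
from nerchem.crf import LinearChainCRF
from nerchem.features import (
    FEATURE_GROUPS,
    BioNEProvider,
    DictionaryResource,
    PosTagger,
    extract_sentence_features,
    rows_to_strings,
)
from nerchem.label_codec import SobieLabel, decode_sobie, encode_sobie, label_alphabet
from nerchem.tokenizer import tokenize_passage

log = logging.getLogger(__name__)

MODEL_FORMAT = "nerchem-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters and feature-group toggles for CRF training."""

    l2_penalty: float = 1.0
    max_iterations: int = 200
    random_seed: int = 0
    feature_toggles: frozenset[str] = frozenset(FEATURE_GROUPS)

    def __post_init__(self) -> None:
        if self.l2_penalty < 0 or self.max_iterations < 1:
            raise ValueError("l2_penalty must be >= 0 and max_iterations >= 1")
        bad = set(self.feature_toggles) - set(FEATURE_GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups: {sorted(bad)}")


@dataclass
class Resources:
    """External lookups the feature extractor consults."""

    dictionaries: Sequence[DictionaryResource] = ()
    bio_ne: Optional[BioNEProvider] = None
    pos_tagger: Optional[PosTagger] = None


@dataclass
class Model:
    """A trained recognizer: CRF weights plus the exact feature-toggle set
    and label alphabet fixed at training time."""

    crf: LinearChainCRF
    feature_toggles: frozenset[str]
    config: TrainingConfig = field(default_factory=TrainingConfig)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "feature_toggles": sorted(self.feature_toggles),
            "config": {
                "l2_penalty": self.config.l2_penalty,
                "max_iterations": self.config.max_iterations,
                "random_seed": self.config.random_seed,
            },
            "crf": self.crf.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: not a recognizer model file")
        if payload.get("version") != MODEL_VERSION:
            raise ValueError(f"{path}: unsupported model version {payload.get('version')}")
        toggles = frozenset(payload["feature_toggles"])
        cfg = TrainingConfig(feature_toggles=toggles, **payload["config"])
        return cls(crf=LinearChainCRF.from_dict(payload["crf"]), feature_toggles=toggles, config=cfg)


def _point_provider_at(resources: Resources, doc_id: str) -> None:
    # sidecar Bio-NE providers key their spans by document
    if hasattr(resources.bio_ne, "doc_id"):
        resources.bio_ne.doc_id = doc_id


def _document_sequences(doc: Document, cfg_toggles: frozenset[str], resources: Resources):
    """Yield (sentence, feature strings, gold labels) for both passages."""
    _point_provider_at(resources, doc.doc_id)
    for passage in ("T", "A"):
        text = doc.passage_text(passage)
        for sentence in tokenize_passage(text, passage):
            rows = extract_sentence_features(
                sentence,
                toggles=cfg_toggles,
                dictionaries=resources.dictionaries,
                bio_ne=resources.bio_ne,
                pos_tagger=resources.pos_tagger,
            )
            labels = encode_sobie(sentence, doc.gold_mentions)
            yield sentence, rows_to_strings(rows), [str(lab) for lab in labels]


def train(
    docs: Sequence[Document],
    cfg: TrainingConfig = TrainingConfig(),
    resources: Resources = Resources(),
) -> Model:
    """Train the CRF on gold-annotated documents.

    Deterministic given (docs, cfg): the engine's optimization is
    seed-free and the feature vocabulary is built in corpus order.
    """
    if not docs:
        raise ValueError("empty training corpus")
    X: list[list[list[str]]] = []
    y: list[list[str]] = []
    for doc in docs:
        for _sent, feats, labels in _document_sequences(doc, cfg.feature_toggles, resources):
            if feats:
                X.append(feats)
                y.append(labels)
    if not X:
        raise ValueError("training corpus contains no sentences")
    alphabet = [str(lab) for lab in label_alphabet()]
    crf = LinearChainCRF(c2=cfg.l2_penalty, max_iterations=cfg.max_iterations)
    crf.fit(X, y, labels=alphabet)
    return Model(crf=crf, feature_toggles=cfg.feature_toggles, config=cfg)


def predict(model: Model, feature_rows: list[list[str]], toggles: Optional[frozenset[str]] = None) -> list[str]:
    """Viterbi-label one featurized sentence.

    ``toggles`` (when given) must equal the training toggle set; a mismatch
    is refused because the feature spaces are incompatible.
    """
    if toggles is not None and frozenset(toggles) != model.feature_toggles:
        diff = frozenset(toggles) ^ model.feature_toggles
        raise ValueError(f"feature toggles differ from training: {sorted(diff)}")
    return model.crf.predict(feature_rows)


def tag_document(model: Model, doc: Document, resources: Resources = Resources()) -> Document:
    """Return a copy of ``doc`` with CRF-predicted mentions attached."""
    out = Document(
        doc_id=doc.doc_id,
        title=doc.title,
        abstract=doc.abstract,
        gold_mentions=list(doc.gold_mentions),
    )
    predicted: list[Mention] = []
    _point_provider_at(resources, doc.doc_id)
    for passage in ("T", "A"):
        text = doc.passage_text(passage)
        for sentence in tokenize_passage(text, passage):
            rows = extract_sentence_features(
                sentence,
                toggles=model.feature_toggles,
                dictionaries=resources.dictionaries,
                bio_ne=resources.bio_ne,
                pos_tagger=resources.pos_tagger,
            )
            feats = rows_to_strings(rows)
            path = model.crf.predict(feats)
            labels = [SobieLabel.parse(p) for p in path]
            mentions = decode_sobie(labels, sentence.sub_tokens, passage, text)
            if mentions:
                conf = model.crf.marginal_path_confidence(feats, path)
                mentions = [replace(m, confidence=round(conf, 6)) for m in mentions]
            predicted.extend(mentions)
    out.predicted_mentions = predicted
    return out


def tag_documents(model: Model, docs: Sequence[Document], resources: Resources = Resources()) -> list[Document]:
    return [tag_document(model, d, resources) for d in docs]
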