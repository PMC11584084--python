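"""Entity vectors from descriptive text.

A short text about an entity (questionnaire answers, an encyclopedia page)
is turned into a single fixed-dimension vector in three steps:

1. sentences are greedily merged into passages of at least ``min_words``
   words (a sentence shorter than the threshold is considered part of the
   same passage as the following sentence);
2. every passage is embedded and only the vectors of content words
   (open-class tokens: nouns, verbs, adjectives, adverbs -- flagged
   upstream as ``is_content``) are retained; for contextual providers the
   top four layers are averaged per token;
3. the retained vectors are averaged per passage, then the passage means
   are averaged into the entity vector.  This two-stage mean weights
   passages equally, not tokens.

Providers are abstract: a static provider maps surface forms to vectors
(out-of-vocabulary words are skipped, never zero-imputed), a contextual
provider encodes a whole passage into per-token, per-layer vectors.  Toy
deterministic providers backed by an explicit lookup table are included;
running real pretrained language models is outside this package's scope.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import List, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .errors import EmptyRepresentationError, InvalidInputError


class Token(NamedTuple):
    surface: str
    is_content: bool


def _is_word(surface: str) -> bool:
    """A token counts toward the passage word threshold iff it contains at
    least one alphanumeric character (pure punctuation does not)."""
    return any(ch.isalnum() for ch in surface)


@dataclass
class Passage:
    """An ordered run of tokens treated as one unit of text."""

    tokens: List[Token]

    @property
    def n_words(self) -> int:
        return sum(1 for t in self.tokens if _is_word(t.surface))

    def __len__(self) -> int:
        return len(self.tokens)


class EmbeddingProvider(ABC):
    """Contract for anything that can embed words or passages."""

    name: str = "provider"
    mode: str = "static"
    dim: int = 0
    layers: int = 1


class StaticProvider(EmbeddingProvider):
    mode = "static"

    @abstractmethod
    def lookup(self, surface: str) -> Optional[np.ndarray]:
        """Vector for a surface form, or None if out of vocabulary."""


class ContextualProvider(EmbeddingProvider):
    mode = "contextual"

    @abstractmethod
    def encode(self, surfaces: Sequence[str]) -> np.ndarray:
        """Embed a passage.

        Returns an array of shape ``(n_tokens, layers, dim)`` with exactly
        one per-layer vector list per input token position.  A row of NaN
        marks a token with no available embedding.
        """


class ToyStaticProvider(StaticProvider):
    """Deterministic static provider backed by an explicit word table."""

    def __init__(self, table: Mapping[str, np.ndarray], name: str = "toy-static"):
        if not table:
            raise InvalidInputError("empty lookup table")
        dims = {np.asarray(v).shape for v in table.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise InvalidInputError("table vectors must share one 1-D shape")
        self._table = {w: np.asarray(v, dtype=float) for w, v in table.items()}
        self.name = name
        self.dim = int(next(iter(dims))[0])
        self.layers = 1

    def lookup(self, surface: str) -> Optional[np.ndarray]:
        return self._table.get(surface)


class ToyContextualProvider(ContextualProvider):
    """Contextual provider that ignores context: every layer of every token
    is the static table vector.  Useful to check provider-agnosticism of the
    pooling pipeline; tokens outside the table yield NaN rows."""

    def __init__(
        self,
        table: Mapping[str, np.ndarray],
        n_layers: int = 4,
        name: str = "toy-contextual",
    ):
        self._static = ToyStaticProvider(table, name=name)
        self.name = name
        self.dim = self._static.dim
        self.layers = int(n_layers)

    def encode(self, surfaces: Sequence[str]) -> np.ndarray:
        out = np.full((len(surfaces), self.layers, self.dim), np.nan)
        for i, s in enumerate(surfaces):
            v = self._static.lookup(s)
            if v is not None:
                out[i] = np.tile(v, (self.layers, 1))
        return out


def assemble_passages(
    sentences: Sequence[Sequence[Token]],
    min_words: int = 20,
    keep_short_tail: bool = True,
) -> List[Passage]:
    """Greedily merge sentences into passages of at least ``min_words`` words.

    Sentences are concatenated in order; a passage is closed as soon as its
    cumulative word count reaches the threshold.  A trailing passage still
    below the threshold when the text runs out is kept as its own passage by
    default (discarding text would waste scarce material); with
    ``keep_short_tail=False`` it is merged backward into the previous
    passage instead (or kept if it is the only one).
    """
    sentences = [list(s) for s in sentences]
    if not sentences or all(len(s) == 0 for s in sentences):
        raise InvalidInputError("need at least one non-empty sentence")
    passages: List[Passage] = []
    current: List[Token] = []
    for sent in sentences:
        current.extend(Token(*t) for t in sent)
        if sum(1 for t in current if _is_word(t.surface)) >= min_words:
            passages.append(Passage(current))
            current = []
    if current:
        if keep_short_tail or not passages:
            passages.append(Passage(current))
        else:
            passages[-1] = Passage(passages[-1].tokens + current)
    return passages


def pool_layers(per_layer_vectors: np.ndarray, top_k: int = 4) -> np.ndarray:
    """Elementwise mean of the last ``min(top_k, L)`` layers of one token."""
    try:
        arr = np.asarray(per_layer_vectors, dtype=float)
    except ValueError:
        raise InvalidInputError("layer vectors have inconsistent lengths")
    if arr.ndim != 2:
        raise InvalidInputError("expected a 2-D (layers, dim) array")
    if arr.shape[0] < 1:
        raise InvalidInputError("need at least one layer")
    k = min(int(top_k), arr.shape[0])
    return arr[-k:].mean(axis=0)


@dataclass
class EntityVector:
    """The model representation of one entity."""

    entity_id: str
    values: np.ndarray
    provider_name: str
    n_passages_used: int
    n_content_tokens_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError(f"{self.entity_id}: non-finite vector")
        if self.n_content_tokens_used < 1:
            raise InvalidInputError(f"{self.entity_id}: no content tokens used")


def entity_vector(
    passages: Sequence[Passage],
    provider: EmbeddingProvider,
    entity_id: str = "entity",
    top_k_layers: int = 4,
) -> EntityVector:
    """Two-stage mean of content-word vectors: per passage, then across
    passages.  Passages whose content words all lack embeddings contribute
    nothing; if no passage contributes, the entity has no representation."""
    if not passages:
        raise InvalidInputError("need at least one passage")
    passage_means: List[np.ndarray] = []
    n_tokens = 0
    for passage in passages:
        vecs: List[np.ndarray] = []
        if isinstance(provider, StaticProvider):
            for tok in passage.tokens:
                if not tok.is_content:
                    continue
                v = provider.lookup(tok.surface)
                if v is not None:
                    vecs.append(v)
        elif isinstance(provider, ContextualProvider):
            encoded = provider.encode([t.surface for t in passage.tokens])
            encoded = np.asarray(encoded, dtype=float)
            if encoded.shape[0] != len(passage.tokens):
                raise InvalidInputError(
                    "contextual provider returned wrong token count"
                )
            for pos, tok in enumerate(passage.tokens):
                if not tok.is_content:
                    continue
                if np.all(np.isfinite(encoded[pos])):
                    vecs.append(pool_layers(encoded[pos], top_k=top_k_layers))
        else:
            raise InvalidInputError(f"unsupported provider type {type(provider)}")
        if vecs:
            passage_means.append(np.mean(vecs, axis=0))
            n_tokens += len(vecs)
    if not passage_means:
        raise EmptyRepresentationError(
            f"entity '{entity_id}': no content word has an available embedding"
        )
    return EntityVector(
        entity_id=entity_id,
        values=np.mean(passage_means, axis=0),
        provider_name=provider.name,
        n_passages_used=len(passage_means),
        n_content_tokens_used=n_tokens,
    )


def vectors_for_records(
    records,
    provider: EmbeddingProvider,
    min_words: int = 20,
    top_k_layers: int = 4,
) -> dict:
    """Entity vectors for a list of entity records (id -> EntityVector)."""
    out = {}
    for rec in records:
        passages = assemble_passages(rec.sentences, min_words=min_words)
        out[rec.entity_id] = entity_vector(
            passages, provider, entity_id=rec.entity_id, top_k_layers=top_k_layers
        )
    return out
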