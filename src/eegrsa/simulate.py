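"""Synthetic study generator: montage, entity texts and evoked EEG.

The generator plants known representational structure in simulated data so
that every downstream stage (vector extraction, confound removal, RSA
encoding, searchlight, group statistics) can be exercised and validated
without access to real recordings.  It emulates the study conditions this
package targets: 32 named entities in a person/place x famous/familiar
design, a 128-channel-like montage on a 95 mm head, evoked responses of
0-800 ms at 200 Hz, and a name-length confound.

Model of one evoked response (entity e, subject s, channel c, time t)::

    x[e, c, t] = (M_s @ v_e)[c] * w(t)                 semantic signal
               + beta * len(name_e) * g[c]             name-length confound
               + eps[e, c, t]                          i.i.d. Gaussian noise

where ``v_e`` is the entity's ground-truth vector, ``M_s`` a
subject-specific mixing matrix whose rows are scaled by a fixed per-channel
loading profile (sparse: half the channels carry no semantic signal),
``w(t)`` a boxcar over the configured signal window and
``g`` a fixed spatial loading for the confound.  Noise is scaled so that
the within-window ratio of signal to noise standard deviations equals
``snr``.

Seed-splitting rule: all randomness derives from one master seed through
``numpy.random.SeedSequence([master_seed, stream, index])`` with the fixed
stream codes below.  Per-subject and per-entity substreams are keyed by
their index, so enlarging ``n_subjects`` extends a dataset without
reshuffling existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .baselines import name_length
from .config import SimulationConfig
from .embeddings import Token
from .errors import InvalidConfigError, InvalidInputError

# Stream codes of the seed-splitting rule (see module docstring).
_STREAM_VECTORS = 1
_STREAM_NAMES = 2
_STREAM_TEXTS = 3
_STREAM_LEXICON = 4
_STREAM_SPATIAL = 5
_STREAM_SUBJECT = 6

HEAD_RADIUS_MM = 95.0

#: Closed-class filler words; they receive vectors in the lexicon but are
#: flagged is_content=False and must never influence an entity vector.
FUNCTION_WORDS = (
    "il", "la", "lo", "di", "da", "un", "una", "che", "per", "con",
    "non", "su", "tra", "come", "ma", "se", "nel", "alla", "dei", "più",
)

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"


def _rng(master_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(stream), int(index)])
    )


@dataclass
class Montage:
    """Electrode labels and 3-D positions in millimetres."""

    channel_names: List[str]
    positions: np.ndarray  # (n_channels, 3), mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.channel_names) != len(self.positions):
            raise InvalidInputError("channel names and positions differ in length")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidInputError("duplicate channel names in montage")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidInputError("positions must be (n, 3)")
        d = self.distance_matrix()
        off = d[~np.eye(len(d), dtype=bool)]
        if off.size and off.min() <= 0:
            raise InvalidInputError("montage has coincident electrodes")

    def __len__(self) -> int:
        return len(self.channel_names)

    def distance_matrix(self) -> np.ndarray:
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise InvalidInputError(f"unknown channel '{name}'") from None


def generate_montage(
    n_channels: int, seed: int = 0, head_radius_mm: float = HEAD_RADIUS_MM
) -> Montage:
    """Quasi-uniform electrode layout on the upper hemisphere of a 95 mm head.

    Uses Fibonacci-sphere sampling restricted to z > 0, which gives
    reproducible quasi-uniform coverage; the layout is fully deterministic
    (the ``seed`` argument is accepted for interface stability but does not
    alter the layout).
    """
    if n_channels < 8:
        raise InvalidConfigError("a montage needs at least 8 channels")
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # heights in (0, 1): upper hemisphere
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r_xy = np.sqrt(1.0 - z**2)
    pos = head_radius_mm * np.column_stack(
        [r_xy * np.cos(phi), r_xy * np.sin(phi), z]
    )
    names = [f"E{k + 1:03d}" for k in range(n_channels)]
    return Montage(names, pos)


@dataclass
class EntityRecord:
    """One stimulus: identity, design cell, name, text and confound value."""

    entity_id: str
    name: str
    category: str  # person | place
    familiarity: str  # famous | familiar
    sentences: List[List[Token]]
    confound_value: float

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("entity name must be non-empty")
        if self.category not in ("person", "place"):
            raise InvalidInputError(f"bad category '{self.category}'")
        if self.familiarity not in ("famous", "familiar"):
            raise InvalidInputError(f"bad familiarity '{self.familiarity}'")
        if not self.sentences or any(len(s) == 0 for s in self.sentences):
            raise InvalidInputError("every sentence must be non-empty")


@dataclass
class Lexicon:
    """Word table backing the toy embedding providers."""

    vectors: Dict[str, np.ndarray]
    is_content: Dict[str, bool]

    @property
    def dim(self) -> int:
        return len(next(iter(self.vectors.values())))


@dataclass
class SimulatedCorpus:
    """Entity records plus the planted ground truth behind them."""

    records: List[EntityRecord]
    true_vectors: Dict[str, np.ndarray]
    lexicon: Lexicon

    @property
    def entity_ids(self) -> List[str]:
        return [r.entity_id for r in self.records]

    def confounds(self) -> Dict[str, float]:
        return {r.entity_id: r.confound_value for r in self.records}

    def names(self) -> Dict[str, str]:
        return {r.entity_id: r.name for r in self.records}


def _word_of_length(rng: np.random.Generator, n_chars: int) -> str:
    """Pronounceable pseudo-word of exactly ``n_chars`` characters."""
    chars = []
    while len(chars) < n_chars:
        chars.append(rng.choice(list(_CONSONANTS)))
        if len(chars) < n_chars:
            chars.append(rng.choice(list(_VOWELS)))
    return "".join(chars)


def _random_name(rng: np.random.Generator, n_chars: int) -> str:
    """Pseudo-name of exactly ``n_chars`` characters (spaces included);
    long names are split into two words about half the time."""
    if n_chars >= 10 and rng.random() < 0.5:
        first = int(rng.integers(4, n_chars - 5))
        return (
            _word_of_length(rng, first).capitalize()
            + " "
            + _word_of_length(rng, n_chars - 1 - first).capitalize()
        )
    return _word_of_length(rng, n_chars).capitalize()


def generate_entity_texts(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedCorpus:
    """Entities with ground-truth vectors and descriptive token streams.

    Ground-truth vectors share topic components within each category and
    familiarity level (category weight 1.0, familiarity weight 0.6,
    idiosyncratic weight 0.8 before the unit components are combined), so
    within-category vector correlations exceed between-category ones.  Each
    entity's content words are noisy copies of its ground-truth vector
    (per-dimension noise sd 0.25/sqrt(dim)); averaged over a text they stay
    within cosine >= 0.9 of the ground truth, which is what lets the
    embedding module recover the planted geometry.

    Name lengths are balanced across the four design cells (every cell
    receives the same multiset of lengths, drawn once between 4 and 16
    characters), emulating the stimulus-level length matching of the study
    this generator imitates; without that control, accidental correlation
    between name-length structure and the planted semantic structure at
    small stimulus counts would let non-semantic baselines inherit real
    signal.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    d = config.vector_dim

    rng_vec = _rng(seed, _STREAM_VECTORS)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    topic_cat = {c: unit(rng_vec.standard_normal(d)) for c in ("person", "place")}
    topic_fam = {f: unit(rng_vec.standard_normal(d)) for f in ("famous", "familiar")}

    rng_names = _rng(seed, _STREAM_NAMES)
    rng_lex = _rng(seed, _STREAM_LEXICON)

    records: List[EntityRecord] = []
    true_vectors: Dict[str, np.ndarray] = {}
    lex_vectors: Dict[str, np.ndarray] = {}
    lex_content: Dict[str, bool] = {}

    for fw in FUNCTION_WORDS:
        lex_vectors[fw] = rng_lex.standard_normal(d) / np.sqrt(d)
        lex_content[fw] = False

    # one pool of name lengths, reused by every design cell (length matching)
    length_pool = rng_names.integers(4, 17, size=config.n_entities_per_cell)

    used_names: set = set()
    idx = 0
    for category in ("person", "place"):
        for familiarity in ("famous", "familiar"):
            cell_lengths = rng_names.permutation(length_pool)
            for k in range(config.n_entities_per_cell):
                entity_id = f"{category}_{familiarity}_{k:02d}"
                name = _random_name(rng_names, int(cell_lengths[k]))
                while name in used_names:
                    name = _random_name(rng_names, int(cell_lengths[k]))
                used_names.add(name)

                v = (
                    1.0 * topic_cat[category]
                    + 0.6 * topic_fam[familiarity]
                    + 0.8 * unit(rng_vec.standard_normal(d))
                )
                true_vectors[entity_id] = v

                rng_txt = _rng(seed, _STREAM_TEXTS, idx)
                pool = [f"{entity_id}.w{w:02d}" for w in range(40)]
                for w in pool:
                    lex_vectors[w] = v + rng_txt.normal(0.0, 0.25 / np.sqrt(d), d)
                    lex_content[w] = True

                n_sent = int(rng_txt.integers(5, 16))
                sentences: List[List[Token]] = []
                for _ in range(n_sent):
                    n_tok = int(rng_txt.integers(5, 41))
                    sent = []
                    for _ in range(n_tok):
                        if rng_txt.random() < 0.6:
                            sent.append(Token(pool[rng_txt.integers(len(pool))], True))
                        else:
                            fw = FUNCTION_WORDS[rng_txt.integers(len(FUNCTION_WORDS))]
                            sent.append(Token(fw, False))
                    sentences.append(sent)

                records.append(
                    EntityRecord(
                        entity_id=entity_id,
                        name=name,
                        category=category,
                        familiarity=familiarity,
                        sentences=sentences,
                        confound_value=float(name_length(name)),
                    )
                )
                idx += 1

    return SimulatedCorpus(
        records=records,
        true_vectors=true_vectors,
        lexicon=Lexicon(lex_vectors, lex_content),
    )


@dataclass
class SubjectDataset:
    """One subject's evoked responses: entity x channel x time."""

    subject_id: str
    entity_ids: List[str]
    data: np.ndarray  # (n_entities, n_channels, n_times)
    channel_names: List[str]
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        e, c, t = self.data.shape
        if e != len(self.entity_ids):
            raise InvalidInputError("entity axis does not match entity_ids")
        if c != len(self.channel_names):
            raise InvalidInputError("channel axis does not match channel_names")
        if t != len(self.times_ms):
            raise InvalidInputError("time axis does not match times_ms")

    def response(self, entity_id: str) -> np.ndarray:
        try:
            return self.data[self.entity_ids.index(entity_id)]
        except ValueError:
            raise InvalidInputError(f"unknown entity '{entity_id}'") from None


def spatial_profiles(config: SimulationConfig, seed: int | None = None):
    """Fixed (subject-independent) spatial profiles of the simulation:
    the confound loading ``g`` and the per-channel signal loading.

    The semantic signal is spatially sparse: a random half of the channels
    carries no signal at all, and the loaded half has exponentially
    distributed gains.  This is the spatial concentration the searchlight
    analysis is meant to recover -- loaded neighbourhoods should light up,
    unloaded ones should behave like noise.
    """
    if seed is None:
        seed = config.seed
    g = _rng(seed, _STREAM_SPATIAL, 0).standard_normal(config.n_channels)
    rng = _rng(seed, _STREAM_SPATIAL, 1)
    loading = rng.exponential(1.0, config.n_channels)
    unloaded = rng.permutation(config.n_channels)[: config.n_channels // 2]
    loading[unloaded] = 0.0
    return g, loading


def generate_evoked(
    records: Sequence[EntityRecord],
    true_vectors: Dict[str, np.ndarray],
    montage: Montage,
    config: SimulationConfig,
    seed: int | None = None,
) -> List[SubjectDataset]:
    """Simulate evoked responses for all subjects (see module docstring).

    Deterministic given the master seed; subject ``s`` always receives the
    substream keyed by its index, independently of ``n_subjects``.
    """
    if not records:
        raise InvalidInputError("need at least one entity record")
    config.validate()
    if len(montage) != config.n_channels:
        raise InvalidInputError("montage size does not match config.n_channels")
    if seed is None:
        seed = config.seed

    times = config.times_ms
    w0, w1 = config.signal_window_ms
    window = ((times >= w0) & (times < w1)).astype(float)

    ids = [r.entity_id for r in records]
    V = np.stack([np.asarray(true_vectors[e], dtype=float) for e in ids])
    lengths = np.asarray([r.confound_value for r in records], dtype=float)
    g, loading = spatial_profiles(config, seed)

    n_e, n_c, n_t = len(ids), config.n_channels, len(times)
    d = V.shape[1]
    subjects: List[SubjectDataset] = []
    for s in range(config.n_subjects):
        rng = _rng(seed, _STREAM_SUBJECT, s)
        mixing = loading[:, None] * rng.standard_normal((n_c, d)) / np.sqrt(d)
        topo = V @ mixing.T  # (entities, channels)
        if config.snr > 0:
            sig_std = topo.std()
            noise_std = sig_std / config.snr if sig_std > 0 else 1.0
        else:
            topo = np.zeros_like(topo)
            noise_std = 1.0
        data = topo[:, :, None] * window[None, None, :]
        data = data + (config.confound_beta * lengths[:, None] * g[None, :])[:, :, None]
        data = data + rng.normal(0.0, noise_std, (n_e, n_c, n_t))
        subjects.append(
            SubjectDataset(
                subject_id=f"sub-{s + 1:02d}",
                entity_ids=list(ids),
                data=data,
                channel_names=list(montage.channel_names),
                times_ms=times,
            )
        )
    return subjects


def simulate_study(config: SimulationConfig, seed: int | None = None):
    """Convenience wrapper: montage + corpus + evoked for one master seed."""
    if seed is None:
        seed = config.seed
    montage = generate_montage(config.n_channels, seed=seed)
    corpus = generate_entity_texts(config, seed=seed)
    subjects = generate_evoked(
        corpus.records, corpus.true_vectors, montage, config, seed=seed
    )
    return montage, corpus, subjects
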