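"""Readers and writers for the package's on-disk formats.

Everything tabular is plain tab-separated text for diffability: montages
(name, x, y, z in millimetres), entity tables plus one token-table file
per entity, the toy lexicon, entity vectors (with a JSON sidecar carrying
provider metadata) and score/stat tables.  Evoked responses are stored as
one array file per entity under a per-subject directory, indexed by a
table, with a JSON sidecar holding the time axis and channel names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd

from .embeddings import EntityVector, Token
from .errors import InvalidInputError
from .simulate import EntityRecord, Lexicon, Montage, SimulatedCorpus, SubjectDataset


# --------------------------------------------------------------------- montage

def write_montage(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        fh.write("channel\tx\ty\tz\n")
        for name, pos in zip(montage.channel_names, montage.positions):
            fh.write(f"{name}\t{pos[0]:.6f}\t{pos[1]:.6f}\t{pos[2]:.6f}\n")


def read_montage(path) -> Montage:
    names: List[str] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InvalidInputError(f"{path}: empty montage file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 4 tab-separated fields"
                )
            name = parts[0]
            if name in names:
                raise InvalidInputError(
                    f"{path}:{lineno}: duplicate channel '{name}'"
                )
            try:
                xyz = [float(v) for v in parts[1:]]
            except ValueError:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from None
            names.append(name)
            rows.append(xyz)
    return Montage(names, np.asarray(rows))


# -------------------------------------------------------------------- entities

def write_corpus(corpus: SimulatedCorpus, out_dir) -> None:
    """Entity table, per-entity token tables and the lexicon."""
    out = Path(out_dir)
    (out / "tokens").mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "entity_id": [r.entity_id for r in corpus.records],
            "name": [r.name for r in corpus.records],
            "category": [r.category for r in corpus.records],
            "familiarity": [r.familiarity for r in corpus.records],
            "confound_value": [r.confound_value for r in corpus.records],
        }
    )
    table.to_csv(out / "entities.tsv", sep="\t", index=False)
    for rec in corpus.records:
        rows = []
        for si, sent in enumerate(rec.sentences):
            for tok in sent:
                rows.append((si, tok.surface, int(tok.is_content)))
        pd.DataFrame(rows, columns=["sentence_index", "surface", "is_content"]).to_csv(
            out / "tokens" / f"{rec.entity_id}.tsv", sep="\t", index=False
        )
    write_lexicon(corpus.lexicon, out / "lexicon.tsv")
    true_mat = pd.DataFrame(
        {e: v for e, v in corpus.true_vectors.items()}
    ).T
    true_mat.index.name = "entity_id"
    true_mat.columns = [f"v{k}" for k in range(true_mat.shape[1])]
    true_mat.to_csv(out / "true_vectors.tsv", sep="\t")


def read_entities(entities_dir) -> List[EntityRecord]:
    out_dir = Path(entities_dir)
    table = pd.read_csv(out_dir / "entities.tsv", sep="\t")
    records: List[EntityRecord] = []
    for row in table.itertuples():
        tok_path = out_dir / "tokens" / f"{row.entity_id}.tsv"
        if not tok_path.exists():
            raise InvalidInputError(f"missing token table {tok_path}")
        toks = pd.read_csv(tok_path, sep="\t")
        sentences: List[List[Token]] = []
        for _, group in toks.groupby("sentence_index", sort=True):
            sentences.append(
                [Token(str(s), bool(c)) for s, c in zip(group.surface, group.is_content)]
            )
        records.append(
            EntityRecord(
                entity_id=str(row.entity_id),
                name=str(row.name),
                category=str(row.category),
                familiarity=str(row.familiarity),
                sentences=sentences,
                confound_value=float(row.confound_value),
            )
        )
    return records


def write_lexicon(lexicon: Lexicon, path) -> None:
    words = sorted(lexicon.vectors)
    dim = lexicon.dim
    with open(path, "w") as fh:
        fh.write("word\tis_content\t" + "\t".join(f"v{k}" for k in range(dim)) + "\n")
        for w in words:
            vec = "\t".join(f"{x:.8g}" for x in lexicon.vectors[w])
            fh.write(f"{w}\t{int(lexicon.is_content[w])}\t{vec}\n")


def read_lexicon(path) -> Lexicon:
    table = pd.read_csv(path, sep="\t")
    vcols = [c for c in table.columns if c.startswith("v")]
    vectors = {
        str(r.word): np.asarray([getattr(r, c) for c in vcols], dtype=float)
        for r in table.itertuples()
    }
    is_content = {str(r.word): bool(r.is_content) for r in table.itertuples()}
    return Lexicon(vectors, is_content)


# --------------------------------------------------------------------- vectors

def write_vectors(vectors: Mapping[str, EntityVector], path) -> None:
    path = Path(path)
    ids = list(vectors)
    dim = len(vectors[ids[0]].values)
    with open(path, "w") as fh:
        fh.write("entity_id\t" + "\t".join(f"v{k}" for k in range(dim)) + "\n")
        for e in ids:
            vec = "\t".join(f"{x:.10g}" for x in vectors[e].values)
            fh.write(f"{e}\t{vec}\n")
    sidecar = {
        "provider_name": vectors[ids[0]].provider_name,
        "dim": dim,
        "n_passages_used": {e: vectors[e].n_passages_used for e in ids},
        "n_content_tokens_used": {
            e: vectors[e].n_content_tokens_used for e in ids
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_vectors(path) -> Dict[str, EntityVector]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    vcols = [c for c in table.columns if c.startswith("v")]
    out: Dict[str, EntityVector] = {}
    for r in table.itertuples():
        e = str(r.entity_id)
        out[e] = EntityVector(
            entity_id=e,
            values=np.asarray([getattr(r, c) for c in vcols], dtype=float),
            provider_name=meta.get("provider_name", "unknown"),
            n_passages_used=meta.get("n_passages_used", {}).get(e, 1),
            n_content_tokens_used=meta.get("n_content_tokens_used", {}).get(e, 1),
        )
    return out


# ---------------------------------------------------------------------- evoked

def write_evoked(subjects: List[SubjectDataset], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    first = subjects[0]
    sidecar = {
        "times_ms": [float(t) for t in first.times_ms],
        "step_ms": float(first.times_ms[1] - first.times_ms[0])
        if len(first.times_ms) > 1
        else None,
        "channel_names": list(first.channel_names),
    }
    (out / "times.json").write_text(json.dumps(sidecar))
    for ds in subjects:
        sdir = out / ds.subject_id
        sdir.mkdir(exist_ok=True)
        with open(sdir / "index.tsv", "w") as fh:
            fh.write("entity_id\tfile\n")
            for e in ds.entity_ids:
                fh.write(f"{e}\t{e}.npy\n")
        for k, e in enumerate(ds.entity_ids):
            np.save(sdir / f"{e}.npy", ds.data[k])


def read_evoked_dir(path) -> List[SubjectDataset]:
    out = Path(path)
    sidecar_path = out / "times.json"
    if not sidecar_path.exists():
        raise InvalidInputError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    times = np.asarray(sidecar["times_ms"], dtype=float)
    channels = list(sidecar["channel_names"])
    subjects: List[SubjectDataset] = []
    problems: List[str] = []
    for sdir in sorted(p for p in out.iterdir() if p.is_dir()):
        index = pd.read_csv(sdir / "index.tsv", sep="\t")
        entity_ids, arrays = [], []
        for row in index.itertuples():
            fpath = sdir / str(row.file)
            if not fpath.exists():
                problems.append(f"{sdir.name}: missing array for {row.entity_id}")
                continue
            try:
                arr = np.load(fpath)
            except Exception:
                problems.append(f"{sdir.name}: unreadable array for {row.entity_id}")
                continue
            if arr.shape != (len(channels), len(times)):
                problems.append(
                    f"{sdir.name}: {row.entity_id} has shape {arr.shape}, "
                    f"expected {(len(channels), len(times))}"
                )
                continue
            entity_ids.append(str(row.entity_id))
            arrays.append(arr)
        if problems:
            continue
        subjects.append(
            SubjectDataset(
                subject_id=sdir.name,
                entity_ids=entity_ids,
                data=np.stack(arrays),
                channel_names=channels,
                times_ms=times,
            )
        )
    if problems:
        raise InvalidInputError("evoked directory invalid: " + "; ".join(problems))
    if not subjects:
        raise InvalidInputError(f"no subject directories under {out}")
    return subjects


# ----------------------------------------------------------------- trial maths

def average_trials(trials) -> np.ndarray:
    """Elementwise mean over the trial axis of a (trials, channels, times)
    stack -- the averaging that turns single trials into one evoked
    response per entity."""
    arr = np.asarray(trials, dtype=float)
    if arr.ndim < 1 or arr.shape[0] == 0:
        raise InvalidInputError("need at least one trial")
    if arr.ndim == 1:
        raise InvalidInputError("trials must be at least 2-D (trial x feature)")
    return arr.mean(axis=0)


# ----------------------------------------------------------------- score tables

def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
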