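#!/usr/bin/env python
"""Direct comparisons between models of the evoked responses.

Two models are run through identical time-resolved encoding and their
per-subject score difference is tested with the one-tailed sign-flip
permutation test (TFCE-corrected), the same machinery the pipeline uses
for model comparison.  Two contrasts are reported:

1. semantic entity vectors vs the orthographic control -- a genuinely
   stronger vs weaker model, expected to separate clearly;
2. full-text vectors vs vectors from each entity's first sentence only --
   with this generator's highly redundant texts a single sentence already
   pins down the entity vector, so the expected outcome is a null
   difference (a known limitation relative to real questionnaire text).

Writes results/stats_model_difference_*.tsv.
"""

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from eegrsa import io as eio
from eegrsa.baselines import orthography_model, scalar_similarity_matrix
from eegrsa.embeddings import ToyStaticProvider, vectors_for_records
from eegrsa.encoding import model_similarity, time_resolved
from eegrsa.pipeline import scores_matrix
from eegrsa.stats import build_adjacency, paired_difference_test

ROOT = Path(__file__).resolve().parent.parent / "results"


def truncated(records, n_sentences=1):
    return [
        dataclasses.replace(r, sentences=r.sentences[:n_sentences])
        for r in records
    ]


def tr_matrix(subjects, sims, confounds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frames = [
            time_resolved(ds, sims, confounds=confounds) for ds in subjects
        ]
    return scores_matrix(frames, "time_ms"), frames[0]["time_ms"].to_numpy()


def report(label, res, times):
    sig = times[res.significant]
    finite = np.isfinite(res.t)
    peak = np.max(res.t[finite]) if finite.any() else float("nan")
    if sig.size:
        print(
            f"{label}: first model better at {sig.size} time points "
            f"({sig.min():g}-{sig.max():g} ms), peak T = {peak:.3f}"
        )
    else:
        print(f"{label}: no significant difference (peak T = {peak:.3f})")


def main() -> None:
    records = eio.read_entities(ROOT / "data" / "entities")
    subjects = eio.read_evoked_dir(ROOT / "data" / "evoked")
    lexicon = eio.read_lexicon(ROOT / "data" / "entities" / "lexicon.tsv")
    provider = ToyStaticProvider(lexicon.vectors)
    confounds = {r.entity_id: r.confound_value for r in records}
    names = {r.entity_id: r.name for r in records}
    ids = [r.entity_id for r in records]

    semantic = model_similarity(vectors_for_records(records, provider))
    ortho = scalar_similarity_matrix(orthography_model(names), ids)
    one_sent = model_similarity(
        vectors_for_records(truncated(records), provider)
    )

    mats = {}
    for label, sims in (
        ("semantic", semantic),
        ("orthography", ortho),
        ("one_sentence", one_sent),
    ):
        mats[label], times = tr_matrix(subjects, sims, confounds)
        print(
            f"{label:14s}: grand-mean peak score "
            f"{np.nanmax(np.nanmean(mats[label], axis=0)):+.4f}"
        )

    adj = build_adjacency("temporal_chain", n_times=len(times))
    for a, b, tag in (
        ("semantic", "orthography", "semantic_vs_orthography"),
        ("semantic", "one_sentence", "full_vs_one_sentence"),
    ):
        keep = np.isfinite(mats[a]).all(axis=0) & np.isfinite(mats[b]).all(axis=0)
        res = paired_difference_test(
            mats[a][:, keep],
            mats[b][:, keep],
            build_adjacency("temporal_chain", n_times=int(keep.sum())),
            n_permutations=1024,
            seed=2024,
        )
        frame = res.to_frame()
        frame["unit"] = times[keep]
        eio.write_table(frame, ROOT / f"stats_model_difference_{tag}.tsv")
        report(f"{a} > {b}", res, times[keep])


if __name__ == "__main__":
    main()
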