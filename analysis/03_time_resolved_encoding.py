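#!/usr/bin/env python
"""Time-resolved RSA encoding, whole scalp, per subject.

For every time point, each held-out entity's channel pattern is predicted
as the similarity-weighted sum of the training entities' patterns
(leave-two-out, confound regression refitted per split) and scored with
Spearman correlation.  Runs the semantic model and the two non-semantic
baselines (name length, orthographic distance); writes tidy score tables
under results/.
"""

import warnings
from pathlib import Path

import pandas as pd

from eegrsa import io as eio
from eegrsa.baselines import (
    name_length_model,
    orthography_model,
    scalar_similarity_matrix,
)
from eegrsa.encoding import model_similarity, time_resolved

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = eio.read_entities(ROOT / "data" / "entities")
    subjects = eio.read_evoked_dir(ROOT / "data" / "evoked")
    vectors = eio.read_vectors(ROOT / "vectors.tsv")
    confounds = {r.entity_id: r.confound_value for r in records}
    names = {r.entity_id: r.name for r in records}
    ids = [r.entity_id for r in records]

    models = {
        "semantic": model_similarity(vectors),
        "name_length": scalar_similarity_matrix(name_length_model(names), ids),
        "orthography": scalar_similarity_matrix(orthography_model(names), ids),
    }
    for model_name, sims in models.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frames = [
                time_resolved(ds, sims, confounds=confounds) for ds in subjects
            ]
        table = pd.concat(frames, ignore_index=True)
        path = ROOT / f"scores_time_resolved_{model_name}.tsv"
        eio.write_table(table, path)
        grand = table.groupby("time_ms").score.mean()
        if grand.notna().any():
            peak_t = grand.idxmax()
            print(
                f"{model_name:12s}: grand-mean score peak {grand.max():+.4f} "
                f"at {peak_t:g} ms -> {path.name}"
            )
        else:
            print(f"{model_name:12s}: no evaluable pairs at this scale")


if __name__ == "__main__":
    main()
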