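#!/usr/bin/env python
"""Spatio-temporal searchlight encoding (30 mm / 50 ms units).

Repeats the RSA encoding inside every electrode-disk x 100 ms window
cluster over 0-800 ms, localizing where on the scalp and when the
semantic model explains the evoked responses.  Writes the cluster
manifest and per-subject cluster scores under results/.
"""

import warnings
from pathlib import Path

import pandas as pd

from eegrsa import io as eio
from eegrsa.encoding import model_similarity
from eegrsa.searchlight import build_clusters, searchlight_encoding

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = eio.read_entities(ROOT / "data" / "entities")
    subjects = eio.read_evoked_dir(ROOT / "data" / "evoked")
    montage = eio.read_montage(ROOT / "data" / "montage.tsv")
    vectors = eio.read_vectors(ROOT / "vectors.tsv")
    confounds = {r.entity_id: r.confound_value for r in records}

    clusters = build_clusters(
        montage, spatial_radius_mm=30.0, temporal_radius_ms=50.0,
        analysis_window_ms=(0.0, 800.0),
    )
    manifest = pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "center": [c.center_channel for c in clusters],
            "members": [",".join(c.member_channels) for c in clusters],
            "window_start_ms": [c.window_ms[0] for c in clusters],
            "window_end_ms": [c.window_ms[1] for c in clusters],
        }
    )
    eio.write_table(manifest, ROOT / "clusters.tsv")

    sims = model_similarity(vectors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frames = [
            searchlight_encoding(ds, sims, clusters, confounds=confounds)
            for ds in subjects
        ]
    table = pd.concat(frames, ignore_index=True)
    eio.write_table(table, ROOT / "scores_searchlight.tsv")

    grand = table.groupby("cluster_id", sort=False).score.mean()
    top = grand.sort_values(ascending=False).head(5)
    sizes = manifest.members.str.count(",") + 1
    print(f"{len(clusters)} clusters ({sizes.min()}-{sizes.max()} channels each)")
    print("top clusters by grand-mean score:")
    for cid, score in top.items():
        print(f"  {cid:18s} {score:+.4f}")
    print(f"wrote {ROOT / 'scores_searchlight.tsv'}")


if __name__ == "__main__":
    main()
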