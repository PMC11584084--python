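#!/usr/bin/env python
"""Group inference: one-tailed sign-flip permutation tests with TFCE.

Tests, across subjects, whether encoding scores exceed chance (0) at each
time point (temporal-chain adjacency) and in each searchlight cluster
(spatial + window-chain adjacency), controlling the family-wise error
rate with the max-TFCE null.  Writes stats tables and prints the
significant time windows and clusters.
"""

from pathlib import Path

import numpy as np

from eegrsa import io as eio
from eegrsa.pipeline import scores_matrix, test_scores
from eegrsa.searchlight import build_clusters
from eegrsa.stats import build_adjacency

ROOT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 1024
SEED = 2024


def main() -> None:
    montage = eio.read_montage(ROOT / "data" / "montage.tsv")

    for model_name in ("semantic", "name_length", "orthography"):
        table = eio.read_table(ROOT / f"scores_time_resolved_{model_name}.tsv")
        frames = [g for _, g in table.groupby("subject_id", sort=True)]
        mat = scores_matrix(frames, "time_ms")
        adj = build_adjacency("temporal_chain", n_times=mat.shape[1])
        res = test_scores(mat, adj, n_permutations=N_PERM, seed=SEED)
        frame = res.to_frame()
        times = frames[0]["time_ms"].to_numpy()
        frame["unit"] = times
        eio.write_table(frame, ROOT / f"stats_time_resolved_{model_name}.tsv")
        sig = times[res.significant]
        span = f"{sig.min():g}-{sig.max():g} ms" if sig.size else "none"
        finite = np.isfinite(res.t)
        peak = np.max(res.t[finite]) if finite.any() else float("nan")
        print(
            f"time-resolved [{model_name:12s}]: {sig.size:3d} significant "
            f"points ({span}); peak T = {peak:.3f}"
        )

    table = eio.read_table(ROOT / "scores_searchlight.tsv")
    frames = [g for _, g in table.groupby("subject_id", sort=True)]
    mat = scores_matrix(frames, "cluster_id")
    clusters = build_clusters(montage)
    order = {c.cluster_id: c for c in clusters}
    clusters = [order[cid] for cid in frames[0]["cluster_id"]]
    adj = build_adjacency(
        "searchlight_spatiotemporal", clusters=clusters, montage=montage
    )
    res = test_scores(mat, adj, n_permutations=N_PERM, seed=SEED)
    frame = res.to_frame()
    frame["unit"] = [c.cluster_id for c in clusters]
    eio.write_table(frame, ROOT / "stats_searchlight.tsv")
    n_sig = int(res.significant.sum())
    print(f"searchlight: {n_sig} of {len(clusters)} clusters significant")
    if n_sig:
        best = int(np.nanargmax(res.t))
        print(
            f"  peak cluster {clusters[best].cluster_id}: "
            f"T = {res.t[best]:.3f}, p = {res.p[best]:.4f}"
        )


if __name__ == "__main__":
    main()
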