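"""End-to-end pipeline driver: simulate -> vectors -> encode -> searchlight
-> stats, with a run manifest for reproducibility.

Every stage writes plain-text tables under the output directory; rerunning
with the same configuration and seed reproduces them byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import scipy

from . import __version__
from . import io as eio
from .baselines import name_length_model, orthography_model, scalar_similarity_matrix
from .config import RunConfig
from .embeddings import ToyContextualProvider, ToyStaticProvider, vectors_for_records
from .encoding import model_similarity, time_resolved
from .errors import EegRsaError, PipelineStageError
from .searchlight import build_clusters, searchlight_encoding
from .simulate import simulate_study
from .stats import GroupStatResult, build_adjacency, sign_flip_permutation_test, subgraph


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except (EegRsaError, OSError) as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return inner

    return wrap


def provider_from_lexicon(lexicon, which: str):
    if which == "toy-static":
        return ToyStaticProvider(lexicon.vectors)
    if which == "toy-contextual":
        return ToyContextualProvider(lexicon.vectors)
    raise PipelineStageError("vectors", f"unknown provider '{which}'")


def scores_matrix(frames: List[pd.DataFrame], unit_col: str) -> np.ndarray:
    """Stack per-subject tidy score frames into (subjects, units)."""
    units = list(frames[0][unit_col])
    rows = []
    for f in frames:
        if list(f[unit_col]) != units:
            raise PipelineStageError("stats", "subjects report different units")
        rows.append(np.asarray(f["score"], dtype=float))
    return np.vstack(rows)


def test_scores(mat: np.ndarray, adjacency, **kwargs) -> GroupStatResult:
    """Sign-flip permutation test tolerating unevaluable units.

    Units with a non-finite score for any subject (e.g. every
    leave-two-out pair skipped as degenerate) are excluded from testing
    and reported with t = NaN, enhancement 0 and p = 1.
    """
    keep = np.isfinite(mat).all(axis=0)
    if keep.all():
        return sign_flip_permutation_test(mat, adjacency, **kwargs)
    if not keep.any():
        return GroupStatResult(
            t=np.full(mat.shape[1], np.nan),
            tfce=np.zeros(mat.shape[1]),
            p=np.ones(mat.shape[1]),
            n_permutations=0,
            alpha=kwargs.get("alpha", 0.05),
            node_ids=adjacency.node_ids,
        )
    sub = sign_flip_permutation_test(mat[:, keep], subgraph(adjacency, keep), **kwargs)
    n = mat.shape[1]
    t = np.full(n, np.nan)
    enh = np.zeros(n)
    p = np.ones(n)
    t[keep], enh[keep], p[keep] = sub.t, sub.tfce, sub.p
    return GroupStatResult(
        t=t,
        tfce=enh,
        p=p,
        n_permutations=sub.n_permutations,
        alpha=sub.alpha,
        node_ids=adjacency.node_ids,
    )


def run_pipeline(config: RunConfig, out_dir) -> Dict[str, str]:
    """Execute all stages; returns a mapping of artifact names to paths."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    artifacts: Dict[str, str] = {}

    @_stage("simulate")
    def stage_simulate():
        montage, corpus, subjects = simulate_study(sim, seed=config.seed)
        eio.write_montage(montage, out / "montage.tsv")
        eio.write_corpus(corpus, out / "entities")
        eio.write_evoked(subjects, out / "evoked")
        return montage, corpus, subjects

    montage, corpus, subjects = stage_simulate()
    artifacts["montage"] = str(out / "montage.tsv")
    artifacts["entities"] = str(out / "entities")
    artifacts["evoked"] = str(out / "evoked")

    @_stage("vectors")
    def stage_vectors():
        provider = provider_from_lexicon(corpus.lexicon, config.provider)
        vectors = vectors_for_records(
            corpus.records, provider, min_words=config.min_words
        )
        eio.write_vectors(vectors, out / "vectors.tsv")
        return vectors

    vectors = stage_vectors()
    artifacts["vectors"] = str(out / "vectors.tsv")

    confounds = corpus.confounds()
    names = corpus.names()
    sims_semantic = model_similarity(vectors)
    baselines = {
        "name_length": scalar_similarity_matrix(
            name_length_model(names), list(sims_semantic.entity_ids)
        ),
        "orthography": scalar_similarity_matrix(
            orthography_model(names), list(sims_semantic.entity_ids)
        ),
    }

    @_stage("encode")
    def stage_encode():
        frames = {}
        for model_name, sims in {"semantic": sims_semantic, **baselines}.items():
            per_subject = [
                time_resolved(
                    ds,
                    sims,
                    confounds=confounds,
                    restrict_test_to=config.restrict,
                    records=corpus.records,
                )
                for ds in subjects
            ]
            table = pd.concat(per_subject, ignore_index=True)
            table.insert(0, "model", model_name)
            frames[model_name] = per_subject
            path = out / f"scores_time_resolved_{model_name}.tsv"
            eio.write_table(table, path)
            artifacts[f"scores_time_resolved_{model_name}"] = str(path)
        return frames

    tr_frames = stage_encode()

    @_stage("searchlight")
    def stage_searchlight():
        clusters = build_clusters(
            montage,
            spatial_radius_mm=config.spatial_radius_mm,
            temporal_radius_ms=config.temporal_radius_ms,
            analysis_window_ms=config.analysis_window_ms,
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
        eio.write_table(manifest, out / "clusters.tsv")
        per_subject = [
            searchlight_encoding(
                ds,
                sims_semantic,
                clusters,
                confounds=confounds,
                restrict_test_to=config.restrict,
                records=corpus.records,
            )
            for ds in subjects
        ]
        table = pd.concat(per_subject, ignore_index=True)
        eio.write_table(table, out / "scores_searchlight.tsv")
        return clusters, per_subject

    clusters, sl_frames = stage_searchlight()
    artifacts["clusters"] = str(out / "clusters.tsv")
    artifacts["scores_searchlight"] = str(out / "scores_searchlight.tsv")

    @_stage("stats")
    def stage_stats():
        n_t = len(sim.times_ms)
        adj_t = build_adjacency("temporal_chain", n_times=n_t)
        for model_name, frames in tr_frames.items():
            mat = scores_matrix(frames, "time_ms")
            res = test_scores(
                mat,
                adj_t,
                n_permutations=config.n_permutations,
                seed=config.seed,
                alpha=config.alpha,
            )
            frame = res.to_frame()
            frame["unit"] = frames[0]["time_ms"].values
            path = out / f"stats_time_resolved_{model_name}.tsv"
            eio.write_table(frame, path)
            artifacts[f"stats_time_resolved_{model_name}"] = str(path)
        adj_s = build_adjacency(
            "searchlight_spatiotemporal",
            clusters=clusters,
            montage=montage,
            neighbor_distance_mm=config.neighbor_distance_mm,
        )
        mat = scores_matrix(sl_frames, "cluster_id")
        res = test_scores(
            mat,
            adj_s,
            n_permutations=config.n_permutations,
            seed=config.seed,
            alpha=config.alpha,
        )
        eio.write_table(res.to_frame(), out / "stats_searchlight.tsv")
        artifacts["stats_searchlight"] = str(out / "stats_searchlight.tsv")

    stage_stats()

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    artifacts["manifest"] = str(out / "manifest.json")

    report(out)
    artifacts["report"] = str(out / "report.txt")
    return artifacts


def _significant_runs(units: np.ndarray, significant: np.ndarray) -> List[str]:
    runs = []
    start = None
    for k, sig in enumerate(significant):
        if sig and start is None:
            start = k
        if (not sig or k == len(significant) - 1) and start is not None:
            end = k if sig else k - 1
            runs.append(f"{units[start]:g}-{units[end]:g} ms")
            start = None
    return runs


def report(out_dir) -> str:
    """Plain-text summary of significant time windows and clusters."""
    out = Path(out_dir)
    lines = ["eegrsa run report", "=" * 40]
    for path in sorted(out.glob("stats_time_resolved_*.tsv")):
        model_name = path.stem.replace("stats_time_resolved_", "")
        frame = eio.read_table(path)
        sig = frame["significant"].to_numpy(dtype=bool)
        runs = _significant_runs(frame["unit"].to_numpy(dtype=float), sig)
        lines.append(
            f"time-resolved [{model_name}]: "
            + (", ".join(runs) if runs else "no significant time points")
        )
    sl = out / "stats_searchlight.tsv"
    if sl.exists():
        frame = eio.read_table(sl)
        sig = frame[frame["significant"]]
        lines.append(f"searchlight: {len(sig)} of {len(frame)} clusters significant")
        for row in sig.itertuples():
            lines.append(f"  {row.unit}: T={row.t:.3f} p={row.p:.4f}")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
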