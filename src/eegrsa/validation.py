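"""End-to-end validation experiments on synthetic data.

These are the package's statistical self-checks: formula-level oracles for
the RSA predictor and the edit distance, null calibration of the encoder
and of the family-wise corrected group test, and recovery of planted
signal in time (time-resolved) and space (searchlight), with non-semantic
baselines staying null after confound regression.  The acceptance test
suite and ``scripts/acceptance.py`` both run these functions; sizes are
parameters so the two callers can choose their own repetition counts.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Dict, List, Tuple

import numpy as np

from .baselines import (
    levenshtein,
    name_length_model,
    orthography_model,
    scalar_similarity_matrix,
)
from .config import SimulationConfig
from .embeddings import ToyStaticProvider, vectors_for_records
from .encoding import (
    SimilarityMatrix,
    leave_two_out,
    model_similarity,
    predict_response,
    time_resolved,
)
from .searchlight import build_clusters, searchlight_encoding
from .simulate import simulate_study, spatial_profiles
from .stats import build_adjacency, paired_difference_test, sign_flip_permutation_test


def _child_seeds(seed: int, n: int, label: int) -> List[int]:
    """Independent 31-bit child seeds for one experiment family."""
    ss = np.random.SeedSequence([int(seed), int(label)])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ------------------------------------------------------------------ formula

def rsa_formula_max_error(n_instances: int = 1000, seed: int = 0) -> float:
    """Max |predict_response - independent brute-force loop| over random
    instances with up to 6 entities."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 7))
        ids = tuple(f"e{k}" for k in range(n))
        vals = rng.normal(size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        sims = SimilarityMatrix(ids, vals, "pearson_vector")
        n_feat = int(rng.integers(2, 6))
        responses = {e: rng.normal(size=n_feat) for e in ids[1:]}
        got = predict_response(ids[0], list(ids[1:]), responses, sims)
        want = np.zeros(n_feat)
        for k, e in enumerate(ids[1:], start=1):
            want = want + vals[0, k] * responses[e]
        worst = max(worst, float(np.abs(got - want).max()))
    return worst


def self_consistent_mean_rho(seed: int = 0) -> float:
    """Leave-two-out score on a noise-free fixture whose responses are the
    predictor's own weighted sums (rank-one responses, all-positive
    similarities), where the expected score is exactly 1."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=8)
    vectors = {f"e{k}": base + 0.1 * rng.normal(size=8) for k in range(5)}
    u = rng.uniform(0.5, 1.5, size=5)
    f = rng.normal(size=12)
    responses = {f"e{k}": u[k] * f for k in range(5)}
    return leave_two_out(vectors, responses).score


# ------------------------------------------------------------- calibration

def null_encoding_grand_mean(
    n_seeds: int = 200,
    n_entities: int = 16,
    n_subjects: int = 20,
    n_features: int = 24,
    seed: int = 0,
) -> float:
    """Grand-mean leave-two-out score over fully random vectors and
    responses; unbiased encoding must land near zero."""
    means = []
    for s in _child_seeds(seed, n_seeds, label=3):
        rng = np.random.default_rng(s)
        vectors = {f"e{k}": rng.normal(size=8) for k in range(n_entities)}
        sims = model_similarity(vectors)
        subj_scores = []
        for _ in range(n_subjects):
            responses = {
                f"e{k}": rng.normal(size=n_features) for k in range(n_entities)
            }
            subj_scores.append(leave_two_out(sims, responses).score)
        means.append(np.mean(subj_scores))
    return float(np.mean(means))


def familywise_error_rate(
    n_experiments: int = 100,
    n_permutations: int = 512,
    n_subjects: int = 20,
    seed: int = 0,
) -> float:
    """Fraction of simulated null experiments (no signal, no confound
    loading, full time-resolved pipeline at 160 time points including
    per-split confound regression) in which any time point reaches
    TFCE-corrected significance."""
    adj = build_adjacency("temporal_chain", n_times=160)
    hits = 0
    for s in _child_seeds(seed, n_experiments, label=4):
        cfg = SimulationConfig(
            n_subjects=n_subjects,
            n_entities_per_cell=2,
            n_channels=16,
            vector_dim=8,
            snr=0.0,
            confound_beta=0.0,
            time_step_ms=5.0,
            seed=s,
        )
        montage, corpus, subjects = simulate_study(cfg)
        vecs = vectors_for_records(
            corpus.records, ToyStaticProvider(corpus.lexicon.vectors)
        )
        sims = model_similarity(vecs)
        conf = corpus.confounds()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = np.vstack(
                [
                    time_resolved(ds, sims, confounds=conf).score.values
                    for ds in subjects
                ]
            )
        res = sign_flip_permutation_test(
            mat, adj, n_permutations=n_permutations, seed=s
        )
        hits += bool(res.significant.any())
    return hits / n_experiments


# --------------------------------------------------------- signal recovery

def signal_recovery_run(seed: int) -> Dict[str, object]:
    """One synthetic experiment with signal planted in 300-500 ms at
    snr 1 and an active name-length confound: time-resolved and
    searchlight pipelines with group statistics.

    Returns the significant time points, and pooled significance counts
    for searchlight clusters that contain at least one strongly loaded
    channel (top quartile of the signal loading) versus clusters whose
    members carry no signal loading at all.
    """
    cfg = SimulationConfig(
        n_subjects=30,
        n_entities_per_cell=4,
        n_channels=64,
        vector_dim=8,
        snr=1.0,
        confound_beta=0.1,
        time_step_ms=20.0,
        seed=seed,
    )
    montage, corpus, subjects = simulate_study(cfg)
    vecs = vectors_for_records(
        corpus.records, ToyStaticProvider(corpus.lexicon.vectors)
    )
    sims = model_similarity(vecs)
    conf = corpus.confounds()
    times = subjects[0].times_ms

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tr = np.vstack(
            [
                time_resolved(ds, sims, confounds=conf).score.values
                for ds in subjects
            ]
        )
    adj_t = build_adjacency("temporal_chain", n_times=len(times))
    res_t = sign_flip_permutation_test(tr, adj_t, n_permutations=512, seed=seed)
    sig_times = times[res_t.significant]

    clusters = build_clusters(montage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sl = np.vstack(
            [
                searchlight_encoding(
                    ds, sims, clusters, confounds=conf
                ).score.values
                for ds in subjects
            ]
        )
    adj_s = build_adjacency(
        "searchlight_spatiotemporal", clusters=clusters, montage=montage
    )
    res_s = sign_flip_permutation_test(sl, adj_s, n_permutations=512, seed=seed)

    _, loading = spatial_profiles(cfg)
    cidx = {n: i for i, n in enumerate(montage.channel_names)}
    thr = np.quantile(loading, 0.75)
    loaded = np.array(
        [
            any(loading[cidx[m]] >= thr for m in c.member_channels)
            for c in clusters
        ]
    )
    unloaded = np.array(
        [
            all(loading[cidx[m]] == 0 for m in c.member_channels)
            for c in clusters
        ]
    )
    sig = res_s.significant
    return {
        "sig_times_ms": sig_times,
        "window_ok": bool(
            sig_times.size > 0
            and sig_times.min() >= 250
            and sig_times.max() <= 550
        ),
        "loaded_sig": int(sig[loaded].sum()),
        "loaded_total": int(loaded.sum()),
        "unloaded_sig": int(sig[unloaded].sum()),
        "unloaded_total": int(unloaded.sum()),
    }


def baseline_null_run(seed: int) -> bool:
    """True if either non-semantic baseline (name length, orthography)
    reaches TFCE-corrected significance anywhere in the time-resolved
    analysis after confound regression, at the study's 32-entity scale."""
    cfg = SimulationConfig(
        n_subjects=30,
        n_entities_per_cell=8,
        n_channels=32,
        vector_dim=8,
        snr=1.0,
        confound_beta=0.1,
        time_step_ms=20.0,
        seed=seed,
    )
    montage, corpus, subjects = simulate_study(cfg)
    conf = corpus.confounds()
    names = corpus.names()
    ids = corpus.entity_ids
    adj = build_adjacency("temporal_chain", n_times=len(subjects[0].times_ms))
    for model in (name_length_model(names), orthography_model(names)):
        sims = scalar_similarity_matrix(model, ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = np.vstack(
                [
                    time_resolved(ds, sims, confounds=conf).score.values
                    for ds in subjects
                ]
            )
        res = sign_flip_permutation_test(mat, adj, n_permutations=512, seed=seed)
        if res.significant.any():
            return True
    return False


# ---------------------------------------------------------------- confound

def confound_orthogonality_max_corr(
    n_entities: int = 20, n_features: int = 50, seed: int = 0
) -> float:
    """Max |correlation| between the confound and train residuals over
    features (an exact OLS property, so this is machine noise)."""
    from . import confound as cf

    rng = np.random.default_rng(seed)
    c = rng.normal(size=n_entities)
    y = rng.normal(size=(n_entities, n_features)) + 0.5 * c[:, None]
    resid = cf.residualize(cf.fit(c, y), c, y)
    cc = c - c.mean()
    r = resid - resid.mean(axis=0)
    corr = (cc @ r) / (
        np.linalg.norm(cc) * np.linalg.norm(r, axis=0)
    )
    return float(np.abs(corr).max())


# ------------------------------------------------------------- edit distance

def levenshtein_oracle_mismatches(max_len: int = 4) -> int:
    """Number of disagreements with an in-function DP oracle over all
    string pairs up to ``max_len`` on a two-letter alphabet."""

    def dp(a: str, b: str) -> int:
        prev = list(range(len(b) + 1))
        for i in range(1, len(a) + 1):
            cur = [i] + [0] * len(b)
            for j in range(1, len(b) + 1):
                cur[j] = min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (a[i - 1] != b[j - 1]),
                )
            prev = cur
        return prev[len(b)]

    strings = [
        "".join(s)
        for n in range(max_len + 1)
        for s in itertools.product("ab", repeat=n)
    ]
    return sum(
        levenshtein(a, b) != dp(a, b) for a in strings for b in strings
    )


# --------------------------------------------------------- model comparison

def paired_difference_rates(
    n_power_seeds: int = 10,
    n_null_seeds: int = 40,
    n_subjects: int = 30,
    n_units: int = 10,
    seed: int = 0,
) -> Tuple[float, float]:
    """(power, null) unit-flagging rates of the paired model-difference
    test: model A = model B + 0.3 with noise sd 0.1, versus A = B."""
    adj = build_adjacency("temporal_chain", n_times=n_units)
    power = []
    for s in _child_seeds(seed, n_power_seeds, label=8):
        rng = np.random.default_rng(s)
        b = rng.normal(scale=0.1, size=(n_subjects, n_units))
        a = b + 0.3 + rng.normal(scale=0.1, size=(n_subjects, n_units))
        res = paired_difference_test(a, b, adj, n_permutations=512, seed=s)
        power.append(res.significant.mean())
    null = []
    for s in _child_seeds(seed, n_null_seeds, label=9):
        rng = np.random.default_rng(s)
        b = rng.normal(scale=0.1, size=(n_subjects, n_units))
        a = b + rng.normal(scale=0.1, size=(n_subjects, n_units))
        res = paired_difference_test(a, b, adj, n_permutations=512, seed=s)
        null.append(res.significant.mean())
    return float(np.mean(power)), float(np.mean(null))
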