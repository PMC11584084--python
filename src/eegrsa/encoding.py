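"""RSA encoding with leave-two-out evaluation.

The encoder predicts a held-out entity's evoked response as a weighted sum
of the training entities' responses, the weights being first-order
similarities between the test entity and each training entity in model
space (Pearson correlations between entity vectors, or the scalar-model
similarity for one-dimensional baselines).  Weights are used as-is --
negative similarities included, no normalization.  A prediction is scored
against the observed response with Spearman rank correlation (average
ranks for ties), and the final encoding score is the mean over all
correlations recorded across leave-two-out splits (two per split, one per
held-out entity).

Confound regression, when requested, is refitted on the training entities
of every split and applied to the full channels-x-times feature vector of
all entities before prediction and scoring.

Category-restricted evaluation draws test pairs from a restricted pool
only, while the training set keeps every other entity (entities outside
the pool remain available for training).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .embeddings import EntityVector
from .errors import (
    DegenerateModelError,
    InvalidConfigError,
    InvalidInputError,
    UndefinedCorrelationError,
)


@dataclass
class SimilarityMatrix:
    """First-order similarities between entities in one model space."""

    entity_ids: Tuple[str, ...]
    values: np.ndarray
    kind: str  # pearson_vector | scalar_negabs

    def __post_init__(self) -> None:
        self.entity_ids = tuple(self.entity_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise InvalidInputError("similarity matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("non-finite similarities")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise InvalidInputError("similarity matrix must be symmetric")

    def index(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(entity_id)
        except ValueError:
            raise InvalidInputError(f"unknown entity '{entity_id}'") from None


@dataclass
class EncodingScore:
    """Mean Spearman correlation for one subject and analysis unit."""

    subject_id: str
    unit: Union[str, float]
    score: float
    n_pairs: int


def _as_vector_matrix(vectors) -> Tuple[List[str], np.ndarray]:
    if isinstance(vectors, Mapping):
        ids = list(vectors.keys())
        rows = []
        for e in ids:
            v = vectors[e]
            rows.append(v.values if isinstance(v, EntityVector) else np.asarray(v))
        return ids, np.asarray(rows, dtype=float)
    ids, rows = [], []
    for v in vectors:
        if not isinstance(v, EntityVector):
            raise InvalidInputError("expected EntityVector items or a mapping")
        ids.append(v.entity_id)
        rows.append(v.values)
    return ids, np.asarray(rows, dtype=float)


def model_similarity(vectors) -> SimilarityMatrix:
    """Pairwise Pearson correlations between entity vectors.

    Accepts a mapping entity_id -> vector/EntityVector or a sequence of
    EntityVector.  Every vector must have variance across dimensions.
    """
    ids, mat = _as_vector_matrix(vectors)
    if len(ids) < 3:
        raise InvalidInputError("model similarity needs >= 3 entities")
    sd = mat.std(axis=1)
    for e, s in zip(ids, sd):
        if s == 0:
            raise DegenerateModelError(
                f"entity '{e}' has a zero-variance vector; Pearson undefined"
            )
    values = np.corrcoef(mat)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(tuple(ids), values, kind="pearson_vector")


def predict_response(
    test_id: str,
    train_ids: Sequence[str],
    train_responses: Mapping[str, np.ndarray],
    sims: SimilarityMatrix,
) -> np.ndarray:
    """Weighted sum of training responses, weights = model similarities
    between the test entity and each training entity (raw, unnormalized)."""
    if test_id in train_ids:
        raise InvalidInputError(f"test entity '{test_id}' appears in the train set")
    ti = sims.index(test_id)
    pred = None
    for tid in train_ids:
        if tid not in train_responses:
            raise InvalidInputError(f"missing response for train entity '{tid}'")
        w = sims.values[ti, sims.index(tid)]
        r = np.asarray(train_responses[tid], dtype=float)
        pred = w * r if pred is None else pred + w * r
    if pred is None:
        raise InvalidInputError("empty train set")
    return pred


def score_prediction(predicted, observed) -> float:
    """Spearman rank correlation between predicted and observed responses."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise InvalidInputError("predicted and observed must be equal-length 1-D")
    if p.size < 3:
        raise InvalidInputError("need at least 3 features to correlate")
    if np.unique(p).size < 2 or np.unique(o).size < 2:
        raise UndefinedCorrelationError(
            "constant input: Spearman correlation undefined"
        )
    return float(spearmanr(p, o).statistic)


# ---------------------------------------------------------------------------
# vectorized leave-two-out core shared by the whole-scalp, time-resolved and
# searchlight drivers


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=-1))
    nb = np.sqrt((b * b).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=-1) / (na * nb)
    r = np.where((na == 0) | (nb == 0), np.nan, r)
    return r


def _spearman_block(block: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Spearman correlations for a (4, ..., k) stack of feature vectors:
    rows 0/2 are prediction/observation of the first test item, rows 1/3 of
    the second.  Returns the two correlation arrays of shape ``(...)``.

    Continuous data almost never tie, so the common case ranks with one
    argsort and uses the closed-form moments of a tie-free rank vector;
    exact ties anywhere fall back to ``scipy.stats.rankdata`` (average
    ranks) with a generic Pearson.
    """
    k = block.shape[-1]
    if k < 2 or _has_ties(block):
        ranks = rankdata(block, axis=-1)
        return (
            _rowwise_pearson(ranks[0], ranks[2]),
            _rowwise_pearson(ranks[1], ranks[3]),
        )
    order = np.argsort(block, axis=-1)
    ranks = np.empty(block.shape)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, k + 1.0), block.shape), -1
    )
    # tie-free ranks are permutations of 1..k: mean and variance are fixed
    m = (k + 1.0) / 2.0
    denom = k * (k * k - 1.0) / 12.0
    r_i = ((ranks[0] * ranks[2]).sum(axis=-1) - k * m * m) / denom
    r_j = ((ranks[1] * ranks[3]).sum(axis=-1) - k * m * m) / denom
    return r_i, r_j


def _has_ties(block: np.ndarray) -> bool:
    s = np.sort(block, axis=-1)
    return bool((s[..., 1:] == s[..., :-1]).any())


def leave_two_out_units(
    sims_values: np.ndarray,
    responses: np.ndarray,
    confounds: Optional[np.ndarray],
    pairs: Sequence[Tuple[int, int]],
    unit_groups: Sequence[Tuple[np.ndarray, np.ndarray]],
    n_units: int,
    chunk_size: int = 32,
) -> Tuple[np.ndarray, np.ndarray]:
    """Leave-two-out scores for many analysis units at once.

    ``unit_groups`` is a list of ``(unit_positions, feature_indices)``
    where ``feature_indices`` has shape (n_units_in_group, unit_size); all
    units inside a group share one size so ranking vectorizes.  Pairs are
    processed in chunks so ranking runs on large arrays.  A pair whose
    Spearman correlation is undefined for a unit (constant prediction or
    observation) is skipped for that unit and counted out of ``n_pairs``.
    Returns ``(mean_scores, n_pairs)`` arrays of length ``n_units``; units
    with no evaluable pair score NaN.
    """
    y = np.asarray(responses, dtype=float)
    sims = np.asarray(sims_values, dtype=float)
    n_ent, n_feat = y.shape
    if n_ent < 4:
        raise InvalidConfigError("leave-two-out needs at least 4 entities")
    sums = np.zeros(n_units)
    counts = np.zeros(n_units, dtype=int)
    n_skipped = 0
    n_degenerate = 0
    pairs = np.asarray(list(pairs), dtype=int).reshape(-1, 2)

    # Predictions are weighted sums over the train set; with the train set
    # being "everyone but the pair", both the weighted sums and the
    # train-fitted confound OLS follow from whole-dataset precomputations
    # via rank-2 corrections, which lets whole chunks of pairs vectorize.
    weighted_all = sims @ y  # (E, F): includes self and partner terms
    w_row_sum = sims.sum(axis=1)
    w_row_ssq = (sims**2).sum(axis=1)
    # scale against which a prediction counts as numerically zero: a
    # weighted sum whose terms cancel to rounding error (possible when the
    # weights are affine in a regressed-out confound) must be skipped, not
    # scored -- correlating rounding noise would bias the mean
    y_rms = np.sqrt((y**2).mean()) * np.sqrt(n_feat)
    _DEGENERATE_PRED_RTOL = 1e-8
    if confounds is not None:
        c = np.asarray(confounds, dtype=float)
        if c.shape != (n_ent,):
            raise InvalidInputError("confounds must align with entities")
        c_sum = c.sum()
        c_ssq = (c**2).sum()
        y_sum = y.sum(axis=0)  # (F,)
        cy_sum = c @ y  # (F,)
        wc_row = sims @ c  # (E,)

    for lo in range(0, len(pairs), chunk_size):
        batch = pairs[lo : lo + chunk_size]
        bi, bj = batch[:, 0], batch[:, 1]
        w_ii = sims[bi, bi]
        w_ij = sims[bi, bj]
        w_jj = sims[bj, bj]
        base_i = weighted_all[bi] - w_ii[:, None] * y[bi] - w_ij[:, None] * y[bj]
        base_j = weighted_all[bj] - w_ij[:, None] * y[bi] - w_jj[:, None] * y[bj]
        if confounds is None:
            pred = np.stack([base_i, base_j])
            obs = np.stack([y[bi], y[bj]])
        else:
            n_train = n_ent - 2
            ci, cj = c[bi], c[bj]
            mean = (c_sum - ci - cj) / n_train
            var = (c_ssq - ci**2 - cj**2) / n_train - mean**2
            var = np.maximum(var, 0.0)
            degenerate = var <= 1e-24
            n_degenerate += int(degenerate.sum())
            sd = np.where(degenerate, 1.0, np.sqrt(var))
            intercept = (y_sum[None, :] - y[bi] - y[bj]) / n_train  # (B, F)
            # slope of the standardized-confound OLS, per feature:
            # sum_T x_e y_e / sum_T x_e^2 with sum x^2 = n_train
            cy_train = cy_sum[None, :] - ci[:, None] * y[bi] - cj[:, None] * y[bj]
            slope = (cy_train - (mean * n_train)[:, None] * intercept) / (
                n_train * sd[:, None]
            )
            slope[degenerate] = 0.0
            x_i = np.where(degenerate, 0.0, (ci - mean) / sd)
            x_j = np.where(degenerate, 0.0, (cj - mean) / sd)
            obs_i = y[bi] - intercept - x_i[:, None] * slope
            obs_j = y[bj] - intercept - x_j[:, None] * slope
            # weighted sums over train residuals, by the same corrections
            wsum_i = w_row_sum[bi] - w_ii - w_ij
            wsum_j = w_row_sum[bj] - w_ij - w_jj
            wc_i = wc_row[bi] - w_ii * ci - w_ij * cj
            wc_j = wc_row[bj] - w_ij * ci - w_jj * cj
            wx_i = np.where(degenerate, 0.0, (wc_i - mean * wsum_i) / sd)
            wx_j = np.where(degenerate, 0.0, (wc_j - mean * wsum_j) / sd)
            pred = np.stack(
                [
                    base_i - wsum_i[:, None] * intercept - wx_i[:, None] * slope,
                    base_j - wsum_j[:, None] * intercept - wx_j[:, None] * slope,
                ]
            )
            obs = np.stack([obs_i, obs_j])
        w_l2 = np.sqrt(
            np.stack(
                [
                    np.maximum(w_row_ssq[bi] - w_ii**2 - w_ij**2, 0.0),
                    np.maximum(w_row_ssq[bj] - w_ij**2 - w_jj**2, 0.0),
                ]
            )
        )  # (2, n_b)
        pred_ok = np.linalg.norm(pred, axis=-1) > (
            _DEGENERATE_PRED_RTOL * w_l2 * y_rms
        )
        pair_ok = pred_ok[0] & pred_ok[1]
        n_skipped += int((~pair_ok).sum()) * n_units
        for upos, fidx in unit_groups:
            # (4, n_b, units_in_group, unit_size): pred_i, pred_j, obs_i, obs_j
            block = np.concatenate([pred[:, :, fidx], obs[:, :, fidx]])
            r_i, r_j = _spearman_block(block)  # (n_b, units_in_group)
            finite = np.isfinite(r_i) & np.isfinite(r_j)
            n_skipped += int((~finite & pair_ok[:, None]).sum())
            valid = finite & pair_ok[:, None]
            both = np.where(valid, r_i + r_j, 0.0)
            sums[upos] += both.sum(axis=0)
            counts[upos] += valid.sum(axis=0)
    if n_degenerate:
        warnings.warn(
            f"confound had zero variance on the train set of {n_degenerate} "
            "pair(s); fitted degenerate slope-0 models",
            stacklevel=2,
        )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} unit/pair evaluations with undefined "
            "Spearman correlation",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = sums / (2 * counts)
    scores[counts == 0] = np.nan
    return scores, counts


def restriction_pool(records, restrict_test_to) -> List[str]:
    """Entity ids eligible as test items under a category/familiarity
    restriction ('person', 'place', 'famous', 'familiar' or 'all')."""
    if restrict_test_to in (None, "all"):
        return [r.entity_id for r in records]
    if restrict_test_to in ("person", "place"):
        return [r.entity_id for r in records if r.category == restrict_test_to]
    if restrict_test_to in ("famous", "familiar"):
        return [r.entity_id for r in records if r.familiarity == restrict_test_to]
    raise InvalidConfigError(f"unknown restriction '{restrict_test_to}'")


def _resolve_model(model, entity_ids=None) -> SimilarityMatrix:
    if isinstance(model, SimilarityMatrix):
        return model
    return model_similarity(model)


def _pool_indices(sims: SimilarityMatrix, restrict_test_to, records) -> List[int]:
    if restrict_test_to is None or restrict_test_to == "all":
        return list(range(len(sims.entity_ids)))
    if isinstance(restrict_test_to, str):
        if records is None:
            raise InvalidConfigError(
                "string restrictions require the entity records"
            )
        pool_ids = restriction_pool(records, restrict_test_to)
    else:
        pool_ids = list(restrict_test_to)
    return [sims.index(e) for e in pool_ids]


def leave_two_out(
    model,
    responses: Mapping[str, np.ndarray],
    confounds: Optional[Mapping[str, float]] = None,
    restrict_test_to=None,
    records=None,
    subject_id: str = "subject",
) -> EncodingScore:
    """Whole-feature leave-two-out encoding score for one subject.

    ``model`` is a mapping entity_id -> vector (first-order similarities
    are computed as Pearson correlations) or a ready
    :class:`SimilarityMatrix`.  ``responses`` maps entity ids to 1-D
    feature vectors.  All unordered pairs from the (possibly restricted)
    test pool are enumerated; the training set is always every other
    entity.
    """
    sims = _resolve_model(model)
    ids = sims.entity_ids
    if len(ids) < 4:
        raise InvalidConfigError("leave-two-out needs at least 4 entities")
    try:
        y = np.asarray([np.asarray(responses[e], dtype=float) for e in ids])
    except KeyError as exc:
        raise InvalidInputError(f"missing response for entity {exc.args[0]!r}")
    if y.ndim != 2:
        raise InvalidInputError("responses must be equal-length 1-D vectors")
    conf = (
        None
        if confounds is None
        else np.asarray([float(confounds[e]) for e in ids])
    )
    pool = _pool_indices(sims, restrict_test_to, records)
    if len(pool) < 2:
        raise InvalidConfigError("test pool must contain at least 2 entities")
    pairs = list(itertools.combinations(sorted(pool), 2))
    groups = [(np.array([0]), np.arange(y.shape[1])[None, :])]
    scores, counts = leave_two_out_units(sims.values, y, conf, pairs, groups, 1)
    return EncodingScore(subject_id, "all", float(scores[0]), int(counts[0]))


def time_resolved(
    dataset,
    model,
    confounds: Optional[Mapping[str, float]] = None,
    restrict_test_to=None,
    records=None,
) -> pd.DataFrame:
    """Encoding score at every time point, all electrodes as the target.

    The confound regression (when given) is refitted per split on the full
    channels-x-times feature vector; scoring then happens per time point
    on the channel pattern at that sample.  Returns a tidy frame with
    columns subject_id, time_ms, score, n_pairs.
    """
    sims = _resolve_model(model)
    ids = list(sims.entity_ids)
    n_e, n_c, n_t = dataset.data.shape
    order = [dataset.entity_ids.index(e) for e in ids]
    y = dataset.data[order].reshape(len(ids), n_c * n_t)
    conf = (
        None
        if confounds is None
        else np.asarray([float(confounds[e]) for e in ids])
    )
    pool = _pool_indices(sims, restrict_test_to, records)
    if len(pool) < 2:
        raise InvalidConfigError("test pool must contain at least 2 entities")
    pairs = list(itertools.combinations(sorted(pool), 2))
    # feature f = c * n_t + t  ->  unit t gathers all channels at sample t
    fidx = (np.arange(n_c)[None, :] * n_t) + np.arange(n_t)[:, None]  # (T, C)
    groups = [(np.arange(n_t), fidx)]
    scores, counts = leave_two_out_units(sims.values, y, conf, pairs, groups, n_t)
    return pd.DataFrame(
        {
            "subject_id": dataset.subject_id,
            "time_ms": dataset.times_ms,
            "score": scores,
            "n_pairs": counts,
        }
    )
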