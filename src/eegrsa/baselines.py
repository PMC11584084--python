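"""Non-semantic control models: name length and orthographic distance.

Each baseline represents an entity by a single scalar.  ``name_length``
counts characters (spaces included by default, since multi-word names are
read as a whole).  ``orthographic_score`` is the mean Levenshtein edit
distance between a name and every other name in the stimulus set.  Scalar
models enter the RSA encoder through :func:`scalar_similarity_matrix`,
which turns values into pairwise similarities as the negative absolute
difference of z-scored values -- the simplest monotone similarity
preserving the encoder's weight-by-resemblance semantics.  The original
study does not state how its scalar baselines were converted to pairwise
weights; this rule is our documented choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import edlib
import numpy as np

from .errors import DegenerateModelError, InvalidInputError


def name_length(name: str, include_spaces: bool = True) -> int:
    """Number of characters in ``name``, internal spaces included by default."""
    if not isinstance(name, str):
        raise InvalidInputError("name must be a string")
    stripped = name.strip()
    if not stripped:
        raise InvalidInputError("name must be non-empty")
    if include_spaces:
        return len(stripped)
    return len(stripped.replace(" ", ""))


def levenshtein(a: str, b: str, lowercase: bool = True) -> int:
    """Unit-cost edit distance (insert/delete/substitute) between two strings.

    Case is folded first: capitalization is typographic, not orthographic
    identity.  Backed by the edlib C implementation.
    """
    if lowercase:
        a, b = a.lower(), b.lower()
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(edlib.align(a, b, task="distance")["editDistance"])


def orthographic_score(name: str, all_names: Sequence[str]) -> float:
    """Mean Levenshtein distance from ``name`` to every other stimulus name."""
    occurrences = sum(1 for n in all_names if n == name)
    if occurrences == 0:
        raise InvalidInputError(f"name '{name}' not present in all_names")
    if occurrences > 1:
        raise InvalidInputError(f"name '{name}' duplicated in all_names")
    if len(all_names) < 2:
        raise InvalidInputError("need at least two names")
    others = [n for n in all_names if n != name]
    return float(np.mean([levenshtein(name, other) for other in others]))


@dataclass
class ScalarModel:
    """One scalar per entity, e.g. name length or mean orthographic distance."""

    model_name: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        arr = np.asarray(list(self.values.values()), dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"{self.model_name}: non-finite values")

    def vector(self, entity_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.asarray([self.values[e] for e in entity_ids], dtype=float)
        except KeyError as exc:
            raise InvalidInputError(
                f"{self.model_name}: missing entity {exc.args[0]!r}"
            ) from None


def name_length_model(names: Mapping[str, str], include_spaces: bool = True) -> ScalarModel:
    """Name-length baseline from a mapping entity_id -> name."""
    return ScalarModel(
        "name_length",
        {e: float(name_length(n, include_spaces)) for e, n in names.items()},
    )


def orthography_model(names: Mapping[str, str]) -> ScalarModel:
    """Mean-Levenshtein baseline from a mapping entity_id -> name."""
    all_names = list(names.values())
    return ScalarModel(
        "orthography",
        {e: orthographic_score(n, all_names) for e, n in names.items()},
    )


def scalar_similarity_matrix(model: ScalarModel, entity_ids: Sequence[str] | None = None):
    """Pairwise similarities for a scalar model.

    Values are z-scored over entities; similarity(i, j) = -|z_i - z_j|, so
    identical values are maximally similar (0) and similarity decreases
    strictly with distance.  The diagonal is set to the maximum off-diagonal
    value plus a small epsilon for bookkeeping only -- the encoder never
    uses self-similarities as weights.
    """
    from .encoding import SimilarityMatrix  # local import avoids a cycle

    if entity_ids is None:
        entity_ids = list(model.values.keys())
    if len(entity_ids) < 3:
        raise InvalidInputError("scalar similarity needs >= 3 entities")
    v = model.vector(entity_ids)
    sd = v.std()
    if sd == 0:
        raise DegenerateModelError(
            f"{model.model_name}: all values identical, similarity undefined"
        )
    z = (v - v.mean()) / sd
    sims = -np.abs(z[:, None] - z[None, :])
    off = sims[~np.eye(len(z), dtype=bool)]
    np.fill_diagonal(sims, off.max() + 1e-9)
    return SimilarityMatrix(tuple(entity_ids), sims, kind="scalar_negabs")
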