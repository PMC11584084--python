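"""Cross-validated confound regression.

Variance linearly explainable by a per-entity scalar nuisance variable
(here: name length) is removed from the evoked responses before encoding.
The regression is fitted on the training entities of each train/test split
only, then applied to train and test alike, so no information leaks from
the test set.  The confound is standardized with train statistics before
the per-feature ordinary least squares fit; the residuals are
mathematically identical to unstandardized OLS, but slopes become
scale-free and extrapolation stays numerically stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass
class ConfoundFit:
    """Per-feature OLS parameters plus the train standardization constants."""

    slope: np.ndarray  # (n_features,)
    intercept: np.ndarray  # (n_features,)
    confound_mean: float
    confound_sd: float

    def __post_init__(self) -> None:
        self.slope = np.asarray(self.slope, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        if self.slope.shape != self.intercept.shape:
            raise InvalidInputError("slope and intercept lengths differ")
        if not (
            np.all(np.isfinite(self.slope)) and np.all(np.isfinite(self.intercept))
        ):
            raise InvalidInputError("non-finite regression parameters")

    @property
    def n_features(self) -> int:
        return self.slope.shape[0]


def fit(train_confounds, train_responses) -> ConfoundFit:
    """OLS with intercept from the standardized confound to every feature.

    ``train_responses`` is an (entities x features) matrix.  Zero confound
    variance on the train set degrades gracefully to slope 0 / intercept =
    feature mean, with a warning: nothing can be removed, but the split is
    still usable.
    """
    c = np.asarray(train_confounds, dtype=float)
    y = np.asarray(train_responses, dtype=float)
    if c.ndim != 1:
        raise InvalidInputError("train_confounds must be 1-D")
    if y.ndim != 2 or y.shape[0] != c.shape[0]:
        raise InvalidInputError("train_responses must be (n_train, n_features)")
    if c.shape[0] < 3:
        raise InvalidInputError("confound fit needs at least 3 training entities")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite training data")

    mean, sd = float(c.mean()), float(c.std())
    intercept = y.mean(axis=0)
    if sd == 0:
        warnings.warn(
            "confound has zero variance on the train set; fitting degenerate "
            "slope-0 model",
            stacklevel=2,
        )
        return ConfoundFit(np.zeros(y.shape[1]), intercept, mean, 1.0)
    x = (c - mean) / sd  # zero mean by construction
    slope = (x @ y) / (x @ x)
    return ConfoundFit(slope, intercept, mean, sd)


def residualize(fit_: ConfoundFit, confounds, responses) -> np.ndarray:
    """Remove the fitted confound component, using train-fitted parameters
    identically for train and test rows (linear extrapolation, no clipping)."""
    c = np.asarray(confounds, dtype=float)
    y = np.asarray(responses, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[None, :]
        c = np.atleast_1d(c)
    if y.ndim != 2 or y.shape[0] != c.shape[0]:
        raise InvalidInputError("responses must be (n_entities, n_features)")
    if y.shape[1] != fit_.n_features:
        raise InvalidInputError(
            f"feature count mismatch: fit has {fit_.n_features}, "
            f"responses have {y.shape[1]}"
        )
    x = (c - fit_.confound_mean) / fit_.confound_sd
    resid = y - (fit_.intercept[None, :] + x[:, None] * fit_.slope[None, :])
    return resid[0] if squeeze else resid


def residualize_split(confounds, responses, train_idx) -> np.ndarray:
    """Fit on ``train_idx`` rows only, then residualize the full matrix."""
    c = np.asarray(confounds, dtype=float)
    y = np.asarray(responses, dtype=float)
    f = fit(c[train_idx], y[train_idx])
    return residualize(f, c, y)
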