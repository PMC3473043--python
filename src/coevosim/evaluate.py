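"""Scoring detectors against simulator truth and structure contacts.

* :func:`recovery_curve` — rank a method's position pairs by score, replace
  each ranked pair's value by the ground-truth covarion count for that same
  pair, and accumulate: the closer the cumulative curve tracks the ideal
  curve (the truth counts in their own descending order), the better the
  method recovered the true coevolution history.
* :func:`contact_recall` — fraction of all close-contact pairs (centroid
  distance below a cutoff) captured among the top-ranked pairs, with a
  minimum sequence-separation filter.
* :func:`merge_curves` — average curves from different runs or families on a
  common normalized grid via shape-preserving piecewise cubic Hermite
  interpolation (PCHIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from coevosim.alignment import ContactMap
from coevosim.detect import CoevolutionMatrix


class UndefinedRecallError(ValueError):
    """Raised when the contact set is empty after filtering."""


class InterpolationError(ValueError):
    """Raised when a curve has too few points to fit."""


@dataclass
class RecoveryCurve:
    """Cumulative true-covariation count over the top-ranked pairs."""

    x: np.ndarray  # rank index, 1-based
    y: np.ndarray  # cumulative truth counts
    ideal: bool = False


@dataclass
class ContactRecallCurve:
    """Percentage of sub-cutoff contact pairs captured in the top-k pairs."""

    x: np.ndarray  # normalized pair count; 100 = one pair per residue
    y: np.ndarray  # percent of all (filtered) contacts captured
    separation: int = 0


def _scores_of(m: CoevolutionMatrix | np.ndarray) -> np.ndarray:
    return m.scores if isinstance(m, CoevolutionMatrix) else np.asarray(m)


def ranked_pairs(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs in descending score order, ties by (i, j)."""
    n = scores.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = scores[iu, ju]
    order = np.lexsort((ju, iu, -vals))  # primary key: -score
    return iu[order], ju[order]


def recovery_curve(
    method: CoevolutionMatrix | np.ndarray, truth: np.ndarray
) -> RecoveryCurve:
    """Cumulative covarion-count recovery of a method's pair ranking."""
    scores = _scores_of(method)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError(
            f"method shape {scores.shape} != truth shape {truth.shape}"
        )
    i_idx, j_idx = ranked_pairs(scores)
    y = np.cumsum(truth[i_idx, j_idx])
    return RecoveryCurve(x=np.arange(1, len(y) + 1), y=y, ideal=False)


def ideal_curve(truth: np.ndarray) -> RecoveryCurve:
    """Upper bound: the truth counts accumulated in their own descending order."""
    truth = np.asarray(truth)
    iu = np.triu_indices(truth.shape[0], 1)
    vals = np.sort(truth[iu])[::-1]
    y = np.cumsum(vals)
    return RecoveryCurve(x=np.arange(1, len(y) + 1), y=y, ideal=True)


def contact_recall(
    method: CoevolutionMatrix | np.ndarray,
    contacts: ContactMap | np.ndarray,
    separation: int = 0,
    max_pairs: int | None = None,
) -> ContactRecallCurve:
    """Recall of close contacts among the top-ranked pairs.

    ``separation`` is the minimum number of intervening sequence positions:
    only pairs with ``|i - j| > separation`` enter both the ranking and the
    contact denominator.  ``max_pairs`` defaults to the number of positions,
    so x = 100 corresponds to one ranked pair per residue.
    """
    scores = _scores_of(method)
    cmap = contacts.contacts if isinstance(contacts, ContactMap) else np.asarray(contacts)
    if scores.shape != cmap.shape:
        raise ValueError(f"score shape {scores.shape} != contact shape {cmap.shape}")
    n = scores.shape[0]
    if max_pairs is None:
        max_pairs = n

    i_idx, j_idx = ranked_pairs(scores)
    keep = (j_idx - i_idx) > separation
    i_idx, j_idx = i_idx[keep], j_idx[keep]
    iu, ju = np.triu_indices(n, 1)
    sep_ok = (ju - iu) > separation
    n_contacts = int(cmap[iu[sep_ok], ju[sep_ok]].sum())
    if n_contacts == 0:
        raise UndefinedRecallError(
            f"no contacts left with separation > {separation}"
        )
    k = min(max_pairs, len(i_idx))
    hits = np.cumsum(cmap[i_idx[:k], j_idx[:k]])
    x = 100.0 * np.arange(1, k + 1) / n
    y = 100.0 * hits / n_contacts
    return ContactRecallCurve(x=x, y=y, separation=separation)


def merge_curves(
    curves: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average curves on a common normalized grid.

    Each curve's x axis is normalized to [0, 1] (so curves spanning different
    pair counts are stretched to the same length), fitted with a
    shape-preserving PCHIP interpolant, and resampled on ``n_grid`` points.

    Returns
    -------
    (grid, mean, spread)
        The normalized grid, the pointwise mean and the pointwise standard
        deviation across curves.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to merge")
    resampled = []
    grid = np.linspace(0.0, 1.0, n_grid)
    for x, y in curves:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 4:
            raise InterpolationError("each curve needs at least 4 points")
        span = x[-1] - x[0]
        if span <= 0:
            raise InterpolationError("curve x values must be increasing")
        xn = (x - x[0]) / span
        resampled.append(PchipInterpolator(xn, y)(grid))
    stack = np.stack(resampled)
    return grid, stack.mean(axis=0), stack.std(axis=0)
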