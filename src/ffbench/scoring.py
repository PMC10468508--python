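"""Cross-ensemble normalisation, multiplicative combination and ranking.

Raw scores of the three measures live on incommensurable scales (inverse
Z-scores, log-likelihoods, correlation coefficients), so each measure is
min–max rescaled across the compared force fields:

    S_norm = (S_raw − min) / (max − min),   then floored at 0.00001,

mapping the best force field to exactly 1 and the worst to the floor.  A
small positive floor (rather than 0) keeps multiplicative combination from
annihilating every other measure's information for the worst performer.
Composite scores are entrywise products of normalised components,
optionally re-normalised; the final three-measure score is the bare
product, ranked descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Floor assigned to the minimum after min-max rescaling.
NORM_FLOOR = 1e-5


@dataclass(frozen=True)
class ScoreVector:
    """Per-force-field values of one measure."""

    values: dict  # label -> float
    measure: str = ""

    def __post_init__(self) -> None:
        vals = {str(k): float(v) for k, v in self.values.items()}
        if any(not np.isfinite(v) for v in vals.values()):
            raise ValueError(f"non-finite score in measure {self.measure!r}")
        object.__setattr__(self, "values", vals)

    @property
    def labels(self) -> tuple:
        return tuple(self.values)

    def array(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = labels or self.labels
        return np.array([self.values[l] for l in labels])


def minmax_normalize(
    scores: ScoreVector,
    floor: float = NORM_FLOOR,
    subtract_min: bool = True,
) -> ScoreVector:
    """Min-max rescale a score vector across force fields.

    The default subtractive form (S−min)/(max−min) maps the maximum to 1
    and the minimum to ``floor``.  ``subtract_min=False`` gives the plain
    range-division variant S/(max−min) instead (kept for comparison; it
    does not bound the result at 1).
    """
    arr = scores.array()
    if arr.size < 2:
        raise ValueError("normalization needs at least 2 force fields")
    rng = arr.max() - arr.min()
    if rng == 0:
        raise ValueError("all raw scores equal: min-max normalization undefined")
    norm = (arr - arr.min()) / rng if subtract_min else arr / rng
    norm = np.maximum(norm, floor)
    return ScoreVector(values=dict(zip(scores.labels, norm)), measure=scores.measure)


def combine_product(
    normalized: Sequence[ScoreVector],
    renormalize: bool = False,
    measure: str = "composite",
) -> ScoreVector:
    """Entrywise product of normalised score vectors over a shared label set."""
    if not normalized:
        raise ValueError("nothing to combine")
    labels = set(normalized[0].labels)
    for v in normalized[1:]:
        if set(v.labels) != labels:
            raise ValueError("score vectors cover different force fields")
    labels = list(normalized[0].labels)
    prod = np.prod([v.array(labels) for v in normalized], axis=0)
    out = ScoreVector(values=dict(zip(labels, prod)), measure=measure)
    if renormalize:
        out = minmax_normalize(out)
    return out


def rank_descending(scores: ScoreVector) -> dict:
    """1-based ranks by descending score; ties keep first-seen order."""
    labels = list(scores.labels)
    order = sorted(range(len(labels)), key=lambda k: -scores.values[labels[k]])
    ranks = {}
    for r, k in enumerate(order, start=1):
        ranks[labels[k]] = r
    return ranks


def final_score(
    rg_norm: ScoreVector,
    ssp_norm: ScoreVector,
    mcc_norm: ScoreVector,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Combine the three normalised measure scores into the final ranking.

    The final score is the bare product of the three normalised components
    (``renormalize=True`` re-runs min-max on the products instead).
    Returns a DataFrame sorted by rank with columns rg_score, ssp_score,
    contact_map_score, final_score, rank.
    """
    combined = combine_product(
        [rg_norm, ssp_norm, mcc_norm], renormalize=renormalize, measure="final")
    ranks = rank_descending(combined)
    labels = sorted(combined.labels, key=lambda l: ranks[l])
    return pd.DataFrame(
        {
            "rg_score": [rg_norm.values[l] for l in labels],
            "ssp_score": [ssp_norm.values[l] for l in labels],
            "contact_map_score": [mcc_norm.values[l] for l in labels],
            "final_score": [combined.values[l] for l in labels],
            "rank": [ranks[l] for l in labels],
        },
        index=pd.Index(labels, name="force_field"),
    )
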