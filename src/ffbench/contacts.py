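"""Intra- and inter-peptide contact maps, confusion matrices and MCC.

A contact is any heavy-atom pair within a distance cutoff (default 5 Å,
inclusive).  Intra-peptide maps live on the pair universe {(i, j): j ≥ i+2}
— sequence neighbours are excluded — which has N(N−1)/2 − (N−1) pairs
(105 for the 16-residue peptide).  Ensemble maps are scored against a
reference structure's boolean map by accumulating every
(snapshot × peptide × pair) instance into a confusion matrix and computing
the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which is in [−1, 1] and penalises non-native contacts as well as missing
native ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import TrimerView

DEFAULT_CUTOFF = 5.0  # Å, inclusive
DEFAULT_MIN_FREQ = 0.01  # contact frequencies below 1% are zeroed


@dataclass(frozen=True)
class PairUniverse:
    """Eligible intra-peptide residue pairs: (i, j), 1-based, j ≥ i + 2."""

    n_residues: int
    pairs: tuple = field(init=False)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        pairs = tuple(
            (i, j)
            for i in range(1, self.n_residues + 1)
            for j in range(i + 2, self.n_residues + 1)
        )
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def index(self) -> dict:
        return {p: k for k, p in enumerate(self.pairs)}


def eligible_pairs(n_residues: int) -> PairUniverse:
    """All residue pairs at sequence separation ≥ 2 within one peptide."""
    return PairUniverse(n_residues)


@dataclass
class ContactMap:
    """Values over a pair universe.

    ``kind`` is one of ``snapshot`` (boolean, one peptide, one frame),
    ``frequency`` (ensemble fraction in [0, 1]) or ``reference`` (boolean,
    from an experimental structure, with per-contact atom-class labels).
    """

    universe: PairUniverse
    values: np.ndarray
    kind: str = "snapshot"
    contact_class: np.ndarray | None = None  # "Sc-Sc" | "Sc-Bb" | "Bb-Bb" | ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.universe),):
            raise ValueError("values must align with the pair universe")

    @property
    def n_contacts(self) -> int:
        return int(np.count_nonzero(self.values))

    def medium_distance_pairs(self) -> list:
        """Contacted pairs with sequence separation > 5 (j > i + 5)."""
        return [
            p for p, v in zip(self.universe.pairs, self.values)
            if v and p[1] - p[0] > 5
        ]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN as percentages of all classified instances."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        # entries rounded to two decimals (as in published tables) may be
        # off by up to 4 * 0.005 in the sum
        total = self.tp + self.fp + self.fn + self.tn
        if abs(total - 100.0) > 0.02:
            raise ValueError(f"confusion percentages sum to {total}, expected 100")
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion entries must be non-negative")

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ConfusionMatrix":
        total = tp + fp + fn + tn
        if total == 0:
            raise ValueError("empty confusion matrix")
        return cls(*(100.0 * np.array([tp, fp, fn, tn]) / total))


@dataclass(frozen=True)
class OligomerState:
    """Oligomeric classification of one snapshot with pairwise contact counts."""

    state: str  # "monomer" | "dimer" | "trimer"
    pairwise_contacts: dict  # {(0,1): count, (0,2): count, (1,2): count}


# ---------------------------------------------------------------------------
# distance machinery


def _residue_min_distances(view: TrimerView, peptide_a: int, peptide_b: int) -> np.ndarray:
    """(N, N) matrix of minimum heavy-atom distances between residues of two
    peptides (peptide_a == peptide_b gives the intra-peptide matrix)."""
    n = view.n_residues
    mask_a = view.peptide_mask(peptide_a) & view.is_heavy
    mask_b = view.peptide_mask(peptide_b) & view.is_heavy
    res_a = view.residue_index[mask_a] - 1
    res_b = view.residue_index[mask_b] - 1
    d = cdist(view.coords[mask_a], view.coords[mask_b])
    out = np.full((n, n), np.inf)
    ra = np.repeat(res_a, len(res_b))
    rb = np.tile(res_b, len(res_a))
    np.minimum.at(out, (ra, rb), d.ravel())
    return out


def snapshot_contact_map(
    view: TrimerView, peptide_index: int, cutoff: float = DEFAULT_CUTOFF
) -> ContactMap:
    """Boolean intra-peptide contact map of one peptide in one snapshot."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    universe = eligible_pairs(view.n_residues)
    dmat = _residue_min_distances(view, peptide_index, peptide_index)
    values = np.array([dmat[i - 1, j - 1] <= cutoff for i, j in universe.pairs])
    return ContactMap(universe=universe, values=values, kind="snapshot")


def ensemble_contact_frequencies(
    per_peptide_maps: Sequence[Sequence[ContactMap]],
    min_freq: float = DEFAULT_MIN_FREQ,
) -> ContactMap:
    """Average contact frequencies across peptides, after per-peptide filtering.

    ``per_peptide_maps[k]`` holds peptide k's boolean maps over all
    snapshots.  Frequencies below ``min_freq`` are zeroed per peptide
    before the three peptides are averaged.
    """
    if not per_peptide_maps or not per_peptide_maps[0]:
        raise ValueError("need at least one snapshot per peptide")
    universe = per_peptide_maps[0][0].universe
    freqs = []
    for maps in per_peptide_maps:
        stack = np.array([m.values for m in maps], dtype=float)
        f = stack.mean(axis=0)
        f[f < min_freq] = 0.0
        freqs.append(f)
    return ContactMap(universe=universe, values=np.mean(freqs, axis=0), kind="frequency")


def reference_contact_map(
    view: TrimerView, peptide_index: int, cutoff: float = DEFAULT_CUTOFF
) -> ContactMap:
    """Boolean reference map with side-chain/backbone contact classes.

    A contact is Bb-Bb if some backbone–backbone atom pair is within the
    cutoff, Sc-Sc if only side-chain–side-chain pairs are, Sc-Bb otherwise
    (classes are assigned by which atom classes achieve a within-cutoff
    pair, preferring the most specific description: both, mixed, or
    side-chain only).
    """
    base = snapshot_contact_map(view, peptide_index, cutoff)
    pmask = view.peptide_mask(peptide_index) & view.is_heavy
    coords = view.coords[pmask]
    res = view.residue_index[pmask]
    bb = view.is_backbone[pmask]
    classes = []
    for (i, j), v in zip(base.universe.pairs, base.values):
        if not v:
            classes.append("")
            continue
        ai = res == i
        aj = res == j
        d = cdist(coords[ai], coords[aj]) <= cutoff
        bi = bb[ai][:, None]
        bj = bb[aj][None, :]
        has_bbbb = bool(np.any(d & bi & bj))
        has_scsc = bool(np.any(d & ~bi & ~bj))
        has_mix = bool(np.any(d & (bi ^ bj)))
        if has_bbbb:
            classes.append("Bb-Bb")
        elif has_mix:
            classes.append("Sc-Bb")
        elif has_scsc:
            classes.append("Sc-Sc")
        else:  # unreachable: v implies some pair within cutoff
            classes.append("Sc-Sc")
    return ContactMap(
        universe=base.universe, values=base.values,
        kind="reference", contact_class=np.array(classes),
    )


def accumulate_confusion(
    snapshot_maps: Iterable[ContactMap], reference: ContactMap
) -> ConfusionMatrix:
    """Pool every (snapshot × peptide × pair) instance against a reference.

    Replicas and peptides are pooled, not averaged: pass all their boolean
    maps in one stream.
    """
    ref = np.asarray(reference.values, bool)
    tp = fp = fn = tn = 0
    n_pairs = len(reference.universe)
    for m in snapshot_maps:
        if len(m.universe) != n_pairs or m.universe.pairs != reference.universe.pairs:
            raise ValueError("snapshot map universe differs from the reference universe")
        pred = np.asarray(m.values, bool)
        tp += int(np.count_nonzero(pred & ref))
        fp += int(np.count_nonzero(pred & ~ref))
        fn += int(np.count_nonzero(~pred & ref))
        tn += int(np.count_nonzero(~pred & ~ref))
    return ConfusionMatrix.from_counts(tp, fp, fn, tn)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when a marginal is degenerate."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if min(factors) <= 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(np.prod(factors)))


# ---------------------------------------------------------------------------
# inter-peptide analysis


def _inter_contact_matrix(view: TrimerView, pa: int, pb: int,
                          cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """(N, N) boolean: residue i of peptide pa within cutoff of j of pb."""
    return _residue_min_distances(view, pa, pb) <= cutoff


def oligomer_state(view: TrimerView, cutoff: float = DEFAULT_CUTOFF) -> OligomerState:
    """Classify a snapshot as monomer, dimer or trimer.

    Two peptides are in contact if any heavy-atom pair is within the
    cutoff.  No contacting pair → monomer; exactly one → dimer; every
    peptide touching at least one other → trimer.  (Two contacting pairs
    already connect all three peptides.)
    """
    counts = {}
    for pa, pb in ((0, 1), (0, 2), (1, 2)):
        counts[(pa, pb)] = int(np.count_nonzero(_inter_contact_matrix(view, pa, pb, cutoff)))
    n_touching = sum(1 for c in counts.values() if c > 0)
    state = {0: "monomer", 1: "dimer"}.get(n_touching, "trimer")
    return OligomerState(state=state, pairwise_contacts=counts)


def middle_peptide_index(view: TrimerView, cutoff: float = DEFAULT_CUTOFF,
                         state: OligomerState | None = None) -> int:
    """Peptide with the most inter-peptide residue-pair contacts.

    In a fibril-like trimer this is the structurally middle peptide.  Ties
    break to the lowest index.  Undefined for monomers.
    """
    if state is None:
        state = oligomer_state(view, cutoff)
    if state.state == "monomer":
        raise ValueError("middle peptide is undefined for a monomer snapshot")
    totals = [0, 0, 0]
    for (pa, pb), c in state.pairwise_contacts.items():
        totals[pa] += c
        totals[pb] += c
    return int(np.argmax(totals))  # argmax breaks ties to the lowest index


def inter_reference_map(view: TrimerView, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Reference inter-peptide map from a fibril structure: (N, N) boolean.

    Rows are residues of the middle peptide (the most-connected one), columns
    residues of its lowest-index edge neighbour, matching the orientation in
    which trajectory middle–edge maps are scored.
    """
    mid = middle_peptide_index(view, cutoff)
    edge = min(p for p in range(3) if p != mid)
    return _inter_contact_matrix(view, mid, edge, cutoff)


def inter_confusion(
    snapshots: Iterable[TrimerView],
    reference_ab: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[ConfusionMatrix, float]:
    """Score middle↔edge inter-peptide maps against a reference chain pair.

    Per snapshot: trimers contribute both middle–edge maps scored against
    the reference; any contact between the two edge peptides is counted as
    an additional false positive.  Dimers score their contacting pair (the
    more-connected peptide playing the middle role); the pairs involving
    the free peptide enter as all-negative predictions, as do all three
    pairs of a monomer snapshot, so that every snapshot contributes to the
    denominator.
    """
    ref = np.asarray(reference_ab, bool)
    tp = fp = fn = tn = 0

    def score(pred: np.ndarray) -> None:
        nonlocal tp, fp, fn, tn
        tp += int(np.count_nonzero(pred & ref))
        fp += int(np.count_nonzero(pred & ~ref))
        fn += int(np.count_nonzero(~pred & ref))
        tn += int(np.count_nonzero(~pred & ~ref))

    none = np.zeros_like(ref, dtype=bool)
    for view in snapshots:
        state = oligomer_state(view, cutoff)
        if state.state == "monomer":
            for _ in range(3):
                score(none)
            continue
        mid = middle_peptide_index(view, cutoff, state)
        others = [p for p in range(3) if p != mid]
        if state.state == "trimer":
            for edge in others:
                score(_inter_contact_matrix(view, mid, edge, cutoff))
            # edge-edge contacts are non-fibrillar by construction: FPs only
            fp += int(np.count_nonzero(
                _inter_contact_matrix(view, others[0], others[1], cutoff)))
        else:  # dimer
            partner = max(
                others,
                key=lambda p: state.pairwise_contacts[(min(mid, p), max(mid, p))],
            )
            free = [p for p in others if p != partner][0]
            score(_inter_contact_matrix(view, mid, partner, cutoff))
            score(none)  # mid-free
            score(none)  # partner-free
    cm = ConfusionMatrix.from_counts(tp, fp, fn, tn)
    return cm, mcc(cm)
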