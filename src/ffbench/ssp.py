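"""Three-state secondary structure and propensity-likelihood scoring.

Per snapshot every residue is labelled H (α-helix), E (β-strand) or C
(coil), either by the built-in simplified Kabsch–Sander assigner or by
parsing external DSSP output.  Labels are accumulated into per-residue
propensities p_{i,ss} over the ensemble (all three peptides pooled), and an
ensemble is scored against a reference structure's labels by the
log-likelihood

    SSP-Score_k = Σ_i ln p_{i, ss=ref_{k,i}}     (≤ 0),

i.e. the probability of drawing the experimental secondary structure
residue-by-residue from the simulated propensities, assuming positional
independence.  Zero propensities are floored at ``epsilon`` so a single
never-observed state does not produce −inf.

The built-in assigner follows the Kabsch–Sander electrostatic model:
backbone hydrogen bond energy

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332  kcal/mol,

a bond when E < −0.5 kcal/mol; helices from runs of i→i+4 turns, strands
from parallel/antiparallel bridge patterns (intra- or inter-peptide),
everything else coil.  It is deliberately 3-state: 3₁₀/π helices, isolated
bridges, turns and bends all map to coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import TrimerView

STATES = ("H", "E", "C")
HBOND_ENERGY_CUTOFF = -0.5   # kcal/mol
KS_PREFACTOR = 0.084 * 332.0  # kcal·Å/mol
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class SSAssignmentSeries:
    """Labels indexed (residue, peptide, snapshot): array of 'H'/'E'/'C'."""

    labels: np.ndarray  # (n_residues, 3, n_snapshots)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or labels.shape[1] != 3:
            raise ValueError("labels must have shape (n_residues, 3, n_snapshots)")
        if not np.all(np.isin(labels, STATES)):
            raise ValueError("labels must be one of H/E/C")
        object.__setattr__(self, "labels", labels)

    @property
    def n_residues(self) -> int:
        return self.labels.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.labels.shape[2]


@dataclass(frozen=True)
class PropensityTable:
    """p[i, s]: probability of state STATES[s] at residue i (0-based row)."""

    p: np.ndarray  # (n_residues, 3)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("propensity table must be (n_residues, 3)")
        if np.any(p < 0):
            raise ValueError("propensities must be non-negative")
        object.__setattr__(self, "p", p)

    @property
    def n_residues(self) -> int:
        return self.p.shape[0]


# ---------------------------------------------------------------------------
# geometric assignment


def _reconstruct_amide_h(n_pos, ca_pos, c_prev_pos):
    """Place the amide hydrogen on the N–H bisector, 1.01 Å from N."""
    u1 = n_pos - c_prev_pos
    u1 /= np.linalg.norm(u1)
    u2 = n_pos - ca_pos
    u2 /= np.linalg.norm(u2)
    u = u1 + u2
    u /= np.linalg.norm(u)
    return n_pos + 1.01 * u


def _backbone_table(view: TrimerView) -> dict:
    """Per (peptide, residue): positions of N, CA, C, O and reconstructed H."""
    table = {}
    for pep in range(3):
        for res in range(1, view.n_residues + 1):
            idx = view.residue_atoms(pep, res)
            names = view.names[idx]
            pos = {}
            for want in ("N", "CA", "C", "O"):
                hit = idx[names == want]
                if hit.size == 0:
                    raise ValueError(
                        f"peptide {pep} residue {res} lacks backbone atom {want}")
                pos[want] = view.coords[hit[0]]
            h_hit = idx[np.isin(names, ("H", "HN"))]
            if h_hit.size:
                pos["H"] = view.coords[h_hit[0]]
            table[(pep, res)] = pos
    # reconstruct missing amide hydrogens (needs previous residue's C)
    for (pep, res), pos in table.items():
        if "H" not in pos and (pep, res - 1) in table:
            pos["H"] = _reconstruct_amide_h(
                pos["N"], pos["CA"], table[(pep, res - 1)]["C"])
    return table


def _hbond_energy(donor: dict, acceptor: dict) -> float:
    """Kabsch–Sander electrostatic energy of donor N–H ... O=C acceptor."""
    if "H" not in donor:
        return 0.0
    r_on = np.linalg.norm(acceptor["O"] - donor["N"])
    r_ch = np.linalg.norm(acceptor["C"] - donor["H"])
    r_oh = np.linalg.norm(acceptor["O"] - donor["H"])
    r_cn = np.linalg.norm(acceptor["C"] - donor["N"])
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing/overlapping: not a bond
        return 0.0
    return KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(view: TrimerView) -> np.ndarray:
    """3-state labels, shape (n_residues, 3), one column per peptide.

    Hydrogen bonds are evaluated between every residue pair (within and
    across peptides) whose N–O distance is under 5.2 Å, self and sequence
    neighbours excluded.  Terminal residues without the needed partners
    default to C.
    """
    n = view.n_residues
    table = _backbone_table(view)
    keys = [(pep, res) for pep in range(3) for res in range(1, n + 1)]
    pos_n = np.array([table[k]["N"] for k in keys])
    pos_o = np.array([table[k]["O"] for k in keys])
    # candidate donor->acceptor pairs by N..O proximity
    from scipy.spatial.distance import cdist

    close = cdist(pos_n, pos_o) < 5.2
    hbond = set()
    for di, dk in enumerate(keys):
        for ai, ak in enumerate(keys):
            if not close[di, ai]:
                continue
            if dk[0] == ak[0] and abs(dk[1] - ak[1]) <= 1:
                continue
            if _hbond_energy(table[dk], table[ak]) < HBOND_ENERGY_CUTOFF:
                hbond.add((dk, ak))  # N-H of dk donates to C=O of ak

    def hb(d, a):
        return (d, a) in hbond

    labels = np.full((n, 3), "C", dtype="<U1")

    # helices: turn(t) := NH(t+4) -> CO(t); two consecutive turns make
    # residues t+1..t+4 helical
    for pep in range(3):
        turns = [hb((pep, t + 4), (pep, t)) for t in range(1, n - 3)]
        for k, t in enumerate(range(1, n - 3)):
            if turns[k] and k + 1 < len(turns) and turns[k + 1]:
                for r in range(t + 1, t + 5):
                    labels[r - 1, pep] = "H"

    # strands: Kabsch-Sander bridge patterns; i, j non-adjacent in sequence
    def bridge(pi, i, pj, j):
        a, b = (pi, i), (pj, j)
        par = (hb((pi, i), (pj, j - 1)) and hb((pj, j + 1), (pi, i))) or \
              (hb((pj, j), (pi, i - 1)) and hb((pi, i + 1), (pj, j)))
        anti = (hb(a, b) and hb(b, a)) or \
               (hb((pi, i - 1), (pj, j + 1)) and hb((pj, j - 1), (pi, i + 1)))
        return par or anti

    for pi in range(3):
        for pj in range(pi, 3):
            for i in range(1, n + 1):
                j_start = i + 3 if pi == pj else 1
                for j in range(j_start, n + 1):
                    if bridge(pi, i, pj, j):
                        if labels[i - 1, pi] != "H":
                            labels[i - 1, pi] = "E"
                        if labels[j - 1, pj] != "H":
                            labels[j - 1, pj] = "E"
    return labels


def assign_series(snapshots: Sequence[TrimerView]) -> SSAssignmentSeries:
    """Run the assigner over an ensemble, stacking into a label series."""
    stacks = [assign_secondary_structure(v) for v in snapshots]
    return SSAssignmentSeries(labels=np.stack(stacks, axis=2))


# ---------------------------------------------------------------------------
# DSSP output parsing

_DSSP_TO_3STATE = {"H": "H", "E": "E"}  # everything else (G, I, B, T, S, ' ') -> C


def parse_dssp_output(path: str | Path, n_residues: int | None = None) -> np.ndarray:
    """Parse a classic DSSP text output into 3-state labels per chain.

    Returns an array of shape (n_residues, n_chains) with H/E/C.  The
    8-state codes collapse as H→H, E→E, all others→C.  Chain breaks
    ('!' rows) separate chains.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ValueError(f"{path} does not look like DSSP output (no '#  RESIDUE' header)")
    chains: list[list[str]] = [[]]
    for ln in lines[start + 1:]:
        if len(ln) > 13 and ln[13] == "!":  # chain break
            if chains[-1]:
                chains.append([])
            continue
        if len(ln) < 17:
            continue
        code = ln[16]
        chains[-1].append(_DSSP_TO_3STATE.get(code, "C"))
    chains = [c for c in chains if c]
    if not chains:
        raise ValueError(f"no residues parsed from {path}")
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError(f"chains have differing lengths {sorted(lengths)} in {path}")
    if n_residues is not None and lengths != {n_residues}:
        raise ValueError(
            f"expected {n_residues} residues per chain, found {lengths.pop()} in {path}")
    return np.array(chains).T  # (n_residues, n_chains)


# ---------------------------------------------------------------------------
# propensities and scoring


def propensity_table(series: SSAssignmentSeries, per_residue: bool = True) -> PropensityTable:
    """Per-residue state propensities, pooling the three peptides.

    With ``per_residue`` (default) each row is normalised by its own count
    (3 · n_snapshots) and sums to 1.  With ``per_residue=False`` the grand
    total over all residues and states is used instead, so every row sums
    to 1/n_residues; the two conventions shift the log-likelihood score of
    every ensemble by the same additive constant and are equivalent after
    min–max normalisation.
    """
    counts = np.stack(
        [(series.labels == s).sum(axis=(1, 2)) for s in STATES], axis=1
    ).astype(float)
    if per_residue:
        denom = counts.sum(axis=1, keepdims=True)
    else:
        denom = counts.sum()
    return PropensityTable(p=counts / denom)


def consensus_reference_ss(models: Sequence[Sequence[str]]) -> np.ndarray:
    """Per-residue majority vote across reference models; ties → C."""
    arr = np.asarray(models)
    if arr.ndim == 1:
        arr = arr[None, :]
    out = []
    for col in arr.T:
        votes = {s: int(np.count_nonzero(col == s)) for s in STATES}
        best = max(votes.values())
        winners = [s for s in STATES if votes[s] == best]
        out.append(winners[0] if len(winners) == 1 else "C")
    return np.array(out)


def ssp_score(
    table: PropensityTable,
    reference: Sequence[str],
    epsilon: float = DEFAULT_EPSILON,
    log_base: float | None = None,
) -> float:
    """Log-likelihood of the reference labels under the ensemble propensities.

    Natural log by default; ``log_base`` rescales all ensembles' scores by
    the same positive constant and therefore does not affect normalised
    scores.  Always ≤ 0 for per-residue propensities; 0 iff the propensity
    is 1 at every reference label.
    """
    reference = np.asarray(reference)
    if reference.shape[0] != table.n_residues:
        raise ValueError("reference length does not match the propensity table")
    state_idx = {s: k for k, s in enumerate(STATES)}
    ref_idx = np.array([state_idx[s] for s in reference])
    probs = np.maximum(table.p[np.arange(table.n_residues), ref_idx], epsilon)
    total = float(np.sum(np.log(probs)))
    if log_base is not None:
        total /= np.log(log_base)
    return total
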