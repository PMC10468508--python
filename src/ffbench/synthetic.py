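"""Synthetic trimer ensembles with the statistical structure the analysis
pipeline assumes.

Real benchmarking inputs are MD trajectories; this module builds stand-in
ensembles good enough to exercise every estimator: snapshots mix a compact
hairpin-trimer template (fibril-like, "U-like"), an extended-strand
template ("L-like") and self-avoiding random coils, with isotropic
Gaussian coordinate noise.  Peptides carry the 16-residue R2-FUS-LC
sequence (residues 50–65 of the FUS low-complexity domain) as backbone
N/CA/C/O plus a Cβ pseudo-side-chain for non-glycine residues — no
physical realism beyond self-avoidance is attempted.

Alongside the geometric generator there are direct statistical samplers
(Rg mixtures, secondary-structure label series, contact series with
prescribed sensitivity/specificity) with closed-form expectations, so each
scoring stage can be validated against an analytic oracle.

All randomness flows from one seed through a fixed spawning scheme
(:func:`child_rngs`), so partial pipelines are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .contacts import ContactMap, PairUniverse
from .io import EnsembleSource, TrimerView, write_ensemble_pdb
from .rg import flory_rg
from .ssp import STATES, PropensityTable, SSAssignmentSeries

#: The 16-residue R2 peptide sequence (one-letter).
R2_SEQUENCE = "YGQSSYSSYGQSQNTG"

_THREE = {
    "Y": "TYR", "G": "GLY", "Q": "GLN", "S": "SER", "N": "ASN", "T": "THR",
}
_MASS = {"N": 14.007, "C": 12.011, "O": 15.999}

# idealized backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

_SEED_COMPONENTS = ("states", "noise", "coil", "rg", "ss", "contacts")


def child_rngs(seed: int) -> dict:
    """Expand one global seed into named per-component generators.

    Children are spawned from ``np.random.SeedSequence(seed)`` in the
    fixed order states, noise, coil, rg, ss, contacts.
    """
    children = np.random.SeedSequence(seed).spawn(len(_SEED_COMPONENTS))
    return {name: np.random.Generator(np.random.PCG64(c))
            for name, c in zip(_SEED_COMPONENTS, children)}


# ---------------------------------------------------------------------------
# backbone construction


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension-reference-frame placement of the next atom."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.cos(chi) * np.sin(theta),
                  bond * np.sin(chi) * np.sin(theta)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi: Sequence[float], psi: Sequence[float],
                   omega: float = 180.0) -> dict:
    """Build idealized backbone coordinates from (φ, ψ) dihedrals.

    Returns arrays N, CA, C, O of shape (n_residues, 3).  φ of the first
    residue and ψ of the last only orient terminal atoms.
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed the first residue explicitly
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        # carbonyl O is anti to the next amide N (torsion ψ+180 about CA-C)
        tor = psi[i] + 180.0
        O[i] = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, tor)
    return {"N": N, "CA": CA, "C": C, "O": O}


def _virtual_cb(n, ca, c):
    """Cβ position from backbone frame (standard virtual-Cβ construction)."""
    b1 = ca - n
    b2 = c - ca
    nv = np.cross(b1, b2)
    return -0.58273431 * nv + 0.56802827 * b1 - 0.54067466 * b2 + ca


def peptide_atoms(backbone: dict, sequence: str = R2_SEQUENCE) -> dict:
    """Expand a backbone dict into flat per-atom arrays (with Cβ for non-Gly)."""
    coords, names, elements, masses, resid, resname = [], [], [], [], [], []
    n_res = backbone["N"].shape[0]
    if len(sequence) != n_res:
        raise ValueError("sequence length must match the backbone")
    for i in range(n_res):
        atom_list = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        pos = {k: backbone[k][i] for k in ("N", "CA", "C", "O")}
        if sequence[i] != "G":
            pos["CB"] = _virtual_cb(pos["N"], pos["CA"], pos["C"])
            atom_list.append(("CB", "C"))
        for name, element in atom_list:
            coords.append(pos[name])
            names.append(name)
            elements.append(element)
            masses.append(_MASS[element])
            resid.append(i + 1)
            resname.append(_THREE[sequence[i]])
    return {
        "coords": np.array(coords), "names": np.array(names),
        "elements": np.array(elements), "masses": np.array(masses),
        "residue_index": np.array(resid), "resnames": np.array(resname),
    }


def _assemble_trimer(peptides: Sequence[dict], source_label: str,
                     model_index: int = 0) -> TrimerView:
    cols = {k: np.concatenate([p[k] for p in peptides])
            for k in ("coords", "names", "elements", "masses",
                      "residue_index", "resnames")}
    pep_idx = np.concatenate(
        [np.full(len(p["names"]), k) for k, p in enumerate(peptides)])
    chain_ids = np.concatenate(
        [np.full(len(p["names"]), c) for c, p in zip("ABC", peptides)])
    return TrimerView(
        coords=cols["coords"], elements=cols["elements"], names=cols["names"],
        masses=cols["masses"], residue_index=cols["residue_index"],
        peptide_index=pep_idx, chain_ids=chain_ids, resnames=cols["resnames"],
        orig_resseq=cols["residue_index"] + 49,  # author numbering 50..65
        source_label=source_label, model_index=model_index,
    )


def _translated(peptide: dict, offset) -> dict:
    out = dict(peptide)
    out["coords"] = peptide["coords"] + np.asarray(offset, float)
    return out


# ---------------------------------------------------------------------------
# templates

#: Cross-β stacking distance between sheets (Å).
STACK_DISTANCE = 4.8


def _orient_principal(peptide: dict) -> dict:
    """Rotate a peptide into its principal frame (flattest direction → z).

    Stacking flattened copies along z mimics the cross-β arrangement:
    within-sheet atoms stay near one plane, so adjacent sheets touch but
    next-nearest ones do not.
    """
    coords = peptide["coords"]
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    out = dict(peptide)
    out["coords"] = centred @ vt.T  # columns ordered by decreasing variance
    return out


def u_template() -> TrimerView:
    """Compact β-hairpin trimer: strands 1–7 and 10–16 joined by a type-I′
    turn, three copies stacked 4.8 Å apart along the fibril axis."""
    phi = [-135.0] * 7 + [60.0, 90.0] + [-135.0] * 7
    psi = [135.0] * 7 + [30.0, 0.0] + [135.0] * 7
    bb = build_backbone(phi, psi)
    pep = _orient_principal(peptide_atoms(bb))
    peps = [_translated(pep, (0.0, 0.0, k * STACK_DISTANCE)) for k in range(3)]
    return _assemble_trimer(peps, "u_template")


def l_template() -> TrimerView:
    """Extended-strand trimer with a single mid-chain bend, stacked 4.8 Å
    apart; substantially larger Rg than the hairpin template."""
    phi = [-135.0] * 8 + [-75.0] + [-135.0] * 7
    psi = [135.0] * 8 + [-30.0] + [135.0] * 7
    bb = build_backbone(phi, psi)
    pep = _orient_principal(peptide_atoms(bb))
    peps = [_translated(pep, (0.0, 0.0, k * STACK_DISTANCE)) for k in range(3)]
    return _assemble_trimer(peps, "l_template")


#: Random-coil (φ, ψ) basins: (weight, φ mean, φ sd, ψ mean, ψ sd).
_COIL_BASINS = (
    (0.45, -120.0, 25.0, 130.0, 20.0),   # β
    (0.35, -75.0, 15.0, 145.0, 15.0),    # polyproline II
    (0.20, -65.0, 15.0, -40.0, 15.0),    # α
)

#: Acceptance band on end-to-end CA distance, as multiples of the Flory Rg.
#: A Gaussian chain has Ree ≈ √6·Rg; the band brackets that ratio.
_REE_BAND = (1.6, 3.4)


def coil_backbone(rng: np.random.Generator, n_res: int = 16,
                  max_tries: int = 500) -> dict:
    """Self-avoiding random-coil backbone targeting Flory dimensions.

    Dihedrals are drawn per residue from coil basins; a conformation is
    accepted when no two CA atoms at sequence separation ≥ 3 clash
    (< 4 Å) and the end-to-end CA distance falls in a band around the
    Gaussian-chain expectation √6·R0·N^ν, which biases accepted coils
    toward Flory statistics.
    """
    target = np.sqrt(6.0) * flory_rg(n_res)
    lo, hi = _REE_BAND[0] / np.sqrt(6.0) * target, _REE_BAND[1] / np.sqrt(6.0) * target
    weights = np.array([b[0] for b in _COIL_BASINS])
    for _ in range(max_tries):
        basins = rng.choice(len(_COIL_BASINS), size=n_res, p=weights)
        phi = np.array([rng.normal(_COIL_BASINS[b][1], _COIL_BASINS[b][2]) for b in basins])
        psi = np.array([rng.normal(_COIL_BASINS[b][3], _COIL_BASINS[b][4]) for b in basins])
        bb = build_backbone(phi, psi)
        ca = bb["CA"]
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
        sep = np.abs(np.arange(n_res)[:, None] - np.arange(n_res)[None, :])
        if np.any(d[sep >= 3] < 4.0):
            continue
        ree = np.linalg.norm(ca[-1] - ca[0])
        if lo <= ree <= hi:
            return bb
    raise RuntimeError(f"coil generation failed after {max_tries} attempts")


def coil_trimer(rng: np.random.Generator) -> TrimerView:
    """Three independent coils placed far apart (monomeric snapshot)."""
    offsets = ((0.0, 0.0, 0.0), (40.0, 0.0, 0.0), (0.0, 40.0, 0.0))
    peps = [_translated(peptide_atoms(coil_backbone(rng)), off) for off in offsets]
    return _assemble_trimer(peps, "coil")


# ---------------------------------------------------------------------------
# ensemble generation


@dataclass
class EnsembleSpec:
    """Recipe for one synthetic ensemble.

    ``state_weights`` mixes (U-like, L-like, coil) snapshots;
    ``coordinate_noise_sd`` is the isotropic Gaussian jitter in Å.
    """

    n_snapshots: int = 200
    state_weights: tuple = (0.4, 0.3, 0.3)
    coordinate_noise_sd: float = 0.3
    seed: int = 0
    label: str = "synthetic"
    time_per_frame: float = 20.0  # ps
    discard_initial: float = 0.0  # ns

    def __post_init__(self) -> None:
        w = np.asarray(self.state_weights, float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("state_weights must be 3 non-negative numbers summing to 1")
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")


def make_trimer_ensemble(spec: EnsembleSpec) -> EnsembleSource:
    """Generate a synthetic trimer ensemble snapshot-by-snapshot.

    Deterministic for a given ``spec.seed``.  Template-state snapshots are
    the (fixed) U/L templates plus noise; coil snapshots are fresh
    self-avoiding walks plus noise.
    """
    rngs = child_rngs(spec.seed)
    templates = (u_template(), l_template())
    states = rngs["states"].choice(3, size=spec.n_snapshots, p=spec.state_weights)
    snapshots = []
    for t, s in enumerate(states):
        base = templates[s] if s < 2 else coil_trimer(rngs["coil"])
        coords = base.coords.copy()
        if spec.coordinate_noise_sd > 0:
            coords = coords + rngs["noise"].normal(
                0.0, spec.coordinate_noise_sd, size=coords.shape)
        snapshots.append(TrimerView(
            coords=coords, elements=base.elements, names=base.names,
            masses=base.masses, residue_index=base.residue_index,
            peptide_index=base.peptide_index, chain_ids=base.chain_ids,
            resnames=base.resnames, orig_resseq=base.orig_resseq,
            source_label=spec.label, model_index=t + 1,
        ))
    return EnsembleSource(
        snapshots=snapshots, replica_id=0,
        time_per_frame=spec.time_per_frame,
        discard_initial=spec.discard_initial,
    )


def write_fixture(spec: EnsembleSpec, path: str | Path) -> EnsembleSource:
    """Generate an ensemble and write it as a multi-model PDB fixture."""
    source = make_trimer_ensemble(spec)
    write_ensemble_pdb(source.snapshots, path)
    return source


# ---------------------------------------------------------------------------
# direct statistical samplers


def sample_rg_mixture(weights: Sequence[float], means: Sequence[float],
                      sds: Sequence[float], n: int, seed: int) -> np.ndarray:
    """I.i.d. draws from a Gaussian mixture (component per draw)."""
    rng = child_rngs(seed)["rg"]
    weights = np.asarray(weights, float)
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    return rng.normal(np.asarray(means, float)[comp], np.asarray(sds, float)[comp])


def sample_ss_series(table: PropensityTable, n_snapshots: int, seed: int,
                     n_peptides: int = 3) -> SSAssignmentSeries:
    """Independent per-(residue, peptide, snapshot) draws from p_{i,ss}."""
    rng = child_rngs(seed)["ss"]
    n_res = table.n_residues
    p = table.p / table.p.sum(axis=1, keepdims=True)
    labels = np.empty((n_res, n_peptides, n_snapshots), dtype="<U1")
    for i in range(n_res):
        draws = rng.choice(3, size=(n_peptides, n_snapshots), p=p[i])
        labels[i] = np.array(STATES)[draws]
    return SSAssignmentSeries(labels=labels)


def sample_contact_series(reference: ContactMap, sensitivity: float,
                          specificity: float, n_snapshots: int,
                          seed: int) -> list[ContactMap]:
    """Boolean contact maps with prescribed per-pair detection rates.

    Each reference-positive pair is in contact with probability
    ``sensitivity`` and each reference-negative pair with probability
    1 − ``specificity``, independently per snapshot.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    rng = child_rngs(seed)["contacts"]
    ref = np.asarray(reference.values, bool)
    p_contact = np.where(ref, sensitivity, 1.0 - specificity)
    out = []
    for _ in range(n_snapshots):
        vals = rng.random(len(ref)) < p_contact
        out.append(ContactMap(universe=reference.universe, values=vals, kind="snapshot"))
    return out


def analytic_mcc(sensitivity: float, specificity: float, prevalence: float) -> float:
    """MCC at the expected confusion matrix for given detection rates.

    Expected fractions: TP = π·sens, FN = π·(1−sens), TN = (1−π)·spec,
    FP = (1−π)·(1−spec) with π the reference contact prevalence.
    """
    tp = prevalence * sensitivity
    fn = prevalence * (1.0 - sensitivity)
    tn = (1.0 - prevalence) * specificity
    fp = (1.0 - prevalence) * (1.0 - specificity)
    factors = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if factors <= 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(factors))
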