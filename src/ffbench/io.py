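"""Reading, selecting and streaming trimer snapshots.

Conformational ensembles are exchanged as multi-model PDB files (one MODEL
per snapshot); reference structures are ordinary (possibly multi-model) PDB
entries.  Everything downstream operates on :class:`TrimerView` — the heavy
and hydrogen atoms of three peptides of equal length, with 1-based residue
numbering inside the selected window.

Coordinates are in Å throughout.  Hydrogens are kept in the arrays but
flagged ``is_heavy=False`` and excluded from every distance and Rg
computation by the analysis modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O")


class SelectionError(ValueError):
    """A requested chain/residue window is absent from the structure."""


class FormatError(ValueError):
    """The input file could not be parsed as a structure."""


@dataclass(frozen=True)
class Atom:
    """One atom of a peptide, in the selected window's 1-based numbering."""

    element: str
    name: str
    coords: np.ndarray  # (3,) Å
    mass: float
    residue_index: int  # 1..n_residues within the peptide
    chain_id: str

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES


@dataclass
class TrimerView:
    """Atoms of three equal-length peptides at a single time point.

    Stored as flat parallel arrays for speed; ``peptide_index`` is 0..2 and
    ``residue_index`` is 1..n_residues inside each peptide.  ``orig_resseq``
    keeps the author residue numbers so a window can be re-selected.
    """

    coords: np.ndarray        # (n_atoms, 3) float64, Å
    elements: np.ndarray      # (n_atoms,) str
    names: np.ndarray         # (n_atoms,) str
    masses: np.ndarray        # (n_atoms,) float64, amu
    residue_index: np.ndarray  # (n_atoms,) int, 1-based within peptide
    peptide_index: np.ndarray  # (n_atoms,) int, 0..2
    chain_ids: np.ndarray     # (n_atoms,) str
    resnames: np.ndarray      # (n_atoms,) str
    orig_resseq: np.ndarray | None = None
    source_label: str = ""
    model_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        n_pep = len(np.unique(self.peptide_index))
        if n_pep != 3:
            raise SelectionError(f"a trimer view needs exactly 3 peptides, got {n_pep}")
        counts = {
            int(p): len(np.unique(self.residue_index[self.peptide_index == p]))
            for p in np.unique(self.peptide_index)
        }
        if len(set(counts.values())) != 1:
            raise SelectionError(f"peptides have unequal residue counts: {counts}")

    # -- basic queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        """Residues per peptide."""
        return len(np.unique(self.residue_index[self.peptide_index == 0]))

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def is_backbone(self) -> np.ndarray:
        return np.isin(self.names, BACKBONE_NAMES)

    def peptide_mask(self, k: int) -> np.ndarray:
        return self.peptide_index == k

    def residue_atoms(self, peptide: int, residue: int) -> np.ndarray:
        """Indices of the atoms of one residue."""
        return np.flatnonzero((self.peptide_index == peptide) & (self.residue_index == residue))

    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                element=str(self.elements[i]),
                name=str(self.names[i]),
                coords=self.coords[i],
                mass=float(self.masses[i]),
                residue_index=int(self.residue_index[i]),
                chain_id=str(self.chain_ids[i]),
            )


@dataclass
class EnsembleSource:
    """One replica of an ensemble: an ordered snapshot sequence plus timing.

    ``time_per_frame`` is in ps and ``discard_initial`` in ns, matching the
    usual bookkeeping of production MD runs whose initial segment is treated
    as equilibration and dropped.
    """

    snapshots: Sequence[TrimerView]
    replica_id: int = 0
    time_per_frame: float = 20.0   # ps
    discard_initial: float = 0.0   # ns

    def __post_init__(self) -> None:
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be >= 0")


def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name
    return name if name else "X"


def read_structure(
    path: str | Path,
    chains: Sequence[str] | None = None,
    first_residue: int | None = None,
    length: int | None = None,
    source_label: str = "",
) -> list[TrimerView]:
    """Read a (multi-model) PDB file into one TrimerView per MODEL.

    ``chains`` defaults to the first three chains of the first model.  If
    ``first_residue``/``length`` are given, only that residue window is kept
    and renumbered 1..length; otherwise each chain must already have a
    common residue count.  Altloc duplicates keep the highest-occupancy
    conformer (ties: first encountered).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    st.setup_entities()

    if chains is None:
        chains = [ch.name for ch in st[0]][:3]
    if len(chains) != 3:
        raise SelectionError(f"need exactly 3 chains, got {list(chains)}")

    views = []
    for m_idx, model in enumerate(st):
        cols: dict[str, list] = {k: [] for k in (
            "coords", "elements", "names", "masses", "residue_index",
            "peptide_index", "chain_ids", "resnames", "orig_resseq")}
        model_chains = {ch.name: ch for ch in model}
        for pep_idx, cname in enumerate(chains):
            if cname not in model_chains:
                raise SelectionError(f"chain {cname!r} missing from model {m_idx + 1} of {path}")
            residues = [r for r in model_chains[cname] if not r.is_water()]
            by_seq = {r.seqid.num: r for r in residues}
            if first_residue is not None:
                if length is None or length < 1:
                    raise SelectionError("length must be >= 1 when first_residue is given")
                wanted = list(range(first_residue, first_residue + length))
                missing = [s for s in wanted if s not in by_seq]
                if missing:
                    raise SelectionError(
                        f"chain {cname!r} lacks residues {missing} in model {m_idx + 1}")
                selected = [(i + 1, by_seq[s]) for i, s in enumerate(wanted)]
            else:
                selected = [(i + 1, r) for i, r in enumerate(residues)]
            for new_idx, res in selected:
                for atom in _dedup_altlocs(res):
                    cols["coords"].append([atom.pos.x, atom.pos.y, atom.pos.z])
                    cols["elements"].append(_element_of(atom))
                    cols["names"].append(atom.name)
                    cols["masses"].append(atom.element.weight)
                    cols["residue_index"].append(new_idx)
                    cols["peptide_index"].append(pep_idx)
                    cols["chain_ids"].append(cname)
                    cols["resnames"].append(res.name)
                    cols["orig_resseq"].append(res.seqid.num)
        views.append(TrimerView(
            coords=np.array(cols["coords"], dtype=float),
            elements=np.array(cols["elements"]),
            names=np.array(cols["names"]),
            masses=np.array(cols["masses"], dtype=float),
            residue_index=np.array(cols["residue_index"], dtype=int),
            peptide_index=np.array(cols["peptide_index"], dtype=int),
            chain_ids=np.array(cols["chain_ids"]),
            resnames=np.array(cols["resnames"]),
            orig_resseq=np.array(cols["orig_resseq"], dtype=int),
            source_label=source_label or path.stem,
            model_index=m_idx + 1,
        ))
    return views


def _dedup_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> first."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order
    seen = set()
    out = []
    for atom in res:
        if atom.name not in seen and best[atom.name] is atom:
            seen.add(atom.name)
            out.append(atom)
        elif atom.name not in seen and best[atom.name] is not atom:
            seen.add(atom.name)
            out.append(best[atom.name])
    return out


def select_peptides(view: TrimerView, first_residue: int, length: int) -> TrimerView:
    """Restrict a view to a residue window and renumber it 1..length.

    The window is interpreted in the view's original author numbering when
    available (``orig_resseq``), else in the current 1-based numbering, so
    re-applying the same window is a no-op.
    """
    if length < 1:
        raise SelectionError("window length must be >= 1")
    numbering = view.orig_resseq if view.orig_resseq is not None else view.residue_index
    wanted = np.arange(first_residue, first_residue + length)
    mask = np.isin(numbering, wanted)
    for pep in range(3):
        present = np.unique(numbering[(view.peptide_index == pep) & mask])
        missing = sorted(set(wanted.tolist()) - set(present.tolist()))
        if missing:
            raise SelectionError(f"peptide {pep} lacks residues {missing} of the window")
    new_resseq = numbering[mask]
    return TrimerView(
        coords=view.coords[mask].copy(),
        elements=view.elements[mask].copy(),
        names=view.names[mask].copy(),
        masses=view.masses[mask].copy(),
        residue_index=(new_resseq - first_residue + 1).astype(int),
        peptide_index=view.peptide_index[mask].copy(),
        chain_ids=view.chain_ids[mask].copy(),
        resnames=view.resnames[mask].copy(),
        orig_resseq=new_resseq.astype(int).copy(),
        source_label=view.source_label,
        model_index=view.model_index,
    )


def iterate_snapshots(sources: EnsembleSource | Iterable[EnsembleSource]) -> Iterator[TrimerView]:
    """Yield analysis-ready snapshots: initial segment discarded, replicas
    concatenated in replica order, frame order preserved within a replica.

    Frame k (0-based) of a replica is taken to be at time (k+1)·Δt with Δt
    = ``time_per_frame``, so discarding D ns removes exactly D/Δt frames.
    """
    if isinstance(sources, EnsembleSource):
        sources = [sources]
    sources = sorted(sources, key=lambda s: s.replica_id)
    yielded = 0
    for src in sources:
        n_discard = int(round(src.discard_initial * 1000.0 / src.time_per_frame))
        kept = len(src.snapshots) - n_discard
        logger.info("replica %d: %d frames, discarding %d, keeping %d",
                    src.replica_id, len(src.snapshots), n_discard, max(kept, 0))
        for snap in list(src.snapshots)[n_discard:]:
            yielded += 1
            yield snap
    if yielded == 0:
        raise ValueError("no snapshots remain after discarding the initial segment")


def write_ensemble_pdb(views: Sequence[TrimerView], path: str | Path) -> None:
    """Write views as a multi-model PDB (one MODEL per view)."""
    st = gemmi.Structure()
    st.name = views[0].source_label or "ensemble"
    for m_idx, view in enumerate(views):
        model = gemmi.Model(m_idx + 1)
        serial = 1
        for pep in range(3):
            chain_name = str(view.chain_ids[view.peptide_index == pep][0])
            chain = gemmi.Chain(chain_name)
            pmask = view.peptide_index == pep
            resseq = view.orig_resseq if view.orig_resseq is not None else view.residue_index
            for r in np.unique(view.residue_index[pmask]):
                idx = np.flatnonzero(pmask & (view.residue_index == r))
                res = gemmi.Residue()
                res.name = str(view.resnames[idx[0]])
                res.seqid = gemmi.SeqId(int(resseq[idx[0]]), " ")
                for i in idx:
                    atom = gemmi.Atom()
                    atom.name = str(view.names[i])
                    atom.element = gemmi.Element(str(view.elements[i]))
                    atom.pos = gemmi.Position(*view.coords[i])
                    atom.occ = 1.0
                    atom.serial = serial
                    serial += 1
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
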