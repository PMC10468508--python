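"""Radius-of-gyration measures and the three raw Rg scores.

An ensemble is summarised by the heavy-atom Rg of the trimer and of each
individual peptide per snapshot.  The trimer Rg distribution, which is
typically bimodal (compact fibril-like vs extended states), is fitted with
a two-component Gaussian mixture; closeness to an experimental reference Rg
is scored as the inverse of the smallest |Z| over the two components:

    Z_i = (Rg_ref − μ_i) / σ_i,        score = 1 / min_i |Z_i|

Peptide-level compactness is compared to the Flory random-coil expectation
Rg_FL = R0·N^ν (R0 = 2.54 Å, ν = 0.522, parameters optimised for
disordered proteins), scored as IQR / |Rg_FL − median|: an ensemble whose
median sits on the coil prediction and which fluctuates broadly scores
high, a rigid or displaced one scores low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .io import TrimerView

#: Flory parameters for intrinsically disordered chains.
FLORY_R0 = 2.54   # Å, persistence length
FLORY_NU = 0.522  # scaling exponent

#: |Z| below this is treated as an exact hit; scores are capped at 1/ZERO_TOL.
ZERO_TOL = 1e-8
SCORE_CAP = 1e8


@dataclass(frozen=True)
class RgSample:
    """Rg values (Å) for one ensemble, at trimer or single-peptide level."""

    values: np.ndarray
    level: str = "trimer"  # "trimer" | "peptide"
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.level not in ("trimer", "peptide"):
            raise ValueError(f"unknown level {self.level!r}")
        if np.any(self.values <= 0):
            raise ValueError("Rg values must be positive")


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.asarray(self.sds, float) <= 0):
            raise ValueError("mixture SDs must be positive")


@dataclass(frozen=True)
class RgReferences:
    """Reference Rg values (Å): experimental U- and L-shaped, Flory coil."""

    rg_u: float = 10.0
    rg_l: float = 14.4
    r0: float = FLORY_R0
    nu: float = FLORY_NU
    n_residues: int = 16

    @property
    def rg_fl(self) -> float:
        return flory_rg(self.n_residues, self.r0, self.nu)


def compute_rg(
    coords: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration of a point set.

    Rg = sqrt( Σ m_a |r_a − r_com|² / Σ m_a ), with r_com the
    (mass-weighted) centroid.  Pass pre-filtered heavy-atom coordinates;
    see :func:`trimer_rg` / :func:`peptide_rg` for TrimerView front-ends.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("no atoms to compute Rg over")
    if masses is None or not mass_weighted:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def trimer_rg(view: TrimerView, heavy_only: bool = True, mass_weighted: bool = True) -> float:
    """Heavy-atom Rg of all three peptides together (Å)."""
    mask = view.is_heavy if heavy_only else np.ones(view.n_atoms, bool)
    return compute_rg(view.coords[mask], view.masses[mask], mass_weighted)


def peptide_rg(view: TrimerView, peptide: int, heavy_only: bool = True,
               mass_weighted: bool = True) -> float:
    """Heavy-atom Rg of a single peptide (Å)."""
    mask = view.peptide_mask(peptide)
    if heavy_only:
        mask = mask & view.is_heavy
    return compute_rg(view.coords[mask], view.masses[mask], mass_weighted)


def flory_rg(n_residues: int, r0: float = FLORY_R0, nu: float = FLORY_NU) -> float:
    """Flory power-law Rg prediction R0·N^ν for an N-residue coil (Å)."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return r0 * n_residues ** nu


def fit_rg_mixture(
    sample: RgSample,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
) -> MixtureFit:
    """EM fit of a 2-component Gaussian mixture to an Rg sample.

    Deterministic for a given seed; components are reported sorted by
    ascending mean so the compact state always comes first.
    """
    values = sample.values
    if values.size < 10:
        raise ValueError("need at least 10 Rg values to fit a mixture")
    if np.ptp(values) == 0:
        raise ValueError(
            "degenerate (constant) Rg sample: a two-component mixture is undefined")
    gm = GaussianMixture(
        n_components=2, covariance_type="full",
        n_init=n_init, tol=tol, random_state=seed,
    ).fit(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
    )


def reference_rg_score(fit: MixtureFit, ref_rg: float) -> float:
    """Raw reference-Rg score: 1 / min_i |(ref − μ_i)/σ_i|, capped at 1e8."""
    z = (ref_rg - np.asarray(fit.means)) / np.asarray(fit.sds)
    z_star = float(np.min(np.abs(z)))
    if z_star < ZERO_TOL:
        return SCORE_CAP
    return 1.0 / z_star


def unfolded_rg_score(peptide_sample: RgSample, rg_fl: float) -> float:
    """Raw unfolded-Rg score: IQR / |Rg_FL − median| on peptide-level Rg.

    Percentiles use linear interpolation.  A median exactly at the Flory
    prediction yields the cap; a constant sample yields 0.
    """
    if peptide_sample.level != "peptide":
        raise ValueError("unfolded score is defined on peptide-level Rg samples")
    values = peptide_sample.values
    if values.size < 4:
        raise ValueError("need at least 4 peptide Rg values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    denom = abs(rg_fl - med)
    if denom < ZERO_TOL:
        return SCORE_CAP
    return float((q3 - q1) / denom)
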