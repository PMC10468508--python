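"""Shared fixtures: templates, small synthetic ensembles, reference files.

Everything is generated programmatically; session scope keeps the slower
geometric constructions to one evaluation per run.
"""

import numpy as np
import pytest

from ffbench.io import TrimerView, write_ensemble_pdb
from ffbench.synthetic import (
    EnsembleSpec, l_template, make_trimer_ensemble, u_template, write_fixture,
)


@pytest.fixture(scope="session")
def u_view():
    return u_template()


@pytest.fixture(scope="session")
def l_view():
    return l_template()


def jitter(view: TrimerView, sd: float, rng: np.random.Generator) -> TrimerView:
    """A noisy copy of a view (used to fake multi-model references)."""
    return TrimerView(
        coords=view.coords + rng.normal(0.0, sd, view.coords.shape),
        elements=view.elements, names=view.names, masses=view.masses,
        residue_index=view.residue_index, peptide_index=view.peptide_index,
        chain_ids=view.chain_ids, resnames=view.resnames,
        orig_resseq=view.orig_resseq, source_label=view.source_label,
        model_index=view.model_index,
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """A 30-snapshot mixed synthetic ensemble."""
    return make_trimer_ensemble(
        EnsembleSpec(n_snapshots=30, state_weights=(0.5, 0.3, 0.2), seed=7))


@pytest.fixture(scope="session")
def benchmark_files(tmp_path_factory, u_view, l_view):
    """Reference PDBs plus three biased ensembles written to disk."""
    root = tmp_path_factory.mktemp("bench")
    rng = np.random.default_rng(42)
    u_models = [jitter(u_view, 0.15, rng) for _ in range(5)]
    write_ensemble_pdb(u_models, root / "ref_u.pdb")
    write_ensemble_pdb([l_view], root / "ref_l.pdb")
    specs = {
        "ubias": EnsembleSpec(n_snapshots=40, state_weights=(0.8, 0.1, 0.1),
                              seed=11, label="ubias"),
        "lbias": EnsembleSpec(n_snapshots=40, state_weights=(0.1, 0.8, 0.1),
                              seed=12, label="lbias"),
        "coil": EnsembleSpec(n_snapshots=40, state_weights=(0.05, 0.05, 0.9),
                             seed=13, label="coil"),
    }
    force_fields = {}
    for label, spec in specs.items():
        path = root / f"{label}.pdb"
        write_fixture(spec, path)
        force_fields[label] = [str(path)]
    return {
        "root": root,
        "force_fields": force_fields,
        "reference_u": str(root / "ref_u.pdb"),
        "reference_l": str(root / "ref_l.pdb"),
    }
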