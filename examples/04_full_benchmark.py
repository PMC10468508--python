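"""End-to-end benchmark of three synthetic 'force fields'.

Generates a U-biased, an L-biased and a coil-dominated ensemble, writes
them (and reference structures) as multi-model PDB, and runs the full
three-measure pipeline to a ranked score table.
"""

import tempfile
from pathlib import Path

import numpy as np

from ffbench.io import TrimerView, write_ensemble_pdb
from ffbench.pipeline import BenchmarkConfig, run_benchmark
from ffbench.synthetic import EnsembleSpec, u_template, l_template, write_fixture

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    rng = np.random.default_rng(0)
    u = u_template()
    u_models = [TrimerView(
        coords=u.coords + rng.normal(0, 0.15, u.coords.shape),
        elements=u.elements, names=u.names, masses=u.masses,
        residue_index=u.residue_index, peptide_index=u.peptide_index,
        chain_ids=u.chain_ids, resnames=u.resnames, orig_resseq=u.orig_resseq)
        for _ in range(5)]
    write_ensemble_pdb(u_models, root / "ref_u.pdb")
    write_ensemble_pdb([l_template()], root / "ref_l.pdb")

    force_fields = {}
    for label, weights, seed in (("ubias", (0.8, 0.1, 0.1), 11),
                                 ("lbias", (0.1, 0.8, 0.1), 12),
                                 ("coil", (0.05, 0.05, 0.9), 13)):
        path = root / f"{label}.pdb"
        write_fixture(EnsembleSpec(n_snapshots=60, state_weights=weights,
                                   seed=seed, label=label), path)
        force_fields[label] = [str(path)]

    config = BenchmarkConfig(
        force_fields=force_fields,
        reference_u=str(root / "ref_u.pdb"),
        reference_l=str(root / "ref_l.pdb"),
    )
    tables = run_benchmark(config)

print("final ranking (bare product of the three normalised measures):")
print(tables["final"].to_string(float_format=lambda x: f"{x:.3g}"))
print("\nRg components (raw scores):")
print(tables["rg"][["raw_u", "raw_l", "raw_unfolded"]].round(3).to_string())
print("\nThe U-biased ensemble wins the U-shaped component and the contact-map"
      "\nMCC; the coil ensemble wins the Unfolded component, mirroring how"
      "\nforce fields with different conformational biases split the measures.")
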