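"""End-to-end benchmark orchestration and printed-table verification.

``run_benchmark`` takes a configuration naming per-force-field ensemble
files (multi-model PDB, optionally several replicas) and two reference
structures, runs the three measures per force field, normalises across
force fields and emits the score tables:

* ``rg``        — normalised U-shaped / L-shaped / Unfolded Rg scores and
                  their renormalised product (final Rg score);
* ``contact``   — raw intra-peptide MCC vs the U-shaped reference and its
                  normalised value, plus the confusion matrices;
* ``ssp``       — normalised U/L secondary-structure likelihood scores and
                  their renormalised product;
* ``final``     — the bare product of the three measure scores, ranked.

``verify_printed_tables`` is a self-contained regression harness over the
published benchmark tables (:mod:`ffbench.published`): it recomputes every
derivable printed value (MCC from the confusion matrices, normalised
columns from raw columns, combined scores from components) and reports the
deviations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import published
from .contacts import (
    ConfusionMatrix, accumulate_confusion, mcc, reference_contact_map,
    snapshot_contact_map,
)
from .io import EnsembleSource, TrimerView, iterate_snapshots, read_structure, select_peptides
from .rg import (
    RgSample, fit_rg_mixture, flory_rg, peptide_rg, reference_rg_score,
    trimer_rg, unfolded_rg_score,
)
from .scoring import ScoreVector, combine_product, final_score, minmax_normalize
from .ssp import (
    assign_secondary_structure, assign_series, consensus_reference_ss,
    parse_dssp_output, propensity_table, ssp_score,
)

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    """Everything one benchmark run needs; loadable from YAML."""

    force_fields: dict                      # label -> list of ensemble PDB paths (replicas)
    reference_u: str                        # multi-model PDB, compact fibril reference
    reference_l: str                        # PDB, extended fibril reference
    first_residue: int | None = None        # selection window (author numbering)
    window_length: int | None = None
    chains: tuple | None = None
    cutoff: float = 5.0                     # Å
    min_contact_freq: float = 0.01
    time_per_frame: float = 20.0            # ps
    discard_initial: float = 0.0            # ns
    reference_model_index: int = 1          # representative model for the contact reference
    mixture_seed: int = 0
    mixture_n_init: int = 10
    mixture_tol: float = 1e-6
    ss_source: str = "internal"             # "internal" | "dssp-files"
    dssp_files: dict = field(default_factory=dict)  # label -> list of DSSP outputs
    subtract_min: bool = True               # min-max normalisation variant
    renormalize_final: bool = False         # final score: bare product by default
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _load_reference_views(config: BenchmarkConfig):
    kw = {}
    if config.first_residue is not None:
        kw = dict(first_residue=config.first_residue, length=config.window_length)
    u_models = read_structure(config.reference_u, chains=config.chains, **kw)
    l_models = read_structure(config.reference_l, chains=config.chains, **kw)
    return u_models, l_models


def _load_snapshots(config: BenchmarkConfig, label: str) -> list[TrimerView]:
    sources = []
    for rid, path in enumerate(config.force_fields[label]):
        views = read_structure(path, chains=config.chains, source_label=label)
        if config.first_residue is not None:
            views = [select_peptides(v, config.first_residue, config.window_length)
                     for v in views]
        sources.append(EnsembleSource(
            snapshots=views, replica_id=rid,
            time_per_frame=config.time_per_frame,
            discard_initial=config.discard_initial,
        ))
    return list(iterate_snapshots(sources))


def _stage(name: str, label: str):
    """Context wrapper so failures name the stage and force field."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed for force field {label!r}: {exc}") from exc
    return _Ctx()


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Run the full multi-measure benchmark; returns the score tables.

    Returns a dict of DataFrames: ``rg``, ``contact``, ``ssp``, ``final``,
    ``confusion`` (plus per-force-field raw values inside each).  When
    ``config.output_dir`` is set, CSVs and a JSON manifest of all options
    are written there.
    """
    labels = list(config.force_fields)
    if len(labels) < 2:
        raise ValueError("benchmarking needs at least 2 force fields (normalization)")

    u_models, l_models = _load_reference_views(config)
    ref_u_rg = float(np.mean([trimer_rg(v) for v in u_models]))
    ref_l_rg = float(np.mean([trimer_rg(v) for v in l_models]))
    n_res = u_models[0].n_residues
    rg_fl = flory_rg(n_res)
    ref_map = reference_contact_map(
        u_models[config.reference_model_index - 1], 0, config.cutoff)
    ref_ss_u = consensus_reference_ss(
        [assign_secondary_structure(m)[:, 0] for m in u_models])
    ref_ss_l = consensus_reference_ss(
        [assign_secondary_structure(l_models[0])[:, 0]])
    logger.info("references: Rg_U=%.2f Å, Rg_L=%.2f Å, Rg_FL=%.2f Å, %d contacts",
                ref_u_rg, ref_l_rg, rg_fl, ref_map.n_contacts)

    raw: dict[str, dict[str, float]] = {m: {} for m in (
        "rg_u", "rg_l", "rg_unfolded", "mcc", "ssp_u", "ssp_l")}
    confusion_rows = {}
    for label in labels:
        with _stage("ensemble_io", label):
            snapshots = _load_snapshots(config, label)
        with _stage("rg_analysis", label):
            trimer = RgSample(np.array([trimer_rg(v) for v in snapshots]),
                              level="trimer", source_label=label)
            peptide = RgSample(
                np.array([peptide_rg(v, p) for v in snapshots for p in range(3)]),
                level="peptide", source_label=label)
            fit = fit_rg_mixture(trimer, seed=config.mixture_seed,
                                 n_init=config.mixture_n_init, tol=config.mixture_tol)
            raw["rg_u"][label] = reference_rg_score(fit, ref_u_rg)
            raw["rg_l"][label] = reference_rg_score(fit, ref_l_rg)
            raw["rg_unfolded"][label] = unfolded_rg_score(peptide, rg_fl)
        with _stage("contact_analysis", label):
            maps = [snapshot_contact_map(v, p, config.cutoff)
                    for v in snapshots for p in range(3)]
            cm = accumulate_confusion(maps, ref_map)
            confusion_rows[label] = cm
            raw["mcc"][label] = mcc(cm)
        with _stage("ssp_analysis", label):
            if config.ss_source == "dssp-files":
                files = config.dssp_files.get(label)
                if not files:
                    raise FileNotFoundError(f"no DSSP files configured for {label}")
                import numpy as _np
                stacks = [parse_dssp_output(f, n_residues=n_res) for f in files]
                from .ssp import SSAssignmentSeries
                series = SSAssignmentSeries(labels=_np.stack(stacks, axis=2))
            else:
                series = assign_series(snapshots)
            table = propensity_table(series)
            raw["ssp_u"][label] = ssp_score(table, ref_ss_u)
            raw["ssp_l"][label] = ssp_score(table, ref_ss_l)

    # normalisation and combination across force fields
    def norm(measure: str) -> ScoreVector:
        return minmax_normalize(
            ScoreVector(values=raw[measure], measure=measure),
            subtract_min=config.subtract_min)

    rg_components = [norm("rg_u"), norm("rg_l"), norm("rg_unfolded")]
    rg_final = combine_product(rg_components, renormalize=True, measure="rg")
    ssp_components = [norm("ssp_u"), norm("ssp_l")]
    ssp_final = combine_product(ssp_components, renormalize=True, measure="ssp")
    mcc_norm = norm("mcc")
    final = final_score(rg_final, ssp_final, mcc_norm,
                        renormalize=config.renormalize_final)

    tables = {
        "rg": pd.DataFrame({
            "raw_u": raw["rg_u"], "raw_l": raw["rg_l"],
            "raw_unfolded": raw["rg_unfolded"],
            "norm_u": rg_components[0].values, "norm_l": rg_components[1].values,
            "norm_unfolded": rg_components[2].values,
            "final_rg": rg_final.values,
        }).rename_axis("force_field"),
        "contact": pd.DataFrame({
            "raw_mcc": raw["mcc"], "norm_mcc": mcc_norm.values,
        }).rename_axis("force_field"),
        "ssp": pd.DataFrame({
            "raw_u": raw["ssp_u"], "raw_l": raw["ssp_l"],
            "norm_u": ssp_components[0].values, "norm_l": ssp_components[1].values,
            "final_ssp": ssp_final.values,
        }).rename_axis("force_field"),
        "final": final,
        "confusion": pd.DataFrame({
            label: {"TP": c.tp, "FP": c.fp, "FN": c.fn, "TN": c.tn}
            for label, c in confusion_rows.items()
        }).T.rename_axis("force_field"),
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}_scores.csv")
        manifest = asdict(config)
        manifest["references"] = {
            "rg_u": ref_u_rg, "rg_l": ref_l_rg, "rg_fl": rg_fl,
            "reference_contacts": ref_map.n_contacts,
            "reference_ss_u": "".join(ref_ss_u),
            "reference_ss_l": "".join(ref_ss_l),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return tables


# ---------------------------------------------------------------------------
# printed-table regression harness


def _sigfig(x: float, n: int = 3) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (n - 1))


def verify_printed_tables() -> pd.DataFrame:
    """Recompute every derivable published value and report deviations.

    Rows carry the check name, force-field label, recomputed and published
    values, the absolute deviation and the tolerance appropriate to the
    published precision.  All inputs are the embedded published tables;
    nothing is read from disk.
    """
    rows = []

    def add(check, label, computed, printed, tol):
        rows.append({
            "check": check, "force_field": label,
            "computed": computed, "published": printed,
            "abs_dev": abs(computed - printed), "tolerance": tol,
            "ok": abs(computed - printed) <= tol,
        })

    # confusion matrices -> raw MCC
    for label, (tp, fp, fn, tn) in published.CONFUSION_TABLE.items():
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        add("confusion_to_mcc", label, mcc(cm),
            published.MCC_TABLE[label][0], 0.005)

    # raw MCC column -> normalised contact-map score
    raw_mcc = ScoreVector(
        values={l: v[0] for l, v in published.MCC_TABLE.items()}, measure="mcc")
    norm = minmax_normalize(raw_mcc)
    for label, (_, printed) in published.MCC_TABLE.items():
        add("mcc_normalization", label, norm.values[label], printed, 1e-4)

    # Rg component columns -> combined Rg score
    comps = [ScoreVector(values={l: v[k] for l, v in published.RG_TABLE.items()},
                         measure=m)
             for k, m in enumerate(("rg_u", "rg_l", "rg_unfolded"))]
    combined = combine_product(comps, renormalize=True)
    for label, vals in published.RG_TABLE.items():
        add("rg_combination", label, combined.values[label], vals[3], 5e-4)

    # SSP component columns -> combined SSP score
    comps = [ScoreVector(values={l: v[k] for l, v in published.SSP_TABLE.items()},
                         measure=m)
             for k, m in enumerate(("ssp_u", "ssp_l"))]
    combined = combine_product(comps, renormalize=True)
    for label, vals in published.SSP_TABLE.items():
        add("ssp_combination", label, combined.values[label], vals[2], 5e-4)

    # final table: bare product of the three components, to 3 significant figures
    for label, (rg_n, ssp_n, cmap_n, final, _) in published.FINAL_TABLE.items():
        prod = _sigfig(rg_n * ssp_n * cmap_n, 3)
        add("final_product", label, prod, final, abs(final) * 5e-3 + 1e-15)

    # final ranking is the descending order of the products
    prods = {l: v[0] * v[1] * v[2] for l, v in published.FINAL_TABLE.items()}
    order = sorted(prods, key=lambda l: -prods[l])
    for rank, label in enumerate(order, start=1):
        add("final_rank", label, rank, published.FINAL_TABLE[label][4], 0)

    return pd.DataFrame(rows)
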