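"""Secondary-structure assignment, propensities and likelihood scoring."""

import numpy as np
import pytest

from ffbench.ssp import (
    PropensityTable, SSAssignmentSeries, assign_secondary_structure,
    consensus_reference_ss, parse_dssp_output, propensity_table, ssp_score,
)
from ffbench.scoring import ScoreVector, minmax_normalize
from ffbench.synthetic import R2_SEQUENCE, build_backbone, peptide_atoms, _assemble_trimer, _translated


def trimer_from_dihedrals(phi, psi, offset=60.0):
    """Three far-apart copies of one backbone (no inter-peptide H-bonds)."""
    pep = peptide_atoms(build_backbone(phi, psi))
    peps = [_translated(pep, (0, 0, 0)), _translated(pep, (offset, 0, 0)),
            _translated(pep, (0, offset, 0))]
    return _assemble_trimer(peps, "test")


class TestAssigner:
    def test_ideal_alpha_helix_interior_is_helical(self):
        view = trimer_from_dihedrals([-57.0] * 16, [-47.0] * 16)
        labels = assign_secondary_structure(view)
        for p in range(3):
            assert all(l == "H" for l in labels[2:14, p])

    def test_isolated_extended_chain_is_coil(self):
        view = trimer_from_dihedrals([-135.0] * 16, [135.0] * 16)
        labels = assign_secondary_structure(view)
        assert np.all(labels == "C")

    def test_stacked_extended_strands_form_sheet(self, l_view):
        # cross-beta stacking provides the inter-peptide hydrogen bonds
        labels = assign_secondary_structure(l_view)
        assert np.count_nonzero(labels == "E") > 0

    def test_missing_backbone_atom_raises(self, u_view):
        broken = u_view
        mask = ~((broken.names == "O") & (broken.residue_index == 5)
                 & (broken.peptide_index == 0))
        from ffbench.io import TrimerView
        view = TrimerView(
            coords=broken.coords[mask], elements=broken.elements[mask],
            names=broken.names[mask], masses=broken.masses[mask],
            residue_index=broken.residue_index[mask],
            peptide_index=broken.peptide_index[mask],
            chain_ids=broken.chain_ids[mask], resnames=broken.resnames[mask])
        with pytest.raises(ValueError, match="residue 5"):
            assign_secondary_structure(view)


class TestDsspParser:
    @staticmethod
    def _dssp_text(chain_codes):
        """Render a minimal classic DSSP output for given per-chain codes."""
        lines = ["==== Secondary Structure Definition ====", "HEADER",
                 "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC"]
        idx = 1
        for c, codes in enumerate(chain_codes):
            if c > 0:
                lines.append(f"{idx:5d}        !      ")
                idx += 1
            for r, code in enumerate(codes, start=50):
                lines.append(f"{idx:5d}{r:5d} {'ABC'[c]} {R2_SEQUENCE[r-50]}  {code}  ")
                idx += 1
        return "\n".join(lines) + "\n"

    def test_three_chain_grid_with_8_to_3_state_mapping(self, tmp_path):
        codes = ["H" * 5 + "G" + "E" * 5 + "T" + "S" + "B" + "I" + " ",
                 "E" * 16, "C" + "H" * 14 + "C"]
        path = tmp_path / "out.dssp"
        path.write_text(self._dssp_text(codes))
        labels = parse_dssp_output(path, n_residues=16)
        assert labels.shape == (16, 3)
        # H->H, E->E, everything else -> C
        assert "".join(labels[:, 0]) == "HHHHH" + "C" + "EEEEE" + "CCCCC"
        assert "".join(labels[:, 1]) == "E" * 16
        assert "".join(labels[:, 2]) == "C" + "H" * 14 + "C"

    def test_wrong_residue_count_raises(self, tmp_path):
        path = tmp_path / "short.dssp"
        path.write_text(self._dssp_text(["HHHH"]))
        with pytest.raises(ValueError):
            parse_dssp_output(path, n_residues=16)

    def test_non_dssp_file_raises(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text("not dssp\n")
        with pytest.raises(ValueError):
            parse_dssp_output(path)


class TestPropensities:
    def test_all_coil_series(self):
        series = SSAssignmentSeries(labels=np.full((16, 3, 5), "C"))
        table = propensity_table(series)
        assert np.allclose(table.p[:, 2], 1.0)

    def test_direct_counting_example(self):
        # residue seen H 3x, E 3x, C 6x over 12 instances -> (0.25, 0.25, 0.5)
        labels = np.array([["H", "E", "C", "C"]])[:, None, :].repeat(3, axis=1)
        table = propensity_table(SSAssignmentSeries(labels=labels))
        assert table.p[0] == pytest.approx([0.25, 0.25, 0.5])

    def test_rows_sum_to_one_and_counts_conserved(self):
        rng = np.random.default_rng(4)
        labels = np.array(["H", "E", "C"])[rng.integers(0, 3, size=(16, 3, 50))]
        series = SSAssignmentSeries(labels=labels)
        table = propensity_table(series)
        assert np.allclose(table.p.sum(axis=1), 1.0)
        counts = table.p * (3 * 50)
        assert np.allclose(counts.sum(axis=1), 3 * 50)

    def test_global_denominator_variant_rows_sum_to_one_over_n(self):
        labels = np.full((16, 3, 5), "E")
        table = propensity_table(SSAssignmentSeries(labels=labels), per_residue=False)
        assert np.allclose(table.p.sum(axis=1), 1.0 / 16)


class TestConsensus:
    def test_single_model_passes_through(self):
        ref = ["H"] * 8 + ["E"] * 8
        assert list(consensus_reference_ss([ref])) == ref

    def test_majority_vote(self):
        models = [["E"] * 16] * 12 + [["C"] * 16] * 8
        assert list(consensus_reference_ss(models)) == ["E"] * 16

    def test_tie_goes_to_coil(self):
        models = [["E"]] * 10 + [["H"]] * 10
        assert list(consensus_reference_ss(models)) == ["C"]


class TestSspScore:
    def test_certain_propensities_score_zero(self):
        p = np.zeros((16, 3))
        p[:, 1] = 1.0  # all E, certain
        score = ssp_score(PropensityTable(p=p), ["E"] * 16)
        assert score == 0.0

    def test_uniform_propensities_closed_form(self):
        p = np.full((16, 3), 1 / 3)
        score = ssp_score(PropensityTable(p=p), ["E"] * 16)
        assert score == pytest.approx(16 * np.log(1 / 3), abs=1e-9)

    def test_zero_propensity_floored_at_epsilon(self):
        p = np.zeros((2, 3))
        p[:, 2] = 1.0  # all coil
        score = ssp_score(PropensityTable(p=p), ["H", "C"], epsilon=1e-6)
        assert score == pytest.approx(np.log(1e-6) + 0.0)

    def test_score_is_nonpositive(self):
        rng = np.random.default_rng(9)
        p = rng.dirichlet(np.ones(3), size=16)
        score = ssp_score(PropensityTable(p=p), ["C"] * 16)
        assert score <= 0.0


class TestScoreInvariances:
    """Changing the log base or the propensity denominator must not change
    normalised scores across ensembles."""

    @staticmethod
    def _random_series(seed, n_snap=40):
        rng = np.random.default_rng(seed)
        labels = np.array(["H", "E", "C"])[rng.integers(0, 3, size=(16, 3, n_snap))]
        return SSAssignmentSeries(labels=labels)

    def test_log_base_invariance_after_normalization(self):
        ref = ["E"] * 8 + ["C"] * 8
        raws_ln, raws_log10 = {}, {}
        for k in range(4):
            table = propensity_table(self._random_series(k))
            raws_ln[f"ff{k}"] = ssp_score(table, ref)
            raws_log10[f"ff{k}"] = ssp_score(table, ref, log_base=10)
        n1 = minmax_normalize(ScoreVector(values=raws_ln, measure="ssp"))
        n2 = minmax_normalize(ScoreVector(values=raws_log10, measure="ssp"))
        for ff in raws_ln:
            assert n1.values[ff] == pytest.approx(n2.values[ff], abs=1e-12)

    def test_denominator_invariance_after_normalization(self):
        ref = ["H"] * 4 + ["E"] * 6 + ["C"] * 6
        raw_res, raw_glob = {}, {}
        for k in range(4):
            series = self._random_series(k + 10)
            raw_res[f"ff{k}"] = ssp_score(propensity_table(series), ref)
            raw_glob[f"ff{k}"] = ssp_score(
                propensity_table(series, per_residue=False), ref)
        # global denominator shifts every score by 16*ln(1/16)
        shift = 16 * np.log(1 / 16)
        for ff in raw_res:
            assert raw_glob[ff] - raw_res[ff] == pytest.approx(shift, abs=1e-9)
        n1 = minmax_normalize(ScoreVector(values=raw_res, measure="ssp"))
        n2 = minmax_normalize(ScoreVector(values=raw_glob, measure="ssp"))
        for ff in raw_res:
            assert n1.values[ff] == pytest.approx(n2.values[ff], abs=1e-12)
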