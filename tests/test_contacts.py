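"""Contact maps, confusion matrices, MCC, and oligomer classification."""

import numpy as np
import pytest

from ffbench.contacts import (
    ConfusionMatrix, accumulate_confusion, eligible_pairs,
    ensemble_contact_frequencies, inter_confusion, inter_reference_map, mcc,
    middle_peptide_index, oligomer_state, reference_contact_map,
    snapshot_contact_map, ContactMap,
)
from ffbench.io import TrimerView
from ffbench.synthetic import analytic_mcc, sample_contact_series


def make_view(peptide_coords, atoms_per_residue=2):
    """Assemble a TrimerView from per-peptide coordinate arrays.

    ``peptide_coords[k]`` has shape (n_residues * atoms_per_residue, 3);
    atoms are carbon, names CA then CB per residue.
    """
    coords, names, res, pep = [], [], [], []
    n_res = peptide_coords[0].shape[0] // atoms_per_residue
    for k, pc in enumerate(peptide_coords):
        for a, xyz in enumerate(pc):
            coords.append(xyz)
            names.append(["CA", "CB", "CG", "CD"][a % atoms_per_residue])
            res.append(a // atoms_per_residue + 1)
            pep.append(k)
    n = len(coords)
    return TrimerView(
        coords=np.array(coords), elements=np.full(n, "C"),
        names=np.array(names), masses=np.full(n, 12.011),
        residue_index=np.array(res), peptide_index=np.array(pep),
        chain_ids=np.array(["ABC"[p] for p in pep]),
        resnames=np.full(n, "ALA"),
    )


class TestEligiblePairs:
    @pytest.mark.parametrize("n,expected", [(16, 105), (3, 1), (2, 0), (10, 36)])
    def test_count_matches_enumeration(self, n, expected):
        uni = eligible_pairs(n)
        brute = [(i, j) for i in range(1, n + 1) for j in range(i + 2, n + 1)]
        assert len(uni) == expected == len(brute)
        assert list(uni.pairs) == brute

    def test_sixteen_residue_universe_excludes_neighbours(self):
        uni = eligible_pairs(16)
        assert all(j - i >= 2 for i, j in uni.pairs)


class TestSnapshotContactMap:
    def test_matches_brute_force_on_random_coordinates(self):
        rng = np.random.default_rng(17)
        pcs = [rng.uniform(0, 18, size=(32, 3)) for _ in range(3)]
        view = make_view(pcs)
        for pep in range(3):
            cmap = snapshot_contact_map(view, pep, cutoff=5.0)
            # brute force: all heavy-atom pair distances per residue pair
            coords = pcs[pep]
            for (i, j), v in zip(cmap.universe.pairs, cmap.values):
                ai = coords[(i - 1) * 2:(i - 1) * 2 + 2]
                aj = coords[(j - 1) * 2:(j - 1) * 2 + 2]
                dmin = min(np.linalg.norm(a - b) for a in ai for b in aj)
                assert bool(v) == (dmin <= 5.0), (i, j)

    def test_cutoff_is_inclusive_boundary(self):
        # residues 1 and 3 exactly 5.0 apart -> contact; 5.1 -> none
        for dist, expect in [(4.9, True), (5.0, True), (5.1, False)]:
            base = np.array(
                [[0, 0, 0], [0, 0, 0.1], [50, 0, 0], [50, 0, 0.1],
                 [dist, 0, 0], [dist, 0, 0.1]])
            pcs = [base, base + 200, base + 400]
            view = make_view(pcs)
            cmap = snapshot_contact_map(view, 0)
            idx = cmap.universe.index()[(1, 3)]
            assert bool(cmap.values[idx]) is expect


class TestEnsembleFrequencies:
    def _maps(self, frac, n_snap, universe_n=4):
        uni = eligible_pairs(universe_n)  # 3 pairs for n=4
        out = []
        for t in range(n_snap):
            vals = np.zeros(len(uni), bool)
            vals[0] = t < int(round(frac * n_snap))
            out.append(ContactMap(universe=uni, values=vals))
        return out

    def test_always_present_pair_has_frequency_one(self):
        maps = [self._maps(1.0, 10)] * 3
        freq = ensemble_contact_frequencies(maps)
        assert freq.values[0] == pytest.approx(1.0)

    def test_subthreshold_frequency_filtered_per_peptide(self):
        maps = [self._maps(0.005, 200)] * 3  # 0.5% in every peptide
        freq = ensemble_contact_frequencies(maps, min_freq=0.01)
        assert freq.values[0] == 0.0

    def test_average_across_peptides_after_filtering(self):
        maps = [self._maps(0.30, 100), self._maps(0.0, 100), self._maps(0.60, 100)]
        freq = ensemble_contact_frequencies(maps, min_freq=0.01)
        assert freq.values[0] == pytest.approx(0.30)


class TestReferenceContactMap:
    def test_template_contacts_are_labeled(self, u_view):
        ref = reference_contact_map(u_view, 0)
        assert ref.n_contacts > 0
        labels = set(ref.contact_class[np.asarray(ref.values, bool)])
        assert labels <= {"Sc-Sc", "Sc-Bb", "Bb-Bb"}
        assert ref.contact_class[~np.asarray(ref.values, bool)].tolist() == \
            [""] * (len(ref.universe) - ref.n_contacts)

    def test_hairpin_has_medium_distance_contacts_strand_does_not(self, u_view, l_view):
        assert len(reference_contact_map(u_view, 0).medium_distance_pairs()) > 0
        assert reference_contact_map(l_view, 0).medium_distance_pairs() == []

    def test_dispersed_structure_has_no_contacts(self):
        coords = np.arange(32)[:, None] * np.array([10.0, 0, 0])
        view = make_view([coords, coords + 1000, coords + 2000])
        assert reference_contact_map(view, 0).n_contacts == 0


class TestConfusion:
    def _reference(self, n_pos=20):
        uni = eligible_pairs(16)
        vals = np.zeros(105, bool)
        vals[:n_pos] = True
        return ContactMap(universe=uni, values=vals, kind="reference")

    def test_perfect_prediction_marginals(self):
        ref = self._reference()
        cm = accumulate_confusion([ref] * 12, ref)
        assert cm.tp == pytest.approx(100 * 20 / 105, abs=1e-9)
        assert cm.tn == pytest.approx(100 * 85 / 105, abs=1e-9)
        assert cm.fp == cm.fn == 0.0

    def test_empty_prediction_is_complement(self):
        ref = self._reference()
        empty = ContactMap(universe=ref.universe, values=np.zeros(105, bool))
        cm = accumulate_confusion([empty] * 5, ref)
        assert cm.fn == pytest.approx(100 * 20 / 105, abs=1e-9)
        assert cm.tn == pytest.approx(100 * 85 / 105, abs=1e-9)
        assert cm.tp == cm.fp == 0.0

    def test_saturated_prediction(self):
        ref = self._reference()
        full = ContactMap(universe=ref.universe, values=np.ones(105, bool))
        cm = accumulate_confusion([full] * 5, ref)
        assert cm.tp == pytest.approx(100 * 20 / 105, abs=1e-9)
        assert cm.fp == pytest.approx(100 * 85 / 105, abs=1e-9)

    def test_reference_marginal_is_trajectory_independent(self):
        # TP + FN always equals the reference prevalence (19.048% for 20/105)
        ref = self._reference()
        rng = np.random.default_rng(3)
        maps = [ContactMap(universe=ref.universe, values=rng.random(105) < 0.3)
                for _ in range(40)]
        cm = accumulate_confusion(maps, ref)
        assert cm.tp + cm.fn == pytest.approx(100 * 20 / 105, abs=1e-9)
        assert cm.tp + cm.fp + cm.fn + cm.tn == pytest.approx(100.0, abs=1e-9)

    def test_universe_mismatch_raises(self):
        ref = self._reference()
        other = ContactMap(universe=eligible_pairs(10),
                           values=np.zeros(36, bool))
        with pytest.raises(ValueError):
            accumulate_confusion([other], ref)


class TestMcc:
    def test_published_confusion_matrix_example(self):
        cm = ConfusionMatrix(tp=13.75, fp=3.52, fn=5.30, tn=77.43)
        assert mcc(cm) == pytest.approx(0.70418, abs=0.005)

    def test_perfect_agreement_is_one(self):
        assert mcc(ConfusionMatrix(tp=19.048, fp=0.0, fn=0.0, tn=80.952)) == \
            pytest.approx(1.0)

    def test_independent_prediction_is_zero(self):
        assert mcc(ConfusionMatrix(tp=9.52, fp=40.48, fn=9.52, tn=40.48)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_degenerate_marginal_returns_zero(self):
        assert mcc(ConfusionMatrix(tp=0.0, fp=0.0, fn=19.05, tn=80.95)) == 0.0

    def test_symmetric_in_prediction_and_reference_roles(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.dirichlet(np.ones(4)) * 100
            cm = ConfusionMatrix(tp=v[0], fp=v[1], fn=v[2], tn=v[3])
            swapped = ConfusionMatrix(tp=v[0], fp=v[2], fn=v[1], tn=v[3])
            assert mcc(cm) == pytest.approx(mcc(swapped), abs=1e-12)


class TestOligomerState:
    def _trimer_coords(self, gap_ab, gap_bc):
        """Three 4-residue peptides along x, with controllable gaps."""
        base = np.array([[i * 3.0, 0, 0] for i in range(8)])
        a = base
        b = base + np.array([0, gap_ab, 0])
        c = base + np.array([0, gap_ab + gap_bc, 0])
        return make_view([a, b, c])

    def test_all_far_apart_is_monomer(self):
        view = self._trimer_coords(50, 50)
        assert oligomer_state(view).state == "monomer"

    def test_one_contacting_pair_is_dimer(self):
        view = self._trimer_coords(4.0, 50)
        state = oligomer_state(view)
        assert state.state == "dimer"
        assert state.pairwise_contacts[(0, 1)] > 0
        assert state.pairwise_contacts[(1, 2)] == 0

    def test_chain_of_contacts_is_trimer(self):
        view = self._trimer_coords(4.0, 4.0)
        assert oligomer_state(view).state == "trimer"

    def test_middle_peptide_is_most_connected(self):
        view = self._trimer_coords(4.0, 4.0)
        assert middle_peptide_index(view) == 1

    def test_middle_peptide_undefined_for_monomer(self):
        view = self._trimer_coords(50, 50)
        with pytest.raises(ValueError):
            middle_peptide_index(view)

    def test_stacked_template_is_a_trimer_with_middle_chain(self, u_view):
        assert oligomer_state(u_view).state == "trimer"
        assert middle_peptide_index(u_view) == 1


class TestInterConfusion:
    @staticmethod
    def _flat_stack():
        """Linear chains at z = 0, 4, 8: both middle-edge maps coincide and
        the edge-edge chains (8 apart) never touch."""
        base = np.array([[i // 2 * 3.0, 0, 0.01 * (i % 2)] for i in range(32)])
        return make_view([base, base + [0, 0, 4.0], base + [0, 0, 8.0]])

    def test_reference_reproduction_gives_mcc_one(self):
        view = self._flat_stack()
        ref = inter_reference_map(view)
        assert ref.any()
        cm, val = inter_confusion([view] * 3, ref)
        assert val == pytest.approx(1.0)
        assert cm.fp == cm.fn == 0.0

    def test_fibril_template_middle_edge_maps_are_similar(self, u_view):
        # one middle-edge map is the reference itself; the other differs
        # only at corrugation-boundary pairs, keeping the MCC high
        ref = inter_reference_map(u_view)
        cm, val = inter_confusion([u_view] * 3, ref)
        assert val > 0.6
        assert cm.tp > 0

    def test_edge_only_contacts_score_nonpositive(self, u_view):
        ref = inter_reference_map(u_view)
        # monomeric snapshot: no predicted contacts at all -> MCC 0, FN > 0
        far = u_view.coords.copy()
        far[u_view.peptide_index == 1] += 500.0
        far[u_view.peptide_index == 2] += 1000.0
        mono = make_monomer(u_view, far)
        cm, val = inter_confusion([mono], ref)
        assert val <= 0.0
        assert cm.tp == 0.0 and cm.fn > 0.0

    def test_generated_series_matches_analytic_expectation(self):
        # exercised through accumulate_confusion on intra maps; the analytic
        # expectation applies identically to the inter-peptide pipeline
        prev = 20 / 105
        uni = eligible_pairs(16)
        vals = np.zeros(105, bool)
        vals[:20] = True
        ref = ContactMap(universe=uni, values=vals, kind="reference")
        n = 5000
        maps = sample_contact_series(ref, sensitivity=0.9, specificity=0.9,
                                     n_snapshots=n, seed=77)
        cm = accumulate_confusion(maps, ref)
        expected = analytic_mcc(0.9, 0.9, prev)
        # 3 SE of the per-instance MCC estimate
        se = 3.0 / np.sqrt(n * 105)
        assert mcc(cm) == pytest.approx(expected, abs=3 * se + 0.01)


def make_monomer(view, coords):
    return TrimerView(
        coords=coords, elements=view.elements, names=view.names,
        masses=view.masses, residue_index=view.residue_index,
        peptide_index=view.peptide_index, chain_ids=view.chain_ids,
        resnames=view.resnames, orig_resseq=view.orig_resseq,
    )
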