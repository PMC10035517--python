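"""Grouping, razor assignment, roll-up, normalization and the PSM ratio."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import xenoquant as xq
from xenoquant.species_assignment import Policy
from xenoquant.synthetic_proteome import MixtureExperiment, ParameterError

from conftest import make_index, view_over


def _experiment(design, rows):
    """rows: (peptide, origin_protein, origin_species, psm, *intensities)."""
    labels = design.channel_labels
    table = pd.DataFrame(
        rows, columns=["peptide", "origin_protein_id", "origin_species", "psm_count", *labels]
    )
    return MixtureExperiment(design, table, noise_cv=0.0, seed=0)


ONE_CHANNEL = xq.MixtureDesign((xq.Channel("126", "s", 1.0, 1),))


class TestGroupProteins:
    def test_subset_proteins_absorbed_into_larger(self):
        index = make_index({"H1": {"p1", "p2", "p3"}, "H2": {"p2", "p3"}, "H3": {"p4"}})
        groups = xq.group_proteins(view_over(index), index)
        by_master = {g.master_id: g.member_ids for g in groups}
        assert by_master == {"H1": {"H1", "H2"}, "H3": {"H3"}}

    def test_identical_sets_master_is_lexicographically_smaller(self):
        index = make_index({"HB": {"p1", "p2"}, "HA": {"p1", "p2"}})
        groups = xq.group_proteins(view_over(index), index)
        assert len(groups) == 1
        assert groups[0].master_id == "HA"
        assert groups[0].member_ids == {"HA", "HB"}

    def test_disjoint_sets_stay_singletons(self):
        index = make_index({"H1": {"p1"}, "H2": {"p2"}, "H3": {"p3"}})
        groups = xq.group_proteins(view_over(index), index)
        assert sorted(g.master_id for g in groups) == ["H1", "H2", "H3"]
        assert all(g.member_ids == {g.master_id} for g in groups)

    def test_matches_exhaustive_minimal_cover_on_nested_families(self):
        # oracle: exhaustive enumeration of the minimum number of proteins
        # covering all peptides; on isoform-style families (variants are
        # subsets of one base, every base keeps a unique peptide) the greedy
        # grouping must find exactly that minimum
        rng = np.random.default_rng(424242)
        for trial in range(40):
            sets: dict[str, set[str]] = {}
            k = 0
            n_base = int(rng.integers(2, 5))
            shared_pool = [f"shared{t}" for t in range(3)]
            for b in range(n_base):
                own = {f"b{b}p{j}" for j in range(int(rng.integers(2, 5)))}
                base = own | {
                    p for p in shared_pool if rng.random() < 0.4
                }
                sets[f"H{k:02d}"] = base
                k += 1
                for _ in range(int(rng.integers(0, 3))):
                    size = int(rng.integers(1, len(base) + 1))
                    sets[f"H{k:02d}"] = set(
                        rng.choice(sorted(base), size=size, replace=False)
                    )
                    k += 1
            if len(sets) > 10:
                continue
            index = make_index(sets)
            groups = xq.group_proteins(view_over(index), index)

            universe = set().union(*sets.values())
            minimal = next(
                r
                for r in range(1, len(sets) + 1)
                for combo in itertools.combinations(sets, r)
                if set().union(*(sets[c] for c in combo)) == universe
            )
            assert len(groups) == minimal
            assert set().union(*(g.peptides for g in groups)) == universe

    def test_empty_view_rejected(self):
        index = make_index({"H1": {"p1"}})
        view = view_over(index)
        empty = xq.PolicyView(view.policy, frozenset(), {}, view.database_species)
        with pytest.raises(ParameterError):
            xq.group_proteins(empty, index)


class TestAssignPeptides:
    @pytest.fixture()
    def shared_peptide_index(self):
        # group A (5 peptides) and group B (2 peptides) share "pshared"
        return make_index(
            {
                "HA": {"p1", "p2", "p3", "p4", "pshared"},
                "HB": {"p5", "pshared"},
            }
        )

    def test_razor_goes_to_group_with_most_peptides(self, shared_peptide_index):
        view = view_over(shared_peptide_index, Policy.FULL_PEPTIDE)
        groups = xq.group_proteins(view, shared_peptide_index)
        assignment = xq.assign_peptides(groups, view)
        assert assignment.roles["pshared"] == ("HA", "razor")

    def test_unique_peptide_policy_discards_shared(self, shared_peptide_index):
        view = view_over(shared_peptide_index, Policy.UNIQUE_PEPTIDE)
        groups = xq.group_proteins(view, shared_peptide_index)
        assignment = xq.assign_peptides(groups, view)
        assert assignment.roles["pshared"] == (None, "discarded")

    def test_single_group_peptide_is_unique_under_any_policy(self, shared_peptide_index):
        for policy in (Policy.FULL_PEPTIDE, Policy.UNIQUE_PEPTIDE):
            view = view_over(shared_peptide_index, policy)
            groups = xq.group_proteins(view, shared_peptide_index)
            assignment = xq.assign_peptides(groups, view)
            assert assignment.roles["p1"] == ("HA", "unique")

    def test_unique_and_razor_sets_disjoint(self, shared_peptide_index):
        view = view_over(shared_peptide_index, Policy.FULL_PEPTIDE)
        groups = xq.group_proteins(view, shared_peptide_index)
        xq.assign_peptides(groups, view)
        for g in groups:
            assert not g.unique_peptides & g.razor_peptides


class TestRollupAbundance:
    def test_peptide_intensities_sum_into_protein(self):
        index = make_index({"H1": {"PEPAAA", "PEPBBB"}})
        exp = _experiment(
            ONE_CHANNEL,
            [
                ("PEPAAA", "H1", "human", 1, 10.0),
                ("PEPBBB", "H1", "human", 2, 30.0),
            ],
        )
        view = xq.apply_policy(index, exp, "full_peptide")
        groups = xq.group_proteins(view, index)
        matrix = xq.rollup_abundance(exp, xq.assign_peptides(groups, view), index)
        assert matrix.data.loc["H1", "126"] == pytest.approx(40.0)
        assert matrix.meta.loc["H1", "n_unique_psm"] == 3

    def test_common_peptide_abundance_rises_with_mouse_fraction(self):
        # protein quantified only by a common peptide under human_only:
        # doubling the mouse fraction at fixed human signal must strictly
        # raise its measured abundance (closed-form: h + m*frac)
        index = make_index(
            {"H1": {"PEPCOM"}, "M1": {"PEPCOM"}}, {"H1": "human", "M1": "mouse"}
        )
        design = xq.MixtureDesign(
            (xq.Channel("126", "a", 0.9, 1), xq.Channel("127N", "b", 0.8, 1))
        )
        exp = _experiment(
            design,
            [
                ("PEPCOM", "H1", "human", 1, 5.0, 5.0),  # fixed human signal
                ("PEPCOM", "M1", "mouse", 1, 1.0, 2.0),  # mouse part doubles
            ],
        )
        view = xq.apply_policy(index, exp, "human_only")
        groups = xq.group_proteins(view, index)
        matrix = xq.rollup_abundance(exp, xq.assign_peptides(groups, view), index)
        assert matrix.data.loc["H1", "127N"] > matrix.data.loc["H1", "126"]
        assert matrix.data.loc["H1", "126"] == pytest.approx(6.0)
        assert matrix.data.loc["H1", "127N"] == pytest.approx(7.0)

    def test_signal_conservation_under_full_peptide(self, ref_index, cell_experiment):
        # razor assignment moves signal between proteins but never loses it
        view = xq.apply_policy(ref_index, cell_experiment, "full_peptide")
        groups = xq.group_proteins(view, ref_index)
        matrix = xq.rollup_abundance(
            cell_experiment, xq.assign_peptides(groups, view), ref_index
        )
        totals = matrix.data.sum(axis=0)
        peptide_totals = cell_experiment.channel_intensities().sum(axis=0)
        assert np.allclose(totals.to_numpy(), peptide_totals.to_numpy(), rtol=1e-9)


class TestNormalizeHumanTotal:
    def _matrix(self, values, species):
        data = pd.DataFrame(values, columns=["126", "127N"])
        data.index = [f"P{i}" for i in range(len(data))]
        meta = pd.DataFrame(
            {"species": species, "n_unique_psm": 1, "n_common_psm": 0}, index=data.index
        )
        return xq.QuantMatrix(data, meta)

    def test_channels_scaled_to_constant(self):
        matrix = self._matrix([[60.0, 150.0], [40.0, 50.0]], ["human", "human"])
        out = xq.normalize_human_total(matrix, 100.0)
        assert out.data["126"].sum() == pytest.approx(100.0)
        assert out.data["127N"].sum() == pytest.approx(100.0)
        # explicit scale factors: 100/100 and 100/200
        assert out.data.loc["P0", "126"] == pytest.approx(60.0)
        assert out.data.loc["P0", "127N"] == pytest.approx(75.0)

    def test_idempotent(self):
        matrix = self._matrix([[60.0, 150.0], [40.0, 50.0]], ["human", "human"])
        once = xq.normalize_human_total(matrix, 100.0)
        twice = xq.normalize_human_total(once, 100.0)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_only_human_rows_define_the_scale(self):
        matrix = self._matrix([[50.0, 25.0], [999.0, 999.0]], ["human", "mouse"])
        out = xq.normalize_human_total(matrix, 100.0)
        assert out.data.loc["P0"].tolist() == pytest.approx([100.0, 100.0])
        assert out.data.loc["P1", "126"] == pytest.approx(999.0 * 2)

    def test_zero_human_total_rejected(self):
        matrix = self._matrix([[0.0, 10.0]], ["human"])
        with pytest.raises(ParameterError):
            xq.normalize_human_total(matrix, 100.0)


class TestPsmRatio:
    def _matrix(self, unique, common):
        data = pd.DataFrame({"126": [1.0] * len(unique)})
        data.index = [f"P{i}" for i in range(len(unique))]
        meta = pd.DataFrame(
            {"species": "human", "n_unique_psm": unique, "n_common_psm": common},
            index=data.index,
        )
        return xq.QuantMatrix(data, meta)

    def test_ratio_definition(self):
        ratios = xq.psm_ratio(self._matrix([5, 7, 0], [5, 0, 3]))
        assert ratios["P0"] == pytest.approx(0.5)
        assert ratios["P1"] == pytest.approx(1.0)
        assert ratios["P2"] == pytest.approx(0.0)

    def test_zero_psm_proteins_excluded(self):
        ratios = xq.psm_ratio(self._matrix([0, 1], [0, 0]))
        assert list(ratios.index) == ["P1"]


class TestNoiseFreeUniqueInvariance:
    def test_normalized_unique_matrix_identical_across_channels(
        self, ref_index, cell_experiment_noise_free
    ):
        # the central property: without noise, discarding common peptides
        # makes normalized human abundances independent of mouse content
        matrix = xq.quantify(cell_experiment_noise_free, ref_index, "unique_peptide")
        human = matrix.data.loc[matrix.human_proteins()]
        reference = human.iloc[:, 0]
        for label in human.columns[1:]:
            assert np.allclose(human[label], reference, rtol=1e-9)
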