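"""Block-averaged statistics, lifetimes, partner counts and the ranked table."""

import numpy as np
import pytest

from conftest import contact_sets_of
from memlens.errors import MemlensError
from memlens.site_classification import build_site_map
from memlens.statistics import (
    AnalysisWindow,
    block_stats,
    distinct_lipid_summary,
    frame_stats,
    lifetime_and_partners,
    pair_mean_contacts,
    residue_table,
    select_window,
)
from memlens.synthetic_data import (
    Placement,
    make_schedule_trajectory,
    schedule_expectations,
)
from memlens.trajectory_io import Species


class TestBlockStats:
    def test_constant_series(self):
        mean, se = block_stats([4.0] * 20, n_blocks=5)
        assert (mean, se) == (4.0, 0.0)

    def test_hand_computed_example(self):
        """1..10 in 5 blocks: block means 1.5,3.5,...,9.5 -> SE = sqrt(2)."""
        mean, se = block_stats(np.arange(1, 11), n_blocks=5)
        assert mean == pytest.approx(5.5)
        assert se == pytest.approx(np.sqrt(2.0))

    def test_single_block_rejected(self):
        with pytest.raises(MemlensError):
            block_stats([1, 2, 3], n_blocks=1)

    def test_ragged_series_needs_opt_in(self):
        with pytest.raises(MemlensError):
            block_stats(np.arange(11), n_blocks=5)
        mean, _ = block_stats(np.arange(11), n_blocks=5, allow_ragged=True)
        assert mean == pytest.approx(np.arange(10).mean())

    @pytest.mark.parametrize("n_blocks", [2, 4, 5, 10])
    def test_mean_independent_of_block_count(self, n_blocks):
        rng = np.random.default_rng(n_blocks)
        series = rng.poisson(3.0, size=40)
        mean, _ = block_stats(series, n_blocks=n_blocks)
        assert mean == pytest.approx(series.mean())

    def test_se_shift_and_scale(self):
        rng = np.random.default_rng(8)
        series = rng.normal(size=50)
        _, se = block_stats(series, n_blocks=5)
        _, se_shift = block_stats(series + 7.0, n_blocks=5)
        _, se_scale = block_stats(series * 3.0, n_blocks=5)
        assert se_shift == pytest.approx(se)
        assert se_scale == pytest.approx(3.0 * se)

    def test_frame_stats_sd(self):
        mean, sd = frame_stats([1.0, 3.0])
        assert mean == 2.0
        assert sd == pytest.approx(np.sqrt(2.0))


class TestLifetimeAndPartners:
    def test_three_of_five_frames_one_partner(self):
        schedule = [Placement(residue_number=1, frames=(0, 2, 4))]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=5, seed=0)
        sets = contact_sets_of(frames, top)
        assert lifetime_and_partners(sets, 1, "PIP2") == (60.0, 1)

    def test_never_bound(self):
        schedule = [Placement(residue_number=1)]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=4, seed=0,
                                                  n_protein_residues=2)
        sets = contact_sets_of(frames, top)
        assert lifetime_and_partners(sets, 2, "PIP2", topology=top) == (0.0, 0)

    def test_alternating_partners_bound_every_frame(self):
        schedule = [
            Placement(residue_number=1, lipid_index=0, frames=(0, 2)),
            Placement(residue_number=1, lipid_index=1, frames=(1, 3)),
        ]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=4, seed=0)
        sets = contact_sets_of(frames, top)
        assert lifetime_and_partners(sets, 1, "PIP2") == (100.0, 2)
        # at most one partner is present simultaneously
        assert lifetime_and_partners(
            sets, 1, "PIP2", partner_mode="max_simultaneous"
        ) == (100.0, 1)

    def test_unknown_residue_lookup_error(self, schedule_system):
        _, top, frames, _ = schedule_system
        sets = contact_sets_of(frames, top)
        with pytest.raises(KeyError):
            lifetime_and_partners(sets, 999, "PIP2", topology=top)

    def test_residue_lifetime_bounds_single_partner_lifetime(self, schedule_system):
        _, top, frames, _ = schedule_system
        sets = contact_sets_of(frames, top)
        whole, _ = lifetime_and_partners(sets, 3, "PIP2")
        for single in (Species.PIP2_P4,):
            part, _ = lifetime_and_partners(sets, 3, single)
            assert whole >= part


class TestResidueTable:
    def test_recovers_planted_schedule_exactly(self, schedule_system):
        schedule, top, frames, _ = schedule_system
        sets = contact_sets_of(frames, top)
        table = residue_table(
            sets, top, species="PIP2", n_blocks=2,
            site_map=build_site_map(top),
        )
        expected = schedule_expectations(schedule, len(frames))["per_residue"]
        # residue 4 binds only POPA and must be absent from the PIP2 table
        assert set(table["residue_number"]) == {1, 2, 3}
        for _, row in table.iterrows():
            exp = expected[row["residue_number"]]
            assert row["mean_contacts"] == pytest.approx(exp["mean_contacts"])
            assert row["lifetime_percent"] == pytest.approx(exp["lifetime_percent"])
            assert row["n_partners"] == exp["n_partners"]

    def test_constant_schedule_zero_se_full_lifetime(self):
        schedule = [Placement(residue_number=1, n_pairs=2)]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=10, seed=1)
        table = residue_table(contact_sets_of(frames, top), top, n_blocks=5)
        row = table.iloc[0]
        assert row["mean_contacts"] == 2.0
        assert row["se_contacts"] == 0.0
        assert row["sd_contacts"] == 0.0
        assert row["lifetime_percent"] == 100.0

    def test_min_mean_filter(self):
        schedule = [
            Placement(residue_number=1, n_pairs=2),
            Placement(residue_number=2, lipid_index=0, frames=(0,)),  # mean 0.25
        ]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=4, seed=1)
        table = residue_table(contact_sets_of(frames, top), top, n_blocks=2)
        assert table["residue_number"].tolist() == [1]
        table_all = residue_table(
            contact_sets_of(frames, top), top, n_blocks=2, min_mean=0.0
        )
        assert set(table_all["residue_number"]) == {1, 2}

    def test_empty_contacts_empty_table(self, schedule_system):
        _, top, _, _ = schedule_system
        assert residue_table([], top).empty

    def test_ranking_descending_with_residue_tiebreak(self):
        schedule = [
            Placement(residue_number=5, n_pairs=1, lipid_index=0),
            Placement(residue_number=2, n_pairs=1, lipid_index=1),
            Placement(residue_number=3, n_pairs=3, lipid_index=2),
        ]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=2, seed=1)
        table = residue_table(contact_sets_of(frames, top), top, n_blocks=2)
        assert table["residue_number"].tolist() == [3, 2, 5]
        assert table["rank"].tolist() == [1, 2, 3]

    def test_row_sums_bounded_by_total_pairs(self, schedule_system):
        _, top, frames, _ = schedule_system
        sets = contact_sets_of(frames, top)
        table = residue_table(sets, top, species=None, n_blocks=2, min_mean=0.0)
        total_pairs = sum(len(cs.pairs) for cs in sets)
        assert table["mean_contacts"].sum() * len(sets) == pytest.approx(total_pairs)


class TestDistinctLipidSummary:
    def test_no_contacts(self):
        schedule = [Placement(residue_number=1)]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=3, seed=0)
        sets = contact_sets_of(frames, top)
        assert distinct_lipid_summary(sets, Species.POPA) == (0, 0.0)

    def test_eighteen_of_sixty_active(self):
        """18 PIP2 touch the protein every frame, 42 never: (18, 18.0)."""
        schedule = [
            Placement(residue_number=(i % 6) + 1,
                      lipid_species=Species.PIP2_P4 if i % 2 else Species.PIP2_P5,
                      lipid_index=i // 2)
            for i in range(18)
        ]
        top, frames, _ = make_schedule_trajectory(
            schedule, n_frames=4, seed=0, n_protein_residues=6,
            n_atoms_per_residue=6,
            extra_lipids={Species.PIP2_P4: 21, Species.PIP2_P5: 21},
        )
        n_pip2 = len(top.molecules_of_species(Species.PIP2_P4)) + len(
            top.molecules_of_species(Species.PIP2_P5)
        )
        assert n_pip2 == 60
        sets = contact_sets_of(frames, top)
        assert distinct_lipid_summary(sets, "PIP2") == (18, 18.0)

    def test_intermittent_lipid_disambiguation(self):
        schedule = [Placement(residue_number=1, frames=(0,))]
        top, frames, _ = make_schedule_trajectory(schedule, n_frames=2, seed=0)
        sets = contact_sets_of(frames, top)
        assert distinct_lipid_summary(sets, "PIP2") == (1, 0.5)


class TestWindowsAndEdges:
    def test_select_window_half_open(self):
        schedule = [Placement(residue_number=1)]
        top, frames, _ = make_schedule_trajectory(
            schedule, n_frames=10, seed=0, frame_interval_ps=100.0
        )
        idx = select_window(frames, AnalysisWindow(0.2, 0.6))
        assert idx == [2, 3, 4, 5]

    def test_window_validation(self):
        with pytest.raises(MemlensError):
            AnalysisWindow(1.0, 1.0)
        with pytest.raises(MemlensError):
            AnalysisWindow(0.0, 1.0, n_blocks=1)

    def test_pair_mean_contacts_edges(self, schedule_system):
        schedule, top, frames, _ = schedule_system
        sets = contact_sets_of(frames, top)
        edges = pair_mean_contacts(sets, top)
        # residue 1 with its single lipid: 2 pairs every frame
        row = edges[(edges["residue_number"] == 1)].iloc[0]
        assert row["mean_contacts"] == 2.0
        # residue 3 splits frames between two lipids: mean 0.5 each
        r3 = edges[edges["residue_number"] == 3]
        assert sorted(r3["mean_contacts"]) == [0.5, 0.5]
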