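"""HDX reduction: filtering, residue assignment rules, differential profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpr import (
    FilterCriteria,
    HDXSimConfig,
    differential_uptake,
    filter_and_merge,
    residue_uptake,
    simulate_hdx,
)
from mrpr.exceptions import InputError
from mrpr.hdx import residue_profile
from mrpr.simulate import residue_uptake_closed_form

from conftest import make_peptide_rows


class TestFiltering:
    @pytest.mark.parametrize(
        "override,kept",
        [
            ({}, True),
            ({"intensity": 9_999.0}, False),
            ({"intensity": 10_000.0}, True),
            ({"n_nondeut_ids": 1}, False),
            ({"n_nondeut_ids": 2}, True),
            ({"n_products": 1}, False),
            ({"mass_error": 26.0}, False),
            ({"mass_error": -26.0}, False),
            ({"rt_delta": 0.6}, False),
        ],
    )
    def test_single_criteria(self, override, kept):
        table = make_peptide_rows([("p1", 1, 10, 2.0)], **override)
        out = filter_and_merge(table)
        assert (len(out) == 1) is kept

    def test_length_31_removed_30_kept(self):
        t31 = make_peptide_rows([("p1", 1, 31, 2.0)])
        t30 = make_peptide_rows([("p2", 1, 30, 2.0)])
        assert len(filter_and_merge(t31)) == 0
        assert len(filter_and_merge(t30)) == 1

    def test_replicate_averaging(self):
        table = make_peptide_rows([("p1", 1, 10, 0.0)], replicates=(1, 2, 3))
        table.loc[:, "uptake"] = [1.0, 2.0, 6.0]
        out = filter_and_merge(table)
        assert len(out) == 1
        assert out.loc[0, "uptake"] == pytest.approx(3.0)
        assert out.loc[0, "n_replicates"] == 3
        assert out.loc[0, "uptake_sd"] == pytest.approx(np.std([1, 2, 6], ddof=1))

    def test_proteases_combined(self):
        a = make_peptide_rows([("pep1", 1, 10, 2.0)], protease="pepsin")
        b = make_peptide_rows([("fun1", 5, 14, 3.0)], protease="fungal")
        out = filter_and_merge([a, b])
        assert set(out["protease"]) == {"pepsin", "fungal"}

    def test_idempotent(self):
        table = make_peptide_rows(
            [("p1", 1, 10, 2.0), ("p2", 8, 20, 4.0)], replicates=(1, 2)
        )
        once = filter_and_merge(table)
        twice = filter_and_merge(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_warns(self):
        table = make_peptide_rows([("p1", 1, 10, 2.0)], intensity=1.0)
        with pytest.warns(UserWarning):
            out = filter_and_merge(table)
        assert out.empty


class TestResidueUptake:
    def test_single_covering_peptide(self):
        table = filter_and_merge(make_peptide_rows([("p1", 5, 12, 2.7)]))
        out = residue_uptake(table, 10.0)
        assert set(out["residue"]) == set(range(5, 13))
        assert np.allclose(out["uptake"], 2.7)

    def test_shortest_peptide_wins(self):
        table = filter_and_merge(
            make_peptide_rows([("long", 1, 12, 6.0), ("short", 2, 10, 3.0)])
        )
        out = residue_uptake(table, 10.0).set_index("residue")
        assert out.loc[5, "uptake"] == 3.0
        assert out.loc[5, "source_peptide_id"] == "short"
        # residues covered only by the long peptide keep its uptake
        assert out.loc[1, "uptake"] == 6.0
        assert out.loc[12, "uptake"] == 6.0

    def test_cterm_distance_breaks_length_tie(self):
        # both length 10 cover residue 18: P1 (10-19) distance 1, P2 (15-24) distance 6
        table = filter_and_merge(
            make_peptide_rows([("P1", 10, 19, 3.0), ("P2", 15, 24, 5.0)])
        )
        out = residue_uptake(table, 10.0).set_index("residue")
        assert out.loc[18, "uptake"] == 3.0
        assert out.loc[18, "source_peptide_id"] == "P1"

    def test_peptide_id_breaks_remaining_tie(self):
        # identical spans: same length and C-terminus distance everywhere
        table = filter_and_merge(
            make_peptide_rows([("b_pep", 3, 9, 1.0), ("a_pep", 3, 9, 2.0)])
        )
        out = residue_uptake(table, 10.0).set_index("residue")
        assert (out["source_peptide_id"] == "a_pep").all()

    def test_missing_timepoint_raises(self):
        table = filter_and_merge(make_peptide_rows([("p1", 1, 10, 2.0)]))
        with pytest.raises(InputError):
            residue_uptake(table, 999.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, seed):
        """Randomized peptide maps: rule-enumeration oracle, 100% agreement."""
        rng = np.random.default_rng(seed)
        n_pep = int(rng.integers(5, 60))
        peptides = []
        for i in range(n_pep):
            start = int(rng.integers(1, 180))
            end = start + int(rng.integers(4, 29))
            peptides.append((f"pep{i:03d}", start, end, float(rng.uniform(0, 10))))
        table = filter_and_merge(make_peptide_rows(peptides))
        out = residue_uptake(table, 10.0).set_index("residue")

        # independent brute force: enumerate covering peptides, sort, take first
        residues = sorted({r for _, s, e, _ in peptides for r in range(s, e + 1)})
        assert sorted(out.index) == residues
        for res in residues:
            covering = [
                (e - s + 1, e - res, pid, u)
                for pid, s, e, u in peptides
                if s <= res <= e
            ]
            covering.sort()
            assert out.loc[res, "source_peptide_id"] == covering[0][2]


class TestPipelineConsistency:
    def test_single_residue_peptides_recover_generator_closed_form(self):
        """Dense length-1 peptides: assigned uptake equals the simulator's law."""
        n, t = 30, 100.0
        rates = np.linspace(0.001, 0.5, n)
        peptides = [
            (f"p{i:02d}", i + 1, i + 1, float(residue_uptake_closed_form(np.array([rates[i]]), t, 0.9)[0]))
            for i in range(n)
        ]
        table = filter_and_merge(make_peptide_rows(peptides, timepoints=(t,)))
        out = residue_uptake(table, t).sort_values("residue")
        expect = residue_uptake_closed_form(rates, t, 0.9)
        assert np.allclose(out["uptake"].to_numpy(), expect)

    def test_simulated_table_reduces_without_loss(self):
        cfg = HDXSimConfig(protein_sequence="ACDEFGHIKLMNPQRSTVWY" * 5, seed=2, noise_sd=0.0)
        table = simulate_hdx(cfg)
        filtered = filter_and_merge(table)
        profile = residue_profile(filtered)
        assert set(profile["timepoint"]) == set(cfg.timepoints)
        assert profile["residue"].max() == 100


class TestDifferentialUptake:
    def _profiles(self):
        peps = [(f"p{i}", 10 * i + 1, 10 * i + 10, 2.0) for i in range(20)]
        table = filter_and_merge(make_peptide_rows(peps, timepoints=(10.0, 100.0)))
        return residue_profile(table)

    def test_identical_profiles_all_unchanged(self):
        prof = self._profiles()
        diff = differential_uptake(prof, prof, threshold=0.3)
        assert np.allclose(diff["delta"], 0.0)
        assert (diff["classification"] == "unchanged").all()

    def test_constructed_increase_flagged_exactly(self):
        prof_a = self._profiles()
        prof_b = prof_a.copy()
        mask = prof_b["residue"].between(100, 150)
        prof_b.loc[mask, "uptake"] += 0.5
        diff = differential_uptake(prof_a, prof_b, threshold=0.3)
        flagged = set(diff.loc[diff["classification"] == "increased", "residue"])
        assert flagged == set(range(100, 151))
        assert not (diff["classification"] == "decreased").any()

    def test_residue_absent_from_one_profile_excluded(self):
        prof_a = self._profiles()
        prof_b = prof_a[prof_a["residue"] > 50].copy()
        diff = differential_uptake(prof_a, prof_b, threshold=0.3)
        assert diff["residue"].min() > 50

    def test_default_threshold_from_pooled_sd(self):
        peps = [("p1", 1, 10, 2.0)]
        table = make_peptide_rows(peps, replicates=(1, 2, 3))
        table.loc[:, "uptake"] = [1.9, 2.0, 2.1]
        prof = residue_profile(filter_and_merge(table))
        diff = differential_uptake(prof, prof)
        assert diff.attrs["threshold"] == pytest.approx(0.2, rel=1e-6)

    def test_disjoint_profiles_warn_empty(self):
        prof_a = self._profiles()
        prof_b = prof_a.copy()
        prof_b["residue"] += 10_000
        with pytest.warns(UserWarning):
            diff = differential_uptake(prof_a, prof_b, threshold=0.1)
        assert diff.empty
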