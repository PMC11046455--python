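"""Active-space selection: pair coefficients, entropies, removal, quotas."""

from __future__ import annotations

import numpy as np
import pytest

from apace_pdft.apc import (
    ActiveSpace,
    EntropyTable,
    PairCoefficientTable,
    apply_virtual_removal,
    orbital_entropies,
    pair_coefficients,
    select_active_space,
    select_apc,
    format_selection_trace,
)
from apace_pdft.backend import run_mean_field
from apace_pdft.fixtures import OrbitalTable, make_h4_linear, make_random_orbital_table

from oracles import oracle_pair_coefficient, oracle_entropies, oracle_select


def _table(occ, fock, k):
    return OrbitalTable(
        occupations=np.array(occ, dtype=np.int64),
        fock_diagonal=np.array(fock, float),
        exchange_diagonal=np.array(k, float),
    )


class TestPairCoefficients:
    def test_hand_evaluated_single_pair(self):
        # one docc at F=-0.5, one virtual at F=0.5 with K=0.1:
        # Δ = 2, A = (2 − sqrt(4 + 0.04)) / 0.2
        t = _table([2, 0], [-0.5, 0.5], [0.9, 0.1])
        val = pair_coefficients(t).values[0, 0]
        expected = (2.0 - np.sqrt(4.0 + 4 * 0.01)) / (2 * 0.1)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(oracle_pair_coefficient(-0.5, 0.5, 0.1))

    @pytest.mark.parametrize("scale", [10.0, 100.0])
    def test_magnitude_strictly_decreases_with_gap(self, scale):
        base_gap = 1.0
        t1 = _table([2, 0], [-0.5, -0.5 + base_gap], [0.5, 0.1])
        t2 = _table([2, 0], [-0.5, -0.5 + base_gap * scale], [0.5, 0.1])
        a1 = abs(pair_coefficients(t1).values[0, 0])
        a2 = abs(pair_coefficients(t2).values[0, 0])
        assert a2 < a1

    def test_identical_virtual_diagonals_give_identical_columns(self):
        t = _table([2, 2, 0, 0], [-1.0, -0.5, 0.4, 0.4], [0.8, 0.6, 0.2, 0.2])
        vals = pair_coefficients(t).values
        assert np.allclose(vals[:, 0], vals[:, 1])

    def test_no_pairs_is_an_error(self):
        t = _table([1, 1], [-0.5, -0.4], [0.3, 0.3])
        with pytest.raises(ValueError, match="doubly occupied"):
            pair_coefficients(t)

    def test_singular_denominator_reports_the_pair(self):
        t = _table([2, 0], [0.5, -0.5], [0.9, 0.0])  # inverted gap, K=0
        with pytest.warns(UserWarning, match=r"\(i=0, a=1\)"):
            vals = pair_coefficients(t).values
        assert vals[0, 0] == 0.0


class TestEntropies:
    def test_zero_coefficients_give_zero_entropy(self):
        t = _table([2, 2, 0], [-1.0, -0.5, 0.5], [0.4, 0.3, 0.0])
        pairs = pair_coefficients(t)  # K_aa = 0 with a positive gap: A → 0
        assert np.all(pairs.values == 0.0)
        ent = orbital_entropies(pairs, t)
        assert np.all(ent.entropy == 0.0)

    def test_hand_evaluated_2docc_1virt(self):
        t = _table([2, 2, 0], [-1.0, -0.5, 0.5], [0.4, 0.3, 0.2])
        pairs = pair_coefficients(t)
        ent = orbital_entropies(pairs, t)
        ref = oracle_entropies(t.fock_diagonal, t.exchange_diagonal, t.occupations)
        for p in range(3):
            assert ent.entropy[p] == pytest.approx(ref[p], rel=1e-12)

    def test_somo_outranks_everything(self):
        t = _table([2, 1, 0, 0], [-1.0, -0.3, 0.2, 0.9], [0.5, 0.4, 0.3, 0.2])
        space, ent, _ = select_apc(t, 3, 3, n_remove=0)
        assert ent.forced_priority(1) > 0
        assert 1 in space.indices
        assert space.provenance[space.indices.index(1)] == "from_somo"


class TestVirtualRemoval:
    def test_zero_removals_is_identity(self):
        t = _table([2, 2, 0, 0], [-1.0, -0.5, 0.3, 0.8], [0.5, 0.4, 0.3, 0.2])
        pairs = pair_coefficients(t)
        ent = orbital_entropies(pairs, t)
        out = apply_virtual_removal(ent, pairs, t, 0)
        assert out is ent

    def test_removal_exceeding_virtual_count_is_error(self):
        t = _table([2, 0], [-1.0, 0.5], [0.5, 0.2])
        pairs = pair_coefficients(t)
        ent = orbital_entropies(pairs, t)
        with pytest.raises(ValueError, match="remove"):
            apply_virtual_removal(ent, pairs, t, 2)

    def test_single_removal_matches_hand_recomputation(self):
        t = _table(
            [2, 2, 0, 0, 0],
            [-1.0, -0.5, 0.3, 0.5, 0.9],
            [0.5, 0.4, 0.45, 0.3, 0.2],
        )
        pairs = pair_coefficients(t)
        ent = orbital_entropies(pairs, t)
        top = max((2, 3, 4), key=lambda a: ent.entropy[a])
        out = apply_virtual_removal(ent, pairs, t, 1)
        assert out.removed_virtuals == [top]
        assert out.forced_priority(top) > 0
        ref = oracle_entropies(
            t.fock_diagonal, t.exchange_diagonal, t.occupations, dropped=[top]
        )
        for p in (0, 1):
            assert out.entropy[p] == pytest.approx(ref[p], rel=1e-12)

    def test_default_n_remove_is_two(self):
        from apace_pdft.reactions import RunConfig

        assert RunConfig().n_remove == 2


class TestSelection:
    def _entropy(self, values, forced=()):
        return EntropyTable(entropy=np.array(values, float), forced_top=list(forced))

    def test_top_k_closed_shell(self):
        t = _table([2, 2, 2, 0, 0], [-3, -2, -1, 1, 2], np.ones(5))
        ent = self._entropy([0.5, 0.3, 0.1, 0.4, 0.2])
        space = select_active_space(ent, t, 4, 4)
        assert space.indices == [0, 1, 3, 4]
        space2 = select_active_space(ent, t, 2, 2)
        assert space2.indices == [0, 3]

    def test_open_shell_quota(self):
        t = _table([2, 1, 0, 0], [-1.0, -0.3, 0.2, 0.9], [0.5, 0.4, 0.3, 0.2])
        ent = self._entropy([0.5, 0.0, 0.4, 0.2], forced=[1])
        space = select_active_space(ent, t, 3, 3)
        assert space.indices == [0, 1, 2]
        assert space.provenance == ["from_docc", "from_somo", "from_virtual"]

    def test_unsatisfiable_quota_names_deficit(self):
        t = _table([2, 0], [-1.0, 0.5], [0.5, 0.2])
        ent = self._entropy([0.5, 0.4])
        with pytest.raises(ValueError, match="virtual"):
            select_active_space(ent, t, 2, 4)

    def test_electron_and_orbital_count_invariants(self):
        t = _table([2, 2, 1, 0, 0, 0], [-2, -1, -0.3, 0.2, 0.5, 1.0],
                   [0.6, 0.5, 0.4, 0.3, 0.25, 0.2])
        space, _, _ = select_apc(t, 3, 4, n_remove=1)
        assert len(space.indices) == 4
        n_docc = space.provenance.count("from_docc")
        n_somo = space.provenance.count("from_somo")
        assert 2 * n_docc + n_somo == 3


class TestOracleEquivalence:
    """Module ranking vs an independent plain-loop transcription on 50
    seeded random orbital tables (exact selected-set agreement)."""

    @pytest.mark.parametrize("seed", range(50))
    def test_selection_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_docc = int(rng.integers(2, 7))
        n_somo = int(rng.integers(0, 3))
        n_virt = int(rng.integers(3, 9))
        t = make_random_orbital_table(n_docc, n_somo, n_virt, seed)
        a_max = 2 * n_docc + n_somo
        n_elec = n_somo + 2 * int(rng.integers(1, n_docc + 1))
        n_orb_max = n_somo + (n_elec - n_somo) // 2 + n_virt
        n_orb_min = n_somo + (n_elec - n_somo) // 2
        n_orb = int(rng.integers(n_orb_min, n_orb_max + 1))
        n_remove = int(rng.integers(0, min(3, n_virt) + 1))
        space, _, _ = select_apc(t, n_elec, n_orb, n_remove=n_remove)
        ref = oracle_select(
            t.fock_diagonal, t.exchange_diagonal, t.occupations,
            n_elec, n_orb, n_remove=n_remove,
        )
        assert space.indices == ref


class TestInvariantProperties:
    def test_permutation_equivariance(self):
        seed = 11
        t = make_random_orbital_table(4, 1, 5, seed)
        space, _, _ = select_apc(t, 5, 5, n_remove=2)
        rng = np.random.default_rng(99)
        perm = rng.permutation(t.n_mo)
        t2 = OrbitalTable(
            occupations=t.occupations[perm],
            fock_diagonal=t.fock_diagonal[perm],
            exchange_diagonal=t.exchange_diagonal[perm],
        )
        space2, _, _ = select_apc(t2, 5, 5, n_remove=2)
        inv = np.argsort(perm)
        mapped = sorted(int(np.where(perm == p)[0][0]) for p in space.indices)
        assert space2.indices == mapped

    @pytest.mark.parametrize("seed", [3, 17, 41])
    def test_monotone_quota_growth(self, seed):
        t = make_random_orbital_table(5, 0, 7, seed)
        s_small, _, _ = select_apc(t, 4, 5, n_remove=2)
        s_more_virt, _, _ = select_apc(t, 4, 6, n_remove=2)
        s_more_docc, _, _ = select_apc(t, 6, 6, n_remove=2)
        virt_small = {p for p, tag in zip(s_small.indices, s_small.provenance)
                      if tag == "from_virtual"}
        virt_big = {p for p, tag in zip(s_more_virt.indices, s_more_virt.provenance)
                    if tag == "from_virtual"}
        assert virt_small <= virt_big
        docc_small = {p for p, tag in zip(s_small.indices, s_small.provenance)
                      if tag == "from_docc"}
        docc_big = {p for p, tag in zip(s_more_docc.indices, s_more_docc.provenance)
                    if tag == "from_docc"}
        assert docc_small <= docc_big

    def test_adiabatic_stability_under_tiny_geometry_change(self):
        base = make_h4_linear(1.0)
        pert = make_h4_linear(1.0 + 1e-4)
        sel = []
        for mol in (base, pert):
            scf = run_mean_field(mol, "sto-3g")
            space, _, _ = select_apc(scf, 2, 2, n_remove=2)
            sel.append(space.indices)
        assert sel[0] == sel[1]


def test_selection_trace_is_tab_separated(h2_scf):
    space, ent, _ = select_apc(h2_scf, 2, 2, n_remove=2)
    trace = format_selection_trace(h2_scf, ent, space)
    lines = trace.strip().splitlines()
    assert lines[0].split("\t") == ["orbital", "occupation", "entropy", "forced", "selected"]
    assert len(lines) == 1 + len(h2_scf.occupations)
    assert sum(int(ln.split("\t")[4]) for ln in lines[1:]) == 2
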