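"""M-diagnostic, categories, C0², SRL deviations and stratified MADs."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from apace_pdft import diagnostics
from apace_pdft.apc import ActiveSpace
from apace_pdft.diagnostics import (
    MrAssessment,
    SrlDeviation,
    aggregate_mad,
    c0_squared,
    classify,
    m_diagnostic,
    srl_deviations,
)


def _cas_stub(occs, provenance, ci=None):
    n = len(provenance)
    n_docc = provenance.count("from_docc")
    n_somo = provenance.count("from_somo")
    return SimpleNamespace(
        natural_occupations=np.array(occs, float),
        active_space=ActiveSpace(
            n_electrons=2 * n_docc + n_somo,
            n_orbitals=n,
            indices=list(range(n)),
            provenance=list(provenance),
        ),
        ci_vector=None if ci is None else np.array(ci, float),
        ci_leading_weight=1.0 if ci is None else float(np.max(np.array(ci) ** 2)),
    )


class TestMDiagnostic:
    def test_closed_shell_ideal_is_zero(self):
        cas = _cas_stub([2.0, 0.0], ["from_docc", "from_virtual"])
        assert m_diagnostic(cas) == 0.0

    def test_diradical_limit_is_one(self):
        cas = _cas_stub([1.0, 1.0], ["from_docc", "from_virtual"])
        assert m_diagnostic(cas) == pytest.approx(1.0)

    def test_somo_contribution(self):
        cas = _cas_stub(
            [2.0, 1.2, 0.0],
            ["from_docc", "from_somo", "from_virtual"],
        )
        # ½(|2−2| + 0 + |1.2−1|) = 0.1
        assert m_diagnostic(cas) == pytest.approx(0.1)

    def test_no_virtual_role_is_error(self):
        cas = _cas_stub([1.0], ["from_somo"])
        with pytest.raises(ValueError, match="virtual"):
            m_diagnostic(cas)

    def test_invariant_under_degenerate_relabeling(self):
        occs = [1.7, 0.3, 0.3]
        prov = ["from_docc", "from_virtual", "from_virtual"]
        m1 = m_diagnostic(_cas_stub(occs, prov))
        m2 = m_diagnostic(_cas_stub([1.7, 0.3, 0.3][::-1], prov))
        assert m1 == pytest.approx(m2)


class TestClassify:
    @pytest.mark.parametrize(
        "m,expected",
        [
            (0.03, "low"),
            (0.05, "low"),  # boundary to the lower category
            (0.07, "moderate"),
            (0.1, "moderate"),
            (0.100001, "high"),
            (0.5, "high"),
        ],
    )
    def test_thresholds(self, m, expected):
        assert classify(m) == expected

    def test_category_monotone_in_m(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        order = {"low": 0, "moderate": 1, "high": 2}

        @given(
            m1=st.floats(min_value=0.0, max_value=2.0),
            m2=st.floats(min_value=0.0, max_value=2.0),
        )
        @settings(max_examples=200, derandomize=True, deadline=None)
        def check(m1, m2):
            lo, hi = sorted([m1, m2])
            assert order[classify(lo)] <= order[classify(hi)]

        check()

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify(-0.01)

    def test_piecewise_constant_with_printed_breakpoints(self):
        ms = np.linspace(0.0, 0.2, 400)
        cats = [classify(m) for m in ms]
        changes = [ms[i] for i in range(1, len(ms)) if cats[i] != cats[i - 1]]
        assert len(changes) == 2
        assert changes[0] == pytest.approx(0.05, abs=1e-3)
        assert changes[1] == pytest.approx(0.1, abs=1e-3)


class TestC0Squared:
    def test_single_determinant(self):
        cas = _cas_stub([2.0, 0.0], ["from_docc", "from_virtual"], ci=[1.0, 0, 0, 0])
        assert c0_squared(cas) == pytest.approx(1.0)

    def test_two_equal_coefficients(self):
        v = [1 / np.sqrt(2), 0, 0, -1 / np.sqrt(2)]
        cas = _cas_stub([1.0, 1.0], ["from_docc", "from_virtual"], ci=v)
        assert c0_squared(cas) == pytest.approx(0.5)

    def test_dissociated_h2(self, h2_far, h2_far_scf):
        from apace_pdft.backend import run_casscf

        space = ActiveSpace(2, 2, [0, 1], ["from_docc", "from_virtual"])
        cas = run_casscf(h2_far_scf, space, h2_far)
        assert c0_squared(cas) == pytest.approx(0.5, abs=0.02)


def _record(delta_e, ea_f, ea_b, ms=(0.01, 0.2, 0.03)):
    def state(m):
        return SimpleNamespace(
            mr=MrAssessment(m_value=m, c0_squared=0.9, category=classify(m))
        )

    return SimpleNamespace(
        reactant=state(ms[0]),
        ts=state(ms[1]),
        product=state(ms[2]),
        delta_e=delta_e,
        ea_forward=ea_f,
        ea_backward=ea_b,
        srl=[],
    )


class TestSrlDeviations:
    def test_identical_energies_give_zero(self):
        rec = _record(
            {"tpbe": -10.0, "hf_pbe": -10.0},
            {"tpbe": 5.0, "hf_pbe": 5.0},
            {"tpbe": 15.0, "hf_pbe": 15.0},
        )
        devs = srl_deviations(rec)
        assert devs and all(d.deviation == 0.0 for d in devs)

    def test_simple_arithmetic(self):
        rec = _record(
            {"tpbe": -10.0, "hf_pbe": -7.0}, {"tpbe": 0.0, "hf_pbe": 0.0},
            {"tpbe": 10.0, "hf_pbe": 7.0},
        )
        d = [x for x in srl_deviations(rec) if x.quantity == "reaction_energy"][0]
        assert d.deviation == pytest.approx(-3.0)
        assert d.abs_deviation == pytest.approx(3.0)

    def test_missing_counterpart_skipped(self, caplog):
        rec = _record({"tpbe": -10.0}, {"tpbe": 1.0}, {"tpbe": 11.0})
        with caplog.at_level("WARNING"):
            devs = srl_deviations(rec)
        assert devs == []
        assert "skipped" in caplog.text

    def test_external_pair_flagged(self):
        rec = _record(
            {"nevpt2": -12.0, "mp2": -9.0}, {"nevpt2": 0.0, "mp2": 0.0},
            {"nevpt2": 12.0, "mp2": 9.0},
        )
        devs = srl_deviations(rec)
        assert all(d.external for d in devs)

    def test_swap_antisymmetry_of_reaction_energy(self):
        fwd = _record(
            {"tpbe": -10.0, "hf_pbe": -7.0},
            {"tpbe": 5.0, "hf_pbe": 6.0},
            {"tpbe": 15.0, "hf_pbe": 13.0},
        )
        rev = _record(
            {"tpbe": 10.0, "hf_pbe": 7.0},
            {"tpbe": 15.0, "hf_pbe": 13.0},
            {"tpbe": 5.0, "hf_pbe": 6.0},
        )
        d_f = {x.quantity: x.deviation for x in srl_deviations(fwd) if x.mr_method == "tpbe"}
        d_r = {x.quantity: x.deviation for x in srl_deviations(rev) if x.mr_method == "tpbe"}
        assert d_f["reaction_energy"] == pytest.approx(-d_r["reaction_energy"])
        assert d_f["ea_forward"] == pytest.approx(d_r["ea_backward"])
        assert d_f["ea_backward"] == pytest.approx(d_r["ea_forward"])


class TestAggregateMad:
    def _rec_with_devs(self, abs_dev, ms):
        rec = _record({}, {}, {}, ms=ms)
        rec.srl = [
            SrlDeviation("reaction_energy", "tpbe", "hf_pbe", abs_dev),
        ]
        return rec

    def test_single_record(self):
        df = aggregate_mad([self._rec_with_devs(3.0, (0.01, 0.2, 0.03))])
        assert len(df) == 1
        assert df.iloc[0]["mad"] == pytest.approx(3.0)
        assert df.iloc[0]["n"] == 1
        assert df.iloc[0]["category"] == "low"  # max(M_r, M_p) = 0.03

    def test_same_category_pools(self):
        recs = [
            self._rec_with_devs(2.0, (0.01, 0.2, 0.03)),
            self._rec_with_devs(4.0, (0.02, 0.2, 0.01)),
        ]
        df = aggregate_mad(recs)
        assert len(df) == 1
        assert df.iloc[0]["mad"] == pytest.approx(3.0)
        assert df.iloc[0]["max_abs_dev"] == pytest.approx(4.0)

    def test_distinct_categories_never_pool(self):
        recs = [
            self._rec_with_devs(2.0, (0.01, 0.2, 0.03)),
            self._rec_with_devs(40.0, (0.5, 0.6, 0.7)),
        ]
        df = aggregate_mad(recs)
        assert set(df["category"]) == {"low", "high"}
        low = df[df["category"] == "low"].iloc[0]
        assert low["mad"] == pytest.approx(2.0)

    def test_union_of_disjoint_category_sets(self):
        a = [self._rec_with_devs(2.0, (0.01, 0.2, 0.03))]
        b = [self._rec_with_devs(40.0, (0.5, 0.6, 0.7))]
        df_union = aggregate_mad(a + b)
        df_a, df_b = aggregate_mad(a), aggregate_mad(b)
        import pandas as pd

        merged = (
            pd.concat([df_a, df_b]).sort_values(df_union.columns.tolist())
            .reset_index(drop=True)
        )
        assert merged.equals(
            df_union.sort_values(df_union.columns.tolist()).reset_index(drop=True)
        )

    def test_empty_input(self):
        df = aggregate_mad([])
        assert df.empty

    def test_barrier_stratified_by_ts_endpoint_max(self):
        rec = _record({}, {}, {}, ms=(0.01, 0.5, 0.02))
        rec.srl = [SrlDeviation("ea_forward", "tpbe", "hf_pbe", 1.0)]
        df = aggregate_mad([rec])
        assert df.iloc[0]["category"] == "high"  # max(M_r, M_ts)
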