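"""Minimal-class catalogue, iff conditions, regime diagram."""

import itertools

import numpy as np
import pytest

from turingmin.catalogue import (
    build_scheme,
    get_class,
    inf_delta_c,
    is_turing_unstable_typeI,
    list_minimal_classes,
    regime_line,
    typeII_structural_ok,
    _TYPE_I_SAMPLES,
)
from turingmin.kinetics import (
    DegenerateSystemError,
    compile_scheme,
    positive_steady_states,
)
from turingmin.stability import jacobian_at, turing_report


class TestCatalogueStructure:
    def test_counts(self):
        assert len(list_minimal_classes("I")) == 11
        assert len(list_minimal_classes("II")) == 14
        assert len(list_minimal_classes("both")) == 25

    def test_type_I_sizes_and_necessary_reactants(self):
        # every in-phase minimal class has three reactions including the
        # auto-amplifying 2U reaction and a U-consuming U+V reaction
        for mc in list_minimal_classes("I"):
            assert len(mc.template) == 3
            assert any(t.p == 2 and t.q == 0 and t.sgn1 == 1 for t in mc.template)
            assert any(t.p == 1 and t.q == 1 and t.sgn1 == -1 for t in mc.template)

    def test_type_II_sizes_and_structural_constraints(self):
        for mc in list_minimal_classes("II"):
            assert len(mc.template) == 4
            assert typeII_structural_ok(mc.template)

    def test_templates_distinct(self):
        seen = {tuple(mc.template) for mc in list_minimal_classes("both")}
        assert len(seen) == 25

    def test_unknown_class_id(self):
        with pytest.raises(KeyError):
            get_class("I.z")


class TestIffConditions:
    @pytest.mark.parametrize(
        "cid,coeffs,expected",
        [
            ("I.a", {"n1": 4, "m1": 3, "n3": 1}, True),    # 4 > 3 > 2
            ("I.a", {"n1": 4, "m1": 5, "n3": 1}, False),   # 5 >= 2(n1-2)
            ("I.a", {"n1": 4, "m1": 2, "n3": 1}, False),   # m1 = n1-2
            ("I.j", {"n1": 5, "m1": 1, "n3": 2}, True),    # 3 > 2
            ("I.j", {"n1": 4, "m1": 1, "n3": 2}, False),   # 2 = 2
            ("I.i", {"n1": 3, "m1": 1}, True),             # unconditional
            ("I.k", {"n1": 3, "m1": 1, "m2": 2}, True),    # unconditional
            ("I.b", {"n1": 4, "m1": 3, "n3": 3, "m3": 1}, True),
            ("I.b", {"n1": 4, "m1": 3, "n3": 1, "m3": 3}, False),  # n3 <= m3
        ],
    )
    def test_examples(self, cid, coeffs, expected):
        assert is_turing_unstable_typeI(cid, coeffs) is expected

    def test_structural_bound_violation_names_the_bound(self):
        with pytest.raises(ValueError, match="n1"):
            is_turing_unstable_typeI("I.a", {"n1": 2, "m1": 1, "n3": 1})

    def test_type_II_has_no_closed_form(self):
        with pytest.raises(ValueError, match="search"):
            is_turing_unstable_typeI("II.a", {})

    def test_every_unconditional_class_has_unique_positive_steady_state(self):
        # each type-I minimal scheme admits exactly one positive uniform
        # state: bistability is impossible
        for cid, sample in _TYPE_I_SAMPLES.items():
            sch = build_scheme(cid, dict(sample), (1.0, 50.0, 1.0))
            assert len(positive_steady_states(compile_scheme(sch))) == 1


class TestAgainstGeneralMachinery:
    @pytest.mark.parametrize("cid", [m.class_id for m in list_minimal_classes("I")])
    def test_iff_condition_matches_stability_pipeline(self, cid):
        """The printed closed-form conditions agree with the full linear
        analysis at a rate ratio far above every candidate threshold."""
        mc = get_class(cid)
        names = mc.coeff_names
        axes = [range(mc.coeff_bounds[n][0], 7) for n in names]
        # large rho guarantees the trace condition whenever it is satisfiable
        tuples = list(itertools.product(*axes))
        rho = 10.0 * _max_rho_c(cid, tuples)
        for vals in tuples:
            coeffs = dict(zip(names, vals))
            predicted = mc.turing_condition(*vals)
            sch = build_scheme(cid, coeffs, (1.0, rho, 1.0))
            try:
                reports = turing_report(compile_scheme(sch))
            except DegenerateSystemError:
                # F and G share a curve of zeros (e.g. m1 = n1-2 with a
                # proportional closure): no isolated strictly stable state
                observed = False
            else:
                observed = any(
                    r.pattern_type == "I" and r.delta_c is not None
                    for r in reports
                )
            assert observed == predicted, (cid, coeffs, rho)


def _max_rho_c(cid, tuples):
    from turingmin.catalogue import _rho_c_bisect

    mc = get_class(cid)
    names = mc.coeff_names
    ok = [v for v in tuples if mc.turing_condition(*v)]
    if not ok:
        return 1.0
    arrays = {n: np.array([v[i] for v in ok], dtype=float)
              for i, n in enumerate(names)}
    rc = _rho_c_bisect(cid, arrays)
    return float(np.nanmax(rc[np.isfinite(rc)], initial=1.0))


class TestRegimeDiagram:
    def test_rho_c_is_exact_trace_root(self):
        # tr(J*) = 0 at rho = rho_c (definitional)
        for cid in ("I.a", "I.c", "I.e", "I.i", "I.k"):
            sample = dict(_TYPE_I_SAMPLES[cid])
            rl = regime_line(cid, sample)
            sch = build_scheme(cid, sample, (1.0, rl.rho_c, 1.0))
            k = compile_scheme(sch)
            (ss,) = positive_steady_states(k)
            j = jacobian_at(k, ss)
            assert j.trace == pytest.approx(0.0, abs=1e-9 * j.scale)

    def test_first_order_closure_threshold(self):
        # classes whose third reaction consumes U to first order have
        # rho_c = n1 - 2 exactly
        for cid in ("I.c", "I.d"):
            sample = dict(_TYPE_I_SAMPLES[cid])
            rl = regime_line(cid, sample)
            assert rl.rho_c == pytest.approx(sample["n1"] - 2, rel=1e-10)

    def test_boundary_linear_through_origin(self):
        # delta_c(rho)/rho constant to 1e-6 and intercept ~ 0
        for mc in list_minimal_classes("I"):
            rl = regime_line(mc.class_id, dict(_TYPE_I_SAMPLES[mc.class_id]))
            assert rl.slope > 0
            assert abs(rl.intercept) <= 1e-9 * rl.slope * max(rl.rho_c, 1.0)

    def test_slope_verified_against_direct_delta_c(self):
        # H rho must reproduce delta_c computed by the stability pipeline
        for cid in ("I.a", "I.f", "I.k"):
            sample = dict(_TYPE_I_SAMPLES[cid])
            rl = regime_line(cid, sample)
            rho = 3.7 * rl.rho_c
            sch = build_scheme(cid, sample, (1.0, rho, 1.0))
            (rep,) = turing_report(compile_scheme(sch))
            assert rep.delta_c == pytest.approx(rl.slope * rho, rel=1e-8)

    def test_type_II_not_supported(self):
        with pytest.raises(ValueError):
            regime_line("II.a", {})


class TestInfDeltaC:
    def test_monotone_in_bound(self):
        for cid in ("I.a", "I.e", "I.j"):
            assert inf_delta_c(cid, 50) <= inf_delta_c(cid, 10) + 1e-12

    def test_three_classes_bounded_away_from_one(self):
        # the classes whose interspecific reaction does not consume V
        special = {"I.i", "I.j", "I.k"}
        floor = (1 + np.sqrt(2)) ** 2
        for cid in special:
            assert inf_delta_c(cid, 50) >= floor - 1e-9

    def test_other_classes_descend_below_special_floor(self):
        floor = (1 + np.sqrt(2)) ** 2
        for cid in ("I.a", "I.c", "I.e", "I.g"):
            assert inf_delta_c(cid, 50) < floor / 2
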