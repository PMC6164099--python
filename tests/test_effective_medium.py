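"""Homogenization formulas: limits, passivity, and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sprsim.effective_medium import (
    CompositeSpec,
    CoreShellGeometry,
    EffectiveMediumPoleError,
    coated_grain_eps,
    composite_eps,
    coreshell_eps,
    coreshell_eps_f,
    maxwell_garnett_eps,
    mg_residual,
)
from sprsim.materials import (
    TABLE_FILL_FRACTION,
    TABLE_SHELL_THICKNESS,
)

# passive permittivities, bounded away from the degenerate eps = 0
passive_eps = st.builds(complex, st.floats(-20, 20), st.floats(0, 5)).filter(
    lambda e: abs(e) > 1e-2
)


class TestCoreShell:
    def test_geometry_validation_and_fill_fraction(self):
        g = CoreShellGeometry(b=10, a=20)
        assert g.f == pytest.approx(0.125)
        assert g.shell_thickness_nm == 10
        with pytest.raises(ValueError):
            CoreShellGeometry(b=-1, a=5)
        with pytest.raises(ValueError):
            CoreShellGeometry(b=6, a=5)

    def test_zero_core_gives_shell(self):
        assert coreshell_eps_f(0.0, 5 + 1j, -9 + 2j) == -9 + 2j

    @given(eps=passive_eps, f=st.floats(0, 1))
    def test_homogeneous_sphere(self, eps, f):
        assert coreshell_eps_f(f, eps, eps) == pytest.approx(eps, rel=1e-12, abs=1e-12)

    def test_depends_on_geometry_only_through_f(self, constituents):
        ec, es = constituents
        small = coreshell_eps(CoreShellGeometry(b=2.5, a=5.0), ec, es)
        large = coreshell_eps(CoreShellGeometry(b=10.0, a=20.0), ec, es)
        assert small == pytest.approx(large, rel=1e-14)

    def test_pole_is_signalled(self):
        # f chosen so the denominator (ec + 2 es) - f (ec - es) vanishes
        ec, es = 2.0 + 0j, -0.75 + 0j
        f = (ec + 2 * es).real / (ec - es).real
        with pytest.raises(EffectiveMediumPoleError):
            coreshell_eps_f(f, ec, es)

    def test_real_part_decreases_with_shell_thickness(self, constituents):
        """Thicker gold shell drags the mixture toward the metallic value."""
        ec, es = constituents
        preds = [
            coreshell_eps(CoreShellGeometry(b, a), ec, es)
            for b, a, _ in TABLE_SHELL_THICKNESS
        ]
        re = np.array([p.real for p in preds])
        assert np.all(np.diff(re) < 0)
        assert re[-1] > es.real  # approaches the shell permittivity from above

    def test_both_parts_increase_with_fill_fraction(self, constituents):
        """Re grows with f over the whole grid; Im grows until the turnover.

        As f -> 1 the mixture tends to the core permittivity, whose Im
        lies below the shell-dominated maximum, so Im must turn over near
        the top of the grid (the characterization values show the same
        dip between the two largest f).  Monotonicity in Im is therefore
        asserted only on the rows below f = 0.75.
        """
        ec, es = constituents
        rows = sorted(TABLE_FILL_FRACTION, key=lambda r: (r[0] / r[1]) ** 3)
        preds = [coreshell_eps(CoreShellGeometry(b, a), ec, es) for b, a, _ in rows]
        assert np.all(np.diff([p.real for p in preds]) > 0)
        low_f = [p for (b, a, _), p in zip(rows, preds) if (b / a) ** 3 < 0.75]
        assert np.all(np.diff([p.imag for p in low_f]) > 0)


def coated_sphere_oracle(e1, e2, alpha, eh):
    """Independent route: coated-sphere polarizability in an arbitrary host.

    The classical quasi-static polarizability factor of a coated sphere
    (core e2, shell e1, core volume ratio alpha) in host eh, inverted
    through the Clausius-Mossotti relation to the equivalent homogeneous
    permittivity.  The result must be independent of the auxiliary host.
    """
    num = (e1 - eh) * (e2 + 2 * e1) + alpha * (e2 - e1) * (eh + 2 * e1)
    den = (e1 + 2 * eh) * (e2 + 2 * e1) + alpha * (e2 - e1) * (2 * e1 - 2 * eh)
    beta = num / den
    return eh * (1 + 2 * beta) / (1 - beta)


class TestCoatedGrain:
    @given(eps=passive_eps, alpha=st.floats(0.01, 1.0))
    def test_homogeneous_particle(self, eps, alpha):
        assert coated_grain_eps(eps, eps, alpha) == pytest.approx(
            eps, rel=1e-12, abs=1e-12
        )

    def test_zero_thickness_shell_returns_grain_exactly(self):
        # algebraic limit at alpha = 1: numerator 3*e1*e2, denominator 3*e1
        assert coated_grain_eps(2.0 + 0.5j, -7 + 1j, 1.0) == -7 + 1j

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            coated_grain_eps(1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            coated_grain_eps(1.0, 2.0, 1.5)

    def test_against_coated_sphere_polarizability(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            e1 = complex(rng.uniform(1, 4), rng.uniform(0, 2))
            e2 = complex(rng.uniform(-15, 5), rng.uniform(0, 4))
            alpha = rng.uniform(0.05, 0.99)
            eh = complex(rng.uniform(1, 3), rng.uniform(0, 1))
            ours = coated_grain_eps(e1, e2, alpha)
            theirs = coated_sphere_oracle(e1, e2, alpha, eh)
            assert ours == pytest.approx(theirs, rel=1e-10)


class TestComposite:
    HOST = 1.7689 + 0j  # water

    def test_host_only_limit_is_exact(self):
        assert maxwell_garnett_eps(2 + 3j, self.HOST, 0.0) == self.HOST

    def test_inclusion_only_limit_is_exact(self):
        assert maxwell_garnett_eps(2 + 3j, self.HOST, 1.0) == 2 + 3j

    @pytest.mark.parametrize("variant", ["paper", "standard"])
    def test_residual_vanishes_for_random_specs(self, variant):
        rng = np.random.default_rng(7)
        for _ in range(100):
            en = complex(rng.uniform(-10, 10), rng.uniform(0, 4))
            em = complex(rng.uniform(1, 3), rng.uniform(0, 0.5))
            F = rng.uniform(0.01, 0.99)
            x = maxwell_garnett_eps(en, em, F, variant=variant)
            assert abs(mg_residual(x, en, em, F, variant)) < 1e-10

    def test_selected_root_is_a_closed_form_quadratic_root(self):
        """The homotopy-tracked solution coincides with one root of np.roots."""
        from sprsim.effective_medium import _mg_coeffs

        en, em, F = 1.45 + 2.52j, self.HOST, 0.35
        x = maxwell_garnett_eps(en, em, F)
        roots = np.roots(_mg_coeffs(en, em, F, "paper"))
        assert min(abs(roots - x)) < 1e-10

    def test_continuity_in_volume_fraction(self):
        en, em = 1.45 + 2.52j, self.HOST
        Fs = np.linspace(0, 1, 51)
        xs = [maxwell_garnett_eps(en, em, float(F)) for F in Fs]
        steps = np.abs(np.diff(xs))
        assert np.all(steps < 0.2)  # no branch jumps
        assert xs[0] == em and xs[-1] == en

    def test_passivity_over_random_passive_specs(self, constituents):
        ec, es = constituents
        rng = np.random.default_rng(11)
        for _ in range(100):
            f = rng.uniform(0.05, 0.95)
            grain = coreshell_eps_f(f, ec, es)
            spec = CompositeSpec(
                eps_grain=grain,
                eps_shell=complex(rng.uniform(1.5, 2.5), rng.uniform(0, 0.2)),
                eps_host=self.HOST,
                alpha=rng.uniform(0.05, 1.0),
                F=rng.uniform(0, 1),
            )
            x = composite_eps(spec)
            assert x.imag >= -1e-12

    def test_paper_and_standard_variants_differ_but_both_solve_their_relation(self):
        en, em, F = 1.45 + 2.52j, self.HOST, 0.4
        xp = maxwell_garnett_eps(en, em, F, variant="paper")
        xs = maxwell_garnett_eps(en, em, F, variant="standard")
        assert abs(mg_residual(xp, en, em, F, "paper")) < 1e-10
        assert abs(mg_residual(xs, en, em, F, "standard")) < 1e-10
        assert xp != pytest.approx(xs, rel=1e-3)  # genuinely different mixing rules

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CompositeSpec(1 + 1j, 2.0, self.HOST, alpha=0.5, F=1.5)
        with pytest.raises(ValueError):
            CompositeSpec(1 - 1j, 2.0, self.HOST, alpha=0.5, F=0.5)  # gain grain
        with pytest.raises(ValueError):
            CompositeSpec(1 + 1j, 2.0, self.HOST, alpha=0.0, F=0.5)
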