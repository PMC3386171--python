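"""Flux operators: event enumeration, conservation laws, damage semantics."""

import itertools

import numpy as np
import pytest

from mitoqc.quality_state import QualityDistribution, random_initial_distribution
from mitoqc.rate_model import HillTimeCourse, ProcessSpec, SelectivityProfile
from mitoqc.operators import (
    EventList,
    FusionFissionKernel,
    RheostatDegenerateError,
    assemble_rhs,
    decay_flux,
    enumerate_events,
    fusion_fission_flux,
    perturb_event_list,
    perturbation_flux_correction,
    random_damage_step,
    sample_perturbation,
    turnover_flux,
)


def const_schedule(v):
    return HillTimeCourse(v, v, 0, 1.0)


def unit_selectivity(zero_at_floor=False):
    return SelectivityProfile(1.0, 1.0, 1.0, 0.0, zero_at_floor=zero_at_floor)


def ff_spec(rate=1.0, selectivity=None):
    if selectivity is None:
        selectivity = unit_selectivity(zero_at_floor=True)
    return ProcessSpec("fusion_fission", const_schedule(rate), selectivity)


def brute_force_events(n):
    """Independent enumeration of quality-conserving transitions."""
    found = set()
    for l, m in itertools.combinations_with_replacement(range(n), 2):
        for lp, mp in itertools.combinations_with_replacement(range(n), 2):
            if lp + mp == l + m and (lp, mp) != (l, m):
                found.add((l, m, lp, mp))
    return found


class TestEnumerateEvents:
    def test_two_states_has_no_events(self):
        assert len(enumerate_events(2)) == 0

    def test_three_states_exact(self):
        ev = enumerate_events(3)
        got = {(e.l_in, e.m_in, e.l_out, e.m_out) for e in ev}
        assert got == {(0, 2, 1, 1), (1, 1, 0, 2)}

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_brute_force(self, n):
        ev = enumerate_events(n)
        got = list(zip(ev.l_in, ev.m_in, ev.l_out, ev.m_out))
        assert len(got) == len(set(got))  # no duplicates
        assert set(got) == brute_force_events(n)

    def test_quality_conserved_by_construction(self):
        ev = enumerate_events(10)
        assert np.all(ev.quality_deficit == 0)
        assert np.all(ev.l_in <= ev.m_in)
        assert np.all(ev.l_out <= ev.m_out)


class TestFusionFissionFlux:
    def test_empty_event_list_zero_flux(self):
        d = QualityDistribution(np.array([0.4, 0.6]))
        flux = fusion_fission_flux(d, enumerate_events(2), ff_spec(), 0.0)
        np.testing.assert_array_equal(flux, 0.0)

    def test_three_state_worked_example(self):
        # only (1,1)->(0,2) is active when state 0 cannot fuse
        d = QualityDistribution(np.array([0.2, 0.3, 0.5]))
        flux = fusion_fission_flux(d, enumerate_events(3), ff_spec(), 0.0)
        np.testing.assert_allclose(flux, [0.09, -0.18, 0.09], atol=1e-15)

    @pytest.mark.parametrize("n", [3, 7, 20])
    def test_conserves_norm_and_quality(self, n, rng):
        ev = enumerate_events(n)
        sel = SelectivityProfile(0.0, 1.0, (n - 1) / 2, 2.0, zero_at_floor=True)
        spec = ff_spec(0.05, sel)
        for seed in range(20):
            d = random_initial_distribution(n, seed)
            flux = fusion_fission_flux(d, ev, spec, 0.0)
            assert abs(flux.sum()) < 1e-12
            assert abs(np.dot(np.arange(n), flux)) < 1e-12

    @pytest.mark.parametrize("n", [3, 8, 25])
    def test_grouped_kernel_equals_event_sum(self, n):
        ev = enumerate_events(n)
        sel = SelectivityProfile(0.1, 0.9, (n - 1) / 3, 2.5, zero_at_floor=True)
        spec = ff_spec(0.3, sel)
        kernel = FusionFissionKernel(n, sel)
        for seed in range(5):
            d = random_initial_distribution(n, seed)
            np.testing.assert_allclose(
                kernel.flux(d.probs, 0.3),
                fusion_fission_flux(d, ev, spec, 0.0),
                atol=1e-15,
            )

    def test_mismatched_state_space_rejected(self):
        d = QualityDistribution(np.full(4, 0.25))
        with pytest.raises(ValueError):
            fusion_fission_flux(d, enumerate_events(5), ff_spec(), 0.0)


class TestPerturbedFlux:
    def test_norm_conserved_quality_destroyed(self, rng):
        n = 10
        ev = enumerate_events(n)
        spec = ff_spec(0.5)
        d = random_initial_distribution(n, 7)
        conserving = fusion_fission_flux(d, ev, spec, 0.0)
        q = np.arange(n)
        for _ in range(10):
            pert = perturb_event_list(ev, 0.25, 0.5, 0.1, rng)
            flux = fusion_fission_flux(d, pert, spec, 0.0)
            assert abs(flux.sum()) < 1e-12
            assert np.dot(q, flux) <= np.dot(q, conserving) + 1e-12

    def test_correction_path_equals_explicit_list(self, rng):
        n = 9
        ev = enumerate_events(n)
        sel = SelectivityProfile(0.0, 1.0, 4.0, 2.0, zero_at_floor=True)
        spec = ff_spec(0.4, sel)
        kernel = FusionFissionKernel(n, sel)
        d = random_initial_distribution(n, 2)
        for eps_max in (None, 1):
            idx, lo, hi = sample_perturbation(ev, 0.4, rng, eps_max)
            explicit_lo = ev.l_out.copy()
            explicit_hi = ev.m_out.copy()
            explicit_lo[idx] = lo
            explicit_hi[idx] = hi
            pert = EventList(n, ev.l_in, ev.m_in, explicit_lo, explicit_hi,
                             "perturbed")
            expected = fusion_fission_flux(d, pert, spec, 0.0)
            got = kernel.flux(d.probs, 0.4) + perturbation_flux_correction(
                ev, idx, lo, hi, d.probs, kernel.s, 0.4
            )
            np.testing.assert_allclose(got, expected, atol=1e-15)


class TestPerturbEventList:
    def test_zero_rate_identity(self, rng):
        ev = enumerate_events(6)
        out = perturb_event_list(ev, 0.0, 0.5, 0.1, rng)
        assert out.flag == "conserving"
        np.testing.assert_array_equal(out.l_out, ev.l_out)
        np.testing.assert_array_equal(out.m_out, ev.m_out)

    def test_maximal_infection_keeps_deficits_nonnegative(self, rng):
        ev = enumerate_events(8)
        out = perturb_event_list(ev, 0.5, 0.5, 0.1, rng)
        assert out.flag == "perturbed"
        assert np.all(out.quality_deficit >= 0)
        assert np.all(out.l_out >= 0)
        assert np.all(out.l_out <= out.m_out)

    def test_eps_max_caps_reduction(self, rng):
        ev = enumerate_events(12)
        out = perturb_event_list(ev, 0.5, 0.5, 0.1, rng, eps_max=1)
        assert np.all(out.quality_deficit <= 2)

    def test_perturbed_fraction_binomial(self, rng):
        # half infection probability: damaged-event count over many
        # regenerations is Binomial(n_events, 1/2)
        ev = enumerate_events(5)
        n_trials = 10_000
        changed = 0
        total = 0
        for _ in range(n_trials):
            out = perturb_event_list(ev, 0.25, 0.5, 0.1, rng)
            # an event is counted as touched when its outputs moved;
            # untouched damaged events (eps1=eps2=0) are rare enough not to
            # bias the 3-sigma check at eps ranges >= 1
            changed += int(
                ((out.l_out != ev.l_out) | (out.m_out != ev.m_out)).sum()
            )
            total += len(ev)
        frac = changed / total
        p_touch = 0.5 * (1 - 1 / 2 * 1 / 3)  # P(damaged) * P(outputs move)
        se = np.sqrt(0.5 * 0.5 / total)
        assert abs(frac - p_touch) < 5 * se + 0.02

    def test_rate_contract_violation(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            perturb_event_list(enumerate_events(4), 0.6, 0.5, 0.1, rng)


class TestDecayFlux:
    def spec(self, rate=0.01, sel=None):
        return ProcessSpec("decay", const_schedule(rate),
                           sel or unit_selectivity())

    def test_floor_state_cannot_decay(self):
        d = QualityDistribution(np.array([1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(decay_flux(d, self.spec(), 0.0), 0.0)

    def test_single_step_down_stencil(self):
        d = QualityDistribution(np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(
            decay_flux(d, self.spec(0.01), 0.0), [0.0, 0.01, -0.01], atol=1e-15
        )

    def test_norm_conserved_mean_quality_falls(self):
        for seed in range(10):
            d = random_initial_distribution(12, seed)
            flux = decay_flux(d, self.spec(), 0.0)
            assert abs(flux.sum()) < 1e-12
            assert np.dot(np.arange(12), flux) <= 0

    def test_unit_selectivity_mean_derivative(self):
        # with no mass at the floor the mean falls at exactly the decay rate
        p = np.zeros(10)
        p[5:] = 0.2
        d = QualityDistribution(p)
        flux = decay_flux(d, self.spec(0.01), 0.0)
        assert np.dot(np.arange(10), flux) == pytest.approx(-0.01)


class TestTurnoverFlux:
    def test_zero_mitophagy_zero_renewal(self):
        d = QualityDistribution(np.array([0.5, 0.5]))
        spec = ProcessSpec("mitophagy", const_schedule(0.0), unit_selectivity())
        flux, renewal = turnover_flux(d, spec, unit_selectivity(), 0.0)
        np.testing.assert_array_equal(flux, 0.0)
        assert renewal == 0.0

    def test_two_state_hand_balance(self):
        d = QualityDistribution(np.array([0.5, 0.5]))
        # selectivity values are exactly (1, 0.5) for mitophagy and (0, 1)
        # for renewal on the two-state ladder
        mito = ProcessSpec(
            "mitophagy",
            const_schedule(0.01),
            SelectivityProfile(1.0, 0.0, 1.0, 1.0),
        )
        renewal_sel = SelectivityProfile(1.0, 1.0, 1.0, 1.0, zero_at_floor=True)
        flux, renewal = turnover_flux(d, mito, renewal_sel, 0.0)
        assert renewal == pytest.approx(0.015)
        np.testing.assert_allclose(flux, [-0.005, 0.005], atol=1e-15)

    def test_norm_conserved_on_random_distributions(self):
        mito = ProcessSpec(
            "mitophagy", const_schedule(0.02),
            SelectivityProfile(1.0, 0.2, 5.0, 2.0),
        )
        ren = SelectivityProfile(0.0, 1.0, 5.0, 2.0, zero_at_floor=True)
        for seed in range(10):
            d = random_initial_distribution(11, seed)
            flux, renewal = turnover_flux(d, mito, ren, 0.0)
            assert abs(flux.sum()) < 1e-12
            assert renewal >= 0

    def test_degenerate_rheostat_raises(self):
        # all mass at the floor, renewal selectivity zero there
        d = QualityDistribution(np.array([1.0, 0.0]))
        mito = ProcessSpec("mitophagy", const_schedule(0.01), unit_selectivity())
        ren = SelectivityProfile(0.0, 1.0, 0.5, 1.0, zero_at_floor=True)
        with pytest.raises(RheostatDegenerateError):
            turnover_flux(d, mito, ren, 0.0)


class _ForcedRng:
    """Deterministic stand-in for a Generator: scripted draws."""

    def __init__(self, poisson, integers, uniforms):
        self._poisson = poisson
        self._integers = list(integers)
        self._uniforms = list(uniforms)

    def poisson(self, mu):
        return self._poisson

    def integers(self, low, high):
        return self._integers.pop(0)

    def random(self):
        return self._uniforms.pop(0)


class TestRandomDamageStep:
    def test_zero_rate_identity(self, rng):
        d = random_initial_distribution(6, 1)
        out = random_damage_step(d, 0.0, 0.5, 0.1, rng)
        np.testing.assert_array_equal(out.probs, d.probs)

    def test_single_forced_event(self):
        # event l=4 -> l'=1, fraction 0.5 halves p(4) and credits p(1)
        p = np.array([0.1, 0.1, 0.2, 0.2, 0.4])
        d = QualityDistribution(p)
        forced = _ForcedRng(poisson=1, integers=[4, 1], uniforms=[0.5])
        out = random_damage_step(d, 1.0, 1.0, 1.0, forced)
        assert out.probs[4] == pytest.approx(0.2)
        assert out.probs[1] == pytest.approx(0.3)

    def test_norm_preserved_exactly(self, rng):
        for seed in range(10):
            d = random_initial_distribution(15, seed)
            out = random_damage_step(d, 5.0, 0.5, 1.0, rng)
            assert abs(out.probs.sum() - d.probs.sum()) < 1e-12
            assert np.all(out.probs >= 0)

    def test_mean_quality_nonincreasing(self, rng):
        q = np.arange(15)
        for seed in range(10):
            d = random_initial_distribution(15, seed)
            out = random_damage_step(d, 5.0, 0.5, 1.0, rng)
            assert np.dot(q, out.probs) <= np.dot(q, d.probs) + 1e-12

    def test_invalid_r_max(self, rng):
        d = random_initial_distribution(5, 0)
        with pytest.raises(Exception):
            random_damage_step(d, 1.0, 0.0, 1.0, rng)


def full_specs(n, ff=0.5, dec=0.01, mito=0.01, rd=0.2, idr=0.05):
    K = (n - 1) / 2
    up = SelectivityProfile(0.0, 1.0, K, 2.0, zero_at_floor=True)
    down = SelectivityProfile(1.0, 0.2, K, 2.0)
    return {
        "fusion_fission": ProcessSpec("fusion_fission", const_schedule(ff), up),
        "decay": ProcessSpec("decay", const_schedule(dec), down),
        "mitophagy": ProcessSpec("mitophagy", const_schedule(mito), down),
        "renewal": ProcessSpec("renewal", None, up),
        "random_damage": ProcessSpec(
            "random_damage", const_schedule(rd), None, {"r_max": 0.5}
        ),
        "infectious_damage": ProcessSpec(
            "infectious_damage", const_schedule(idr), None,
            {"rd_limit": 0.1, "id_max": idr, "eps_max": 1},
        ),
    }


class TestAssembleRhs:
    def test_all_rates_zero_gives_zero_flux(self):
        d = random_initial_distribution(6, 3)
        specs = full_specs(6, ff=0.0, dec=0.0, mito=0.0)
        res = assemble_rhs(d, enumerate_events(6), specs, 0.0, "none")
        np.testing.assert_array_equal(res.flux, 0.0)
        assert res.renewal_rate == 0.0

    def test_mode_none_conserves_norm(self):
        specs = full_specs(8)
        ev = enumerate_events(8)
        for seed in range(10):
            d = random_initial_distribution(8, seed)
            res = assemble_rhs(d, ev, specs, 0.0, "none")
            assert abs(res.flux.sum()) < 1e-12

    def test_infectious_quality_flux_not_above_conserving(self, rng):
        specs = full_specs(8)
        ev = enumerate_events(8)
        d = random_initial_distribution(8, 5)
        q = np.arange(8)
        base = assemble_rhs(d, ev, specs, 0.0, "none")
        for _ in range(10):
            res = assemble_rhs(d, ev, specs, 0.0, "infectious", rng, 0.1)
            assert res.events_used.flag == "perturbed"
            assert np.dot(q, res.flux) <= np.dot(q, base.flux) + 1e-12

    def test_missing_spec_rejected(self):
        specs = full_specs(5)
        del specs["random_damage"]
        d = random_initial_distribution(5, 0)
        with pytest.raises(Exception, match="random_damage"):
            assemble_rhs(d, enumerate_events(5), specs, 0.0, "random",
                         np.random.default_rng(0), 0.1)
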