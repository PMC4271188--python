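"""Kinetic assay simulator: pyranine readout, clamped-voltage fluxes,
coupling conservation, determinism, and agreement with the closed-form
thermodynamics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepflux import (
    AssayConditions,
    AssayEvent,
    AssayProtocol,
    LiposomeParams,
    ProtocolError,
    Stoichiometry,
    accumulation_ratio,
    bisect_reversal,
    pyranine_ratio,
    required_k_out,
    reversal_potential,
    simulate_assay,
    simulate_kinetics,
    simulate_replicates,
)
from pepflux.simulate import (
    SubstrateSpec,
    alanine,
    di_alanine,
    tetra_alanine,
    tri_alanine,
)


def clamped_protocol(cond, substrate, voltage_mv, **kwargs):
    """Protocol whose K+ gradient clamps the stated voltage on valinomycin
    addition at t = 10 s."""
    c = replace(cond, k_out=required_k_out(voltage_mv, cond.k_in))
    defaults = dict(duration=70.0, sample_interval=0.5, noise_sd=0.0, seed=0)
    defaults.update(kwargs)
    return AssayProtocol(
        conditions=c,
        substrate=substrate,
        events=(AssayEvent(10.0, "valinomycin"),),
        **defaults,
    )


class TestPyranineRatio:
    def test_midpoint_at_pka(self, liposome):
        mid = 0.5 * (liposome.ratio_min + liposome.ratio_max)
        assert pyranine_ratio(liposome.pyranine_pka, liposome) == pytest.approx(mid)

    def test_asymptotes(self, liposome):
        assert pyranine_ratio(14.0, liposome) == pytest.approx(
            liposome.ratio_max, rel=1e-4
        )
        assert pyranine_ratio(0.0, liposome) == pytest.approx(
            liposome.ratio_min, rel=1e-4
        )

    @settings(max_examples=50, deadline=None)
    @given(ph_lo=st.floats(2.0, 12.0), delta=st.floats(0.01, 2.0))
    def test_strictly_increasing_in_ph(self, ph_lo, delta):
        lip = LiposomeParams()
        assert pyranine_ratio(ph_lo, lip) < pyranine_ratio(ph_lo + delta, lip)


class TestSubstrateGating:
    def test_only_di_and_tri_transported(self):
        assert di_alanine().transported
        assert tri_alanine().transported
        assert not tetra_alanine().transported
        assert not alanine().transported

    def test_tetra_peptide_gives_flat_trace(self, standard_conditions, liposome):
        proto = clamped_protocol(standard_conditions, tetra_alanine(), -120.0)
        kin = simulate_kinetics(proto, liposome)
        assert np.allclose(kin.ph_in, kin.ph_in[0])

    def test_no_valinomycin_means_no_flux(self, standard_conditions, liposome):
        proto = AssayProtocol(
            conditions=standard_conditions,
            substrate=tri_alanine(),
            events=(),
            noise_sd=0.0,
        )
        kin = simulate_kinetics(proto, liposome)
        assert np.allclose(kin.ph_in, kin.ph_in[0])
        assert np.all(kin.applied_mv == 0.0)


class TestFluxDirections:
    def test_acidification_below_and_alkalinization_above_reversal(
        self, standard_conditions, liposome, tri_ala
    ):
        """3:1 tri-peptide, 100-fold inward gradient: reversal at -40 mV, so
        -60 mV acidifies the lumen and -30 mV alkalinizes it."""
        kin_acid = simulate_kinetics(
            clamped_protocol(standard_conditions, tri_ala, -60.0), liposome
        )
        kin_alk = simulate_kinetics(
            clamped_protocol(standard_conditions, tri_ala, -30.0), liposome
        )
        assert kin_acid.ph_in[-1] < kin_acid.ph_in[0] - 0.05
        assert kin_alk.ph_in[-1] > kin_alk.ph_in[0] + 0.02

    def test_zero_drive_at_reversal(self, standard_conditions, liposome, tri_ala):
        rev = reversal_potential(standard_conditions, tri_ala.stoichiometry)
        kin = simulate_kinetics(
            clamped_protocol(standard_conditions, tri_ala, rev), liposome
        )
        assert np.max(np.abs(kin.ph_in - kin.ph_in[0])) < 1e-6

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(1, 6),
        offset=st.floats(-40.0, 40.0),
        log_gradient=st.floats(-2.0, 2.0),
        dph=st.floats(-0.8, 0.8),
    )
    def test_initial_direction_matches_driving_force(
        self, n, offset, log_gradient, dph
    ):
        """The sign of the initial pH slope equals the sign of the negated
        driving force for randomized gradients, voltages and coupling."""
        if abs(offset) < 1.0:
            offset = math.copysign(1.0, offset or 1.0)
        cond = AssayConditions(
            ph_in=6.8 + dph, ph_out=6.8, pep_in=1.0 * 10**log_gradient, pep_out=1.0
        )
        sub = SubstrateSpec("probe", 3, 125.0, Stoichiometry(n))
        rev = reversal_potential(cond, sub.stoichiometry)
        applied = rev + offset
        proto = clamped_protocol(cond, sub, applied, duration=12.0)
        kin = simulate_kinetics(proto)
        dph_net = kin.ph_in[-1] - kin.ph_in[0]
        # driving = applied - rev = offset; negative => inward protons,
        # i.e. the lumen pH falls
        assert math.copysign(1.0, dph_net) == math.copysign(1.0, offset)

    def test_peptide_spike_accelerates_uptake(self, liposome, tri_ala):
        """Raising external peptide mid-run (grey-arrow spike) increases the
        saturation term and deepens acidification."""
        cond = AssayConditions(ph_in=6.8, ph_out=6.8, pep_in=10.0, pep_out=0.05)
        base = clamped_protocol(cond, tri_ala, -120.0)
        spiked = replace(
            base,
            events=(
                AssayEvent(10.0, "valinomycin"),
                AssayEvent(30.0, "peptide_spike", 0.5),
            ),
        )
        kin_base = simulate_kinetics(base, liposome)
        kin_spiked = simulate_kinetics(spiked, liposome)
        assert kin_spiked.pep_out[-1] == pytest.approx(0.55)
        assert kin_spiked.ph_in[-1] < kin_base.ph_in[-1]

    def test_unknown_event_kind_raises(self, standard_conditions, tri_ala):
        proto = AssayProtocol(
            conditions=standard_conditions,
            substrate=tri_ala,
            events=(AssayEvent(5.0, "cccp"),),
        )
        with pytest.raises(ProtocolError):
            simulate_kinetics(proto)

    def test_event_outside_run_raises(self, standard_conditions, tri_ala):
        with pytest.raises(ProtocolError):
            AssayProtocol(
                conditions=standard_conditions,
                substrate=tri_ala,
                events=(AssayEvent(200.0, "valinomycin"),),
                duration=70.0,
            )


class TestConservationAndAccuracy:
    def test_proton_peptide_coupling_conservation(
        self, standard_conditions, liposome, tri_ala
    ):
        """With the leak off, protons moved (buffer * -dpH) equal n/m times
        peptides moved at every sample."""
        proto = clamped_protocol(standard_conditions, tri_ala, -80.0)
        kin = simulate_kinetics(proto, liposome)
        protons = -(kin.ph_in - kin.ph_in[0]) * liposome.buffer_capacity
        peptides = kin.pep_in - kin.pep_in[0]
        ratio = tri_ala.stoichiometry.n_protons / tri_ala.stoichiometry.m_peptides
        assert np.allclose(protons, ratio * peptides, atol=1e-10)

    def test_step_halving_self_check(self, standard_conditions, liposome, tri_ala):
        """Halving the integration step changes the 60 s readout by far less
        than 1e-4 pH units."""
        proto = clamped_protocol(standard_conditions, tri_ala, -60.0)
        coarse = simulate_kinetics(proto, liposome, substeps=10)
        fine = simulate_kinetics(proto, liposome, substeps=20)
        i60 = int(round(60.0 / proto.sample_interval))
        assert abs(coarse.ph_in[i60] - fine.ph_in[i60]) < 1e-6

    def test_long_time_equilibrium_matches_accumulation_ratio(self, liposome):
        """Run to equilibrium: the final internal/external peptide ratio
        matches the closed-form accumulation ratio at the clamped voltage
        evaluated at the final lumen pH."""
        cond = AssayConditions(ph_in=6.8, ph_out=6.8, pep_in=1.0, pep_out=0.5)
        sub = di_alanine(2)
        proto = clamped_protocol(cond, sub, -25.0, duration=4000.0, sample_interval=2.0)
        kin = simulate_kinetics(proto, liposome)
        expected = accumulation_ratio(
            sub.stoichiometry, cond.ph_out, kin.ph_in[-1], -25.0
        )
        assert kin.pep_in[-1] / kin.pep_out[-1] == pytest.approx(expected, rel=0.01)

    def test_bisection_recovers_reversal(self, standard_conditions, tri_ala):
        """Bisection on the noise-free simulator locates the closed-form
        reversal potential to better than 0.5 mV."""
        rev = reversal_potential(standard_conditions, tri_ala.stoichiometry)
        found = bisect_reversal(standard_conditions, tri_ala)
        assert abs(found - rev) < 0.5

    def test_leak_pulls_ph_toward_proton_equilibrium(self, liposome):
        """With only a leak (no transportable substrate), a negative clamp
        drags protons inward."""
        cond = AssayConditions(ph_in=6.8, ph_out=6.8, pep_in=1.0, pep_out=1.0)
        leaky = replace(liposome, leak_conductance=1e-3)
        proto = clamped_protocol(cond, tetra_alanine(), -100.0)
        kin = simulate_kinetics(proto, leaky)
        assert kin.ph_in[-1] < kin.ph_in[0] - 0.1


class TestReplicatesAndNoise:
    def test_seeded_determinism(self, standard_conditions, tri_ala):
        proto = clamped_protocol(standard_conditions, tri_ala, -60.0, noise_sd=0.01)
        a = simulate_replicates(proto, n_replicates=3)
        b = simulate_replicates(proto, n_replicates=3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.f460, tb.f460)
            assert np.array_equal(ta.f415, tb.f415)

    def test_zero_noise_replicates_identical(self, standard_conditions, tri_ala):
        proto = clamped_protocol(standard_conditions, tri_ala, -60.0, noise_sd=0.0)
        reps = simulate_replicates(proto, n_replicates=3)
        for tr in reps[1:]:
            assert np.array_equal(tr.f460, reps[0].f460)

    def test_replicate_mean_converges_to_noise_free(
        self, standard_conditions, liposome, tri_ala
    ):
        """Law of large numbers: the replicate mean at 60 s approaches the
        noise-free channel value as the replicate count grows."""
        proto = clamped_protocol(standard_conditions, tri_ala, -60.0, noise_sd=0.02)
        reps = simulate_replicates(proto, liposome, n_replicates=200)
        i60 = int(round(60.0 / proto.sample_interval))
        noise_free = simulate_assay(replace(proto, noise_sd=0.0), liposome)
        mean460 = np.mean([tr.f460[i60] for tr in reps])
        sem = 0.02 * liposome.f415_scale / np.sqrt(200)
        assert abs(mean460 - noise_free.f460[i60]) < 5 * sem


class TestProtocolSerialisation:
    def test_round_trip(self, standard_conditions, tri_ala):
        proto = clamped_protocol(standard_conditions, tri_ala, -60.0, seed=42)
        assert AssayProtocol.from_dict(proto.to_dict()) == proto

    def test_unsupported_schema_version(self, standard_conditions, tri_ala):
        data = clamped_protocol(standard_conditions, tri_ala, -60.0).to_dict()
        data["schema_version"] = 99
        with pytest.raises(ProtocolError):
            AssayProtocol.from_dict(data)
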