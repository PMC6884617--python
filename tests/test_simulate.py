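"""Measurement emulation: seeding, noise, media accounting, MID realism."""

import numpy as np
import pandas as pd
import pytest

from glutrace.mid import IsotopeAbundances, MIDVector, correct_mid, natural_mid
from glutrace.network import steady_state_labeling
from glutrace.presets import PRESETS
from glutrace.simulate import (
    MEDIA_BLANK_MM,
    ExperimentDesign,
    measured_mid,
    simulate_biomass_enrichment,
    simulate_experiment,
    simulate_feature_table,
    tracked_correction_matrix,
)


@pytest.fixture(scope="module")
def hepl_states():
    return steady_state_labeling(PRESETS["HEP-L"].network(), "U13C15N2-Gln")


class TestSeeding:
    def test_same_seed_bit_identical(self):
        d = ExperimentDesign(condition="HEP-L", n_replicates=3, seed=11)
        b1, b2 = simulate_experiment(d), simulate_experiment(d)
        pd.testing.assert_frame_equal(b1.media, b2.media)
        pd.testing.assert_frame_equal(b1.mids, b2.mids)
        pd.testing.assert_frame_equal(b1.fa_mids, b2.fa_mids)
        np.testing.assert_array_equal(b1.biomass_atom_pct, b2.biomass_atom_pct)

    def test_different_seed_differs(self):
        b1 = simulate_experiment(ExperimentDesign(condition="HEP-L", n_replicates=3, seed=1))
        b2 = simulate_experiment(ExperimentDesign(condition="HEP-L", n_replicates=3, seed=2))
        assert not np.allclose(
            b1.media["harvest_mM"].to_numpy(), b2.media["harvest_mM"].to_numpy()
        )


class TestMediaAccounting:
    def test_zero_net_flux_keeps_blank_concentration(self):
        from glutrace.network import build_default_network

        net = build_default_network(
            {"gln_uptake": 0.5, "gls": 0.5, "glu_secretion": 0.2, "glu_uptake": 0.2,
             "glu_to_akg": 0.3, "akg_ox": 0.3, "mal_to_oaa": 0.3}
        )
        d = ExperimentDesign(condition="HEP-L", n_replicates=2, conc_noise_cv=0.0, seed=0)
        bundle = simulate_experiment(d, network=net)
        glu = bundle.media[bundle.media["metabolite"] == "glutamate"]
        np.testing.assert_allclose(glu["harvest_mM"], glu["blank_mM"])

    def test_depletion_guard(self):
        d = ExperimentDesign(condition="HEP-L", hours=120.0, n_replicates=2, seed=0)
        with pytest.raises(ValueError, match="reduce fluxes|shorten"):
            simulate_experiment(d)

    def test_uptake_depletes_secretion_accumulates(self):
        d = ExperimentDesign(condition="HEP-L", n_replicates=2, conc_noise_cv=0.0, seed=0)
        bundle = simulate_experiment(d)
        media = bundle.media.groupby("metabolite").first()
        assert media.loc["glutamine", "harvest_mM"] < MEDIA_BLANK_MM["glutamine"]
        assert media.loc["glutamate", "harvest_mM"] > MEDIA_BLANK_MM["glutamate"]


class TestMeasurementModel:
    def test_noiseless_mid_is_natural_convolution(self, hepl_states):
        """CV 0: the measured MID equals true labeling + natural abundance."""
        d = ExperimentDesign(condition="HEP-L", n_replicates=1, mid_noise_cv=0.0, seed=0)
        bundle = simulate_experiment(d)
        for met in ("Cit", "Mal", "Lac"):
            expected = measured_mid(hepl_states[met])
            got = bundle.mid_vectors(met)[0].abundances
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_unlabeled_state_measures_as_natural_mid(self, hepl_states):
        """An unlabeled molecule's measured MID is its theoretical natural MID."""
        from glutrace.network import IsotopomerState, Metabolite

        met = Metabolite("Lac", 3, formula="C3H6O3")
        dist = np.zeros(8)
        dist[0] = 1.0
        got = measured_mid(IsotopomerState(met, dist))
        expected = natural_mid("C3H6O3", max_shift=3).abundances
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_correction_inverts_measurement_single_isotope(self):
        """Carbon-only tracer: correcting the noiseless measured MID
        recovers the true labeling exactly."""
        states = steady_state_labeling(PRESETS["HEP-L"].network(), "5-13C-Gln")
        for name in ("Cit", "Mal"):
            st = states[name]
            raw = MIDVector(name, measured_mid(st), corrected=False)
            matrix = tracked_correction_matrix(st.metabolite)
            corrected = correct_mid(raw, matrix)
            np.testing.assert_allclose(corrected.abundances, st.mid().abundances, atol=1e-6)

    def test_correction_inverts_measurement_dual_isotope(self, hepl_states):
        """Dual 13C/15N tracer: the carbon-first correction matrix is an
        approximation of the exact element-aware measurement; the
        residual error stays far below the measurement noise floor."""
        st = hepl_states["Glu"]
        raw = MIDVector("Glu", measured_mid(st), corrected=False)
        corrected = correct_mid(raw, tracked_correction_matrix(st.metabolite))
        np.testing.assert_allclose(corrected.abundances, st.mid().abundances, atol=5e-3)


class TestPoolsBiomassFattyAcids:
    def test_labeled_pool_scales_with_labeled_fraction(self, hepl_states):
        d = ExperimentDesign(condition="HEP-L", n_replicates=4, mid_noise_cv=0.0, seed=0)
        bundle = simulate_experiment(d)
        pro = bundle.labeled_pools[bundle.labeled_pools["metabolite"] == "Pro"]
        expected = PRESETS["HEP-L"].pool_eic_scale * hepl_states["Pro"].labeled_fraction()
        np.testing.assert_allclose(pro["eic_per_mg"], expected)

    def test_biomass_baseline_without_incorporation(self):
        from glutrace.network import build_default_network
        from glutrace.rates import CIRMS_BASELINE_ATOM_PCT

        fluxes = dict(PRESETS["HEP-L"].fluxes)
        fluxes["glu_to_protein"] = 0.0
        d = ExperimentDesign(condition="HEP-L", n_replicates=3, seed=0)
        bundle = simulate_experiment(d, network=build_default_network(fluxes))
        assert bundle.truth["biomass_enrichment"] == pytest.approx(0.0)
        assert np.allclose(bundle.biomass_atom_pct, CIRMS_BASELINE_ATOM_PCT, atol=0.01)

    def test_biomass_helper_is_seeded(self):
        a = simulate_biomass_enrichment("HDF", n=4, seed=5)
        b = simulate_biomass_enrichment("HDF", n=4, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_fatty_acid_mid_matches_forward_model(self):
        from glutrace.isa import ISAModelSpec, isa_forward

        d = ExperimentDesign(
            condition="HEP-L", tracer="5-13C-Gln", n_replicates=1, mid_noise_cv=0.0, seed=0
        )
        bundle = simulate_experiment(d)
        spec = ISAModelSpec(n_units=7, unit_shift=1)
        expected = isa_forward(spec, bundle.truth["isa_D"], bundle.truth["isa_g"]).abundances
        got = bundle.fa_mids[bundle.fa_mids["replicate"] == 0].sort_values("shift")
        np.testing.assert_allclose(got["abundance"].to_numpy(), expected, atol=1e-12)


class TestFeatureTableSim:
    def test_shapes_and_groups(self):
        t = simulate_feature_table(n_features=50, n_per_group=4, n_changed=5, seed=0)
        assert t.intensities.shape == (50, 8)
        assert sorted(t.groups.unique()) == ["HDF", "HEP-L"]
        assert len(t.changed_features) == 5

    def test_null_table_has_no_planted_effects(self):
        t = simulate_feature_table(n_features=200, n_per_group=6, n_changed=0, seed=1)
        a = np.log2(t.intensities[t.samples_of("HEP-L")]).mean(axis=1)
        b = np.log2(t.intensities[t.samples_of("HDF")]).mean(axis=1)
        # group-mean differences center on zero
        assert abs((a - b).mean()) < 0.1

    def test_effect_size_zero_equals_null(self):
        t = simulate_feature_table(n_features=100, n_per_group=4, n_changed=20,
                                   log2_effect=0.0, seed=2)
        a = np.log2(t.intensities[t.samples_of("HEP-L")]).mean(axis=1)
        b = np.log2(t.intensities[t.samples_of("HDF")]).mean(axis=1)
        assert abs((a - b).mean()) < 0.15

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_feature_table(n_features=10, n_changed=11)
        with pytest.raises(ValueError):
            simulate_feature_table(n_per_group=1)
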