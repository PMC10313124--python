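"""Chord sampling, track counts, damage realizations, SDD export."""

import io

import numpy as np
import pytest

from mgm.core import discretized_complexity_pmf
from mgm.damage_metrics import complexity_score
from mgm.generator import (
    NucleusGeometry,
    decompose_complexity,
    expected_tracks,
    generate,
    realization_to_point_cloud,
    realization_to_sdd,
    sample_chord,
)
from mgm.microdosimetry import BeamSpectrum, KEV_TO_J
from mgm.sdd_io import read_sdd, write_sdd


class TestSampleChord:
    def test_chord_length_bounded_by_diameter(self, nucleus, rng):
        for _ in range(100):
            _, _, length = sample_chord(nucleus, rng)
            assert 0 <= length <= nucleus.diameter_um

    def test_mean_chord_matches_cauchy_formula(self, nucleus, rng):
        lengths = np.array(
            [sample_chord(nucleus, rng)[2] for _ in range(50_000)])
        se = lengths.std() / np.sqrt(lengths.size)
        assert abs(lengths.mean() - 2 * nucleus.diameter_um / 3) < 4 * se

    def test_entry_point_on_sphere_surface(self, nucleus, rng):
        entry, direction, length = sample_chord(nucleus, rng)
        assert np.linalg.norm(entry) == pytest.approx(nucleus.radius_um)
        exit_point = entry + length * direction
        assert np.linalg.norm(exit_point) == pytest.approx(nucleus.radius_um)

    def test_isotropic_directions_cover_the_sphere(self, nucleus, rng):
        dirs = np.array(
            [sample_chord(nucleus, rng, isotropic=True)[1] for _ in range(2000)])
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        assert np.abs(dirs.mean(axis=0)).max() < 0.05


class TestExpectedTracks:
    def test_printed_example_high_let_alpha(self, nucleus):
        # yF = 115.3 keV/um in the 9.65 um nucleus: zF ~ 0.2526 Gy/event,
        # so 6 Gy needs ~23.75 tracks
        assert expected_tracks(6.0, 115.3, nucleus) == pytest.approx(23.75, rel=2e-3)

    def test_linear_in_dose(self, nucleus):
        assert expected_tracks(4.0, 50.0, nucleus) == pytest.approx(
            2 * expected_tracks(2.0, 50.0, nucleus))

    def test_diameter_squared_scaling(self):
        # zF ~ 1/d^2, so track count at fixed dose and yF scales as d^2
        small = expected_tracks(1.0, 50.0, NucleusGeometry(diameter_um=5.0))
        large = expected_tracks(1.0, 50.0, NucleusGeometry(diameter_um=20.0))
        assert large / small == pytest.approx(16.0, rel=1e-12)


class TestGenerate:
    def test_zero_dose_is_empty(self, truth_params, beam, nucleus):
        real = generate(0.0, beam, truth_params, nucleus, seed=0)
        assert real.n_tracks == 0 and real.n_sites == 0

    def test_sites_inside_nucleus(self, truth_params, beam, nucleus):
        real = generate(4.0, beam, truth_params, nucleus, seed=3)
        assert real.n_sites > 0
        radii = np.linalg.norm([s.position_um for s in real.sites], axis=1)
        assert radii.max() <= nucleus.radius_um + 1e-9

    def test_fixed_seed_bit_reproducible(self, truth_params, beam, nucleus):
        a = generate(2.0, beam, truth_params, nucleus, seed=42)
        b = generate(2.0, beam, truth_params, nucleus, seed=42)
        assert a.n_tracks == b.n_tracks
        assert np.array_equal(a.complexities, b.complexities)
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.array_equal(ta.entry_um, tb.entry_um)

    def test_mean_site_count_matches_dose_scaled_yield(
            self, truth_params, beam, nucleus):
        dose, n_real = 1.0, 400
        yF = beam.yF_values[0]
        mu = expected_tracks(dose, yF, nucleus) * \
            truth_params.yields.n_ds_with_dsb(yF)
        counts = np.array([
            generate(dose, beam, truth_params, nucleus, seed=s).n_sites
            for s in range(n_real)])
        # compound Poisson variance: nu*(m + m^2)
        nu = expected_tracks(dose, yF, nucleus)
        m = truth_params.yields.n_ds_with_dsb(yF)
        se = np.sqrt(nu * (m + m**2) / n_real)
        assert abs(counts.mean() - mu) < 4 * se

    def test_energy_bookkeeping_recovers_dose(self, truth_params, nucleus):
        # total imparted energy / nucleus mass ~ dose, within Poisson error
        beam = BeamSpectrum.single(115.3)
        dose = 6.0
        doses = []
        for s in range(300):
            real = generate(dose, beam, truth_params, nucleus, seed=s)
            energy_J = real.energy_imparted_keV() * KEV_TO_J
            doses.append(energy_J / nucleus.as_site().mass_kg)
        doses = np.array(doses)
        se = doses.std() / np.sqrt(doses.size)
        assert abs(doses.mean() - dose) < 4 * se

    def test_mixture_complexities_follow_weighted_mixture(self, truth_params,
                                                          nucleus):
        """Pooled complexity distribution of a two-component beam equals the
        site-count-weighted mixture of the component laws."""
        beam = BeamSpectrum([(0.5, 10.0), (0.5, 150.0)])
        nucleus_small = NucleusGeometry(diameter_um=6.0)
        all_c = np.concatenate([
            generate(3.0, beam, truth_params, nucleus_small, seed=s).complexities
            for s in range(300)])
        # expected mixture pmf, weighted by expected site counts per component
        weights, pmfs, supports = [], [], []
        for w, yF in beam.components:
            mu = expected_tracks(w * 3.0, yF, nucleus_small) * \
                truth_params.yields.n_ds_with_dsb(yF)
            ks, masses = discretized_complexity_pmf(yF, truth_params.gamma)
            weights.append(mu)
            pmfs.append(masses)
            supports.append(ks)
        weights = np.array(weights) / np.sum(weights)
        kmax = max(s.max() for s in supports)
        mix = np.zeros(kmax + 1)
        for w, ks, masses in zip(weights, supports, pmfs):
            mix[ks] += w * masses
        n = all_c.size
        for k in range(2, 15):
            freq = np.mean(all_c == k)
            se = np.sqrt(mix[k] * (1 - mix[k]) / n)
            assert abs(freq - mix[k]) < 5 * se + 5e-3

    def test_invalid_params_fail_before_sampling(self, truth_params, nucleus):
        from mgm.core import GammaComplexityParams, MGMParameters
        bad = MGMParameters(
            yields=truth_params.yields,
            gamma=GammaComplexityParams(poly_a=(1.0, -0.1, 0), poly_b=(1.0, 0, 0)),
        )
        with pytest.raises(ValueError):
            generate(1.0, BeamSpectrum.single(50.0), bad, nucleus, seed=0)


class TestSddExport:
    def test_simple_dsb_decomposes_to_one_break_per_strand(self):
        assert decompose_complexity(2) == (1, 1, 0)

    @pytest.mark.parametrize("c", range(2, 20))
    @pytest.mark.parametrize("bd_fraction", [0.0, 0.5, 1.0])
    def test_decomposition_scores_back_to_complexity(self, c, bd_fraction):
        sb1, sb2, bd = decompose_complexity(c, bd_fraction)
        assert sb1 >= 1 and sb2 >= 1
        assert sb1 + sb2 + bd == c

    def test_records_rescore_to_generated_complexities(
            self, truth_params, beam, nucleus):
        real = generate(3.0, beam, truth_params, nucleus, seed=9)
        _, records = realization_to_sdd(real, seed=1)
        assert len(records) == real.n_sites
        scores = [complexity_score(r) for r in records]
        assert scores == [s.complexity for s in real.sites]

    def test_export_reparses_and_rescores_identically(
            self, truth_params, beam, nucleus):
        real = generate(5.0, beam, truth_params, nucleus, seed=13)
        header, records = realization_to_sdd(real, seed=2)
        buf = io.StringIO()
        write_sdd(header, records, buf)
        _, records2 = read_sdd(io.StringIO(buf.getvalue()))
        assert records2 == records
        assert [complexity_score(r) for r in records2] == \
            [s.complexity for s in real.sites]

    def test_point_cloud_shape(self, truth_params, beam, nucleus):
        real = generate(2.0, beam, truth_params, nucleus, seed=4)
        cloud = realization_to_point_cloud(real)
        assert cloud.shape == (real.n_sites, 4)
        assert np.array_equal(cloud[:, 3].astype(int), real.complexities)
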