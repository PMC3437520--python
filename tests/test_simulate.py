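"""Synthetic-data generators: stated structure, determinism, validity."""

import numpy as np
import pytest
from scipy.stats import linregress, spearmanr

from shallowseq import SimulationConfig, ValidationError
from shallowseq.simulate import (
    _module_sizes,
    gen_abundances,
    gen_eqtl_catalog,
    gen_expression_matrix,
    gen_modules,
    gen_time_course,
)


class TestConfig:
    def test_yaml_round_trip_lossless(self, small_config):
        restored = SimulationConfig.from_yaml(small_config.to_yaml())
        assert restored == small_config
        assert restored.config_hash() == small_config.config_hash()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_modules": 10, "n_genes": 5},
            {"gamma": -0.5},
            {"cis_fraction": 1.5},
            {"hotspots": (("9", 5.0),)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationConfig(**kwargs)


class TestModules:
    def test_sizes_sum_exactly(self):
        for n, m, g in [(1000, 37, 1.0), (22746, 1000, 1.0), (500, 500, 0.8)]:
            assert _module_sizes(n, m, g).sum() == n

    def test_gamma_zero_gives_near_equal_sizes(self):
        sizes = _module_sizes(1003, 10, 0.0)
        assert sizes.max() - sizes.min() <= 1

    def test_every_gene_assigned_once(self, small_config):
        assignment = gen_modules(small_config)
        assert len(assignment.membership) == small_config.n_genes
        assert len(assignment.groups()) == small_config.n_modules

    def test_fixed_seed_reproduces_assignment(self, small_config):
        a = gen_modules(small_config)
        b = gen_modules(small_config)
        assert a.membership == b.membership

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 1.5])
    def test_loglog_slope_recovers_gamma(self, gamma):
        """log(size) vs log(rank) regression slope is -gamma +- 0.3."""
        sizes = _module_sizes(50_000, 200, gamma)
        ranks = np.arange(1, len(sizes) + 1)
        keep = sizes > 0
        fit = linregress(np.log(ranks[keep]), np.log(sizes[keep]))
        assert fit.slope == pytest.approx(-gamma, abs=0.3)


class TestExpression:
    def test_values_positive_finite(self, small_config):
        assignment = gen_modules(small_config)
        profile = gen_expression_matrix(assignment, small_config)
        vals = np.array(list(profile.values.values()))
        assert np.all(np.isfinite(vals)) and np.all(vals > 0)

    def test_large_modules_span_two_decades(self, full_config):
        """Each of the 10 largest modules covers >= 2 orders of magnitude."""
        assignment = gen_modules(full_config)
        profile = gen_expression_matrix(assignment, full_config)
        by_module: dict[str, list[float]] = {}
        for g, m in assignment.membership.items():
            by_module.setdefault(m, []).append(profile.values[g])
        largest = sorted(by_module, key=lambda m: -len(by_module[m]))[:10]
        for m in largest:
            vals = by_module[m]
            assert max(vals) / min(vals) >= 100

    def test_degenerate_spreads_give_constant_per_module(self, small_config):
        cfg = SimulationConfig(
            **{
                **small_config.__dict__,
                "gene_spread_sd": 0.0,
                "expression_noise_sd": 0.0,
                "module_offset_sd": 0.0,
            }
        )
        assignment = gen_modules(cfg)
        profile = gen_expression_matrix(assignment, cfg)
        vals = set(round(v, 9) for v in profile.values.values())
        assert len(vals) == 1


class TestEQTLCatalog:
    def test_cis_fraction_one_puts_eqtl_at_own_position(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "cis_fraction": 1.0})
        cat = gen_eqtl_catalog(cfg)
        assert cat.n_records > 0
        assert all(r.kind == "cis" for r in cat.records)
        by_transcript: dict[str, set] = {}
        for r in cat.records:
            by_transcript.setdefault(r.transcript, set()).add(
                (r.chromosome, round(r.position_cm, 9))
            )
        assert all(len(pos) == 1 for pos in by_transcript.values())

    def test_zero_rate_gives_empty_catalog(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "eqtl_rate": 0.0})
        assert gen_eqtl_catalog(cfg).n_records == 0

    def test_planted_hotspots_are_top_two_bins(self, small_config):
        from shallowseq import assign_bins

        cat = gen_eqtl_catalog(small_config)
        gmap = small_config.genetic_map(1.0)
        counts = assign_bins(cat, gmap)
        top2 = sorted(counts.counts, key=lambda k: -counts.counts[k])[:2]
        planted = {
            gmap.bin_label(c, gmap.bin_index(c, p)) for c, p in small_config.hotspots
        }
        assert set(top2) == planted

    def test_positions_on_map(self, small_config):
        cat = gen_eqtl_catalog(small_config)
        lengths = dict(small_config.chromosomes)
        for r in cat.records:
            assert 0.0 <= r.position_cm < lengths[r.chromosome]


class TestTimeCourse:
    def test_zero_amplitude_constant_up_to_noise(self, small_config):
        cfg = SimulationConfig(
            **{**small_config.__dict__, "amplitude": 0.0, "circadian_noise_sd": 0.0}
        )
        matrix, _ = gen_time_course(cfg)
        assert np.allclose(matrix.data.std(axis=1), 0.0)

    def test_noiseless_peak_at_assigned_phase(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "circadian_noise_sd": 0.0})
        matrix, phases = gen_time_course(cfg)
        grid = np.array(matrix.unique_times)
        for g in list(matrix.genes)[:50]:
            prof = np.array(
                [matrix.column_profile(t)[g] for t in matrix.unique_times]
            )
            peak = grid[np.argmax(prof)] % 24.0
            # peak lands on the grid point nearest the true phase
            dist = min(abs(peak - phases.phases[g]), 24 - abs(peak - phases.phases[g]))
            assert dist <= 2.0 + 1e-9  # half the 4 h sampling step

    def test_rank_turnover_between_day_and_night(self, small_config):
        matrix, _ = gen_time_course(small_config)
        p0 = matrix.column_profile(0.0)
        p12 = matrix.column_profile(12.0)
        genes = sorted(p0)
        rho = spearmanr([p0[g] for g in genes], [p12[g] for g in genes]).statistic
        assert rho < 0.8

    def test_phases_cover_cycle_uniformly(self, small_config):
        _, phases = gen_time_course(small_config)
        vals = np.array(list(phases.phases.values()))
        assert vals.min() >= 0 and vals.max() < 24
        hist, _ = np.histogram(vals, bins=24, range=(0, 24))
        assert hist.min() > 0


class TestAbundances:
    def test_normalised_and_reproducible(self, small_config):
        a = gen_abundances(small_config)
        b = gen_abundances(small_config)
        assert abs(a.probabilities.sum() - 1.0) < 1e-9
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_sigma_zero_limit_uniform(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "abundance_sigma": 1e-12})
        prof = gen_abundances(cfg)
        assert np.allclose(prof.probabilities, 1.0 / cfg.n_genes)

    def test_top_5000_carry_half_of_abundance(self, full_config):
        prof = gen_abundances(full_config)
        top = np.sort(prof.probabilities)[::-1][:5000]
        assert top.sum() >= 0.5


class TestSeedStreams:
    def test_generators_independent_of_each_other(self, small_config):
        """Each child stream is reproducible in isolation."""
        mods_alone = gen_modules(small_config)
        _ = gen_abundances(small_config)
        _ = gen_time_course(small_config)
        assert gen_modules(small_config).membership == mods_alone.membership

    def test_different_seeds_differ(self, small_config):
        other = SimulationConfig(**{**small_config.__dict__, "seed": 2})
        a = gen_abundances(small_config).probabilities
        b = gen_abundances(other).probabilities
        assert not np.array_equal(a, b)
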