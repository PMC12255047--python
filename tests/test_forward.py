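"""Linked-locus simulators: Balding-Nichols drift, latent-AR(1) panels,
Wright-Fisher evolution, mosaic copying, segment bookkeeping."""

import numpy as np
import pytest

from admixld import forward


class TestGeneticMap:
    def test_uniform_map(self):
        gmap = forward.GeneticMap.uniform(100, 1_000_000, 1e-8)
        assert gmap.n_loci == 100
        assert gmap.morgans[0] == 0.0
        assert np.all(np.diff(gmap.morgans) > 0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            forward.GeneticMap(bp=[0, 10, 5], morgans=[0.0, 1e-4, 2e-4])

    def test_locus_weights_sum_to_span(self):
        gmap = forward.GeneticMap.uniform(50, 5_000_000, 1e-8)
        assert gmap.locus_weights_morgans().sum() == pytest.approx(gmap.total_morgans)


class TestAncestralFreqs:
    def test_low_fst_limit_stays_near_ancestral(self):
        f = forward.ancestral_freqs(0.5, (1e-4, 1e-4), n_loci=500, seed=0)
        assert np.all(np.abs(f.freqs - 0.5) < 0.15)

    def test_cross_population_divergence_moment(self):
        # E[(f1 - f2)^2] = (F1 + F2) p (1 - p)
        p, F = 0.5, 0.1
        f = forward.ancestral_freqs(p, (F, F), n_loci=10_000, seed=1)
        d2 = (f.freqs[0] - f.freqs[1]) ** 2
        expect = 2 * F * p * (1 - p)
        se = d2.std(ddof=1) / np.sqrt(d2.size)
        assert abs(d2.mean() - expect) < 3 * se

    def test_clipping(self):
        f = forward.ancestral_freqs(0.01, (0.5, 0.5), n_loci=2000, seed=2, clip=1 / 400)
        assert f.freqs.min() >= 1 / 400
        assert f.freqs.max() <= 1 - 1 / 400

    @pytest.mark.parametrize("bad_f", [0.0, 1.0])
    def test_degenerate_fst_rejected(self, bad_f):
        with pytest.raises(ValueError):
            forward.ancestral_freqs(0.5, (bad_f, 0.1), n_loci=10, seed=0)


class TestSimulatePanel:
    def test_realized_frequencies(self, small_linked_world):
        panel = small_linked_world["panels"][0]
        err = np.abs(panel.realized_freqs() - panel.target_freqs)
        se = np.sqrt(panel.target_freqs * (1 - panel.target_freqs) / panel.n_hap)
        assert np.mean(err < 3.5 * se) > 0.95

    def test_tiny_lambda_gives_independent_loci(self):
        gmap = forward.GeneticMap.uniform(60, 6_000_000, 1e-8)
        panel = forward.simulate_panel(np.full(60, 0.5), gmap, 1e-6, 4000, seed=3)
        h = panel.haplotypes.astype(float)
        r = np.corrcoef(h.T)
        off = r[np.triu_indices(60, 1)]
        assert np.abs(off).mean() < 3 / np.sqrt(4000)

    def test_allele_correlation_matches_orthant_oracle(self):
        # two loci with latent correlation 0.8, f = 0.5:
        # allele correlation = (2/pi) arcsin(0.8)
        lam = 0.01
        d = -lam * np.log(0.8)
        gmap = forward.GeneticMap(bp=[0, 1000], morgans=[0.0, d])
        panel = forward.simulate_panel(np.array([0.5, 0.5]), gmap, lam, 100_000, seed=4)
        r_emp = np.corrcoef(panel.haplotypes[:, 0], panel.haplotypes[:, 1])[0, 1]
        oracle = forward.latent_to_allele_corr(0.8, 0.5, 0.5)
        assert oracle == pytest.approx(2 / np.pi * np.arcsin(0.8), rel=1e-6)
        assert abs(r_emp - oracle) < 3 / np.sqrt(100_000) * 2

    def test_correlation_decreases_with_distance(self, small_linked_world):
        panel = small_linked_world["panels"][0]
        h = panel.haplotypes.astype(float)
        r01 = abs(np.corrcoef(h[:, 0], h[:, 1])[0, 1])
        r0_far = abs(np.corrcoef(h[:, 0], h[:, 100])[0, 1])
        assert r01 > r0_far

    def test_bad_lambda_rejected(self, small_linked_world):
        with pytest.raises(ValueError):
            forward.simulate_panel(np.full(300, 0.5), small_linked_world["gmap"],
                                   0.0, 10, seed=0)


class TestFoundAdmixed:
    def test_single_ancestry_pi(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 30, (1.0, 0.0), seed=5)
        assert np.all(pop.labels == 0)

    def test_founder_fraction(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 5000, (0.8, 0.2), seed=6)
        frac = (pop.labels[:, 0] == 0).mean()
        assert abs(frac - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 10_000)

    def test_founder_haplotypes_single_segment(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 20, (0.5, 0.5), seed=7)
        assert np.all(pop.labels.min(axis=1) == pop.labels.max(axis=1))
        assert all(bp.size == 0 for bp in pop.breakpoints)

    def test_allele_traceability(self, small_linked_world):
        panels = small_linked_world["panels"]
        pop = forward.found_admixed(panels, 40, (0.5, 0.5), seed=8)
        for l, panel in enumerate(panels):
            mask = pop.labels == l
            # every copied allele exists somewhere in the source panel column
            present = (panel.haplotypes.max(axis=0) >= pop.haplotypes.max(axis=0,
                       where=mask, initial=0))
            assert np.all(present)


class TestWrightFisher:
    def test_zero_generations_identity(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 30, (0.5, 0.5), seed=9)
        out = forward.evolve_wright_fisher(pop, 0, seed=10)
        assert np.array_equal(out.haplotypes, pop.haplotypes)

    def test_allele_conservation(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 50, (0.8, 0.2), seed=11)
        out = forward.evolve_wright_fisher(pop, 5, seed=12)
        # no mutation: monomorphic founder columns stay monomorphic
        fixed = pop.haplotypes.min(axis=0) == pop.haplotypes.max(axis=0)
        assert np.all(out.haplotypes[:, fixed] == pop.haplotypes[0, fixed])

    def test_labels_and_alleles_inherited_jointly(self, small_linked_world):
        panels = small_linked_world["panels"]
        # make the two panels' alleles perfectly distinguish ancestry
        marked = [
            forward.HaplotypePanel(p.label, np.full_like(p.haplotypes, l),
                                   p.gmap, p.target_freqs, p.lam)
            for l, p in enumerate(panels)
        ]
        pop = forward.found_admixed(marked, 40, (0.6, 0.4), seed=13)
        out = forward.evolve_wright_fisher(pop, 6, seed=14)
        assert np.array_equal(out.haplotypes, out.labels)

    def test_la_autocovariance_decay(self, small_linked_world):
        # single-pulse prediction: cov at distance d ~ pi1 pi2 exp(-g d)
        panels = small_linked_world["panels"]
        pop = forward.found_admixed(panels, 4000, (0.8, 0.2), seed=15)
        out = forward.evolve_wright_fisher(pop, 12, seed=16)
        gmap = small_linked_world["gmap"]
        ind = (out.labels == 0).astype(float)
        for d in (0.01, 0.05, 0.2):
            k = int(round(d / (gmap.total_morgans / (gmap.n_loci - 1))))
            x, y = ind[:, 0], ind[:, k]
            emp = np.mean(x * y) - x.mean() * y.mean()
            pred = 0.8 * 0.2 * np.exp(-12 * (gmap.morgans[k] - gmap.morgans[0]))
            se = np.std(x * y) / np.sqrt(x.size) * 2.5
            assert abs(emp - pred) < 3 * se + 0.01

    def test_final_size_expansion(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 20, (0.5, 0.5), seed=17)
        out = forward.evolve_wright_fisher(pop, 3, seed=18, final_size=100)
        assert out.n_individuals == 100

    def test_negative_generations_rejected(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 10, (0.5, 0.5), seed=19)
        with pytest.raises(ValueError):
            forward.evolve_wright_fisher(pop, -1, seed=0)


class TestMosaicCopy:
    def test_zero_rate_reduces_to_founding(self, small_linked_world):
        pop = forward.mosaic_copy(small_linked_world["panels"], 30, (0.7, 0.3), 0, seed=20)
        assert pop.flavor == "mosaic_copy"
        assert np.all(pop.labels.min(axis=1) == pop.labels.max(axis=1))

    def test_interior_segment_mean_matches_poisson_window_oracle(self, small_linked_world):
        pop = forward.mosaic_copy(small_linked_world["panels"], 2000, (0.8, 0.2), 12, seed=21)
        seg = forward.segment_lengths(pop)
        oracle = forward.interior_segment_mean_oracle(12, pop.gmap.total_morgans)
        se = seg.std(ddof=1) / np.sqrt(seg.size)
        assert abs(seg.mean() - oracle) < 3 * se

    def test_oracle_converges_to_naive_mean_on_large_window(self):
        assert forward.interior_segment_mean_oracle(12, 1e4) == pytest.approx(100 / 12, rel=1e-3)

    def test_oracle_matches_direct_poisson_simulation(self):
        rng = np.random.default_rng(22)
        g, T = 12, 0.5
        lens = []
        for _ in range(4000):
            nb = rng.poisson(g * T)
            pos = np.sort(rng.random(nb) * T)
            if nb >= 2:
                lens.extend(np.diff(pos))
        lens = np.asarray(lens) * 100
        oracle = forward.interior_segment_mean_oracle(g, T)
        assert abs(lens.mean() - oracle) < 3 * lens.std(ddof=1) / np.sqrt(lens.size)

    def test_cross_segment_alleles_independent(self, small_linked_world):
        # distal pair (> 20 cM apart): correlation conditional on ancestry ~ 0
        pop = forward.mosaic_copy(small_linked_world["panels"], 4000, (0.5, 0.5), 12, seed=23)
        j, k = 0, pop.n_loci - 1
        both0 = (pop.labels[:, j] == 0) & (pop.labels[:, k] == 0)
        x = pop.haplotypes[both0, j].astype(float)
        y = pop.haplotypes[both0, k].astype(float)
        assert abs(np.corrcoef(x, y)[0, 1]) < 3 / np.sqrt(x.size)


class TestSegmentLengths:
    def test_midpoint_rule_from_label_runs(self):
        gmap = forward.GeneticMap(bp=np.arange(5) * 10_000,
                                  morgans=np.arange(5) * 0.01)
        pop = forward.AdmixedPopulation(
            haplotypes=np.zeros((2, 5), dtype=np.int8),
            labels=np.array([[0, 0, 1, 1, 1], [0, 0, 0, 0, 0]], dtype=np.int8),
            gmap=gmap, pi=np.array([0.5, 0.5]), generations=1,
            flavor="forward_wf", n_ancestries=2, breakpoints=None,
        )
        interior, censored = forward.segment_lengths(pop, include_censored=True)
        assert interior.size == 0  # both runs touch a region end
        assert sorted(censored.tolist()) == pytest.approx([1.5, 2.5, 4.0])

    def test_founder_population_spans_whole_region(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 10, (0.5, 0.5), seed=24)
        interior, censored = forward.segment_lengths(pop, include_censored=True)
        assert interior.size == 0
        assert np.allclose(censored, pop.gmap.total_morgans * 100)


class TestRealizedGlobalAncestry:
    def test_single_ancestry_individual(self, small_linked_world):
        pop = forward.found_admixed(small_linked_world["panels"], 10, (1.0, 0.0), seed=25)
        ga = forward.realized_global_ancestry(pop)
        assert np.allclose(ga.proportions[:, 0], 1.0)
        assert ga.source == "realized"

    def test_cohort_mean_near_pi(self, small_linked_world):
        pop = forward.mosaic_copy(small_linked_world["panels"], 3000, (0.8, 0.2), 12, seed=26)
        ga = forward.realized_global_ancestry(pop)
        assert abs(ga.proportions[:, 0].mean() - 0.8) < 0.02

    def test_independent_of_bp_scale(self, small_linked_world):
        pop = forward.mosaic_copy(small_linked_world["panels"], 20, (0.5, 0.5), 12, seed=27)
        ga1 = forward.realized_global_ancestry(pop)
        rescaled = forward.AdmixedPopulation(
            haplotypes=pop.haplotypes, labels=pop.labels,
            gmap=forward.GeneticMap(bp=pop.gmap.bp * 10, morgans=pop.gmap.morgans),
            pi=pop.pi, generations=pop.generations, flavor=pop.flavor,
            n_ancestries=2, breakpoints=pop.breakpoints,
        )
        ga2 = forward.realized_global_ancestry(rescaled)
        assert np.allclose(ga1.proportions, ga2.proportions)


class TestSimConfig:
    def test_defaults_build_a_50cm_map(self):
        cfg = forward.SimConfig()
        gmap = cfg.build_map()
        assert gmap.total_morgans == pytest.approx(0.5, rel=0.01)
        assert cfg.pi == (0.8, 0.2) and cfg.generations == 12

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            forward.SimConfig(pi=(0.9, 0.2))
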