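"""Stand generator: genotype structure, mating model, reference labels."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from matenet import simstand


class TestGenerateStand:
    def test_invariants(self, small_stand):
        s = small_stand
        assert len(set(s.ids)) == s.n_adults == 50
        assert s.genotypes.shape == (50, 12, 2)
        s.validate()  # raises on violated invariants

    def test_single_species_stand(self):
        s = simstand.generate_stand(0, 50, seed=1)
        assert (s.species == "B").all()

    def test_zero_differentiation_equalizes_frequencies(self):
        s = simstand.generate_stand(10, 10, differentiation=0.0, seed=2)
        for fa, fb in zip(s.allele_freqs["A"], s.allele_freqs["B"]):
            np.testing.assert_allclose(fa, fb)

    @pytest.mark.parametrize("bad", [dict(differentiation=1.5), dict(extent=(0, 10)),
                                     dict(n_A=0, n_B=1)])
    def test_invalid_arguments(self, bad):
        kwargs = dict(n_A=5, n_B=5, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            simstand.generate_stand(**kwargs)

    def test_differentiation_separates_hybrid_index(self):
        """Mean hybrid-index separation grows with the differentiation knob."""
        seps = {}
        for d in (0.1, 0.9):
            vals = []
            for seed in range(20):
                s = simstand.generate_stand(100, 100, differentiation=d, seed=seed)
                h = simstand.hybrid_index(s)
                vals.append(h[s.species == "A"].mean() - h[s.species == "B"].mean())
            seps[d] = np.mean(vals)
        assert seps[0.9] > seps[0.1] > 0

    def test_reproducible(self):
        a = simstand.generate_stand(20, 20, seed=5)
        b = simstand.generate_stand(20, 20, seed=5)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestMendelian:
    def test_forced_cross(self):
        mo = np.array([[1, 1]], dtype=np.int16)
        fa = np.array([[2, 2]], dtype=np.int16)
        off = simstand.mendelian_offspring(mo, fa, seed=0)
        assert sorted(off[0].tolist()) == [1, 2]

    def test_het_cross_segregation(self):
        """(1,2) x (1,2) gives genotype (1,1) in about a quarter of offspring."""
        rng = np.random.default_rng(7)
        mo = np.array([[1, 2]], dtype=np.int16)
        count = 0
        n = 10_000
        for _ in range(n):
            off = simstand.mendelian_offspring(mo, mo, rng=rng)
            count += tuple(sorted(off[0])) == (1, 1)
        assert abs(count / n - 0.25) < 0.015

    def test_full_error_follows_locus_frequencies(self):
        rng = np.random.default_rng(8)
        mo = np.array([[0, 0]], dtype=np.int16)
        freqs = [np.array([0.1, 0.9])]
        draws = [
            simstand.mendelian_offspring(mo, mo, error_rate=1.0, locus_freqs=freqs, rng=rng)
            for _ in range(2000)
        ]
        alleles = np.concatenate([d[0] for d in draws])
        assert abs(np.mean(alleles == 1) - 0.9) < 0.03

    def test_error_requires_frequencies(self):
        mo = np.array([[0, 0]], dtype=np.int16)
        with pytest.raises(ValueError, match="locus_freqs"):
            simstand.mendelian_offspring(mo, mo, error_rate=0.1, seed=0)


class TestSimulateMating:
    def test_no_interspecific_when_incompatible(self, small_stand):
        off = simstand.simulate_mating(small_stand, n_mothers=10, offspring_per_mother=20,
                                       compatibility=0.0, immigration=0.0, seed=3)
        species = dict(zip(small_stand.ids, small_stand.species))
        for o in off:
            assert species[o.mother_id] == species[o.true_father_id]

    def test_full_immigration(self, small_stand):
        off = simstand.simulate_mating(small_stand, n_mothers=5, offspring_per_mother=10,
                                       immigration=1.0, seed=4)
        assert all(o.true_father_id == simstand.EXTERNAL for o in off)

    def test_uniform_fathers_at_large_dispersal(self):
        """With one species and a flat kernel the father draw is uniform."""
        stand = simstand.generate_stand(20, 0, seed=9)
        off = simstand.simulate_mating(stand, n_mothers=1, offspring_per_mother=5000,
                                       dispersal_scale=1e9, compatibility=1.0,
                                       immigration=0.0, seed=10)
        mother = off[0].mother_id
        counts = {i: 0 for i in stand.ids if i != mother}
        for o in off:
            counts[o.true_father_id] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_mendelian_consistency(self, small_stand, small_progeny):
        """With zero error every offspring allele traces to a parent."""
        geno = dict(zip(small_stand.ids, small_stand.genotypes))
        for o in small_progeny:
            if o.true_father_id == simstand.EXTERNAL:
                continue
            mo, fa = geno[o.mother_id], geno[o.true_father_id]
            for l in range(small_stand.n_loci):
                a, b = o.genotype[l]
                assert (a in mo[l] and b in fa[l]) or (b in mo[l] and a in fa[l])

    def test_hybridization_monotone_in_compatibility(self, small_stand):
        species = dict(zip(small_stand.ids, small_stand.species))
        fracs = []
        for c in (0.0, 0.1, 0.5, 1.0):
            off = simstand.simulate_mating(small_stand, n_mothers=15, offspring_per_mother=30,
                                           compatibility=c, immigration=0.0, seed=77)
            hyb = np.mean([species[o.mother_id] != species[o.true_father_id] for o in off])
            fracs.append(hyb)
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_neighborhood_effect_on_hybrid_offspring(self):
        """Mothers with more allospecific neighbors sire more hybrids."""
        from matenet.congruence import allospecific_fraction
        import pandas as pd

        wins = 0
        for seed in range(10):
            stand = simstand.generate_stand(90, 60, extent=(150.0, 150.0), seed=seed)
            off = simstand.simulate_mating(stand, n_mothers=30, offspring_per_mother=40,
                                           dispersal_scale=40.0, compatibility=0.2,
                                           immigration=0.0, seed=1000 + seed)
            species = dict(zip(stand.ids, stand.species))
            labels = pd.Series(stand.species, index=stand.ids).map({"A": "S1", "B": "S2"})
            frac = allospecific_fraction(stand.coords_frame().set_index("id"), labels, radius=40.0)
            per_mother = {}
            for o in off:
                hyb = species[o.mother_id] != species[o.true_father_id]
                per_mother.setdefault(o.mother_id, []).append(hyb)
            mothers = sorted(per_mother)
            rho, _ = spearmanr([frac[m] for m in mothers],
                               [np.mean(per_mother[m]) for m in mothers])
            wins += rho > 0
        assert wins >= 9

    def test_reproducible(self, small_stand):
        a = simstand.simulate_mating(small_stand, n_mothers=5, offspring_per_mother=5, seed=42)
        b = simstand.simulate_mating(small_stand, n_mothers=5, offspring_per_mother=5, seed=42)
        for x, y in zip(a, b):
            assert x.offspring_id == y.offspring_id
            assert x.mother_id == y.mother_id
            assert x.true_father_id == y.true_father_id
            np.testing.assert_array_equal(x.genotype, y.genotype)

    def test_degenerate_parameters(self):
        stand = simstand.generate_stand(1, 1, seed=0)
        with pytest.raises(simstand.DegenerateParameterError):
            simstand.simulate_mating(stand, n_mothers=2, offspring_per_mother=1,
                                     compatibility=0.0, immigration=0.0, seed=0)


class TestReferenceAssignments:
    def test_noiseless_morphology_matches_species(self, small_stand):
        refs = simstand.synthetic_reference_assignments(small_stand, trait_noise=0.0, seed=0)
        expected = np.where(small_stand.species == "A", "S1", "S2")
        assert (refs["morphology"].to_numpy() == expected).all()

    def test_all_A_stand_labels_S1(self):
        """A single-species stand yields no opposite-species label; the
        admixture index at 12 loci leaves at most a few individuals in
        the intermediate band (finite-panel sampling noise)."""
        stand = simstand.generate_stand(40, 0, differentiation=0.9, seed=3)
        refs = simstand.synthetic_reference_assignments(stand, trait_noise=0.0, seed=0)
        assert (refs["morphology"] == "S1").all()
        assert (refs["genotype"] != "S2").all()
        assert (refs["genotype"] == "S1").mean() >= 0.9

    def test_f1_hybrids_intermediate(self):
        """F1 genotypes (one gamete per species) land near index 0.5."""
        rng = np.random.default_rng(5)
        stand = simstand.generate_stand(50, 50, differentiation=0.9, seed=5)
        gA = stand.genotypes[stand.species == "A"]
        gB = stand.genotypes[stand.species == "B"]
        m = 200
        f1 = np.empty((m, stand.n_loci, 2), dtype=np.int16)
        for k in range(m):
            a = gA[rng.integers(len(gA))]
            b = gB[rng.integers(len(gB))]
            f1[k, :, 0] = simstand._gamete(a, rng)
            f1[k, :, 1] = simstand._gamete(b, rng)
        h = simstand.hybrid_index(stand, genotypes=f1)
        assert np.mean((h > 0.1) & (h < 0.9)) >= 0.95
        assert abs(h.mean() - 0.5) < 0.05

    def test_threshold_validation(self, small_stand):
        with pytest.raises(ValueError):
            simstand.synthetic_reference_assignments(small_stand, hybrid_thresholds=(0.9, 0.1))
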