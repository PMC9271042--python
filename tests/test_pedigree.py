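"""Marker diagnostics, LOD scores and maternity assignment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import batlife as bl
from batlife.pedigree import (AssignmentConfig, GenotypeTable, LOD_IMPOSSIBLE,
                              LodCalculator, assign_maternity,
                              calibrate_delta_threshold,
                              expected_heterozygosity, locus_diagnostics,
                              lod_score, mismatch_count,
                              non_exclusion_first_parent,
                              non_exclusion_first_parent_enumeration,
                              polymorphic_information_content)


def equifreq(k):
    return {i: 1.0 / k for i in range(k)}


class TestDiagnosticsFormulas:
    def test_two_equifrequent_alleles_he_half(self):
        assert expected_heterozygosity(equifreq(2)) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3, 5, 8, 12])
    def test_k_equifrequent_alleles_he(self, k):
        assert expected_heterozygosity(equifreq(k)) == pytest.approx(1 - 1 / k)

    def test_pic_below_he(self):
        p = {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}
        assert polymorphic_information_content(p) < expected_heterozygosity(p)

    @pytest.mark.parametrize("p", [
        [0.5, 0.5],
        [0.3, 0.25, 0.2, 0.15, 0.1],
        [0.7, 0.1, 0.1, 0.05, 0.05],
        [1 / 8] * 8,
    ])
    def test_ne1_closed_form_matches_enumeration(self, p):
        assert non_exclusion_first_parent(p) == pytest.approx(
            non_exclusion_first_parent_enumeration(p), abs=1e-10)

    @given(st.lists(st.floats(0.05, 1.0), min_size=2, max_size=6))
    def test_ne1_closed_form_matches_enumeration_random(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        assert non_exclusion_first_parent(p) == pytest.approx(
            non_exclusion_first_parent_enumeration(p), abs=1e-10)


class TestLocusDiagnostics:
    def test_combined_ne_is_product_and_decreasing_in_loci(self, default_pop):
        gt = default_pop.genotypes
        diag = locus_diagnostics(gt)
        per = diag.per_locus
        assert diag.combined_ne1 == pytest.approx(per["NE1"].prod())
        partial = np.cumprod(per["NE1"].to_numpy())
        assert np.all(np.diff(partial) < 0)

    def test_bounds(self, default_pop):
        per = locus_diagnostics(default_pop.genotypes).per_locus
        for col in ("Ho", "He", "PIC", "NE1"):
            assert per[col].between(0, 1).all()

    def test_invariance_under_allele_relabeling(self, default_pop):
        gt = default_pop.genotypes
        frame = gt.to_frame()
        relabeled = frame.copy()
        k = default_pop.config.alleles_per_locus
        perm = {i: k - 1 - i for i in range(k)}
        loc = gt.loci[0]
        a = relabeled[f"{loc}_a"].map(perm)
        b = relabeled[f"{loc}_b"].map(perm)
        relabeled[f"{loc}_a"] = np.minimum(a, b)
        relabeled[f"{loc}_b"] = np.maximum(a, b)
        d1 = locus_diagnostics(gt).per_locus.set_index("locus")
        d2 = locus_diagnostics(GenotypeTable(relabeled)).per_locus.set_index("locus")
        for col in ("Ho", "He", "PIC", "NE1"):
            assert d1.loc[loc, col] == pytest.approx(d2.loc[loc, col])


class TestMismatch:
    def test_identical_genotypes_zero(self):
        g = {"L1": (1, 2), "L2": (3, 3)}
        assert mismatch_count(g, g) == 0

    def test_disjoint_alleles_at_all_loci(self):
        g1 = {f"L{i}": (0, 1) for i in range(13)}
        g2 = {f"L{i}": (2, 3) for i in range(13)}
        assert mismatch_count(g1, g2) == 13

    def test_error_free_true_mothers_have_zero_mismatches(self):
        cfg = bl.SimulationConfig(seed=12, n_colonies=2, n_years=15,
                                  genotyping_error_rate=0.0)
        pop = bl.simulate_population(cfg)
        gt = pop.genotypes
        pairs = [(r.individual_id, r.mother_id) for r in pop.individuals
                 if r.mother_id is not None]
        assert pairs
        for off, mom in pairs:
            assert mismatch_count(gt.genotype(off), gt.genotype(mom)) == 0


class TestLodScore:
    def test_hand_calculation_single_biallelic_locus(self):
        freqs = {"L1": {0: 0.5, 1: 0.5}}
        lod = lod_score({"L1": (0, 0)}, {"L1": (0, 0)}, freqs, error_rate=0.0)
        assert lod == pytest.approx(math.log(2.0), abs=1e-10)

    def test_excluded_candidate_gives_sentinel_minimum(self):
        freqs = {"L1": {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}}
        lod = lod_score({"L1": (0, 1)}, {"L1": (2, 3)}, freqs, error_rate=0.0)
        assert lod == LOD_IMPOSSIBLE

    def test_error_rate_keeps_lod_finite_and_decreasing_in_mismatches(self):
        freqs = {f"L{i}": equifreq(4) for i in range(4)}
        calc = LodCalculator(freqs, error_rate=0.02)
        off = {f"L{i}": (0, 1) for i in range(4)}
        lods = []
        for n_bad in range(4):
            cand = {f"L{i}": ((2, 3) if i < n_bad else (0, 2)) for i in range(4)}
            lods.append(calc.lod(off, cand))
        assert np.all(np.isfinite(lods))
        assert np.all(np.diff(lods) < 0)

    def test_true_mother_beats_unrelated_on_average(self):
        freqs = {f"L{i}": equifreq(6) for i in range(8)}
        calc = LodCalculator(freqs, error_rate=0.0)
        r = np.random.default_rng(21)
        diffs = []
        for _ in range(1000):
            mom = {loc: tuple(r.integers(0, 6, 2)) for loc in freqs}
            off = {loc: (mom[loc][r.integers(2)], r.integers(0, 6))
                   for loc in freqs}
            unrel = {loc: tuple(r.integers(0, 6, 2)) for loc in freqs}
            l_unrel = calc.lod(off, unrel)
            if l_unrel == LOD_IMPOSSIBLE:
                l_unrel = -50.0
            diffs.append(calc.lod(off, mom) - l_unrel)
        assert np.mean(diffs) > 0

    def test_unknown_allele_raises(self):
        freqs = {"L1": {0: 0.5, 1: 0.5}}
        calc = LodCalculator(freqs, error_rate=0.0)
        with pytest.raises(KeyError):
            calc.lod({"L1": (0, 7)}, {"L1": (0, 0)})


class TestAssignment:
    def test_single_true_mother_candidate_accepted(self):
        cfg = bl.SimulationConfig(seed=13, n_colonies=1, n_years=10,
                                  colony_size_range=(10, 12),
                                  genotyping_error_rate=0.0)
        pop = bl.simulate_population(cfg)
        gt = pop.genotypes
        pair = next((r.individual_id, r.mother_id) for r in pop.individuals
                    if r.mother_id is not None)
        res = assign_maternity([pair[0]], {pair[0]: [pair[1]]}, gt,
                               AssignmentConfig(error_rate=0.0,
                                                n_simulations=500,
                                                n_candidates=5))
        row = res.iloc[0]
        assert row["accepted"] and row["mismatch_count"] == 0
        assert row["best_candidate_id"] == pair[1]

    def test_error_free_colony_fully_assigned_and_correct(self, default_pop):
        cfg = bl.SimulationConfig(seed=14, n_colonies=2, n_years=15,
                                  genotyping_error_rate=0.0)
        pop = bl.simulate_population(cfg)
        gt = pop.genotypes
        ind = pop.individuals_frame()
        ev = pop.events_frame()
        offs = ind[(ind["mother_id"] != "") & ind["mother_id"].notna()]
        cand = {}
        for _, r in offs.iterrows():
            pool = ev[(ev["colony_id"] == r["colony_id"])
                      & (ev["year"] == r["birth_year"])]["individual_id"]
            ids = [x for x in pool if x != r["individual_id"]]
            if ids:
                cand[r["individual_id"]] = ids
        res = assign_maternity(list(cand), cand, gt,
                               AssignmentConfig(error_rate=0.0,
                                                n_simulations=2000))
        assert res["accepted"].all()  # perfect information: 100% assignment
        truth = ind.set_index("individual_id")["mother_id"]
        correct = (res.set_index("offspring_id")["best_candidate_id"]
                   == truth.loc[res["offspring_id"]].values).mean()
        # a homozygous relative can out-score the true mother on LOD, so
        # correctness is high but not guaranteed even without typing error
        assert correct >= 0.95

    def test_assignment_rate_with_typing_error_above_90pct(self):
        freqs = {f"L{i:02d}": equifreq(8) for i in range(13)}
        config = AssignmentConfig(error_rate=0.01, n_simulations=3000,
                                  n_candidates=20, seed=99)
        threshold = calibrate_delta_threshold(freqs, config)
        calc = LodCalculator(freqs, error_rate=0.01)
        r = np.random.default_rng(31)
        assigned_correct = 0
        trials = 200
        for _ in range(trials):
            def draw():
                return {loc: tuple(r.integers(0, 8, 2)) for loc in freqs}

            def observe(g):
                out = {}
                for loc, (a, b) in g.items():
                    a2 = r.integers(0, 8) if r.random() < 0.01 else a
                    b2 = r.integers(0, 8) if r.random() < 0.01 else b
                    out[loc] = (int(a2), int(b2))
                return out

            mom = draw()
            off = observe({loc: (mom[loc][r.integers(2)], r.integers(0, 8))
                           for loc in freqs})
            cands = [observe(mom)] + [observe(draw()) for _ in range(19)]
            lods = np.array([calc.lod(off, c) for c in cands])
            best = int(np.argmax(lods))
            delta = np.sort(lods)[-1] - np.sort(lods)[-2]
            mism = mismatch_count(off, cands[best])
            if best == 0 and (delta >= threshold or mism == 0):
                assigned_correct += 1
        assert assigned_correct / trials >= 0.90

    def test_empty_candidate_set_raises(self, default_pop):
        gt = default_pop.genotypes
        some_id = gt.individual_ids[0]
        with pytest.raises(ValueError, match="empty candidate"):
            assign_maternity([some_id], {some_id: []}, gt,
                             AssignmentConfig(n_simulations=100))
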