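"""Recombinant screen vs gamete enumeration, distance, clustering, placement."""
import itertools

import numpy as np
import pandas as pd
import pytest

from d2finemap import io as fio
from d2finemap.linkage import (CALL_TO_COUNT, cluster_markers,
                               find_recombinants, flag_double_recombinants,
                               map_distance, place_trait)
from d2finemap.progeny_test import classify_population
from d2finemap.synthdata import MarkerDef, SimConfig, simulate_f2
from conftest import make_table

GAMETES = [("A", "A"), ("B", "B"), ("A", "B"), ("B", "A")]  # (locus1, locus2)
PARENTAL = {("A", "A"), ("B", "B")}


def enumeration_min_recombinants(g1: str, g2: str) -> int:
    """Oracle: minimum recombinant gametes over all gamete pairs giving (g1, g2)."""
    best = None
    for ga, gb in itertools.product(GAMETES, repeat=2):
        geno1 = "".join(sorted(ga[0] + gb[0]))
        geno2 = "".join(sorted(ga[1] + gb[1]))
        if (geno1, geno2) != (g1, g2):
            continue
        n_rec = (ga not in PARENTAL) + (gb not in PARENTAL)
        best = n_rec if best is None else min(best, n_rec)
    assert best is not None
    return best


class TestFindRecombinants:
    def test_matches_gamete_enumeration_for_all_genotype_pairs(self):
        combos = list(itertools.product(["AA", "AB", "BB"], repeat=2))
        table = make_table({"L1": [c[0] for c in combos],
                            "L2": [c[1] for c in combos]})
        screen = find_recombinants(table, "L1", "L2")
        for plant, (g1, g2) in zip(table.plants, combos):
            expected = enumeration_min_recombinants(g1, g2)
            got = screen.recombinant_chromosomes.get(plant, 0)
            assert got == expected, (g1, g2)

    def test_missing_calls_excluded_and_reported(self):
        table = make_table({"L1": ["AA", "NA", "AA"],
                            "L2": ["AB", "AB", "NA"]})
        screen = find_recombinants(table, "L1", "L2")
        assert screen.excluded_missing == ["p1", "p2"]
        assert screen.n_plants_screened == 1
        assert screen.informative_plants == ["p0"]

    def test_dominant_locus_rejected(self):
        table = make_table({"L1": ["AA"], "L2": ["A-"]},
                           modes={"L1": "codominant", "L2": "dominant"})
        with pytest.raises(ValueError):
            find_recombinants(table, "L1", "L2")

    def test_absent_locus_rejected(self):
        table = make_table({"L1": ["AA"], "L2": ["AB"]})
        with pytest.raises(KeyError):
            find_recombinants(table, "L1", "LX")


class TestMapDistance:
    def test_published_screen_rounds_to_1_6_cM(self):
        est = map_distance(29, 915)
        assert est.cm == pytest.approx(1.5847, abs=1e-4)
        assert round(est.cm, 1) == 1.6

    def test_zero_recombinants(self):
        assert map_distance(0, 500).cm == 0.0

    def test_full_recombination_capped(self):
        est = map_distance(2 * 40, 40)
        assert est.capped and est.cm == 100.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            map_distance(-1, 10)
        with pytest.raises(ValueError):
            map_distance(21, 10)
        with pytest.raises(ValueError):
            map_distance(1, 0)

    @pytest.mark.parametrize("d_cm", [0.5, 1.6, 5.0, 10.0])
    def test_distance_recovery_within_3_se(self, d_cm):
        """Parameter recovery at n=5000 using the map-function estimate."""
        cfg = SimConfig(n_f2=5000, markers=[MarkerDef("A"), MarkerDef("B")],
                        distances_cm=[d_cm], seed=int(d_cm * 10))
        table, _ = simulate_f2(cfg)
        screen = find_recombinants(table, "A", "B")
        est = map_distance(screen.total_recombinant_chromosomes,
                           screen.n_plants_screened)
        f = est.recombinant_chromosomes / (2 * screen.n_plants_screened)
        se_d = est.se_cm / (1 - 2 * f)  # delta method on the map function
        assert abs(est.cm_mapfn - d_cm) < 3 * se_d


class TestClusterMarkers:
    def test_two_clusters_in_second_population(self, pt732b_table):
        loci = ["RGR1963", "Ca_Sb07g023910", "Ca_Sb07g024020",
                "Ca_Sb07g023810", "Ca_Sb07g023630", "Ca_Sb07g023520",
                "Ca_Sb07g023430"]
        sub = pt732b_table.calls[loci]
        from d2finemap.linkage import GenotypeTable
        table = GenotypeTable(sub, {l: "codominant" for l in loci})
        cmap = cluster_markers(table)
        assert len(cmap.clusters) == 2
        groups = {frozenset(c.loci) for c in cmap.clusters}
        assert frozenset(loci[:4]) in groups and frozenset(loci[4:]) in groups

    def test_identical_vectors_single_cluster(self):
        table = make_table({"L1": ["AA", "AB", "BB"],
                            "L2": ["AA", "AB", "BB"],
                            "L3": ["AA", "AB", "BB"]})
        assert len(cluster_markers(table).clusters) == 1

    def test_cluster_count_equals_distinct_vectors(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 3, size=(16, 6))
        inv = {0: "AA", 1: "AB", 2: "BB"}
        table = make_table({f"L{j}": [inv[c] for c in counts[:, j]]
                            for j in range(6)})
        distinct = len({tuple(counts[:, j]) for j in range(6)})
        assert len(cluster_markers(table).clusters) == distinct

    def test_order_invariant_to_allele_and_plant_relabeling(self, tift_table):
        # the collapsed dominant code A- is tied to one allele and cannot be
        # relabeled, so the invariance check runs on the codominant loci
        from d2finemap.linkage import GenotypeTable
        loci = [l for l, m in tift_table.modes.items() if m == "codominant"]
        base = GenotypeTable(tift_table.calls[loci],
                             {l: "codominant" for l in loci})
        cmap1 = cluster_markers(base, anchor_loci=("B224C4P2", "PSMP305"))
        flipped = base.calls.replace({"AA": "BB", "BB": "AA"})
        flipped = flipped.iloc[::-1]  # reverse plant order too
        table2 = GenotypeTable(flipped, {l: "codominant" for l in loci})
        cmap2 = cluster_markers(table2, anchor_loci=("B224C4P2", "PSMP305"))
        assert [sorted(c.loci) for c in cmap1.clusters] == \
               [sorted(c.loci) for c in cmap2.clusters]
        assert cmap1.adjacent_events == cmap2.adjacent_events

    def test_dominant_locus_attaches_to_compatible_cluster(self, tift_table):
        cmap = cluster_markers(tift_table,
                               anchor_loci=("B224C4P2", "PSMP305"))
        host = cmap.clusters[cmap.cluster_of("Ca_Sb07g023840")]
        assert "Ca_Sb07g023850" in host.loci  # sits with the 8-marker cluster
        assert not cmap.unplaced


class TestPlaceTrait:
    def slot_cost_oracle(self, cluster_vectors, trait_vector, slot):
        """Total adjacent events of the full order with the trait inserted."""
        seq = list(cluster_vectors)
        seq.insert(slot, trait_vector)
        total = 0
        for u, v in zip(seq, seq[1:]):
            total += int(np.abs(np.asarray(u) - np.asarray(v)).sum())
        return total

    def test_matches_bruteforce_insertion(self):
        rng = np.random.default_rng(12)
        inv = {0: "AA", 1: "AB", 2: "BB"}
        for _ in range(30):
            n_plants = int(rng.integers(4, 9))
            n_loci = int(rng.integers(2, 6))
            counts = rng.integers(0, 3, size=(n_plants, n_loci))
            table = make_table({f"L{j}": [inv[c] for c in counts[:, j]]
                                for j in range(n_loci)})
            cmap = cluster_markers(table)
            trait = rng.integers(0, 3, size=n_plants)
            calls = {f"p{i}": ("dd", "Dd", "DD")[t]
                     for i, t in enumerate(trait)}
            placement = place_trait(cmap, calls)
            vectors = [c.counts_min.to_numpy() for c in cmap.clusters]
            base = self.slot_cost_oracle(vectors, vectors[0], 0) \
                - int(np.abs(vectors[0] - vectors[0]).sum())
            base = sum(int(np.abs(u - v).sum())
                       for u, v in zip(vectors, vectors[1:]))
            oracle = [self.slot_cost_oracle(vectors, trait, s) - base
                      for s in range(len(vectors) + 1)]
            assert placement.slot_costs == oracle
            assert placement.total_events == min(oracle)

    def test_trait_equal_to_cluster_vector_has_zero_distance(self):
        table = make_table({"L1": ["AA", "AB", "BB"],
                            "L2": ["AA", "BB", "BB"]})
        cmap = cluster_markers(table)
        calls = {"p0": "dd", "p1": "Dd", "p2": "DD"}  # equals L1 vector
        placement = place_trait(cmap, calls)
        assert placement.events_to_host == 0
        assert "L1" in cmap.clusters[placement.host_cluster].loci

    def test_all_unresolved_rejected(self, tift_table):
        cmap = cluster_markers(tift_table)
        with pytest.raises(ValueError):
            place_trait(cmap, {"1": "tall_unresolved", "55": "no_data"})


class TestFixtureEndToEnd:
    """The 23-plant informative set against its published summary counts."""

    @pytest.fixture()
    def calls_and_map(self, tift_table, family_fixture):
        calls = classify_population(family_fixture)
        cmap = cluster_markers(tift_table,
                               anchor_loci=("B224C4P2", "PSMP305"))
        return calls, cmap

    def test_trait_cosegregates_with_eight_marker_cluster(self,
                                                          calls_and_map):
        calls, cmap = calls_and_map
        placement = place_trait(cmap, calls.as_mapping())
        host = cmap.clusters[placement.host_cluster]
        assert len(host.loci) == 8
        # the rule-consistent calls carry one double recombination (2 events)
        assert placement.total_events == 2

    def test_double_recombinant_flag_and_recall(self, calls_and_map):
        calls, cmap = calls_and_map
        pvals = {c.f2_id: c.p_value_3to1 for c in calls.calls
                 if c.p_value_3to1 is not None}
        flags = flag_double_recombinants(cmap, calls.as_mapping(), pvals)
        assert [f.f2_id for f in flags] == ["612"]
        assert flags[0].suggested_call == "DD"
        assert flags[0].p_value_3to1 == pytest.approx(0.071, abs=5e-4)
        recalled = dict(calls.as_mapping())
        recalled["612"] = "DD"
        assert place_trait(cmap, recalled).total_events == 0
        assert flag_double_recombinants(cmap, recalled) == []

    def test_injected_miscall_is_flagged_exactly(self):
        cfg = SimConfig(n_f2=60, markers=[MarkerDef(n) for n in "ABC"],
                        distances_cm=[5.0, 5.0], trait_position_cm=5.0,
                        seed=21)
        table, truth = simulate_f2(cfg)
        cmap = cluster_markers(table, anchor_loci=("A", "C"))
        calls = {p: {"dd": "dd", "Dd": "Dd", "DD": "DD"}[g]
                 for p, g in truth.items()}
        assert flag_double_recombinants(cmap, calls) == []
        # flip one non-recombinant plant's call
        victim = next(p for p in table.plants
                      if len(set(table.calls.loc[p])) == 1)
        calls[victim] = "Dd" if calls[victim] != "Dd" else "DD"
        flagged = flag_double_recombinants(cmap, calls)
        assert [f.f2_id for f in flagged] == [victim]

    def test_pipeline_places_trait_in_correct_interval(self):
        """Seeded synthetic cross: trait lands between its true neighbours."""
        cfg = SimConfig(n_f2=400, markers=[MarkerDef(n) for n in "ABC"],
                        distances_cm=[5.0, 5.0], trait_position_cm=7.5,
                        seed=33)
        table, truth = simulate_f2(cfg)
        cmap = cluster_markers(table, anchor_loci=("A", "C"))
        placement = place_trait(cmap, dict(truth))
        idx_b = cmap.cluster_of("B")
        idx_c = cmap.cluster_of("C")
        assert placement.best_slots == [max(idx_b, idx_c)]  # between B and C
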