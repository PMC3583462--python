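"""Two-point linkage analysis around a qualitative trait locus in an F2 cross.

This module screens an F2 genotype table for plants that carry a recombination
event between two flanking codominant markers ("informative plants"), converts
recombinant-chromosome counts into a genetic distance, merges cosegregating
markers into clusters, orders the clusters by minimum recombination, places the
trait locus into the cluster map, and flags plants whose trait call would
require a double recombination inside a non-recombinant marker stretch.

Genotype calls are written with ``A`` the allele of the recessive (dwarf)
parent and ``B`` the allele of the tall parent.  A codominant call is one of
``AA``/``AB``/``BB``; a dominant locus collapses ``AA`` and ``AB`` into
``A-``.  Internally genotypes are handled as counts of ``B``-carrying
chromosomes (0, 1 or 2), so the minimum number of recombinant gametes needed
to explain a two-locus genotype is simply ``|count_a - count_b|``.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CODOMINANT = "codominant"
DOMINANT = "dominant"
NA = "NA"

#: genotype call -> number of tall-parent (B) chromosomes
CALL_TO_COUNT = {"AA": 0, "AB": 1, "BB": 2}
#: trait-locus genotype -> number of tall-allele (D) chromosomes
TRAIT_TO_COUNT = {"dd": 0, "Dd": 1, "DD": 2}
COUNT_TO_TRAIT = {0: "dd", 1: "Dd", 2: "DD"}

#: allowed B-chromosome counts per call at a dominant locus (A dominant)
DOMINANT_SETS = {"A-": frozenset({0, 1}), "BB": frozenset({2})}

RESOLVED_CALLS = frozenset(TRAIT_TO_COUNT)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane_to_r(d_cm: float) -> float:
    """Recombination fraction for a distance in cM (no interference)."""
    if d_cm < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def r_to_haldane(r: float) -> float:
    """Inverse Haldane map function; r must lie in [0, 0.5)."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


def kosambi_to_r(d_cm: float) -> float:
    if d_cm < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * math.tanh(2.0 * d_cm / 100.0)


def r_to_kosambi(r: float) -> float:
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


MAP_FUNCTIONS = {"haldane": (haldane_to_r, r_to_haldane),
                 "kosambi": (kosambi_to_r, r_to_kosambi)}


def detected_fraction_to_r(f: float) -> float:
    """Invert the expectation of the two-locus recombinant screen.

    The screen cannot see plants formed from two complementary recombinant
    gametes (their genotype is AB/AB), so the expected detected fraction of
    recombinant chromosomes is ``f = r - r^2/2`` rather than ``r``.  Solving
    for ``r`` gives ``1 - sqrt(1 - 2f)``.
    """
    if not 0 <= f <= 0.5:
        raise ValueError("detected fraction must be in [0, 0.5]")
    return 1.0 - math.sqrt(1.0 - 2.0 * f)


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Plants x marker loci calls with a per-locus scoring mode.

    Parameters
    ----------
    calls
        DataFrame indexed by plant id, one column per locus, values in
        ``{"AA", "AB", "BB", "A-", "NA"}``.
    modes
        Mapping locus name -> ``"codominant"`` or ``"dominant"``.
    """

    calls: pd.DataFrame
    modes: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(str)
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].tolist()
            raise ValueError(f"duplicate plant ids: {dups}")
        for locus in self.calls.columns:
            mode = self.modes.get(locus)
            if mode not in (CODOMINANT, DOMINANT):
                raise ValueError(f"locus {locus!r} has no declared mode")
            allowed = ({"AA", "AB", "BB", NA} if mode == CODOMINANT
                       else {"A-", "BB", NA})
            bad = ~self.calls[locus].isin(allowed)
            if bad.any():
                plant = self.calls.index[bad][0]
                value = self.calls.loc[plant, locus]
                raise ValueError(
                    f"invalid call {value!r} at plant {plant!r}, locus "
                    f"{locus!r} (mode {mode})")

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def plants(self) -> list[str]:
        return list(self.calls.index)

    def counts(self, locus: str) -> pd.Series:
        """B-chromosome counts for a codominant locus (NaN where missing)."""
        if self.modes[locus] != CODOMINANT:
            raise ValueError(f"locus {locus!r} is not codominant")
        return self.calls[locus].map(CALL_TO_COUNT).astype(float)

    def count_sets(self, locus: str) -> pd.Series:
        """Per-plant sets of B-counts compatible with the recorded call."""
        if self.modes[locus] == CODOMINANT:
            return self.calls[locus].map(
                lambda c: frozenset({CALL_TO_COUNT[c]}) if c in CALL_TO_COUNT
                else frozenset({0, 1, 2}))
        return self.calls[locus].map(
            lambda c: DOMINANT_SETS.get(c, frozenset({0, 1, 2})))

    def drop_nonparental(self) -> "GenotypeTable":
        """Return a table without plants carrying any unexpected call."""
        valid = {"AA", "AB", "BB", "A-", NA}
        keep = self.calls.isin(valid).all(axis=1)
        return GenotypeTable(self.calls.loc[keep], dict(self.modes))


# ---------------------------------------------------------------------------
# recombinant screening and distance
# ---------------------------------------------------------------------------

@dataclass
class RecombinantScreen:
    """Result of screening two flanking codominant loci."""

    locus_a: str
    locus_b: str
    #: per informative plant: minimum number of recombinant chromosomes (1 or 2)
    recombinant_chromosomes: pd.Series
    #: plants with a missing call at either locus (excluded from counts)
    excluded_missing: list[str]
    n_plants_screened: int

    @property
    def informative_plants(self) -> list[str]:
        return list(self.recombinant_chromosomes.index)

    @property
    def n_informative(self) -> int:
        return len(self.recombinant_chromosomes)

    @property
    def total_recombinant_chromosomes(self) -> int:
        return int(self.recombinant_chromosomes.sum())


def find_recombinants(table: GenotypeTable, locus_a: str,
                      locus_b: str) -> RecombinantScreen:
    """Identify F2 plants whose two-locus genotype requires >=1 recombinant gamete.

    A plant is informative iff its genotypes at the two loci differ in
    B-chromosome count; plants of type AA/BB require two recombinant
    chromosomes, all other informative types one.  Plants with a missing call
    at either locus are excluded and reported.
    """
    for locus in (locus_a, locus_b):
        if locus not in table.calls.columns:
            raise KeyError(f"locus {locus!r} not in table")
        if table.modes[locus] != CODOMINANT:
            raise ValueError(
                f"locus {locus!r} is dominant; recombinant screening needs "
                "codominant flanking loci")
    ca = table.counts(locus_a)
    cb = table.counts(locus_b)
    missing = ca.isna() | cb.isna()
    rec = (ca - cb).abs()
    informative = rec[~missing & (rec >= 1)].astype(int)
    return RecombinantScreen(
        locus_a=locus_a, locus_b=locus_b,
        recombinant_chromosomes=informative,
        excluded_missing=list(ca.index[missing]),
        n_plants_screened=int((~missing).sum()))


@dataclass
class DistanceEstimate:
    """Genetic distance from a recombinant-chromosome count over 2N gametes."""

    recombinant_chromosomes: int
    n_plants: int
    #: naive estimate, 100 * c / 2N (the fraction of recombinant chromosomes)
    cm: float
    se_cm: float
    #: detection-corrected, map-function-inverted estimate
    cm_mapfn: float
    map_function: str
    capped: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.cm:.1f} cM (SE {self.se_cm:.2f})"


def map_distance(recombinant_chromosomes: int, n_plants: int,
                 map_function: str = "haldane") -> DistanceEstimate:
    """Estimate genetic distance in cM from a two-locus recombinant screen.

    The primary estimate is ``100 * c / (2N)`` — the percentage of recombinant
    chromosomes among the 2N screened — with a binomial standard error.  A
    second estimate (``cm_mapfn``) first corrects the detected fraction for the
    invisible complementary double recombinants and then inverts the chosen
    map function; the two agree closely for tightly linked loci.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    if recombinant_chromosomes < 0:
        raise ValueError("recombinant chromosome count must be >= 0")
    n_chrom = 2 * n_plants
    if recombinant_chromosomes > n_chrom:
        raise ValueError(
            f"{recombinant_chromosomes} recombinant chromosomes exceeds "
            f"2N = {n_chrom}")
    f = recombinant_chromosomes / n_chrom
    se = 100.0 * math.sqrt(f * (1.0 - f) / n_chrom)
    capped = False
    cm = 100.0 * f
    if cm >= 100.0:
        capped = True
        cm = 100.0
    if f < 0.5:
        _, inv = MAP_FUNCTIONS[map_function]
        cm_mapfn = inv(detected_fraction_to_r(f))
    else:
        capped = True
        cm_mapfn = float("inf")
    return DistanceEstimate(recombinant_chromosomes, n_plants, cm, se,
                            cm_mapfn, map_function, capped)


# ---------------------------------------------------------------------------
# marker clustering
# ---------------------------------------------------------------------------

@dataclass
class MarkerCluster:
    """A set of cosegregating marker loci sharing one genotype vector.

    ``counts_min``/``counts_max`` bound the B-chromosome count per plant;
    they differ only where every member locus is dominant (the collapsed
    ``A-`` call is compatible with counts 0 and 1).
    """

    loci: list[str]
    counts_min: pd.Series
    counts_max: pd.Series

    @property
    def resolved(self) -> pd.Series:
        """Point counts where unambiguous, NaN elsewhere."""
        eq = self.counts_min == self.counts_max
        out = self.counts_min.where(eq)
        return out

    def count_sets(self) -> pd.Series:
        return pd.Series(
            [frozenset(range(int(lo), int(hi) + 1))
             if not (np.isnan(lo) or np.isnan(hi)) else frozenset({0, 1, 2})
             for lo, hi in zip(self.counts_min, self.counts_max)],
            index=self.counts_min.index)


def _pair_events(sets_i: pd.Series, sets_j: pd.Series) -> tuple[int, int]:
    """Min and max recombination events between two per-plant count-set vectors."""
    lo = hi = 0
    for si, sj in zip(sets_i, sets_j):
        if si == frozenset({0, 1, 2}) or sj == frozenset({0, 1, 2}):
            continue  # missing data: no information
        diffs = [abs(x - y) for x in si for y in sj]
        lo += min(diffs)
        hi += max(diffs)
    return lo, hi


@dataclass
class ClusterMap:
    """Ordered marker clusters with adjacent recombination-event counts."""

    clusters: list[MarkerCluster]
    #: (min, max) recombination events between adjacent clusters
    adjacent_events: list[tuple[int, int]]
    unplaced: list[str] = field(default_factory=list)
    ambiguous: dict[str, list[int]] = field(default_factory=dict)

    def cluster_of(self, locus: str) -> int:
        for i, c in enumerate(self.clusters):
            if locus in c.loci:
                return i
        raise KeyError(locus)


def _merge_codominant(table: GenotypeTable, plants: list[str]) -> list[MarkerCluster]:
    loci = [l for l in table.loci if table.modes[l] == CODOMINANT]
    clusters: list[MarkerCluster] = []
    for locus in loci:
        counts = table.counts(locus).loc[plants]
        placed = False
        for cl in clusters:
            both = ~counts.isna() & ~cl.counts_min.isna()
            if (counts[both] == cl.counts_min[both]).all():
                cl.loci.append(locus)
                # fill the consensus where the cluster was missing
                fill = cl.counts_min.isna() & ~counts.isna()
                cl.counts_min[fill] = counts[fill]
                cl.counts_max[fill] = counts[fill]
                placed = True
                break
        if not placed:
            clusters.append(MarkerCluster([locus], counts.copy(), counts.copy()))
    return clusters


def cluster_markers(table: GenotypeTable, plants: list[str] | None = None,
                    anchor_loci: tuple[str, str] | None = None) -> ClusterMap:
    """Merge cosegregating loci and order the clusters by minimum recombination.

    Codominant loci with identical genotype vectors (over the given plants,
    ignoring missing calls) merge into one cluster; dominant loci attach to
    the unique compatible cluster, are recorded as ambiguous when several
    clusters are compatible, and as unplaced when none is.  Cluster order
    minimizes the total of adjacent minimum recombination-event counts; when
    ``anchor_loci`` is given the clusters containing those loci are pinned to
    the two ends of the order.
    """
    if plants is None:
        plants = table.plants
    if not plants:
        raise ValueError("at least one informative plant is required")
    plants = list(plants)

    clusters = _merge_codominant(table, plants)
    unplaced: list[str] = []
    ambiguous: dict[str, list[int]] = {}
    for locus in table.loci:
        if table.modes[locus] != DOMINANT:
            continue
        sets = table.count_sets(locus).loc[plants]
        compatible = []
        for i, cl in enumerate(clusters):
            ok = True
            for p in plants:
                v = cl.counts_min[p]
                if np.isnan(v):
                    continue
                if int(v) not in sets[p]:
                    ok = False
                    break
            if ok:
                compatible.append(i)
        if len(compatible) == 1:
            clusters[compatible[0]].loci.append(locus)
        elif len(compatible) > 1:
            ambiguous[locus] = compatible
        else:
            unplaced.append(locus)

    if not clusters:
        raise ValueError("no codominant loci to cluster")

    # order clusters to minimize total adjacent min-event counts
    sets_list = [cl.count_sets() for cl in clusters]
    n = len(clusters)
    dmin = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        lo, _ = _pair_events(sets_list[i], sets_list[j])
        dmin[i, j] = dmin[j, i] = lo

    order = _best_order(clusters, dmin, table, anchor_loci)
    clusters = [clusters[i] for i in order]
    adjacent = []
    sets_list = [sets_list[i] for i in order]
    for i in range(len(clusters) - 1):
        adjacent.append(_pair_events(sets_list[i], sets_list[i + 1]))
    # remap ambiguous indices to the new order
    remap = {old: new for new, old in enumerate(order)}
    ambiguous = {loc: sorted(remap[i] for i in idxs)
                 for loc, idxs in ambiguous.items()}
    return ClusterMap(clusters, adjacent, unplaced, ambiguous)


def _best_order(clusters, dmin, table, anchor_loci) -> list[int]:
    n = len(clusters)
    if n == 1:
        return [0]
    first = last = None
    if anchor_loci is not None:
        a, b = anchor_loci
        for i, cl in enumerate(clusters):
            if a in cl.loci:
                first = i
            if b in cl.loci:
                last = i
    best: tuple | None = None
    if n <= 8:
        for perm in itertools.permutations(range(n)):
            if first is not None and perm[0] != first:
                continue
            if last is not None and perm[-1] != last:
                continue
            cost = sum(dmin[perm[i], perm[i + 1]] for i in range(n - 1))
            key = (cost, tuple(clusters[i].loci[0] for i in perm))
            if best is None or key < best[0]:
                best = (key, perm)
        return list(best[1])
    # fallback for many clusters: greedy nearest-neighbour from the anchor
    start = first if first is not None else 0
    order = [start]
    remaining = set(range(n)) - {start}
    while remaining:
        cur = order[-1]
        nxt = min(remaining,
                  key=lambda j: (dmin[cur, j], clusters[j].loci[0]))
        order.append(nxt)
        remaining.remove(nxt)
    return order


# ---------------------------------------------------------------------------
# trait placement
# ---------------------------------------------------------------------------

@dataclass
class TraitPlacement:
    """Position of the trait locus in the ordered cluster map.

    ``slots`` are insertion positions: slot ``i`` lies before cluster ``i``
    (slot ``len(clusters)`` after the last).  ``best_slots`` lists every slot
    achieving the minimal total of extra recombination events; a run of tied
    slots is the placement interval.
    """

    best_slots: list[int]
    total_events: int
    slot_costs: list[int]
    host_cluster: int
    events_to_host: int
    per_plant_events: pd.Series

    @property
    def interval(self) -> tuple[int, int]:
        return (min(self.best_slots), max(self.best_slots))


def _trait_counts(trait_calls) -> pd.Series:
    """Resolved trait B-chromosome counts from call labels or TraitCall-likes."""
    items = {}
    for plant, call in dict(trait_calls).items():
        label = getattr(call, "call", call)
        if label in TRAIT_TO_COUNT:
            items[plant] = TRAIT_TO_COUNT[label]
    return pd.Series(items, dtype=float)


def place_trait(cluster_map: ClusterMap, trait_calls) -> TraitPlacement:
    """Insert the trait locus where it adds the fewest recombination events.

    ``trait_calls`` maps plant id to a call label (``dd``/``Dd``/``DD``/
    ``tall_unresolved``/``no_data``) or to an object with a ``.call``
    attribute; unresolved and no-data plants are excluded.
    """
    counts = _trait_counts(trait_calls)
    if counts.empty:
        raise ValueError("no resolved trait calls to place")
    clusters = cluster_map.clusters
    # restrict every distance to plants with a resolved trait call, so the
    # insertion costs and the adjacent cluster distances are comparable
    plants = clusters[0].counts_min.index.intersection(counts.index)
    if plants.empty:
        raise ValueError("no resolved trait calls among the mapped plants")
    counts = counts.reindex(plants)

    trait_sets = pd.Series(
        [frozenset({int(v)}) for v in counts], index=plants)
    sets_list = [cl.count_sets().reindex(
        plants, fill_value=frozenset({0, 1, 2})) for cl in clusters]

    def d(si, sj):
        return _pair_events(si, sj)[0]

    n = len(clusters)
    slot_costs = []
    for slot in range(n + 1):
        if slot == 0:
            cost = d(trait_sets, sets_list[0])
        elif slot == n:
            cost = d(sets_list[-1], trait_sets)
        else:
            cost = (d(sets_list[slot - 1], trait_sets)
                    + d(trait_sets, sets_list[slot])
                    - d(sets_list[slot - 1], sets_list[slot]))
        slot_costs.append(cost)
    total = min(slot_costs)
    best_slots = [s for s, c in enumerate(slot_costs) if c == total]

    pair = [d(trait_sets, s) for s in sets_list]
    host = int(np.argmin(pair))
    # per-plant extra events against the host cluster
    per_plant = {}
    host_sets = sets_list[host]
    for p in plants:
        per_plant[p] = _pair_events(pd.Series([trait_sets[p]]),
                                    pd.Series([host_sets[p]]))[0]
    return TraitPlacement(best_slots, total, slot_costs, host, pair[host],
                          pd.Series(per_plant))


@dataclass
class DoubleRecombinantFlag:
    f2_id: str
    flank_pattern: str
    observed_call: str
    suggested_call: str
    p_value_3to1: float | None = None


def flag_double_recombinants(cluster_map: ClusterMap, trait_calls,
                             family_pvalues: dict[str, float] | None = None
                             ) -> list[DoubleRecombinantFlag]:
    """Flag plants whose trait call requires recombination on both sides.

    A plant is flagged when the host cluster (the cluster the trait
    cosegregates with) and both neighbouring clusters all carry the same
    genotype in that plant while the trait call differs: explaining the call
    would need two recombination events inside an interval with no observed
    marker recombination.  The suggested re-call removes both events.
    """
    counts = _trait_counts(trait_calls)
    if counts.empty:
        return []
    placement = place_trait(cluster_map, trait_calls)
    clusters = cluster_map.clusters
    host = placement.host_cluster
    neighbours = [i for i in (host - 1, host + 1) if 0 <= i < len(clusters)]
    flags = []
    for plant, tcount in counts.items():
        v = clusters[host].resolved.get(plant, np.nan)
        if np.isnan(v):
            continue
        flank_vals = [clusters[i].resolved.get(plant, np.nan) for i in neighbours]
        if any(np.isnan(x) for x in flank_vals):
            continue
        if all(x == v for x in flank_vals) and tcount != v:
            pattern = "-".join(COUNT_TO_TRAIT[int(x)] for x in
                               [flank_vals[0], v] + flank_vals[1:])
            flags.append(DoubleRecombinantFlag(
                f2_id=str(plant),
                flank_pattern=pattern,
                observed_call=COUNT_TO_TRAIT[int(tcount)],
                suggested_call=COUNT_TO_TRAIT[int(v)],
                p_value_3to1=(family_pvalues or {}).get(str(plant))))
    return flags
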