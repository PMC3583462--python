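"""Synthetic F2/F3 populations and dual-genome gene-order tables.

The generators reproduce the statistical structure the downstream analyses
assume, so every stage of the pipeline can be exercised end to end without
field data:

* an F2 population formed from two independent gametes of a fully
  heterozygous F1, with crossovers between adjacent loci at the recombination
  fraction given by a map function (Haldane by default, i.e. no crossover
  interference) and a recessive height locus placed on the same map;
* F3 families obtained by selfing an F2 plant, with plant heights drawn from
  a two-component Gaussian mixture (dwarf vs tall) plus additive family and
  batch random effects;
* homologous gene-pair (anchor) tables for two genomes, genome B carrying
  planted inversions and unanchored gene insertions, with ground-truth
  breakpoint gaps returned alongside.

Every generator takes an explicit seed and is reproducible call for call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import (CODOMINANT, DOMINANT, GenotypeTable, MAP_FUNCTIONS,
                      COUNT_TO_TRAIT)
from .progeny_test import F3Family

COUNT_TO_CALL = {0: "AA", 1: "AB", 2: "BB"}


@dataclass
class HeightModel:
    """Two-component Gaussian height mixture with family and batch effects.

    Units are cm.  Defaults put <2% of dwarf plants at or above the 110-cm
    short-plant cutoff while keeping within-family standard deviations in the
    low-to-mid twenties for tall families, as observed in glasshouse-grown
    material segregating for additional minor height genes.
    """

    mu_dwarf: float = 70.0
    sd_dwarf: float = 14.0
    mu_tall: float = 165.0
    sd_tall: float = 24.0
    family_effect_sd: float = 5.0
    batch_effect_sd: float = 3.0
    n_batches: int = 3

    def __post_init__(self) -> None:
        if min(self.sd_dwarf, self.sd_tall) <= 0:
            raise ValueError("component SDs must be > 0")
        if min(self.family_effect_sd, self.batch_effect_sd) < 0:
            raise ValueError("effect SDs must be >= 0")


@dataclass
class MarkerDef:
    name: str
    mode: str = CODOMINANT


@dataclass
class SimConfig:
    """Design of a simulated F2 population segregating for a recessive locus.

    ``distances_cm[i]`` is the map distance between ``markers[i]`` and
    ``markers[i+1]``.  ``trait_position_cm`` places the recessive locus on the
    same map (position 0 is the first marker); ``None`` simulates an unlinked
    trait locus (r = 0.5 to every marker).
    """

    n_f2: int
    markers: list[MarkerDef]
    distances_cm: list[float]
    trait_position_cm: float | None = None
    f3_family_size_range: tuple[int, int] = (13, 25)
    height_model: HeightModel = field(default_factory=HeightModel)
    missing_rate: float = 0.0
    map_function: str = "haldane"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker map must contain at least one locus")
        if len(self.distances_cm) != len(self.markers) - 1:
            raise ValueError("need one inter-locus distance per adjacent pair")
        if any(d < 0 for d in self.distances_cm):
            raise ValueError("distances must be >= 0")
        span = sum(self.distances_cm)
        if self.trait_position_cm is not None and not (
                0 <= self.trait_position_cm <= span):
            raise ValueError(
                f"trait position {self.trait_position_cm} outside map span "
                f"[0, {span}]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.f3_family_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid family size range")
        if self.map_function not in MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")


def _simulate_gametes(rng: np.random.Generator, n: int,
                      r: np.ndarray) -> np.ndarray:
    """Alleles (0=A, 1=B) of ``2n`` F1 gametes over ``len(r)+1`` ordered loci."""
    n_loci = len(r) + 1
    first = rng.integers(0, 2, size=(2 * n, 1))
    if n_loci == 1:
        return first
    switches = rng.random((2 * n, n_loci - 1)) < r[None, :]
    cum = np.cumsum(switches, axis=1) % 2
    return np.concatenate([first, (first + cum) % 2], axis=1).astype(np.int8)


def simulate_f2(config: SimConfig) -> tuple[GenotypeTable, pd.Series]:
    """Simulate an F2 population; returns the genotype table and truth labels.

    Each plant is the union of two independent F1 gametes.  Crossovers occur
    independently in each marker interval with recombination fraction given by
    the configured map function.  Dominant loci are reported with the
    heterozygote and the dominant homozygote collapsed to ``A-``; missing
    calls are injected uniformly at random at ``missing_rate``.  Truth labels
    for the trait locus (``dd``/``Dd``/``DD``) are returned unmasked.
    """
    rng = np.random.default_rng(config.seed)
    to_r, _ = MAP_FUNCTIONS[config.map_function]

    positions = np.concatenate([[0.0], np.cumsum(config.distances_cm)])
    names = [m.name for m in config.markers]
    if config.trait_position_cm is not None:
        t_idx = int(np.searchsorted(positions, config.trait_position_cm))
        all_pos = np.insert(positions, t_idx, config.trait_position_cm)
    else:
        t_idx = None
        all_pos = positions
    r = np.array([to_r(d) for d in np.diff(all_pos)])

    gametes = _simulate_gametes(rng, config.n_f2, r)
    counts = gametes[0::2] + gametes[1::2]  # B-chromosome count per locus

    if t_idx is not None:
        trait_counts = counts[:, t_idx]
        counts = np.delete(counts, t_idx, axis=1)
    else:
        unlinked = _simulate_gametes(rng, config.n_f2, np.array([]))
        trait_counts = (unlinked[0::2] + unlinked[1::2])[:, 0]

    plant_ids = [f"p{i + 1:04d}" for i in range(config.n_f2)]
    calls = pd.DataFrame(
        np.vectorize(COUNT_TO_CALL.get)(counts),
        index=plant_ids, columns=names)
    modes = {m.name: m.mode for m in config.markers}
    for m in config.markers:
        if m.mode == DOMINANT:
            calls[m.name] = calls[m.name].replace({"AA": "A-", "AB": "A-"})
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(pd.DataFrame(mask, index=calls.index,
                                        columns=calls.columns), "NA")
    truth = pd.Series([COUNT_TO_TRAIT[c] for c in trait_counts],
                      index=plant_ids, name="trait_genotype")
    return GenotypeTable(calls, modes), truth


_SELFING = {"dd": [1.0, 0.0, 0.0],
            "Dd": [0.25, 0.5, 0.25],
            "DD": [0.0, 0.0, 1.0]}


def simulate_f3_heights(f2_trait_genotype: str, n_plants: int,
                        model: HeightModel | None = None,
                        seed: int = 0, f2_id: str = "F2",
                        batch: str = "1",
                        batch_effect: float | None = None) -> F3Family:
    """Simulate the heights of one selfed F3 family.

    Progeny genotypes follow the selfing rules (``dd`` fixes, ``Dd``
    segregates 1:2:1, ``DD`` fixes); a plant draws from the dwarf height
    component iff it is ``dd``, from the tall component otherwise.  One
    family effect is drawn per family; the batch effect may be supplied to
    share it across families grown concurrently.
    """
    if f2_trait_genotype not in _SELFING:
        raise ValueError(f"invalid trait genotype {f2_trait_genotype!r}")
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    model = model or HeightModel()
    rng = np.random.default_rng(seed)
    probs = _SELFING[f2_trait_genotype]
    genos = rng.choice(3, size=n_plants, p=probs)  # 0=dd, 1=Dd, 2=DD
    dwarf = genos == 0
    heights = np.where(
        dwarf,
        rng.normal(model.mu_dwarf, model.sd_dwarf, n_plants),
        rng.normal(model.mu_tall, model.sd_tall, n_plants))
    fam_eff = rng.normal(0.0, model.family_effect_sd)
    if batch_effect is None:
        batch_effect = rng.normal(0.0, model.batch_effect_sd)
    heights = heights + fam_eff + batch_effect
    heights = np.maximum(heights, 1.0)  # heights are physical, > 0
    return F3Family(f2_id=f2_id, heights=list(np.round(heights, 1)),
                    batch=batch)


def simulate_f3_population(truth: pd.Series, config: SimConfig,
                           plants: list[str] | None = None) -> list[F3Family]:
    """Simulate one F3 family per selected F2 plant, batching them round-robin."""
    rng = np.random.default_rng(config.seed + 1)
    model = config.height_model
    batch_effects = rng.normal(0.0, model.batch_effect_sd, model.n_batches)
    lo, hi = config.f3_family_size_range
    families = []
    ids = plants if plants is not None else list(truth.index)
    for k, plant in enumerate(ids):
        batch = k % model.n_batches
        n = int(rng.integers(lo, hi + 1))
        families.append(simulate_f3_heights(
            truth[plant], n, model,
            seed=int(rng.integers(0, 2**31 - 1)),
            f2_id=str(plant), batch=str(batch + 1),
            batch_effect=float(batch_effects[batch])))
    return families


def gamete_recombinant_fraction(n_gametes: int, d_cm: float,
                                map_function: str = "haldane",
                                seed: int = 0) -> float:
    """Fraction of simulated F1 gametes recombinant between two loci d cM apart."""
    rng = np.random.default_rng(seed)
    to_r, _ = MAP_FUNCTIONS[map_function]
    r = np.array([to_r(d_cm)])
    g = _simulate_gametes(rng, (n_gametes + 1) // 2, r)[:n_gametes]
    return float(np.mean(g[:, 0] != g[:, 1]))


# ---------------------------------------------------------------------------
# anchor tables
# ---------------------------------------------------------------------------

@dataclass
class AnchorTruth:
    """Ground truth emitted next to a simulated anchor table."""

    #: per-gene block label (0 = collinear backbone, 1.. = inversion index)
    block_labels: np.ndarray
    #: per planted inversion: dict with gene index range and true breakpoint
    #: gaps (bp intervals) on both genomes
    inversions: list[dict]


def simulate_anchor_tables(n_genes: int,
                           inversions: list[tuple[int, int]] = (),
                           insertions: int = 0,
                           deletions: int = 0,
                           evalue_neglog10_range: tuple[float, float] = (20.0, 60.0),
                           gap_bp_model: tuple[float, float] = (8000.0, 0.6),
                           chr_a: str = "A1", chr_b: str = "B1",
                           seed: int = 0) -> tuple[pd.DataFrame, AnchorTruth]:
    """Simulate a homologous gene-pair table for two genomes.

    Genome A carries ``n_genes`` genes in identity order; genome B carries the
    same genes with each ``(start, end)`` index range (inclusive) reversed.
    Inter-gene distances are log-normal with median ``gap_bp_model[0]`` bp and
    log-sd ``gap_bp_model[1]``; ``insertions``/``deletions`` insert unanchored
    genes into genome B/A, widening the local gap.  E-values are drawn as
    ``10**-x`` with ``x`` uniform over ``evalue_neglog10_range``.
    """
    rng = np.random.default_rng(seed)
    ivs = sorted(tuple(v) for v in inversions)
    for (s, e) in ivs:
        if not (0 <= s <= e < n_genes):
            raise ValueError(f"inversion ({s}, {e}) outside gene range")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError("overlapping inversions")

    median_gap, log_sd = gap_bp_model

    def draw_positions(n_extra: int) -> np.ndarray:
        gaps = rng.lognormal(math.log(median_gap), log_sd, n_genes + n_extra)
        return np.cumsum(gaps)

    pos_a_all = draw_positions(deletions)
    pos_b_all = draw_positions(insertions)
    # unanchored genes occupy random slots, widening the realised gaps
    keep_a = np.sort(rng.choice(n_genes + deletions, n_genes, replace=False))
    keep_b = np.sort(rng.choice(n_genes + insertions, n_genes, replace=False))
    pos_a = pos_a_all[keep_a]
    pos_b_slots = pos_b_all[keep_b]

    order_b = np.arange(n_genes)
    labels = np.zeros(n_genes, dtype=int)
    for k, (s, e) in enumerate(ivs, start=1):
        order_b[s:e + 1] = order_b[s:e + 1][::-1]
        labels[s:e + 1] = k
    # gene at B slot i is order_b[i]; invert to per-gene B position
    pos_b = np.empty(n_genes)
    pos_b[order_b] = pos_b_slots

    neglog = rng.uniform(*evalue_neglog10_range, n_genes)
    anchors = pd.DataFrame({
        "gene_a": [f"ga{i:05d}" for i in range(n_genes)],
        "chr_a": chr_a,
        "pos_a": np.round(pos_a).astype(int),
        "gene_b": [f"gb{i:05d}" for i in range(n_genes)],
        "chr_b": chr_b,
        "pos_b": np.round(pos_b).astype(int),
        "evalue": 10.0 ** (-neglog),
    })

    truth_inversions = []
    for (s, e) in ivs:
        gap_a_left = (int(anchors.pos_a[s - 1]), int(anchors.pos_a[s])) \
            if s > 0 else None
        gap_a_right = (int(anchors.pos_a[e]), int(anchors.pos_a[e + 1])) \
            if e + 1 < n_genes else None
        # on B the segment occupies slots s..e; its neighbours in B order are
        # genes s-1 and e+1 (order outside inversions is preserved)
        seg_b = sorted(anchors.pos_b[s:e + 1])
        gap_b_left = (int(anchors.pos_b[s - 1]), int(seg_b[0])) \
            if s > 0 else None
        gap_b_right = (int(seg_b[-1]), int(anchors.pos_b[e + 1])) \
            if e + 1 < n_genes else None
        truth_inversions.append({
            "start_gene": s, "end_gene": e,
            "gap_a_left": gap_a_left, "gap_a_right": gap_a_right,
            "gap_b_left": gap_b_left, "gap_b_right": gap_b_right})
    return anchors, AnchorTruth(labels, truth_inversions)
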