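"""Progeny-test genotype calling for a recessive height locus.

An F2 plant's genotype at a recessive dwarfing locus cannot be read from its
own phenotype when it carries the dominant tall allele, but it segregates in
its selfed F3 family: ``dd`` parents give all-dwarf families, ``Dd`` parents
give 3 tall : 1 dwarf, and ``DD`` parents give all-tall families.  The caller
implements the conservative decision rule used for field data:

* family median height < 90 cm          -> ``dd``
* family median height > 135 cm and
    - no plant below 110 cm             -> ``DD``
    - short fraction compatible with 25%
      (Pearson chi-square, alpha=0.05)  -> ``Dd``
    - short fraction significantly below
      25%                               -> ``DD``
* median in the 90-135 cm band          -> ``tall_unresolved``
* empty family                          -> ``no_data``

The 110-cm cutoff separates dwarfs from talls with <2% of dwarf plants above
it; the wide unresolved band absorbs families whose median is pulled down by
other segregating height genes and environmental effects.
"""
from __future__ import annotations

import math
import statistics
from collections import Counter
from dataclasses import dataclass, field

from scipy import stats

CALL_LABELS = ("dd", "Dd", "DD", "tall_unresolved", "no_data")


@dataclass
class Thresholds:
    """Decision-rule thresholds (cm and test level)."""

    dwarf_median: float = 90.0
    tall_median: float = 135.0
    short_plant: float = 110.0
    alpha: float = 0.05
    #: divide alpha by the number of tested families (off by default)
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if min(self.dwarf_median, self.tall_median, self.short_plant) <= 0:
            raise ValueError("thresholds must be positive")
        if self.dwarf_median >= self.tall_median:
            raise ValueError("dwarf_median must be below tall_median")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class F3Family:
    """Heights of the selfed progeny of one F2 plant (one phenotyping batch).

    Either per-plant ``heights`` or the pre-computed summary fields must be
    supplied.  ``n_below_cutoff`` refers to the 110-cm short-plant cutoff of
    the decision rule.
    """

    f2_id: str
    heights: list[float] | None = None
    batch: str = "1"
    n: int | None = None
    median_cm: float | None = None
    mean_cm: float | None = None
    sd_cm: float | None = None
    n_below_cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.heights is not None:
            self.heights = [float(h) for h in self.heights]
            if any(h <= 0 for h in self.heights):
                raise ValueError(f"family {self.f2_id}: heights must be > 0")
            if self.n is None:
                self.n = len(self.heights)
            elif self.n != len(self.heights):
                raise ValueError(
                    f"family {self.f2_id}: n={self.n} does not match "
                    f"{len(self.heights)} heights")
            if self.median_cm is None and self.heights:
                self.median_cm = statistics.median(self.heights)
            if self.mean_cm is None and self.heights:
                self.mean_cm = statistics.fmean(self.heights)
            if self.sd_cm is None and len(self.heights) > 1:
                self.sd_cm = statistics.stdev(self.heights)
        if self.n is None:
            self.n = 0
        if self.n_below_cutoff is not None and self.n_below_cutoff > self.n:
            raise ValueError(
                f"family {self.f2_id}: n_below_cutoff exceeds family size")

    def n_short(self, cutoff: float) -> int | None:
        if self.heights is not None:
            return sum(h < cutoff for h in self.heights)
        return self.n_below_cutoff


@dataclass
class TraitCall:
    """Inferred F2 genotype at the trait locus with supporting statistics."""

    f2_id: str
    call: str
    chi2_3to1: float | None = None
    p_value_3to1: float | None = None
    rule_fired: str = ""
    warning: str = ""

    def __post_init__(self) -> None:
        if self.call not in CALL_LABELS:
            raise ValueError(f"invalid call label {self.call!r}")


def chisq_3to1(n_short: int, n_total: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of an observed short:tall split against 1:3.

    One degree of freedom, no continuity correction; returns ``(chi2, p)``
    with ``p`` the upper-tail chi-square probability.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_short <= n_total:
        raise ValueError("n_short must lie in [0, n_total]")
    chi2, p = stats.chisquare(
        [n_short, n_total - n_short],
        f_exp=[n_total / 4.0, 3.0 * n_total / 4.0])
    return float(chi2), float(p)


def classify_family(family: F3Family,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> TraitCall:
    """Apply the decision rule to a single F3 family."""
    if family.n == 0:
        return TraitCall(family.f2_id, "no_data", rule_fired="empty family")
    median = family.median_cm
    if median is None or (isinstance(median, float) and math.isnan(median)):
        raise ValueError(f"family {family.f2_id}: median height required")
    if median < thresholds.dwarf_median:
        return TraitCall(family.f2_id, "dd",
                         rule_fired=f"median {median:g} < "
                                    f"{thresholds.dwarf_median:g} cm")
    if median > thresholds.tall_median:
        n_short = family.n_short(thresholds.short_plant)
        if n_short is None:
            raise ValueError(
                f"family {family.f2_id}: short-plant count required for a "
                "tall-median family")
        if n_short == 0:
            return TraitCall(family.f2_id, "DD",
                             rule_fired="no plants below "
                                        f"{thresholds.short_plant:g} cm")
        chi2, p = chisq_3to1(n_short, family.n)
        if p > thresholds.alpha:
            return TraitCall(family.f2_id, "Dd", chi2, p,
                             rule_fired=f"{n_short}/{family.n} short "
                                        "compatible with 3:1")
        if n_short / family.n < 0.25:
            return TraitCall(family.f2_id, "DD", chi2, p,
                             rule_fired=f"{n_short}/{family.n} short "
                                        "significantly below 25%")
        return TraitCall(family.f2_id, "Dd", chi2, p,
                         rule_fired=f"{n_short}/{family.n} short "
                                    "significantly ABOVE 25%",
                         warning="short fraction above expectation for a "
                                 "heterozygote; check for misphenotyping")
    return TraitCall(family.f2_id, "tall_unresolved",
                     rule_fired=f"median {median:g} within "
                                f"[{thresholds.dwarf_median:g}, "
                                f"{thresholds.tall_median:g}] cm")


def _merge_batches(calls: list[TraitCall]) -> TraitCall:
    """Consensus call for one family phenotyped in several batches."""
    real = [c for c in calls if c.call != "no_data"]
    if not real:
        return calls[0]
    labels = {c.call for c in real}
    if len(labels) == 1:
        merged = real[0]
        merged.rule_fired += f" (consensus of {len(real)} batches)"
        return merged
    return TraitCall(real[0].f2_id, "tall_unresolved",
                     rule_fired="batch calls disagree: "
                                + "/".join(sorted(labels)),
                     warning="downgraded to tall_unresolved")


@dataclass
class PopulationCalls:
    calls: list[TraitCall]
    tally: dict[str, int]

    def call_for(self, f2_id: str) -> TraitCall:
        for c in self.calls:
            if c.f2_id == f2_id:
                return c
        raise KeyError(f2_id)

    def as_mapping(self) -> dict[str, str]:
        return {c.f2_id: c.call for c in self.calls}


def classify_population(families: list[F3Family],
                        thresholds: Thresholds = DEFAULT_THRESHOLDS
                        ) -> PopulationCalls:
    """Classify every family; families split over batches are merged by consensus.

    Returns one :class:`TraitCall` per F2 plant plus a tally over the five
    call labels.  F2 ids must be unique up to batch splits (the same id may
    appear once per batch, never twice within a batch).
    """
    if thresholds.bonferroni and families:
        n_tests = len({f.f2_id for f in families})
        thresholds = Thresholds(thresholds.dwarf_median, thresholds.tall_median,
                                thresholds.short_plant,
                                thresholds.alpha / n_tests)
    seen: dict[tuple[str, str], bool] = {}
    grouped: dict[str, list[TraitCall]] = {}
    order: list[str] = []
    for fam in families:
        key = (fam.f2_id, fam.batch)
        if key in seen:
            raise ValueError(
                f"duplicate f2_id {fam.f2_id!r} within batch {fam.batch!r}")
        seen[key] = True
        if fam.f2_id not in grouped:
            order.append(fam.f2_id)
            grouped[fam.f2_id] = []
        grouped[fam.f2_id].append(classify_family(fam, thresholds))
    calls = [_merge_batches(grouped[fid]) for fid in order]
    tally = Counter({label: 0 for label in CALL_LABELS})
    tally.update(c.call for c in calls)
    return PopulationCalls(calls, dict(tally))
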