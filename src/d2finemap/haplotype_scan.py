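"""Haplotype discrimination scan across tall and dwarf inbred panels.

All dwarf inbreds derived from one mutational source share a haplotype around
the recessive locus.  Scanning an allele matrix of tall vs dwarf lines locus
by locus, a locus *discriminates* the classes when the dwarfs are uniform for
an allele no tall line carries; sporadic allele sharing by a single tall line
(homoplasy or a near-isogenic background) is tolerated as an *exception*; a
locus where the dwarfs are heterogeneous, or where too many tall lines share
the dwarf allele, is *broken*.  The maximal run of discriminating loci, with
at most ``max_exceptions`` exception loci per block, delineates the shared
introgression; the first locus that terminates the run on each side sets the
candidate-interval boundary.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

ND = "ND"
TALL = "tall"
DWARF = "dwarf"

DISCRIMINATING = "discriminating"
EXCEPTION = "exception"
BROKEN = "broken"
UNINFORMATIVE = "uninformative"


@dataclass
class HaplotypeMatrix:
    """Inbred lines x ordered loci allele calls with a height-class label.

    ``alleles`` is indexed by line name with one column per locus, ordered
    consistently with the linkage map (distal to proximal); calls are
    arbitrary labels with ``"ND"`` for missing.  ``classes`` maps line name
    to ``"tall"`` or ``"dwarf"``.
    """

    alleles: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        self.alleles = self.alleles.astype(str)
        self.classes = self.classes.reindex(self.alleles.index)
        bad = ~self.classes.isin([TALL, DWARF])
        if bad.any():
            raise ValueError(
                f"lines without a tall/dwarf class: "
                f"{list(self.classes.index[bad])}")
        for cls in (TALL, DWARF):
            if not (self.classes == cls).any():
                raise ValueError(f"need at least one {cls} line")

    @property
    def loci(self) -> list[str]:
        return list(self.alleles.columns)

    def tall_lines(self) -> list[str]:
        return list(self.classes.index[self.classes == TALL])

    def dwarf_lines(self) -> list[str]:
        return list(self.classes.index[self.classes == DWARF])


@dataclass
class LocusVerdict:
    locus: str
    status: str
    #: tall lines sharing the dwarf allele (exception status)
    exception_lines: list[str] = field(default_factory=list)
    dwarf_allele: str | None = None


def assess_locus(column: pd.Series, classes: pd.Series,
                 max_exceptions: int = 1) -> LocusVerdict:
    """Classify one locus column; only the partition of allele labels matters.

    ``discriminating``: all non-missing dwarf calls identical and no tall
    line carries that allele.  ``exception``: at most ``max_exceptions`` tall
    lines share the dwarf allele while at least one tall line differs.
    ``broken``: dwarfs heterogeneous, or too many tall lines share.
    ``uninformative``: one class has no data.
    """
    name = str(column.name)
    dw = column[(classes == DWARF) & (column != ND)]
    tl = column[(classes == TALL) & (column != ND)]
    if dw.empty or tl.empty:
        return LocusVerdict(name, UNINFORMATIVE)
    alleles = set(dw)
    if len(alleles) > 1:
        return LocusVerdict(name, BROKEN)
    a = alleles.pop()
    sharing = list(tl.index[tl == a])
    if not sharing:
        return LocusVerdict(name, DISCRIMINATING, dwarf_allele=a)
    if len(sharing) <= max_exceptions and len(sharing) < len(tl):
        return LocusVerdict(name, EXCEPTION, exception_lines=sharing,
                            dwarf_allele=a)
    return LocusVerdict(name, BROKEN, exception_lines=sharing, dwarf_allele=a)


@dataclass
class BlockResult:
    """Maximal discriminating block and its boundaries."""

    block_loci: list[str]
    verdicts: list[LocusVerdict]
    #: first terminating locus beyond the block on the distal side (None =
    #: the block reaches the end of the scanned loci: open end)
    distal_boundary: str | None
    proximal_boundary: str | None
    n_discriminating: int = 0
    n_exceptions: int = 0

    def verdict_for(self, locus: str) -> LocusVerdict:
        for v in self.verdicts:
            if v.locus == locus:
                return v
        raise KeyError(locus)


def delineate_block(matrix: HaplotypeMatrix, max_exceptions: int = 1,
                    break_run: int = 1) -> BlockResult:
    """Find the maximal run of class-discriminating loci and its boundaries.

    The block is the contiguous window containing the most
    discriminating-plus-exception loci subject to (a) no run of ``break_run``
    consecutive broken loci inside it and (b) at most ``max_exceptions``
    exception loci in total — the per-block budget is what lets a single
    tall-line homoplasy pass while a second shared allele terminates the
    block.  Uninformative loci neither extend nor break a run.  The boundary
    on each side is the nearest informative locus beyond the block; ``None``
    flags an open end.
    """
    loci = matrix.loci
    if len(loci) < 2:
        raise ValueError("need at least two loci to delineate a block")
    verdicts = [assess_locus(matrix.alleles[l], matrix.classes, max_exceptions)
                for l in loci]
    status = [v.status for v in verdicts]

    best = None  # ((count, -start), (i, j))
    n = len(loci)
    for i in range(n):
        if status[i] not in (DISCRIMINATING, EXCEPTION):
            continue
        exceptions = 0
        broken_run = 0
        for j in range(i, n):
            s = status[j]
            if s == BROKEN:
                broken_run += 1
                if broken_run >= break_run:
                    break
            else:
                broken_run = 0
            if s == EXCEPTION:
                exceptions += 1
                if exceptions > max_exceptions:
                    break
            if s in (DISCRIMINATING, EXCEPTION):
                count = sum(1 for k in range(i, j + 1)
                            if status[k] in (DISCRIMINATING, EXCEPTION))
                key = (count, -i)
                if best is None or key > best[0]:
                    best = (key, (i, j))
    if best is None:
        warnings.warn("no discriminating locus: empty block")
        return BlockResult([], verdicts, None, None)
    (count, _), (i, j) = best
    block = loci[i:j + 1]

    def boundary(idx_range) -> str | None:
        for k in idx_range:
            if status[k] != UNINFORMATIVE:
                return loci[k]
        return None

    distal = boundary(range(i - 1, -1, -1))
    proximal = boundary(range(j + 1, n))
    n_disc = sum(1 for k in range(i, j + 1) if status[k] == DISCRIMINATING)
    n_exc = sum(1 for k in range(i, j + 1) if status[k] == EXCEPTION)
    return BlockResult(block, verdicts, distal, proximal, n_disc, n_exc)


def haplotype_concordance(matrix: HaplotypeMatrix,
                          loci: list[str] | None = None) -> pd.DataFrame:
    """Pairwise allele-sharing fractions between lines over the given loci.

    Returns one row per line pair with the fraction of shared alleles over
    loci where both lines have data, plus the class pair (dwarf-dwarf,
    tall-tall, tall-dwarf).
    """
    cols = loci if loci is not None else matrix.loci
    sub = matrix.alleles[cols]
    rows = []
    for l1, l2 in combinations(sub.index, 2):
        a1, a2 = sub.loc[l1], sub.loc[l2]
        both = (a1 != ND) & (a2 != ND)
        n = int(both.sum())
        share = float((a1[both] == a2[both]).mean()) if n else float("nan")
        pair = "-".join(sorted([matrix.classes[l1], matrix.classes[l2]]))
        rows.append({"line_1": l1, "line_2": l2, "class_pair": pair,
                     "n_loci": n, "sharing": share})
    return pd.DataFrame(rows)
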