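"""Collinear synteny-block chaining, rearrangement calls and interval projection.

Anchors are homologous gene pairs (one gene per genome, with the homology
E-value).  Blocks are score-maximal monotone chains of anchors under the
empirical scoring scheme ``min{-log10 E, 50}`` per pair minus a gap penalty
of 1 per 10 kb between consecutive pairs; ascending (``+``) and descending
(``-``) chains are computed independently and compete during non-overlapping
extraction, so an inversion surfaces as a ``-`` block between ``+`` blocks.
A marker-bounded candidate interval is projected onto a reference genome by
taking the span between the two boundary markers' ortholog positions and
listing the annotated genes inside it.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCHOR_COLUMNS = ["gene_a", "chr_a", "pos_a", "gene_b", "chr_b", "pos_b",
                  "evalue"]

SCORE_CAP = 50.0


def pair_score(evalue: float) -> float:
    """Score of one gene pair: ``min(-log10 E, 50)``; ``E = 0`` maps to 50."""
    if evalue < 0:
        raise ValueError("E-value must be >= 0")
    if evalue == 0:
        return SCORE_CAP
    return min(-math.log10(evalue), SCORE_CAP)


def filter_anchors(raw: pd.DataFrame, emax: float = 1e-5,
                   max_hits: int = 4) -> pd.DataFrame:
    """Apply the homology-search retention rule to raw gene pairs.

    Pairs with ``evalue >= emax`` are removed; per query gene at most the
    ``max_hits`` best-E pairs are retained, ties broken by subject gene id;
    duplicate (gene_a, gene_b) records are dropped.
    """
    df = raw.copy()
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anchor table lacks columns {missing}")
    df = df[df["evalue"] < emax]
    df = df.drop_duplicates(subset=["gene_a", "gene_b"])
    df = df.sort_values(["gene_a", "evalue", "gene_b"], kind="stable")
    df = df.groupby("gene_a", sort=False).head(max_hits)
    return df.sort_values(["chr_a", "pos_a", "chr_b", "pos_b"],
                          kind="stable").reset_index(drop=True)


GAP_AGGREGATES = {"max": max, "min": min, "mean": lambda a, b: (a + b) / 2.0,
                  "sum": lambda a, b: a + b}


def gap_penalty(d_a: float, d_b: float, gap_unit_bp: float = 10000.0,
                gap_agg: str = "max") -> float:
    """Continuous gap penalty: 1 per ``gap_unit_bp`` of inter-anchor distance."""
    return GAP_AGGREGATES[gap_agg](abs(d_a), abs(d_b)) / gap_unit_bp


@dataclass
class SyntenyBlock:
    """A scored, oriented chain of anchor pairs on one chromosome pair."""

    anchors: pd.DataFrame  # ordered by pos_a
    orientation: str       # "+" or "-"
    score: float
    chr_a: str
    chr_b: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    gap_unit_bp: float = 10000.0
    gap_agg: str = "max"

    def __len__(self) -> int:
        return len(self.anchors)

    def recompute_score(self) -> float:
        """Score from scratch, anchor by anchor (consistency invariant)."""
        rows = self.anchors
        total = sum(pair_score(e) for e in rows["evalue"])
        pa = rows["pos_a"].to_numpy()
        pb = rows["pos_b"].to_numpy()
        for i in range(len(rows) - 1):
            total -= gap_penalty(pa[i + 1] - pa[i], pb[i + 1] - pb[i],
                                 self.gap_unit_bp, self.gap_agg)
        return total


def _best_chain(pa: np.ndarray, pb: np.ndarray, scores: np.ndarray,
                orientation: str, gap_unit_bp: float,
                gap_agg: str) -> tuple[list[int], float]:
    """Best monotone chain (indices in pos_a order) by dynamic programming.

    Chains are strictly increasing in ``pos_a`` and strictly increasing
    (``+``) or decreasing (``-``) in ``pos_b``; a chain may start at any
    anchor, so a predecessor is used only when it improves the total.
    """
    n = len(pa)
    agg = GAP_AGGREGATES[gap_agg]
    dp = scores.astype(float).copy()
    back = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            if pa[j] >= pa[i]:
                continue
            if orientation == "+":
                if pb[j] >= pb[i]:
                    continue
            else:
                if pb[j] <= pb[i]:
                    continue
            gap = agg(abs(pa[i] - pa[j]), abs(pb[i] - pb[j])) / gap_unit_bp
            cand = dp[j] - gap + scores[i]
            if cand > dp[i] or (cand == dp[i] and back[i] == -1):
                dp[i] = cand
                back[i] = j
    best_end = int(np.argmax(dp))
    chain = []
    k = best_end
    while k != -1:
        chain.append(k)
        k = back[k]
    return chain[::-1], float(dp[best_end])


def best_chain_score(anchors: pd.DataFrame, gap_unit_bp: float = 10000.0,
                     gap_agg: str = "max") -> float:
    """Score of the single best monotone chain over the given anchors.

    Runs the same dynamic programme as :func:`chain_blocks` for both
    orientations and returns the optimum — the quantity an exhaustive
    enumeration of monotone chains must reproduce.
    """
    sub = anchors.sort_values(["pos_a", "pos_b"], kind="stable")
    pa = sub["pos_a"].to_numpy(dtype=float)
    pb = sub["pos_b"].to_numpy(dtype=float)
    sc = np.array([pair_score(e) for e in sub["evalue"]])
    return max(_best_chain(pa, pb, sc, orient, gap_unit_bp, gap_agg)[1]
               for orient in ("+", "-"))


def chain_blocks(anchors: pd.DataFrame, gap_unit_bp: float = 10000.0,
                 score_min: float = 300.0, gap_agg: str = "max"
                 ) -> list[SyntenyBlock]:
    """Extract non-overlapping score-maximal collinear chains per chromosome pair.

    Ascending and descending chains are computed independently on the
    remaining anchors; the best-scoring chain is extracted, its anchors are
    removed, and the search repeats until no chain scores above
    ``score_min``.  Chains with score <= ``score_min`` are discarded.
    """
    blocks: list[SyntenyBlock] = []
    # extract down to a floor below score_min: a chain may transiently lose
    # an edge anchor to a longer chain and only regain it (and its score)
    # during boundary relocation, so the final threshold is applied after
    extraction_floor = max(0.0, score_min - 2 * SCORE_CAP)
    for (ca, cb), sub in anchors.groupby(["chr_a", "chr_b"], sort=True):
        base = sub.sort_values(["pos_a", "pos_b"],
                               kind="stable").reset_index(drop=True)
        remaining = base.copy()  # index labels stay positions into base
        chains: list[tuple[list[int], str]] = []
        while len(remaining):
            pa = remaining["pos_a"].to_numpy(dtype=float)
            pb = remaining["pos_b"].to_numpy(dtype=float)
            sc = np.array([pair_score(e) for e in remaining["evalue"]])
            best = None
            for orient in ("+", "-"):
                chain, score = _best_chain(pa, pb, sc, orient, gap_unit_bp,
                                           gap_agg)
                if best is None or score > best[1]:
                    best = (chain, score, orient)
            chain, score, orient = best
            if score <= extraction_floor:
                break
            members = [int(remaining.index[i]) for i in chain]
            chains.append((members, orient))
            remaining = remaining.drop(index=members)
        member_lists = _relocate_members(base, chains, gap_unit_bp, gap_agg)
        for members, orient in member_lists:
            rows = base.iloc[members].sort_values(
                ["pos_a", "pos_b"], kind="stable").reset_index(drop=True)
            blk = SyntenyBlock(
                anchors=rows, orientation=orient, score=0.0,
                chr_a=str(ca), chr_b=str(cb),
                span_a=(int(rows["pos_a"].min()), int(rows["pos_a"].max())),
                span_b=(int(rows["pos_b"].min()), int(rows["pos_b"].max())),
                gap_unit_bp=gap_unit_bp, gap_agg=gap_agg)
            blk.score = blk.recompute_score()
            if blk.score > score_min:
                blocks.append(blk)
    blocks.sort(key=lambda b: (b.chr_a, b.span_a[0], b.chr_b))
    return blocks


def _relocate_members(base: pd.DataFrame, chains, gap_unit_bp: float,
                      gap_agg: str, max_passes: int = 10):
    """Re-home anchors between chains by local collinearity.

    Greedy extraction lets a long collinear chain absorb a single anchor of a
    reverse-orientation segment (one anchor never violates monotonicity), and
    keeping it there is nearly score-neutral because the long chain bridges
    the segment either way.  The anchor's *adjacent gap distances*, however,
    identify its true neighbours: it is moved to another chain of the same
    chromosome pair when the insertion is monotone there and the sum of its
    adjacent gap penalties strictly decreases.  Breakpoints at inversion
    edges then fall in the true inter-gene gaps.
    """
    pa_all = base["pos_a"].to_numpy(dtype=float)
    pb_all = base["pos_b"].to_numpy(dtype=float)
    agg = GAP_AGGREGATES[gap_agg]

    def gap(i: int, j: int) -> float:
        return agg(abs(pa_all[i] - pa_all[j]),
                   abs(pb_all[i] - pb_all[j])) / gap_unit_bp

    # members kept sorted by pos_a
    chains = [(sorted(members, key=lambda i: (pa_all[i], pb_all[i])), orient)
              for members, orient in chains]

    def adjacent_sum(members: list[int], k: int) -> float:
        total = 0.0
        if k > 0:
            total += gap(members[k - 1], members[k])
        if k < len(members) - 1:
            total += gap(members[k], members[k + 1])
        return total

    for _ in range(max_passes):
        moved = False
        for si, (src, s_orient) in enumerate(chains):
            if len(src) <= 1:
                continue
            for di, (dst, d_orient) in enumerate(chains):
                if di == si:
                    continue
                k = 0
                while k < len(src):
                    x = src[k]
                    pos = int(np.searchsorted(
                        pa_all[dst], pa_all[x]))
                    # monotone fit between dst[pos-1] and dst[pos]
                    ok = True
                    if pos > 0:
                        l = dst[pos - 1]
                        if pa_all[l] >= pa_all[x]:
                            ok = False
                        elif (pb_all[l] >= pb_all[x] if d_orient == "+"
                              else pb_all[l] <= pb_all[x]):
                            ok = False
                    if ok and pos < len(dst):
                        r = dst[pos]
                        if pa_all[r] <= pa_all[x]:
                            ok = False
                        elif (pb_all[r] <= pb_all[x] if d_orient == "+"
                              else pb_all[r] >= pb_all[x]):
                            ok = False
                    if not ok:
                        k += 1
                        continue
                    here = adjacent_sum(src, k)
                    there = 0.0
                    if pos > 0:
                        there += gap(dst[pos - 1], x)
                    if pos < len(dst):
                        there += gap(x, dst[pos])
                    if there >= here - 1e-9:
                        k += 1
                        continue
                    dst.insert(pos, x)
                    src.pop(k)
                    moved = True
                if not src:
                    break
            chains = [(m, o) for m, o in chains if m]
        if not moved:
            break
    return chains


def dotplot_data(anchors: pd.DataFrame,
                 blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """One row per anchor with block membership, for dot-plot rendering."""
    out = anchors.copy().reset_index(drop=True)
    out["block_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["orientation"] = pd.array([pd.NA] * len(out), dtype="string")
    key = out["gene_a"].astype(str) + "\t" + out["gene_b"].astype(str)
    lookup = {}
    for bid, blk in enumerate(blocks):
        for _, row in blk.anchors.iterrows():
            lookup[f"{row['gene_a']}\t{row['gene_b']}"] = (bid, blk.orientation)
    hits = key.map(lookup)
    mask = hits.notna()
    out.loc[mask, "block_id"] = [h[0] for h in hits[mask]]
    out.loc[mask, "orientation"] = [h[1] for h in hits[mask]]
    return out


def plot_dotplot(dot: pd.DataFrame, ax=None):  # pragma: no cover - thin wrapper
    """Render a dot plot (requires matplotlib; optional extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    noblock = dot["block_id"].isna()
    ax.scatter(dot.loc[noblock, "pos_a"], dot.loc[noblock, "pos_b"],
               s=4, c="lightgrey")
    for bid, sub in dot[~noblock].groupby("block_id"):
        color = "crimson" if (sub["orientation"] == "-").all() else "navy"
        ax.scatter(sub["pos_a"], sub["pos_b"], s=6, c=color)
    ax.set_xlabel("genome A position (bp)")
    ax.set_ylabel("genome B position (bp)")
    return ax


@dataclass
class Rearrangement:
    """An inversion or translocation boundary between neighbouring blocks."""

    kind: str  # "inversion" | "translocation-boundary"
    block_index: int
    #: (lo, hi) bp interval on genome A containing the left/right breakpoint;
    #: None at a chromosome end
    breakpoint_a_left: tuple[int, int] | None = None
    breakpoint_a_right: tuple[int, int] | None = None
    breakpoint_b_left: tuple[int, int] | None = None
    breakpoint_b_right: tuple[int, int] | None = None


def _assigned_anchors(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    frames = []
    for bid, blk in enumerate(blocks):
        sub = blk.anchors.copy()
        sub["block_id"] = bid
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def detect_rearrangements(blocks: list[SyntenyBlock]) -> list[Rearrangement]:
    """Call inversions and translocation boundaries from the chained blocks.

    A ``-`` block whose nearest block-assigned anchors on either side (along
    each genome) belong to ``+`` blocks — or fall off the chromosome end —
    is an inversion; the breakpoint interval on each genome is the gap
    between the block's terminal anchor and that neighbouring anchor.  A
    change of genome-B chromosome between genome-A-adjacent blocks marks a
    translocation boundary.
    """
    if not blocks:
        return []
    calls: list[Rearrangement] = []
    assigned = _assigned_anchors(blocks)

    def neighbour(bid: int, genome: str, side: str):
        """Nearest anchor of another block beyond the block's span."""
        blk = blocks[bid]
        chrom = blk.chr_a if genome == "a" else blk.chr_b
        chr_col, pos_col = (("chr_a", "pos_a") if genome == "a"
                            else ("chr_b", "pos_b"))
        span = blk.span_a if genome == "a" else blk.span_b
        sub = assigned[(assigned[chr_col] == chrom)
                       & (assigned["block_id"] != bid)]
        if side == "left":
            sub = sub[sub[pos_col] < span[0]]
            if sub.empty:
                return None
            row = sub.loc[sub[pos_col].idxmax()]
            return int(row[pos_col]), int(row["block_id"]), span[0]
        sub = sub[sub[pos_col] > span[1]]
        if sub.empty:
            return None
        row = sub.loc[sub[pos_col].idxmin()]
        return int(row[pos_col]), int(row["block_id"]), span[1]

    # translocation boundaries: genome-A-adjacent blocks on different chr_b
    by_chr: dict[str, list[int]] = {}
    for i in sorted(range(len(blocks)),
                    key=lambda i: (blocks[i].chr_a, blocks[i].span_a[0])):
        by_chr.setdefault(blocks[i].chr_a, []).append(i)
    for idxs in by_chr.values():
        for k in range(1, len(idxs)):
            prev, cur = blocks[idxs[k - 1]], blocks[idxs[k]]
            if prev.chr_b != cur.chr_b:
                calls.append(Rearrangement(
                    "translocation-boundary", idxs[k],
                    breakpoint_a_left=(prev.span_a[1], cur.span_a[0])))

    for bid, blk in enumerate(blocks):
        if blk.orientation != "-":
            continue
        flanks = {}
        ok = True
        for genome in ("a", "b"):
            for side in ("left", "right"):
                nb = neighbour(bid, genome, side)
                if nb is None:
                    flanks[(genome, side)] = None  # chromosome end
                    continue
                pos, nb_bid, edge = nb
                nb_blk = blocks[nb_bid]
                if nb_blk.orientation != "+" or nb_blk.chr_b != blk.chr_b:
                    ok = False
                flanks[(genome, side)] = ((pos, edge) if side == "left"
                                          else (edge, pos))
        if not ok:
            continue
        calls.append(Rearrangement(
            "inversion", bid,
            breakpoint_a_left=flanks[("a", "left")],
            breakpoint_a_right=flanks[("a", "right")],
            breakpoint_b_left=flanks[("b", "left")],
            breakpoint_b_right=flanks[("b", "right")]))
    return calls


@dataclass
class CandidateInterval:
    """A marker-bounded interval projected onto a reference genome."""

    genome: str
    chromosome: str
    start_bp: int
    end_bp: int
    marker_distal: str
    marker_proximal: str
    genes: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def to_bed_row(self) -> str:
        """0-based half-open BED line (internal coordinates are 1-based)."""
        return (f"{self.chromosome}\t{self.start_bp - 1}\t{self.end_bp}\t"
                f"{self.marker_distal}--{self.marker_proximal}")


def project_interval(marker_1: tuple[str, str, int],
                     marker_2: tuple[str, str, int],
                     annotation: pd.DataFrame | None = None,
                     genome: str = "reference") -> CandidateInterval:
    """Project two boundary markers onto a reference genome interval.

    Each marker is ``(name, chromosome, ortholog position in bp)``.  The
    interval spans the two ortholog positions (ordered); when an annotation
    table (``gene_id``, ``chrom``, ``start`` [, ``end``]) is supplied, genes
    whose representative coordinate (``start``) lies within the closed
    interval are listed.
    """
    (n1, c1, p1), (n2, c2, p2) = marker_1, marker_2
    if c1 != c2:
        raise ValueError(
            f"boundary markers on different chromosomes: {n1} on {c1!r}, "
            f"{n2} on {c2!r}")
    (start, ms), (end, me) = sorted([(int(p1), n1), (int(p2), n2)])
    if start == end:
        warnings.warn(f"zero-length interval at {start} bp "
                      f"({n1} and {n2} coincide)")
    genes: list[str] = []
    if annotation is not None:
        sub = annotation[(annotation["chrom"].astype(str) == str(c1))
                         & (annotation["start"] >= start)
                         & (annotation["start"] <= end)]
        genes = [str(g) for g in sub.sort_values("start")["gene_id"]]
    return CandidateInterval(genome, str(c1), start, end, ms, me, genes)
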