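"""Recombination-bin collapsing and genetic-map construction.

Corrected genotype matrices are collapsed into bins (maximal runs of
adjacent loci with identical genotype vectors), filtered for Mendelian
1:2:1 segregation, grouped by two-point linkage (LOD and recombination
thresholds), ordered within groups by a weighted least-squares criterion
and placed on a Kosambi centimorgan scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._mapfun import MAX_RF, kosambi, kosambi_inverse
from .genotyping import SYM_AA, SYM_BB, SYM_H, SYM_MISS

__all__ = [
    "Bin",
    "PairLinkage",
    "LinkageGroup",
    "GeneticMap",
    "collapse_bins",
    "segregation_filter",
    "two_locus_probs",
    "estimate_rf",
    "pairwise_linkages",
    "group_bins",
    "order_bins",
    "build_map",
    "map_statistics",
    "average_interval",
    "kosambi",
    "kosambi_inverse",
]


@dataclass
class Bin:
    """A maximal run of adjacent co-segregating loci.

    All member loci share one identical corrected genotype vector, which
    therefore represents the bin across the population.
    """

    bin_id: int
    scaffold: str
    start_pos: int
    end_pos: int
    locus_indices: np.ndarray
    vector: np.ndarray  # int8 over progeny, {AA,H,BB,missing}
    n_aa: int = 0
    n_h: int = 0
    n_bb: int = 0
    n_missing: int = 0
    chi2: float = float("nan")
    p_value: float = float("nan")

    @property
    def n_markers(self) -> int:
        return len(self.locus_indices)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_aa, self.n_h, self.n_bb)


@dataclass(frozen=True)
class PairLinkage:
    """Two-point linkage estimate between a pair of bins."""

    r: float
    lod: float
    n_informative: int
    informative: bool = True


@dataclass
class LinkageGroup:
    """An ordered set of bins with cumulative Kosambi cM positions."""

    lg_id: int
    bin_ids: list[int]
    positions_cm: np.ndarray

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.positions_cm) else 0.0


@dataclass
class GeneticMap:
    """A full genetic map: linkage groups plus the bins they order."""

    groups: list[LinkageGroup]
    bins: list[Bin]
    discarded_groups: list[list[int]] = field(default_factory=list)

    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))


def collapse_bins(corrected: np.ndarray, loci: pd.DataFrame) -> list[Bin]:
    """Collapse adjacent loci with identical corrected vectors into bins.

    Runs never span scaffolds; every locus belongs to exactly one bin.
    Vector identity is exact, missing entries included.
    """
    if len(corrected) != len(loci):
        raise ValueError("corrected matrix and locus table length mismatch")
    bins: list[Bin] = []
    scaffolds = loci["scaffold"].to_numpy()
    positions = loci["pos"].to_numpy()
    for scaf, idx in loci.groupby("scaffold", sort=False).indices.items():
        block = corrected[idx]
        change = np.any(block[1:] != block[:-1], axis=1)
        starts = np.concatenate([[0], np.flatnonzero(change) + 1])
        ends = np.concatenate([starts[1:], [len(idx)]])
        for s, e in zip(starts, ends):
            members = idx[s:e]
            vec = corrected[members[0]]
            bins.append(
                Bin(
                    bin_id=len(bins),
                    scaffold=str(scaf),
                    start_pos=int(positions[members[0]]),
                    end_pos=int(positions[members[-1]]),
                    locus_indices=members,
                    vector=vec,
                    n_aa=int((vec == SYM_AA).sum()),
                    n_h=int((vec == SYM_H).sum()),
                    n_bb=int((vec == SYM_BB).sum()),
                    n_missing=int((vec == SYM_MISS).sum()),
                )
            )
    return bins


def segregation_filter(
    bins: list[Bin], alpha: float = 0.05
) -> tuple[list[Bin], dict]:
    """Retain bins fitting the 1:2:1 F2 ratio (chi-square, df=2, p > alpha).

    Missing entries are excluded from the test; all-missing bins are
    discarded with their own reason.  Each bin's statistic and p-value are
    filled in as a side effect.
    """
    retained: list[Bin] = []
    n_distorted = n_empty = 0
    for b in bins:
        n = b.n_aa + b.n_h + b.n_bb
        if n == 0:
            n_empty += 1
            continue
        expected = np.array([0.25, 0.5, 0.25]) * n
        b.chi2, b.p_value = (
            float(x) for x in stats.chisquare(list(b.counts), expected)
        )
        if b.p_value > alpha:
            retained.append(b)
        else:
            n_distorted += 1
    report = {
        "input": len(bins),
        "retained": len(retained),
        "discarded_distorted": n_distorted,
        "discarded_all_missing": n_empty,
        "alpha": alpha,
    }
    return retained, report


def two_locus_probs(r: float) -> np.ndarray:
    """Joint F2 genotype probabilities for two loci, shape (3, 3).

    Indices are P2-haplotype dosage at each locus; built from the four
    gamete haplotypes with recombination fraction ``r``.
    """
    gametes = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2, (0, 1): r / 2, (1, 0): r / 2}
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in gametes.items():
        for (a2, b2), p2 in gametes.items():
            probs[a1 + a2, b1 + b2] += p1 * p2
    return probs


# recombinant gametes per two-locus genotype class; the double het (1,1)
# is ambiguous (0 or 2) and handled in expectation during EM
_REC_COUNT = np.array([[0, 1, 2], [1, -1, 1], [2, 1, 0]], dtype=float)


def estimate_rf(
    vec_a: np.ndarray, vec_b: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> PairLinkage:
    """Maximum-likelihood recombination fraction between two bin vectors.

    EM over recombinant-gamete counts for F2 codominant data: all nine
    two-locus classes have a known recombinant count except the double
    heterozygote, whose two phases are weighted by their relative
    likelihood.  LOD is against the unlinked (r = 0.5) null.

    Pairs with fewer than two co-observed progeny are flagged
    uninformative.
    """
    mask = (vec_a <= SYM_BB) & (vec_b <= SYM_BB)
    n_co = int(mask.sum())
    if n_co < 2:
        return PairLinkage(r=float("nan"), lod=0.0, n_informative=n_co, informative=False)
    counts = np.zeros((3, 3))
    np.add.at(counts, (vec_a[mask].astype(int), vec_b[mask].astype(int)), 1.0)
    fixed_rec = float((counts * np.where(_REC_COUNT >= 0, _REC_COUNT, 0.0)).sum())
    n_hh = float(counts[1, 1])
    total_gametes = 2.0 * n_co

    r = 0.25
    for _ in range(max_iter):
        if n_hh:
            w2 = r * r / ((1 - r) ** 2 + r * r)  # P(2 recombinant gametes | double het)
            exp_rec = fixed_rec + 2.0 * n_hh * w2
        else:
            exp_rec = fixed_rec
        r_new = min(exp_rec / total_gametes, 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(counts > 0, np.log10(np.clip(two_locus_probs(r), 1e-300, None)), 0.0)
        logp0 = np.where(counts > 0, np.log10(two_locus_probs(0.5)), 0.0)
    lod = float((counts * (logp - logp0)).sum())
    return PairLinkage(r=float(r), lod=max(lod, 0.0), n_informative=n_co)


def pairwise_linkages(bins: list[Bin]) -> dict[tuple[int, int], PairLinkage]:
    """All-pairs two-point linkage, keyed by sorted (bin_id, bin_id)."""
    out: dict[tuple[int, int], PairLinkage] = {}
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            out[(bins[i].bin_id, bins[j].bin_id)] = estimate_rf(
                bins[i].vector, bins[j].vector
            )
    return out


def _get_linkage(
    linkages: dict[tuple[int, int], PairLinkage], a: int, b: int
) -> PairLinkage | None:
    return linkages.get((a, b) if a < b else (b, a))


def group_bins(
    bins: list[Bin],
    linkages: dict[tuple[int, int], PairLinkage],
    min_lod: float = 8.0,
    max_rf: float = 0.35,
    min_group_size: int = 10,
) -> tuple[list[list[int]], list[list[int]]]:
    """Partition bins into linkage groups.

    Groups are connected components of the graph with an edge wherever
    LOD >= ``min_lod`` AND r <= ``max_rf`` (both thresholds inclusive).
    Groups with <= ``min_group_size`` bins are discarded and returned
    separately.
    """
    graph = nx.Graph()
    graph.add_nodes_from(b.bin_id for b in bins)
    for (a, b), link in linkages.items():
        if link.informative and link.lod >= min_lod and link.r <= max_rf:
            graph.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    kept = [c for c in components if len(c) > min_group_size]
    discarded = [c for c in components if len(c) <= min_group_size]
    return kept, discarded


# -- ordering ----------------------------------------------------------------


class _OrderScorer:
    """Weighted least-squares stress of an ordering.

    S = sum over informative pairs (LOD >= lod_floor) of
    w_ij * (D_ij - d_ij)^2 where D_ij is the map distance implied by the
    order (summed adjacent Kosambi distances) and d_ij the two-point
    Kosambi distance.
    """

    def __init__(self, members, linkages, lod_floor):
        self.members = list(members)
        self.index = {b: k for k, b in enumerate(self.members)}
        n = len(self.members)
        self.adj_d = np.full((n, n), kosambi(MAX_RF))
        ii, jj, dd, ww = [], [], [], []
        for a in range(n):
            for b in range(a + 1, n):
                link = _get_linkage(linkages, self.members[a], self.members[b])
                if link is None or not link.informative or np.isnan(link.r):
                    continue
                d = kosambi(min(link.r, MAX_RF))
                self.adj_d[a, b] = self.adj_d[b, a] = d
                if link.lod >= lod_floor:
                    ii.append(a)
                    jj.append(b)
                    dd.append(d)
                    ww.append(link.lod)
        self.ii = np.array(ii, dtype=int)
        self.jj = np.array(jj, dtype=int)
        self.dd = np.array(dd)
        self.ww = np.array(ww)

    def positions(self, order: list[int]) -> np.ndarray:
        idx = np.fromiter((self.index[b] for b in order), dtype=int)
        steps = self.adj_d[idx[:-1], idx[1:]] if len(idx) > 1 else np.empty(0)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def score(self, order: list[int]) -> float:
        """Stress of a (possibly partial) order; pairs with an absent
        endpoint are ignored."""
        if len(self.ii) == 0:
            return 0.0
        pos = self.positions(order)
        idx = np.fromiter((self.index[b] for b in order), dtype=int)
        pos_of = np.zeros(len(self.members))
        present = np.zeros(len(self.members), dtype=bool)
        pos_of[idx] = pos
        present[idx] = True
        use = present[self.ii] & present[self.jj]
        resid = np.abs(pos_of[self.ii[use]] - pos_of[self.jj[use]]) - self.dd[use]
        return float((self.ww[use] * resid * resid).sum())


def _informative_components(members, linkages, lod_floor):
    g = nx.Graph()
    g.add_nodes_from(members)
    for a in members:
        for b in members:
            if a < b:
                link = _get_linkage(linkages, a, b)
                if link is not None and link.informative and link.lod >= lod_floor:
                    g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g)]


def _order_component(members, scorer: _OrderScorer) -> list[int]:
    """Greedy best-position insertion, then window-3 ripple and 2-opt."""
    weight_sum = {b: 0.0 for b in members}
    for i, j, w in zip(scorer.ii, scorer.jj, scorer.ww):
        a, b = scorer.members[i], scorer.members[j]
        if a in weight_sum:
            weight_sum[a] += w
        if b in weight_sum:
            weight_sum[b] += w
    queue = sorted(members, key=lambda b: (-weight_sum[b], b))
    order = [queue.pop(0)]
    for b in queue:
        best = None
        for slot in range(len(order) + 1):
            cand = order[:slot] + [b] + order[slot:]
            s = scorer.score(cand)
            if best is None or s < best[0] - 1e-12:
                best = (s, cand)
        order = best[1]

    improved = True
    while improved:
        improved = False
        current = scorer.score(order)
        # window-3 ripple
        for start in range(len(order) - 2):
            window = order[start : start + 3]
            for perm in permutations(window):
                if list(perm) == window:
                    continue
                cand = order[:start] + list(perm) + order[start + 3 :]
                s = scorer.score(cand)
                if s < current - 1e-12:
                    order, current, improved = cand, s, True
        # 2-opt segment reversal
        for i in range(len(order) - 1):
            for j in range(i + 2, len(order) + 1):
                cand = order[:i] + order[i:j][::-1] + order[j:]
                s = scorer.score(cand)
                if s < current - 1e-12:
                    order, current, improved = cand, s, True
    return _canonical(order)


def _canonical(order: list[int]) -> list[int]:
    # deterministic orientation: smaller endpoint id first
    if len(order) > 1 and order[-1] < order[0]:
        return order[::-1]
    return order


def order_bins(
    members: list[int],
    linkages: dict[tuple[int, int], PairLinkage],
    lod_floor: float = 3.0,
) -> tuple[list[int], np.ndarray]:
    """Order one linkage group's bins and assign cumulative cM positions.

    Minimizes the weighted least-squares stress over pairs with
    LOD >= ``lod_floor``; if the informative subgraph is disconnected the
    components are ordered independently and concatenated with a warning.
    Returns (ordered bin ids, positions in cM).
    """
    if len(members) < 2:
        return list(members), np.zeros(len(members))
    scorer = _OrderScorer(members, linkages, lod_floor)
    comps = _informative_components(members, linkages, lod_floor)
    if len(comps) > 1:
        warnings.warn(
            f"ordering subgraph disconnected ({len(comps)} components); "
            "components ordered independently and concatenated"
        )
    order: list[int] = []
    for comp in comps:
        order.extend(_order_component(comp, scorer) if len(comp) > 1 else comp)
    return order, scorer.positions(order)


def build_map(
    bins: list[Bin],
    linkages: dict[tuple[int, int], PairLinkage] | None = None,
    min_lod: float = 8.0,
    max_rf: float = 0.35,
    min_group_size: int = 10,
    ordering_lod: float = 3.0,
) -> GeneticMap:
    """Group, order and position bins into a :class:`GeneticMap`.

    Linkage groups are numbered by descending marker count (the source
    study numbered them arbitrarily, which is not reproducible).
    """
    if linkages is None:
        linkages = pairwise_linkages(bins)
    by_id = {b.bin_id: b for b in bins}
    kept, discarded = group_bins(bins, linkages, min_lod, max_rf, min_group_size)
    groups = []
    for members in kept:
        order, positions = order_bins(members, linkages, ordering_lod)
        groups.append((order, positions))
    groups.sort(key=lambda g: (-sum(by_id[b].n_markers for b in g[0]), g[0][0]))
    lgs = [
        LinkageGroup(lg_id=k + 1, bin_ids=order, positions_cm=positions)
        for k, (order, positions) in enumerate(groups)
    ]
    return GeneticMap(groups=lgs, bins=bins, discarded_groups=discarded)


def average_interval(length_cm: float, count: int) -> float:
    """Mean interval = length / count, to 2 decimals (division by count,
    not count - 1, reproducing the published table arithmetic)."""
    return round(length_cm / count, 2) if count else 0.0


def map_statistics(gmap: GeneticMap, gap_threshold_cm: float = 5.0) -> pd.DataFrame:
    """Per-LG summary table: bin/marker counts, length, mean intervals, gaps.

    A gap is an adjacent-bin interval strictly greater than
    ``gap_threshold_cm``.  A totals row is appended.
    """
    by_id = {b.bin_id: b for b in gmap.bins}
    rows = []
    for lg in gmap.groups:
        n_bins = len(lg.bin_ids)
        n_markers = sum(by_id[b].n_markers for b in lg.bin_ids)
        length = round(lg.length_cm, 2)
        gaps = int((np.diff(lg.positions_cm) > gap_threshold_cm).sum())
        rows.append(
            {
                "lg": f"LG{lg.lg_id}",
                "bins": n_bins,
                "markers": n_markers,
                "length_cm": length,
                "avg_bin_interval_cm": average_interval(length, n_bins),
                "avg_marker_interval_cm": average_interval(length, n_markers),
                "gaps_gt_threshold": gaps,
            }
        )
    total_bins = sum(r["bins"] for r in rows)
    total_markers = sum(r["markers"] for r in rows)
    total_length = round(sum(r["length_cm"] for r in rows), 2)
    rows.append(
        {
            "lg": "Total",
            "bins": total_bins,
            "markers": total_markers,
            "length_cm": total_length,
            "avg_bin_interval_cm": average_interval(total_length, total_bins),
            "avg_marker_interval_cm": average_interval(total_length, total_markers),
            "gaps_gt_threshold": sum(r["gaps_gt_threshold"] for r in rows),
        }
    )
    return pd.DataFrame(rows)


def write_map(path, gmap: GeneticMap) -> None:
    """Export the map as TSV: LG, bin id, position cM, member locus count."""
    by_id = {b.bin_id: b for b in gmap.bins}
    rows = []
    for lg in gmap.groups:
        for b_id, pos in zip(lg.bin_ids, lg.positions_cm):
            b = by_id[b_id]
            rows.append(
                {
                    "lg": lg.lg_id,
                    "bin_id": b_id,
                    "position_cm": round(float(pos), 4),
                    "scaffold": b.scaffold,
                    "start_pos": b.start_pos,
                    "end_pos": b.end_pos,
                    "n_markers": b.n_markers,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
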