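"""NeighborNet circular split networks from binary marker profiles.

Pipeline: uncorrected-P distances between accession profiles → an
agglomerative NeighborNet circular ordering (neighbor-joining-style
cluster selection, node-level selection within the chosen clusters, and
the 3-to-2 node reduction with 2/3–1/3 averaging) → split weights by
nonnegative least squares over all n(n-1)/2 splits compatible with the
circular ordering → locus bootstrap for split supports.

Only split computation is handled here; drawing the planar network is
left to external viewers via the NEXUS SPLITS interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform

from .marker_data import MarkerMatrix

__all__ = [
    "DistanceMatrix",
    "Split",
    "SplitNetwork",
    "uncorrected_p_distance",
    "neighbor_net",
    "neighbor_net_ordering",
    "circular_split_weights",
    "bootstrap_confidence_network",
    "write_splits_nexus",
    "read_splits_nexus",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with labelled taxa."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if (v < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Split:
    """A taxon bipartition with a weight and optional bootstrap support.

    ``side`` holds the part not containing the first taxon in the cycle,
    as a frozenset of labels; the complement is implicit.
    """

    side: frozenset[str]
    weight: float
    support: float | None = None


@dataclass(frozen=True)
class SplitNetwork:
    """Circular taxon ordering plus weighted (optionally supported) splits."""

    cycle: tuple[str, ...]
    splits: tuple[Split, ...]

    def __post_init__(self) -> None:
        pos = {t: i for i, t in enumerate(self.cycle)}
        for sp in self.splits:
            if sp.weight < 0:
                raise ValueError("split weights must be nonnegative")
            if sp.support is not None and not 0 <= sp.support <= 1:
                raise ValueError("supports must lie in [0, 1]")
            if not sp.side or len(sp.side) >= len(self.cycle):
                raise ValueError("split sides must be proper non-empty subsets")
            if not _is_circular(sp.side, pos, len(self.cycle)):
                raise ValueError(f"split {sorted(sp.side)} not circular in cycle")

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        full = frozenset(self.cycle)
        return {frozenset({sp.side, full - sp.side}) for sp in self.splits}

    def fitted_distances(self) -> DistanceMatrix:
        """Pairwise distances implied by the split system (sum of weights
        of splits separating each pair)."""
        n = len(self.cycle)
        idx = {t: i for i, t in enumerate(self.cycle)}
        d = np.zeros((n, n))
        for sp in self.splits:
            mask = np.zeros(n, dtype=bool)
            for t in sp.side:
                mask[idx[t]] = True
            sep = mask[:, None] != mask[None, :]
            d[sep] += sp.weight
        return DistanceMatrix(labels=self.cycle, values=d)


def _is_circular(side: frozenset[str], pos: dict[str, int], n: int) -> bool:
    """A split is circular iff one side is a contiguous arc of the cycle."""
    idxs = sorted(pos[t] for t in side)
    contiguous = idxs[-1] - idxs[0] + 1 == len(idxs)
    if contiguous:
        return True
    comp = sorted(i for i in range(n) if i not in set(idxs))
    return comp[-1] - comp[0] + 1 == len(comp)


def uncorrected_p_distance(m: MarkerMatrix) -> DistanceMatrix:
    """Proportion of loci at which two accession profiles differ."""
    if m.n_loci == 0:
        raise ValueError("no loci")
    profiles = m.calls.T.astype(float)
    d = squareform(pdist(profiles, metric="hamming"))
    return DistanceMatrix(labels=m.accession_ids, values=d)


# ---------------------------------------------------------------------------
# NeighborNet circular ordering (agglomerative, with 3->2 node reduction)


def _reduce_three(d: np.ndarray, x: int, y: int, z: int) -> None:
    """Replace the chain nodes (x, y, z) by two nodes stored at x and z.

    The new nodes average the old distances with weights 2/3 on the outer
    node and 1/3 on the middle one; their mutual distance is the mean of
    the three pairwise distances.
    """
    u = 2 / 3 * d[x, :] + d[y, :] / 3
    v = 2 / 3 * d[z, :] + d[y, :] / 3
    uv = (d[x, y] + d[x, z] + d[y, z]) / 3
    d[x, :] = u
    d[:, x] = u
    d[z, :] = v
    d[:, z] = v
    d[y, :] = 0.0
    d[:, y] = 0.0
    d[x, z] = d[z, x] = uv
    d[x, x] = d[z, z] = 0.0


def _cluster_means(d: np.ndarray, clusters: list[list[int]]) -> np.ndarray:
    m = len(clusters)
    dm = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dm[i, j] = dm[j, i] = d[np.ix_(clusters[i], clusters[j])].mean()
    return dm


def neighbor_net_ordering(d: DistanceMatrix) -> tuple[str, ...]:
    """Circular taxon ordering by the agglomerative NeighborNet process.

    Clusters are chains holding one or two active representative nodes.
    Each iteration picks the cluster pair with the minimal NJ-style
    Q-criterion on cluster-averaged distances, then the representative
    pair with the minimal criterion treating the two clusters' nodes as
    singletons alongside the remaining clusters, links them, and reduces
    the merged chain back to two representatives.  Ties break at the
    lowest index, making the ordering deterministic.
    """
    n = d.n
    if n <= 3:
        return d.labels
    dist = d.values.copy()
    clusters: list[list[int]] = [[i] for i in range(n)]     # representative nodes
    orders: list[list[int]] = [[i] for i in range(n)]       # original taxa, chain order

    while len(clusters) > 1:
        m = len(clusters)
        dm = _cluster_means(dist, clusters)
        if m > 2:
            r = dm.sum(axis=1) / (m - 2)
            q = dm - r[:, None] - r[None, :]
            np.fill_diagonal(q, np.inf)
            e1, e2 = np.unravel_index(np.argmin(q), q.shape)
            if e1 > e2:
                e1, e2 = e2, e1
        else:
            e1, e2 = 0, 1
        c1, c2 = clusters[e1], clusters[e2]
        n1, n2 = len(c1), len(c2)
        others = [clusters[i] for i in range(m) if i not in (e1, e2)]

        if n1 == 1 and n2 == 1:
            new_nodes = c1 + c2
            new_order = orders[e1] + orders[e2]
        else:
            nodes = c1 + c2
            m_hat = len(nodes) + len(others)
            rr = np.zeros(len(nodes))
            for i, x in enumerate(nodes):
                tot = sum(dist[x, yy] for j, yy in enumerate(nodes) if j != i)
                tot += sum(dist[x, c].mean() for c in (np.array(c) for c in others))
                rr[i] = tot / (m_hat - 2) if m_hat > 2 else tot
            sub = dist[np.ix_(nodes, nodes)] - rr[:, None] - rr[None, :]
            pair = sub[:n1, n1:]
            bi, bj = np.unravel_index(np.argmin(pair), pair.shape)
            x, y = c1[bi], c2[bj]
            # orient the chains so ... a - x | y - b ... and reduce
            if n1 == 2 and n2 == 1:
                a = c1[1 - bi]
                _reduce_three(dist, a, x, y)
                new_nodes = [a, y]
                new_order = (orders[e1] if bi == 1 else orders[e1][::-1]) + orders[e2]
            elif n1 == 1 and n2 == 2:
                b = c2[1 - bj]
                _reduce_three(dist, x, y, b)
                new_nodes = [x, b]
                new_order = orders[e1] + (orders[e2] if bj == 0 else orders[e2][::-1])
            else:  # 2 and 2: reduce twice, 4 nodes -> 2
                a, b = c1[1 - bi], c2[1 - bj]
                _reduce_three(dist, a, x, y)
                _reduce_three(dist, a, y, b)
                new_nodes = [a, b]
                left = orders[e1] if bi == 1 else orders[e1][::-1]
                right = orders[e2] if bj == 0 else orders[e2][::-1]
                new_order = left + right
        clusters[e1] = new_nodes
        orders[e1] = new_order
        del clusters[e2]
        del orders[e2]

    return tuple(d.labels[i] for i in orders[0])


def _circular_split_sides(cycle: tuple[str, ...]) -> list[frozenset[str]]:
    """All n(n-1)/2 splits whose sides are contiguous arcs of the cycle.

    Arcs never containing the first taxon parameterize each split once.
    """
    n = len(cycle)
    sides = []
    for i in range(1, n):
        for j in range(i, n):
            sides.append(frozenset(cycle[i:j + 1]))
    return sides


def circular_split_weights(
    d: DistanceMatrix, cycle: tuple[str, ...], keep_zero: bool = False,
    min_weight: float = 1e-10,
) -> tuple[Split, ...]:
    """Nonnegative least-squares split weights for a fixed circular ordering."""
    sides = _circular_split_sides(cycle)
    pos = {t: i for i, t in enumerate(cycle)}
    n = len(cycle)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    design = np.zeros((len(pairs), len(sides)))
    for s_idx, side in enumerate(sides):
        mask = np.zeros(n, dtype=bool)
        for t in side:
            mask[pos[t]] = True
        for p_idx, (i, j) in enumerate(pairs):
            if mask[i] != mask[j]:
                design[p_idx, s_idx] = 1.0
    order = [d.labels.index(t) for t in cycle]
    target = np.array([d.values[order[i], order[j]] for i, j in pairs])
    weights, _ = nnls(design, target)
    splits = []
    for side, w in zip(sides, weights):
        if keep_zero or w > min_weight:
            splits.append(Split(side=side, weight=float(w)))
    return tuple(splits)


def neighbor_net(d: DistanceMatrix) -> SplitNetwork:
    """Full NeighborNet: circular ordering plus NNLS split weights.

    For three taxa the star decomposition is exact and computed in closed
    form; for two, the single split carries the pairwise distance.
    """
    if d.n < 2:
        raise ValueError("need at least 2 taxa")
    if d.n == 2:
        a, b = d.labels
        w = d.values[0, 1]
        splits = (Split(side=frozenset({b}), weight=float(w)),) if w > 0 else ()
        return SplitNetwork(cycle=d.labels, splits=splits)
    if d.n == 3:
        v = d.values
        splits = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            w = (v[i, j] + v[i, k] - v[j, k]) / 2
            if w > 1e-10:
                splits.append(Split(side=frozenset({d.labels[i]}), weight=float(w)))
        return SplitNetwork(cycle=d.labels, splits=tuple(splits))
    cycle = neighbor_net_ordering(d)
    return SplitNetwork(cycle=cycle, splits=circular_split_weights(d, cycle))


def bootstrap_confidence_network(
    m: MarkerMatrix, n_boot: int = 1000, threshold: float = 0.95,
    seed: int | None = None,
) -> tuple[SplitNetwork, SplitNetwork]:
    """Locus bootstrap supports and the support-filtered network.

    Loci are resampled with replacement ``n_boot`` times; a split's
    support is the fraction of replicate networks containing the same
    bipartition.  Returns the full network annotated with supports and
    the filtered network keeping splits with support >= ``threshold``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = neighbor_net(uncorrected_p_distance(m))
    full = frozenset(base.cycle)
    counts = {frozenset({sp.side, full - sp.side}): 0 for sp in base.splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, m.n_loci, size=m.n_loci)
        rep = MarkerMatrix(
            te_family=m.te_family,
            locus_ids=tuple(f"b{i}" for i in range(m.n_loci)),
            accession_ids=m.accession_ids,
            calls=m.calls[idx, :],
        )
        rep_net = neighbor_net(uncorrected_p_distance(rep))
        rep_bips = rep_net.bipartitions()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    annotated = SplitNetwork(
        cycle=base.cycle,
        splits=tuple(
            replace(sp, support=counts[frozenset({sp.side, full - sp.side})] / n_boot)
            for sp in base.splits
        ),
    )
    filtered = SplitNetwork(
        cycle=annotated.cycle,
        splits=tuple(sp for sp in annotated.splits if sp.support >= threshold),
    )
    return annotated, filtered


# ---------------------------------------------------------------------------
# NEXUS SPLITS interchange (SplitsTree-compatible)


def write_splits_nexus(net: SplitNetwork, path: str | Path) -> None:
    """Write TAXA + SPLITS blocks loadable by split-network viewers."""
    path = Path(path)
    n = len(net.cycle)
    has_conf = any(sp.support is not None for sp in net.splits)
    idx = {t: i + 1 for i, t in enumerate(net.cycle)}
    with path.open("w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={n};\n    TAXLABELS\n")
        for t in net.cycle:
            fh.write(f"        '{t}'\n")
        fh.write("    ;\nEND;\n\nBEGIN SPLITS;\n")
        fh.write(f"    DIMENSIONS NTAX={n} NSPLITS={len(net.splits)};\n")
        conf = "CONFIDENCES=YES " if has_conf else ""
        fh.write(f"    FORMAT LABELS=NO WEIGHTS=YES {conf};\n")
        fh.write("    CYCLE " + " ".join(str(i + 1) for i in range(n)) + ";\n")
        fh.write("    MATRIX\n")
        for sp in net.splits:
            members = " ".join(str(idx[t]) for t in sorted(sp.side, key=lambda t: idx[t]))
            if has_conf:
                support = sp.support if sp.support is not None else 0.0
                fh.write(f"        {sp.weight:.10g} {support:.10g} {members},\n")
            else:
                fh.write(f"        {sp.weight:.10g} {members},\n")
        fh.write("    ;\nEND;\n")


def read_splits_nexus(path: str | Path) -> SplitNetwork:
    """Reparse a file produced by :func:`write_splits_nexus`."""
    path = Path(path)
    taxa: list[str] = []
    splits: list[Split] = []
    has_conf = False
    section = None
    in_matrix = in_taxlabels = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        upper = line.upper()
        if upper.startswith("BEGIN TAXA"):
            section = "taxa"
        elif upper.startswith("BEGIN SPLITS"):
            section = "splits"
        elif upper.startswith("END"):
            section = None
            in_matrix = in_taxlabels = False
        elif section == "taxa":
            if upper.startswith("TAXLABELS"):
                in_taxlabels = True
            elif in_taxlabels:
                if line == ";":
                    in_taxlabels = False
                else:
                    taxa.append(line.strip("'"))
        elif section == "splits":
            if upper.startswith("FORMAT"):
                has_conf = "CONFIDENCES=YES" in upper
            elif upper.startswith("MATRIX"):
                in_matrix = True
            elif in_matrix:
                if line == ";":
                    in_matrix = False
                    continue
                fields = line.rstrip(",").split()
                weight = float(fields[0])
                if has_conf:
                    support: float | None = float(fields[1])
                    members = fields[2:]
                else:
                    support = None
                    members = fields[1:]
                side = frozenset(taxa[int(i) - 1] for i in members)
                splits.append(Split(side=side, weight=weight, support=support))
    return SplitNetwork(cycle=tuple(taxa), splits=tuple(splits))
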