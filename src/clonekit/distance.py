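"""Pairwise p-distances over diploidized genotypes and sample partitioning.

The p-distance between two samples is the proportion of differing
allele-dosage units over the loci where both calls are present (pairwise
deletion).  Per locus the unordered pairs contribute 0 (identical), 1 (one
shared allele) or 2 (no shared allele) units, with denominator 2 x shared
loci — this reduces to the haploid p-distance when both samples are
homozygous everywhere.  Pairs sharing no loci have an undefined (NaN)
distance and are reported, never silently zeroed.

Partitioning groups samples whose distance does not exceed ``1 - cutoff``
(single linkage by default), reproducing the reduced-data-set construction
used before within-group clone analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparison counts.

    ``d[i, j]`` is NaN when samples i and j share no called loci;
    ``n_compared[i, j]`` is the number of loci entering the comparison.
    """

    sample_ids: list[str]
    d: np.ndarray
    n_compared: np.ndarray

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.d[i, j]):
                    out.append((self.sample_ids[i], self.sample_ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def filter_loci_by_missingness(
    m: GenotypeMatrix, max_missing_frac: float
) -> GenotypeMatrix:
    """Keep loci whose missing fraction across samples is <= the threshold
    (boundary inclusive); locus order is preserved."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValidationError("max_missing_frac must be within [0, 1]")
    missing_frac = m.missing_mask().mean(axis=0)
    keep = np.flatnonzero(missing_frac <= max_missing_frac + 1e-12)
    return m.select_loci(keep)


def p_distance_matrix(m: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of missing calls."""
    if m.n_samples < 2:
        raise ValidationError("need at least two samples for a distance matrix")
    a = m.calls[:, :, 0].astype(np.int32)
    b = m.calls[:, :, 1].astype(np.int32)
    present = ~m.missing_mask()
    n = m.n_samples
    d = np.zeros((n, n))
    n_comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            n_shared = int(shared.sum())
            n_comp[i, j] = n_comp[j, i] = n_shared
            if n_shared == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            ai, a2i, aj, a2j = a[i][shared], b[i][shared], a[j][shared], b[j][shared]
            same_pair = (ai == aj) & (a2i == a2j)
            any_shared = (ai == aj) | (ai == a2j) | (a2i == aj) | (a2i == a2j)
            units = np.where(same_pair, 0, np.where(any_shared, 1, 2))
            dist = units.sum() / (2.0 * n_shared)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(m.sample_ids), d, n_comp)


def partition_samples(
    dm: DistanceMatrix, similarity_cutoff: float, method: str = "single"
) -> list[list[str]]:
    """Partition samples into groups of overall similarity >= cutoff.

    ``method='single'`` takes connected components of the graph whose edges
    join pairs with distance <= 1 - cutoff; ``method='complete'`` uses
    complete-linkage agglomeration cut at the same height.  Undefined
    (NaN) distances are treated as above threshold.  Groups are returned
    largest first, ties broken by their lexicographically smallest member;
    members are sorted within each group.
    """
    if not 0.0 <= similarity_cutoff < 1.0:
        raise ValidationError("similarity_cutoff must be in [0, 1)")
    threshold = 1.0 - similarity_cutoff
    d = np.where(np.isnan(dm.d), 9.0, dm.d)
    n = len(dm.sample_ids)
    if method == "single":
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] <= threshold:
                    graph.add_edge(i, j)
        components = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "complete":
        if n == 1:
            components = [[0]]
        else:
            condensed = squareform(d, checks=False)
            labels = fcluster(linkage(condensed, method="complete"), t=threshold,
                              criterion="distance")
            components = [
                sorted(np.flatnonzero(labels == lab).tolist())
                for lab in np.unique(labels)
            ]
    else:
        raise ValidationError(f"unknown linkage method {method!r}")
    groups = [sorted(dm.sample_ids[i] for i in comp) for comp in components]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def count_parsimony_informative(m: GenotypeMatrix) -> int:
    """Number of loci with at least two alleles each carried (in any dosage)
    by at least two samples."""
    count = 0
    present = ~m.missing_mask()
    for j in range(m.n_loci):
        carriers: dict[int, int] = {}
        for i in np.flatnonzero(present[:, j]):
            for allele in set(m.calls[i, j].tolist()):
                carriers[allele] = carriers.get(allele, 0) + 1
        if sum(1 for c in carriers.values() if c >= 2) >= 2:
            count += 1
    return count
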