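"""Heterozygous-locus similarity, threshold calibration and clone assignment.

The core statistic: for the ordered direction A->B, take every locus where A
is heterozygous and B has any call, and record the percentage at which B
carries the *identical* unordered genotype.  The symmetric similarity of a
pair is the mean of its two directional percentages.  Clone mates (and
duplicate libraries of one tissue sample) score near 100 %; sexually
produced relatives — even full sibs — score far lower, because each meiosis
reshuffles the heterozygous loci.  A threshold through the empty interval
between those two regimes separates clones from non-clones; duplicate
libraries pin the technical ceiling and must always sit above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .io import GenotypeMatrix

DEFAULT_THRESHOLD_PERCENT = 85.0


@dataclass(frozen=True)
class HetSimilarity:
    """Similarity of one unordered sample pair.

    ``sim_percent`` is the mean of the defined directional percentages and is
    None when neither sample has a comparable heterozygous locus
    (an incomparable pair).  ``n_het_compared`` counts loci entering either
    direction; pairs under ``min_overlap`` are flagged unreliable but still
    reported.
    """

    sample_a: str
    sample_b: str
    sim_percent: float | None
    n_het_compared: int
    a_to_b: float | None
    b_to_a: float | None
    reliable: bool


class SimilarityTable:
    """All pairwise heterozygous-locus similarities within a data set."""

    def __init__(self, frame: pd.DataFrame, min_overlap: int):
        self.frame = frame
        self.min_overlap = min_overlap

    def sample_ids(self) -> list[str]:
        return sorted(set(self.frame["sample_a"]) | set(self.frame["sample_b"]))

    def defined(self) -> pd.DataFrame:
        return self.frame[self.frame["sim_percent"].notna()]

    def pair(self, a: str, b: str) -> pd.Series:
        a, b = sorted((a, b))
        rows = self.frame[(self.frame["sample_a"] == a) & (self.frame["sample_b"] == b)]
        if rows.empty:
            raise KeyError(f"pair ({a}, {b}) not in similarity table")
        return rows.iloc[0]

    def sorted_values(self) -> np.ndarray:
        """Defined similarity values, low to high (the diagnostic curve)."""
        return np.sort(self.defined()["sim_percent"].to_numpy())

    def write_tsv(self, path: str | Path) -> None:
        self.frame.sort_values("sim_percent").to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ThresholdCalibration:
    threshold_percent: float
    gap: tuple[float, float] | None
    used_default: bool
    duplicate_pairs_validated: bool


@dataclass
class CloneAssignment:
    """A partition of samples into clones.

    Clone ids are deterministic: the lexicographically smallest member names
    the clone.  Components held together by similarity >= threshold that
    nevertheless contain an internal below-threshold pair are kept intact but
    listed in ``transitivity_violations``.
    """

    clone_of: dict[str, str]
    clone_members: dict[str, list[str]]
    threshold_percent: float
    gap: tuple[float, float] | None = None
    duplicate_pairs_validated: bool = False
    transitivity_violations: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.clone_members)


def _directional(
    het: np.ndarray, present: np.ndarray, codes: np.ndarray, i: int, j: int
) -> tuple[float | None, int]:
    mask = het[i] & present[j]
    n = int(mask.sum())
    if n == 0:
        return None, 0
    matches = int((codes[i][mask] == codes[j][mask]).sum())
    return 100.0 * matches / n, n


def het_similarity(
    a: str, b: str, m: GenotypeMatrix, min_overlap: int = 20
) -> HetSimilarity:
    """Heterozygous-locus similarity of one sample pair (see module docstring)."""
    het = m.het_mask()
    present = ~m.missing_mask()
    codes = m.pair_codes()
    i, j = m.sample_index(a), m.sample_index(b)
    return _pair_similarity(m, het, present, codes, i, j, min_overlap)


def _pair_similarity(m, het, present, codes, i, j, min_overlap) -> HetSimilarity:
    ab, n_ab = _directional(het, present, codes, i, j)
    ba, n_ba = _directional(het, present, codes, j, i)
    union = int(((het[i] & present[j]) | (het[j] & present[i])).sum())
    defined = [v for v in (ab, ba) if v is not None]
    sim = float(np.mean(defined)) if defined else None
    sa, sb = sorted((m.sample_ids[i], m.sample_ids[j]))
    if sa != m.sample_ids[i]:
        ab, ba = ba, ab
    return HetSimilarity(
        sample_a=sa,
        sample_b=sb,
        sim_percent=sim,
        n_het_compared=union,
        a_to_b=ab,
        b_to_a=ba,
        reliable=union >= min_overlap,
    )


def pairwise_het_similarities(
    m: GenotypeMatrix, min_overlap: int = 20
) -> SimilarityTable:
    """Similarity of every unordered sample pair: n(n-1)/2 rows."""
    if m.n_samples < 2:
        raise ValidationError("need at least two samples")
    het = m.het_mask()
    present = ~m.missing_mask()
    codes = m.pair_codes()
    order = np.argsort(np.asarray(m.sample_ids, dtype=object))
    records = []
    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            records.append(_pair_similarity(m, het, present, codes, i, j, min_overlap))
    frame = pd.DataFrame(
        {
            "sample_a": [r.sample_a for r in records],
            "sample_b": [r.sample_b for r in records],
            "sim_percent": [r.sim_percent for r in records],
            "n_het_compared": [r.n_het_compared for r in records],
            "a_to_b": [r.a_to_b for r in records],
            "b_to_a": [r.b_to_a for r in records],
            "reliable": [r.reliable for r in records],
        }
    )
    return SimilarityTable(frame, min_overlap)


def calibrate_threshold(
    table: SimilarityTable,
    duplicates: Sequence[tuple[str, str]] = (),
    default_percent: float = DEFAULT_THRESHOLD_PERCENT,
    min_gap_width: float = 5.0,
) -> ThresholdCalibration:
    """Place the clone threshold in the widest empty similarity interval.

    Candidate gaps are the intervals between consecutive sorted similarity
    values whose upper end does not exceed the smallest duplicate-library
    similarity; the threshold is the midpoint of the widest gap.  Without
    duplicates, or when the widest gap is narrower than ``min_gap_width``
    percentage points, the method falls back to ``default_percent`` with a
    warning.  Every duplicate pair must exceed the returned threshold —
    a duplicate below it indicates contamination and raises
    :class:`CalibrationError`.
    """
    if len(table) == 0:
        raise ValidationError("similarity table is empty")
    dup_sims: dict[tuple[str, str], float] = {}
    for a, b in duplicates:
        row = table.pair(a, b)
        if pd.isna(row["sim_percent"]):
            raise CalibrationError(f"duplicate pair ({a}, {b}) is incomparable")
        dup_sims[(row["sample_a"], row["sample_b"])] = float(row["sim_percent"])

    threshold = default_percent
    gap = None
    used_default = True
    if dup_sims:
        min_dup = min(dup_sims.values())
        values = np.unique(table.defined()["sim_percent"].to_numpy())
        best: tuple[float, float] | None = None
        for low, high in zip(values[:-1], values[1:]):
            if high > min_dup + 1e-9:
                continue
            if best is None or (high - low) > (best[1] - best[0]) + 1e-12:
                best = (float(low), float(high))
        if best is not None and best[1] - best[0] >= min_gap_width:
            gap = best
            threshold = (best[0] + best[1]) / 2.0
            used_default = False
    if used_default:
        warnings.warn(
            f"no calibrated similarity gap of >= {min_gap_width} points below the "
            f"duplicate floor; falling back to the default threshold "
            f"({default_percent} %)",
            stacklevel=2,
        )
    low_dups = sorted(pair for pair, sim in dup_sims.items() if sim <= threshold)
    if low_dups:
        raise CalibrationError(
            f"duplicate-library pairs fall below the {threshold:.2f} % threshold: "
            f"{low_dups} — possible contamination"
        )
    return ThresholdCalibration(
        threshold_percent=float(threshold),
        gap=gap,
        used_default=used_default,
        duplicate_pairs_validated=bool(dup_sims),
    )


def assign_clones(
    table: SimilarityTable,
    threshold_percent: float,
    calibration: ThresholdCalibration | None = None,
) -> CloneAssignment:
    """Clones are connected components of the >= threshold similarity graph.

    Incomparable pairs contribute no edge.  Components containing an internal
    below-threshold pair are recorded as transitivity violations but kept.
    """
    if not 0.0 < threshold_percent < 100.0:
        raise ValidationError("threshold_percent must be in (0, 100)")
    graph = nx.Graph()
    graph.add_nodes_from(table.sample_ids())
    defined = table.defined()
    for _, row in defined.iterrows():
        if row["sim_percent"] >= threshold_percent:
            graph.add_edge(row["sample_a"], row["sample_b"])
    clone_of: dict[str, str] = {}
    clone_members: dict[str, list[str]] = {}
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        clone_id = members[0]
        clone_members[clone_id] = members
        for s in members:
            clone_of[s] = clone_id
    violations = [
        (row["sample_a"], row["sample_b"], float(row["sim_percent"]))
        for _, row in defined.iterrows()
        if row["sim_percent"] < threshold_percent
        and clone_of[row["sample_a"]] == clone_of[row["sample_b"]]
    ]
    return CloneAssignment(
        clone_of=clone_of,
        clone_members=dict(sorted(clone_members.items())),
        threshold_percent=float(threshold_percent),
        gap=calibration.gap if calibration else None,
        duplicate_pairs_validated=(
            calibration.duplicate_pairs_validated if calibration else False
        ),
        transitivity_violations=sorted(violations),
    )
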