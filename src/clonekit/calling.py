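"""Depth-to-genotype calling with minor-allele-frequency band rules.

A locus is called from its per-allele read counts.  With ``total`` the summed
depth and ``minor_frac`` the fraction of reads not carrying the most frequent
allele, the default bands are:

* ``total < 30``                        -> NO_CALL (insufficient stack depth)
* ``minor_frac <= 0.05``                -> HOM  (minor reads treated as error)
* ``0.05 < minor_frac <= 0.10``         -> DISCARDED (ambiguous band)
* ``minor_frac > 0.10``                 -> HET

The 5 % boundary is assigned to HOM and the 10 % boundary to DISCARDED; both
bands are configurable through :class:`CallParams`.  A locus with more than
two alleles individually above the heterozygote threshold is DISCARDED.

Because a diploidized matrix is agnostic to true ploidy, these calls are what
polyploid samples look like through a diploid caller: any intermediate allele
dosage surfaces as HET.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DepthTable, GenotypeMatrix


class CallState(enum.Enum):
    HOM = "HOM"
    HET = "HET"
    DISCARDED = "DISCARDED"
    NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class CallParams:
    """Thresholds for depth-based genotype calling.

    ``error_max_frac`` is the upper bound of the sequencing-error band (HOM);
    ``het_min_frac`` is the exclusive lower bound for a heterozygote call.
    The discard band is the interval between them.
    """

    min_depth: int = 30
    het_min_frac: float = 0.10
    error_max_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        if not (0.0 <= self.error_max_frac <= self.het_min_frac <= 1.0):
            raise ValidationError(
                "need 0 <= error_max_frac <= het_min_frac <= 1, got "
                f"{self.error_max_frac}, {self.het_min_frac}"
            )

    @property
    def discard_band(self) -> tuple[float, float]:
        return (self.error_max_frac, self.het_min_frac)


@dataclass(frozen=True)
class LocusCall:
    state: CallState
    alleles: tuple[int, int] | None
    total_depth: int
    minor_frac: float | None


def call_locus(depths: Mapping[int, int], params: CallParams = CallParams()) -> LocusCall:
    """Call one locus from an allele -> read-count mapping.

    Returns a :class:`LocusCall`; all-zero depth is a NO_CALL, not an error.
    Ties in allele counts are broken toward the smaller allele code so the
    call is deterministic.
    """
    if not depths:
        raise ValidationError("depths mapping is empty")
    if any(c < 0 for c in depths.values()):
        raise ValidationError("read counts must be non-negative")
    total = int(sum(depths.values()))
    if total < params.min_depth:
        return LocusCall(CallState.NO_CALL, None, total, None)
    ranked = sorted(depths.items(), key=lambda kv: (-kv[1], kv[0]))
    major_allele, major_count = ranked[0]
    minor_count = total - major_count
    minor_frac = minor_count / total
    # band comparisons on integer counts: a locus at exactly the 5 % or 10 %
    # boundary must land deterministically despite float rounding
    eps = 1e-9 * total
    n_above = sum(1 for _, c in ranked if c > params.het_min_frac * total + eps)
    if n_above > 2:
        return LocusCall(CallState.DISCARDED, None, total, minor_frac)
    if minor_count <= params.error_max_frac * total + eps:
        return LocusCall(
            CallState.HOM, (major_allele, major_allele), total, minor_frac
        )
    if minor_count <= params.het_min_frac * total + eps:
        return LocusCall(CallState.DISCARDED, None, total, minor_frac)
    second_allele = ranked[1][0]
    pair = tuple(sorted((major_allele, second_allele)))
    return LocusCall(CallState.HET, pair, total, minor_frac)


def build_genotype_matrix(
    table: DepthTable,
    params: CallParams = CallParams(),
    return_tallies: bool = False,
):
    """Vectorised application of :func:`call_locus` over a depth table.

    DISCARDED and NO_CALL both surface as missing in the resulting matrix,
    as do (sample, locus) cells absent from the table.  Sample and locus
    order is sorted, so the result is invariant to input record order.

    With ``return_tallies=True`` also returns a per-sample DataFrame of
    call-state counts (for logging).
    """
    frame = table.frame
    if frame.empty:
        raise ValidationError("depth table is empty")
    df = frame.sort_values(
        ["sample_id", "locus_id", "count", "allele"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    grp = df.groupby(["sample_id", "locus_id"], sort=True)
    df["total"] = grp["count"].transform("sum")
    df["rank"] = grp.cumcount()
    eps = 1e-9 * df["total"]
    above = df["count"] > params.het_min_frac * df["total"] + eps
    n_above = above.groupby([df["sample_id"], df["locus_id"]], sort=True).sum()

    top = df[df["rank"] == 0].set_index(["sample_id", "locus_id"])
    second = df[df["rank"] == 1].set_index(["sample_id", "locus_id"])

    cells = pd.DataFrame(index=top.index)
    cells["total"] = top["total"]
    cells["major"] = top["allele"]
    cells["major_count"] = top["count"]
    cells["second"] = second["allele"].reindex(cells.index)
    cells["n_above"] = n_above.reindex(cells.index).fillna(0)
    cells["minor_count"] = cells["total"] - cells["major_count"]

    cell_eps = 1e-9 * cells["total"]
    no_call = cells["total"] < params.min_depth
    multi = ~no_call & (cells["n_above"] > 2)
    hom = ~no_call & ~multi & (
        cells["minor_count"] <= params.error_max_frac * cells["total"] + cell_eps
    )
    disc = ~no_call & ~multi & ~hom & (
        cells["minor_count"] <= params.het_min_frac * cells["total"] + cell_eps
    )
    het = ~(no_call | multi | hom | disc)

    a = np.zeros(len(cells), dtype=np.int16)
    b = np.zeros(len(cells), dtype=np.int16)
    a[hom.values] = cells.loc[hom, "major"].astype(np.int16)
    b[hom.values] = cells.loc[hom, "major"].astype(np.int16)
    a[het.values] = cells.loc[het, "major"].astype(np.int16)
    b[het.values] = cells.loc[het, "second"].astype(np.int16)

    sample_ids = sorted(frame["sample_id"].unique().tolist())
    locus_ids = sorted(frame["locus_id"].unique().tolist())
    si = {s: i for i, s in enumerate(sample_ids)}
    li = {l: j for j, l in enumerate(locus_ids)}
    calls = np.zeros((len(sample_ids), len(locus_ids), 2), dtype=np.int16)
    rows = cells.index.get_level_values(0).map(si).to_numpy()
    cols = cells.index.get_level_values(1).map(li).to_numpy()
    calls[rows, cols, 0] = a
    calls[rows, cols, 1] = b
    matrix = GenotypeMatrix(sample_ids, locus_ids, calls)

    if not return_tallies:
        return matrix
    state = np.select(
        [no_call.values, multi.values | disc.values, hom.values],
        [CallState.NO_CALL.value, CallState.DISCARDED.value, CallState.HOM.value],
        default=CallState.HET.value,
    )
    tallies = (
        pd.DataFrame({"sample_id": cells.index.get_level_values(0), "state": state})
        .value_counts()
        .unstack(fill_value=0)
    )
    return matrix, tallies


def minor_fraction(
    depths: Mapping[int, int],
    min_total: int = 20,
    min_frac: float = 0.05,
) -> float | None:
    """Minor-allele depth fraction of a biallelic locus, or None.

    Returns None when total depth is below ``min_total``, when fewer or more
    than two alleles pass the ``min_frac`` calling cut-off, and otherwise the
    second-largest passing count divided by the sum of the two passing
    counts — the normalised pair ratio, always in (0, 0.5].
    """
    if any(c < 0 for c in depths.values()):
        raise ValidationError("read counts must be non-negative")
    total = sum(depths.values())
    if total < min_total:
        return None
    passing = sorted(
        (c for c in depths.values()
         if c > 0 and c >= min_frac * total - 1e-9 * total),
        reverse=True,
    )
    if len(passing) != 2:
        return None
    c1, c2 = passing
    return c2 / (c1 + c2)
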