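"""Readers, writers and core containers for the formats the pipeline touches.

The central container is :class:`GenotypeMatrix`, a samples x loci matrix of
*diploidized* unordered allele pairs, the shape in which Stacks-style
genotypes reach downstream analyses regardless of the true ploidy of the
organism.  Allele codes are small positive integers; code 0 marks a missing
call (genepop convention), and a genotype containing a 0 is wholly missing.

Also defined here: per-(sample, locus, allele) read-depth tables, sample
metadata records and replicate flow-cytometry (2C genome size) measurements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DialectError, FormatError, ValidationError

MISSING_ALLELE = 0

HABITS = ("solitary", "stoloniferous")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library.

    ``duplicate_group`` ties together libraries prepared independently from
    the same biological tissue sample; such pairs calibrate the technical
    error floor of the clone-similarity statistic.  ``habit`` distinguishes
    solitary herbs (no vegetative spread) from stoloniferous ones, which
    matters when clonality is interpreted as evidence of apomixis.
    """

    sample_id: str
    taxon_label: str
    locality_id: str
    duplicate_group: str | None = None
    habit: str = "solitary"
    native: bool = True
    males_recorded: bool = False

    def __post_init__(self) -> None:
        if self.habit not in HABITS:
            raise ValidationError(
                f"unknown growth habit {self.habit!r} for sample {self.sample_id!r};"
                f" expected one of {HABITS}"
            )


class GenotypeMatrix:
    """Samples x loci matrix of unordered, diploidized allele-pair calls.

    Parameters
    ----------
    sample_ids, locus_ids :
        Ordered identifiers; lengths must match the call array.
    calls :
        Integer array of shape ``(n_samples, n_loci, 2)``.  Pairs are stored
        unordered: the constructor sorts each pair so ``(a, b) == (b, a)``.
        Any pair containing allele code 0 is normalised to ``(0, 0)`` and
        treated as missing.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int16)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValidationError(f"calls must have shape (n, m, 2), got {calls.shape}")
        if calls.shape[0] != len(sample_ids) or calls.shape[1] != len(locus_ids):
            raise ValidationError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(locus_ids)} loci"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("sample_ids are not unique")
        if (calls < 0).any():
            raise ValidationError("allele codes must be non-negative")
        calls = np.sort(calls, axis=2)
        # half-calls are not supported: one zero allele blanks the whole call
        partial = calls[:, :, 0] == MISSING_ALLELE
        calls[partial] = MISSING_ALLELE
        self.sample_ids = list(sample_ids)
        self.locus_ids = list(locus_ids)
        self.calls = calls

    # -- basic shape -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    # -- masks and codes ---------------------------------------------------

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, m) array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING_ALLELE

    def het_mask(self) -> np.ndarray:
        """Boolean (n, m) array, True where the call is heterozygous."""
        return (self.calls[:, :, 0] != self.calls[:, :, 1]) & ~self.missing_mask()

    def pair_codes(self) -> np.ndarray:
        """Integer (n, m) encoding of each unordered pair (0 = missing)."""
        return self.calls[:, :, 0].astype(np.int64) * 1024 + self.calls[:, :, 1]

    # -- selection ---------------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.locus_ids, self.calls[idx])

    def select_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            self.sample_ids, [self.locus_ids[i] for i in idx], self.calls[:, idx]
        )

    def call(self, sample_id: str, locus_index: int) -> tuple[int, int] | None:
        """The unordered pair at (sample, locus), or None when missing."""
        row = self.calls[self.sample_index(sample_id), locus_index]
        if row[0] == MISSING_ALLELE:
            return None
        return (int(row[0]), int(row[1]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


@dataclass
class DepthTable:
    """Per-(sample, locus, allele) read counts, backed by a DataFrame.

    Columns: ``sample_id``, ``locus_id``, ``allele`` (int), ``count`` (int >= 0).
    The (sample, locus, allele) key is unique.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "locus_id", "allele", "count")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing_cols:
            raise ValidationError(f"depth table missing columns: {missing_cols}")
        frame = self.frame.loc[:, list(self.REQUIRED)].copy()
        for col in ("allele", "count"):
            values = frame[col]
            as_int = pd.to_numeric(values, errors="coerce")
            if as_int.isna().any() or not np.allclose(as_int, as_int.round()):
                raise ValidationError(f"column {col!r} must be integer-valued")
            frame[col] = as_int.astype(np.int64)
        if (frame["count"] < 0).any():
            bad = frame.loc[frame["count"] < 0].iloc[0]
            raise ValidationError(
                f"negative read count for ({bad.sample_id}, {bad.locus_id}, {bad.allele})"
            )
        key = ["sample_id", "locus_id", "allele"]
        dup = frame.duplicated(subset=key, keep=False)
        if dup.any():
            offending = frame.loc[dup, key].drop_duplicates().values.tolist()
            raise ValidationError(f"duplicated (sample, locus, allele) keys: {offending}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def sample_ids(self) -> list[str]:
        return sorted(self.frame["sample_id"].unique().tolist())

    def locus_ids(self) -> list[str]:
        return sorted(self.frame["locus_id"].unique().tolist())

    def depths_for(self, sample_id: str, locus_id: str) -> dict[int, int]:
        sub = self.frame[
            (self.frame["sample_id"] == sample_id) & (self.frame["locus_id"] == locus_id)
        ]
        return dict(zip(sub["allele"].tolist(), sub["count"].tolist()))

    def subset_samples(self, sample_ids: Iterable[str]) -> "DepthTable":
        wanted = set(sample_ids)
        return DepthTable(self.frame[self.frame["sample_id"].isin(wanted)].copy())

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FcmReplicates:
    """Replicate flow-cytometry 2C measurements (pg) for one plant.

    Each measurement carries the index of the day on which it was taken;
    replicate acceptance looks at day-to-day variation.
    """

    sample_id: str
    measurements: tuple[tuple[int, float], ...]  # (day, 2C value in pg)

    def __post_init__(self) -> None:
        if len(self.measurements) < 1:
            raise ValidationError(f"{self.sample_id}: at least one measurement required")

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.measurements]


# ---------------------------------------------------------------------------
# genepop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path, allele_digits: int | None = None) -> GenotypeMatrix:
    """Read a genepop genotype file into a :class:`GenotypeMatrix`.

    Accepts both header dialects: one locus name per line, or a single
    comma-separated line.  The allele-code width (2 or 3 digits) is
    auto-detected from the genotype strings unless ``allele_digits`` is given.
    ``Pop`` block structure is parsed but flattened; sample order is
    preserved.  An allele code of 00/000 marks the whole call missing.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: too short to be a genepop file")
    pop_lines = [i for i, ln in enumerate(lines) if _POP_RE.match(ln.strip())]
    if not pop_lines:
        raise FormatError(f"{path}: no 'Pop' separator found")
    first_pop = pop_lines[0]
    locus_ids: list[str] = []
    for ln in lines[1:first_pop]:
        locus_ids.extend(tok.strip() for tok in ln.split(",") if tok.strip())
    if not locus_ids:
        raise FormatError(f"{path}: no locus names before first 'Pop'")

    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, ln in enumerate(lines[first_pop:], start=first_pop + 1):
        stripped = ln.strip()
        if not stripped or _POP_RE.match(stripped):
            continue
        if "," not in stripped:
            raise FormatError(f"{path}:{lineno}: sample row lacks the ',' separator")
        name, _, geno = stripped.partition(",")
        tokens = geno.split()
        if len(tokens) != len(locus_ids):
            raise FormatError(
                f"{path}:{lineno}: expected {len(locus_ids)} genotypes, got {len(tokens)}"
            )
        sample_ids.append(name.strip())
        rows.append(tokens)
    if not rows:
        raise FormatError(f"{path}: no sample rows")

    widths = {len(tok) for row in rows for tok in row}
    if len(widths) != 1 or widths.pop() not in (4, 6):
        raise DialectError(
            f"{path}: genotype strings must be uniformly 4 (2-digit alleles) or "
            f"6 (3-digit) characters wide"
        )
    detected = len(rows[0][0]) // 2
    if allele_digits is not None and allele_digits != detected:
        raise DialectError(
            f"{path}: declared allele_digits={allele_digits} but genotypes are "
            f"{detected}-digit"
        )
    d = detected

    calls = np.zeros((len(sample_ids), len(locus_ids), 2), dtype=np.int16)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            if not tok.isdigit():
                raise FormatError(f"{path}: non-numeric genotype {tok!r} for {sample_ids[i]}")
            calls[i, j] = (int(tok[:d]), int(tok[d:]))
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def write_genepop(
    m: GenotypeMatrix,
    path: str | Path,
    allele_digits: int = 2,
    title: str = "clonekit genotype export",
) -> None:
    """Write a :class:`GenotypeMatrix` as a genepop file (one locus per line,
    a single ``Pop`` block, missing calls as 00/000)."""
    if allele_digits not in (2, 3):
        raise DialectError(f"allele_digits must be 2 or 3, got {allele_digits}")
    if int(m.calls.max(initial=0)) >= 10**allele_digits:
        raise DialectError(
            f"allele code {int(m.calls.max())} does not fit in {allele_digits} digits"
        )
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in m.locus_ids:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for i, sample in enumerate(m.sample_ids):
            tokens = [
                f"{a:0{allele_digits}d}{b:0{allele_digits}d}" for a, b in m.calls[i]
            ]
            fh.write(f"{sample} ,  " + " ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# TSV / CSV tables
# ---------------------------------------------------------------------------


def read_depth_table(path: str | Path) -> DepthTable:
    """Read a tab-separated depth table (sample_id, locus_id, allele, count)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    return DepthTable(frame)


_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


def _parse_bool(value: object, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean {value!r} in column {column!r}")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a CSV of sample metadata and validate its invariants.

    Required columns: sample_id, taxon_label, locality_id, habit, native,
    males_recorded; optional: duplicate_group (blank means none).  Duplicate
    sample ids are rejected, and libraries sharing a duplicate_group must
    carry the same taxon label.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = ["sample_id", "taxon_label", "locality_id", "habit", "native", "males_recorded"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing columns: {missing_cols}")
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id values: {dups}")
    metas = []
    for _, row in frame.iterrows():
        group = row.get("duplicate_group", "") or None
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                taxon_label=row["taxon_label"],
                locality_id=row["locality_id"],
                duplicate_group=group,
                habit=row["habit"],
                native=_parse_bool(row["native"], "native"),
                males_recorded=_parse_bool(row["males_recorded"], "males_recorded"),
            )
        )
    by_group: dict[str, set[str]] = {}
    for meta in metas:
        if meta.duplicate_group:
            by_group.setdefault(meta.duplicate_group, set()).add(meta.taxon_label)
    for group, taxa in by_group.items():
        if len(taxa) > 1:
            raise ValidationError(
                f"duplicate_group {group!r} spans multiple taxa: {sorted(taxa)}"
            )
    return metas


def write_sample_metadata(metas: Sequence[SampleMeta], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "taxon_label": [m.taxon_label for m in metas],
            "locality_id": [m.locality_id for m in metas],
            "duplicate_group": [m.duplicate_group or "" for m in metas],
            "habit": [m.habit for m in metas],
            "native": [m.native for m in metas],
            "males_recorded": [m.males_recorded for m in metas],
        }
    )
    frame.to_csv(path, index=False)


def read_fcm_replicates(path: str | Path) -> dict[str, FcmReplicates]:
    """Read replicate 2C measurements from a CSV with columns
    sample_id, day, two_c_pg; returns one record per sample."""
    frame = pd.read_csv(path)
    required = ["sample_id", "day", "two_c_pg"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"FCM table missing columns: {missing_cols}")
    out: dict[str, FcmReplicates] = {}
    for sample_id, sub in frame.groupby("sample_id", sort=True):
        measurements = tuple(
            (int(day), float(value)) for day, value in zip(sub["day"], sub["two_c_pg"])
        )
        out[str(sample_id)] = FcmReplicates(str(sample_id), measurements)
    return out


def duplicate_pairs(metas: Sequence[SampleMeta]) -> list[tuple[str, str]]:
    """All unordered sample pairs that are duplicate libraries of one tissue."""
    by_group: dict[str, list[str]] = {}
    for meta in metas:
        if meta.duplicate_group:
            by_group.setdefault(meta.duplicate_group, []).append(meta.sample_id)
    pairs = []
    for members in by_group.values():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return sorted(pairs)
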