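"""Allele-balance ploidy inference from minor-allele depth fractions.

At a heterozygous locus the minor allele is carried by d of p homologues and
is expected to draw d/p of the reads, so pooling minor-allele depth fractions
across loci produces a spectrum whose peaks sit at the allele-dosage
fractions min(d, p-d)/p: 1/2 for diploids, 1/3 for triploids, 1/4 (and 1/2)
for tetraploids, 1/5 and 2/5 for pentaploids.  Only the fraction axis is
informative for reduced-representation data — locus coverage is wildly
non-uniform, so peak *positions*, not heights, carry the ploidy signal.

Numerical note: the minor fraction is folded into (0, 0.5], which would bias
a diploid peak that sits exactly on the fold.  Peak detection therefore
mirrors every observed fraction f to 1 - f, finds maxima on the symmetric
(0, 1) histogram, and folds peak positions back, which removes the boundary
bias without affecting interior peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import NoPeakError, SpectrumError, StabilityError, ValidationError
from .io import DepthTable


@dataclass
class Spectrum:
    """Histogram of minor-allele depth fractions over (0, 0.5]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray  # the raw pooled values, kept for peak detection
    n_loci: int
    n_excluded: int
    params: dict

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass(frozen=True)
class Peak:
    position: float
    mass_frac: float


@dataclass
class PloidyCall:
    """A ploidy assignment from spectrum peaks.

    ``consistency`` is True when every peak lies within tolerance of the
    allowed fraction set {min(d, p-d)/p} for the assigned ploidy and the
    lowest peak matches 1/p; otherwise the best-fitting p is reported with
    ``consistency=False``.
    """

    ploidy: int
    peak_positions: list[float]
    peak_masses: list[float]
    consistency: bool


@dataclass
class MergeReport:
    """Peak agreement between individual library sets and their union."""

    set_peaks: list[list[Peak]]
    union_peaks: list[Peak]
    set_n_loci: list[int]
    union_n_loci: int
    stable: bool
    max_shift: float


def allowed_peak_fractions(ploidy: int) -> list[float]:
    """Allowed minor-fraction peak positions {min(d, p-d)/p : d=1..p-1}."""
    if ploidy < 2:
        raise ValidationError("ploidy must be >= 2")
    return sorted({min(d, ploidy - d) / ploidy for d in range(1, ploidy)})


def spectrum_from_fractions(
    fractions: Iterable[float],
    bin_width: float = 0.01,
    n_excluded: int = 0,
    params: dict | None = None,
) -> Spectrum:
    values = np.asarray(list(fractions), dtype=float)
    if values.size == 0:
        raise SpectrumError("no usable loci: empty minor-fraction spectrum")
    if (values <= 0).any() or (values > 0.5).any():
        raise ValidationError("minor fractions must lie in (0, 0.5]")
    n_bins = int(round(0.5 / bin_width))
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return Spectrum(
        bin_edges=edges,
        counts=counts,
        fractions=values,
        n_loci=values.size,
        n_excluded=n_excluded,
        params=params or {"bin_width": bin_width},
    )


def pooled_minor_fractions(
    table: DepthTable,
    samples: Iterable[str],
    min_total: int = 20,
    min_frac: float = 0.05,
) -> tuple[np.ndarray, int]:
    """Minor-allele depth fractions pooled over (sample, locus) cells.

    Vectorised equivalent of applying :func:`clonekit.calling.minor_fraction`
    to every cell; returns (fractions, number of excluded cells).
    """
    wanted = sorted(set(samples))
    known = set(table.frame["sample_id"].unique())
    unknown = [s for s in wanted if s not in known]
    if unknown:
        raise ValidationError(f"samples not in depth table: {unknown}")
    df = table.frame[table.frame["sample_id"].isin(wanted)]
    df = df[df["count"] > 0]
    df = df.sort_values(
        ["sample_id", "locus_id", "count", "allele"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    grp = df.groupby(["sample_id", "locus_id"], sort=False)
    total = grp["count"].transform("sum")
    passing = df["count"] >= min_frac * total - 1e-9 * total
    cells = pd.DataFrame(
        {
            "total": grp["count"].sum(),
            "n_passing": passing.groupby(
                [df["sample_id"], df["locus_id"]], sort=False
            ).sum(),
        }
    )
    rank = grp.cumcount()
    top1 = df.loc[rank == 0, "count"].to_numpy()
    top2 = np.zeros(len(cells), dtype=np.int64)
    has_second = grp.size().to_numpy() >= 2
    top2[has_second] = df.loc[rank == 1, "count"].to_numpy()
    ok = (cells["total"].to_numpy() >= min_total) & (cells["n_passing"].to_numpy() == 2)
    fractions = top2[ok] / (top1[ok] + top2[ok])
    return fractions, int((~ok).sum())


def build_spectrum(
    table: DepthTable,
    samples: Iterable[str],
    min_total: int = 20,
    min_frac: float = 0.05,
    bin_width: float = 0.01,
) -> Spectrum:
    """Pool minor-allele fractions for the given samples into a spectrum.

    Cells failing the coverage (``min_total``) or allele-calling
    (``min_frac``, exactly two passing alleles) filters are excluded and
    counted; zero usable loci raise :class:`SpectrumError`.
    """
    fractions, n_excluded = pooled_minor_fractions(table, samples, min_total, min_frac)
    if fractions.size == 0:
        raise SpectrumError("no usable loci after coverage/allele filters")
    return spectrum_from_fractions(
        fractions,
        bin_width=bin_width,
        n_excluded=n_excluded,
        params={"min_total": min_total, "min_frac": min_frac, "bin_width": bin_width},
    )


def detect_peaks(
    s: Spectrum,
    min_mass_frac: float = 0.10,
    smooth_window: int = 3,
    min_separation: float = 0.05,
    min_prominence_frac: float = 0.25,
) -> list[Peak]:
    """Find spectrum peaks: prominent smoothed maxima holding enough mass.

    The histogram is mirrored around 0.5 (see module docstring) and smoothed
    with a ``smooth_window``-bin moving average.  Local maxima qualify when
    they are at least ``min_separation`` apart (two distinct allele-dosage
    fractions are never closer than the 1/5-vs-1/4 gap of 0.05) and rise
    with a topographic prominence of at least ``min_prominence_frac`` of the
    tallest smoothed bin — which rejects noise bumps riding on the flank of
    a real peak.  Each surviving peak must hold ``min_mass_frac`` of the
    total mass within ``min_separation`` of its centre; the centre itself is
    refined by mean-shift (the mean of the raw fractions within the moving
    window), which decouples the reported position from histogram bin
    placement.  Positions are folded back into (0, 0.5]; mirror twins
    collapse onto one reported peak.  Raises :class:`NoPeakError` when
    nothing passes.
    """
    bw = s.bin_width
    n_bins = int(round(1.0 / bw))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mirrored = np.concatenate([s.fractions, 1.0 - s.fractions])
    counts, _ = np.histogram(mirrored, bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    sep_bins = max(1, int(round(min_separation / bw)))

    idxs, _ = signal.find_peaks(
        smooth,
        distance=sep_bins,
        prominence=min_prominence_frac * smooth.max(),
        # a plateau wider than the separation scale is structureless noise
        # (e.g. a uniform histogram), not a peak
        plateau_size=(None, sep_bins),
    )

    total_mass = counts.sum()
    scored = []
    for idx in idxs:
        pos = centers[idx]
        mass = 0
        for _ in range(50):  # flat-kernel mean-shift, converges in a few steps
            sel = mirrored[np.abs(mirrored - pos) <= min_separation]
            mass = sel.size
            if mass == 0:
                break
            new = float(sel.mean())
            if abs(new - pos) < 1e-9:
                break
            pos = new
        if total_mass == 0 or mass == 0 or mass / total_mass < min_mass_frac:
            continue
        scored.append((mass, pos))
    scored.sort(key=lambda t: (-t[0], t[1]))

    accepted: list[tuple[float, float]] = []  # (position folded, mass_frac)
    for mass, centroid in scored:
        pos = centroid if centroid <= 0.5 else 1.0 - centroid
        if any(abs(pos - p) < min_separation for p, _ in accepted):
            continue
        accepted.append((pos, mass / total_mass))
    if not accepted:
        raise NoPeakError(
            f"no peak retains >= {min_mass_frac:.0%} of spectrum mass within "
            f"+-{min_separation} of a prominent maximum"
        )
    accepted.sort()
    return [Peak(position=p, mass_frac=mf) for p, mf in accepted]


def infer_ploidy(
    peaks: Sequence[Peak], tolerance: float = 0.03, max_ploidy: int = 8
) -> PloidyCall:
    """Assign the smallest ploidy whose allowed fraction set explains the peaks.

    A ploidy p fits when every peak is within ``tolerance`` of some member of
    {min(d, p-d)/p} *and* the lowest peak matches 1/p — the latter anchors
    the assignment so a lone 0.25 peak reads as tetraploid, not octoploid.
    When no p in 2..max_ploidy fits, the best-effort p (smallest worst-case
    deviation) is returned with ``consistency=False``.
    """
    if not peaks:
        raise ValidationError("need at least one peak")
    positions = sorted(p.position for p in peaks)
    masses = [p.mass_frac for p in sorted(peaks, key=lambda q: q.position)]
    best_p, best_score = None, np.inf
    for p in range(2, max_ploidy + 1):
        allowed = allowed_peak_fractions(p)
        dev = max(min(abs(pos - a) for a in allowed) for pos in positions)
        anchor = abs(positions[0] - 1.0 / p)
        score = max(dev, anchor)
        if score <= tolerance:
            return PloidyCall(p, positions, masses, consistency=True)
        if score < best_score:
            best_p, best_score = p, score
    return PloidyCall(int(best_p), positions, masses, consistency=False)


def merge_stability(
    table: DepthTable,
    library_sets: Sequence[Iterable[str]],
    min_total: int = 20,
    min_frac: float = 0.05,
    bin_width: float = 0.01,
    min_mass_frac: float = 0.10,
    strict: bool = False,
) -> MergeReport:
    """Check that pooling putatively clonal library sets leaves peaks in place.

    Builds a spectrum per set and for the union; the merge is stable when
    every set shows the same number of peaks as the union, each within one
    bin width of its union counterpart.  A shifted or extra peak means the
    libraries are unlikely to be clonal (``strict=True`` raises
    :class:`StabilityError` in that case).
    """
    if len(library_sets) < 2:
        raise ValidationError("need at least two library sets")
    sets = [sorted(set(s)) for s in library_sets]
    union = sorted({s for group in sets for s in group})
    spectra = [
        build_spectrum(table, group, min_total, min_frac, bin_width) for group in sets
    ]
    union_spectrum = build_spectrum(table, union, min_total, min_frac, bin_width)
    set_peaks = [detect_peaks(sp, min_mass_frac) for sp in spectra]
    union_peaks = detect_peaks(union_spectrum, min_mass_frac)

    stable = True
    max_shift = 0.0
    for peaks in set_peaks:
        if len(peaks) != len(union_peaks):
            stable = False
            max_shift = np.inf
            continue
        for a, b in zip(peaks, union_peaks):
            shift = abs(a.position - b.position)
            max_shift = max(max_shift, shift)
            if shift > bin_width:
                stable = False
    report = MergeReport(
        set_peaks=set_peaks,
        union_peaks=union_peaks,
        set_n_loci=[sp.n_loci for sp in spectra],
        union_n_loci=union_spectrum.n_loci,
        stable=stable,
        max_shift=float(max_shift),
    )
    if strict and not stable:
        raise StabilityError(
            "peak positions shifted after merging libraries; sets are likely not clonal"
        )
    return report
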