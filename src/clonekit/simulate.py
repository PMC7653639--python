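"""Synthetic ddRAD-style data with ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage is testable without any sequencing download:

* **Taxa** diverge through independent per-locus allele frequencies, so
  between-taxon genotype distances dwarf within-taxon ones.
* **Clonal lineages** share one founder genotype across all ramets and
  duplicate libraries; only per-library noise (depth sampling, per-read
  substitution error, heterozygote-to-homozygote dropout) separates them.
* **Sexual sibships** arise by Mendelian gamete union from two diploid
  parents, so sibs share roughly half of each other's heterozygous loci —
  the contrast that clone detection exploits.
* **Polyploid allele dosage** (2x-5x founders) drives the minor-allele
  depth fractions toward d/p, the signal used for ploidy inference; locus
  depths are negative-binomially dispersed as in real reduced-representation
  libraries.
* **Diploidized emission**: whatever the true dosage, the emitted genotype
  call is a two-allele code (any intermediate dosage reads HET), mirroring
  how a diploid-assuming caller reports polyploids.  True dosage reaches the
  pipeline only through read depths.

Every draw flows from a single seeded generator, so a configuration is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    DepthTable,
    GenotypeMatrix,
    SampleMeta,
    write_genepop,
    write_sample_metadata,
)

REF_ALLELE = 1
ALT_ALLELE = 2

# Overall-similarity cutoff matched to the divergence scale of the default
# scenario: simulated taxa differ at a large fraction of loci (between-taxon
# p-distance ~0.4) while sexual sibs within a taxon sit near 0.1-0.13, so the
# least ambiguous grouping cutoff lies mid-gap.  Real data sets, where
# species-level divergence is a far smaller fraction of the genotyped loci,
# need a far higher cutoff (the pipeline default).
SCENARIO_PARTITION_SIMILARITY = 0.75


@dataclass(frozen=True)
class TaxonConfig:
    """One simulated taxon: a set of clones or a sexual sibship."""

    name: str
    ploidy: int
    n_clones: int
    ramets_per_clone: int = 1
    n_localities: int = 1
    habit: str = "solitary"
    reproduce: str = "clonal"  # "clonal" | "sexual_diploid"
    males_recorded: bool = False

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3, 4, 5):
            raise ValidationError("ploidy must be in 2..5")
        if self.reproduce not in ("clonal", "sexual_diploid"):
            raise ValidationError(f"unknown reproduce mode {self.reproduce!r}")
        if self.reproduce == "sexual_diploid" and self.ploidy != 2:
            raise ValidationError("sexual_diploid taxa must be diploid")


def _default_taxa() -> list[TaxonConfig]:
    # Shaped like the study system: a widespread uniclonal solitary triploid,
    # a single-locality sexual diploid with several stoloniferous clones, and
    # a uniclonal solitary pentaploid.
    return [
        TaxonConfig("Taxon_A_triploid", ploidy=3, n_clones=1, ramets_per_clone=12,
                    n_localities=12, habit="solitary", reproduce="clonal"),
        TaxonConfig("Taxon_B_diploid", ploidy=2, n_clones=8, ramets_per_clone=1,
                    n_localities=1, habit="stoloniferous",
                    reproduce="sexual_diploid", males_recorded=True),
        TaxonConfig("Taxon_C_pentaploid", ploidy=5, n_clones=1, ramets_per_clone=6,
                    n_localities=6, habit="solitary", reproduce="clonal"),
    ]


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the reference conditions
    used throughout the test-suite.

    ``allele_freq_prior`` may be a Beta (a, b) tuple, a fixed frequency, or a
    pre-drawn per-locus frequency vector.  ``depth_mean``/``depth_dispersion``
    parametrise a negative binomial with variance mean*(1 + dispersion*mean).
    ``genotype_error_rate`` is the per-library probability that a
    heterozygous call drops to homozygous (allelic dropout, the dominant
    reduced-representation error mode).  A seed is mandatory.
    """

    seed: int
    n_loci: int = 2000
    allele_freq_prior: tuple[float, float] | float = (0.5, 0.5)
    taxa: list[TaxonConfig] = field(default_factory=_default_taxa)
    depth_mean: float = 250.0
    depth_dispersion: float = 0.3
    seq_error_rate: float = 0.001
    genotype_error_rate: float = 0.005
    duplicate_library_rate: float = 0.15
    min_emit_depth: int = 30

    def __post_init__(self) -> None:
        for name in ("seq_error_rate", "genotype_error_rate", "duplicate_library_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated data set."""

    clone_of: dict[str, str]
    ploidy_of: dict[str, int]
    taxon_of: dict[str, str]
    founder_dosages: dict[str, list[int]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    depth_table: DepthTable
    genotypes: GenotypeMatrix
    metadata: list[SampleMeta]
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def draw_allele_freqs(
    n_loci: int,
    prior: tuple[float, float] | float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-locus alternate-allele frequencies from the configured prior."""
    if isinstance(prior, np.ndarray):
        if prior.shape != (n_loci,):
            raise ValidationError("frequency vector length must equal n_loci")
        return prior
    if isinstance(prior, tuple):
        a, b = prior
        return rng.beta(a, b, size=n_loci)
    return np.full(n_loci, float(prior))


def simulate_founder(
    p: int,
    n_loci: int,
    prior: tuple[float, float] | float | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder allele dosages: d ~ Binomial(p, q) with q per locus from the
    prior; loci at d in {0, p} are homozygous."""
    if p < 2:
        raise ValidationError("ploidy must be >= 2")
    q = draw_allele_freqs(n_loci, prior, rng)
    return rng.binomial(p, q).astype(np.int16)


def diploidize(dosages: np.ndarray, p: int) -> np.ndarray:
    """Collapse dosage 0..p to a two-allele diploid-style call: any
    intermediate dosage is (REF, ALT)."""
    out = np.empty((dosages.size, 2), dtype=np.int16)
    out[:, 0] = np.where(dosages == p, ALT_ALLELE, REF_ALLELE)
    out[:, 1] = np.where(dosages == 0, REF_ALLELE, ALT_ALLELE)
    return out


def _negbin_depths(n: int, mean: float, dispersion: float,
                   rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=n)


def simulate_library(
    dosages: np.ndarray,
    ploidy: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One sequencing library of a genotype.

    Returns ``(ref_counts, alt_counts, genotype)`` where the counts are
    per-locus read depths of the two alleles and ``genotype`` is the emitted
    diploidized call: missing (0, 0) below ``min_emit_depth``, and subject to
    heterozygote dropout at ``genotype_error_rate``.
    """
    m = dosages.size
    total = _negbin_depths(m, cfg.depth_mean, cfg.depth_dispersion, rng)
    alt_true = rng.binomial(total, dosages / ploidy)
    ref_true = total - alt_true
    e = cfg.seq_error_rate
    if e > 0:
        alt = alt_true - rng.binomial(alt_true, e) + rng.binomial(ref_true, e)
    else:
        alt = alt_true
    ref = total - alt

    genotype = diploidize(dosages, ploidy)
    het = (dosages > 0) & (dosages < ploidy)
    drop = het & (rng.random(m) < cfg.genotype_error_rate)
    keep_major = np.where(ref >= alt, REF_ALLELE, ALT_ALLELE)
    genotype[drop, 0] = keep_major[drop]
    genotype[drop, 1] = keep_major[drop]
    genotype[total < cfg.min_emit_depth] = 0
    return ref, alt, genotype


def simulate_sexual_family(
    founder_a: np.ndarray,
    founder_b: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploid offspring dosages by Mendelian gamete union (no selfing:
    one gamete from each distinct founder)."""
    for f in (founder_a, founder_b):
        if f.min() < 0 or f.max() > 2:
            raise ValidationError("founders must be diploid (dosages 0..2)")
    m = founder_a.size
    ga = rng.binomial(1, np.tile(founder_a / 2.0, (n_offspring, 1)))
    gb = rng.binomial(1, np.tile(founder_b / 2.0, (n_offspring, 1)))
    return (ga + gb).astype(np.int16)


# ---------------------------------------------------------------------------
# whole data sets
# ---------------------------------------------------------------------------


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full data set (depths, diploidized genotypes, metadata,
    truth) for the configured taxa.  Duplicate libraries share the biological
    genotype but draw depths and errors independently."""
    rng = np.random.default_rng(cfg.seed)
    locus_ids = [f"L{j:05d}" for j in range(cfg.n_loci)]

    sample_ids: list[str] = []
    metadata: list[SampleMeta] = []
    genotype_rows: list[np.ndarray] = []
    depth_frames: list[pd.DataFrame] = []
    clone_of: dict[str, str] = {}
    ploidy_of: dict[str, int] = {}
    taxon_of: dict[str, str] = {}
    founder_dosages: dict[str, list[int]] = {}
    serial = 0

    def add_library(sample_id, taxon, clone_id, dosages, locality, dup_group):
        ref, alt, genotype = simulate_library(dosages, taxon.ploidy, cfg, rng)
        frame = pd.DataFrame(
            {
                "sample_id": sample_id,
                "locus_id": locus_ids * 2,
                "allele": [REF_ALLELE] * cfg.n_loci + [ALT_ALLELE] * cfg.n_loci,
                "count": np.concatenate([ref, alt]),
            }
        )
        depth_frames.append(frame[frame["count"] > 0])
        genotype_rows.append(genotype)
        sample_ids.append(sample_id)
        metadata.append(
            SampleMeta(
                sample_id=sample_id,
                taxon_label=taxon.name,
                locality_id=locality,
                duplicate_group=dup_group,
                habit=taxon.habit,
                native=True,
                males_recorded=taxon.males_recorded,
            )
        )
        clone_of[sample_id] = clone_id
        ploidy_of[sample_id] = taxon.ploidy
        taxon_of[sample_id] = taxon.name

    for taxon in cfg.taxa:
        q_taxon = draw_allele_freqs(cfg.n_loci, cfg.allele_freq_prior, rng)
        if taxon.reproduce == "clonal":
            founders = [
                rng.binomial(taxon.ploidy, q_taxon).astype(np.int16)
                for _ in range(taxon.n_clones)
            ]
        else:
            parent_a = rng.binomial(2, q_taxon).astype(np.int16)
            parent_b = rng.binomial(2, q_taxon).astype(np.int16)
            founders = list(simulate_sexual_family(parent_a, parent_b,
                                                   taxon.n_clones, rng))
        localities = [f"{taxon.name}:LOC{k:02d}" for k in range(taxon.n_localities)]
        first_in_taxon = True
        loc_cursor = 0
        for c, dosages in enumerate(founders):
            clone_id = f"{taxon.name}/clone{c:02d}"
            founder_dosages[clone_id] = [int(d) for d in dosages]
            for _ in range(taxon.ramets_per_clone):
                sample_id = f"HAN{serial:03d}"
                serial += 1
                locality = localities[loc_cursor % len(localities)]
                loc_cursor += 1
                duplicated = first_in_taxon or (
                    rng.random() < cfg.duplicate_library_rate
                )
                first_in_taxon = False
                dup_group = sample_id if duplicated else None
                add_library(sample_id, taxon, clone_id, dosages, locality, dup_group)
                if duplicated:
                    add_library(sample_id + "b", taxon, clone_id, dosages,
                                locality, dup_group)

    depth_table = DepthTable(pd.concat(depth_frames, ignore_index=True))
    calls = np.stack(genotype_rows)
    genotypes = GenotypeMatrix(sample_ids, locus_ids, calls)
    truth = TruthSet(clone_of, ploidy_of, taxon_of, founder_dosages)
    return SimulatedDataset(depth_table, genotypes, metadata, truth, cfg)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated data set to disk (genepop, depth TSV, metadata CSV,
    truth JSON); returns the path of each artefact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genepop": outdir / "genotypes.gen",
        "depths": outdir / "depths.tsv",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    write_genepop(ds.genotypes, paths["genepop"], allele_digits=2,
                  title="clonekit simulated genotypes")
    ds.depth_table.write(paths["depths"])
    write_sample_metadata(ds.metadata, paths["metadata"])
    ds.truth.to_json(paths["truth"])
    return paths
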