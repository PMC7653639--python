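"""End-to-end orchestration: genotypes -> partition -> clones -> ploidy -> system.

Stages mirror the analysis workflow for a clonality survey:

1. Load (or call from depths) the diploidized genotype matrix.
2. Filter loci by global missingness and split samples into overall-similarity
   groups via p-distances (the reduced data sets).
3. Within each group, refilter loci to zero missingness, compute pairwise
   heterozygous-locus similarities, calibrate the clone threshold against
   duplicate libraries (falling back to the default when no clear gap
   exists) and assign clones.
4. If depth data are available, build per-clone minor-allele-fraction
   spectra and infer ploidy.
5. Combine clone counts, localities, habit, male records and ploidy into a
   per-taxon breeding-system call.

The two-pass locus filtering (lenient globally, strict within groups)
reflects that overall grouping tolerates missing data while clone
comparison must not: a locus absent from one library would otherwise mimic
genotype divergence.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .breeding import TaxonEvidence, classify
from .calling import CallParams, build_genotype_matrix
from .clones import (
    DEFAULT_THRESHOLD_PERCENT,
    assign_clones,
    calibrate_threshold,
    pairwise_het_similarities,
)
from .distance import filter_loci_by_missingness, p_distance_matrix, partition_samples
from .errors import ClonekitError, SpectrumError, NoPeakError, ValidationError
from .io import (
    GenotypeMatrix,
    duplicate_pairs,
    read_depth_table,
    read_genepop,
    read_sample_metadata,
)
from .ploidy import build_spectrum, detect_peaks, infer_ploidy

log = logging.getLogger("clonekit.pipeline")


@dataclass
class PipelineConfig:
    """Paths and stage parameters; defaults follow the reference analysis."""

    metadata: str | Path
    genepop: str | Path | None = None
    depth_table: str | Path | None = None
    out_dir: str | Path | None = None

    call_params: CallParams = field(default_factory=CallParams)
    partition_similarity: float = 0.9978
    partition_max_missing: float = 0.30
    within_group_max_missing: float = 0.0
    clone_default_threshold: float = DEFAULT_THRESHOLD_PERCENT
    clone_min_overlap: int = 20
    clone_min_gap_width: float = 5.0
    ploidy_min_total: int = 20
    ploidy_min_frac: float = 0.05
    ploidy_bin_width: float = 0.01
    ploidy_tolerance: float = 0.03
    ploidy_max_ploidy: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "call_params" in raw:
            raw["call_params"] = CallParams(**raw["call_params"])
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and return a JSON-serialisable report.

    With an output directory configured, intermediates (similarity tables,
    clone assignments, the report itself) are also written to disk.
    """
    if cfg.genepop is None and cfg.depth_table is None:
        raise ValidationError("need a genepop file or a depth table")
    metas = read_sample_metadata(cfg.metadata)
    meta_by_id = {m.sample_id: m for m in metas}

    depth_table = read_depth_table(cfg.depth_table) if cfg.depth_table else None
    if cfg.genepop is not None:
        matrix = read_genepop(cfg.genepop)
    else:
        matrix = build_genotype_matrix(depth_table, cfg.call_params)
    unknown = [s for s in matrix.sample_ids if s not in meta_by_id]
    if unknown:
        raise ValidationError(f"samples without metadata: {unknown}")

    report: dict = {
        "clonekit_version": __version__,
        "n_samples": matrix.n_samples,
        "n_loci_input": matrix.n_loci,
    }

    # --- stage: partition -------------------------------------------------
    global_matrix = filter_loci_by_missingness(matrix, cfg.partition_max_missing)
    log.info("partition stage: %d/%d loci pass %.0f%% missingness",
             global_matrix.n_loci, matrix.n_loci, 100 * cfg.partition_max_missing)
    report["n_loci_partition"] = global_matrix.n_loci
    dm = p_distance_matrix(global_matrix)
    groups = partition_samples(dm, cfg.partition_similarity)
    report["partition_similarity"] = cfg.partition_similarity
    report["groups"] = groups

    # --- stage: clonality per group ---------------------------------------
    group_reports = []
    clone_of_all: dict[str, str] = {}
    for gi, group in enumerate(groups):
        gr: dict = {"group_index": gi, "samples": group}
        if len(group) == 1:
            clone_of_all[group[0]] = group[0]
            gr.update(n_loci=None, n_clones=1,
                      clones={group[0]: group}, threshold_percent=None)
            group_reports.append(gr)
            continue
        sub = matrix.select_samples(group)
        sub = filter_loci_by_missingness(sub, cfg.within_group_max_missing)
        gr["n_loci"] = sub.n_loci
        table = pairwise_het_similarities(sub, cfg.clone_min_overlap)
        in_group = set(group)
        dups = [
            (a, b) for a, b in duplicate_pairs(metas)
            if a in in_group and b in in_group
        ]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            calibration = calibrate_threshold(
                table, dups,
                default_percent=cfg.clone_default_threshold,
                min_gap_width=cfg.clone_min_gap_width,
            )
        for w in caught:
            log.warning("group %d: %s", gi, w.message)
        assignment = assign_clones(table, calibration.threshold_percent, calibration)
        clone_of_all.update(assignment.clone_of)
        gr.update(
            threshold_percent=calibration.threshold_percent,
            threshold_gap=calibration.gap,
            threshold_from_default=calibration.used_default,
            n_duplicate_pairs=len(dups),
            n_clones=assignment.n_clones,
            clones=assignment.clone_members,
            transitivity_violations=assignment.transitivity_violations,
        )
        group_reports.append(gr)
        if cfg.out_dir:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            table.write_tsv(out / f"similarity_group{gi}.tsv")
    report["group_results"] = group_reports

    # --- stage: per-taxon summary and ploidy ------------------------------
    taxa = sorted({m.taxon_label for m in metas if m.sample_id in clone_of_all})
    taxon_reports = []
    for taxon in taxa:
        t_samples = sorted(
            s for s, m in meta_by_id.items()
            if m.taxon_label == taxon and s in clone_of_all
        )
        t_clones = sorted({clone_of_all[s] for s in t_samples})
        # distinct biological samples: duplicate libraries collapse onto
        # their duplicate_group
        biological = {
            (meta_by_id[s].duplicate_group or s) for s in t_samples
        }
        localities_per_clone = {
            c: sorted({meta_by_id[s].locality_id for s in t_samples
                       if clone_of_all[s] == c})
            for c in t_clones
        }
        tr: dict = {
            "taxon": taxon,
            "n_libraries": len(t_samples),
            "n_biological_samples": len(biological),
            "n_clones": len(t_clones),
            "clones": t_clones,
            "localities_per_clone": localities_per_clone,
        }
        ploidy_call = None
        if depth_table is not None:
            clone_calls = {}
            for clone in t_clones:
                members = [s for s in t_samples if clone_of_all[s] == clone]
                try:
                    spectrum = build_spectrum(
                        depth_table, members,
                        min_total=cfg.ploidy_min_total,
                        min_frac=cfg.ploidy_min_frac,
                        bin_width=cfg.ploidy_bin_width,
                    )
                    peaks = detect_peaks(spectrum)
                    call = infer_ploidy(peaks, cfg.ploidy_tolerance,
                                        cfg.ploidy_max_ploidy)
                    clone_calls[clone] = {
                        "ploidy": call.ploidy,
                        "consistent": call.consistency,
                        "peaks": [round(p, 4) for p in call.peak_positions],
                    }
                except (SpectrumError, NoPeakError) as exc:
                    clone_calls[clone] = {"ploidy": None, "error": str(exc)}
            tr["ploidy_by_clone"] = clone_calls
            consistent = [c["ploidy"] for c in clone_calls.values()
                          if c.get("ploidy") and c.get("consistent")]
            ploidy_call = consistent[0] if consistent else None
            tr["ploidy"] = ploidy_call
        else:
            log.warning("no depth table given: ploidy stage skipped")
            tr["ploidy"] = None

        meta0 = meta_by_id[t_samples[0]]
        n_localities = len({meta_by_id[s].locality_id for s in t_samples})
        evidence = TaxonEvidence(
            taxon=taxon,
            n_clones=len(t_clones),
            n_localities=n_localities,
            habit=meta0.habit,
            males_recorded=meta0.males_recorded,
            ploidy=ploidy_call,
            n_samples=len(biological),
        )
        try:
            call = classify(evidence)
            tr["system"] = call.call
            tr["system_inferred"] = call.inferred
            tr["system_flagged_inconclusive"] = call.flagged_inconclusive
            tr["system_rationale"] = call.rationale
        except ClonekitError as exc:
            tr["system"] = None
            tr["system_error"] = str(exc)
        taxon_reports.append(tr)
    report["taxon_results"] = taxon_reports
    report["n_clones_total"] = len(set(clone_of_all.values()))

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        with open(out / "clones.csv", "w") as fh:
            fh.write("sample_id,clone_id\n")
            for s in sorted(clone_of_all):
                fh.write(f"{s},{clone_of_all[s]}\n")
    return report
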