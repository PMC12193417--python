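"""End-to-end orchestration: traits -> resistance -> barcode -> scot -> concordance.

:func:`run_all` executes the marker-system stages independently (a failure in
one never corrupts another's completed outputs), writes each stage's tables
under the output directory, logs one structured line per stage, and finishes
with the cross-marker concordance of whatever cluster assignments succeeded.
The resolved configuration is written alongside the outputs so every report
is self-describing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import barcode as bc
from . import concordance as cc
from . import resistance as rs
from . import scot as sc
from . import traits as tr
from .cluster import ClusterAssignment, cut_dendrogram
from .errors import EchinodivError, ValidationError
from .io import (
    read_alignment,
    read_band_matrix,
    read_resistance_table,
    read_trait_table,
    write_assignment,
    write_newick,
)

log = logging.getLogger("echinodiv")

STAGES = ("traits", "resistance", "barcode", "scot", "concordance")


@dataclass
class RunConfig:
    """Inputs, thresholds and toggles for a full pipeline run."""

    trait_table: Optional[str] = None
    barcode_fastas: dict[str, str] = field(default_factory=dict)  # locus -> path
    barcode_references: dict[str, str] = field(default_factory=dict)
    combine_loci: list[str] = field(default_factory=list)  # e.g. ["ITS", "psbA"]
    band_matrix: Optional[str] = None
    primer_map: Optional[str] = None
    resistance_table: Optional[str] = None
    soa_map: Optional[dict[str, str]] = None
    out_dir: str = "echinodiv_out"
    trait_cut: float = 15.0
    rescale_spss: bool = True
    scot_cut: float = 0.62
    core_locus: str = "ITS"
    bootstrap_replicates: int = 1000
    seed: int = 42
    pic_include_monomorphic: bool = False
    skip: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }


def _sha1(path: str | Path) -> str:
    return hashlib.sha1(Path(path).read_bytes()).hexdigest()[:12]


def _check_shared_samples(sample_sets: dict[str, set]) -> None:
    names = list(sample_sets)
    base = sample_sets[names[0]]
    for name in names[1:]:
        diff = base ^ sample_sets[name]
        if diff:
            raise ValidationError(
                f"sample ids differ between {names[0]} and {name}: {sorted(diff)}"
            )


def run_all(cfg: RunConfig) -> dict:
    """Run every configured stage; returns a summary dict (also written).

    Raises only on configuration errors; stage failures are recorded in the
    summary's ``errors`` mapping and leave other stages' outputs intact.
    The process exit code (via the CLI) is nonzero if any stage failed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skip = set(cfg.skip)
    unknown = skip - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s) in skip: {sorted(unknown)}")

    summary: dict = {"stages": {}, "errors": {}, "group_counts": {}}
    assignments: dict[str, ClusterAssignment] = {}
    sample_sets: dict[str, set] = {}

    trait_table = None
    if cfg.trait_table and "traits" not in skip:
        try:
            trait_table = read_trait_table(cfg.trait_table)
            sample_sets["traits"] = set(trait_table.populations)
            summary_df, dist = tr.diversity_table(trait_table)
            summary_df.to_csv(out / "trait_summary.csv", index_label="trait")
            dist.frequencies.to_csv(out / "trait_level_frequencies.csv")
            z = tr.standardize(trait_table)
            dend = tr.ward_cluster(z, rescale_spss=cfg.rescale_spss)
            pd.DataFrame(
                dend.merges, columns=["a", "b", "height", "size"]
            ).to_csv(out / "trait_merges.csv", index=False)
            assignment = cut_dendrogram(dend, cfg.trait_cut)
            assignments["MT"] = assignment
            write_assignment(assignment, out / "trait_clusters.csv")
            tr.cluster_profiles(assignment, trait_table).to_csv(
                out / "trait_cluster_profiles.csv"
            )
            summary["group_counts"]["MT"] = assignment.n_clusters
            summary["stages"]["traits"] = {
                "input": _sha1(cfg.trait_table),
                "cut": cfg.trait_cut,
                "rescale_spss": cfg.rescale_spss,
                "mean_cv": summary_df.attrs["mean_cv"],
                "mean_hprime": summary_df.attrs["mean_hprime"],
            }
            log.info(
                "stage=traits input=%s cut=%.3f clusters=%d",
                _sha1(cfg.trait_table), cfg.trait_cut, assignment.n_clusters,
            )
        except EchinodivError as exc:
            summary["errors"]["traits"] = str(exc)
            log.error("stage=traits failed: %s", exc)

    if cfg.resistance_table and "resistance" not in skip:
        try:
            res = read_resistance_table(cfg.resistance_table)
            profiles = rs.resistance_profiles(res, cfg.soa_map)
            profiles.to_csv(out / "resistance_profiles.csv")
            summary["stages"]["resistance"] = {
                "input": _sha1(cfg.resistance_table),
                "n_resistant_any": int((profiles["n_resistant"] > 0).sum()),
            }
            if trait_table is not None:
                corr = rs.trait_resistance_correlation(trait_table, profiles)
                corr.to_csv(out / "trait_resistance_correlation.csv")
                summary["stages"]["resistance"]["n"] = corr.attrs["n"]
            log.info("stage=resistance input=%s", _sha1(cfg.resistance_table))
        except EchinodivError as exc:
            summary["errors"]["resistance"] = str(exc)
            log.error("stage=resistance failed: %s", exc)

    alignments = {}
    if cfg.barcode_fastas and "barcode" not in skip:
        for locus, path in cfg.barcode_fastas.items():
            try:
                aln = read_alignment(path, locus, cfg.barcode_references.get(locus))
                alignments[locus] = aln
                sample_sets.setdefault("barcode", set(aln.ids))
                _run_barcode_locus(aln, cfg, out, summary, assignments)
            except EchinodivError as exc:
                summary["errors"][f"barcode:{locus}"] = str(exc)
                log.error("stage=barcode locus=%s failed: %s", locus, exc)
        if len(cfg.combine_loci) >= 2 and all(
            l in alignments for l in cfg.combine_loci
        ):
            try:
                combined = bc.concatenate_barcodes(
                    [alignments[l] for l in cfg.combine_loci]
                )
                _run_barcode_locus(combined, cfg, out, summary, assignments)
            except EchinodivError as exc:
                summary["errors"]["barcode:combined"] = str(exc)
                log.error("stage=barcode combined failed: %s", exc)

    if cfg.band_matrix and cfg.primer_map and "scot" not in skip:
        try:
            bands = read_band_matrix(cfg.band_matrix, cfg.primer_map)
            sample_sets["scot"] = set(bands.samples)
            table2 = sc.primer_summary(
                bands, include_monomorphic=cfg.pic_include_monomorphic
            )
            table2.to_csv(out / "scot_primer_summary.csv", index_label="primer")
            sim = sc.sm_similarity(bands)
            pd.DataFrame(sim.matrix, index=sim.ids, columns=sim.ids).to_csv(
                out / "scot_sm_matrix.csv"
            )
            dend, assignment = sc.scot_cluster(sim, cfg.scot_cut)
            pd.DataFrame(
                dend.merges, columns=["a", "b", "height", "size"]
            ).to_csv(out / "scot_merges.csv", index=False)
            assignments["SCoT"] = assignment
            write_assignment(assignment, out / "scot_clusters.csv")
            _, overall_rate, _ = sc.polymorphic_loci(bands)
            summary["group_counts"]["SCoT"] = assignment.n_clusters
            summary["stages"]["scot"] = {
                "input": _sha1(cfg.band_matrix),
                "cut": cfg.scot_cut,
                "polymorphism_rate": overall_rate,
            }
            log.info(
                "stage=scot input=%s cut=%.2f clusters=%d",
                _sha1(cfg.band_matrix), cfg.scot_cut, assignment.n_clusters,
            )
        except EchinodivError as exc:
            summary["errors"]["scot"] = str(exc)
            log.error("stage=scot failed: %s", exc)

    if len(assignments) >= 2 and "concordance" not in skip:
        try:
            _check_shared_samples(
                {k: set(v.ids) for k, v in assignments.items()}
            )
            order = assignments[next(iter(assignments))].ids
            vectors = {
                name: cc.encode_labels(a, order)
                for name, a in assignments.items()
            }
            result = cc.pearson_concordance(vectors)
            result.table().to_csv(out / "concordance.csv")
            result.r.to_csv(out / "concordance_r.csv")
            result.p.to_csv(out / "concordance_p.csv")
            summary["stages"]["concordance"] = {
                "methods": result.methods,
                "n": result.n,
            }
            log.info("stage=concordance methods=%s", ",".join(result.methods))
        except EchinodivError as exc:
            summary["errors"]["concordance"] = str(exc)
            log.error("stage=concordance failed: %s", exc)

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(_plain(summary), fh, sort_keys=True)
    return summary


def _run_barcode_locus(aln, cfg: RunConfig, out: Path, summary: dict, assignments) -> None:
    profile = bc.variable_sites(aln)
    pd.DataFrame(
        {
            "sample_id": aln.ids,
            "haplotype": [profile.haplotype[s] for s in aln.ids],
            **{
                f"pos_{p}": [profile.states[s][i] for s in aln.ids]
                for i, p in enumerate(profile.positions)
            },
        }
    ).to_csv(out / f"barcode_{_safe(aln.locus)}_snp.csv", index=False)
    assignment = bc.barcode_cluster(aln)
    write_assignment(assignment, out / f"barcode_{_safe(aln.locus)}_clusters.csv")
    dmat = bc.k2p_matrix(aln)
    pd.DataFrame(dmat.matrix, index=dmat.ids, columns=dmat.ids).to_csv(
        out / f"barcode_{_safe(aln.locus)}_k2p.csv"
    )
    stage: dict = {
        "n_variable_sites": len(profile.positions),
        "n_haplotypes": profile.n_haplotypes,
    }
    if profile.n_haplotypes >= 3 and not dmat.undefined:
        # collapse to one representative per haplotype before tree building:
        # identical sequences carry no topology information
        reps = {}
        for sid in aln.ids:
            reps.setdefault(profile.haplotype[sid], sid)
        if len(reps) >= 3:
            rep_ids = list(reps.values())
            sub = type(aln)(
                aln.locus, rep_ids,
                {s: aln.sequences[s] for s in rep_ids},
            )
            tree = bc.bootstrap_support(
                sub, cfg.bootstrap_replicates, cfg.seed
            )
            write_newick(tree, out / f"barcode_{_safe(aln.locus)}.nwk")
    assignments[aln.locus] = assignment
    summary["group_counts"][aln.locus] = assignment.n_clusters
    summary["stages"][f"barcode:{aln.locus}"] = stage
    log.info(
        "stage=barcode locus=%s sites=%d haplotypes=%d",
        aln.locus, len(profile.positions), profile.n_haplotypes,
    )


def _safe(name: str) -> str:
    return name.replace("/", "_").replace("+", "_")


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
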