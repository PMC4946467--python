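"""End-to-end orchestration of the two analysis branches.

The perfusion branch compares post-perfusion (0h) DBD and DCD samples
against the PRE baseline without pairing: expression filter -> TMM ->
CPM -> unpaired NB-GLM LRT per contrast -> consistency at tolerance 0 ->
DCD-specific gene sets -> optional ontology enrichment.

The cold-storage branch follows each donor through storage with pairing:
expression filter -> log2 -> batch adjustment -> back-transform -> CPM ->
paired NB-GLM LRT for 3h-vs-0h and 6h-vs-0h within DCD and within DBD ->
consistency at tolerance 1.

Every run writes deterministic TSV tables plus a manifest (config hash,
seed, input checksums) under the output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consistency as cons
from . import diffexpr as de
from . import enrichment as enr
from . import preprocess as pp
from .datatypes import CountMatrix
from .io import write_table


@dataclass
class AnalysisConfig:
    """Thresholds and knobs of both branches, with the published defaults."""

    branch: str = "perfusion"           # or "cold-storage"
    fdr_threshold: float | None = None  # default 0.001 perfusion, 0.25 cold-storage
    fc_threshold: float = 0.5
    tolerance: int | None = None        # default 0 perfusion, 1 cold-storage
    min_observed: int = 5
    enrichment_fdr: float = 0.001
    count_pseudocount: float = 1.0      # for the cold-storage log2 step
    cpm_pseudocount: float = 1.0        # for per-subject fold changes
    dispersion_prior_df: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch not in ("perfusion", "cold-storage"):
            raise ValueError("branch must be 'perfusion' or 'cold-storage'")
        if self.fdr_threshold is None:
            self.fdr_threshold = 0.001 if self.branch == "perfusion" else 0.25
        if self.tolerance is None:
            self.tolerance = 0 if self.branch == "perfusion" else 1
        if not 0.0 <= self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _write_manifest(outdir: Path, config: AnalysisConfig, cm: CountMatrix) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": _sha256(yaml.safe_dump(asdict(config), sort_keys=True).encode()),
        "seed": config.seed,
        "counts_checksum": _sha256(cm.counts.to_csv(sep="\t").encode()),
        "meta_checksum": _sha256(cm.meta.to_csv(sep="\t").encode()),
        "n_genes": int(cm.counts.shape[0]),
        "n_samples": int(cm.counts.shape[1]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _n_subjects(meta: pd.DataFrame) -> int:
    return meta["donor_id"].nunique()


def run_perfusion(cm: CountMatrix, config: AnalysisConfig | None = None,
                  outdir=None, ontology=None, annotations=None) -> dict:
    """Perfusion-branch analysis; returns a result bundle dict.

    ``ontology``/``annotations`` (networkx DAG + gene/term DataFrame)
    switch on the enrichment stage for the DCD-specific up and down sets.
    """
    config = config or AnalysisConfig(branch="perfusion")
    if config.branch != "perfusion":
        raise ValueError("config.branch must be 'perfusion'")
    groups = set(cm.meta["group"])
    needed = {"PRE", "DBD", "DCD"}
    if not needed <= groups:
        raise ValueError(f"missing groups: {sorted(needed - groups)}")

    filtered = pp.filter_expressed(cm, _n_subjects(cm.meta))
    log = {"genes_in": int(cm.counts.shape[0]), "genes_filtered": int(filtered.counts.shape[0])}

    zero_h = cm.meta["timepoint"].isin(["pre", "0h"])
    sub = filtered.subset_samples(cm.meta.index[zero_h])
    nf = pp.tmm_factors(sub)
    cpm = pp.to_cpm(sub.counts, factors=nf)
    offsets = de.offsets_from_factors(nf)

    results: dict = {"config": config, "log": log, "tmm": nf, "cpm": cpm}
    called_dirs = {}
    for grp in ("DCD", "DBD"):
        design = de.unpaired_design(sub.meta, "PRE", grp, offsets)
        table = de.nb_lrt_pipeline(sub.counts, design, prior_df=config.dispersion_prior_df)
        baseline = sub.meta.index[sub.meta["group"] == "PRE"]
        treated = sub.meta.index[sub.meta["group"] == grp]
        lfc = cons.subject_log2fc(cpm, sub.meta, baseline, treated,
                                  paired=False, pseudocount=config.cpm_pseudocount)
        ci = cons.consistency_index(lfc, fc_threshold=config.fc_threshold)
        called = cons.call_de(table, ci, config.fdr_threshold, config.tolerance)
        results[f"de_{grp.lower()}"] = table
        results[f"consistency_{grp.lower()}"] = ci
        results[f"called_{grp.lower()}"] = called
        called_dirs[grp] = called["direction"]

    sets = cons.dcd_specific_sets(called_dirs["DCD"], called_dirs["DBD"])
    results["dcd_specific"] = sets

    if ontology is not None and annotations is not None:
        direct = enr.annotation_table_to_direct(annotations)
        universe = set(filtered.genes)
        for direction, genes in (("up", sets.dcd_specific_up),
                                 ("down", sets.dcd_specific_down)):
            study = set(genes) & universe
            if study:
                table = enr.hypergeom_enrich(ontology, direct, study, universe,
                                             min_observed=config.min_observed)
                reported = enr.leaf_filter(table, ontology, config.enrichment_fdr)
            else:
                table = pd.DataFrame(columns=["name", "N", "K", "n", "k", "p", "q"])
                reported = table.assign(leaf=pd.Series(dtype=bool))
            results[f"enrichment_{direction}"] = table
            results[f"enrichment_{direction}_leaves"] = reported

    results["summary"] = {
        "n_genes_filtered": log["genes_filtered"],
        "n_de_dcd": int(len(results["called_dcd"])),
        "n_de_dbd": int(len(results["called_dbd"])),
        "n_dcd_specific_up": len(sets.dcd_specific_up),
        "n_dcd_specific_down": len(sets.dcd_specific_down),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_manifest(outdir, config, cm)
        write_table(pd.DataFrame({"factor": nf.factors, "library_size": nf.library_sizes}),
                    outdir / "tmm_factors.tsv")
        for grp in ("dcd", "dbd"):
            write_table(results[f"de_{grp}"], outdir / f"de_{grp}_0h_vs_pre.tsv")
            write_table(results[f"consistency_{grp}"], outdir / f"consistency_{grp}.tsv")
            write_table(results[f"called_{grp}"], outdir / f"called_{grp}.tsv")
        spec_rows = [{"gene": g, "direction": "up"} for g in sets.dcd_specific_up] + \
                    [{"gene": g, "direction": "down"} for g in sets.dcd_specific_down]
        write_table(pd.DataFrame(spec_rows, columns=["gene", "direction"]),
                    outdir / "dcd_specific.tsv", index=False)
        for key in ("enrichment_up_leaves", "enrichment_down_leaves"):
            if key in results:
                write_table(results[key], outdir / f"{key}.tsv")
        (outdir / "summary.json").write_text(
            json.dumps(results["summary"], indent=2, sort_keys=True) + "\n")
    return results


COLD_COMPARISONS = (("DBD", "3h"), ("DBD", "6h"), ("DCD", "3h"), ("DCD", "6h"))


def run_cold_storage(cm: CountMatrix, config: AnalysisConfig | None = None,
                     outdir=None) -> dict:
    """Cold-storage branch: paired 3h/6h-vs-0h tests within each group."""
    config = config or AnalysisConfig(branch="cold-storage")
    if config.branch != "cold-storage":
        raise ValueError("config.branch must be 'cold-storage'")
    storage = cm.meta["timepoint"].isin(["0h", "3h", "6h"])
    sub = cm.subset_samples(cm.meta.index[storage])
    if sub.counts.shape[1] == 0:
        raise ValueError("no cold-storage samples present")

    filtered = pp.filter_expressed(sub, _n_subjects(sub.meta))
    logmat = pp.log2_transform(filtered.counts, config.count_pseudocount)
    adjusted, batch_model = pp.batch_adjust(logmat, filtered.meta["batch"])
    back = pp.back_transform(adjusted, config.count_pseudocount)
    pseudo_counts = back.round().astype(np.int64)
    lib = pseudo_counts.sum(axis=0).astype(float).clip(lower=1.0)
    cpm = pp.to_cpm(back, library_sizes=lib)
    offsets = de.offsets_from_library_sizes(lib)

    results: dict = {"config": config, "batch_model": batch_model, "cpm": cpm}
    summary = {"n_genes_filtered": int(filtered.counts.shape[0])}
    for grp, tp in COLD_COMPARISONS:
        label = f"{grp.lower()}_{tp}_vs_0h"
        gmask = filtered.meta["group"] == grp
        gmeta = filtered.meta[gmask]
        design = de.paired_design(gmeta, "0h", tp, offsets)
        counts_g = pseudo_counts[design.X.index]
        table = de.nb_lrt_pipeline(counts_g, design, prior_df=config.dispersion_prior_df)
        baseline = gmeta.index[gmeta["timepoint"] == "0h"]
        treated = gmeta.index[gmeta["timepoint"] == tp]
        lfc = cons.subject_log2fc(cpm, gmeta, baseline, treated,
                                  paired=True, pseudocount=config.cpm_pseudocount)
        ci = cons.consistency_index(lfc, fc_threshold=config.fc_threshold)
        called = cons.call_de(table, ci, config.fdr_threshold, config.tolerance)
        results[f"de_{label}"] = table
        results[f"consistency_{label}"] = ci
        results[f"called_{label}"] = called
        summary[f"n_called_{label}"] = int(len(called))
    results["summary"] = summary

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_manifest(outdir, config, cm)
        for grp, tp in COLD_COMPARISONS:
            label = f"{grp.lower()}_{tp}_vs_0h"
            write_table(results[f"de_{label}"], outdir / f"de_{label}.tsv")
            write_table(results[f"consistency_{label}"], outdir / f"consistency_{label}.tsv")
            write_table(results[f"called_{label}"], outdir / f"called_{label}.tsv")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return results
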