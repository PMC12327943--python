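"""End-to-end orchestration of the read-level isoform analyses.

``run_pipeline`` executes, in order: model loading, exon-bin flattening,
optional internal-priming artifact filtering, bin counting and first-exon
statistics, donor readthrough and junction counting, coverage-based
alternative-splicing estimation, and group statistics; every stage writes
its TSV and the run ends with a machine-readable manifest (package
version, seed, config hash, per-stage read counts).  Two runs with the
same configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
import yaml

from . import __version__
from .alignments import read_alignments
from .artifact import ArtifactRuleSet, filter_reads
from .exon_quant import count_bins, first_exon_counts
from .gene_model import flatten_isoforms, load_gtf, name_junction, write_bins_bed
from .splice import (
    altsplice_proportion,
    compare_readthrough,
    count_junction_reads,
    coverage_profile,
    readthrough_table,
)
from .stats import kruskal_dunn, welch_t_bootstrap

log = logging.getLogger("isoreads")

__all__ = ["RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see docs/methods.md for schema)."""

    raw: dict
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw=raw, base_dir=os.path.dirname(os.path.abspath(path)))

    def path(self, key: str, required: bool = True) -> str | None:
        p = self.raw.get("paths", {}).get(key)
        if p is None:
            if required:
                raise PipelineError(f"config: paths.{key} is required")
            return None
        p = p if os.path.isabs(p) else os.path.join(self.base_dir, p)
        if not os.path.exists(p):
            raise PipelineError(f"config: paths.{key} does not exist: {p}")
        return p

    def validate(self) -> None:
        self.path("gtf")
        self.path("alignments")
        if self.raw.get("artifact", {}).get("enabled", False):
            self.path("fasta")

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


class _FastaGenome:
    """fetch() adapter over an indexed FASTA."""

    def __init__(self, path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = len(self._fa[chrom])
        return self._fa[chrom][max(start, 0) : min(end, n)].seq

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    cfg = config.raw
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "stages": {},
        "outputs": [],
    }

    def out(name: str) -> str:
        p = os.path.join(outdir, name)
        manifest["outputs"].append(name)
        return p

    # -- load -------------------------------------------------------------
    stage = "load_models"
    models = {g.gene_id: g for g in load_gtf(config.path("gtf"))}
    if not models:
        raise PipelineError(f"{stage}: no gene models in GTF")
    for gcfg in cfg.get("sites", []):
        gene = models[gcfg["gene"]]
        gene.add_site(gcfg["name"], int(gcfg["pos"]), gcfg["kind"])
    for gid, roles in cfg.get("first_exon_roles", {}).items():
        models[gid].first_exon_labels.update(roles)
    reads = read_alignments(
        config.path("alignments"), config.path("truth", required=False)
    )
    log.info("%s: %d genes, %d reads", stage, len(models), len(reads))
    manifest["stages"][stage] = {"genes": len(models), "reads": len(reads)}

    # -- flatten ----------------------------------------------------------
    stage = "flatten"
    bins_by_gene = {gid: flatten_isoforms(g) for gid, g in models.items()}
    all_bins = [b for bl in bins_by_gene.values() for b in bl]
    write_bins_bed(all_bins, out("exon_bins.bed"))
    manifest["stages"][stage] = {"bins": len(all_bins)}

    # -- artifact filter --------------------------------------------------
    art_cfg = cfg.get("artifact", {})
    if art_cfg.get("enabled", False):
        stage = "artifact_filter"
        genome = _FastaGenome(config.path("fasta"))
        window = int(art_cfg.get("window", 30))
        kept, removed, report = filter_reads(
            reads, genome, ArtifactRuleSet(), window=window
        )
        report.to_csv(out("artifact_report.tsv"), sep="\t", index=False)
        with open(out("removed_read_ids.txt"), "w") as fh:
            for r, fired in removed:
                fh.write(f"{r.read_id}\t{','.join(fired)}\n")
        log.info("%s: removed %d of %d reads", stage, len(removed), len(reads))
        manifest["stages"][stage] = {"kept": len(kept), "removed": len(removed)}
        reads = kept

    # -- bin counts + first-exon stats ------------------------------------
    stage = "count_bins"
    table = count_bins(reads, all_bins, by="cell_id")
    table.to_tsv(out("bin_counts_raw.tsv"), out("bin_counts_per_kb.tsv"))
    manifest["stages"][stage] = {"bins": len(table.counts), "cells": table.counts.shape[1]}

    fe_cfg = cfg.get("first_exon")
    fe_df = None
    if fe_cfg:
        stage = "first_exon"
        gene = models[fe_cfg["gene"]]
        fe_df = first_exon_counts(
            reads, gene,
            tr_label=fe_cfg.get("tr_label", "exon1T"),
            f_label=fe_cfg.get("f_label", "exon1"),
        )
        _write_tsv(fe_df.reset_index(), out("first_exon_counts.tsv"))
        manifest["stages"][stage] = {"cells": len(fe_df)}

    # -- readthrough + junctions ------------------------------------------
    rt_cfg = cfg.get("readthrough")
    rt_table = None
    if rt_cfg:
        stage = "readthrough"
        gene = models[rt_cfg["gene"]]
        donors = list(rt_cfg["donors"])
        rt_table = readthrough_table(
            reads, gene, donors,
            min_readthrough=int(rt_cfg.get("min_readthrough", 10)),
        )
        _write_tsv(rt_table, out("readthrough_summary.tsv"))
        manifest["stages"][stage] = {"donors": len(donors)}

    jx_cfg = cfg.get("junctions", [])
    if jx_cfg:
        stage = "junctions"
        rows = []
        for j in jx_cfg:
            gene = models[j["gene"]]
            key = name_junction(gene, int(j["donor"]), int(j["acceptor"]))
            rows.append(
                {
                    "name": j.get("name", f"{key[0]}:{key[1]}-{key[2]}"),
                    "chrom": key[0],
                    "left": key[1],
                    "right": key[2],
                    "strand": key[3],
                    "n_reads": count_junction_reads(reads, key),
                }
            )
        _write_tsv(pd.DataFrame(rows), out("junction_counts.tsv"))
        manifest["stages"][stage] = {"junctions": len(rows)}

    # -- altsplice ---------------------------------------------------------
    as_cfg = cfg.get("altsplice")
    if as_cfg:
        stage = "altsplice"
        gene = models[as_cfg["gene"]]
        span = gene.span
        rows = []
        groups = sorted({r.group for r in reads})
        for grp in groups:
            grp_reads = [r for r in reads if r.group == grp]
            prof = coverage_profile(grp_reads, gene.chrom, span.start, span.end)
            prof.write_bedgraph(out(f"coverage_{grp}.bedgraph"))
            prop = altsplice_proportion(
                prof,
                int(as_cfg["acceptor"]),
                int(as_cfg["internal_donor"]),
                int(as_cfg["exon_end"]),
                strand=gene.strand,
            )
            rows.append({"group": grp, "altsplice_proportion": prop})
        _write_tsv(pd.DataFrame(rows), out("altsplice_proportions.tsv"))
        manifest["stages"][stage] = {"groups": len(groups)}

    # -- statistics --------------------------------------------------------
    stage = "stats"
    st_cfg = cfg.get("stats", {})
    n_boot = int(st_cfg.get("n_boot", 10_000))
    alpha = float(st_cfg.get("alpha", 0.05))
    results = []
    if fe_df is not None:
        clean = fe_df.dropna(subset=["relative_difference"])
        groups = sorted(clean["group"].unique())
        samples = [
            clean.loc[clean["group"] == g, "relative_difference"].to_numpy()
            for g in groups
        ]
        if len(groups) >= 3:
            res = kruskal_dunn(samples, labels=groups, alpha=alpha)
            row = res.to_row()
            row["comparison"] = "first_exon_relative_difference"
            results.append(row)
            _write_tsv(res.pairwise, out("first_exon_dunn_pairwise.tsv"))
        elif len(groups) == 2:
            res = welch_t_bootstrap(
                samples[0], samples[1], n_boot=n_boot, seed=config.seed
            )
            row = res.to_row()
            row["comparison"] = "first_exon_relative_difference"
            results.append(row)
    if rt_table is not None:
        groups = sorted(rt_table["group"].unique())
        for donor in rt_table["donor"].unique():
            for ga, gb in combinations(groups, 2):
                try:
                    res = compare_readthrough(rt_table, donor, ga, gb)
                except Exception as exc:
                    log.warning("stats: readthrough %s %s/%s skipped: %s",
                                donor, ga, gb, exc)
                    continue
                row = res.to_row()
                row["comparison"] = f"readthrough:{donor}:{ga}_vs_{gb}"
                results.append(row)
    if results:
        _write_tsv(pd.DataFrame(results), out("stats_results.tsv"))
    manifest["stages"][stage] = {"tests": len(results)}

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
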