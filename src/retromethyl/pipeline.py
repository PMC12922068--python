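"""End-to-end per-subtype orchestration.

For each molecular subtype the pipeline runs: cross-tool concordance and
consensus locus selection; locus-gene association (intragenic hosts and
50-kb neighbours); CpG pairing, filtering, Spearman correlation and the
interaction regressions for both CpG-gene and CpG-locus pairs. Gene-side
CpG pairing is restricted to genes hosting a consensus locus, mirroring
the analysis design (methylation around retroelement-containing genes).

Every stage output is a pure function of (inputs, config): reruns are
byte-identical, and all filter kept/dropped counts are logged to the run
summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List

import pandas as pd
import yaml

from . import __version__
from .association import annotate_links, find_host_genes, find_nearby_genes
from .concordance import ConsensusPolicy, consensus_select, pairwise_agreement
from .coupling import (
    PairFilterReport,
    filter_pairs,
    fit_gene_model,
    fit_locus_model,
    pair_cpg_gene,
    pair_cpg_locus,
    spearman_coupling,
)
from .features import (
    FilterConfig,
    read_de_table,
    read_gtf,
    read_locus_bed,
    read_methylation_table,
)

__all__ = ["RunConfig", "SubtypeInputs", "run_subtype", "run", "load_run_config"]

_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure with subtype and stage context."""

    def __init__(self, subtype: str, stage: str, message: str):
        super().__init__(f"[{subtype}/{stage}] {message}")
        self.subtype = subtype
        self.stage = stage


@dataclass
class SubtypeInputs:
    locus_de: Dict[str, str]  # tool -> TSV path
    gene_de: str
    meth: str
    manifest: str
    genes_gtf: str
    loci_bed: str


@dataclass
class RunConfig:
    subtypes: List[str]
    inputs: Dict[str, SubtypeInputs]
    outdir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    consensus: ConsensusPolicy = field(default_factory=ConsensusPolicy)
    gene_pair_window: int = 3_000
    locus_pair_window: int = 10_000
    nearby_window: int = 50_000
    seed: int = 0


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    inputs = {
        st: SubtypeInputs(**spec) for st, spec in raw["inputs"].items()
    }
    return RunConfig(
        subtypes=list(raw["subtypes"]),
        inputs=inputs,
        outdir=raw["outdir"],
        filter=FilterConfig(**raw.get("filter", {})),
        consensus=ConsensusPolicy(**raw.get("consensus", {})),
        gene_pair_window=raw.get("gene_pair_window", 3_000),
        locus_pair_window=raw.get("locus_pair_window", 10_000),
        nearby_window=raw.get("nearby_window", 50_000),
        seed=raw.get("seed", 0),
    )


def _links_frame(links) -> pd.DataFrame:
    return pd.DataFrame({
        "locus_id": [l.locus_id for l in links],
        "gene_id": [l.gene_id for l in links],
        "relation": [l.relation for l in links],
        "distance_bp": [l.distance_bp for l in links],
        "locus_strand_glyph": ["+" if l.same_strand else "-/+" for l in links],
        "same_strand": [l.same_strand for l in links],
        "locus_log2fc": [l.locus_de.log2fc if l.locus_de else math.nan for l in links],
        "locus_padj": [
            (l.locus_de.padj if l.locus_de and l.locus_de.padj is not None
             else math.nan) for l in links],
        "gene_log2fc": [l.gene_de.log2fc if l.gene_de else math.nan for l in links],
        "gene_padj": [
            (l.gene_de.padj if l.gene_de and l.gene_de.padj is not None
             else math.nan) for l in links],
    })


def _pairs_frame(pairs) -> pd.DataFrame:
    def quadrant(p):
        # scatter classes: meth up/down x expression up/down
        if p.Y is None:
            return "unfiltered"
        if p.X1 > 0:
            return "meth_up_expr_up" if p.Y > 0 else "meth_up_expr_down"
        return "meth_down_expr_up" if p.Y > 0 else "meth_down_expr_down"

    return pd.DataFrame({
        "cpg_id": [p.cpg_id for p in pairs],
        "partner_id": [p.partner_id for p in pairs],
        "pair_kind": [p.pair_kind for p in pairs],
        "X1_meth_log2fc": [p.X1 for p in pairs],
        "X2_same_strand": [p.X2 for p in pairs],
        "X3_promoter": [p.X3 if p.X3 is not None else "" for p in pairs],
        "Y_expr_log2fc": [p.Y if p.Y is not None else math.nan for p in pairs],
        "distance_bp": [p.distance_bp for p in pairs],
        "quadrant": [quadrant(p) for p in pairs],
    })


def _regression_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        if not res.applicable:
            rows.append((res.model, "", math.nan, math.nan, math.nan, math.nan,
                         res.n_pairs, False, res.inapplicability_reason or ""))
            continue
        for term, (est, se, t, p) in res.coefficients.items():
            rows.append((res.model, term, est, se, t, p, res.n_pairs, True, ""))
    return pd.DataFrame(rows, columns=[
        "model", "term", "estimate", "se", "t", "pvalue",
        "n_pairs", "applicable", "reason",
    ])


def run_subtype(cfg: RunConfig, subtype: str) -> Dict[str, object]:
    """Execute every stage for one subtype and write its report bundle."""
    if subtype not in cfg.inputs:
        raise PipelineError(subtype, "inputs", "no inputs configured")
    inp = cfg.inputs[subtype]
    outdir = os.path.join(cfg.outdir, subtype)
    os.makedirs(outdir, exist_ok=True)
    summary: Dict[str, object] = {"subtype": subtype}

    # ---- load
    if cfg.consensus.mode == "anchor_plus_one":
        required = {cfg.consensus.anchor_tool}
    else:
        required = set(inp.locus_de)
    missing = [t for t in sorted(required) if t not in inp.locus_de
               or not os.path.exists(inp.locus_de[t])]
    if missing:
        raise PipelineError(subtype, "load",
                            f"missing DE table(s) for tool(s): {missing}")
    locus_tables = {
        tool: read_de_table(path, tool=tool, subtype=subtype)
        for tool, path in sorted(inp.locus_de.items())
    }
    gene_table = read_de_table(inp.gene_de, tool="generic", subtype=subtype)
    genes = read_gtf(inp.genes_gtf)
    loci = read_locus_bed(inp.loci_bed)
    sites = read_methylation_table(inp.meth, inp.manifest)
    summary["n_genes"] = len(genes)
    summary["n_loci"] = len(loci)
    summary["n_cpg_sites"] = len(sites)
    summary["n_cpg_dropped_no_manifest"] = sites.stats.n_rejected

    # ---- concordance + consensus
    agreement = pairwise_agreement(
        locus_tables, alpha=cfg.consensus.alpha, lfc_min=cfg.consensus.lfc_min)
    pd.DataFrame({
        "tool_a": [a.tool_pair[0] for a in agreement],
        "tool_b": [a.tool_pair[1] for a in agreement],
        "kappa": [a.kappa for a in agreement],
        "p0": [a.p0 for a in agreement],
        "pe": [a.pe for a in agreement],
        "pearson_r": [a.pearson_r for a in agreement],
        "r_squared": [a.r_squared for a in agreement],
        "n_features": [a.n_features for a in agreement],
    }).to_csv(os.path.join(outdir, "agreement.tsv"), sep="\t", index=False,
              float_format=_FLOAT)

    consensus_calls = consensus_select(locus_tables, cfg.consensus)
    consensus_ids = {c.feature_id for c in consensus_calls}
    pd.DataFrame({
        "feature_id": [c.feature_id for c in consensus_calls],
        "direction": [c.direction for c in consensus_calls],
    }).to_csv(os.path.join(outdir, "consensus.tsv"), sep="\t", index=False)
    summary["n_consensus_loci"] = len(consensus_ids)

    # ---- association
    de_loci = [l for l in loci if l.feature_id in consensus_ids]
    anchor = (cfg.consensus.anchor_tool
              if cfg.consensus.mode == "anchor_plus_one"
              else sorted(locus_tables)[0])
    host = annotate_links(find_host_genes(de_loci, genes),
                          locus_de=locus_tables[anchor], gene_de=gene_table)
    nearby = annotate_links(
        find_nearby_genes(de_loci, genes, window=cfg.nearby_window),
        locus_de=locus_tables[anchor], gene_de=gene_table)
    _links_frame(host).to_csv(os.path.join(outdir, "host_links.tsv"),
                              sep="\t", index=False, float_format=_FLOAT)
    _links_frame(nearby).to_csv(os.path.join(outdir, "nearby_links.tsv"),
                                sep="\t", index=False, float_format=_FLOAT)
    summary["n_host_genes"] = len({l.gene_id for l in host})
    summary["n_nearby_genes"] = len({l.gene_id for l in nearby})

    # ---- methylation-expression coupling
    host_gene_ids = {l.gene_id for l in host}
    host_genes = [g for g in genes if g.feature_id in host_gene_ids]
    gene_pairs_raw = pair_cpg_gene(sites, host_genes,
                                   window=cfg.gene_pair_window)
    locus_pairs_raw = pair_cpg_locus(sites, loci,
                                     window=cfg.locus_pair_window)
    gene_report, locus_report = PairFilterReport(), PairFilterReport()
    gene_pairs = filter_pairs(gene_pairs_raw, sites, gene_table,
                              cfg.filter, report=gene_report)
    locus_pairs = filter_pairs(locus_pairs_raw, sites, locus_tables[anchor],
                               cfg.filter, consensus=consensus_ids,
                               report=locus_report)
    _pairs_frame(gene_pairs).to_csv(os.path.join(outdir, "gene_pairs.tsv"),
                                    sep="\t", index=False, float_format=_FLOAT)
    _pairs_frame(locus_pairs).to_csv(os.path.join(outdir, "locus_pairs.tsv"),
                                     sep="\t", index=False, float_format=_FLOAT)
    for name, rep in (("gene", gene_report), ("locus", locus_report)):
        summary[f"{name}_pairs_input"] = rep.n_input
        summary[f"{name}_pairs_kept"] = rep.n_kept
        summary[f"{name}_pairs_failed_meth"] = rep.n_failed_meth
        summary[f"{name}_pairs_failed_expr"] = rep.n_failed_expr
        summary[f"{name}_pairs_no_de"] = rep.n_no_de_record
        summary[f"{name}_pairs_not_consensus"] = rep.n_not_in_consensus

    corr_rows = []
    for name, pairs in (("cpg_gene", gene_pairs), ("cpg_locus", locus_pairs)):
        if len(pairs) >= 3:
            c = spearman_coupling(pairs)
            corr_rows.append((subtype, name, c.rho, c.pvalue, c.n_pairs,
                              c.n_unique_cpgs, c.n_unique_partners, c.defined))
            summary[f"{name}_pairs_line"] = (
                f"{c.n_pairs} pairs, {c.n_unique_cpgs} unique CpG sites, "
                f"{c.n_unique_partners} unique partners"
            )
        else:
            corr_rows.append((subtype, name, math.nan, math.nan, len(pairs),
                              len({p.cpg_id for p in pairs}),
                              len({p.partner_id for p in pairs}), False))
    pd.DataFrame(corr_rows, columns=[
        "subtype", "pair_kind", "rho", "pvalue", "n_pairs",
        "n_unique_cpgs", "n_unique_partners", "defined",
    ]).to_csv(os.path.join(outdir, "correlation.tsv"), sep="\t", index=False,
              float_format=_FLOAT)

    reg_locus = fit_locus_model(locus_pairs)
    reg_gene = fit_gene_model(gene_pairs)
    _regression_frame([reg_locus, reg_gene]).to_csv(
        os.path.join(outdir, "regression.tsv"), sep="\t", index=False,
        float_format=_FLOAT)
    summary["locus_model_applicable"] = reg_locus.applicable
    summary["gene_model_applicable"] = reg_gene.applicable
    if reg_gene.applicable:
        summary["gene_model_promoter_sign_flip"] = reg_gene.promoter_sign_flip

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run(cfg: RunConfig) -> Dict[str, object]:
    """Run all configured subtypes; failures are isolated per subtype."""
    os.makedirs(cfg.outdir, exist_ok=True)
    results: Dict[str, object] = {}
    failures: Dict[str, str] = {}
    for subtype in cfg.subtypes:
        try:
            results[subtype] = run_subtype(cfg, subtype)
        except Exception as exc:  # noqa: BLE001 - isolate per subtype
            failures[subtype] = str(exc)
    sidecar = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "config_sha256": _config_hash(cfg),
        "subtypes_ok": sorted(results),
        "subtypes_failed": failures,
    }
    with open(os.path.join(cfg.outdir, "run_metadata.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    if failures:
        raise PipelineError(",".join(sorted(failures)), "run",
                            f"subtype failures: {failures}")
    return results


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
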