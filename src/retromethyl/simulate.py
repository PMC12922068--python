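"""Synthetic data generation with known ground truth for every stage.

Generates genomic layouts (genes and retroelement loci with controlled
intragenic / nearby / isolated placement), per-tool differential-expression
tables under an additive measurement-noise model, CpG methylation tables
whose partner expression follows the strand/promoter interaction forward
model, and paired tumor-normal qPCR cohorts. Identical configuration and
seed give byte-identical output files.

The additive DE model: each feature carries a true log2FC; every pseudo-
tool observes it plus independent Normal(0, tool_noise_sd) noise, so the
expected inter-tool Pearson correlation is Var(true) / (Var(true) +
tool_noise_sd^2), which the truth metadata records.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coupling import PairRecord
from .features import (
    CpGSite,
    DEResult,
    GenomicFeature,
    write_de_table,
    write_gtf,
    write_locus_bed,
)
from .qpcr import QPCRMeasurement

__all__ = [
    "SimulationConfig",
    "simulate_layout",
    "simulate_de_tables",
    "simulate_methylation",
    "simulate_pairs",
    "simulate_qpcr",
    "simulate_all",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic cohort.

    Defaults emulate the study setting at desk scale: three quantification
    tools in strong but imperfect agreement, ~30% of features truly
    differentially expressed, negative methylation-expression coupling at
    retroelement loci and a promoter-dependent sign flip at genes, and a
    paired qPCR cohort with tumor-elevated targets.
    """

    seed: int = 0
    n_genes: int = 200
    n_loci: int = 80
    n_cpgs: int = 2500
    cpgs_per_gene: int = 6
    cpgs_per_locus: int = 4
    chrom_name: str = "chrS1"
    chrom_length: int = 100_000_000
    frac_intragenic_loci: float = 0.6
    frac_nearby_loci: float = 0.25
    # differential expression
    de_effect_sd: float = 1.5
    tool_noise_sd: float = 0.25
    frac_true_de: float = 0.3
    core_de_frac: float = 0.8  # fraction of true-DE features with |lfc| >= 1 guaranteed
    # methylation-expression coupling (locus model: beta0..beta3;
    # gene model: beta0..beta5)
    coupling_beta: Dict[str, float] = field(default_factory=lambda: {
        "beta0": 0.0, "beta1": -1.5, "beta2": 0.0, "beta3": 0.0,
    })
    gene_coupling_beta: Dict[str, float] = field(default_factory=lambda: {
        "beta0": 0.0, "beta1": 1.6, "beta2": 0.0, "beta3": 0.0,
        "beta4": 0.0, "beta5": -3.0,
    })
    noise_sd: float = 0.4
    promoter_frac: float = 0.3
    same_strand_frac: float = 0.5
    meth_se: float = 0.04  # measurement scale for methylation p-values
    region_x1_sd: float = 0.3  # spread of passenger CpGs around their region's driver
    meth_active_frac: float = 0.65  # fraction of regions with a clear methylation shift
    # qPCR cohort
    n_patients: int = 40
    qpcr_mean_ddct: float = -0.92
    qpcr_sd: float = 1.16
    qpcr_targets: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "env": (-0.92, 1.16), "gag": (-0.52, 1.30),
    })
    qpcr_reference: str = "RPL32"

    def __post_init__(self):
        for name in ("frac_intragenic_loci", "frac_nearby_loci",
                     "frac_true_de", "core_de_frac", "promoter_frac",
                     "same_strand_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_intragenic_loci + self.frac_nearby_loci > 1.0 + 1e-9:
            raise ValueError("intragenic + nearby locus fractions exceed 1")
        for name in ("de_effect_sd", "tool_noise_sd", "noise_sd", "qpcr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_GENE_LEN = (2_000, 20_000)
_LOCUS_LEN = (500, 5_000)
_NEARBY_GAP_MAX = 40_000
_ISOLATION = 50_000


def _rng(cfg: SimulationConfig, rng: Optional[np.random.Generator],
         salt: int) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def simulate_layout(cfg: SimulationConfig,
                    rng: Optional[np.random.Generator] = None,
                    ) -> Tuple[List[GenomicFeature], List[GenomicFeature], Dict]:
    """Place genes and loci on one synthetic chromosome.

    Genes sit on a regular grid with ample spacing; each locus is placed
    strictly inside a partner gene, within 1-40,000 bp of one, or more
    than 50,000 bp from every gene, per the configured fractions. The
    truth table records each locus's intended relation and partner.
    """
    rng = _rng(cfg, rng, 1)
    spacing = cfg.chrom_length // (cfg.n_genes + 1)
    needed = _GENE_LEN[1] + 2 * _ISOLATION + _LOCUS_LEN[1] + 30_000
    if spacing < needed:
        raise ValueError(
            f"infeasible packing: {cfg.n_genes} genes on a "
            f"{cfg.chrom_length} bp chromosome leave {spacing} bp spacing, "
            f"need >= {needed}"
        )
    if cfg.n_loci > cfg.n_genes:
        raise ValueError("infeasible packing: more loci than partner genes")

    genes: List[GenomicFeature] = []
    for i in range(cfg.n_genes):
        start = (i + 1) * spacing
        length = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GenomicFeature(
            feature_id=f"G{i:04d}", kind="gene", chrom=cfg.chrom_name,
            start=start, end=start + length - 1, strand=strand,
            biotype="protein_coding",
            tss=start if strand == "+" else start + length - 1,
        ))

    n_intra = int(round(cfg.frac_intragenic_loci * cfg.n_loci))
    n_near = int(round(cfg.frac_nearby_loci * cfg.n_loci))
    n_near = min(n_near, cfg.n_loci - n_intra)
    relations = (["intragenic"] * n_intra + ["nearby"] * n_near
                 + ["isolated"] * (cfg.n_loci - n_intra - n_near))
    partner_idx = rng.permutation(cfg.n_genes)[:cfg.n_loci]

    loci: List[GenomicFeature] = []
    truth: Dict[str, Dict] = {}
    for j, relation in enumerate(relations):
        gene = genes[partner_idx[j]]
        if relation == "intragenic":
            length = int(rng.integers(_LOCUS_LEN[0],
                                      min(_LOCUS_LEN[1], gene.length) + 1))
            start = int(rng.integers(gene.start, gene.end - length + 2))
            gap = 0
        elif relation == "nearby":
            length = int(rng.integers(_LOCUS_LEN[0], _LOCUS_LEN[1] + 1))
            gap = int(rng.integers(1, _NEARBY_GAP_MAX + 1))
            start = gene.end + 1 + gap
        else:
            length = int(rng.integers(_LOCUS_LEN[0], _LOCUS_LEN[1] + 1))
            start = gene.end + _ISOLATION + 10_000 + int(
                rng.integers(0, spacing - needed + 1))
            gap = None
        if relation == "isolated":
            strand = "+" if rng.random() < 0.5 else "-"
        elif rng.random() < cfg.same_strand_frac:
            strand = gene.strand
        else:
            strand = "+" if gene.strand == "-" else "-"
        locus_id = f"HML-2_S{j:03d}"
        loci.append(GenomicFeature(
            feature_id=locus_id, kind="locus", chrom=cfg.chrom_name,
            start=start, end=start + length - 1, strand=strand,
        ))
        truth[locus_id] = {
            "relation": relation,
            "partner_gene": None if relation == "isolated" else gene.feature_id,
            "gap_bp": gap,
            "same_strand": None if relation == "isolated"
            else strand == gene.strand,
        }
    return genes, loci, truth


def _true_effects(cfg: SimulationConfig, feature_ids: Sequence[str],
                  rng: np.random.Generator) -> Tuple[Dict[str, float], List[str]]:
    effects: Dict[str, float] = {}
    core: List[str] = []
    for fid in feature_ids:
        if rng.random() >= cfg.frac_true_de:
            effects[fid] = 0.0
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if rng.random() < cfg.core_de_frac:
            mag = 1.0 + abs(rng.normal(0.0, cfg.de_effect_sd))
            core.append(fid)
        else:
            mag = abs(rng.normal(0.0, cfg.de_effect_sd))
        effects[fid] = sign * mag
    return effects, core


def simulate_de_tables(cfg: SimulationConfig,
                       feature_ids: Sequence[str],
                       tools: Sequence[str] = ("toolA", "toolB", "toolC"),
                       true_lfc: Optional[Dict[str, float]] = None,
                       subtype: str = "CMS1",
                       rng: Optional[np.random.Generator] = None,
                       ) -> Tuple[Dict[str, List[DEResult]], Dict]:
    """Per-tool DE tables under the additive measurement-noise model.

    Each tool observes the true log2FC plus independent Normal noise;
    p-values come from a z-test of the observation against the tool noise
    scale and are BH-adjusted per tool. ``true_lfc`` overrides the internal
    effect model (used to wire coupling-derived expression into the tables).
    """
    rng = _rng(cfg, rng, 2)
    if true_lfc is None:
        effects, core = _true_effects(cfg, feature_ids, rng)
    else:
        effects = {fid: true_lfc.get(fid, 0.0) for fid in feature_ids}
        core = [fid for fid, e in effects.items() if abs(e) >= 1.0]
    eff = np.array([effects[fid] for fid in feature_ids])
    sd = cfg.tool_noise_sd

    tables: Dict[str, List[DEResult]] = {}
    for tool in tools:
        obs = eff + rng.normal(0.0, sd, size=len(eff)) if sd > 0 else eff.copy()
        if sd > 0:
            pvals = 2.0 * sps.norm.sf(np.abs(obs) / sd)
        else:
            pvals = np.where(obs != 0.0, 0.0, 1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        tables[tool] = [
            DEResult(feature_id=fid, log2fc=float(obs[i]),
                     pvalue=float(pvals[i]), padj=float(padj[i]),
                     tool=tool, subtype=subtype)
            for i, fid in enumerate(feature_ids)
        ]
    var_true = float(np.var(eff))
    truth = {
        "true_lfc": effects,
        "core_de": core,
        "expected_pearson_r": var_true / (var_true + sd ** 2)
        if var_true + sd ** 2 > 0 else float("nan"),
        "tool_noise_sd": sd,
    }
    return tables, truth


def _draw_x1(cfg: SimulationConfig, rng: np.random.Generator,
             active_prob: float = 0.8) -> float:
    """Differential-methylation mixture: mostly clear effects beyond the
    +/-0.1 filter threshold, some near-zero null sites."""
    if rng.random() < active_prob:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * (0.15 + abs(rng.normal(0.0, 0.6)))
    return float(rng.normal(0.0, 0.03))


def _forward_y(cfg: SimulationConfig, kind: str, x1: float, x2: int,
               x3: Optional[int], rng: np.random.Generator) -> float:
    if kind == "cpg_locus":
        b = cfg.coupling_beta
        mu = (b.get("beta0", 0.0) + b.get("beta1", 0.0) * x1
              + b.get("beta2", 0.0) * x2 + b.get("beta3", 0.0) * x1 * x2)
    else:
        b = cfg.gene_coupling_beta
        mu = (b.get("beta0", 0.0) + b.get("beta1", 0.0) * x1
              + b.get("beta2", 0.0) * x2 + b.get("beta3", 0.0) * (x3 or 0)
              + b.get("beta4", 0.0) * x1 * x2
              + b.get("beta5", 0.0) * x1 * (x3 or 0))
    if cfg.noise_sd > 0:
        mu += rng.normal(0.0, cfg.noise_sd)
    return mu


def simulate_pairs(cfg: SimulationConfig, n: int, kind: str = "cpg_locus",
                   rng: Optional[np.random.Generator] = None,
                   ) -> List[PairRecord]:
    """Independent design-variable pairs from the interaction forward model.

    Each pair has its own synthetic CpG and partner id, X2 ~
    Bernoulli(same_strand_frac), X3 ~ Bernoulli(promoter_frac) for gene
    pairs, and Y from the configured coefficients plus Normal(0, noise_sd).
    """
    if kind not in ("cpg_locus", "cpg_gene"):
        raise ValueError(f"unknown pair kind {kind!r}")
    rng = _rng(cfg, rng, 3)
    pairs: List[PairRecord] = []
    for i in range(n):
        x1 = _draw_x1(cfg, rng, active_prob=1.0)
        x2 = int(rng.random() < cfg.same_strand_frac)
        x3 = int(rng.random() < cfg.promoter_frac) if kind == "cpg_gene" else None
        y = _forward_y(cfg, kind, x1, x2, x3, rng)
        pairs.append(PairRecord(
            pair_kind=kind, cpg_id=f"cg{i:06d}", partner_id=f"P{i:05d}",
            X1=x1, X2=x2, X3=x3, Y=y,
            distance_bp=int(rng.integers(0, 3000)),
        ))
    return pairs


def simulate_methylation(cfg: SimulationConfig,
                         genes: Sequence[GenomicFeature],
                         loci: Sequence[GenomicFeature],
                         rng: Optional[np.random.Generator] = None,
                         ) -> Tuple[List[CpGSite], Dict[str, float], Dict]:
    """CpG sites geometrically coupled to genes and loci.

    Every partner receives ``cpgs_per_gene`` / ``cpgs_per_locus`` CpGs
    inside its pairing window; the first ("driver") feeds the forward
    model for the partner's true expression log2FC (returned for wiring
    into DE tables), the rest carry independent methylation effects, as on
    a real array where several probes tile one region. Remaining probes
    are null background scattered over the chromosome. Gene CpGs land in
    the TSS200 promoter zone with probability promoter_frac, recorded in
    the manifest.
    """
    rng = _rng(cfg, rng, 4)
    sites_raw: List[Dict] = []
    partner_lfc: Dict[str, float] = {}
    truth: Dict[str, Dict] = {}
    k = 0

    def _gene_site(gene, driver: bool, driver_x1=None):
        nonlocal k
        # passenger probes track their region's methylation state
        x1 = (_draw_x1(cfg, rng, active_prob=cfg.meth_active_frac) if driver
              else float(driver_x1 + rng.normal(0.0, cfg.region_x1_sd)))
        same = rng.random() < cfg.same_strand_frac
        strand = gene.strand if same else ("+" if gene.strand == "-" else "-")
        in_promoter = rng.random() < cfg.promoter_frac
        if in_promoter:
            if gene.strand == "+":
                pos = int(rng.integers(max(1, gene.tss - 200), gene.tss))
            else:
                pos = int(rng.integers(gene.tss + 1, gene.tss + 201))
        else:
            pos = int(rng.integers(max(1, gene.start - 3_000), gene.end + 3_001))
        if driver:
            y = _forward_y(cfg, "cpg_gene", x1, int(same), int(in_promoter), rng)
            partner_lfc[gene.feature_id] = y
        cpg_id = f"cg{k:06d}"
        k += 1
        sites_raw.append(dict(
            cpg_id=cpg_id, position=pos, x1=x1, strand=strand,
            promoter_of=frozenset({gene.feature_id}) if in_promoter else frozenset(),
        ))
        truth[cpg_id] = {"driver_of": gene.feature_id if driver else None,
                         "near": gene.feature_id, "kind": "gene",
                         "same_strand": same, "promoter": in_promoter}
        return x1

    def _locus_site(locus, driver: bool, driver_x1=None):
        nonlocal k
        x1 = (_draw_x1(cfg, rng, active_prob=cfg.meth_active_frac) if driver
              else float(driver_x1 + rng.normal(0.0, cfg.region_x1_sd)))
        same = rng.random() < cfg.same_strand_frac
        strand = locus.strand if same else ("+" if locus.strand == "-" else "-")
        if driver:
            pos = int(rng.integers(locus.start, locus.end + 1))
            y = _forward_y(cfg, "cpg_locus", x1, int(same), None, rng)
            partner_lfc[locus.feature_id] = y
        else:
            pos = int(rng.integers(max(1, locus.start - 10_000),
                                   locus.end + 10_001))
        cpg_id = f"cg{k:06d}"
        k += 1
        sites_raw.append(dict(cpg_id=cpg_id, position=pos, x1=x1,
                              strand=strand, promoter_of=frozenset()))
        truth[cpg_id] = {"driver_of": locus.feature_id if driver else None,
                         "near": locus.feature_id, "kind": "locus",
                         "same_strand": same, "promoter": False}
        return x1

    for gene in genes:
        dx1 = _gene_site(gene, driver=True)
        for _ in range(max(1, cfg.cpgs_per_gene) - 1):
            _gene_site(gene, driver=False, driver_x1=dx1)
    for locus in loci:
        dx1 = _locus_site(locus, driver=True)
        for _ in range(max(1, cfg.cpgs_per_locus) - 1):
            _locus_site(locus, driver=False, driver_x1=dx1)

    n_background = max(0, cfg.n_cpgs - k)
    for _ in range(n_background):
        cpg_id = f"cg{k:06d}"
        k += 1
        sites_raw.append(dict(
            cpg_id=cpg_id,
            position=int(rng.integers(1, cfg.chrom_length + 1)),
            x1=float(rng.normal(0.0, 0.03)),
            strand="+" if rng.random() < 0.5 else "-",
            promoter_of=frozenset(),
        ))
        truth[cpg_id] = {"driver_of": None, "near": None, "kind": "background",
                         "same_strand": None, "promoter": False}

    x1s = np.array([s["x1"] for s in sites_raw])
    pvals = 2.0 * sps.norm.sf(np.abs(x1s) / cfg.meth_se)
    padj = multipletests(pvals, method="fdr_bh")[1]
    betas_n = rng.uniform(0.1, 0.9, size=len(sites_raw))
    sites = [
        CpGSite(
            cpg_id=s["cpg_id"], chrom=cfg.chrom_name, position=s["position"],
            meth_log2fc=float(s["x1"]), pvalue=float(pvals[i]),
            padj=float(padj[i]),
            beta_normal=float(betas_n[i]),
            beta_tumor=float(np.clip(betas_n[i] * 2.0 ** s["x1"], 0.0, 1.0)),
            promoter_of=s["promoter_of"], strand=s["strand"],
        )
        for i, s in enumerate(sites_raw)
    ]
    return sites, partner_lfc, truth


def simulate_qpcr(cfg: SimulationConfig,
                  rng: Optional[np.random.Generator] = None,
                  ) -> Tuple[List[QPCRMeasurement], Dict]:
    """Paired tumor/normal Ct measurements per patient and target.

    Per patient, the normal-tissue dCt is drawn around 5 cycles and the
    tumor dCt offset by ddCt ~ Normal(qpcr_mean_ddct, qpcr_sd); reference
    Cts hover near 20 cycles.
    """
    rng = _rng(cfg, rng, 5)
    out: List[QPCRMeasurement] = []
    truth: Dict[str, Dict] = {}
    targets = cfg.qpcr_targets or {"target": (cfg.qpcr_mean_ddct, cfg.qpcr_sd)}
    for target, (mean_ddct, sd_ddct) in sorted(targets.items()):
        ddcts = []
        for p in range(cfg.n_patients):
            pid = f"P{p:03d}"
            dct_n = rng.normal(5.0, 1.0)
            ddct = rng.normal(mean_ddct, sd_ddct) if sd_ddct > 0 else mean_ddct
            dct_t = dct_n + ddct
            for tissue, dct in (("normal", dct_n), ("tumor", dct_t)):
                ct_ref = rng.normal(20.0, 0.15)
                out.append(QPCRMeasurement(
                    patient_id=pid, tissue=tissue, target=target,
                    ct_target=ct_ref + dct, ct_reference=ct_ref,
                ))
            ddcts.append(ddct)
        truth[target] = {"mean_ddct": mean_ddct, "sd_ddct": sd_ddct,
                         "realized_mean_ddct": float(np.mean(ddcts))}
    return out, truth


# ---------------------------------------------------------------------------
# file export


def write_methylation_tsv(sites: Sequence[CpGSite], path) -> None:
    pd.DataFrame({
        "cpg_id": [s.cpg_id for s in sites],
        "log2FoldChange": [s.meth_log2fc for s in sites],
        "pvalue": [s.pvalue for s in sites],
        "padj": [s.padj for s in sites],
        "beta_tumor": [s.beta_tumor for s in sites],
        "beta_normal": [s.beta_normal for s in sites],
    }).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def write_manifest_tsv(sites: Sequence[CpGSite], path) -> None:
    pd.DataFrame({
        "cpg_id": [s.cpg_id for s in sites],
        "chrom": [s.chrom for s in sites],
        "position": [s.position for s in sites],
        "strand": [s.strand for s in sites],
        "TSS200": [";".join(sorted(s.promoter_of)) for s in sites],
    }).to_csv(path, sep="\t", index=False)


def write_qpcr_csv(measurements: Sequence[QPCRMeasurement], path,
                   reference: str = "RPL32") -> None:
    rows = []
    for m in measurements:
        rows.append((m.patient_id, m.tissue, m.target, m.target, m.ct_target))
        rows.append((m.patient_id, m.tissue, m.target, reference, m.ct_reference))
    pd.DataFrame(rows, columns=["patient_id", "tissue", "target", "gene", "ct"]
                 ).to_csv(path, index=False, float_format="%.10g")


def simulate_all(cfg: SimulationConfig, outdir,
                 subtype: str = "CMS1") -> Dict[str, str]:
    """Generate and write a complete coherent synthetic dataset.

    Partner expression log2FCs derived from the methylation forward model
    feed the per-tool locus DE tables and the gene DE table, so consensus
    calling, association and coupling all see one consistent world.
    Returns the mapping of logical names to file paths.
    """
    os.makedirs(outdir, exist_ok=True)
    genes, loci, layout_truth = simulate_layout(cfg)
    sites, partner_lfc, meth_truth = simulate_methylation(cfg, genes, loci)
    locus_lfc = {f.feature_id: partner_lfc[f.feature_id] for f in loci}
    gene_lfc = {f.feature_id: partner_lfc[f.feature_id] for f in genes}
    locus_tables, locus_de_truth = simulate_de_tables(
        cfg, [f.feature_id for f in loci], true_lfc=locus_lfc, subtype=subtype)
    gene_tables, gene_de_truth = simulate_de_tables(
        cfg, [f.feature_id for f in genes], tools=("generic",),
        true_lfc=gene_lfc, subtype=subtype,
        rng=_rng(cfg, None, 6))

    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_gtf(genes, _p("genes.gtf"))
    write_locus_bed(loci, _p("loci.bed"))
    for tool, table in locus_tables.items():
        write_de_table(table, _p(f"de_loci_{tool}.tsv"))
    write_de_table(gene_tables["generic"], _p("de_genes.tsv"))
    write_methylation_tsv(sites, _p("meth.tsv"))
    write_manifest_tsv(sites, _p("manifest.tsv"))
    qpcr_meas, qpcr_truth = simulate_qpcr(cfg)
    write_qpcr_csv(qpcr_meas, _p("qpcr.csv"), reference=cfg.qpcr_reference)

    truth = {
        "config": dataclasses.asdict(cfg),
        "layout": layout_truth,
        "methylation": meth_truth,
        "locus_de": _jsonable(locus_de_truth),
        "gene_de": _jsonable(gene_de_truth),
        "qpcr": qpcr_truth,
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
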