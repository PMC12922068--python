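"""CpG methylation-expression coupling: pairing, filtering, correlation,
and strand/promoter interaction regressions.

CpG sites are paired geometrically with genes (site within +/-3000 bp of
the gene body by default) or with retroelement loci (+/-10,000 bp). Pairs
surviving effect-size and significance filters enter:

* a Spearman rank correlation between differential methylation (X1) and
  the partner's differential expression (Y), and
* ordinary-least-squares interaction models

      locus model:  Y = b0 + b1*X1 + b2*X2 + b3*X1*X2 + e
      gene model:   Y = b0 + b1*X1 + b2*X2 + b3*X3 + b4*X1*X2 + b5*X1*X3 + e

  where X2 indicates same-strand location of the CpG and its partner and
  X3 indicates that the CpG lies in the partner gene's promoter (TSS200).
  When any design column is constant (e.g. every pair same-strand) the
  model is reported as not applicable rather than fitted on a rank-
  deficient design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .features import CpGSite, DEResult, FilterConfig, GenomicFeature

__all__ = [
    "PairRecord",
    "CorrelationResult",
    "RegressionResult",
    "PairFilterReport",
    "aggregate_promoter_beta",
    "pair_cpg_gene",
    "pair_cpg_locus",
    "filter_pairs",
    "spearman_coupling",
    "fit_locus_model",
    "fit_gene_model",
]

DEFAULT_GENE_WINDOW = 3_000
DEFAULT_LOCUS_WINDOW = 10_000

EQ6_TERMS = ("const", "X1", "X2", "X1:X2")
EQ7_TERMS = ("const", "X1", "X2", "X3", "X1:X2", "X1:X3")


@dataclass(frozen=True)
class PairRecord:
    """One CpG-partner pair with the regression design variables.

    ``Y`` (partner expression log2FC) is None until the pair is joined to a
    DE table by :func:`filter_pairs`. ``X3`` is None for locus pairs.
    """

    pair_kind: str  # "cpg_gene" | "cpg_locus"
    cpg_id: str
    partner_id: str
    X1: float
    X2: int
    X3: Optional[int] = None
    Y: Optional[float] = None
    distance_bp: int = 0

    def __post_init__(self):
        if self.pair_kind == "cpg_locus" and self.X3 is not None:
            raise ValueError("cpg_locus pairs carry no promoter indicator X3")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    n_pairs: int
    n_unique_cpgs: int
    n_unique_partners: int
    defined: bool = True


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of the locus (4-term) or gene (6-term) interaction model."""

    model: str  # "locus" | "gene"
    coefficients: Dict[str, Tuple[float, float, float, float]]  # est, se, t, p
    n_pairs: int
    residual_sd: float
    applicable: bool
    inapplicability_reason: Optional[str] = None
    promoter_sign_flip: Optional[bool] = None

    def estimate(self, term: str) -> float:
        return self.coefficients[term][0]

    def se(self, term: str) -> float:
        return self.coefficients[term][1]

    def pvalue(self, term: str) -> float:
        return self.coefficients[term][3]


@dataclass
class PairFilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_no_de_record: int = 0
    n_failed_meth: int = 0
    n_failed_expr: int = 0
    n_not_in_consensus: int = 0


def aggregate_promoter_beta(sites: Sequence[CpGSite],
                            which: str = "tumor") -> Dict[str, float]:
    """Per-gene arithmetic mean of promoter (TSS200) CpG beta-values.

    Genes without any promoter site are absent from the result. Sites
    lacking the requested beta channel are skipped.
    """
    if which not in ("tumor", "normal"):
        raise ValueError("which must be 'tumor' or 'normal'")
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for site in sites:
        beta = site.beta_tumor if which == "tumor" else site.beta_normal
        if beta is None:
            continue
        if not (0.0 <= beta <= 1.0):
            raise ValueError(f"beta-value of site {site.cpg_id} outside [0, 1]: {beta}")
        for gid in site.promoter_of:
            sums[gid] = sums.get(gid, 0.0) + beta
            counts[gid] = counts.get(gid, 0) + 1
    return {gid: sums[gid] / counts[gid] for gid in sums}


def _distance_to_interval(pos: int, start: int, end: int) -> int:
    return max(0, start - pos, pos - end)


def _pair(sites: Sequence[CpGSite], partners: Sequence[GenomicFeature],
          window: int, kind: str) -> List[PairRecord]:
    by_chrom: Dict[str, List[GenomicFeature]] = {}
    for p in partners:
        by_chrom.setdefault(p.chrom, []).append(p)
    pairs: List[PairRecord] = []
    for site in sites:
        for partner in by_chrom.get(site.chrom, ()):
            d = _distance_to_interval(site.position, partner.start, partner.end)
            if d > window:
                continue
            x2 = 1 if site.strand == partner.strand else 0
            x3 = None
            if kind == "cpg_gene":
                x3 = 1 if partner.feature_id in site.promoter_of else 0
            pairs.append(PairRecord(
                pair_kind=kind,
                cpg_id=site.cpg_id,
                partner_id=partner.feature_id,
                X1=site.meth_log2fc,
                X2=x2,
                X3=x3,
                distance_bp=d,
            ))
    return pairs


def pair_cpg_gene(sites: Sequence[CpGSite], genes: Sequence[GenomicFeature],
                  window: int = DEFAULT_GENE_WINDOW) -> List[PairRecord]:
    """Pair each CpG with every gene whose body +/- window contains it.

    The promoter indicator X3 comes from the manifest's TSS200 membership
    (authoritative over geometry); X2 compares probe strand with gene
    strand.
    """
    return _pair(sites, genes, window, "cpg_gene")


def pair_cpg_locus(sites: Sequence[CpGSite], loci: Sequence[GenomicFeature],
                   window: int = DEFAULT_LOCUS_WINDOW) -> List[PairRecord]:
    """Pair each CpG with every retroelement locus within the window."""
    return _pair(sites, loci, window, "cpg_locus")


def filter_pairs(pairs: Sequence[PairRecord],
                 cpg_table: Sequence[CpGSite],
                 partner_de: Sequence[DEResult],
                 cfg: FilterConfig = FilterConfig(),
                 consensus: Optional[Set[str]] = None,
                 report: Optional[PairFilterReport] = None) -> List[PairRecord]:
    """Apply effect-size and significance filters and attach Y.

    A pair survives iff |X1| > meth_lfc_min with methylation significance
    < meth_alpha AND its partner's |log2FC| > expr_lfc_min with expression
    significance < expr_alpha (all inequalities strict). When a consensus
    locus set is supplied, the partner must belong to it. Pairs whose
    partner lacks a DE record are dropped and counted. Idempotent.
    """
    site_map = {s.cpg_id: s for s in cpg_table}
    de_map = {d.feature_id: d for d in partner_de}
    rep = report if report is not None else PairFilterReport()
    rep.n_input += len(pairs)
    out: List[PairRecord] = []
    for pair in pairs:
        site = site_map.get(pair.cpg_id)
        if site is None:
            rep.n_failed_meth += 1
            continue
        meth_p = site.padj if cfg.use_adjusted_meth_p else site.pvalue
        if meth_p is None or not (meth_p < cfg.meth_alpha):
            rep.n_failed_meth += 1
            continue
        if not (abs(pair.X1) > cfg.meth_lfc_min):
            rep.n_failed_meth += 1
            continue
        de = de_map.get(pair.partner_id)
        if de is None:
            rep.n_no_de_record += 1
            continue
        if consensus is not None and pair.partner_id not in consensus:
            rep.n_not_in_consensus += 1
            continue
        expr_p = de.padj if cfg.use_adjusted_expr_p else de.pvalue
        if expr_p is None or not (expr_p < cfg.expr_alpha):
            rep.n_failed_expr += 1
            continue
        if not (abs(de.log2fc) > cfg.expr_lfc_min):
            rep.n_failed_expr += 1
            continue
        out.append(replace(pair, Y=de.log2fc))
        rep.n_kept += 1
    return out


def spearman_coupling(pairs: Sequence[PairRecord],
                      exact_max_n: int = 10) -> CorrelationResult:
    """Spearman correlation between X1 (methylation) and Y (expression).

    Ties get midranks. The two-sided p-value uses the t approximation for
    n > ``exact_max_n`` and exact enumeration of all pairings otherwise.
    Constant X1 or Y leaves rho undefined (flagged, not raised).
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 pairs for a correlation test, got {n}")
    if any(p.Y is None for p in pairs):
        raise ValueError("pairs must carry Y (run filter_pairs first)")
    x = np.array([p.X1 for p in pairs], dtype=float)
    y = np.array([p.Y for p in pairs], dtype=float)
    n_cpg = len({p.cpg_id for p in pairs})
    n_partner = len({p.partner_id for p in pairs})
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CorrelationResult(math.nan, math.nan, n, n_cpg, n_partner,
                                 defined=False)
    if n <= exact_max_n:
        rho, pval = _exact_spearman(x, y)
    else:
        res = stats.spearmanr(x, y)
        rho, pval = float(res.statistic), float(res.pvalue)
    return CorrelationResult(rho, pval, n, n_cpg, n_partner)


def _exact_spearman(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Exact permutation p-value for Spearman rho at small n (<= 10).

    Enumerates all n! pairings of the midranked vectors; the p-value is the
    fraction of pairings with |rho| >= |observed| (two-sided)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    observed = float(np.mean(rx * ry))
    count = 0
    total = 0
    perms = itertools.permutations(range(n))
    chunk_size = 40_320  # 8! pairings per vectorized batch
    while True:
        chunk = list(itertools.islice(perms, chunk_size))
        if not chunk:
            break
        idx = np.array(chunk, dtype=np.intp)
        rhos = ry[idx] @ rx / n
        count += int(np.sum(np.abs(rhos) >= abs(observed) - 1e-12))
        total += len(chunk)
    return observed, count / total


def _design(pairs: Sequence[PairRecord], terms: Tuple[str, ...]) -> np.ndarray:
    x1 = np.array([p.X1 for p in pairs], dtype=float)
    x2 = np.array([p.X2 for p in pairs], dtype=float)
    cols = {"const": np.ones(len(pairs)), "X1": x1, "X2": x2, "X1:X2": x1 * x2}
    if "X3" in terms:
        x3 = np.array([p.X3 for p in pairs], dtype=float)
        cols["X3"] = x3
        cols["X1:X3"] = x1 * x3
    return np.column_stack([cols[t] for t in terms])


def _not_applicable(model: str, n: int, reason: str) -> RegressionResult:
    return RegressionResult(
        model=model, coefficients={}, n_pairs=n, residual_sd=math.nan,
        applicable=False, inapplicability_reason=reason,
    )


def _fit_ols(pairs: Sequence[PairRecord], model: str,
             terms: Tuple[str, ...], min_n: int) -> RegressionResult:
    n = len(pairs)
    if n < min_n:
        return _not_applicable(model, n, f"fewer than {min_n} pairs (n={n})")
    if any(p.Y is None for p in pairs):
        raise ValueError("pairs must carry Y (run filter_pairs first)")
    X = _design(pairs, terms)
    for j, term in enumerate(terms):
        if term != "const" and np.ptp(X[:, j]) == 0.0:
            return _not_applicable(
                model, n, f"design column {term} is constant "
                f"(all pairs share the same value)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _not_applicable(model, n, "rank-deficient design matrix")
    y = np.array([p.Y for p in pairs], dtype=float)
    fit = sm.OLS(y, X).fit()
    coeffs = {
        term: (float(fit.params[j]), float(fit.bse[j]),
               float(fit.tvalues[j]), float(fit.pvalues[j]))
        for j, term in enumerate(terms)
    }
    resid_sd = float(np.sqrt(fit.ssr / fit.df_resid)) if fit.df_resid > 0 else math.nan
    flip = None
    if "X1:X3" in terms:
        b1 = coeffs["X1"][0]
        slope_promoter = b1 + coeffs["X1:X3"][0]
        flip = (b1 > 0) != (slope_promoter > 0) and b1 != 0 and slope_promoter != 0
    return RegressionResult(
        model=model, coefficients=coeffs, n_pairs=n, residual_sd=resid_sd,
        applicable=True, promoter_sign_flip=flip,
    )


def fit_locus_model(pairs: Sequence[PairRecord]) -> RegressionResult:
    """OLS of Y on X1, X2 and their interaction for CpG-locus pairs.

    When every pair lies on the same strand (X2 constant) — the situation
    observed when all filtered pairs share a chain — the model is reported
    as not applicable instead of being fitted.
    """
    if any(p.pair_kind != "cpg_locus" for p in pairs):
        raise ValueError("fit_locus_model expects cpg_locus pairs")
    return _fit_ols(pairs, "locus", EQ6_TERMS, min_n=5)


def fit_gene_model(pairs: Sequence[PairRecord]) -> RegressionResult:
    """OLS of Y on X1, X2, X3 and interactions for CpG-gene pairs.

    ``promoter_sign_flip`` reports whether the promoter interaction changes
    the sign of the methylation slope (slope b1 outside promoters vs
    b1 + b5 inside). Constant X3 (e.g. no promoter CpGs at all) makes the
    model not applicable; callers may fall back to the reduced locus-style
    model.
    """
    if any(p.pair_kind != "cpg_gene" for p in pairs):
        raise ValueError("fit_gene_model expects cpg_gene pairs")
    return _fit_ols(pairs, "gene", EQ7_TERMS, min_n=7)
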