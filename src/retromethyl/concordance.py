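"""Cross-tool agreement statistics and consensus locus selection.

Per-tool differential-expression calls are reduced to three nominal
categories (up / down / not significant); agreement between tools is then
scored with the unweighted Cohen's kappa

    kappa = (P0 - Pe) / (1 - Pe)

where P0 is the observed fraction of matching categories and Pe the
agreement expected by chance from the two raters' marginals. Pearson r and
R^2 on the continuous log2 fold changes complement kappa. Consensus rules
select loci called concordantly across tools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .features import DEResult

__all__ = [
    "CATEGORIES",
    "CallCategory",
    "AgreementResult",
    "ConsensusPolicy",
    "ConsensusCall",
    "categorize",
    "categorize_table",
    "cohen_kappa",
    "pairwise_agreement",
    "consensus_select",
    "subtype_venn",
]

CATEGORIES = ("up", "down", "ns")


@dataclass(frozen=True)
class CallCategory:
    feature_id: str
    category: str  # "up" | "down" | "ns"


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between one unordered pair of tools."""

    tool_pair: Tuple[str, str]
    kappa: float
    p0: float
    pe: float
    pearson_r: float
    r_squared: float
    n_features: int
    computable: bool = True
    degenerate: bool = False


@dataclass(frozen=True)
class ConsensusPolicy:
    """Rule for cross-tool consensus.

    ``all_significant_two_lfc``: significant (padj < alpha) in every tool
    and |log2FC| >= lfc_min in at least two tools.
    ``anchor_plus_one``: passes significance and fold change in the anchor
    tool and in at least one other tool.
    """

    mode: str = "all_significant_two_lfc"
    alpha: float = 0.05
    lfc_min: float = 1.0
    anchor_tool: Optional[str] = None

    def __post_init__(self):
        if self.mode not in ("all_significant_two_lfc", "anchor_plus_one"):
            raise ValueError(f"unknown consensus mode {self.mode!r}")
        if self.mode == "anchor_plus_one" and self.anchor_tool is None:
            raise ValueError("anchor_plus_one mode requires anchor_tool")


@dataclass(frozen=True)
class ConsensusCall:
    feature_id: str
    direction: str  # "up" | "down"


def categorize(de: DEResult, alpha: float = 0.05, lfc_min: float = 1.0) -> CallCategory:
    """Reduce one DE result to an up/down/ns call.

    Boundary conventions follow the selection rule used throughout:
    |log2FC| >= lfc_min is inclusive, padj < alpha is strict, and a missing
    adjusted p-value is not significant.
    """
    if alpha <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    if de.padj is None or not (de.padj < alpha):
        cat = "ns"
    elif de.log2fc >= lfc_min:
        cat = "up"
    elif de.log2fc <= -lfc_min:
        cat = "down"
    else:
        cat = "ns"
    return CallCategory(de.feature_id, cat)


def categorize_table(table: Iterable[DEResult], alpha: float = 0.05,
                     lfc_min: float = 1.0) -> List[CallCategory]:
    return [categorize(de, alpha, lfc_min) for de in table]


def cohen_kappa(calls_a: Sequence[CallCategory],
                calls_b: Sequence[CallCategory]) -> Tuple[float, float, float, bool]:
    """Unweighted multi-category Cohen's kappa over matched features.

    Returns (kappa, p0, pe, degenerate). Calls are matched by feature_id;
    features present in only one list raise an error when none are shared.
    When both raters are constant and identical (pe == 1) kappa is reported
    as 1 with the degenerate flag set.
    """
    a_map = {c.feature_id: c.category for c in calls_a}
    b_map = {c.feature_id: c.category for c in calls_b}
    shared = [fid for fid in a_map if fid in b_map]
    if not shared:
        raise ValueError("call lists share no feature ids")
    n = len(shared)
    if n < 2:
        raise ValueError(f"need >= 2 shared features, got {n}")
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    conf = np.zeros((3, 3), dtype=float)
    for fid in shared:
        conf[idx[a_map[fid]], idx[b_map[fid]]] += 1.0
    p0 = float(np.trace(conf)) / n
    row = conf.sum(axis=1) / n
    col = conf.sum(axis=0) / n
    pe = float(np.dot(row, col))
    if pe >= 1.0 - 1e-15:
        return 1.0, p0, pe, True
    kappa = (p0 - pe) / (1.0 - pe)
    return kappa, p0, pe, False


def pairwise_agreement(tables: Mapping[str, Sequence[DEResult]],
                       alpha: float = 0.05,
                       lfc_min: float = 1.0) -> List[AgreementResult]:
    """Pearson r / R^2 on log2FC and Cohen's kappa for every tool pair.

    The feature universe per pair is the intersection of feature ids
    quantified by both tools with non-missing log2FC. Pairs with fewer
    than 3 shared features are flagged not computable.
    """
    if len(tables) < 2:
        raise ValueError("pairwise agreement needs at least two tools")
    results = []
    for tool_a, tool_b in itertools.combinations(sorted(tables), 2):
        a_map = {d.feature_id: d for d in tables[tool_a]}
        b_map = {d.feature_id: d for d in tables[tool_b]}
        shared = [
            fid for fid in a_map
            if fid in b_map
            and not math.isnan(a_map[fid].log2fc)
            and not math.isnan(b_map[fid].log2fc)
        ]
        n = len(shared)
        if n < 3:
            results.append(AgreementResult(
                (tool_a, tool_b), math.nan, math.nan, math.nan,
                math.nan, math.nan, n, computable=False,
            ))
            continue
        x = np.array([a_map[fid].log2fc for fid in shared])
        y = np.array([b_map[fid].log2fc for fid in shared])
        if x.std() == 0.0 or y.std() == 0.0:
            r = math.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        calls_a = categorize_table([a_map[fid] for fid in shared], alpha, lfc_min)
        calls_b = categorize_table([b_map[fid] for fid in shared], alpha, lfc_min)
        kappa, p0, pe, degen = cohen_kappa(calls_a, calls_b)
        results.append(AgreementResult(
            (tool_a, tool_b), kappa, p0, pe, r,
            r * r if not math.isnan(r) else math.nan, n, degenerate=degen,
        ))
    return results


def _passes(de: DEResult, alpha: float, lfc_min: float) -> bool:
    return (de.padj is not None and de.padj < alpha
            and abs(de.log2fc) >= lfc_min)


def consensus_select(tables: Mapping[str, Sequence[DEResult]],
                     policy: ConsensusPolicy) -> List[ConsensusCall]:
    """Select consensus differentially expressed features across tools.

    Under ``all_significant_two_lfc`` a feature is kept iff padj < alpha in
    all tools and |log2FC| >= lfc_min in at least two; under
    ``anchor_plus_one`` iff it passes both thresholds in the anchor tool and
    at least one other. Direction is the shared sign of log2FC among the
    tools counted by the rule; features whose counted tools disagree in
    sign are excluded.
    """
    tools = sorted(tables)
    if policy.mode == "anchor_plus_one":
        if policy.anchor_tool not in tables:
            raise ValueError(
                f"anchor tool {policy.anchor_tool!r} not among tools {tools}"
            )
    elif len(tools) < 2:
        raise ValueError("all_significant_two_lfc requires >= 2 tools")

    maps = {t: {d.feature_id: d for d in tables[t]} for t in tools}
    out: List[ConsensusCall] = []
    all_ids = sorted(set().union(*(m.keys() for m in maps.values())))
    for fid in all_ids:
        if policy.mode == "all_significant_two_lfc":
            des = [maps[t].get(fid) for t in tools]
            if any(d is None for d in des):
                continue
            if not all(d.padj is not None and d.padj < policy.alpha for d in des):
                continue
            if sum(abs(d.log2fc) >= policy.lfc_min for d in des) < 2:
                continue
            counted = des
        else:
            anchor = maps[policy.anchor_tool].get(fid)
            if anchor is None or not _passes(anchor, policy.alpha, policy.lfc_min):
                continue
            confirming = [
                maps[t][fid] for t in tools
                if t != policy.anchor_tool and fid in maps[t]
                and _passes(maps[t][fid], policy.alpha, policy.lfc_min)
            ]
            if not confirming:
                continue
            counted = [anchor] + confirming
        signs = {1 if d.log2fc > 0 else -1 for d in counted if d.log2fc != 0}
        if len(signs) != 1:
            continue  # direction conflict (or all-zero): excluded
        out.append(ConsensusCall(fid, "up" if signs.pop() > 0 else "down"))
    return out


def subtype_venn(sets: Mapping[str, Set[str]]) -> Dict[str, Set[str]]:
    """Exclusive Venn regions across 2-4 subtype sets.

    Region labels join member subtype names with "&"; all 2^k - 1 regions
    are returned (possibly empty), they partition the union of inputs.
    """
    names = sorted(sets)
    if not (2 <= len(names) <= 4):
        raise ValueError("subtype_venn requires 2-4 sets")
    regions: Dict[str, Set[str]] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[m]) for m in members))
            for other in names:
                if other not in members:
                    inside -= set(sets[other])
            regions["&".join(members)] = inside
    return regions
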