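"""Relative qPCR quantification for paired tumor-normal samples.

Per measurement, dCt = Ct(target) - Ct(reference gene); per patient,
ddCt = dCt(tumor) - dCt(normal) and fold change = 2^-ddCt, so a negative
ddCt means elevated expression in tumor. Cohort summaries report both the
mean of per-patient fold changes and 2^-(mean ddCt); the two differ
(Jensen's inequality for the convex map 2^-x) and both are emitted.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "QPCRMeasurement",
    "QPCRSummary",
    "delta_ct",
    "fold_change",
    "summarize",
    "read_ct_table",
]


@dataclass(frozen=True)
class QPCRMeasurement:
    patient_id: str
    tissue: str  # "tumor" | "normal"
    target: str  # e.g. "gag", "env"
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor or normal, got {self.tissue!r}")
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class QPCRSummary:
    target: str
    n_pairs: int
    mean_delta_delta_ct: float
    sd_delta_delta_ct: Optional[float]  # None for a single pair
    mean_fold_change: float
    median_fold_change: float
    fold_change_of_mean: float  # 2^-(mean ddCt)
    per_patient_log2fc: List[float]
    patient_ids: List[str]


def delta_ct(m: QPCRMeasurement) -> float:
    """Ct(target) - Ct(reference) for one measurement."""
    return m.ct_target - m.ct_reference


def fold_change(tumor: QPCRMeasurement,
                normal: QPCRMeasurement) -> Tuple[float, float]:
    """(ddCt, 2^-ddCt) for a matched tumor/normal pair of one patient."""
    if tumor.patient_id != normal.patient_id or tumor.target != normal.target:
        raise ValueError(
            "unmatched pair: "
            f"({tumor.patient_id}, {tumor.target}) vs "
            f"({normal.patient_id}, {normal.target})"
        )
    if tumor.tissue != "tumor" or normal.tissue != "normal":
        raise ValueError("fold_change expects (tumor, normal) in that order")
    ddct = delta_ct(tumor) - delta_ct(normal)
    return ddct, 2.0 ** (-ddct)


def summarize(measurements: Sequence[QPCRMeasurement]) -> Dict[str, QPCRSummary]:
    """Per-target cohort summary over matched tumor/normal patient pairs.

    Patients lacking either tissue for a target are skipped. SD uses the
    sample (n-1) denominator and is None when only one pair exists.
    """
    by_key: Dict[Tuple[str, str, str], QPCRMeasurement] = {}
    for m in measurements:
        by_key[(m.target, m.patient_id, m.tissue)] = m
    targets = sorted({m.target for m in measurements})
    out: Dict[str, QPCRSummary] = {}
    for target in targets:
        patients = sorted({
            pid for (t, pid, _tis) in by_key if t == target
        })
        ddcts, fcs, pids = [], [], []
        for pid in patients:
            tm = by_key.get((target, pid, "tumor"))
            nm = by_key.get((target, pid, "normal"))
            if tm is None or nm is None:
                continue
            ddct, fc = fold_change(tm, nm)
            ddcts.append(ddct)
            fcs.append(fc)
            pids.append(pid)
        if not ddcts:
            continue
        n = len(ddcts)
        mean_ddct = sum(ddcts) / n
        out[target] = QPCRSummary(
            target=target,
            n_pairs=n,
            mean_delta_delta_ct=mean_ddct,
            sd_delta_delta_ct=statistics.stdev(ddcts) if n > 1 else None,
            mean_fold_change=sum(fcs) / n,
            median_fold_change=statistics.median(fcs),
            fold_change_of_mean=2.0 ** (-mean_ddct),
            per_patient_log2fc=[-d for d in ddcts],
            patient_ids=pids,
        )
    return out


def read_ct_table(path, reference: str = "RPL32") -> List[QPCRMeasurement]:
    """Read a long-format Ct CSV (patient_id, tissue, target, gene, ct).

    ``gene`` is the assayed gene for each well: rows where gene equals the
    reference supply Ct(reference), the rest Ct(target). Technical
    replicates (duplicate rows per patient/tissue/target/gene) are averaged
    before the dCt step. Groups missing either Ct are excluded and counted
    in the returned list's length deficit.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    needed = {"patient_id", "tissue", "target", "gene", "ct"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: List[QPCRMeasurement] = []
    grouped = df.groupby(["patient_id", "tissue", "target"], sort=True)
    for (pid, tissue, target), g in grouped:
        ref_ct = g.loc[g["gene"] == reference, "ct"]
        tgt_ct = g.loc[g["gene"] != reference, "ct"]
        if ref_ct.empty or tgt_ct.empty:
            continue
        out.append(QPCRMeasurement(
            patient_id=str(pid), tissue=str(tissue), target=str(target),
            ct_target=float(tgt_ct.mean()), ct_reference=float(ref_ct.mean()),
        ))
    return out
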