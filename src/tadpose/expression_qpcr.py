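"""Relative-expression (2^-ddCt) pipeline for qPCR Ct tables.

Target-gene Ct values are normalized to a housekeeping gene (default TBP) to
give dCt = Ct_target - Ct_housekeeping per sample; ddCt subtracts the mean
control dCt, and fold change is 2^-ddCt.  Fold changes >= 1.5 are classified
``elevated`` and <= 0.66 ``decreased`` (both bounds inclusive, as the printed
thresholds read); everything between is ``normal``.

Replicates are averaged on the Ct scale within sample x gene before
normalization (averaging 2^-ddCt per replicate instead is exposed as
``replicate_scale="fold"``).  Multiple control samples are pooled by averaging
their dCt per gene.  Genes annotated as not expressed in blood are excluded
from the pipeline, mirroring their exclusion from the assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome_model import (
    DELETED,
    DEFAULT_WINDOW,
    DISTAL,
    PARTIALLY_DELETED,
    WITHIN_WINDOW,
    Deletion,
    GeneAnnotation,
    classify_gene_vs_deletion,
)

__all__ = [
    "ELEVATED",
    "NORMAL",
    "DECREASED",
    "ExpressionThresholds",
    "QPCRResult",
    "delta_ct",
    "fold_change",
    "classify_expression",
    "status_group",
    "summarize_by_status",
    "run_qpcr_pipeline",
]

ELEVATED = "elevated"
NORMAL = "normal"
DECREASED = "decreased"

#: Status groups used for the status-stratified summary table.
GROUP_NOT_DELETED = "not_deleted"
GROUP_DELETED = "deleted"
GROUP_WITHIN_WINDOW = "within_window"
STATUS_GROUPS = (GROUP_NOT_DELETED, GROUP_DELETED, GROUP_WITHIN_WINDOW)


@dataclass(frozen=True)
class ExpressionThresholds:
    """Inclusive fold-change bounds for the elevated/decreased calls."""

    elevated: float = 1.5
    decreased: float = 0.66

    def __post_init__(self) -> None:
        if not 0 < self.decreased < self.elevated:
            raise ValueError(
                f"need 0 < decreased < elevated, got {self.decreased}, {self.elevated}"
            )


def delta_ct(ct_gene: float, ct_housekeeping: float) -> float:
    """dCt: target Ct minus housekeeping Ct (element-wise on arrays)."""
    return np.subtract(ct_gene, ct_housekeeping)


def fold_change(delta_ct_sample: float, delta_ct_control: float) -> float:
    """Relative expression 2^-(dCt_sample - dCt_control)."""
    return np.power(2.0, -(np.subtract(delta_ct_sample, delta_ct_control)))


def classify_expression(
    fold: float, thresholds: Optional[ExpressionThresholds] = None
) -> str:
    thresholds = thresholds or ExpressionThresholds()
    if not math.isfinite(fold) or fold <= 0:
        raise ValueError(f"fold change must be positive and finite, got {fold}")
    if fold >= thresholds.elevated:
        return ELEVATED
    if fold <= thresholds.decreased:
        return DECREASED
    return NORMAL


def status_group(status: str) -> str:
    """Map a gene-vs-deletion status to its summary group."""
    if status in (DELETED, PARTIALLY_DELETED):
        return GROUP_DELETED
    if status == WITHIN_WINDOW:
        return GROUP_WITHIN_WINDOW
    if status == DISTAL:
        return GROUP_NOT_DELETED
    raise ValueError(f"unknown status {status!r}")


def summarize_by_status(
    folds: pd.DataFrame, statuses: pd.DataFrame
) -> pd.DataFrame:
    """Arithmetic mean fold change per gene within each status group.

    ``folds`` needs columns (sample_id, gene_symbol, fold_change); ``statuses``
    (sample_id, gene_symbol, group) with group in ``{not_deleted, deleted,
    within_window}``.  Empty groups are reported as NaN (printed "N/A").
    """
    merged = folds.merge(statuses, on=["sample_id", "gene_symbol"], how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), ["sample_id", "gene_symbol"]]
        raise ValueError(
            "missing status for fold records: "
            + ", ".join(f"{r.sample_id}/{r.gene_symbol}" for r in missing.itertuples())
        )
    table = (
        merged.groupby(["gene_symbol", "group"])["fold_change"]
        .mean()
        .unstack("group")
        .reindex(columns=list(STATUS_GROUPS))
    )
    table.columns.name = None
    return table


@dataclass
class QPCRResult:
    """Outputs of the Ct pipeline."""

    records: pd.DataFrame  # per sample x gene: dCt, ddCt, fold, category, status
    summary: pd.DataFrame  # per-gene mean folds by status group
    matrix: pd.DataFrame  # genes x samples fold-change matrix (heat-map ready)


def _replicate_means(ct_table: pd.DataFrame) -> pd.DataFrame:
    df = ct_table.copy()
    required = {"sample_id", "gene", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if not np.isfinite(ct).all() or (ct <= 0).any():
        bad = df.loc[~np.isfinite(ct) | (ct <= 0)]
        raise ValueError(
            f"Ct values must be finite and positive; offending rows:\n{bad}"
        )
    df["ct"] = ct
    return df.groupby(["sample_id", "gene"], as_index=False)["ct"].mean()


def run_qpcr_pipeline(
    ct_table: pd.DataFrame,
    control_ids: Sequence[str],
    deletions: Sequence[Deletion],
    annotation: Sequence[GeneAnnotation],
    housekeeping: str = "TBP",
    thresholds: Optional[ExpressionThresholds] = None,
    window: int = DEFAULT_WINDOW,
    replicate_scale: str = "ct",
) -> QPCRResult:
    """Run the full dCt -> ddCt -> fold -> category pipeline.

    ``ct_table`` is long-format (sample_id, gene, replicate, ct).  Fold changes
    are computed for every sample (controls fold to ~1 against their own
    pooled mean); status-stratified summaries cover patient samples only.
    Genes absent from ``annotation`` get status ``unknown`` and are excluded
    from the summary; genes annotated as not blood-expressed are dropped.

    The genes x samples matrix orders rows by genomic coordinate and columns
    by deletion size descending (controls appended last), the layout used for
    heat-map rendering.
    """
    thresholds = thresholds or ExpressionThresholds()
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("at least one control sample is required")
    if replicate_scale not in ("ct", "fold"):
        raise ValueError("replicate_scale must be 'ct' or 'fold'")

    by_symbol = {g.symbol: g for g in annotation}
    not_in_blood = {s for s, g in by_symbol.items() if not g.expressed_in_blood}
    ct_table = ct_table[~ct_table["gene"].isin(not_in_blood)]

    means = _replicate_means(ct_table)
    wide = means.pivot(index="sample_id", columns="gene", values="ct")
    if housekeeping not in wide.columns:
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from Ct table")
    if wide[housekeeping].isna().any():
        missing = wide.index[wide[housekeeping].isna()].tolist()
        raise ValueError(
            f"samples missing housekeeping ({housekeeping}) Ct: {missing}"
        )
    dct = wide.drop(columns=[housekeeping]).sub(wide[housekeeping], axis=0)

    absent = [c for c in control_ids if c not in dct.index]
    if absent:
        raise ValueError(f"control samples absent from Ct table: {absent}")
    control_dct = dct.loc[control_ids].mean(axis=0)
    ddct = dct.sub(control_dct, axis=1)

    if replicate_scale == "ct":
        folds = np.power(2.0, -ddct)
    else:
        # Fold-scale alternative: fold per replicate against the pooled control
        # dCt, then the arithmetic mean of replicate folds per sample x gene.
        df = ct_table.copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        rep = df.groupby(["sample_id", "gene", "replicate"], as_index=False)["ct"].mean()
        wide_rep = rep.pivot_table(
            index=["sample_id", "replicate"], columns="gene", values="ct"
        )
        dct_rep = wide_rep.drop(columns=[housekeeping]).sub(
            wide_rep[housekeeping], axis=0
        )
        ddct_rep = dct_rep.sub(control_dct, axis=1)
        folds = np.power(2.0, -ddct_rep).groupby(level="sample_id").mean()
        folds = folds.reindex(index=dct.index)

    deletions_by_patient = {d.patient_id: d for d in deletions}
    # Patient columns ordered by deletion size descending; controls last.
    patient_order = sorted(
        (p for p in folds.index if p in deletions_by_patient),
        key=lambda p: -deletions_by_patient[p].interval.length,
    )
    other = [p for p in folds.index if p not in deletions_by_patient]

    records = []
    for sample_id in folds.index:
        deletion = deletions_by_patient.get(sample_id)
        for gene in folds.columns:
            fold = folds.loc[sample_id, gene]
            if pd.isna(fold):
                continue
            if sample_id in control_ids:
                status = "control"
            elif deletion is None or gene not in by_symbol:
                status = "unknown"
            else:
                status = classify_gene_vs_deletion(by_symbol[gene], deletion, window)
            records.append(
                {
                    "sample_id": sample_id,
                    "gene_symbol": gene,
                    "delta_ct": dct.loc[sample_id, gene],
                    "delta_delta_ct": ddct.loc[sample_id, gene],
                    "fold_change": fold,
                    "category": classify_expression(fold, thresholds),
                    "status": status,
                }
            )
    records = pd.DataFrame(records)

    patient_records = records[
        records["status"].isin([DELETED, PARTIALLY_DELETED, WITHIN_WINDOW, DISTAL])
    ].copy()
    patient_records["group"] = patient_records["status"].map(status_group)
    summary = summarize_by_status(
        patient_records[["sample_id", "gene_symbol", "fold_change"]],
        patient_records[["sample_id", "gene_symbol", "group"]],
    )

    gene_order = sorted(
        folds.columns,
        key=lambda g: (
            by_symbol[g].interval.start if g in by_symbol else float("inf"),
            g,
        ),
    )
    matrix = folds.T.reindex(index=gene_order, columns=patient_order + other)
    matrix.index.name = "gene_symbol"
    return QPCRResult(records=records, summary=summary, matrix=matrix)
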