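"""Candidate-gene prediction and ranking around a deletion.

The procedure evaluates, for each gene near a deletion, five pieces of
evidence: disruption of the gene's regulatory contacts by the deletion,
membership in a TAD that a breakpoint falls into, location within a flanking
window (default 2 Mb) of a breakpoint, a haploinsufficiency flag (%HI <= 10),
and phenotypic overlap with the patient above a percentile gate (default
75th).  Genes are then partitioned into candidates dysregulated *by deletion*
(the gene itself is lost, wholly or partly) and *by position effect* (the gene
is intact but its regulatory landscape is disrupted).

The combination rule is an explicit additive score::

    rank_score = w1 * min(contacts, cap)/cap + w2 * [in disrupted TAD]
               + w3 * [within window] + w4 * [HI flag]
               + w5 * [phenotype percentile > gate]

with default weights (1, 1, 1, 1, 1) and cap 5.  The source criteria do not
fix a combination rule; an additive score with deterministic tie-breaking
(distance to nearest breakpoint, then symbol) is chosen so ranked output is
reproducible and every term is auditable in the output table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .genome_model import (
    DELETED,
    DEFAULT_WINDOW,
    DISTAL,
    PARTIALLY_DELETED,
    WITHIN_WINDOW,
    Deletion,
    GeneAnnotation,
    GenomicInterval,
    RegulatoryContact,
    TADMap,
    classify_gene_vs_deletion,
    distance,
    overlaps,
    point,
)

__all__ = [
    "BY_DELETION",
    "BY_POSITION_EFFECT",
    "NOT_CANDIDATE",
    "CandidateFeatures",
    "PatientPhenotype",
    "RankingParams",
    "flanking_windows",
    "tads_disrupted",
    "disrupted_contacts",
    "phenotype_overlap",
    "percentile_rank",
    "predict_candidates",
    "aggregate_cohort",
    "candidates_to_frame",
    "write_candidates",
]

BY_DELETION = "by_deletion"
BY_POSITION_EFFECT = "by_position_effect"
NOT_CANDIDATE = "none"


@dataclass(frozen=True)
class PatientPhenotype:
    """A patient's clinical features as a set of term identifiers."""

    patient_id: str
    terms: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))


@dataclass(frozen=True)
class RankingParams:
    """Tunables of the candidate search.

    window
        Flanking-window size in bp on each side of a breakpoint (default 2 Mb).
    hi_threshold
        %HI at or below which a gene is flagged likely haploinsufficient
        (default 10).  A ranking feature, not a hard filter.
    percentile_gate
        Phenotype-overlap percentile a gene must exceed to count as
        phenotype-relevant (default 75).
    weights, contact_cap
        Additive-score weights (contacts, TAD, window, HI, phenotype) and the
        contact-count saturation.
    combine
        ``"and"`` (default): a preserved gene is a position-effect candidate if
        it is within the window AND (in a disrupted TAD OR has >= 1 disrupted
        contact).  ``"or"``: within the window OR in a disrupted TAD OR has a
        disrupted contact.
    """

    window: int = DEFAULT_WINDOW
    hi_threshold: float = 10.0
    percentile_gate: float = 75.0
    weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    contact_cap: int = 5
    combine: str = "and"

    def __post_init__(self) -> None:
        if self.combine not in ("and", "or"):
            raise ValueError(f"combine must be 'and' or 'or', got {self.combine!r}")
        if len(self.weights) != 5:
            raise ValueError("weights must have five entries")
        if self.contact_cap < 1:
            raise ValueError("contact_cap must be >= 1")


@dataclass(frozen=True)
class CandidateFeatures:
    """Per gene x patient ranking evidence."""

    gene_symbol: str
    patient_id: str
    status: str
    in_disrupted_tad: bool
    disrupted_contact_count: int
    hi_flag: bool
    phenotype_overlap: float
    phenotype_percentile: float
    rank_score: float
    candidate_class: str
    breakpoint_distance: int
    hi_score: Optional[float] = None


def flanking_windows(
    deletion: Deletion, window: int = DEFAULT_WINDOW
) -> list[GenomicInterval]:
    """Windows of up to ``window`` bp on either side of the breakpoints.

    The proximal window ``[start - window, start]`` is clipped at position 1;
    the distal window ``[end, end + window]`` is omitted for terminal
    deletions (nothing lies beyond the chromosome end).
    """
    iv = deletion.interval
    out = [GenomicInterval(iv.chrom, max(1, iv.start - window), iv.start)]
    if not deletion.terminal:
        out.append(GenomicInterval(iv.chrom, iv.end, iv.end + window))
    return out


def tads_disrupted(deletion: Deletion, tadmap: TADMap) -> list[GenomicInterval]:
    """TADs containing a deletion breakpoint strictly in their interior.

    A breakpoint exactly on a TAD edge disrupts nothing: TADs are half-open
    like every interval here, and a cut at a boundary leaves both domains
    intact.
    """
    iv = deletion.interval
    breakpoints = (iv.start, iv.end)
    return [
        tad
        for tad in tadmap
        if tad.chrom == iv.chrom
        and any(tad.start < bp < tad.end for bp in breakpoints)
    ]


def disrupted_contacts(
    gene: GeneAnnotation,
    deletion: Deletion,
    contacts: Iterable[RegulatoryContact],
) -> int:
    """Number of the gene's regulatory contacts whose element the deletion removes."""
    iv = deletion.interval
    return sum(
        1
        for c in contacts
        if c.gene_symbol == gene.symbol
        and c.element.chrom == iv.chrom
        and overlaps(c.element, iv)
    )


def phenotype_overlap(patient: PatientPhenotype, gene: GeneAnnotation) -> float:
    """Jaccard index between the patient's and the gene's phenotype-term sets."""
    if not patient.terms:
        raise ValueError(
            f"patient {patient.patient_id!r} has no phenotype terms; "
            "phenotype scoring needs a non-empty term set"
        )
    if not gene.phenotype_terms:
        return 0.0
    a, b = patient.terms, gene.phenotype_terms
    return len(a & b) / len(a | b)


def percentile_rank(scores: Sequence[float]) -> list[float]:
    """Percentile of each score within the list, in [0, 100].

    Defined as ``100 * (# strictly below) / (n - 1)``; ties share a
    percentile, and a single element gets 100.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("percentile_rank needs a non-empty list")
    if n == 1:
        return [100.0]
    ordered = sorted(scores)
    out = []
    for s in scores:
        below = sum(1 for v in ordered if v < s)
        out.append(100.0 * below / (n - 1))
    return out


def _breakpoint_distance(gene: GeneAnnotation, deletion: Deletion) -> int:
    iv = deletion.interval
    return min(
        distance(gene.interval, point(iv.chrom, iv.start)),
        distance(gene.interval, point(iv.chrom, iv.end)),
    )


def predict_candidates(
    deletion: Deletion,
    annotation: Sequence[GeneAnnotation],
    tadmap: TADMap,
    contacts: Sequence[RegulatoryContact],
    patient_phenotype: PatientPhenotype,
    params: Optional[RankingParams] = None,
) -> list[CandidateFeatures]:
    """Rank genes near one patient's deletion and partition into candidates.

    Every gene with status other than ``distal`` receives a feature row.
    Deleted (or partially deleted) genes become ``by_deletion`` candidates when
    they pass the relevance gate (HI flag OR phenotype percentile above the
    gate) — deletion alone does not make a gene phenotype-relevant.  Preserved
    genes become ``by_position_effect`` candidates per ``params.combine``.
    Output is sorted by rank score descending, ties broken by distance to the
    nearest breakpoint (ascending) then symbol.
    """
    params = params or RankingParams()
    known = {g.symbol for g in annotation}
    unknown = sorted({c.gene_symbol for c in contacts} - known)
    if unknown:
        warnings.warn(
            f"skipping contacts for unknown gene symbols: {', '.join(unknown)}",
            stacklevel=2,
        )
        contacts = [c for c in contacts if c.gene_symbol in known]

    disrupted = tads_disrupted(deletion, tadmap)
    rows = []
    for gene in annotation:
        if gene.interval.chrom != deletion.interval.chrom:
            continue
        status = classify_gene_vs_deletion(gene, deletion, params.window)
        if status == DISTAL:
            continue
        in_tad = any(overlaps(gene.interval, tad) for tad in disrupted)
        n_contacts = (
            0
            if status in (DELETED, PARTIALLY_DELETED)
            else disrupted_contacts(gene, deletion, contacts)
        )
        hi_flag = gene.hi_score is not None and gene.hi_score <= params.hi_threshold
        overlap = phenotype_overlap(patient_phenotype, gene)
        rows.append((gene, status, in_tad, n_contacts, hi_flag, overlap))

    if not rows:
        return []

    percentiles = percentile_rank([r[5] for r in rows])
    w1, w2, w3, w4, w5 = params.weights
    features = []
    for (gene, status, in_tad, n_contacts, hi_flag, overlap), pct in zip(
        rows, percentiles
    ):
        pheno_gate = pct > params.percentile_gate
        score = (
            w1 * min(n_contacts, params.contact_cap) / params.contact_cap
            + w2 * in_tad
            + w3 * (status == WITHIN_WINDOW)
            + w4 * hi_flag
            + w5 * pheno_gate
        )
        if status in (DELETED, PARTIALLY_DELETED):
            candidate = BY_DELETION if (hi_flag or pheno_gate) else NOT_CANDIDATE
        else:
            evidence = in_tad or n_contacts > 0
            if params.combine == "and":
                is_pe = status == WITHIN_WINDOW and evidence
            else:
                is_pe = status == WITHIN_WINDOW or evidence
            candidate = BY_POSITION_EFFECT if is_pe else NOT_CANDIDATE
        features.append(
            CandidateFeatures(
                gene_symbol=gene.symbol,
                patient_id=deletion.patient_id,
                status=status,
                in_disrupted_tad=in_tad,
                disrupted_contact_count=n_contacts,
                hi_flag=hi_flag,
                phenotype_overlap=overlap,
                phenotype_percentile=pct,
                rank_score=score,
                candidate_class=candidate,
                breakpoint_distance=_breakpoint_distance(gene, deletion),
                hi_score=gene.hi_score,
            )
        )
    features.sort(key=lambda f: (-f.rank_score, f.breakpoint_distance, f.gene_symbol))
    return features


def aggregate_cohort(
    per_patient_candidates: Sequence[Sequence[CandidateFeatures]],
) -> pd.DataFrame:
    """Per-gene detection counts across a cohort, split by candidate class.

    Returns a frame indexed by gene symbol with columns ``n_by_deletion``,
    ``n_by_position_effect``, ``n_candidate`` (their sum) and ``n_evaluated``
    (patients in which the gene received a feature row at all).
    """
    if len(per_patient_candidates) == 0:
        raise ValueError("aggregate_cohort needs at least one patient")
    counts: dict = {}
    for candidates in per_patient_candidates:
        for f in candidates:
            entry = counts.setdefault(
                f.gene_symbol,
                {"n_by_deletion": 0, "n_by_position_effect": 0, "n_evaluated": 0},
            )
            entry["n_evaluated"] += 1
            if f.candidate_class == BY_DELETION:
                entry["n_by_deletion"] += 1
            elif f.candidate_class == BY_POSITION_EFFECT:
                entry["n_by_position_effect"] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(
            columns=["n_by_deletion", "n_by_position_effect", "n_evaluated"]
        )
    df["n_candidate"] = df.get("n_by_deletion", 0) + df.get("n_by_position_effect", 0)
    df.index.name = "gene_symbol"
    return df


def candidates_to_frame(candidates: Iterable[CandidateFeatures]) -> pd.DataFrame:
    cols = [
        "patient_id",
        "gene_symbol",
        "status",
        "in_disrupted_tad",
        "disrupted_contact_count",
        "hi_score",
        "phenotype_overlap",
        "phenotype_percentile",
        "rank_score",
        "candidate_class",
        "breakpoint_distance",
    ]
    rows = [{c: getattr(f, c) for c in cols} for f in candidates]
    return pd.DataFrame(rows, columns=cols)


def write_candidates(
    candidates: Iterable[CandidateFeatures], path: Union[str, Path]
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
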