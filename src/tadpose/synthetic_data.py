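"""Seeded generators emulating every input the analysis consumes.

The generators stand in for patient data that is not publicly deposited:

* a gene / TAD / regulatory-contact landscape resembling a ~50 Mb chromosome
  arm tip (``gen_locus``),
* cohorts of terminal (or interstitial) deletions spanning the observed
  0.1-8.5 Mb size range (``gen_cohort``),
* qPCR Ct tables in which deleted genes sit at 0.5x control expression (one
  lost allele, no compensation) and planted position-effect genes at known
  fold changes (``gen_ct_table``),
* phenotype-microarray plates with logistic NADH kinetics, a 50-line control
  panel, empty-plate triplicates, and well effects planted in units of the
  per-observation SD (``gen_plate_data``).

Every generator is a pure function of its parameters and a seed, and the
ground truth is serialized alongside the data (:class:`SyntheticTruth`), so
parameter-recovery tests can score themselves.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome_model import (
    DELETED,
    DEFAULT_WINDOW,
    PARTIALLY_DELETED,
    WITHIN_WINDOW,
    Deletion,
    GeneAnnotation,
    GenomicInterval,
    RegulatoryContact,
    TADMap,
    assign_size_class,
    classify_gene_vs_deletion,
    overlaps,
)
from .metabolic_profiling import WELL_LABELS
from .position_effect import PatientPhenotype

__all__ = [
    "PHENOTYPE_VOCABULARY",
    "SyntheticTruth",
    "SyntheticLocus",
    "PlateData",
    "gen_locus",
    "gen_cohort",
    "plant_truth",
    "gen_patient_phenotypes",
    "gen_ct_table",
    "gen_plate_data",
]

#: Fixed vocabulary of phenotype term identifiers (ICD-chapter-style codes).
PHENOTYPE_VOCABULARY = tuple(f"T{i:02d}" for i in range(30))


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, serialized with the data."""

    seed: int
    planted_position_effect_genes: frozenset = frozenset()
    planted_deletion_genes: frozenset = frozenset()
    true_fold_changes: dict = field(default_factory=dict)
    true_well_effects: dict = field(default_factory=dict)  # plate -> well -> SD units
    compensated_genes: frozenset = frozenset()
    #: patient_id -> tuple of planted position-effect genes for that patient.
    planted_pairs: dict = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "seed": self.seed,
            "planted_position_effect_genes": sorted(self.planted_position_effect_genes),
            "planted_deletion_genes": sorted(self.planted_deletion_genes),
            "true_fold_changes": dict(sorted(self.true_fold_changes.items())),
            "true_well_effects": {
                p: dict(sorted(w.items())) for p, w in self.true_well_effects.items()
            },
            "compensated_genes": sorted(self.compensated_genes),
            "planted_pairs": {p: sorted(g) for p, g in self.planted_pairs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            planted_position_effect_genes=frozenset(
                payload["planted_position_effect_genes"]
            ),
            planted_deletion_genes=frozenset(payload["planted_deletion_genes"]),
            true_fold_changes=payload["true_fold_changes"],
            true_well_effects=payload["true_well_effects"],
            compensated_genes=frozenset(payload["compensated_genes"]),
            planted_pairs={
                p: tuple(g) for p, g in payload.get("planted_pairs", {}).items()
            },
        )


@dataclass
class SyntheticLocus:
    """A generated gene/TAD/contact landscape on one chromosome."""

    genes: list
    tadmap: TADMap
    contacts: list
    chrom: str
    chrom_length: int


def gen_locus(
    n_genes: int = 50,
    chrom_length: int = 51_300_000,
    tad_count: int = 12,
    contact_rate: float = 2.0,
    seed: int = 0,
    chrom: str = "chr22",
    hi_low_fraction: float = 0.15,
    hi_missing_fraction: float = 0.05,
    gene_length_range: tuple = (5_000, 100_000),
    terms_per_gene: tuple = (2, 6),
    vocab: Sequence[str] = PHENOTYPE_VOCABULARY,
) -> SyntheticLocus:
    """Generate non-overlapping genes, a TAD partition, and regulatory contacts.

    HI scores are uniform on [0, 100] with ``hi_low_fraction`` of genes drawn
    from the likely-haploinsufficient 0-10% band and a small fraction missing.
    Contacts link each gene to Poisson(``contact_rate``) elements placed within
    2 Mb of the gene.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(
        gene_length_range[0], gene_length_range[1] + 1, size=n_genes
    )
    free = chrom_length - 1 - int(lengths.sum())
    if free < n_genes:
        raise ValueError(
            f"infeasible packing: {n_genes} genes of total length "
            f"{int(lengths.sum())} bp do not fit in {chrom_length} bp"
        )
    gaps = np.floor(rng.dirichlet(np.ones(n_genes + 1)) * free).astype(int)
    genes = []
    pos = 1
    for i in range(n_genes):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        pos = end
        if rng.random() < hi_missing_fraction:
            hi = None
        elif rng.random() < hi_low_fraction:
            hi = float(rng.uniform(0.0, 10.0))
        else:
            hi = float(rng.uniform(10.0, 100.0))
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        terms = frozenset(rng.choice(vocab, size=k, replace=False).tolist())
        genes.append(
            GeneAnnotation(
                symbol=f"G{i:03d}",
                interval=GenomicInterval(chrom, start, end),
                hi_score=hi,
                phenotype_terms=terms,
                expressed_in_blood=True,
            )
        )

    boundaries = np.sort(
        rng.choice(np.arange(2, chrom_length), size=tad_count - 1, replace=False)
    )
    edges = np.concatenate([[1], boundaries, [chrom_length]])
    tadmap = TADMap(
        GenomicInterval(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])
    )

    contacts = []
    for gene in genes:
        for _ in range(rng.poisson(contact_rate)):
            elem_len = int(rng.integers(1_000, 10_001))
            center = int(
                rng.uniform(
                    max(1, gene.interval.start - DEFAULT_WINDOW),
                    min(chrom_length, gene.interval.end + DEFAULT_WINDOW),
                )
            )
            start = max(1, center - elem_len // 2)
            contacts.append(
                RegulatoryContact(
                    gene_symbol=gene.symbol,
                    element=GenomicInterval(chrom, start, start + elem_len),
                )
            )
    return SyntheticLocus(
        genes=genes, tadmap=tadmap, contacts=contacts,
        chrom=chrom, chrom_length=chrom_length,
    )


def gen_cohort(
    n_patients: int = 5,
    size_range: tuple = (100_000, 8_500_000),
    terminal_fraction: float = 1.0,
    seed: int = 0,
    chrom: str = "chr22",
    chrom_end: int = 51_244_566,
) -> list:
    """Generate a cohort of deletions spanning the observed size range.

    Sizes are log-uniform over ``size_range`` so small and large deletions are
    both represented; terminal deletions share the chromosome end.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    deletions = []
    for i in range(n_patients):
        size = int(
            np.exp(rng.uniform(np.log(size_range[0]), np.log(size_range[1])))
        )
        terminal = bool(rng.random() < terminal_fraction)
        if terminal:
            start, end = chrom_end - size, chrom_end
        else:
            end = int(rng.uniform(size + 1, chrom_end))
            start = end - size
        deletion = Deletion(
            patient_id=f"SIM{i + 1:02d}",
            interval=GenomicInterval(chrom, start, end),
            terminal=terminal,
        )
        deletions.append(assign_size_class(deletion))
    return deletions


def plant_truth(
    locus: SyntheticLocus,
    deletions: Sequence[Deletion],
    n_position_effect: int = 3,
    position_effect_fold: float = 0.5,
    deleted_fold: float = 0.5,
    compensated_genes: Sequence[str] = (),
    compensated_fold: float = 2.0,
    contacts_per_planted: int = 3,
    require_tad: bool = True,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> tuple:
    """Plant position-effect genes and return ``(truth, augmented_locus)``.

    Planted genes are chosen among genes lying within the flanking window of a
    deletion (preferring genes inside a TAD the deletion disrupts, so the
    planted signal matches the mechanism the predictor looks for) and receive
    ``contacts_per_planted`` extra regulatory contacts whose elements fall
    inside the corresponding deletion.  ``compensated_genes`` are expressed at
    ``compensated_fold`` in every patient regardless of deletion status,
    emulating dosage compensation of an enzyme-coding gene.
    """
    rng = np.random.default_rng(seed)
    from .position_effect import tads_disrupted  # local import avoids cycle

    eligible = []  # (deletion, gene)
    for deletion in deletions:
        disrupted = tads_disrupted(deletion, locus.tadmap)
        for gene in locus.genes:
            status = classify_gene_vs_deletion(gene, deletion, window)
            if status != WITHIN_WINDOW:
                continue
            in_tad = any(overlaps(gene.interval, tad) for tad in disrupted)
            if require_tad and not in_tad:
                continue
            eligible.append((deletion, gene))
    if require_tad and not eligible:
        # fall back to the window-only criterion when no TAD co-membership exists
        for deletion in deletions:
            for gene in locus.genes:
                if classify_gene_vs_deletion(gene, deletion, window) == WITHIN_WINDOW:
                    eligible.append((deletion, gene))

    chosen: list = []
    if eligible:
        idx = rng.permutation(len(eligible))
        seen_genes: set = set()
        for i in idx:
            deletion, gene = eligible[i]
            if gene.symbol in seen_genes:
                continue
            chosen.append((deletion, gene))
            seen_genes.add(gene.symbol)
            if len(chosen) >= n_position_effect:
                break

    extra_contacts = []
    planted_pairs: dict = {}
    for deletion, gene in chosen:
        planted_pairs.setdefault(deletion.patient_id, []).append(gene.symbol)
        iv = deletion.interval
        for _ in range(contacts_per_planted):
            elem_len = int(rng.integers(1_000, 10_001))
            max_offset = max(1, min(iv.length - elem_len, window))
            offset = int(rng.integers(0, max_offset))
            if gene.interval.end <= iv.start:  # gene proximal of the deletion
                start = iv.start + offset
            else:  # gene distal: anchor at the distal breakpoint
                start = max(iv.start, iv.end - offset - elem_len)
            extra_contacts.append(
                RegulatoryContact(
                    gene_symbol=gene.symbol,
                    element=GenomicInterval(iv.chrom, start, start + elem_len),
                )
            )

    deleted_genes = set()
    for deletion in deletions:
        for gene in locus.genes:
            if classify_gene_vs_deletion(gene, deletion, window) in (
                DELETED,
                PARTIALLY_DELETED,
            ):
                deleted_genes.add(gene.symbol)

    folds = {g: deleted_fold for g in deleted_genes}
    folds.update({gene.symbol: position_effect_fold for _, gene in chosen})
    folds.update({g: compensated_fold for g in compensated_genes})

    truth = SyntheticTruth(
        seed=seed,
        planted_position_effect_genes=frozenset(g.symbol for _, g in chosen),
        planted_deletion_genes=frozenset(deleted_genes),
        true_fold_changes=folds,
        compensated_genes=frozenset(compensated_genes),
        planted_pairs={p: tuple(gs) for p, gs in planted_pairs.items()},
    )
    augmented = dataclasses.replace(
        locus, contacts=list(locus.contacts) + extra_contacts
    )
    return truth, augmented


def gen_patient_phenotypes(
    deletions: Sequence[Deletion],
    locus: SyntheticLocus,
    truth: Optional[SyntheticTruth] = None,
    seed: int = 0,
    n_extra_terms: tuple = (3, 8),
    vocab: Sequence[str] = PHENOTYPE_VOCABULARY,
) -> list:
    """Patient term sets: planted genes' terms plus random background terms."""
    rng = np.random.default_rng(seed)
    by_symbol = {g.symbol: g for g in locus.genes}
    out = []
    for deletion in deletions:
        terms: set = set()
        if truth is not None:
            for symbol in truth.planted_pairs.get(deletion.patient_id, ()):
                terms |= set(by_symbol[symbol].phenotype_terms)
        k = int(rng.integers(n_extra_terms[0], n_extra_terms[1] + 1))
        terms |= set(rng.choice(vocab, size=k, replace=False).tolist())
        out.append(PatientPhenotype(patient_id=deletion.patient_id, terms=frozenset(terms)))
    return out


def gen_ct_table(
    annotation: Sequence[GeneAnnotation],
    deletions: Sequence[Deletion],
    truth: SyntheticTruth,
    control_ids: Sequence[str] = ("C1", "C2"),
    noise_sd: float = 0.2,
    n_replicates: int = 2,
    housekeeping: str = "TBP",
    hk_baseline: float = 25.0,
    baseline_range: tuple = (22.0, 30.0),
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table (sample_id, gene, replicate, ct) with planted folds.

    Ct = baseline_gene - log2(relative expression) + Gaussian noise; the
    housekeeping gene is constant across samples up to noise, controls sit at
    expression 1, deleted genes at their planted fold (default 0.5x), planted
    position-effect genes at their fold when within the window, and
    compensated genes at their fold in every patient sample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [g for g in annotation if g.expressed_in_blood]
    baselines = {
        g.symbol: float(rng.uniform(*baseline_range)) for g in genes
    }

    def expression(sample_id: str, gene: GeneAnnotation) -> float:
        if sample_id in control_ids:
            return 1.0
        deletion = next(d for d in deletions if d.patient_id == sample_id)
        if gene.symbol in truth.compensated_genes:
            return float(truth.true_fold_changes[gene.symbol])
        status = classify_gene_vs_deletion(gene, deletion, window)
        if status in (DELETED, PARTIALLY_DELETED):
            return float(truth.true_fold_changes.get(gene.symbol, 0.5))
        if (
            status == WITHIN_WINDOW
            and gene.symbol in truth.planted_position_effect_genes
        ):
            pairs = truth.planted_pairs
            if not pairs or gene.symbol in pairs.get(sample_id, ()):
                return float(truth.true_fold_changes[gene.symbol])
        return 1.0

    rows = []
    sample_ids = [d.patient_id for d in deletions] + list(control_ids)
    for sample_id in sample_ids:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": housekeeping,
                    "replicate": rep,
                    "ct": hk_baseline + rng.normal(0.0, noise_sd),
                }
            )
            for gene in genes:
                ct = (
                    baselines[gene.symbol]
                    - np.log2(expression(sample_id, gene))
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "gene": gene.symbol,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PlateData:
    """Generated plate datasets in the CSV dialects the pipeline reads."""

    sample: pd.DataFrame
    control: pd.DataFrame
    empty: pd.DataFrame
    sample_kinetics: Optional[pd.DataFrame] = None
    control_kinetics: Optional[pd.DataFrame] = None


def gen_plate_data(
    plate_ids: Sequence[str] = ("PM-M1",),
    n_controls: int = 50,
    n_sample_replicates: int = 3,
    truth: Optional[SyntheticTruth] = None,
    sample_id: str = "SIM-PMS",
    seed: int = 0,
    line_sd: float = 0.06,
    noise_sd: float = 0.015,
    background_sd: float = 0.003,
    baseline: float = 0.1,
    dye_background: float = 0.05,
    kinetics: bool = False,
    n_timepoints: int = 96,
    total_hours: float = 24.0,
) -> PlateData:
    """Generate sample replicate runs, a control panel, and empty plates.

    Each well follows a logistic NADH curve ``OD(t) = A / (1 + exp(-k (t -
    t0))) + baseline`` with well-specific (A, k, t0).  Observations (control
    lines and sample replicate runs alike) draw an iid amplitude perturbation
    ``N(0, line_sd)``; planted well effects from ``truth.true_well_effects``
    shift the sample amplitude by the stated number of ``line_sd`` units.
    Kinetic output samples the curve every ``total_hours * 60 /
    n_timepoints`` minutes (default 15 min over 24 h, 96 points); endpoint
    output reads A590 as the final OD plus dye background, A750 as background.
    Empty plates are baseline plus noise, in triplicate.
    """
    if n_controls < 2:
        raise ValueError("n_controls must be >= 2")
    if n_sample_replicates < 2:
        raise ValueError(
            "n_sample_replicates must be >= 2: the per-well test needs "
            "replicate observations on the sample side"
        )
    rng = np.random.default_rng(seed)
    effects = truth.true_well_effects if truth is not None else {}
    t_minutes = (np.arange(n_timepoints) + 1) * (total_hours * 60.0 / n_timepoints)
    t_hours = t_minutes / 60.0

    sample_rows, control_rows, empty_rows = [], [], []
    sample_kin, control_kin = [], []
    control_ids = [f"CTRL{i + 1:02d}" for i in range(n_controls)]
    replicate_ids = [f"{sample_id}-r{i + 1}" for i in range(n_sample_replicates)]

    def od_curve(A: float, k: float, t0: float) -> np.ndarray:
        return A / (1.0 + np.exp(-k * (t_hours - t0))) + baseline

    for plate_id in plate_ids:
        shifts = effects.get(plate_id, {})
        for well in WELL_LABELS:
            A0 = float(rng.uniform(0.6, 1.4))
            k = float(rng.uniform(0.2, 0.6))
            t0 = float(rng.uniform(6.0, 16.0))
            shift = float(shifts.get(well, 0.0)) * line_sd

            for ids, rows, kin_rows, eff in (
                (replicate_ids, sample_rows, sample_kin, shift),
                (control_ids, control_rows, control_kin, 0.0),
            ):
                for obs_id in ids:
                    A = A0 + float(rng.normal(0.0, line_sd)) + eff
                    curve = od_curve(A, k, t0)
                    if kinetics:
                        noisy = curve + rng.normal(0.0, noise_sd, size=n_timepoints)
                        for tm, od in zip(t_minutes, noisy):
                            kin_rows.append(
                                {
                                    "plate_id": plate_id,
                                    "well": well,
                                    "sample_id": obs_id,
                                    "time_minutes": float(tm),
                                    "od": float(od),
                                }
                            )
                        od_end = float(noisy[-1])
                    else:
                        od_end = float(curve[-1] + rng.normal(0.0, noise_sd))
                    a750 = dye_background + float(rng.normal(0.0, background_sd))
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "well": well,
                            "sample_id": obs_id,
                            "a590": od_end + a750,
                            "a750": a750,
                        }
                    )

            for rep in range(1, 4):
                a750 = dye_background + float(rng.normal(0.0, background_sd))
                empty_rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "sample_id": f"empty-{rep}",
                        "a590": baseline + a750 + float(rng.normal(0.0, background_sd)),
                        "a750": a750,
                    }
                )

    return PlateData(
        sample=pd.DataFrame(sample_rows),
        control=pd.DataFrame(control_rows),
        empty=pd.DataFrame(empty_rows),
        sample_kinetics=pd.DataFrame(sample_kin) if kinetics else None,
        control_kinetics=pd.DataFrame(control_kin) if kinetics else None,
    )
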