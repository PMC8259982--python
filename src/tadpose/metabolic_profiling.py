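"""Phenotype-microarray (PM-M) plate analysis.

Per-well NADH readouts from 96-well PM plates are processed as: relative
absorbance (A590 - A750) or a kinetic parameter of the optical-density curve,
normalized against the mean of the corresponding empty-plate triplicate,
floored at a small epsilon so all 96 wells stay in the analysis, log10
transformed, and compared well-by-well against a panel of control cell lines
with a two-sided Mann-Whitney U test at p <= alpha (default 0.05).  Direction
of utilization (increased / decreased NADH production) is the sign of the
median difference, reported only for significant wells.  An optional
Benjamini-Hochberg adjustment is available for the well-level p values.

The unit of replication matters and is stated loudly: the sample side of each
per-well test needs **at least two replicate observations** (replicate plate
runs or replicate kinetic statistics); single-replicate input is rejected
rather than silently tested.  The control side is one value per control line
(the study design used a 50-line panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EPSILON",
    "INCREASED",
    "DECREASED",
    "NO_DIRECTION",
    "WELL_LABELS",
    "PlateLayout",
    "KineticParams",
    "WellComparison",
    "BiologResult",
    "relative_absorbance",
    "normalize_to_empty",
    "log_transform",
    "kinetic_params",
    "mann_whitney_well",
    "benjamini_hochberg",
    "plate_summary",
    "format_well_fraction",
    "run_biolog_pipeline",
    "default_layouts",
]

#: Floor applied after empty-plate subtraction and inside the log transform.
EPSILON = 1e-6

INCREASED = "increased"
DECREASED = "decreased"
NO_DIRECTION = "none"

#: Standard 96-well labels A1..H12, row-major.
WELL_LABELS = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))


@dataclass(frozen=True)
class PlateLayout:
    """A plate identifier with its 96-well compound map."""

    plate_id: str
    wells: dict  # well label -> compound name

    def __post_init__(self) -> None:
        if set(self.wells) != set(WELL_LABELS):
            raise ValueError(
                f"plate {self.plate_id}: layout must map exactly the 96 wells A1-H12"
            )


def default_layouts(plate_ids: Sequence[str] = ()) -> dict:
    """Generic layouts for PM-M1..M8 and the custom tryptophan plate.

    Only a handful of well assignments are public knowledge (e.g. manganese
    chloride in PM-M5 C8, iodine in PM-M5 C10-C11, D-glucose-1-phosphate in
    PM-M1 B2); all other wells get placeholder compound names.  The Trp plate
    follows its twelve 8-well-column design: glucose, empty, tryptophan alone
    and five tryptophan dipeptides, one condition per column pair.
    """
    plate_ids = tuple(plate_ids) or tuple(f"PM-M{i}" for i in range(1, 9)) + ("Trp",)
    named = {
        ("PM-M1", "B2"): "D-glucose-1-phosphate",
        ("PM-M5", "C8"): "manganese chloride",
        ("PM-M5", "C10"): "iodine",
        ("PM-M5", "C11"): "iodine",
    }
    trp_columns = [
        "D-glucose",
        "empty",
        "L-tryptophan",
        "Gly-Trp",
        "Lys-Trp",
        "Leu-Trp",
        "Arg-Trp",
        "Ala-Trp",
        "D-glucose",
        "L-tryptophan",
        "Trp-Gly",
        "Trp-Ala",
    ]
    layouts = {}
    for pid in plate_ids:
        wells = {}
        for label in WELL_LABELS:
            col = int(label[1:])
            if pid == "Trp":
                wells[label] = trp_columns[col - 1]
            else:
                wells[label] = named.get((pid, label), f"{pid} {label} substrate")
        layouts[pid] = PlateLayout(plate_id=pid, wells=wells)
    return layouts


def relative_absorbance(a590, a750):
    """Endpoint relative absorbance: dye peak minus background (A590 - A750)."""
    return np.subtract(a590, a750)


def normalize_to_empty(readings: dict, empty_plate: dict, eps: float = EPSILON) -> dict:
    """Subtract the per-well empty-plate triplicate mean; floor at ``eps``.

    ``readings`` maps well -> value, ``empty_plate`` maps well -> exactly three
    replicate values (plates run with media and dye but no cells).
    """
    out = {}
    for well, value in readings.items():
        if well not in empty_plate:
            raise ValueError(f"empty plate is missing well {well}")
        empties = np.asarray(empty_plate[well], dtype=float)
        if empties.shape != (3,):
            raise ValueError(
                f"well {well}: expected an empty-plate triplicate, got {empties.shape}"
            )
        out[well] = max(float(value) - float(empties.mean()), eps)
    return out


def log_transform(values, eps: float = EPSILON):
    """log10(value + eps); negative input is an error (normalize first)."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log_transform expects non-negative values")
    return np.log10(arr + eps)


@dataclass(frozen=True)
class KineticParams:
    """Summary parameters of one well's NADH kinetic curve."""

    slope: float  # max OD change per hour over sliding 1-h windows
    endpoint: float  # final reading
    auc: float  # trapezoid area, OD * hours


def kinetic_params(
    times_minutes: Sequence[float], values: Sequence[float]
) -> KineticParams:
    """Slope / endpoint / AUC of a kinetic curve.

    ``slope`` is the maximum least-squares slope (per hour) over sliding
    windows spanning one hour of readings; ``auc`` is the trapezoid integral
    over the full span in OD*hours.
    """
    t = np.asarray(times_minutes, dtype=float) / 60.0
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("kinetic curve needs >= 2 (time, value) points")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("kinetic curve contains non-finite values")

    best = -np.inf
    for i in range(t.size):
        j = np.searchsorted(t, t[i] + 1.0, side="right")
        j = max(j, i + 2)
        if j > t.size:
            break
        tw, yw = t[i:j], y[i:j]
        slope = np.polyfit(tw, yw, 1)[0]
        best = max(best, slope)
    auc = float(np.trapezoid(y, t))
    return KineticParams(slope=float(best), endpoint=float(y[-1]), auc=auc)


@dataclass
class WellComparison:
    """One well's sample-vs-control-panel comparison."""

    well: str
    plate_id: str
    n_sample: int
    n_control: int
    median_sample: float
    median_control: float
    p_value: float
    significant: bool
    direction: str
    p_adjusted: Optional[float] = None


def mann_whitney_well(
    sample_values: Sequence[float],
    control_values: Sequence[float],
    alpha: float = 0.05,
    well: str = "",
    plate_id: str = "",
) -> WellComparison:
    """Two-sided Mann-Whitney U comparison of one well against the control panel.

    Uses the exact U distribution when min(n) <= 8 and the pooled data are
    tie-free, otherwise the normal approximation with tie correction.  When
    every value in both groups is identical the comparison is degenerate:
    p = 1, no direction.
    """
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"well {well or '?'}: need >= 2 values per side "
            f"(got {x.size} sample, {y.size} control); replicate observations "
            "are required for a per-well test"
        )
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return WellComparison(
            well=well, plate_id=plate_id, n_sample=x.size, n_control=y.size,
            median_sample=float(pooled[0]), median_control=float(pooled[0]),
            p_value=1.0, significant=False, direction=NO_DIRECTION,
        )
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    significant = p <= alpha
    med_s, med_c = float(np.median(x)), float(np.median(y))
    if significant and med_s > med_c:
        direction = INCREASED
    elif significant and med_s < med_c:
        direction = DECREASED
    else:
        direction = NO_DIRECTION
    return WellComparison(
        well=well, plate_id=plate_id, n_sample=x.size, n_control=y.size,
        median_sample=med_s, median_control=med_c,
        p_value=p, significant=significant, direction=direction,
    )


def benjamini_hochberg(p_values: Sequence[float], alpha: float = 0.05):
    """BH false-discovery-rate adjustment; returns (reject, adjusted_p)."""
    reject, adjusted, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject, adjusted


def format_well_fraction(significant: int, total: int) -> str:
    """Render counts the way results are printed: ``43/96 (44.8%)``.

    Percentages carry one decimal except the exact 100% case, which prints as
    an integer.
    """
    pct = round(100.0 * significant / total, 1)
    pct_str = "100%" if pct == 100 else f"{pct:.1f}%"
    return f"{significant}/{total} ({pct_str})"


def plate_summary(comparisons: Sequence[WellComparison]) -> dict:
    """Counts of significant wells for one plate, with the printed-style string."""
    total = len(comparisons)
    if total == 0:
        raise ValueError("plate_summary needs at least one well comparison")
    if total > 96:
        raise ValueError(f"a plate has at most 96 wells, got {total}")
    plate_ids = {c.plate_id for c in comparisons}
    if len(plate_ids) > 1:
        raise ValueError(f"comparisons span multiple plates: {sorted(plate_ids)}")
    k = sum(c.significant for c in comparisons)
    return {
        "plate_id": next(iter(plate_ids)),
        "significant": k,
        "total": total,
        "percent": round(100.0 * k / total, 1),
        "fraction": format_well_fraction(k, total),
        "increased": sum(c.direction == INCREASED for c in comparisons),
        "decreased": sum(c.direction == DECREASED for c in comparisons),
    }


@dataclass
class BiologResult:
    """Per-well comparison table plus per-plate summaries."""

    per_well: pd.DataFrame
    summaries: list


_ENDPOINT_COLS = {"plate_id", "well", "sample_id", "a590", "a750"}
_KINETIC_COLS = {"plate_id", "well", "sample_id", "time_minutes", "od"}


def _is_kinetic(df: pd.DataFrame) -> bool:
    cols = set(df.columns)
    if _KINETIC_COLS <= cols:
        return True
    if _ENDPOINT_COLS <= cols:
        return False
    raise ValueError(
        f"plate table needs columns {sorted(_ENDPOINT_COLS)} (endpoint) or "
        f"{sorted(_KINETIC_COLS)} (kinetics); got {sorted(cols)}"
    )


def _empty_means(empty_df: pd.DataFrame) -> pd.DataFrame:
    """Per (plate, well) mean of the empty-plate triplicate relative absorbance."""
    df = empty_df.copy()
    df["relative"] = relative_absorbance(df["a590"], df["a750"])
    counts = df.groupby(["plate_id", "well"])["relative"].count()
    bad = counts[counts != 3]
    if not bad.empty:
        raise ValueError(
            "empty plate must have exactly 3 replicates per well; offending wells: "
            + ", ".join(f"{p}:{w} (n={n})" for (p, w), n in bad.items())
        )
    return df.groupby(["plate_id", "well"], as_index=False)["relative"].mean().rename(
        columns={"relative": "empty_mean"}
    )


def _well_statistics(
    df: pd.DataFrame, empty_means: pd.DataFrame, statistic: str, eps: float
) -> pd.DataFrame:
    """One normalized log10 statistic per (plate, well, sample_id)."""
    kinetic = _is_kinetic(df)
    if statistic != "endpoint" and not kinetic:
        raise ValueError(
            f"statistic {statistic!r} needs kinetic input (time_minutes, od)"
        )
    if kinetic:
        empty_lookup = {
            (r.plate_id, r.well): r.empty_mean for r in empty_means.itertuples()
        }
        rows = []
        for (pid, well, sid), grp in df.groupby(["plate_id", "well", "sample_id"]):
            if (pid, well) not in empty_lookup:
                raise ValueError(f"empty plate is missing well {pid}:{well}")
            grp = grp.sort_values("time_minutes")
            norm = np.maximum(
                grp["od"].to_numpy() - empty_lookup[(pid, well)], eps
            )
            curve = np.log10(norm + eps)
            params = kinetic_params(grp["time_minutes"].to_numpy(), curve)
            rows.append(
                {
                    "plate_id": pid,
                    "well": well,
                    "sample_id": sid,
                    "value": getattr(params, statistic),
                }
            )
        return pd.DataFrame(rows)
    df = df.copy()
    df["relative"] = relative_absorbance(df["a590"], df["a750"])
    stat = df.groupby(["plate_id", "well", "sample_id"], as_index=False)[
        "relative"
    ].mean()
    stat = stat.merge(empty_means, on=["plate_id", "well"], how="left")
    if stat["empty_mean"].isna().any():
        missing = stat.loc[stat["empty_mean"].isna(), ["plate_id", "well"]]
        raise ValueError(
            "empty plate is missing wells: "
            + ", ".join(f"{r.plate_id}:{r.well}" for r in missing.itertuples())
        )
    stat["value"] = np.log10(np.maximum(stat["relative"] - stat["empty_mean"], eps) + eps)
    return stat[["plate_id", "well", "sample_id", "value"]]


def run_biolog_pipeline(
    sample_df: pd.DataFrame,
    control_df: pd.DataFrame,
    empty_df: pd.DataFrame,
    statistic: str = "endpoint",
    alpha: float = 0.05,
    adjust: str = "none",
    eps: float = EPSILON,
) -> BiologResult:
    """Normalize, log-transform, test each well, and summarize per plate.

    ``sample_df`` holds the patient line's replicate runs (>= 2 per well),
    ``control_df`` the control panel (one observation per line per well), and
    ``empty_df`` the empty-plate triplicates; endpoint tables need (plate_id,
    well, sample_id, a590, a750), kinetic tables (plate_id, well, sample_id,
    time_minutes, od).  ``statistic`` is ``endpoint`` (default), ``slope`` or
    ``auc``.  ``adjust="bh"`` applies Benjamini-Hochberg across each plate's
    96 p values before calling significance.
    """
    if statistic not in ("endpoint", "slope", "auc"):
        raise ValueError("statistic must be 'endpoint', 'slope' or 'auc'")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")

    empty_means = _empty_means(empty_df)
    sample_stat = _well_statistics(sample_df, empty_means, statistic, eps)
    control_stat = _well_statistics(control_df, empty_means, statistic, eps)

    sample_wells = set(map(tuple, sample_stat[["plate_id", "well"]].to_numpy()))
    control_wells = set(map(tuple, control_stat[["plate_id", "well"]].to_numpy()))
    if sample_wells != control_wells:
        diff = sorted(sample_wells ^ control_wells)
        raise ValueError(f"sample/control plate layouts differ at wells: {diff[:10]}")

    comparisons = []
    sample_groups = sample_stat.groupby(["plate_id", "well"])["value"]
    control_groups = control_stat.groupby(["plate_id", "well"])["value"]
    for key in sorted(sample_wells):
        comparisons.append(
            mann_whitney_well(
                sample_groups.get_group(key).to_numpy(),
                control_groups.get_group(key).to_numpy(),
                alpha=alpha,
                well=key[1],
                plate_id=key[0],
            )
        )

    if adjust == "bh":
        by_plate: dict = {}
        for c in comparisons:
            by_plate.setdefault(c.plate_id, []).append(c)
        for plate_comparisons in by_plate.values():
            reject, adjusted = benjamini_hochberg(
                [c.p_value for c in plate_comparisons], alpha=alpha
            )
            for c, rej, adj in zip(plate_comparisons, reject, adjusted):
                c.p_adjusted = float(adj)
                c.significant = bool(rej)
                if not c.significant:
                    c.direction = NO_DIRECTION
                elif c.direction == NO_DIRECTION and c.median_sample != c.median_control:
                    c.direction = (
                        INCREASED if c.median_sample > c.median_control else DECREASED
                    )

    per_well = pd.DataFrame(
        [
            {
                "plate_id": c.plate_id,
                "well": c.well,
                "n_sample": c.n_sample,
                "n_control": c.n_control,
                "median_sample": c.median_sample,
                "median_control": c.median_control,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted,
                "significant": c.significant,
                "direction": c.direction,
            }
            for c in comparisons
        ]
    )
    summaries = []
    for plate_id, grp in per_well.groupby("plate_id", sort=True):
        plate_comps = [c for c in comparisons if c.plate_id == plate_id]
        summaries.append(plate_summary(plate_comps))
    return BiologResult(per_well=per_well, summaries=summaries)
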