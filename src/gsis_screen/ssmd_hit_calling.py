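"""SSMD scoring against on-plate NT wells, hit calling and condition integration.

Effect size for a gene is the strictly standardized mean difference

    beta = (X1 - X2) / sqrt(s1**2 + s2**2)

between its replicate wells and the non-targeting (NT) wells of the same
physical plate, computed independently for the secretion signal and the cell
count. Down-hits whose cell-number beta also falls below the viability cut
are excluded as secretion losses explained by cell loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gsis_screen.errors import PlateScoringError
from gsis_screen.library_layout import DEFAULT_CONDITIONS, PlateSet

UP_CUT = 1.5
DOWN_CUT = -1.5
VIABILITY_CUT = -1.5

FLAG_DEGENERATE = "degenerate_variance"
FLAG_INSUFFICIENT = "insufficient_replicates"


@dataclass(frozen=True)
class GroupStats:
    """Mean, sample SD (n-1 denominator) and size of one well group."""

    mean: float
    sd: float | None
    n: int


def summarize_group(values: Iterable[float]) -> GroupStats:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return GroupStats(mean=float(np.mean(arr)), sd=sd, n=int(arr.size))


def ssmd(g1: GroupStats, g2: GroupStats) -> float:
    """SSMD effect size of group 1 versus group 2.

    Both groups need n >= 2. If both SDs are zero the result is 0 for equal
    means and signed infinity otherwise (degenerate variance).
    """
    if g1.n < 2 or g2.n < 2 or g1.sd is None or g2.sd is None:
        raise ValueError("ssmd requires n >= 2 in both groups")
    denom = math.sqrt(g1.sd**2 + g2.sd**2)
    diff = g1.mean - g2.mean
    if denom == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / denom


@dataclass
class GeneConditionScore:
    gene: str
    condition: str
    set_id: int
    role: str
    beta_secretion: float | None
    beta_cellnumber: float | None
    secretion_candidate: GroupStats | None
    secretion_nt: GroupStats | None
    cellnumber_candidate: GroupStats | None
    cellnumber_nt: GroupStats | None
    flags: set[str] = field(default_factory=set)


READOUT_COLUMNS = {"secretion": "signal", "cell_count": "cell_count"}


def score_plate(
    measurements: pd.DataFrame,
    plate_set: PlateSet,
    readout: str = "secretion",
) -> dict[str, tuple[float | None, GroupStats | None, GroupStats, set[str]]]:
    """Score every candidate/control gene of one condition plate vs its NT wells.

    ``measurements`` holds the rows of a single condition plate with columns
    ``well`` and the readout column. Returns, per gene: (beta, candidate
    stats, NT stats, flags). Genes with fewer than two usable wells get no
    beta and are flagged.
    """
    if readout not in READOUT_COLUMNS:
        raise ValueError(f"unknown readout {readout!r}")
    column = READOUT_COLUMNS[readout]
    by_well = dict(zip(measurements["well"], measurements[column]))

    def usable(wells: list[str]) -> list[float]:
        vals = [by_well.get(w) for w in wells]
        return [float(v) for v in vals if v is not None and np.isfinite(v)]

    nt_wells = [a.well for a in plate_set.layout if a.role == "nt"]
    nt_values = usable(nt_wells)
    if len(nt_values) < 2:
        raise PlateScoringError(
            f"set {plate_set.set_id}: fewer than 2 usable NT wells "
            f"({len(nt_values)}) — plate unscoreable"
        )
    nt_stats = summarize_group(nt_values)

    gene_wells: dict[str, list[str]] = {}
    for a in plate_set.layout:
        if a.role in ("candidate", "control") and a.gene_symbol is not None:
            gene_wells.setdefault(a.gene_symbol, []).append(a.well)

    scores: dict[str, tuple[float | None, GroupStats | None, GroupStats, set[str]]] = {}
    for gene, wells in gene_wells.items():
        values = usable(wells)
        flags: set[str] = set()
        if len(values) < 2:
            flags.add(FLAG_INSUFFICIENT)
            stats = summarize_group(values) if values else None
            scores[gene] = (None, stats, nt_stats, flags)
            continue
        stats = summarize_group(values)
        beta = ssmd(stats, nt_stats)
        if math.isinf(beta):
            flags.add(FLAG_DEGENERATE)
        scores[gene] = (beta, stats, nt_stats, flags)
    return scores


def score_screen(
    measurements: pd.DataFrame, plate_sets: Sequence[PlateSet]
) -> pd.DataFrame:
    """SSMD scores for every gene x condition over all plate sets.

    One row per gene per condition (each gene lives on exactly one set) with
    both the secretion and the cell-number beta plus the underlying group
    statistics. Returned as a tidy frame ready for ``call_hits``.
    """
    records = []
    for ps in plate_sets:
        roles = {
            a.gene_symbol: a.role
            for a in ps.layout
            if a.role in ("candidate", "control") and a.gene_symbol is not None
        }
        for condition, plate in ps.condition_plates.items():
            sub = measurements[
                (measurements["set_id"] == ps.set_id)
                & (measurements["condition"] == condition)
            ]
            sec = score_plate(sub, ps, readout="secretion")
            cel = score_plate(sub, ps, readout="cell_count")
            for gene in roles:
                beta_s, stats_s, nt_s, flags_s = sec[gene]
                beta_c, stats_c, nt_c, flags_c = cel[gene]
                flags = flags_s | flags_c
                records.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "set_id": ps.set_id,
                        "role": roles[gene],
                        "beta_secretion": beta_s,
                        "beta_cellnumber": beta_c,
                        "mean_candidate": stats_s.mean if stats_s else np.nan,
                        "sd_candidate": (
                            stats_s.sd if stats_s and stats_s.sd is not None else np.nan
                        ),
                        "n_candidate": stats_s.n if stats_s else 0,
                        "mean_nt": nt_s.mean,
                        "sd_nt": nt_s.sd if nt_s.sd is not None else np.nan,
                        "n_nt": nt_s.n,
                        "flags": ";".join(sorted(flags)),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Hit calling


def call_hits(
    scores: pd.DataFrame,
    up_cut: float = UP_CUT,
    down_cut: float = DOWN_CUT,
    viability_cut: float = VIABILITY_CUT,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> pd.DataFrame:
    """Apply the beta cut-offs and the viability filter per condition.

    A gene is *up* in a condition if its secretion beta >= ``up_cut``
    (inclusive) and *down* if <= ``down_cut`` unless its cell-number beta is
    also <= ``viability_cut``, in which case the condition is excluded for
    viability. A gene is a hit if up or down in at least one condition.
    """
    candidates = scores[scores.get("role", "candidate") == "candidate"]
    rows = []
    for gene, grp in candidates.groupby("gene", sort=True):
        directions = {c: "none" for c in conditions}
        excluded = False
        for r in grp.itertuples(index=False):
            beta = r.beta_secretion
            if beta is None or (isinstance(beta, float) and math.isnan(beta)):
                continue
            if beta >= up_cut:
                directions[r.condition] = "up"
            elif beta <= down_cut:
                beta_c = r.beta_cellnumber
                dead = (
                    beta_c is not None
                    and not (isinstance(beta_c, float) and math.isnan(beta_c))
                    and beta_c <= viability_cut
                )
                if dead:
                    excluded = True
                else:
                    directions[r.condition] = "down"
        conditions_hit = [c for c in conditions if directions[c] != "none"]
        rows.append(
            {
                "gene": gene,
                **{f"direction_{c}": directions[c] for c in conditions},
                "conditions_hit": ";".join(conditions_hit),
                "viability_excluded": excluded,
                "is_hit": bool(conditions_hit),
            }
        )
    columns = (
        ["gene"]
        + [f"direction_{c}" for c in conditions]
        + ["conditions_hit", "viability_excluded", "is_hit"]
    )
    return pd.DataFrame.from_records(rows, columns=columns)


def integrate_conditions(
    hits: pd.DataFrame, conditions: Sequence[str] = DEFAULT_CONDITIONS
) -> dict:
    """Venn-style integration of hit sets across conditions.

    Returns per-direction per-condition hit sets, exclusive Venn region
    counts keyed like ``"0mM&20mM"``, and union counts per direction.
    """
    summary: dict = {"conditions": list(conditions), "directions": {}}
    for direction in ("up", "down"):
        per_condition: dict[str, set[str]] = {c: set() for c in conditions}
        if len(hits):
            for r in hits.itertuples(index=False):
                for c in conditions:
                    if getattr(r, f"direction_{c}", "none") == direction:
                        per_condition[c].add(r.gene)
        regions: dict[str, int] = {}
        union: set[str] = set().union(*per_condition.values()) if per_condition else set()
        for gene in union:
            member = frozenset(c for c in conditions if gene in per_condition[c])
            key = "&".join(c for c in conditions if c in member)
            regions[key] = regions.get(key, 0) + 1
        summary["directions"][direction] = {
            "per_condition": {c: sorted(per_condition[c]) for c in conditions},
            "regions": regions,
            "union_count": len(union),
        }
    summary["total_hits"] = int(hits["is_hit"].sum()) if len(hits) else 0
    return summary


# ---------------------------------------------------------------------------
# QC


#: (gene, condition or None for all, comparison, threshold)
DEFAULT_CONTROL_EXPECTATIONS: tuple[tuple[str, str | None, str, float], ...] = (
    ("INSULIN", None, "le", -2.0),
    ("PLK1", None, "le", -2.0),
    ("ZMIZ1", "20mM", "le", -2.0),
    ("HNF4A", "20mM", "ge", 1.5),
)

#: Per-set minimum NT fold inductions. Looser than the benchmark means
#: (2-3x and 5-6x) because single-set ratios carry the plate-effect noise of
#: two physical plates; the mean across sets is what the benchmark pins down.
DEFAULT_FOLD_EXPECTATIONS: dict[str, float] = {"20mM": 1.5, "20mM+IBMX": 3.0}


def fold_induction(
    measurements: pd.DataFrame,
    plate_sets: Sequence[PlateSet],
    basal_condition: str = "0mM",
) -> pd.DataFrame:
    """Per-set fold induction of the mean NT signal over the basal plate."""
    records = []
    for ps in plate_sets:
        nt_wells = {a.well for a in ps.layout if a.role == "nt"}
        sub = measurements[
            (measurements["set_id"] == ps.set_id) & measurements["well"].isin(nt_wells)
        ]
        means = sub.groupby("condition")["signal"].mean()
        if basal_condition not in means.index:
            raise PlateScoringError(
                f"set {ps.set_id}: no NT wells for basal condition {basal_condition!r}"
            )
        basal = means[basal_condition]
        if not np.isfinite(basal) or basal <= 0:
            raise PlateScoringError(
                f"set {ps.set_id}: basal NT mean is {basal}, cannot form folds"
            )
        for condition in ps.condition_plates:
            if condition == basal_condition:
                continue
            if condition not in means.index:
                raise PlateScoringError(
                    f"set {ps.set_id}: no NT wells for condition {condition!r}"
                )
            records.append(
                {
                    "set_id": ps.set_id,
                    "condition": condition,
                    "fold": float(means[condition] / basal),
                }
            )
    return pd.DataFrame.from_records(records, columns=["set_id", "condition", "fold"])


def qc_controls(
    scores: pd.DataFrame,
    folds: pd.DataFrame | None = None,
    expectations: Sequence[tuple[str, str | None, str, float]] = DEFAULT_CONTROL_EXPECTATIONS,
    fold_expectations: Mapping[str, float] = DEFAULT_FOLD_EXPECTATIONS,
) -> dict:
    """Check control-reagent betas (and NT fold inductions) per plate.

    Missing controls are reported as failures with status ``missing`` rather
    than raised.
    """
    report: dict = {"controls": [], "folds": [], "all_pass": True}
    indexed = {
        (r.gene, r.condition, r.set_id): r.beta_secretion
        for r in scores.itertuples(index=False)
    }
    set_ids = sorted(scores["set_id"].unique()) if len(scores) else []
    conditions = list(dict.fromkeys(scores["condition"])) if len(scores) else []
    for gene, cond_filter, op, threshold in expectations:
        for set_id in set_ids:
            for condition in conditions:
                if cond_filter is not None and condition != cond_filter:
                    continue
                beta = indexed.get((gene, condition, set_id))
                if beta is None or (isinstance(beta, float) and math.isnan(beta)):
                    status = "missing"
                    ok = False
                else:
                    ok = beta <= threshold if op == "le" else beta >= threshold
                    status = "pass" if ok else "fail"
                report["controls"].append(
                    {
                        "gene": gene,
                        "set_id": int(set_id),
                        "condition": condition,
                        "beta": None if beta is None or math.isnan(beta) else float(beta),
                        "op": op,
                        "threshold": threshold,
                        "status": status,
                    }
                )
                report["all_pass"] &= ok
    if folds is not None:
        for r in folds.itertuples(index=False):
            expected = fold_expectations.get(r.condition)
            ok = expected is None or r.fold >= expected
            report["folds"].append(
                {
                    "set_id": int(r.set_id),
                    "condition": r.condition,
                    "fold": float(r.fold),
                    "min_expected": expected,
                    "status": "pass" if ok else "fail",
                }
            )
            report["all_pass"] &= ok
    report["all_pass"] = bool(report["all_pass"])
    return report
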