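"""Synthetic screen generator.

Produces per-well secretion signals and cell counts with the statistical
structure the scoring stage assumes: multiplicative condition folds, gene
effects, per-plate scale factors and log-normal well noise. Also provides a
synthetic siRNA library and a Ct-table generator for the ddCt stage, so the
whole pipeline is testable without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gsis_screen.errors import ConfigurationError
from gsis_screen.library_layout import (
    CONTROL_GENES,
    DEFAULT_CONDITIONS,
    NT_GENE,
    PlateSet,
    SirnaLibraryEntry,
    all_wells,
    parse_well,
)

#: Canonical control-reagent secretion multipliers per condition. Values are
#: calibration constants chosen so that, under default noise, the expected
#: control behavior (INSULIN/PLK1 beta <= -2 everywhere, ZMIZ1 <= -2 at
#: 20 mM, HNF4A >= 1.5 at 20 mM) holds with high probability.
CONTROL_SECRETION_EFFECTS: dict[str, dict[str, float]] = {
    "INSULIN": {"0mM": 0.2, "20mM": 0.2, "20mM+IBMX": 0.2},
    "PLK1": {"0mM": 0.2, "20mM": 0.2, "20mM+IBMX": 0.2},
    "ZMIZ1": {"0mM": 0.45, "20mM": 0.45, "20mM+IBMX": 0.7},
    "HNF4A": {"0mM": 1.0, "20mM": 2.2, "20mM+IBMX": 1.0},
}
CONTROL_CELLNUMBER_EFFECTS: dict[str, float] = {"PLK1": 0.3}


@dataclass
class NoiseConfig:
    """Generative-model parameters for one synthetic screen."""

    well_cv: float = 0.15
    plate_sigma: float = 0.1
    base_signal: float = 1000.0
    condition_fold: dict[str, float] = field(
        default_factory=lambda: {"0mM": 1.0, "20mM": 2.5, "20mM+IBMX": 5.5}
    )
    base_cells: float = 3000.0
    cell_cv: float = 0.12
    row_gradient: float = 0.0  # optional positional effect, off by default

    def __post_init__(self) -> None:
        for name in ("well_cv", "base_signal", "base_cells", "cell_cv"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.plate_sigma < 0:
            raise ConfigurationError("plate_sigma must be >= 0")
        if any(f <= 0 for f in self.condition_fold.values()):
            raise ConfigurationError("condition folds must be positive")
        basal = self.condition_fold.get("0mM")
        if basal is not None and basal != 1.0:
            raise ConfigurationError("basal (0mM) condition fold must equal 1")


@dataclass
class EffectMap:
    """Ground-truth multiplicative effects per gene.

    ``secretion[gene][condition]`` scales the secreted signal;
    ``cellnumber[gene]`` scales the expected cell count. Absent genes (and
    the NT reagent, always) have multiplier 1.
    """

    secretion: dict[str, dict[str, float]] = field(default_factory=dict)
    cellnumber: dict[str, float] = field(default_factory=dict)

    def secretion_multiplier(self, gene: str | None, condition: str) -> float:
        if gene is None or gene == NT_GENE:
            return 1.0
        return self.secretion.get(gene, {}).get(condition, 1.0)

    def cellnumber_multiplier(self, gene: str | None) -> float:
        if gene is None or gene == NT_GENE:
            return 1.0
        return self.cellnumber.get(gene, 1.0)

    def validate(self) -> None:
        for gene, per_cond in self.secretion.items():
            if gene == NT_GENE and any(m != 1.0 for m in per_cond.values()):
                raise ConfigurationError("NT secretion multiplier must stay 1")
            if any(m <= 0 for m in per_cond.values()):
                raise ConfigurationError(f"non-positive multiplier for {gene}")
        for gene, m in self.cellnumber.items():
            if gene == NT_GENE and m != 1.0:
                raise ConfigurationError("NT cell-number multiplier must stay 1")
            if m <= 0:
                raise ConfigurationError(f"non-positive cell multiplier for {gene}")

    def to_frame(self, conditions: Sequence[str] = DEFAULT_CONDITIONS) -> pd.DataFrame:
        genes = sorted(set(self.secretion) | set(self.cellnumber))
        records = []
        for g in genes:
            for c in conditions:
                records.append(
                    {
                        "gene": g,
                        "condition": c,
                        "secretion_multiplier": self.secretion_multiplier(g, c),
                        "cellnumber_multiplier": self.cellnumber_multiplier(g),
                    }
                )
        return pd.DataFrame.from_records(
            records,
            columns=["gene", "condition", "secretion_multiplier", "cellnumber_multiplier"],
        )


def true_standardized_effect(multiplier: float, well_cv: float) -> float:
    """Population SSMD of a gene with the given secretion multiplier vs NT.

    Under the generative model both groups share the plate factor, so the
    population effect size is ``(m - 1) / (cv * sqrt(m**2 + 1))``.
    """
    return (multiplier - 1.0) / (well_cv * math.sqrt(multiplier**2 + 1.0))


def plant_effects(
    genes: Sequence[str],
    n_up: int = 0,
    n_down: int = 0,
    up_multiplier: float = 2.5,
    down_multiplier: float = 0.4,
    viability_killed: Iterable[str] = (),
    seed: int = 0,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    up_genes: Iterable[str] | None = None,
    down_genes: Iterable[str] | None = None,
    killed_cell_multiplier: float = 0.3,
    killed_secretion_multiplier: float = 0.5,
) -> EffectMap:
    """Build a ground-truth effect map with planted regulators.

    ``n_up`` genes receive ``up_multiplier`` (> 1) and ``n_down`` receive
    ``down_multiplier`` (< 1) in every condition; genes in
    ``viability_killed`` get reduced cell number and secretion. Explicit
    ``up_genes``/``down_genes`` override the random draw. Control reagents,
    if present in ``genes``, always carry their canonical effects.
    """
    if up_multiplier <= 1:
        raise ConfigurationError("up_multiplier must be > 1")
    if not 0 < down_multiplier < 1:
        raise ConfigurationError("down_multiplier must be in (0, 1)")
    killed = list(dict.fromkeys(viability_killed))
    pool = [g for g in genes if g not in CONTROL_GENES and g != NT_GENE]
    if up_genes is not None or down_genes is not None:
        up = list(dict.fromkeys(up_genes or []))
        down = list(dict.fromkeys(down_genes or []))
    else:
        if n_up + n_down + len(killed) > len(pool):
            raise ConfigurationError("more planted effects than candidate genes")
        rng = np.random.default_rng(seed)
        available = [g for g in pool if g not in killed]
        chosen = rng.choice(len(available), size=n_up + n_down, replace=False)
        up = [available[i] for i in chosen[:n_up]]
        down = [available[i] for i in chosen[n_up:]]
    overlaps = (set(up) & set(down)) | (set(up) & set(killed)) | (set(down) & set(killed))
    if overlaps:
        raise ConfigurationError(f"planted effect sets overlap: {sorted(overlaps)}")

    effects = EffectMap()
    for g in up:
        effects.secretion[g] = {c: up_multiplier for c in conditions}
    for g in down:
        effects.secretion[g] = {c: down_multiplier for c in conditions}
    for g in killed:
        effects.secretion[g] = {c: killed_secretion_multiplier for c in conditions}
        effects.cellnumber[g] = killed_cell_multiplier
    for g in genes:
        if g in CONTROL_SECRETION_EFFECTS:
            effects.secretion[g] = {
                c: CONTROL_SECRETION_EFFECTS[g].get(c, 1.0) for c in conditions
            }
        if g in CONTROL_CELLNUMBER_EFFECTS:
            effects.cellnumber[g] = CONTROL_CELLNUMBER_EFFECTS[g]
    effects.validate()
    return effects


MEASUREMENT_COLUMNS = (
    "set_id",
    "condition",
    "plate",
    "well",
    "signal",
    "cell_count",
)


def simulate_screen(
    plate_sets: Sequence[PlateSet],
    effects: EffectMap,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one measurement per non-empty well per condition plate.

    signal = base * fold[cond] * secretion_mult[gene, cond] * plate_effect * eps
    with plate_effect ~ LogNormal(0, plate_sigma^2) drawn once per physical
    plate and eps a unit-mean log-normal with CV ``well_cv``. Cell counts are
    truncated rounded Gaussians around ``base_cells * cell_mult[gene]``.
    """
    noise = noise or NoiseConfig()
    effects.validate()
    rng = np.random.default_rng(seed)
    # log-normal with mean 1 and coefficient of variation cv
    sigma_w = math.sqrt(math.log(1.0 + noise.well_cv**2))
    mu_w = -0.5 * sigma_w**2

    records: list[dict] = []
    for ps in plate_sets:
        layout = ps.non_empty()
        n = len(layout)
        for condition, plate in ps.condition_plates.items():
            fold = noise.condition_fold.get(condition)
            if fold is None:
                raise ConfigurationError(f"no condition fold for {condition!r}")
            plate_effect = float(rng.lognormal(0.0, noise.plate_sigma))
            eps = rng.lognormal(mu_w, sigma_w, size=n)
            cell_noise = rng.normal(0.0, noise.cell_cv * noise.base_cells, size=n)
            for i, a in enumerate(layout):
                s_mult = effects.secretion_multiplier(a.gene_symbol, condition)
                c_mult = effects.cellnumber_multiplier(a.gene_symbol)
                signal = noise.base_signal * fold * s_mult * plate_effect * eps[i]
                if noise.row_gradient:
                    row, _ = parse_well(a.well)
                    signal *= 1.0 + noise.row_gradient * (row / 15.0 - 0.5)
                cells = max(0, round(noise.base_cells * c_mult + cell_noise[i]))
                records.append(
                    {
                        "set_id": ps.set_id,
                        "condition": condition,
                        "plate": plate,
                        "well": a.well,
                        "signal": signal,
                        "cell_count": int(cells),
                    }
                )
    return pd.DataFrame.from_records(records, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Synthetic library


def make_synthetic_library(
    n_genes: int = 521,
    seed: int = 0,
    include_controls: bool = True,
    wells_per_source_plate: int = 384,
) -> list[SirnaLibraryEntry]:
    """Fabricate a plausibly-shaped siRNA library table.

    Candidate genes get synthetic accessions and are laid out row-major
    across numbered source plates; control reagents (NT + control genes) sit
    on a dedicated control source plate so picklists can resolve them.
    """
    wells = all_wells()[:wells_per_source_plate]
    entries: list[SirnaLibraryEntry] = []
    if include_controls:
        for i, gene in enumerate((NT_GENE, *CONTROL_GENES)):
            entries.append(
                SirnaLibraryEntry(
                    uniprot_id=f"CTRL{i:02d}",
                    gene_symbol=gene,
                    source_plate="SRC-CTRL",
                    source_well=wells[i],
                    catalog_id=f"D-00{i:04d}",
                )
            )
    for i in range(n_genes):
        plate_idx, well_idx = divmod(i, len(wells))
        entries.append(
            SirnaLibraryEntry(
                uniprot_id=f"Q{i + 1:05d}",
                gene_symbol=f"GENE{i + 1:04d}",
                source_plate=f"SRC{plate_idx + 1:02d}",
                source_well=wells[well_idx],
            )
        )
    return entries


# ---------------------------------------------------------------------------
# qPCR Ct generator


def simulate_qpcr(
    knockdown: Mapping[str, float],
    ct_target_nt: float = 22.0,
    ct_reference: float = 18.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    calibrator_condition: str = "NT",
    reference_gene: str = "REF",
) -> pd.DataFrame:
    """Generate a Ct table consistent with the ddCt model.

    Residual expression ``r = 1 - knockdown`` shifts the target Ct of the
    knocked-down sample by ``-log2(r)`` cycles relative to the calibrator;
    Gaussian noise with SD ``noise_sd`` cycles is added to every Ct.
    """
    rng = np.random.default_rng(seed)
    records = []

    def _rows(condition: str, target_gene: str, ct_shift: float) -> None:
        for rep in range(1, n_replicates + 1):
            records.append(
                {
                    "sample_id": f"{condition}_rep{rep}",
                    "condition": condition,
                    "target_gene": target_gene,
                    "target_ct": ct_target_nt
                    + ct_shift
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                    "reference_gene": reference_gene,
                    "reference_ct": ct_reference
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                }
            )

    for gene, kd in knockdown.items():
        if not 0 <= kd < 1:
            raise ConfigurationError(
                f"knockdown fraction for {gene} must be in [0, 1): got {kd}"
            )
        _rows(calibrator_condition, gene, 0.0)
        _rows(f"siRNA-{gene}", gene, -math.log2(1.0 - kd))
    return pd.DataFrame.from_records(records)
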