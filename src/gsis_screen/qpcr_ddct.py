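"""Relative transcript abundance by the comparative Ct (ddCt) method.

Per sample, dCt = target Ct - reference Ct; ddCt subtracts the mean dCt of
the calibrator condition; relative expression is 2**(-ddCt). Amplification
efficiency is fixed at 100% (base 2) — no efficiency correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "sample_id",
    "condition",
    "target_gene",
    "target_ct",
    "reference_gene",
    "reference_ct",
)


def relative_expression(
    records: pd.DataFrame, calibrator_condition: str = "NT"
) -> pd.DataFrame:
    """Per-sample relative abundance versus the calibrator condition.

    The calibrator statistic is the mean dCt of the calibrator replicates per
    target gene, so the calibrator group has mean ddCt = 0 (relative
    abundance 1) by construction.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if records["reference_gene"].nunique() > 1:
        raise ValueError(
            "mismatched reference genes in one experiment: "
            f"{sorted(records['reference_gene'].unique())}"
        )
    if not np.isfinite(records[["target_ct", "reference_ct"]].to_numpy()).all():
        raise ValueError("non-finite Ct values in table")

    out = records.copy()
    out["delta_ct"] = out["target_ct"] - out["reference_ct"]
    parts = []
    for target, grp in out.groupby("target_gene", sort=False):
        calibrator = grp[grp["condition"] == calibrator_condition]
        if calibrator.empty:
            raise ValueError(
                f"no calibrator ({calibrator_condition!r}) records for "
                f"target {target!r}"
            )
        grp = grp.copy()
        grp["delta_delta_ct"] = grp["delta_ct"] - calibrator["delta_ct"].mean()
        parts.append(grp)
    out = pd.concat(parts, ignore_index=True)
    out["relative_expression"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def knockdown_summary(rel: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD relative expression and percent knockdown per condition.

    SD is NaN for single-replicate conditions.
    """
    records = []
    for (condition, target), grp in rel.groupby(
        ["condition", "target_gene"], sort=True
    ):
        values = grp["relative_expression"].to_numpy(dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")
        records.append(
            {
                "condition": condition,
                "target_gene": target,
                "mean_rel_expr": mean,
                "sd": sd,
                "n": int(values.size),
                "percent_knockdown": 100.0 * (1.0 - mean),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "condition",
            "target_gene",
            "mean_rel_expr",
            "sd",
            "n",
            "percent_knockdown",
        ],
    )
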