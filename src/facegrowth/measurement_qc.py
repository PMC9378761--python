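"""Measurement-level outlier exclusion.

For each phenotype, the values of all photos (past and current, pooled
over the whole cohort) are trimmed at the tails: anything strictly below
the ``lower_pct`` percentile or strictly above the ``100 - upper_pct``
percentile is flagged and excluded from trajectory building.  Percentiles
use linear interpolation on the pooled empirical distribution.

Strict inequalities mean a value lying exactly on a threshold survives,
so at the default 2%/2% at least 96% of records are kept.  Trimming is
NOT idempotent: re-running it on already-trimmed data trims again.

An alternative boxplot-style rule (1.5 x IQR whiskers) is available via
``method="iqr"`` for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["KEPT", "LOW_TAIL", "HIGH_TAIL", "tail_flags", "trim_tails", "apply_mask"]

KEPT = "kept"
LOW_TAIL = "low_tail"
HIGH_TAIL = "high_tail"


def tail_flags(
    values: np.ndarray,
    lower_pct: float = 2.0,
    upper_pct: float = 2.0,
    method: str = "percentile",
) -> np.ndarray:
    """Flag each value as kept / low_tail / high_tail.

    Parameters
    ----------
    values
        Pooled measurements of a single phenotype.
    lower_pct, upper_pct
        Tail percentages; must satisfy ``0 <= lower_pct + upper_pct < 100``.
    method
        ``"percentile"`` trims strictly outside the [lower_pct,
        100 - upper_pct] percentile interval; ``"iqr"`` flags values
        outside the 1.5 x IQR boxplot whiskers instead.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to trim")
    if not (0 <= lower_pct and 0 <= upper_pct and lower_pct + upper_pct < 100):
        raise ValueError("need 0 <= lower_pct + upper_pct < 100")

    if method == "percentile":
        lo = np.percentile(values, lower_pct)
        hi = np.percentile(values, 100.0 - upper_pct)
    elif method == "iqr":
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError(f"unknown method {method!r}")

    flags = np.full(values.shape, KEPT, dtype=object)
    flags[values < lo] = LOW_TAIL
    flags[values > hi] = HIGH_TAIL
    return flags


def trim_tails(
    phenotypes: pd.DataFrame,
    lower_pct: float = 2.0,
    upper_pct: float = 2.0,
    method: str = "percentile",
) -> pd.DataFrame:
    """Build a QC mask for a long-format phenotype table.

    Returns one row per input record with columns ``person_id``,
    ``photo_id``, ``phenotype``, ``reason`` (kept/low_tail/high_tail)
    and boolean ``kept``.  Trimming is per phenotype, pooled across all
    photos and persons.
    """
    required = {"person_id", "photo_id", "phenotype", "value"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing column(s): {sorted(missing)}")
    if len(phenotypes) == 0:
        raise ValueError("empty phenotype table")

    mask = phenotypes[["person_id", "photo_id", "phenotype"]].copy()
    reason = np.empty(len(phenotypes), dtype=object)
    for _, idx in phenotypes.groupby("phenotype", sort=False).indices.items():
        reason[idx] = tail_flags(
            phenotypes["value"].to_numpy()[idx], lower_pct, upper_pct, method
        )
    mask["reason"] = reason
    mask["kept"] = reason == KEPT
    return mask


def apply_mask(phenotypes: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Return the phenotype records whose mask row says kept."""
    keys = ["person_id", "photo_id", "phenotype"]
    merged = phenotypes.merge(mask[keys + ["kept"]], on=keys, how="left", validate="1:1")
    if merged["kept"].isna().any():
        raise ValueError("mask does not cover every phenotype record")
    return merged[merged["kept"]].drop(columns="kept").reset_index(drop=True)
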