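"""Descriptive statistics of stranding records and drifter trials.

Percentages are reported at the precision used in field reports (integer
percent, except the gear-mark fraction at one decimal); full-precision values
are available via ``decimals=None``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "recovery_rate",
    "species_composition",
    "site_shares",
    "monthly_frequencies",
    "stranding_rate",
    "gear_mark_fraction",
    "trial_summary",
]


def _round(value: float, decimals: int | None):
    if decimals is None:
        return value
    return round(value, decimals) if decimals > 0 else int(round(value))


def recovery_rate(deployed: int, retrieved: int, decimals: int | None = 0):
    """Percent of deployed drifters later found stranded on monitored beaches."""
    if deployed < 1:
        raise ValueError("deployed must be >= 1")
    if not (0 <= retrieved <= deployed):
        raise ValueError("retrieved must lie in [0, deployed]")
    return _round(100.0 * retrieved / deployed, decimals)


def trial_summary(trials: pd.DataFrame, decimals: int | None = 0) -> pd.DataFrame:
    """Per-trial deployed/retrieved counts with recovery-rate percent."""
    out = trials.copy()
    out["recovery_rate"] = [
        recovery_rate(d, r, decimals) for d, r in zip(out["deployed"], out["retrieved"])
    ]
    return out


def _composition(
    records: pd.DataFrame, column: str, decimals: int | None
) -> pd.DataFrame:
    total = len(records)
    counts = records[column].value_counts()
    out = counts.rename("count").to_frame().reset_index(names=column)
    out["percent"] = [
        _round(100.0 * n / total, decimals) if total else np.nan for n in out["count"]
    ]
    out.attrs["total"] = total
    return out


def species_composition(records: pd.DataFrame, decimals: int | None = 0) -> pd.DataFrame:
    """Carcass counts and percents of the grand total by species.

    Records of unknown species stay in the denominator (the grand total) but
    appear as their own row, so named-species percents need not sum to 100.
    """
    return _composition(records, "species", decimals)


def site_shares(records: pd.DataFrame, decimals: int | None = 0) -> pd.DataFrame:
    """Carcass counts and percents of the grand total by monitoring site."""
    return _composition(records, "site_id", decimals)


def monthly_frequencies(
    records: pd.DataFrame, site_id: str, decimals: int | None = 1
) -> pd.Series:
    """Calendar-month percents of a site's total strandings across the study.

    Returns a length-12 Series indexed 1..12 summing to 100 up to rounding.
    A site with no records yields an all-zero vector with
    ``attrs["empty"] = True``.
    """
    sub = records[records["site_id"] == site_id]
    out = pd.Series(0.0, index=range(1, 13), name=site_id)
    out.index.name = "month"
    if len(sub) == 0:
        out.attrs["empty"] = True
        return out
    months = pd.to_datetime(sub["date"]).dt.month.value_counts()
    for mo, n in months.items():
        out.loc[mo] = 100.0 * n / len(sub)
    if decimals is not None:
        out = out.round(decimals)
    out.attrs["empty"] = False
    return out


def stranding_rate(n_carcasses: int, shoreline_km: float, months: int) -> float:
    """Strandings per kilometre of monitored shoreline per month."""
    if shoreline_km <= 0:
        raise ValueError("shoreline_km must be positive")
    if months < 1:
        raise ValueError("months must be >= 1")
    return n_carcasses / (shoreline_km * months)


def gear_mark_fraction(records: pd.DataFrame, decimals: int | None = 1):
    """Percent of carcasses with definitive fishing-gear marks (hooks, net marks).

    NaN for an empty record set.
    """
    if len(records) == 0:
        return float("nan")
    frac = 100.0 * records["gear_marks"].astype(bool).sum() / len(records)
    return _round(float(frac), decimals) if decimals is not None else float(frac)
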