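"""Translational-engagement readouts from protein fraction tables.

The primary readout is the polysome/free abundance ratio; polysome/monosome
serves as a secondary readout and monosome/free as an initiation proxy.
Hypoxic activation is ranked by the log2 ratio-of-ratios of the primary
readout between conditions.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import SchemaError
from .scheme import FREE, MONOSOME, POLYSOME, FractionScheme

log = logging.getLogger(__name__)

_TABLE_COLUMNS = ("protein_id", "fraction_id", "condition", "channel", "abundance")


def _check_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing columns: {missing}")


def filter_silac(table: pd.DataFrame,
                 return_dropped: bool = False):
    """Retain light-channel rows only; heavy pulse signals are excluded.

    Proteins with no light signal in any fraction (all-zero or absent) are
    dropped and logged. Idempotent on an already light-only table.
    """
    _check_columns(table, _TABLE_COLUMNS)
    light = table[table["channel"] == "light"].copy()
    totals = light.groupby("protein_id")["abundance"].sum()
    detected = set(totals[totals > 0].index)
    all_proteins = set(table["protein_id"])
    dropped = sorted(all_proteins - detected)
    if dropped:
        log.info("filter_silac: dropping %d protein(s) with no light signal: %s",
                 len(dropped), dropped[:20])
    out = light[light["protein_id"].isin(detected)].reset_index(drop=True)
    if return_dropped:
        return out, dropped
    return out


def engagement_ratios(table: pd.DataFrame, scheme: FractionScheme,
                      condition: str, agg: str = "sum") -> pd.DataFrame:
    """Per-protein compartment ratios for one condition.

    ``pf = Σ_polysome / Σ_free`` (primary), ``pm = Σ_polysome /
    Σ_monosome`` (secondary), ``mf = Σ_monosome / Σ_free`` (initiation
    proxy). A zero denominator leaves the ratio undefined (NaN) with its
    ``*_defined`` flag false; no pseudocount is applied.

    ``agg`` may be ``"sum"`` (default; equal-volume fractions) or
    ``"mean"``.
    """
    _check_columns(table, ("protein_id", "fraction_id", "condition", "abundance"))
    if agg not in ("sum", "mean"):
        raise SchemaError("agg must be 'sum' or 'mean'")
    sub = table[table["condition"] == condition]
    unknown = set(sub["fraction_id"]) - set(scheme.fraction_ids)
    if unknown:
        raise SchemaError(f"fractions not in scheme: {sorted(unknown)}")
    comp = sub["fraction_id"].map(scheme.compartment)
    agg_fn = getattr(sub.groupby(["protein_id", comp])["abundance"], agg)
    sums = agg_fn().unstack(fill_value=0.0)
    for c in (FREE, MONOSOME, POLYSOME):
        if c not in sums.columns:
            sums[c] = 0.0

    def ratio(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = sums[num] / sums[den]
        return r.where(sums[den] > 0)

    out = pd.DataFrame({
        "protein_id": sums.index,
        "condition": condition,
        "pf_ratio": ratio(POLYSOME, FREE).to_numpy(),
        "pm_ratio": ratio(POLYSOME, MONOSOME).to_numpy(),
        "mf_ratio": ratio(MONOSOME, FREE).to_numpy(),
    })
    for col in ("pf", "pm", "mf"):
        out[f"{col}_defined"] = out[f"{col}_ratio"].notna()
    return out.reset_index(drop=True)


def activation_ranking(normoxia: pd.DataFrame, hypoxia: pd.DataFrame,
                       return_excluded: bool = False):
    """Rank proteins by hypoxic activation of the primary readout.

    ``primary_score = log2(pf_hypoxia / pf_normoxia)``; the secondary
    score is the same for the polysome/monosome ratio. Sorted descending
    by primary score, ties broken by secondary score descending, then
    protein id. Proteins whose primary ratio is undefined or zero in
    either condition are excluded and reported separately.
    """
    merged = normoxia.merge(hypoxia, on="protein_id", suffixes=("_n", "_h"))
    if merged.empty:
        raise SchemaError("no shared proteins between conditions")
    ok = (merged["pf_defined_n"] & merged["pf_defined_h"]
          & (merged["pf_ratio_n"] > 0) & (merged["pf_ratio_h"] > 0))
    excluded = sorted(merged.loc[~ok, "protein_id"])
    if excluded:
        log.info("activation_ranking: excluding %d protein(s) with undefined "
                 "primary ratios", len(excluded))
    kept = merged[ok].copy()
    kept["primary_score"] = np.log2(kept["pf_ratio_h"] / kept["pf_ratio_n"])
    sec_ok = (kept["pm_defined_n"] & kept["pm_defined_h"]
              & (kept["pm_ratio_n"] > 0) & (kept["pm_ratio_h"] > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        sec = np.log2(kept["pm_ratio_h"] / kept["pm_ratio_n"])
    kept["secondary_score"] = sec.where(sec_ok)
    kept = kept.sort_values(
        ["primary_score", "secondary_score", "protein_id"],
        ascending=[False, False, True], kind="stable",
        na_position="last")
    kept["rank"] = np.arange(1, len(kept) + 1)
    out = kept[["protein_id", "primary_score", "secondary_score", "rank"]]
    out = out.reset_index(drop=True)
    if return_excluded:
        return out, excluded
    return out
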