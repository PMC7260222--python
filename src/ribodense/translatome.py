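"""TMT pulse-label translatome analysis.

Relative protein output per channel, oxygen-response classes (I/II/III at
an inclusive ±15% boundary), RBP-dependency calls, and class-composition
chi-square tests.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, SchemaError

OXYGEN_CLASSES = ("I", "II", "III")

_TMT_COLUMNS = ("protein_id", "sample_id", "condition", "perturbation", "intensity")


def _check(table: pd.DataFrame) -> None:
    missing = [c for c in _TMT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"TMT table is missing columns: {missing}")


def tmt_total_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Equalize channel loading: rescale every channel to the grand mean
    of channel totals. Idempotent; relative within-channel structure is
    preserved. An all-zero channel is an error."""
    _check(table)
    totals = table.groupby("sample_id")["intensity"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise ConfigurationError(
            f"channel(s) with zero total intensity: {list(zero.index)}")
    target = totals.mean()
    factors = target / totals
    out = table.copy()
    out["intensity"] = out["intensity"] * out["sample_id"].map(factors)
    return out


def relative_output(table: pd.DataFrame, protein_id: str, sample_id: str,
                    include_self: bool = True) -> float:
    """Fold difference of one channel against its condition average.

    The denominator is the mean intensity over all samples of the
    queried sample's condition — including the queried sample itself by
    default (set ``include_self=False`` to leave it out). Returns NaN
    when the condition mean is zero.
    """
    _check(table)
    rows = table[table["protein_id"] == protein_id]
    hit = rows[rows["sample_id"] == sample_id]
    if hit.empty:
        raise SchemaError(f"no intensity for ({protein_id!r}, {sample_id!r})")
    condition = hit["condition"].iloc[0]
    pool = rows[rows["condition"] == condition]
    if not include_self:
        pool = pool[pool["sample_id"] != sample_id]
    mean = pool["intensity"].mean()
    if not mean > 0:
        return float("nan")
    return float(hit["intensity"].iloc[0] / mean)


def relative_output_table(table: pd.DataFrame,
                          include_self: bool = True) -> pd.DataFrame:
    """Vectorized :func:`relative_output` for every (protein, sample).

    Adds a ``relative_output`` column; NaN where the condition mean is
    zero. Within each (protein, condition) block the relative outputs
    average to 1 wherever the mean is positive.
    """
    _check(table)
    out = table.copy()
    grp = out.groupby(["protein_id", "condition"])["intensity"]
    if include_self:
        mean = grp.transform("mean")
    else:
        n = grp.transform("count")
        mean = (grp.transform("sum") - out["intensity"]) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = out["intensity"] / mean
    out["relative_output"] = rel.where(mean > 0)
    return out


def classify_oxygen_response(hypoxic_output: float,
                             normoxic_output: float) -> str:
    """Oxygen-response class from condition-level outputs.

    ``r = hypoxic / normoxic``; ``r >= 1.15`` → III (hypoxia-enriched,
    at least 15% increase), ``r <= 0.85`` → I (normoxia-enriched),
    otherwise II. Boundaries inclusive.
    """
    if not (hypoxic_output > 0 and normoxic_output > 0):
        raise ConfigurationError("outputs must be positive")
    r = hypoxic_output / normoxic_output
    if r >= 1.15:
        return "III"
    if r <= 0.85:
        return "I"
    return "II"


def call_dependency(relative_output_of_silenced_sample: float,
                    threshold: float = 0.15) -> str:
    """Dependency call from the silenced channel's relative output.

    ``ratio <= 1 - threshold`` → ``dependent_down`` (the RBP promotes
    output of this protein); ``ratio >= 1 + threshold`` →
    ``dependent_up``; otherwise ``none``. Boundaries inclusive.
    """
    if not (0 < threshold < 1):
        raise ConfigurationError("threshold must be in (0, 1)")
    r = relative_output_of_silenced_sample
    if not r > 0:
        raise ConfigurationError("relative output must be positive")
    if r <= 1 - threshold:
        return "dependent_down"
    if r >= 1 + threshold:
        return "dependent_up"
    return "none"


def classify_experiment(table: pd.DataFrame, threshold: float = 0.15,
                        include_self: bool = True) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-protein analysis of a TMT experiment.

    Oxygen classes compare the mean NS output between hypoxia and
    normoxia; silenced channels feed the per-RBP dependency calls via
    their within-condition relative outputs.

    Returns ``(classes, dependencies)``: classes has columns
    ``protein_id, output_ratio, oxygen_class``; dependencies has
    ``protein_id, rbp, condition, relative_output, dependency``.
    """
    _check(table)
    rel = relative_output_table(table, include_self=include_self)

    ns = table[table["perturbation"] == "NS"]
    ns_mean = ns.groupby(["protein_id", "condition"])["intensity"].mean().unstack()
    for cond in ("normoxia", "hypoxia"):
        if cond not in ns_mean.columns:
            raise ConfigurationError(f"no NS sample in condition {cond!r}")
    ratio = ns_mean["hypoxia"] / ns_mean["normoxia"]
    classes = pd.DataFrame({
        "protein_id": ratio.index,
        "output_ratio": ratio.to_numpy(),
    })
    classes["oxygen_class"] = [
        classify_oxygen_response(h, n) if (h > 0 and n > 0) else pd.NA
        for h, n in zip(ns_mean["hypoxia"], ns_mean["normoxia"])
    ]

    sil = rel[rel["perturbation"] != "NS"].copy()
    calls = []
    for r in sil["relative_output"]:
        calls.append(call_dependency(r, threshold) if r > 0 else pd.NA)
    sil["dependency"] = calls
    deps = sil[["protein_id", "perturbation", "condition",
                "relative_output", "dependency"]]
    deps = deps.rename(columns={"perturbation": "rbp"}).reset_index(drop=True)
    return classes.reset_index(drop=True), deps


def dependency_portfolios(dependencies: pd.DataFrame,
                          condition: str = "hypoxia",
                          direction: str = "dependent_down") -> Dict[str, frozenset]:
    """Per-RBP target sets from dependency calls in one condition."""
    sub = dependencies[(dependencies["condition"] == condition)
                       & (dependencies["dependency"] == direction)]
    return {rbp: frozenset(g["protein_id"])
            for rbp, g in sub.groupby("rbp")}


def composition_test(subset_class_counts: Mapping[str, int],
                     background_class_counts: Mapping[str, int],
                     zero_policy: str = "error") -> Tuple[float, float, int]:
    """Pearson chi-square of a subset's class composition against the
    background proportions.

    Expected counts are the subset total apportioned by background
    proportions over the nonzero background classes; ``df`` is the
    number of nonzero background classes minus one. Classes with zero
    background count are dropped when the subset observes nothing there
    (``zero_policy="merge"`` folds such observations into the largest
    background class instead of raising).

    Returns ``(statistic, p_value, df)``.
    """
    classes = sorted(set(subset_class_counts) | set(background_class_counts))
    obs = np.array([subset_class_counts.get(c, 0) for c in classes], dtype=float)
    bg = np.array([background_class_counts.get(c, 0) for c in classes], dtype=float)
    if obs.sum() <= 0:
        raise ConfigurationError("subset total must be positive")
    if bg.sum() <= 0:
        raise ConfigurationError("background total must be positive")
    nonzero = bg > 0
    if np.any(obs[~nonzero] > 0):
        if zero_policy == "merge":
            target = int(np.argmax(bg))
            obs[target] += obs[~nonzero].sum()
        else:
            bad = [c for c, nz, o in zip(classes, nonzero, obs) if not nz and o > 0]
            raise ConfigurationError(
                f"observed counts in zero-background class(es) {bad}; "
                "use zero_policy='merge' to fold them in")
    obs = obs[nonzero]
    bg = bg[nonzero]
    expected = obs.sum() * bg / bg.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = int(nonzero.sum()) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0:
        stat = 0.0
    return stat, p, df


def composition_tests_by_rbp(portfolios: Mapping[str, frozenset],
                             classes: pd.DataFrame) -> pd.DataFrame:
    """Chi-square composition test for each RBP's target set.

    Raw p-values per RBP plus Benjamini–Hochberg adjusted values across
    RBPs (the adjustment is an addition to the raw per-RBP report).
    """
    background = classes["oxygen_class"].value_counts().to_dict()
    class_of = classes.set_index("protein_id")["oxygen_class"]
    rows = []
    for rbp, members in portfolios.items():
        sub = class_of.reindex(sorted(members)).dropna().value_counts().to_dict()
        stat, p, df = composition_test(sub, background)
        row = {"rbp": rbp, "n_targets": int(sum(sub.values())),
               "chi2": stat, "df": df, "p_value": p}
        for c in OXYGEN_CLASSES:
            row[f"n_class_{c}"] = int(sub.get(c, 0))
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
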