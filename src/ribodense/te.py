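"""Fraction-level RNA-seq analytics.

Translation efficiency (polysomal FPKM over free+monosomal FPKM),
steady-state RNA (aggregate FPKM across fractions), knockdown/control
delta classification into regulatory quadrants at an inclusive two-fold
boundary, polysome area-under-curve, and the comparative Ct helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .scheme import FREE, MONOSOME, POLYSOME, FractionScheme

_FPKM_COLUMNS = ("gene_id", "sample_id", "fraction_id", "fpkm")

QUADRANTS = ("te_only", "rna_only", "both", "neither")


def _check(table: pd.DataFrame) -> None:
    missing = [c for c in _FPKM_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"FPKM table is missing columns: {missing}")
    if (table["fpkm"] < 0).any():
        raise ConfigurationError("FPKM values must be non-negative")


def translation_efficiency(table: pd.DataFrame, scheme: FractionScheme,
                           pseudocount: float = 0.0,
                           denominator: str = "free_monosome") -> pd.DataFrame:
    """Per-(gene, sample) translation efficiency and steady-state RNA.

    ``te = Σ_polysome FPKM / (Σ_free FPKM + Σ_monosome FPKM)`` with an
    optional pseudocount added to both sides (default 0: a zero
    denominator leaves TE undefined, flagged via ``te_defined``).
    ``steady_state_rna`` is the aggregate (sum) FPKM across all
    fractions. ``denominator="free"`` restricts the denominator to the
    free compartment.
    """
    _check(table)
    if denominator not in ("free_monosome", "free"):
        raise ConfigurationError("denominator must be 'free_monosome' or 'free'")
    unknown = set(table["fraction_id"]) - set(scheme.fraction_ids)
    if unknown:
        raise SchemaError(f"fractions not in scheme: {sorted(unknown)}")
    comp = table["fraction_id"].map(scheme.compartment)
    sums = (table.groupby(["gene_id", "sample_id", comp])["fpkm"]
            .sum().unstack(fill_value=0.0))
    for c in (FREE, MONOSOME, POLYSOME):
        if c not in sums.columns:
            sums[c] = 0.0
    num = sums[POLYSOME] + pseudocount
    den = sums[FREE] + (sums[MONOSOME] if denominator == "free_monosome" else 0.0)
    den = den + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        te = num / den
    te = te.where(den > 0)
    out = sums.reset_index()[["gene_id", "sample_id"]]
    out.columns.name = None
    out["te"] = te.to_numpy()
    out["te_defined"] = out["te"].notna()
    out["steady_state_rna"] = (sums[FREE] + sums[MONOSOME] + sums[POLYSOME]).to_numpy()
    return out


def steady_state_rna(fpkm_by_fraction: Sequence[float]) -> float:
    """Aggregate (sum) FPKM across all fractions of one gene."""
    arr = np.asarray(fpkm_by_fraction, dtype=float)
    if (arr < 0).any():
        raise ConfigurationError("FPKM values must be non-negative")
    return float(arr.sum())


def _significant(ratio: float, fold: float) -> bool:
    return ratio >= fold or ratio <= 1.0 / fold


def delta_classification(te_kd: float, te_ns: float, rna_kd: float,
                         rna_ns: float, fold_threshold: float = 2.0) -> dict:
    """Classify one gene's knockdown deltas into a regulatory quadrant.

    ``delta_te = te_kd / te_ns`` and ``delta_rna = rna_kd / rna_ns``. A
    delta is significant iff it is ``>= fold_threshold`` or
    ``<= 1/fold_threshold`` (inclusive). The quadrant follows from the
    two significance flags (``te_only``, ``rna_only``, ``both``,
    ``neither``); direction is ``down``/``up`` from the significant
    side(s), ``mixed`` when the two significant deltas disagree, and
    ``none`` for the neither quadrant.
    """
    if fold_threshold <= 1:
        raise ConfigurationError("fold_threshold must be > 1")
    for name, v in (("te_ns", te_ns), ("rna_ns", rna_ns)):
        if not (v is not None and v > 0 and math.isfinite(v)):
            raise ConfigurationError(f"{name} must be positive and finite")
    if te_kd is None or not math.isfinite(te_kd) or te_kd < 0:
        raise ConfigurationError("te_kd must be a non-negative finite value")
    if rna_kd is None or not math.isfinite(rna_kd) or rna_kd < 0:
        raise ConfigurationError("rna_kd must be a non-negative finite value")
    delta_te = te_kd / te_ns
    delta_rna = rna_kd / rna_ns
    sig_te = _significant(delta_te, fold_threshold)
    sig_rna = _significant(delta_rna, fold_threshold)
    if sig_te and sig_rna:
        quadrant = "both"
    elif sig_te:
        quadrant = "te_only"
    elif sig_rna:
        quadrant = "rna_only"
    else:
        quadrant = "neither"
    dirs = []
    if sig_te:
        dirs.append("down" if delta_te < 1 else "up")
    if sig_rna:
        dirs.append("down" if delta_rna < 1 else "up")
    if not dirs:
        direction = "none"
    elif len(set(dirs)) == 1:
        direction = dirs[0]
    else:
        direction = "mixed"
    return {"delta_te": delta_te, "delta_rna": delta_rna,
            "quadrant": quadrant, "direction": direction}


def delta_table(te_records: pd.DataFrame, ns_sample: str, kd_sample: str,
                fold_threshold: float = 2.0, min_expr: float = 1.0,
                return_unclassifiable: bool = False):
    """Per-gene delta classification between a knockdown and NS control.

    Genes with undefined TE in either sample, an NS steady-state RNA
    below ``min_expr`` (a conservative ratio-stability filter; set 0 to
    disable), or a zero NS denominator are routed to an unclassifiable
    report instead of the output.
    """
    piv = te_records.pivot(index="gene_id", columns="sample_id",
                           values=["te", "steady_state_rna", "te_defined"])
    for s in (ns_sample, kd_sample):
        if s not in piv["te"].columns:
            raise SchemaError(f"sample {s!r} not present in TE records")
    rows, bad = [], []
    for gene in piv.index:
        te_ns = piv.loc[gene, ("te", ns_sample)]
        te_kd = piv.loc[gene, ("te", kd_sample)]
        rna_ns = piv.loc[gene, ("steady_state_rna", ns_sample)]
        rna_kd = piv.loc[gene, ("steady_state_rna", kd_sample)]
        defined = bool(piv.loc[gene, ("te_defined", ns_sample)]
                       and piv.loc[gene, ("te_defined", kd_sample)])
        if (not defined or not te_ns > 0 or not rna_ns > 0
                or rna_ns < min_expr):
            bad.append(gene)
            continue
        rec = delta_classification(te_kd, te_ns, rna_kd, rna_ns, fold_threshold)
        rec["gene_id"] = gene
        rows.append(rec)
    cols = ["gene_id", "delta_te", "delta_rna", "quadrant", "direction"]
    out = pd.DataFrame(rows, columns=cols)
    if return_unclassifiable:
        return out, bad
    return out


def quadrant_summary(deltas: pd.DataFrame) -> Dict[str, int]:
    """Quadrant counts plus the TE-/RNA-affected marginals.

    ``te_affected = te_only + both`` and ``rna_affected = rna_only +
    both``; the quadrant counts partition the classifiable genes.
    """
    counts = deltas["quadrant"].value_counts().to_dict()
    out = {q: int(counts.get(q, 0)) for q in QUADRANTS}
    out["te_affected"] = out["te_only"] + out["both"]
    out["rna_affected"] = out["rna_only"] + out["both"]
    out["classified"] = int(len(deltas))
    return out


def summarize_magnitudes(deltas: pd.DataFrame) -> Dict[str, float]:
    """Mean percent change of the delta ratios per axis.

    ``percent_decrease = 100 × (1 − geometric mean of ratios)`` (the
    headline statistic); the arithmetic-mean variant is reported
    alongside, clearly labeled.
    """
    if deltas.empty:
        raise ConfigurationError("cannot summarize an empty delta set")
    out = {}
    for axis in ("te", "rna"):
        ratios = deltas[f"delta_{axis}"].to_numpy(dtype=float)
        if (ratios <= 0).any():
            raise ConfigurationError("ratios must be positive to summarize")
        gmean = float(np.exp(np.mean(np.log(ratios))))
        amean = float(np.mean(ratios))
        out[f"{axis}_percent_change_geometric"] = 100.0 * (1.0 - gmean)
        out[f"{axis}_percent_change_arithmetic"] = 100.0 * (1.0 - amean)
    return out


def polysome_auc(position: Sequence[float], signal: Sequence[float],
                 polysome_boundary: float) -> float:
    """Proportion of trapezoidal area at positions >= the boundary.

    The trace is linearly interpolated at the boundary so the split is
    exact for piecewise-linear signals. Returns NaN (flagged undefined)
    when the total area is zero.
    """
    x = np.asarray(position, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ConfigurationError("trace needs >= 2 matching (position, signal) points")
    if (np.diff(x) <= 0).any():
        raise ConfigurationError("positions must be strictly increasing")
    if (y < 0).any():
        raise ConfigurationError("signal must be non-negative")
    if not (x[0] <= polysome_boundary <= x[-1]):
        raise ConfigurationError("boundary outside the trace range")
    total = float(np.trapezoid(y, x))
    if total <= 0:
        return float("nan")
    if polysome_boundary not in x:
        yb = float(np.interp(polysome_boundary, x, y))
        idx = int(np.searchsorted(x, polysome_boundary))
        x = np.insert(x, idx, polysome_boundary)
        y = np.insert(y, idx, yb)
    mask = x >= polysome_boundary
    poly = float(np.trapezoid(y[mask], x[mask])) if mask.sum() >= 2 else 0.0
    return poly / total


def ddct(ct_target_test: float, ct_reference_test: float,
         ct_target_calibrator: float, ct_reference_calibrator: float) -> float:
    """Comparative Ct fold change: ``2**-ΔΔCt``.

    ``ΔΔCt = (Ct_target − Ct_reference)_test − (Ct_target −
    Ct_reference)_calibrator``; the reference is typically 18S rRNA.
    """
    vals = (ct_target_test, ct_reference_test,
            ct_target_calibrator, ct_reference_calibrator)
    if not all(math.isfinite(v) for v in vals):
        raise ConfigurationError("Ct values must be finite")
    ddct_val = ((ct_target_test - ct_reference_test)
                - (ct_target_calibrator - ct_reference_calibrator))
    return float(2.0 ** (-ddct_val))
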