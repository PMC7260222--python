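"""Forward simulators for the fractionation / labeling experiments.

Every simulator is a pure function of ``(truth, scheme, noise config)``:
the same seed and configuration reproduce identical tables. The noise-free
regime (``lognormal_sigma=0, tmt_kappa=1, nb_dispersion=0``) is exactly
identifiable by the downstream estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import NoiseConfig
from .errors import ConfigurationError
from .scheme import FREE, MONOSOME, POLYSOME, FractionScheme
from .truth import CONDITIONS, TruthTable

# ---------------------------------------------------------------------------
# pulse-label kinetics
# ---------------------------------------------------------------------------


def heavy_fraction(pulse_hours, halflife_hours):
    """Heavy-label share after a pulse: ``h = 1 - 2**(-t / halflife)``.

    First-order turnover with the given half-life; ``h(0) = 0``,
    ``h`` is strictly increasing in ``t`` and always ``< 1``.
    """
    t = np.asarray(pulse_hours, dtype=float)
    hl = np.asarray(halflife_hours, dtype=float)
    if np.any(hl <= 0):
        raise ConfigurationError("halflife_hours must be positive")
    if np.any(t < 0):
        raise ConfigurationError("pulse_hours must be >= 0")
    return 1.0 - np.exp2(-t / hl)


def simulate_psilac_split(truth: TruthTable, pulse_hours: float) -> pd.Series:
    """Per-entity heavy-label share for a pulse of ``pulse_hours``."""
    h = heavy_fraction(pulse_hours, truth.table["halflife_hours"].to_numpy())
    return pd.Series(h, index=truth.entity_ids, name="heavy_fraction")


# ---------------------------------------------------------------------------
# protein fraction tables (engagement readout input)
# ---------------------------------------------------------------------------


def simulate_protein_fractions(
    truth: TruthTable,
    scheme: FractionScheme,
    noise: NoiseConfig,
    *,
    conditions: Sequence[str] = CONDITIONS,
    pulse_hours: float = 4.0,
) -> pd.DataFrame:
    """Simulate per-protein abundance across gradient fractions.

    Each entity's mass is split across compartments by its per-condition
    engagement weights and spread uniformly over the compartment's
    fractions. A heavy/light pulse split is applied per entity, then
    multiplicative lognormal noise per cell. Columns:
    ``protein_id, fraction_id, condition, channel, abundance``.
    """
    rng = np.random.default_rng(noise.seed)
    comp_fracs = {c: scheme.fractions_in(c) for c in (FREE, MONOSOME, POLYSOME)}
    t = truth.table
    h = heavy_fraction(pulse_hours, t["halflife_hours"].to_numpy())
    base = t["base_abundance"].to_numpy()

    frames = []
    for condition in conditions:
        w = {
            FREE: t[f"w_free_{condition}"].to_numpy(),
            MONOSOME: t[f"w_mono_{condition}"].to_numpy(),
            POLYSOME: t[f"w_poly_{condition}"].to_numpy(),
        }
        for comp, fracs in comp_fracs.items():
            per_frac = base * w[comp] / len(fracs)
            for f in fracs:
                for channel, share in (("light", 1.0 - h), ("heavy", h)):
                    frames.append(pd.DataFrame({
                        "protein_id": t["entity_id"],
                        "fraction_id": f,
                        "condition": condition,
                        "channel": channel,
                        "abundance": per_frac * share,
                    }))
    out = pd.concat(frames, ignore_index=True)
    # canonical order keeps seeded noise reproducible across runs
    out = out.sort_values(
        ["condition", "channel", "fraction_id", "protein_id"],
        ignore_index=True, kind="stable")
    if noise.lognormal_sigma > 0:
        out["abundance"] *= np.exp(
            rng.normal(0.0, noise.lognormal_sigma, size=len(out)))
    return out


# ---------------------------------------------------------------------------
# TMT pulse-label intensities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TmtSample:
    sample_id: str
    condition: str
    perturbation: str = "NS"


def default_tmt_design(rbps: Sequence[str],
                       conditions: Sequence[str] = CONDITIONS) -> Tuple[TmtSample, ...]:
    """One NS channel plus one silenced channel per RBP, per condition."""
    design = []
    for cond in conditions:
        design.append(TmtSample(f"{cond}_NS", cond, "NS"))
        for r in rbps:
            design.append(TmtSample(f"{cond}_si{r}", cond, r))
    return tuple(design)


def simulate_tmt(
    truth: TruthTable,
    design: Sequence[TmtSample],
    noise: NoiseConfig,
    *,
    pulse_hours: float = 16.0,
    reference: Tuple[str, str] = ("normoxia", "NS"),
) -> pd.DataFrame:
    """Simulate newly-synthesized (heavy) TMT channel intensities.

    True per-channel output is ``base_abundance × heavy_share × hypoxic
    output ratio (hypoxia channels) × silencing effect (targets of the
    silenced RBP)``. Ratio compression is applied per protein relative to
    the reference channel (default: normoxia NS): the observed
    ratio-to-reference is the true ratio raised to ``tmt_kappa``. Then
    lognormal noise. Columns: ``protein_id, sample_id, condition,
    perturbation, intensity``.
    """
    conditions = {s.condition for s in design}
    for cond in conditions:
        if not any(s.condition == cond and s.perturbation == "NS" for s in design):
            raise ConfigurationError(f"design has no NS sample in condition {cond!r}")
    if not design:
        raise ConfigurationError("design has no samples")

    rng = np.random.default_rng(noise.seed + 1)
    t = truth.table
    h = heavy_fraction(pulse_hours, t["halflife_hours"].to_numpy())
    base = t["base_abundance"].to_numpy() * h

    def true_intensity(sample: TmtSample) -> np.ndarray:
        x = base.copy()
        if sample.condition == "hypoxia":
            x = x * t["output_ratio"].to_numpy()
        if sample.perturbation != "NS":
            col = f"effect_output_{sample.perturbation}"
            if col not in t.columns:
                raise ConfigurationError(
                    f"unknown perturbation {sample.perturbation!r}")
            x = x * t[col].to_numpy()
        return x

    ref_sample = next(s for s in design
                      if (s.condition, s.perturbation) == reference)
    ref = true_intensity(ref_sample)

    frames = []
    for sample in design:
        x = true_intensity(sample)
        if noise.tmt_kappa != 1.0:
            with np.errstate(divide="ignore", invalid="ignore"):
                obs = np.where(ref > 0, ref * (x / ref) ** noise.tmt_kappa, x)
        else:
            obs = x
        frames.append(pd.DataFrame({
            "protein_id": t["entity_id"],
            "sample_id": sample.sample_id,
            "condition": sample.condition,
            "perturbation": sample.perturbation,
            "intensity": obs,
        }))
    out = pd.concat(frames, ignore_index=True)
    if noise.lognormal_sigma > 0:
        out["intensity"] *= np.exp(
            rng.normal(0.0, noise.lognormal_sigma, size=len(out)))
    return out


# ---------------------------------------------------------------------------
# fraction-level RNA counts / FPKM
# ---------------------------------------------------------------------------


def ribosome_load_pmf(lam: float, kmax: int) -> np.ndarray:
    """Poisson(λ) ribosome-count pmf truncated (lumped) at ``kmax``."""
    if lam < 0:
        raise ConfigurationError("ribosome load must be >= 0")
    k = np.arange(kmax + 1)
    p = stats.poisson.pmf(k, lam)
    p[-1] = max(stats.poisson.sf(kmax - 1, lam), 0.0)
    return p


def planted_te(lam: float) -> float:
    """Translation efficiency implied by a ribosome load λ.

    ``TE = P(k >= 2) / P(k <= 1)`` under the Poisson load model;
    lumping the tail does not change either side.
    """
    if lam < 0:
        raise ConfigurationError("ribosome load must be >= 0")
    denom = math.exp(-lam) * (1.0 + lam)
    return 1.0 / denom - 1.0


def lambda_for_te(target_te: float) -> float:
    """Inverse of :func:`planted_te` (monotone, solved by bisection)."""
    if target_te < 0:
        raise ConfigurationError("target TE must be >= 0")
    if target_te == 0:
        return 0.0
    return float(optimize.brentq(
        lambda lam: planted_te(lam) - target_te, 0.0, 700.0, xtol=1e-12))


def _fraction_probabilities(lam: np.ndarray, scheme: FractionScheme) -> pd.DataFrame:
    """Per-gene probability mass assigned to each fraction.

    k=0 is spread over free fractions, k=1 over monosome fractions, and
    each k>=2 over the polysome fractions annotated with that ribosome
    count (tail lumped into the deepest annotation). Without ribosome
    annotations the whole k>=2 mass is spread evenly over polysome
    fractions.
    """
    free = scheme.fractions_in(FREE)
    mono = scheme.fractions_in(MONOSOME)
    poly = scheme.fractions_in(POLYSOME)
    kmax = scheme.max_ribosome_count or 2
    n = len(lam)
    pmf = np.vstack([ribosome_load_pmf(l, kmax) for l in lam])  # (n, kmax+1)

    cols: Dict[str, np.ndarray] = {}
    for f in free:
        cols[f] = pmf[:, 0] / len(free)
    for f in mono:
        cols[f] = pmf[:, 1] / len(mono)
    p_poly = pmf[:, 2:].sum(axis=1)
    if scheme.ribosome_count:
        for k in range(2, kmax + 1):
            fracs = scheme.fractions_with_count(k)
            if not fracs:
                continue
            for f in fracs:
                cols[f] = pmf[:, k] / len(fracs)
        covered = {f for k in range(2, kmax + 1)
                   for f in scheme.fractions_with_count(k)}
        rest = [f for f in poly if f not in covered]
        for f in rest:
            cols[f] = np.zeros(n)
    else:
        for f in poly:
            cols[f] = p_poly / len(poly)
    return pd.DataFrame(cols, columns=list(scheme.fraction_ids))


def _sample_abundances(truth: TruthTable, scheme: FractionScheme,
                       condition: str, perturbation: str) -> pd.DataFrame:
    """Expected transcript mass per (gene, fraction) for one sample."""
    t = truth.table
    lam_base = t[f"lambda_{condition}"].to_numpy().astype(float)
    rna = t["base_abundance"].to_numpy().astype(float)
    if perturbation != "NS":
        te_col = f"effect_te_{perturbation}"
        rna_col = f"effect_rna_{perturbation}"
        if te_col not in t.columns:
            raise ConfigurationError(f"unknown perturbation {perturbation!r}")
        rna = rna * t[rna_col].to_numpy()
        te_eff = t[te_col].to_numpy()
        lam = lam_base.copy()
        for i, (l0, e) in enumerate(zip(lam_base, te_eff)):
            if e != 1.0 and l0 > 0:
                lam[i] = lambda_for_te(planted_te(l0) * e)
    else:
        lam = lam_base
    probs = _fraction_probabilities(lam, scheme)
    ab = probs.mul(rna, axis=0)
    ab.index = truth.entity_ids
    return ab


def simulate_fraction_counts(
    truth: TruthTable,
    scheme: FractionScheme,
    noise: NoiseConfig,
    samples: Sequence[Tuple[str, str]] = (("NS", "NS"),),
    *,
    condition: str = "hypoxia",
    fpkm_norm: str = "sample",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-fraction RNA-seq counts and derive FPKM.

    ``samples`` is a sequence of ``(sample_id, perturbation)`` pairs, all
    within ``condition``. Expected reads per (gene, fraction) are
    proportional to transcript mass × gene length, scaled so a sample
    totals ``library_size × n_fractions`` reads; counts are negative
    binomial with dispersion ``nb_dispersion`` (0 → rounded
    expectations). FPKM divides counts by gene length (kb) and millions
    of mapped reads — per whole sample when ``fpkm_norm="sample"``
    (default; preserves cross-fraction ratios, so planted TE is
    recovered) or per fraction when ``fpkm_norm="fraction"``.

    Returns ``(fpkm_table, counts_table)`` with columns
    ``gene_id, sample_id, fraction_id, fpkm|count``.
    """
    if fpkm_norm not in ("sample", "fraction"):
        raise ConfigurationError("fpkm_norm must be 'sample' or 'fraction'")
    rng = np.random.default_rng(noise.seed + 2)
    kb = truth.table["gene_length_kb"].to_numpy()
    total_reads = noise.library_size * len(scheme.fraction_ids)

    fpkm_frames, count_frames = [], []
    for sample_id, perturbation in samples:
        ab = _sample_abundances(truth, scheme, condition, perturbation)
        read_mass = ab.mul(kb, axis=0)
        mu = read_mass * (total_reads / read_mass.to_numpy().sum())
        if noise.nb_dispersion == 0:
            counts = np.rint(mu.to_numpy())
        else:
            shape = 1.0 / noise.nb_dispersion
            lam_draw = rng.gamma(shape, 1.0, size=mu.shape) / shape
            counts = rng.poisson(mu.to_numpy() * lam_draw).astype(float)
        counts_df = pd.DataFrame(counts, index=ab.index, columns=ab.columns)
        if fpkm_norm == "sample":
            mapped_m = counts.sum() / 1e6
            denom = np.full(counts.shape[1], mapped_m)
        else:
            denom = counts.sum(axis=0) / 1e6
        with np.errstate(divide="ignore", invalid="ignore"):
            fpkm = counts / kb[:, None] / denom[None, :]
        fpkm = np.nan_to_num(fpkm)
        fpkm_df = pd.DataFrame(fpkm, index=ab.index, columns=ab.columns)
        for df, frames, value in ((fpkm_df, fpkm_frames, "fpkm"),
                                  (counts_df, count_frames, "count")):
            long = df.stack().rename(value).reset_index()
            long.columns = ["gene_id", "fraction_id", value]
            long.insert(1, "sample_id", sample_id)
            frames.append(long)
    return (pd.concat(fpkm_frames, ignore_index=True),
            pd.concat(count_frames, ignore_index=True))


def expected_fpkm(
    truth: TruthTable,
    scheme: FractionScheme,
    samples: Sequence[Tuple[str, str]] = (("NS", "NS"),),
    *,
    condition: str = "hypoxia",
) -> pd.DataFrame:
    """Noise-free FPKM expectations (no count rounding).

    The reference path for identifiability tests: FPKM is proportional to
    per-(gene, fraction) transcript mass with one constant per sample, so
    TE and steady-state ratios computed from it equal the planted values
    exactly.
    """
    kb = truth.table["gene_length_kb"].to_numpy()
    frames = []
    for sample_id, perturbation in samples:
        ab = _sample_abundances(truth, scheme, condition, perturbation)
        total_kb_mass = ab.mul(kb, axis=0).to_numpy().sum()
        fpkm = ab * (1e6 / total_kb_mass)
        long = fpkm.stack().rename("fpkm").reset_index()
        long.columns = ["gene_id", "fraction_id", "fpkm"]
        long.insert(1, "sample_id", sample_id)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
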