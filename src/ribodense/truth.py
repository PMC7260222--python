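"""Planted-truth generation.

The truth table fixes, per entity, an oxygen-response class, compartment
engagement weights per condition, ribosome loads, a protein half-life and
per-RBP knockdown effects. Every simulator in :mod:`ribodense.simulate`
is a deterministic function of a truth table, a fraction scheme and a
noise configuration, so all downstream estimators can be checked against
a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CONDITIONS = ("normoxia", "hypoxia")

#: Inclusive multiplicative boundaries of the oxygen-response classes.
CLASS_DOWN = 0.85
CLASS_UP = 1.15

#: Hypoxic/normoxic output-ratio ranges the generator draws from, per class.
DEFAULT_CLASS_RATIO_RANGES = {
    "I": (0.55, 0.85),
    "II": (0.90, 1.10),
    "III": (1.15, 1.95),
}


def largest_remainder(n: int, proportions: Sequence[float]) -> Tuple[int, ...]:
    """Deterministically apportion ``n`` into integer counts.

    Uses largest-remainder (Hamilton) rounding; ties broken by position.
    """
    props = np.asarray(proportions, dtype=float)
    if np.any(props < 0):
        raise ConfigurationError("proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1")
    quotas = n * props
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    # stable argsort => ties broken by position
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return tuple(int(c) for c in counts)


@dataclass(frozen=True)
class RbpConfig:
    """Portfolio layout for the simulated RBP knockdowns.

    Parameters
    ----------
    sizes
        Mapping ``rbp_name -> portfolio size`` (targets drawn without
        replacement from the entity pool).
    overlaps
        Mapping ``(rbp_a, rbp_b) -> requested |A ∩ B|``. Pairs not listed
        are built disjoint. Overlap elements are taken from members that
        belong to no third portfolio, so requested pairwise overlaps are
        honored exactly.
    output_effect, te_effect, rna_effect
        Multiplicative effect of silencing the RBP on its targets'
        protein output, translation efficiency and RNA level
        (1 = no effect). Scalars apply to every RBP; mappings override
        per RBP.
    """

    sizes: Mapping[str, int]
    overlaps: Mapping[Tuple[str, str], int] = field(default_factory=dict)
    output_effect: object = 0.8
    te_effect: object = 1.0
    rna_effect: object = 1.0

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.sizes)

    def effect(self, which: str, rbp: str) -> float:
        val = getattr(self, which + "_effect")
        if isinstance(val, Mapping):
            return float(val.get(rbp, 1.0))
        return float(val)


@dataclass
class TruthTable:
    """Planted ground truth: one row per entity plus portfolio metadata.

    ``table`` columns: ``entity_id, class_label, base_abundance,
    output_ratio, halflife_hours, gene_length_kb, activated,
    engagement_shift, lambda_normoxia, lambda_hypoxia,
    w_{free,mono,poly}_{normoxia,hypoxia}`` and, per RBP ``R``,
    ``effect_output_R, effect_te_R, effect_rna_R``.
    """

    table: pd.DataFrame
    rbps: Tuple[str, ...] = ()

    @property
    def entity_ids(self) -> pd.Index:
        return pd.Index(self.table["entity_id"])

    @property
    def n_entities(self) -> int:
        return len(self.table)

    def weights(self, condition: str) -> pd.DataFrame:
        """Per-entity ``(w_free, w_mono, w_poly)`` for ``condition``."""
        cols = [f"w_{c}_{condition}" for c in ("free", "mono", "poly")]
        out = self.table.set_index("entity_id")[cols]
        out.columns = ["w_free", "w_mono", "w_poly"]
        return out

    def portfolio(self, rbp: str) -> frozenset:
        col = f"effect_output_{rbp}"
        t = self.table
        hit = (t[col] != 1.0)
        for which in ("te", "rna"):
            hit |= (t[f"effect_{which}_{rbp}"] != 1.0)
        return frozenset(t.loc[hit, "entity_id"])

    def portfolios(self) -> Dict[str, frozenset]:
        return {r: self.portfolio(r) for r in self.rbps}


def _build_portfolios(entities: Sequence[str], cfg: RbpConfig,
                      rng: np.random.Generator) -> Dict[str, set]:
    """Draw portfolios honoring requested pairwise overlaps exactly.

    Portfolios are built in declaration order. For each new portfolio the
    requested overlap with every earlier portfolio is satisfied by
    sampling from that portfolio's single-membership elements, and the
    remainder is sampled from entities in no portfolio. This keeps every
    entity in at most two portfolios, so all pairwise overlaps (listed or
    implied zero) are exact.
    """
    n = len(entities)
    names = list(cfg.names)
    overlaps: Dict[Tuple[str, str], int] = {}
    for (a, b), k in cfg.overlaps.items():
        if a not in names or b not in names:
            raise ConfigurationError(f"overlap refers to unknown RBP pair ({a}, {b})")
        key = (a, b) if names.index(a) < names.index(b) else (b, a)
        overlaps[key] = int(k)

    for name, size in cfg.sizes.items():
        if size < 0 or size > n:
            raise ConfigurationError(
                f"portfolio size for {name} must be in [0, n_entities]")
    for (a, b), k in overlaps.items():
        if k > min(cfg.sizes[a], cfg.sizes[b]):
            raise ConfigurationError(
                f"requested overlap {k} exceeds portfolio size for pair ({a}, {b})")

    membership: Dict[str, list] = {e: [] for e in entities}
    portfolios: Dict[str, set] = {}
    for j, name in enumerate(names):
        chosen: set = set()
        needed = cfg.sizes[name]
        for prev in names[:j]:
            key = (prev, name)
            k = overlaps.get(key, 0)
            if k == 0:
                continue
            pool = [e for e in sorted(portfolios[prev]) if membership[e] == [prev]]
            if len(pool) < k:
                raise ConfigurationError(
                    f"infeasible overlap specification for pair ({prev}, {name}): "
                    f"requested {k}, only {len(pool)} single-membership "
                    f"elements available")
            chosen.update(rng.choice(pool, size=k, replace=False))
        if len(chosen) > needed:
            raise ConfigurationError(
                f"overlaps requested for {name} exceed its portfolio size")
        free_pool = [e for e in entities if not membership[e]]
        extra = needed - len(chosen)
        if len(free_pool) < extra:
            raise ConfigurationError(
                f"not enough unassigned entities to fill portfolio {name}")
        chosen.update(rng.choice(free_pool, size=extra, replace=False))
        portfolios[name] = chosen
        for e in chosen:
            membership[e].append(name)
    return portfolios


def generate_truth(
    n_entities: int,
    class_proportions: Sequence[float] = (0.2, 0.5, 0.3),
    rbp_config: Optional[RbpConfig] = None,
    seed: int = 0,
    *,
    n_activated: int = 0,
    activation_ratio: float = 4.0,
    engagement_jitter: float = 0.05,
    abundance_sigma: float = 0.5,
    halflife_hours: float = 8.0,
    lambda_normoxia: float = 2.0,
    lambda_hypoxia: float = 2.5,
    gene_length_kb_range: Tuple[float, float] = (0.5, 5.0),
    class_ratio_ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    rbp_targets_from_class: Optional[str] = None,
) -> TruthTable:
    """Generate a planted-truth table.

    Class counts follow deterministic largest-remainder rounding of
    ``n_entities × class_proportions`` (order I, II, III; default 30%
    hypoxia-induced). ``n_activated`` entities additionally receive a
    hypoxic engagement shift: their planted polysome/free ratio-of-ratios
    equals ``activation_ratio`` exactly. Identical ``(config, seed)``
    reproduces an identical table.

    Parameters not documented above are plumbing knobs: lognormal
    ``abundance_sigma`` for base masses, per-condition ribosome loads,
    log-uniform gene lengths, and an optional restriction of RBP
    portfolios to one class (``rbp_targets_from_class``).
    """
    if n_entities <= 0:
        raise ConfigurationError("n_entities must be positive")
    if len(class_proportions) != 3:
        raise ConfigurationError("class_proportions must be a triple (I, II, III)")
    counts = largest_remainder(n_entities, class_proportions)
    rng = np.random.default_rng(seed)

    ids = [f"g{i:05d}" for i in range(1, n_entities + 1)]
    labels = np.repeat(["I", "II", "III"], counts)
    labels = labels[rng.permutation(n_entities)]

    ranges = dict(DEFAULT_CLASS_RATIO_RANGES)
    if class_ratio_ranges:
        ranges.update(class_ratio_ranges)
    ratio = np.empty(n_entities)
    for cls in ("I", "II", "III"):
        m = labels == cls
        lo, hi = ranges[cls]
        ratio[m] = rng.uniform(lo, hi, size=m.sum())

    base = np.exp(rng.normal(np.log(100.0), abundance_sigma, size=n_entities))
    lo, hi = gene_length_kb_range
    length_kb = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_entities))

    # normoxic engagement weights: Dirichlet, renormalized to 1e-9 exactness
    w_n = rng.dirichlet((2.0, 3.0, 5.0), size=n_entities)
    w_n /= w_n.sum(axis=1, keepdims=True)

    activated = np.zeros(n_entities, dtype=bool)
    if n_activated:
        if n_activated > n_entities:
            raise ConfigurationError("n_activated exceeds n_entities")
        activated[rng.choice(n_entities, size=n_activated, replace=False)] = True

    # hypoxic weights: per-weight lognormal jitter; activated entities get a
    # deterministic multiplicative boost of w_poly so that the planted
    # polysome/free ratio-of-ratios equals activation_ratio exactly
    # (renormalization cancels in the ratio).
    jit = np.exp(rng.normal(0.0, engagement_jitter, size=(n_entities, 3)))
    jit[activated] = 1.0  # keep the planted shift exact
    w_h = w_n * jit
    shift = np.ones(n_entities)
    shift[activated] = activation_ratio
    w_h[:, 2] *= shift
    w_h /= w_h.sum(axis=1, keepdims=True)

    # planted polysome/free ratio-of-ratios actually realized
    eng_shift = (w_h[:, 2] / w_h[:, 0]) / (w_n[:, 2] / w_n[:, 0])

    data = {
        "entity_id": ids,
        "class_label": labels,
        "base_abundance": base,
        "output_ratio": ratio,
        "halflife_hours": np.full(n_entities, float(halflife_hours)),
        "gene_length_kb": length_kb,
        "activated": activated,
        "engagement_shift": eng_shift,
        "lambda_normoxia": np.full(n_entities, float(lambda_normoxia)),
        "lambda_hypoxia": np.full(n_entities, float(lambda_hypoxia)),
        "w_free_normoxia": w_n[:, 0],
        "w_mono_normoxia": w_n[:, 1],
        "w_poly_normoxia": w_n[:, 2],
        "w_free_hypoxia": w_h[:, 0],
        "w_mono_hypoxia": w_h[:, 1],
        "w_poly_hypoxia": w_h[:, 2],
    }
    table = pd.DataFrame(data)

    rbps: Tuple[str, ...] = ()
    if rbp_config is not None:
        pool = ids
        if rbp_targets_from_class is not None:
            pool = [i for i, c in zip(ids, labels) if c == rbp_targets_from_class]
        portfolios = _build_portfolios(pool, rbp_config, rng)
        rbps = rbp_config.names
        for name in rbps:
            members = table["entity_id"].isin(portfolios[name]).to_numpy()
            for which in ("output", "te", "rna"):
                col = np.ones(n_entities)
                col[members] = rbp_config.effect(which, name)
                table[f"effect_{which}_{name}"] = col
    return TruthTable(table=table, rbps=rbps)
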