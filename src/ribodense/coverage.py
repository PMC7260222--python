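"""Set-level reporting for RBP target portfolios.

Union coverage of a protein universe, exclusive (UpSet-style) intersection
counts, and overlap with a named annotation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Sequence, Tuple

from .errors import ConfigurationError

log = logging.getLogger(__name__)

MAX_SETS = 10


@dataclass
class CoverageReport:
    universe_size: int
    union_size: int
    union_fraction: float
    per_rbp: Dict[str, Tuple[int, float]]
    exclusive_patterns: Dict[FrozenSet[str], int]
    dropped_outside_universe: Dict[str, int] = field(default_factory=dict)


def exclusive_intersections(portfolios: Mapping[str, frozenset]) -> Dict[FrozenSet[str], int]:
    """Count elements by exact membership pattern.

    Every element of the union is assigned the frozenset of portfolio
    names containing it; counts over patterns sum to the union size.
    Refuses more than 10 sets (2**k patterns stop being enumerable
    sensibly — aggregate or split the portfolios first).
    """
    if len(portfolios) > MAX_SETS:
        raise ConfigurationError(
            f"{len(portfolios)} sets requested; exclusive patterns are only "
            f"supported for <= {MAX_SETS}. Merge related portfolios or "
            "report per-RBP counts instead.")
    patterns: Dict[FrozenSet[str], int] = {}
    union = set().union(*portfolios.values()) if portfolios else set()
    for element in union:
        pat = frozenset(name for name, members in portfolios.items()
                        if element in members)
        patterns[pat] = patterns.get(pat, 0) + 1
    return patterns


def union_coverage(universe: frozenset,
                   portfolios: Mapping[str, frozenset]) -> CoverageReport:
    """Coverage of a universe by the union of portfolios.

    Portfolio members outside the universe are dropped (with a logged
    count per portfolio) before any arithmetic; the union fraction is
    ``|∪ portfolios ∩ universe| / |universe|``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ConfigurationError("universe must be non-empty")
    dropped = {}
    restricted = {}
    for name, members in portfolios.items():
        members = frozenset(members)
        outside = len(members - universe)
        if outside:
            log.info("union_coverage: dropping %d element(s) of %s outside "
                     "the universe", outside, name)
            dropped[name] = outside
        restricted[name] = members & universe
    union = frozenset().union(*restricted.values()) if restricted else frozenset()
    per_rbp = {name: (len(m), len(m) / len(universe))
               for name, m in restricted.items()}
    return CoverageReport(
        universe_size=len(universe),
        union_size=len(union),
        union_fraction=len(union) / len(universe),
        per_rbp=per_rbp,
        exclusive_patterns=exclusive_intersections(restricted),
        dropped_outside_universe=dropped,
    )


def annotate_overlap(targets: frozenset, annotation: frozenset,
                     universe: frozenset | None = None) -> Dict[str, float]:
    """Overlap between a target set and a named annotation set.

    Reports the intersection size, the fraction of the annotation
    covered by the targets, and the fraction of targets annotated. When
    a universe is given, both sets are first restricted to it (with a
    logged drop count).
    """
    annotation = frozenset(annotation)
    if not annotation:
        raise ConfigurationError("annotation must be non-empty")
    targets = frozenset(targets)
    if universe is not None:
        universe = frozenset(universe)
        for name, s in (("annotation", annotation), ("targets", targets)):
            outside = len(s - universe)
            if outside:
                log.info("annotate_overlap: dropping %d %s element(s) outside "
                         "the universe", outside, name)
        annotation = annotation & universe
        targets = targets & universe
        if not annotation:
            raise ConfigurationError("annotation is empty after universe restriction")
    inter = targets & annotation
    return {
        "n_targets": len(targets),
        "n_annotation": len(annotation),
        "n_intersection": len(inter),
        "fraction_of_annotation_covered": len(inter) / len(annotation),
        "fraction_of_targets_annotated": (len(inter) / len(targets)
                                          if targets else 0.0),
    }
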