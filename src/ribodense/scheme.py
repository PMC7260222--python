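"""Gradient fraction schemes.

A :class:`FractionScheme` records the ordered fractions collected from a
sucrose gradient, the compartment (``free`` / ``monosome`` / ``polysome``)
each fraction belongs to, and, optionally, the ribosome count annotated on
polysome fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError, SchemaError

COMPARTMENTS = ("free", "monosome", "polysome")

FREE = "free"
MONOSOME = "monosome"
POLYSOME = "polysome"


@dataclass(frozen=True)
class FractionScheme:
    """Ordered gradient fractions with compartment assignment.

    Parameters
    ----------
    fraction_ids
        Fraction identifiers in gradient order (top to bottom).
    compartment
        Mapping ``fraction_id -> {"free", "monosome", "polysome"}``.
        Every fraction must be assigned exactly one compartment and every
        compartment must contain at least one fraction.
    ribosome_count
        Optional mapping ``fraction_id -> ribosome count`` (non-negative,
        non-decreasing along the gradient order).
    """

    fraction_ids: tuple
    compartment: Mapping[str, str]
    ribosome_count: Optional[Mapping[str, int]] = None

    def __post_init__(self):
        object.__setattr__(self, "fraction_ids", tuple(self.fraction_ids))
        object.__setattr__(self, "compartment", dict(self.compartment))
        if self.ribosome_count is not None:
            object.__setattr__(self, "ribosome_count", dict(self.ribosome_count))
        if len(set(self.fraction_ids)) != len(self.fraction_ids):
            raise ConfigurationError("duplicate fraction identifiers")
        missing = [f for f in self.fraction_ids if f not in self.compartment]
        if missing:
            raise ConfigurationError(f"fractions without compartment: {missing}")
        extra = [f for f in self.compartment if f not in self.fraction_ids]
        if extra:
            raise ConfigurationError(f"compartment entries for unknown fractions: {extra}")
        for f, c in self.compartment.items():
            if c not in COMPARTMENTS:
                raise ConfigurationError(f"unknown compartment {c!r} for fraction {f!r}")
        for c in COMPARTMENTS:
            if not self.fractions_in(c):
                raise ConfigurationError(f"scheme has no {c} fraction")
        if self.ribosome_count is not None:
            counts = [self.ribosome_count[f] for f in self.fraction_ids
                      if f in self.ribosome_count]
            if any(k < 0 for k in counts):
                raise ConfigurationError("ribosome counts must be non-negative")
            if any(b < a for a, b in zip(counts, counts[1:])):
                raise ConfigurationError(
                    "ribosome counts must be non-decreasing along the gradient")

    def fractions_in(self, compartment: str) -> tuple:
        """Fractions belonging to ``compartment``, in gradient order."""
        return tuple(f for f in self.fraction_ids if self.compartment[f] == compartment)

    def compartment_of(self, fraction_id: str) -> str:
        try:
            return self.compartment[fraction_id]
        except KeyError:
            raise SchemaError(f"fraction {fraction_id!r} not present in scheme") from None

    @property
    def max_ribosome_count(self) -> Optional[int]:
        if not self.ribosome_count:
            return None
        return max(self.ribosome_count.values())

    def fractions_with_count(self, k: int) -> tuple:
        if not self.ribosome_count:
            return ()
        return tuple(f for f in self.fraction_ids
                     if self.ribosome_count.get(f) == k)

    # serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "fraction_ids": list(self.fraction_ids),
            "compartment": dict(self.compartment),
        }
        if self.ribosome_count is not None:
            d["ribosome_count"] = {k: int(v) for k, v in self.ribosome_count.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FractionScheme":
        return cls(
            fraction_ids=tuple(d["fraction_ids"]),
            compartment=dict(d["compartment"]),
            ribosome_count=dict(d["ribosome_count"]) if d.get("ribosome_count") else None,
        )

    @classmethod
    def default(cls) -> "FractionScheme":
        """Twelve equal-volume fractions: 2 free, 3 monosome, 7 polysome.

        Polysome fractions are annotated with ribosome counts 2..8; the
        deepest fraction collects everything at or beyond 8 ribosomes.
        The compartment boundaries are a convention, not a measured fact.
        """
        ids = tuple(f"f{i:02d}" for i in range(1, 13))
        comp = {}
        counts = {}
        for i, f in enumerate(ids, start=1):
            if i <= 2:
                comp[f] = FREE
            elif i <= 5:
                comp[f] = MONOSOME
            else:
                comp[f] = POLYSOME
                counts[f] = i - 4  # 2..8
        return cls(ids, comp, counts)
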