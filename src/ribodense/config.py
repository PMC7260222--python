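"""Simulation noise configuration."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class NoiseConfig:
    """Noise knobs shared by all simulators.

    ``tmt_kappa = 1``, ``lognormal_sigma = 0`` and ``nb_dispersion = 0``
    together define the noise-free regime in which every downstream
    estimator recovers the planted quantities.

    Attributes
    ----------
    lognormal_sigma
        Standard deviation (natural-log scale) of multiplicative
        measurement noise applied per cell. ``>= 0``.
    tmt_kappa
        Isobaric ratio-compression exponent in ``(0, 1]``: an observed
        ratio-to-reference equals the true ratio raised to ``tmt_kappa``.
    nb_dispersion
        Negative-binomial dispersion (``size**-1``) of simulated read
        counts; ``0`` makes counts equal rounded expectations. ``>= 0``.
    library_size
        Sequencing reads per fraction (positive integer).
    seed
        Seed for all random draws.
    """

    lognormal_sigma: float = 0.0
    tmt_kappa: float = 1.0
    nb_dispersion: float = 0.0
    library_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.lognormal_sigma < 0:
            raise ConfigurationError("lognormal_sigma must be >= 0")
        if not (0 < self.tmt_kappa <= 1):
            raise ConfigurationError("tmt_kappa must be in (0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")

    @property
    def noise_free(self) -> bool:
        return (self.lognormal_sigma == 0 and self.tmt_kappa == 1
                and self.nb_dispersion == 0)
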