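"""Parameter containers for the trafficking model and its measurement layer.

The kinetic scheme tracks a pulse-labeled cohort of nascent channel through
four compartments::

    ER (core-glycosylated) --k_mat--> mature pool --k_pm--> degraded
          |                              |
        k_erad (ERAD)            surface <-> endosome (k_int, k_rec)
          v                              |
       degraded                        k_lys --> lysosome

Biosynthetic rates (k_mat, k_erad, k_pm) are per hour; peripheral rates
(k_int, k_rec, k_lys) are per minute, matching the time scales of the
pulse-chase (hours) and surface-ELISA (minutes) assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class KineticParams:
    """Per-construct rate constants of the trafficking model.

    Parameters
    ----------
    construct_name
        Label, e.g. ``"WT"`` or ``"T65P"``.
    k_mat
        ER maturation/export rate (per hour).
    k_erad
        ER-associated degradation rate of the nascent pool (per hour).
    k_int
        Internalization rate from the cell surface (per minute).
    k_rec
        Endosome-to-surface recycling rate (per minute).
    k_lys
        Endosome-to-lysosome sorting rate (per minute).
    k_pm
        Mature-pool degradation rate at 37 degC (per hour).
    temp_factor
        Multiplier applied to ``k_pm`` at 41 degC (dimensionless, >= 1).
    mrna_level
        Relative transcript abundance (arbitrary units, > 0).
    """

    construct_name: str
    k_mat: float
    k_erad: float
    k_int: float
    k_rec: float
    k_lys: float
    k_pm: float
    temp_factor: float = 1.0
    mrna_level: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_mat", "k_erad", "k_int", "k_rec", "k_lys", "k_pm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.temp_factor < 1.0:
            raise ParameterError(f"temp_factor must be >= 1, got {self.temp_factor}")
        if self.mrna_level <= 0:
            raise ParameterError(f"mrna_level must be > 0, got {self.mrna_level}")

    @property
    def recycling_fraction(self) -> float:
        """Fraction of endosomal exits returning to the surface; 0 when both exits vanish."""
        total = self.k_rec + self.k_lys
        if total == 0.0:
            return 0.0
        return self.k_rec / total

    @property
    def nascent_decay_rate(self) -> float:
        """Total disappearance rate of the core-glycosylated pool, k_mat + k_erad (per hour)."""
        return self.k_mat + self.k_erad


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise for densitometry bands and ELISA wells.

    Band and well intensities are perturbed by a unit-mean lognormal factor
    with the stated coefficient of variation; isotype-control background wells
    emit ``background_frac`` of the initial specific signal.
    """

    cv_band: float = 0.1
    cv_well: float = 0.08
    background_frac: float = 0.05
    n_wells: int = 4

    def __post_init__(self) -> None:
        if self.cv_band < 0 or self.cv_well < 0:
            raise ParameterError("coefficients of variation must be >= 0")
        if not (0.0 <= self.background_frac < 1.0):
            raise ParameterError("background_frac must lie in [0, 1)")
        if self.n_wells < 1:
            raise ParameterError("n_wells must be >= 1")


NOISELESS = NoiseModel(cv_band=0.0, cv_well=0.0, background_frac=0.0, n_wells=1)


@dataclass(frozen=True)
class PHMixtureSpec:
    """Gaussian-mixture description of a vesicular pH distribution.

    ``components`` is a list of ``(weight, mean_ph, sd_ph)`` tuples. Weights
    must sum to one; component means must lie in the physiological vesicular
    range (early/recycling endosomes ~6.5-6.8 down to lysosomes ~4.5-5.5).
    """

    components: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        comps = tuple(tuple(c) for c in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ParameterError("mixture needs at least one component")
        total = sum(w for w, _, _ in comps)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"component weights must sum to 1, got {total}")
        for w, mean, sd in comps:
            if w < 0:
                raise ParameterError("component weights must be >= 0")
            if not (4.0 <= mean <= 7.5):
                raise ParameterError(f"component mean pH {mean} outside [4.0, 7.5]")
            if sd <= 0:
                raise ParameterError("component sd must be > 0")

    @property
    def mean_ph(self) -> float:
        """Weight-averaged mean pH of the mixture."""
        return sum(w * m for w, m, _ in self.components)
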