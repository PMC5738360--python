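"""Parameter containers for the inducible-effector and receptor-cleavage models.

All parameter sets are immutable pydantic models that serialize to flat JSON
documents (keys exactly matching the field names); unknown keys are rejected on
load. Units are arbitrary but consistent: time in hours, fluorescence readouts
in arbitrary units (AU), ligand doses in nM when mirroring typical experiments.
The models are scale-free, so units are documented, not enforced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, model_validator


class ParamsBase(BaseModel):
    """Common JSON (de)serialization for parameter sets."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    def to_json(self, **kwargs: Any) -> str:
        return self.model_dump_json(**kwargs)

    @classmethod
    def from_json(cls, text: str):
        return cls.model_validate(json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path):
        return cls.from_json(Path(path).read_text())


def _require_positive(obj: BaseModel, names: tuple[str, ...]) -> None:
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


class DoxInductionParams(ParamsBase):
    """Lumped parameters of the doxycycline-inducible effector cascade.

    ``kappa1`` and ``kappa2`` are production/degradation ratios (alpha1/beta1 in
    AU and alpha2/beta2 in AU per AU); ``K_D`` is the dox affinity constant and
    carries units of D**n_hill (the induction term is D**n_hill/(K_D + D**n_hill),
    with K_D as printed rather than K_D**n_hill); ``n_hill`` is the Hill
    cooperativity of dox induction; ``m`` is the lumped effector-to-reporter
    exponent (binding, transcription, translation in series), default 1.

    The theoretical maximum reporter level is ``kappa1 * kappa2`` when m = 1.
    """

    kappa1: float
    kappa2: float
    K_D: float
    n_hill: float
    m: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "DoxInductionParams":
        _require_positive(self, ("kappa1", "kappa2", "K_D", "n_hill", "m"))
        return self

    @property
    def g_max(self) -> float:
        """Theoretical maximum reporter level kappa1*kappa2 (exact for m=1)."""
        return self.kappa1 * self.kappa2


class ChaChaRateParams(ParamsBase):
    """Mass-action rate constants of the receptor-cleavage reporter system.

    The model couples four processes: ligand activation of the inactive
    receptor R -> R*, active-receptor-mediated cleavage of the adaptor-effector
    fusion A releasing free effector C, and effector-driven production of the
    reporter G.

    Units: productions (alpha_R, alpha_A) in concentration/hour;
    alpha_Rstar in 1/(concentration*hour); degradations (beta_*) in 1/hour;
    gamma_C in 1/(concentration**n_stoich * hour); gamma_G in 1/hour.
    ``n_stoich`` is the number of adaptor-effector molecules processed per
    active receptor; it may be non-integer and enters as a real-valued power.
    """

    alpha_R: float
    alpha_Rstar: float
    alpha_A: float
    beta_R: float
    beta_Rstar: float
    beta_A: float
    beta_C: float
    beta_G: float
    gamma_C: float
    gamma_G: float
    n_stoich: float

    @model_validator(mode="after")
    def _check(self) -> "ChaChaRateParams":
        _require_positive(
            self,
            (
                "alpha_R",
                "alpha_Rstar",
                "alpha_A",
                "beta_R",
                "beta_Rstar",
                "beta_A",
                "beta_C",
                "beta_G",
                "gamma_C",
                "gamma_G",
                "n_stoich",
            ),
        )
        return self


class SteadyStateParams(ParamsBase):
    """Lumped parameters of the closed-form steady-state reporter surface.

    G_ss = G_max * L/(L + K_L) * A**n/(K_A + A**n).

    ``G_max`` (AU) is the plateau at saturating ligand and adaptor;
    ``K_L`` (concentration) the ligand half-maximal set-point;
    ``K_A`` (concentration**n_stoich) the adaptor half-maximal constant;
    ``n_stoich`` the per-receptor effector stoichiometry exponent.
    """

    G_max: float
    K_L: float
    K_A: float
    n_stoich: float

    @model_validator(mode="after")
    def _check(self) -> "SteadyStateParams":
        _require_positive(self, ("G_max", "K_L", "K_A", "n_stoich"))
        return self


class DoseResponseParams(ParamsBase):
    """Four-parameter Hill (4PL) dose-response curve.

    response(d) = bottom + (top - bottom) * d**h / (EC50**h + d**h)
    """

    bottom: float
    top: float
    EC50: float
    hill_slope: float

    @model_validator(mode="after")
    def _check(self) -> "DoseResponseParams":
        if self.bottom < 0:
            raise ValueError(f"bottom must be >= 0, got {self.bottom!r}")
        if not self.top > self.bottom:
            raise ValueError(
                f"top must exceed bottom, got top={self.top!r} bottom={self.bottom!r}"
            )
        _require_positive(self, ("EC50", "hill_slope"))
        return self


class DoxRateConstants(ParamsBase):
    """Explicit rate-constant split of the dox-induction cascade for dynamics.

    The split (alpha1, beta1, alpha2, beta2) is only identifiable dynamically;
    at steady state only the ratios kappa1 = alpha1/beta1 and
    kappa2 = alpha2/beta2 matter.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    K_D: float
    n_hill: float
    m: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "DoxRateConstants":
        _require_positive(
            self, ("alpha1", "beta1", "alpha2", "beta2", "K_D", "n_hill", "m")
        )
        return self

    def to_induction_params(self) -> DoxInductionParams:
        return DoxInductionParams(
            kappa1=self.alpha1 / self.beta1,
            kappa2=self.alpha2 / self.beta2,
            K_D=self.K_D,
            n_hill=self.n_hill,
            m=self.m,
        )
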