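"""Seeded synthetic datasets with the statistical structure of the experiments.

The generators emulate well-level flow-cytometry summaries: a grid of
adaptor-expression levels (dox-titrated, read out as an mCherry-proxy in AU)
crossed with ligand doses; single-variable ligand dose-response series; dox
titration series; and qPCR Ct plates with a housekeeping gene and explicit
undetected wells. Noise is applied per record; everything is reproducible
from the seed carried by the :class:`NoiseModel` (or passed explicitly for
qPCR plates).

Default design mirrors the characterization experiments: 6 adaptor levels
(10–10,000 AU, log-spaced), 8 ligand doses log-spaced 1–10,000 nM, 3
replicates, multiplicative lognormal noise with cv 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import chacha_steady_state_gfp, dox_steady_state_gfp
from .params import DoseResponseParams, DoxInductionParams, SteadyStateParams

__all__ = [
    "NoiseModel",
    "GRID_COLUMNS",
    "DOSE_COLUMNS",
    "DOX_COLUMNS",
    "QPCR_COLUMNS",
    "default_adaptor_levels",
    "default_ligand_doses",
    "hill_response",
    "generate_grid_dataset",
    "generate_dose_response",
    "generate_dox_induction",
    "generate_qpcr_plate",
]

GRID_COLUMNS = ("adaptor_level", "ligand_dose", "replicate", "gfp", "adaptor_readout")
DOSE_COLUMNS = ("ligand_dose", "replicate", "gfp")
DOX_COLUMNS = ("dox_level", "replicate", "gfp")
QPCR_COLUMNS = ("sample", "gene", "replicate", "ct")


def default_adaptor_levels() -> np.ndarray:
    """Six log-spaced adaptor expression levels, 10–10,000 AU."""
    return np.geomspace(10.0, 10000.0, 6)


def default_ligand_doses(lo: float = 1.0, hi: float = 10000.0, n: int = 8) -> np.ndarray:
    """Eight log-spaced ligand doses (nM), default 1–10,000."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class NoiseModel:
    """Per-record measurement noise.

    ``multiplicative-lognormal`` multiplies each expected value by a lognormal
    factor with unit mean and coefficient of variation ``cv_or_sd`` —
    fluorescence readouts are positive with roughly scale-proportional spread.
    ``additive-gaussian`` adds N(0, sd) and clips at zero. ``cv_or_sd = 0``
    reproduces expectations exactly.
    """

    kind: str = "multiplicative-lognormal"
    cv_or_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv_or_sd < 0:
            raise ValueError("cv_or_sd must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        expected = np.asarray(expected, dtype=float)
        if self.cv_or_sd == 0:
            return expected.copy()
        if self.kind == "multiplicative-lognormal":
            sigma = np.sqrt(np.log1p(self.cv_or_sd**2))
            # mean of the lognormal factor is exactly 1
            factors = rng.lognormal(-0.5 * sigma**2, sigma, size=expected.shape)
            return expected * factors
        return np.clip(expected + rng.normal(0.0, self.cv_or_sd, expected.shape), 0, None)


def _long_design(levels: Sequence[float], doses: Sequence[float], replicates: int):
    lev, dos, rep = np.meshgrid(
        np.asarray(levels, float),
        np.asarray(doses, float),
        np.arange(1, replicates + 1),
        indexing="ij",
    )
    return lev.ravel(), dos.ravel(), rep.ravel()


def generate_grid_dataset(
    truth: SteadyStateParams,
    adaptor_levels: Sequence[float] | None = None,
    ligand_doses: Sequence[float] | None = None,
    replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Adaptor-level x ligand-dose grid with per-well reporter readouts.

    Each record's expected ``gfp`` is the closed-form steady-state surface at
    its (dose, adaptor level); ``adaptor_readout`` is the true adaptor level
    passed through the same noise model, mimicking a fluorescent-proxy
    measurement of the covariate.
    """
    levels = default_adaptor_levels() if adaptor_levels is None else np.asarray(
        adaptor_levels, float
    )
    doses = default_ligand_doses() if ligand_doses is None else np.asarray(
        ligand_doses, float
    )
    if levels.size < 2 or doses.size < 2 or replicates < 1:
        raise ValueError("need >=2 adaptor levels, >=2 doses and >=1 replicate")
    lev, dos, rep = _long_design(levels, doses, replicates)
    expected = chacha_steady_state_gfp(dos, lev, truth)
    rng = noise.rng()
    gfp = noise.apply(expected, rng)
    readout = noise.apply(lev, rng)
    return pd.DataFrame(
        {
            "adaptor_level": lev,
            "ligand_dose": dos,
            "replicate": rep.astype(int),
            "gfp": gfp,
            "adaptor_readout": readout,
        }
    )


def hill_response(dose, p: DoseResponseParams):
    """4PL evaluation: bottom + (top-bottom) * d^h / (EC50^h + d^h)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    dh = np.power(d, p.hill_slope)
    out = p.bottom + (p.top - p.bottom) * dh / (p.EC50**p.hill_slope + dh)
    return out if out.ndim else float(out)


def generate_dose_response(
    truth: DoseResponseParams,
    doses: Sequence[float] | None = None,
    replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Single-variable ligand dose-response series from a 4PL truth curve."""
    doses = default_ligand_doses() if doses is None else np.asarray(doses, float)
    if doses.size < 2 or replicates < 1:
        raise ValueError("need >=2 doses and >=1 replicate")
    dos, rep = np.meshgrid(doses, np.arange(1, replicates + 1), indexing="ij")
    dos, rep = dos.ravel(), rep.ravel()
    gfp = noise.apply(hill_response(dos, truth), noise.rng())
    return pd.DataFrame(
        {"ligand_dose": dos, "replicate": rep.astype(int), "gfp": gfp}
    )


def generate_dox_induction(
    truth: DoxInductionParams,
    dox_levels: Sequence[float],
    replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Dox titration series from the induction cascade's steady-state curve."""
    levels = np.asarray(dox_levels, float)
    if levels.size < 2 or replicates < 1:
        raise ValueError("need >=2 dox levels and >=1 replicate")
    dox, rep = np.meshgrid(levels, np.arange(1, replicates + 1), indexing="ij")
    dox, rep = dox.ravel(), rep.ravel()
    gfp = noise.apply(dox_steady_state_gfp(dox, truth), noise.rng())
    return pd.DataFrame({"dox_level": dox, "replicate": rep.astype(int), "gfp": gfp})


def generate_qpcr_plate(
    true_rel_expression: Mapping[str, Mapping[str, float]],
    gapdh_ct: float = 20.0,
    noise_sd: float = 0.0,
    dropout_rel_threshold: float | None = None,
    replicates: int = 3,
    seed: int = 0,
    housekeeping: str = "GAPDH",
) -> pd.DataFrame:
    """Ct plate for samples x genes with a shared housekeeping gene.

    ``true_rel_expression`` maps sample -> gene -> relative-expression factor
    (vs. the housekeeping baseline). Detected Ct values follow
    ``gapdh_ct - log2(factor) + N(0, noise_sd)`` — one cycle per twofold
    expression change. Genes whose factor falls below
    ``dropout_rel_threshold`` emit undetected wells (NaN Ct), which are kept
    explicitly, never dropped.
    """
    if not 10.0 < gapdh_ct < 35.0:
        raise ValueError("gapdh_ct must lie in (10, 35)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for sample in true_rel_expression:
        genes = true_rel_expression[sample]
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {"sample": sample, "gene": housekeeping, "replicate": rep,
                 "ct": gapdh_ct + noise}
            )
        for gene, factor in genes.items():
            if not factor > 0:
                raise ValueError(f"factor for {sample}/{gene} must be positive")
            for rep in range(1, replicates + 1):
                if dropout_rel_threshold is not None and factor < dropout_rel_threshold:
                    ct = np.nan
                else:
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    ct = gapdh_ct - np.log2(factor) + noise
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows, columns=list(QPCR_COLUMNS))
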