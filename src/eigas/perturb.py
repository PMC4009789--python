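"""Randomized coordinate perturbation from experimental uncertainty.

Structure coordinates are never exact.  X-ray crystallography reports a
B-factor per atom, B = 8π²·E‖r − r̄‖², i.e. a scaled total positional
variance; NMR deposits an ensemble of models whose spread estimates the
same thing.  Both are converted to independent per-axis normal
distributions for each Cα:

  * B-factor mode: per-axis variance s²·B/(24π²) — a third of the total
    variance B/(8π²) split isotropically over x, y, z and scaled by s²;
  * NMR mode: per-axis variance s²·(sample variance over the models).

The dimensionless scale s dials uncertainty up or down (s = 1 reproduces
the experiment's own spread); sampling at increasing s probes how far an
alignment method can be pushed before family recognition degrades.
Correlations between atoms are deliberately ignored — an isotropic,
uncorrelated model overstates the real variability, making the robustness
test one-sided (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .structures import CalphaChain, EnsembleStats

__all__ = [
    "PerturbationModel",
    "coordinate_sigma",
    "bfactor_model",
    "nmr_model",
    "perturb_chain",
    "derive_seed",
]

_B_TO_VAR = 1.0 / (24.0 * np.pi**2)  # per-axis variance per unit B at s=1


@dataclass
class PerturbationModel:
    """Per-residue, per-axis normal perturbation of a Cα trace.

    ``sigmas`` is an ``(n, 3)`` array of standard deviations in Å with the
    scale ``s`` already applied (so ``s = 0`` forces all of them to zero).
    """

    mode: Literal["bfactor", "nmr"]
    sigmas: np.ndarray
    s: float
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.sigmas.ndim != 2 or self.sigmas.shape[1] != 3:
            raise ValueError("sigmas must be an (n, 3) array")
        if np.any(self.sigmas < 0):
            raise ValueError("standard deviations must be non-negative")
        if self.s < 0:
            raise ValueError("scale s must be non-negative")
        if self.s == 0 and np.any(self.sigmas != 0):
            raise ValueError("s = 0 requires all standard deviations to be 0")


def coordinate_sigma(B: float | np.ndarray, s: float) -> float | np.ndarray:
    """Per-axis standard deviation (Å) from a B-factor (Å²) at scale s.

    √(s²·B/(24π²)): the B-factor's total positional variance B/(8π²) is
    split equally over the three axes, then scaled by s².
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("B-factors must be non-negative")
    if s < 0:
        raise ValueError("scale s must be non-negative")
    out = s * np.sqrt(B * _B_TO_VAR)
    return float(out) if out.ndim == 0 else out


def bfactor_model(
    chain: CalphaChain, s: float, seed: int | None = None
) -> PerturbationModel:
    """Perturbation model for an X-ray structure from its B-factors.

    A chain whose B-factors are all zero yields an identity perturbation
    (warning logged) rather than an error, so B-factor-free fixtures can
    opt out of perturbation.
    """
    sig = coordinate_sigma(chain.bfactors, s)
    sigmas = np.repeat(np.asarray(sig).reshape(-1, 1), 3, axis=1)
    if np.all(chain.bfactors == 0):
        import logging

        logging.getLogger(__name__).warning(
            "chain %s has all-zero B-factors; perturbation is the identity",
            chain.chain_id,
        )
    return PerturbationModel(mode="bfactor", sigmas=sigmas, s=s, seed=seed)


def nmr_model(stats: EnsembleStats, s: float, seed: int | None = None) -> PerturbationModel:
    """Perturbation model from NMR ensemble statistics: per-axis standard
    deviations √(s²·sample variance)."""
    if s < 0:
        raise ValueError("scale s must be non-negative")
    return PerturbationModel(
        mode="nmr", sigmas=s * np.sqrt(stats.variance), s=s, seed=seed
    )


def perturb_chain(chain: CalphaChain, model: PerturbationModel) -> CalphaChain:
    """Draw one random realisation of a chain under a perturbation model.

    Each coordinate is drawn independently from N(original, σ²); the chain
    id, family label and B-factors pass through unchanged.  Reproducible
    from ``model.seed``.
    """
    if len(model.sigmas) != len(chain):
        raise ValueError(
            f"model describes {len(model.sigmas)} residues, chain has {len(chain)}"
        )
    if model.s == 0 or np.all(model.sigmas == 0):
        coords = chain.coords.copy()
    else:
        rng = np.random.default_rng(model.seed)
        coords = chain.coords + rng.normal(size=chain.coords.shape) * model.sigmas
    return CalphaChain(
        chain_id=chain.chain_id,
        coords=coords,
        bfactors=chain.bfactors.copy(),
        family_id=chain.family_id,
    )


def derive_seed(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Deterministic per-sample seed stream derived from a master seed and
    any number of indices (experiment, sample, chain ...), so repeated runs
    are bit-identical while samples stay statistically independent."""
    return np.random.SeedSequence([int(master_seed), *map(int, indices)])
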