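"""Poissonian tumor control probability and the erf-sigmoid recurrence curve.

The radiobiological core. A tumor with ``N0`` clonogenic cells, of which a
fraction ``f(S_k)`` responds with survival fraction ``S_k``, is controlled with
Poisson probability

    TCP = prod_k exp(-N0 * f(S_k) * S_k) = exp(-N0 * <S>),

so TCP depends on the clonogen-weighted *mean* survival only, whatever the
shape of the survival distribution. Because the mean voxel-wise SUV ratio
<SUV_R> = <SUV_after / SUV_before> is a surrogate for mean effective survival,
TCP is modelled as a sigmoid in <SUV_R>. The tumor recurrence probability
TRP = 1 - TCP is written with the error function as

    TRP(x) = 0.5 * (1 + erf(sqrt(pi) * gamma50 * (x - suvr50)))

where ``suvr50`` is the <SUV_R> at which TCP (and TRP) equals 0.5 and
``gamma50`` is the slope of the TRP curve at that point: differentiating gives
d TRP/dx |_{suvr50} = 0.5 * (2/sqrt(pi)) * sqrt(pi) * gamma50 = gamma50
exactly, which is what fixes this parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "CompartmentTumor",
    "SigmoidParams",
    "tcp_compartments",
    "tcp_mean_survival",
    "trp",
    "tcp_from_suvr",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the recurrence sigmoid.

    Parameters
    ----------
    suvr50 : float
        The <SUV_R> at which TCP = TRP = 0.5. Dimensionless, > 0.
    gamma50 : float
        Slope of the TRP curve at ``suvr50`` (probability per unit <SUV_R>),
        >= 0. ``gamma50 = 0`` degenerates to the constant 0.5 curve.
    """

    suvr50: float
    gamma50: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.suvr50) and self.suvr50 > 0):
            raise ValueError(f"suvr50 must be finite and > 0, got {self.suvr50}")
        if not (np.isfinite(self.gamma50) and self.gamma50 >= 0):
            raise ValueError(f"gamma50 must be finite and >= 0, got {self.gamma50}")

    def to_dict(self) -> dict:
        return {"suvr50": float(self.suvr50), "gamma50": float(self.gamma50)}


@dataclass(frozen=True)
class CompartmentTumor:
    """A tumor partitioned into compartments of differing effective survival.

    ``compartments`` is a sequence of ``(fraction, survival)`` pairs: the
    fraction of the initial clonogen pool ``n0`` in the compartment and its
    effective survival fraction after therapy (repopulation absorbed).
    Fractions must sum to 1. ``volumes`` is informational only.
    """

    n0: float
    compartments: tuple[tuple[float, float], ...]
    volumes: tuple[float, ...] | None = None

    def __init__(
        self,
        n0: float,
        compartments: Sequence[Sequence[float]],
        volumes: Sequence[float] | None = None,
    ) -> None:
        object.__setattr__(self, "n0", float(n0))
        object.__setattr__(
            self, "compartments", tuple((float(f), float(s)) for f, s in compartments)
        )
        object.__setattr__(
            self, "volumes", None if volumes is None else tuple(float(v) for v in volumes)
        )
        self._validate()

    def _validate(self) -> None:
        if not (np.isfinite(self.n0) and self.n0 > 0):
            raise ValueError(f"n0 must be finite and > 0, got {self.n0}")
        if not self.compartments:
            raise ValueError("at least one compartment is required")
        fracs = np.array([f for f, _ in self.compartments])
        survs = np.array([s for _, s in self.compartments])
        if np.any(fracs < 0):
            raise ValueError("compartment fractions must be >= 0")
        if abs(fracs.sum() - 1.0) > _FRACTION_TOL:
            raise ValueError(f"compartment fractions must sum to 1, got {fracs.sum()!r}")
        if np.any(survs < 0) or not np.all(np.isfinite(survs)):
            raise ValueError("survival fractions must be finite and >= 0")

    @property
    def mean_survival(self) -> float:
        """Clonogen-fraction-weighted mean survival, sum_k f_k * S_k."""
        return float(sum(f * s for f, s in self.compartments))


def tcp_compartments(tumor: CompartmentTumor) -> float:
    """Poisson TCP of a compartmentalized tumor, prod_k exp(-n0 * f_k * S_k).

    Evaluated literally as the product over compartments so the identity with
    :func:`tcp_mean_survival` is a genuine cross-check, not a tautology.
    """
    factors = [math.exp(-tumor.n0 * f * s) for f, s in tumor.compartments]
    return float(np.prod(factors))


def tcp_mean_survival(n0: float, mean_survival: float) -> float:
    """Poisson TCP from the mean survival alone, exp(-n0 * <S>)."""
    if not (np.isfinite(n0) and n0 > 0):
        raise ValueError(f"n0 must be finite and > 0, got {n0}")
    if not (np.isfinite(mean_survival) and mean_survival >= 0):
        raise ValueError(f"mean_survival must be finite and >= 0, got {mean_survival}")
    return float(math.exp(-n0 * mean_survival))


def trp(suvr, params: SigmoidParams):
    """Tumor recurrence probability at ``suvr``.

    TRP(x) = 0.5 * (1 + erf(sqrt(pi) * gamma50 * (x - suvr50))). Strictly
    increasing in ``suvr`` when ``gamma50 > 0``; identically 0.5 when
    ``gamma50 = 0``. Accepts scalars or arrays.
    """
    x = np.asarray(suvr, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("suvr must be finite")
    z = math.sqrt(math.pi) * params.gamma50 * (x - params.suvr50)
    out = 0.5 * (1.0 + special.erf(z))
    return float(out) if np.isscalar(suvr) or out.ndim == 0 else out


def tcp_from_suvr(suvr, params: SigmoidParams):
    """Tumor control probability at ``suvr``: 1 - TRP(suvr)."""
    out = 1.0 - np.asarray(trp(suvr, params))
    return float(out) if np.isscalar(suvr) or out.ndim == 0 else out
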