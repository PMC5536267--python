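"""The seven effort-discounting subjective-value functions.

Every model maps a nominal amount ``A`` and effort intensity ``E`` to a
subjective value ``SV``, governed by a discounting-rate parameter ``l``
("laziness" index; larger l = steeper devaluation) and, for the two-parameter
models, a second parameter ``s``:

==============  =======================  ====================================
name            SV(A, E)                 role of s
==============  =======================  ====================================
hyperbolic      A / (1 + lE)             --
exponential     A * exp(-lE)             --
parabolic       A - l E^2                --
myerson_green   A / (1 + lE)^s           exponent of the whole denominator
rachlin         A / (1 + l E^s)          exponent of effort intensity only
exp2            (A - s) exp(-lE) + s     asymptote in PLN (s < A)
power           A - l E^s                exponent of effort intensity
==============  =======================  ====================================

The convex hyperbola-like and exponential forms approach 0 asymptotically;
the concave parabolic and power forms can cross 0, and their negative
predictions are deliberately not clamped (an effort cost can exceed the
reward's worth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["ModelSpec", "registry", "get_model", "sv", "MODEL_NAMES"]


class ParameterDomainError(ValueError):
    """Parameter outside the model's admissible domain."""


def _hyperbolic(A, E, l, s=None):
    return A / (1.0 + l * E)


def _exponential(A, E, l, s=None):
    return A * np.exp(-l * E)


def _parabolic(A, E, l, s=None):
    return A - l * np.asarray(E, dtype=float) ** 2


def _myerson_green(A, E, l, s):
    return A / (1.0 + l * E) ** s


def _rachlin(A, E, l, s):
    return A / (1.0 + l * np.asarray(E, dtype=float) ** s)


def _exp2(A, E, l, s):
    return (A - s) * np.exp(-l * np.asarray(E, dtype=float)) + s


def _power(A, E, l, s):
    return A - l * np.asarray(E, dtype=float) ** s


def _grad_hyperbolic(A, E, l, s=None):
    return (-A * E / (1.0 + l * E) ** 2,)


def _grad_exponential(A, E, l, s=None):
    return (-A * E * np.exp(-l * E),)


def _grad_parabolic(A, E, l, s=None):
    return (-np.asarray(E, dtype=float) ** 2,)


def _grad_myerson_green(A, E, l, s):
    base = 1.0 + l * E
    return (-A * s * E * base ** (-s - 1.0),
            -A * np.log(base) * base ** (-s))


def _grad_rachlin(A, E, l, s):
    E = np.asarray(E, dtype=float)
    Es = E ** s
    denom = (1.0 + l * Es) ** 2
    logE = np.log(np.where(E > 0, E, 1.0))
    return (-A * Es / denom, -A * l * Es * logE / denom)


def _grad_exp2(A, E, l, s):
    E = np.asarray(E, dtype=float)
    decay = np.exp(-l * E)
    return (-E * (A - s) * decay, 1.0 - decay)


def _grad_power(A, E, l, s):
    E = np.asarray(E, dtype=float)
    Es = E ** s
    logE = np.log(np.where(E > 0, E, 1.0))
    return (-Es, -l * Es * logE)


@dataclass(frozen=True)
class ModelSpec:
    """A named subjective-value function and its parameter layout."""

    name: str
    n_params: int                      # free parameters per reward magnitude
    fn: Callable
    #: analytic gradient: tuple of dSV/dl (and dSV/ds) arrays.
    grad: Callable | None = None
    #: admissible range of s at fit time (lo, hi); None for one-parameter
    #: models.  exp2's upper bound is the amount A, marked with +inf here and
    #: substituted per magnitude by the fitter.
    s_bounds: tuple[float, float] | None = None
    #: multi-start grid of s values used by the fitter.
    s_starts: tuple[float, ...] = ()

    def __call__(self, A, E, l, s=None):
        return sv(self, A, E, l, s)


_S_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)

_REGISTRY: tuple[ModelSpec, ...] = (
    # one-parameter models first, in the conventional comparison order
    ModelSpec("hyperbolic", 1, _hyperbolic, _grad_hyperbolic),
    ModelSpec("exponential", 1, _exponential, _grad_exponential),
    ModelSpec("parabolic", 1, _parabolic, _grad_parabolic),
    ModelSpec("myerson_green", 2, _myerson_green, _grad_myerson_green,
              (1e-9, 10.0), _S_GRID),
    ModelSpec("rachlin", 2, _rachlin, _grad_rachlin, (1e-9, 10.0), _S_GRID),
    # exp2's s < A bound is set per fit
    ModelSpec("exp2", 2, _exp2, _grad_exp2, (-np.inf, np.inf), ()),
    ModelSpec("power", 2, _power, _grad_power, (1e-9, 10.0), _S_GRID),
)

MODEL_NAMES = tuple(m.name for m in _REGISTRY)


def registry() -> list[ModelSpec]:
    """The seven models in stable order (one-parameter models first)."""
    return list(_REGISTRY)


def get_model(name: str) -> ModelSpec:
    for model in _REGISTRY:
        if model.name == name:
            return model
    raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def sv(model: ModelSpec | str, A, E, l, s=None):
    """Evaluate ``SV(A, E)`` for ``model``.

    ``E`` may be a scalar or array.  Validates l >= 0 and, for two-parameter
    models, that s is supplied; s > 0 is required for the exponent models
    (myerson_green, rachlin, power) and s < A for exp2 evaluation is *not*
    enforced here (the constraint binds only at fit time).
    """
    if isinstance(model, str):
        model = get_model(model)
    if l < 0:
        raise ParameterDomainError(f"{model.name}: l must be >= 0, got {l}")
    if model.n_params == 2:
        if s is None:
            raise ParameterDomainError(f"{model.name} requires parameter s")
        if model.name in ("myerson_green", "rachlin", "power") and s <= 0:
            raise ParameterDomainError(
                f"{model.name}: s must be > 0, got {s}")
    if np.any(np.asarray(A) <= 0):
        raise ParameterDomainError(f"amount must be positive, got {A}")
    if np.any(np.asarray(E) < 0):
        raise ParameterDomainError(f"effort must be non-negative, got {E}")
    return model.fn(A, E, l, s)
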