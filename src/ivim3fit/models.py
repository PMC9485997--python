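"""IVIM parameter types and forward signal-decay models.

Intravoxel incoherent motion (IVIM) imaging separates molecular diffusion
from perfusion-driven pseudo-diffusion in diffusion-weighted MRI.  The signal
at diffusion weighting ``b`` (s/mm²) is modelled either bi-exponentially,

    S(b) = S0 * ((1 - f) * exp(-b D) + f * exp(-b D*)),

or tri-exponentially, with a second pseudo-diffusion compartment that
captures the rapid decay at very low b-values,

    S(b) = S0 * ((1 - f1 - f2) * exp(-b D)
                 + f1 * exp(-b D1*) + f2 * exp(-b D2*)).

For fitting, the tri-exponential model is more conveniently expressed in a
"primed" form without the explicit normalisation,

    S(b) = f0' exp(-b D) + f1' exp(-b D1*) + f2' exp(-b D2*),

with S0 = f0' + f1' + f2', f1 = f1'/S0 and f2 = f2'/S0.  Both forms are
provided here and agree to floating-point round-off under that conversion.

All decay constants are in mm²/s and b-values in s/mm², so products b·D are
dimensionless.  Parameter containers validate their invariants at
construction; the forward models assume valid inputs, which lets bounded
optimisers evaluate freely at interior iterates and validate only what they
return.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BValueScheme",
    "BiParams",
    "TriParams",
    "TriParamsPrime",
    "bi_signal",
    "tri_signal",
    "tri_signal_prime",
    "DEFAULT_BVALUES",
]

#: The 18-b-value acquisition scheme (s/mm²) used throughout simulations.
DEFAULT_BVALUES = (
    0, 1, 2, 5, 10, 20, 30, 40, 50, 75, 100, 150, 200, 300, 400, 500, 600, 700
)


class ValidationError(ValueError):
    """Raised when a parameter container violates a model invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite, got {x!r}")
    return arr


@dataclass(frozen=True)
class BValueScheme:
    """Ordered vector of diffusion weightings (s/mm²).

    Duplicates are permitted (repeated acquisitions of one weighting); all
    entries must be non-negative and, by default, at least one must equal 0
    so that signals can be normalised to S(b=0).
    """

    values: np.ndarray
    require_b0: dataclasses.InitVar[bool] = True

    def __post_init__(self, require_b0: bool):
        arr = _as_float_array(self.values, "b-values").ravel()
        if arr.size == 0:
            raise ValidationError("b-value scheme is empty")
        if np.any(arr < 0):
            raise ValidationError("b-values must be non-negative")
        if require_b0 and not np.any(arr == 0):
            raise ValidationError("b-value scheme contains no b=0 entry")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def has_b0(self) -> bool:
        return bool(np.any(self.values == 0))

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.values == 0)

    def sorted(self) -> "BValueScheme":
        return BValueScheme(np.sort(self.values), require_b0=self.has_b0)

    @classmethod
    def default_scheme(cls) -> "BValueScheme":
        """The 18-value scheme 0–700 s/mm² the simulator emulates."""
        return cls(np.array(DEFAULT_BVALUES, dtype=float))


def _broadcast_fields(names, values):
    arrs = [np.asarray(v, dtype=float) for v in values]
    try:
        shape = np.broadcast_shapes(*(a.shape for a in arrs))
    except ValueError as e:
        raise ValidationError(f"incompatible parameter shapes: {e}") from e
    out = []
    for name, a in zip(names, arrs):
        if not np.all(np.isfinite(a)):
            raise ValidationError(f"{name} must be finite")
        out.append(np.broadcast_to(a, shape) if a.shape != shape else a)
    return out, shape


@dataclass(frozen=True)
class BiParams:
    """Bi-exponential IVIM parameters, scalar or voxel-wise arrays.

    S0 is the (dimensionless) signal at b=0, D the tissue diffusion
    coefficient (mm²/s), Dstar the pseudo-diffusion coefficient (mm²/s) and
    f the perfusion fraction in [0, 1].
    """

    S0: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        (S0, D, Ds, f), _ = _broadcast_fields(
            ("S0", "D", "Dstar", "f"), (self.S0, self.D, self.Dstar, self.f)
        )
        if np.any(S0 <= 0):
            raise ValidationError("S0 must be positive")
        if np.any(D < 0) or np.any(Ds < 0):
            raise ValidationError("decay constants must be non-negative")
        if np.any(f < 0) or np.any(f > 1):
            raise ValidationError("f must lie in [0, 1]")
        for name, v in zip(("S0", "D", "Dstar", "f"), (S0, D, Ds, f)):
            object.__setattr__(self, name, v)

    @property
    def shape(self):
        return np.asarray(self.S0).shape

    def as_dict(self) -> dict:
        return {"S0": self.S0, "D": self.D, "Dstar": self.Dstar, "f": self.f}


# f1+f2 may exceed 1 by round-off after the primed conversion
_FRACTION_SLACK = 1e-9


@dataclass(frozen=True)
class TriParams:
    """Tri-exponential IVIM parameters, scalar or voxel-wise arrays.

    D1star is the slow (microvascular) and D2star the fast (large-vessel)
    pseudo-diffusion coefficient; f1 and f2 the corresponding signal
    fractions with f1 + f2 <= 1.  The derived ``f1plus2`` map is the summed
    perfusion fraction directly comparable to the bi-exponential f.
    """

    S0: np.ndarray
    D: np.ndarray
    D1star: np.ndarray
    D2star: np.ndarray
    f1: np.ndarray
    f2: np.ndarray

    def __post_init__(self):
        names = ("S0", "D", "D1star", "D2star", "f1", "f2")
        (S0, D, D1, D2, f1, f2), _ = _broadcast_fields(
            names, (self.S0, self.D, self.D1star, self.D2star, self.f1, self.f2)
        )
        if np.any(S0 <= 0):
            raise ValidationError("S0 must be positive")
        if np.any(D < 0) or np.any(D1 < 0) or np.any(D2 < 0):
            raise ValidationError("decay constants must be non-negative")
        if np.any(f1 < 0) or np.any(f2 < 0):
            raise ValidationError("fractions must be non-negative")
        if np.any(f1 + f2 > 1 + _FRACTION_SLACK):
            raise ValidationError("f1 + f2 must not exceed 1")
        for name, v in zip(names, (S0, D, D1, D2, f1, f2)):
            object.__setattr__(self, name, v)

    @property
    def f1plus2(self) -> np.ndarray:
        return self.f1 + self.f2

    @property
    def shape(self):
        return np.asarray(self.S0).shape

    def as_dict(self) -> dict:
        return {
            "S0": self.S0,
            "D": self.D,
            "D1star": self.D1star,
            "D2star": self.D2star,
            "f1": self.f1,
            "f2": self.f2,
            "f1plus2": self.f1plus2,
        }

    def to_prime(self) -> "TriParamsPrime":
        """Convert to the primed (unnormalised-fraction) parameterisation."""
        return TriParamsPrime(
            f0p=self.S0 * (1.0 - self.f1 - self.f2),
            f1p=self.S0 * self.f1,
            f2p=self.S0 * self.f2,
            D=self.D,
            D1star=self.D1star,
            D2star=self.D2star,
        )


@dataclass(frozen=True)
class TriParamsPrime:
    """Primed tri-exponential parameters: unnormalised compartment amplitudes.

    S0 = f0' + f1' + f2'; the normalised fractions are f1 = f1'/S0 and
    f2 = f2'/S0.  The conversion to :class:`TriParams` is an exact algebraic
    inverse (round-trips to ~1e-16 relative).
    """

    f0p: np.ndarray
    f1p: np.ndarray
    f2p: np.ndarray
    D: np.ndarray
    D1star: np.ndarray
    D2star: np.ndarray

    def __post_init__(self):
        names = ("f0p", "f1p", "f2p", "D", "D1star", "D2star")
        (f0, f1, f2, D, D1, D2), _ = _broadcast_fields(
            names, (self.f0p, self.f1p, self.f2p, self.D, self.D1star, self.D2star)
        )
        if np.any(f0 < 0) or np.any(f1 < 0) or np.any(f2 < 0):
            raise ValidationError("primed fractions must be non-negative")
        if np.any(D < 0) or np.any(D1 < 0) or np.any(D2 < 0):
            raise ValidationError("decay constants must be non-negative")
        for name, v in zip(names, (f0, f1, f2, D, D1, D2)):
            object.__setattr__(self, name, v)

    @property
    def S0(self) -> np.ndarray:
        return self.f0p + self.f1p + self.f2p

    def to_triparams(self) -> TriParams:
        S0 = self.S0
        if np.any(S0 <= 0):
            raise ValidationError("sum of primed fractions must be positive")
        return TriParams(
            S0=S0,
            D=self.D,
            D1star=self.D1star,
            D2star=self.D2star,
            f1=self.f1p / S0,
            f2=self.f2p / S0,
        )


def _outer_decay(rate: np.ndarray, b: np.ndarray) -> np.ndarray:
    """exp(-b*rate) broadcast so voxel axes come first, b last."""
    return np.exp(-np.multiply.outer(rate, b))


def _bvals(b) -> np.ndarray:
    if isinstance(b, BValueScheme):
        return b.values
    return _as_float_array(b, "b-values").ravel()


def bi_signal(p: BiParams, b) -> np.ndarray:
    """Evaluate the bi-exponential decay S0*((1-f)e^{-bD} + f e^{-bD*}).

    Returns an array of shape ``p.shape + (len(b),)`` (``(len(b),)`` for
    scalar parameters).
    """
    bv = _bvals(b)
    tissue = (1.0 - p.f)[..., None] * _outer_decay(p.D, bv)
    perf = p.f[..., None] * _outer_decay(p.Dstar, bv)
    return p.S0[..., None] * (tissue + perf)


def tri_signal(p: TriParams, b) -> np.ndarray:
    """Evaluate the tri-exponential decay for normalised fractions."""
    bv = _bvals(b)
    tissue = (1.0 - p.f1 - p.f2)[..., None] * _outer_decay(p.D, bv)
    slow = p.f1[..., None] * _outer_decay(p.D1star, bv)
    fast = p.f2[..., None] * _outer_decay(p.D2star, bv)
    return p.S0[..., None] * (tissue + slow + fast)


def tri_signal_prime(p: TriParamsPrime, b) -> np.ndarray:
    """Evaluate the primed tri-exponential decay f0'e^{-bD}+f1'e^{-bD1*}+f2'e^{-bD2*}."""
    bv = _bvals(b)
    return (
        p.f0p[..., None] * _outer_decay(p.D, bv)
        + p.f1p[..., None] * _outer_decay(p.D1star, bv)
        + p.f2p[..., None] * _outer_decay(p.D2star, bv)
    )
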