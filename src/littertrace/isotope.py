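"""Shared stable-isotope arithmetic.

Everything downstream — respiration partitioning, fraction accounting,
PLFA label detection, NanoSIMS ratios — reduces to three primitives:
conversion between delta notation and atom fraction, and two-pool linear
mixing of delta values.

Delta notation expresses a sample's 13C/12C ratio R_sample as a per-mil
deviation from the V-PDB standard ratio R_std:

    delta = (R_sample / R_std - 1) * 1000        [permil V-PDB]

Atom fraction is the share of 13C among all carbon atoms:

    af = R / (1 + R),   R = R_std * (1 + delta / 1000)

Two-pool mixing: a measured delta that is a mass-weighted mixture of two
end members with distinct signatures yields the source-A mass fraction

    f_A = (delta_mix - delta_B) / (delta_A - delta_B)

which is linear in delta because delta itself is linear in R for a fixed
standard. Measurement noise can push f_A slightly outside [0, 1]; the
clamping policy is explicit and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R13_VPDB",
    "DELTA_CONTROL_DEFAULT",
    "CLAMP_TOLERANCE_DEFAULT",
    "IsotopeStandard",
    "DegenerateMixingError",
    "MixingClampWarning",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "two_pool_fraction",
]

#: 13C/12C ratio of the Vienna Pee Dee Belemnite standard.
R13_VPDB = 0.0111802

#: Default natural-abundance delta13C of unlabeled soil organic matter
#: (permil V-PDB). Temperate soil OM sits near -28 permil; override per
#: experiment via config.
DELTA_CONTROL_DEFAULT = -28.0

#: Mixing fractions outside [0, 1] by at most this amount are clamped
#: silently; larger excursions are clamped with a warning.
CLAMP_TOLERANCE_DEFAULT = 0.02


@dataclass(frozen=True)
class IsotopeStandard:
    """Reference isotope ratio used for delta <-> atom-fraction conversion."""

    r13: float = R13_VPDB

    def __post_init__(self) -> None:
        if not self.r13 > 0:
            raise ValueError(f"standard ratio must be positive, got {self.r13}")


VPDB = IsotopeStandard()


class DegenerateMixingError(ValueError):
    """Raised when the two mixing end members have identical signatures."""


class MixingClampWarning(UserWarning):
    """A mixing fraction fell outside [0, 1] by more than the tolerance."""


def delta_to_atom_fraction(delta, standard: IsotopeStandard = VPDB):
    """Convert delta13C (permil) to the 13C atom fraction.

    Parameters
    ----------
    delta : float or array_like
        delta13C in permil relative to the standard. Must exceed -1000
        (at -1000 the sample would contain no 13C at all).
    standard : IsotopeStandard
        Reference ratio; defaults to V-PDB.

    Returns
    -------
    float or ndarray
        Atom fraction 13C/(12C + 13C) in (0, 1). Multiply by 100 for
        atom %; natural abundance (delta = 0) gives ~1.1 atom %.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta13C must be > -1000 permil (atom fraction must be positive)")
    r = standard.r13 * (1.0 + delta / 1000.0)
    af = r / (1.0 + r)
    return af if af.ndim else float(af)


def atom_fraction_to_delta(af, standard: IsotopeStandard = VPDB):
    """Convert a 13C atom fraction in (0, 1) back to delta13C (permil).

    Exact inverse of :func:`delta_to_atom_fraction`.
    """
    af = np.asarray(af, dtype=float)
    if np.any((af <= 0.0) | (af >= 1.0)):
        raise ValueError("atom fraction must lie strictly inside (0, 1)")
    r = af / (1.0 - af)
    delta = (r / standard.r13 - 1.0) * 1000.0
    return delta if delta.ndim else float(delta)


def two_pool_fraction(
    d_mix,
    d_source_a: float,
    d_source_b: float,
    *,
    clamp_tolerance: float = CLAMP_TOLERANCE_DEFAULT,
    warn: bool = True,
):
    """Fraction of source A in a two-end-member delta13C mixture.

    Parameters
    ----------
    d_mix : float or array_like
        Measured delta13C of the mixture (permil).
    d_source_a, d_source_b : float
        End-member signatures (permil); here typically labeled litter
        (~2129 permil) and native soil (~-28 permil).
    clamp_tolerance : float
        Unclamped fractions within ``[-tol, 1 + tol]`` are clamped
        silently; beyond that, clamped with :class:`MixingClampWarning`.
    warn : bool
        Set False to suppress the warning (the clamp still applies).

    Returns
    -------
    float or ndarray
        Fraction of source A, clamped to [0, 1].
    """
    if d_source_a == d_source_b:
        raise DegenerateMixingError(
            f"source signatures identical ({d_source_a} permil): mixture is unresolvable"
        )
    d_mix = np.asarray(d_mix, dtype=float)
    f = (d_mix - d_source_b) / (d_source_a - d_source_b)
    out_of_band = (f < -clamp_tolerance) | (f > 1.0 + clamp_tolerance)
    if warn and np.any(out_of_band):
        worst = float(np.max(np.abs(np.clip(f, 0.0, 1.0) - f)))
        warnings.warn(
            f"mixing fraction outside [0, 1] by up to {worst:.4f} "
            f"(tolerance {clamp_tolerance}); clamped",
            MixingClampWarning,
            stacklevel=2,
        )
    f = np.clip(f, 0.0, 1.0)
    return f if f.ndim else float(f)
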