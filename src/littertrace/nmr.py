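"""Solid-state 13C CP-MAS NMR: region integration and molecular mixing model.

A 13C CP-MAS spectrum of soil organic matter is quantified by
integrating intensity over standard chemical-shift regions:

* quantification set — alkyl C (-10..45 ppm), O/N-alkyl C (45..110),
  aromatic C (110..160), carbonyl/carboxyl C (160..220); the
  alkyl : O/N-alkyl ratio describes the degree of aliphaticity;
* molecular-mixing-model (MMM) set — 0..45, 45..60, 60..95, 95..110,
  110..145, 145..165, 165..215 ppm.

The MMM expresses the observed region fractions b as a convex
combination of compound-class signatures (carbohydrate, protein,
lignin, lipid, carbonyl, char): it solves

    min ||A x - b||_2   subject to   x >= 0,  sum(x) = 1

where column j of A gives class j's C-intensity distribution over the
MMM regions. The signature matrix is a data asset (editable TOML); the
solver and its validation are independent of any particular matrix.

Spectra are assumed phased and baseline-corrected upstream; a simple
linear-baseline subtraction is available behind a flag.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "QUANT_REGIONS",
    "MMM_REGIONS",
    "SignatureMatrix",
    "load_signatures",
    "read_spectrum",
    "integrate_regions",
    "aliphaticity_ratio",
    "mmm_fit",
    "MolecularMixingModel",
    "MmmResults",
]

#: Quantification regions (ppm, closed-lower / open-upper).
QUANT_REGIONS: dict[str, tuple[float, float]] = {
    "alkyl": (-10.0, 45.0),
    "o_n_alkyl": (45.0, 110.0),
    "aromatic": (110.0, 160.0),
    "carboxyl": (160.0, 220.0),
}

#: Molecular-mixing-model regions (ppm).
MMM_REGIONS: dict[str, tuple[float, float]] = {
    "r0_45": (0.0, 45.0),
    "r45_60": (45.0, 60.0),
    "r60_95": (60.0, 95.0),
    "r95_110": (95.0, 110.0),
    "r110_145": (110.0, 145.0),
    "r145_165": (145.0, 165.0),
    "r165_215": (165.0, 215.0),
}

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class SignatureMatrix:
    """Compound-class C-intensity distribution over the MMM regions."""

    regions: tuple
    classes: tuple
    matrix: np.ndarray  # shape (n_regions, n_classes), columns sum to 1

    def __post_init__(self) -> None:
        a = self.matrix
        if a.shape != (len(self.regions), len(self.classes)):
            raise ValueError("signature matrix shape mismatch")
        if np.any(a < 0):
            raise ValueError("signature entries must be non-negative")
        if not np.allclose(a.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("signature columns must each sum to 1")


def load_signatures(path: str | Path | None = None) -> SignatureMatrix:
    """Load a signature matrix from TOML (default: the bundled asset)."""
    path = Path(path) if path is not None else _DATA_DIR / "mmm_signatures.toml"
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    regions = tuple(raw["regions"])
    classes = tuple(raw["classes"].keys())
    matrix = np.column_stack([np.asarray(raw["classes"][c], dtype=float) for c in classes])
    matrix = matrix / matrix.sum(axis=0)  # tolerate rounding in the asset
    return SignatureMatrix(regions=regions, classes=classes, matrix=matrix)


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (ppm, intensity) text spectrum (whitespace or CSV)."""
    try:
        arr = np.loadtxt(path)
    except ValueError:
        arr = np.loadtxt(path, delimiter=",")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return arr[:, 0], arr[:, 1]


def _as_ascending(ppm: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ppm.shape != intensity.shape or ppm.ndim != 1:
        raise ValueError("ppm and intensity must be 1-D arrays of equal length")
    if not np.all(np.isfinite(intensity)):
        raise ValueError("intensities must be finite")
    d = np.diff(ppm)
    if np.all(d > 0):
        return ppm, intensity
    if np.all(d < 0):
        return ppm[::-1], intensity[::-1]
    raise ValueError("ppm axis must be strictly monotone")


def _region_integral(ppm: np.ndarray, intensity: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi), endpoints linearly interpolated."""
    inside = (ppm > lo) & (ppm < hi)
    x = ppm[inside]
    y = intensity[inside]
    xs, ys = [lo], [np.interp(lo, ppm, intensity)]
    xs.extend(x)
    ys.extend(y)
    xs.append(hi)
    ys.append(np.interp(hi, ppm, intensity))
    return float(np.trapezoid(ys, xs))


def integrate_regions(
    ppm,
    intensity,
    regions: dict[str, tuple[float, float]] = QUANT_REGIONS,
    *,
    baseline: bool = False,
) -> pd.Series:
    """Region fractions of total spectral intensity.

    Trapezoidal integration on the native ppm grid; the result is
    normalised to sum to 1 over the supplied regions. Regions extending
    beyond the recorded axis contribute only their covered part.
    """
    ppm, intensity = _as_ascending(ppm, intensity)
    if baseline:
        base = np.interp(ppm, [ppm[0], ppm[-1]], [intensity[0], intensity[-1]])
        intensity = intensity - base
    vals = {}
    for name, (lo, hi) in regions.items():
        if lo >= hi:
            raise ValueError(f"region {name}: lower bound must be below upper")
        lo_eff, hi_eff = max(lo, ppm[0]), min(hi, ppm[-1])
        vals[name] = _region_integral(ppm, intensity, lo_eff, hi_eff) if lo_eff < hi_eff else 0.0
    s = pd.Series(vals)
    total = s.sum()
    if total <= 0:
        raise ValueError("total spectral intensity over the regions is non-positive")
    return s / total


def aliphaticity_ratio(region_fractions: pd.Series) -> float | None:
    """Alkyl : O/N-alkyl intensity ratio (degree of aliphaticity).

    Returns None when the O/N-alkyl integral is zero (undefined).
    """
    denom = region_fractions["o_n_alkyl"]
    if denom <= 0:
        return None
    return float(region_fractions["alkyl"] / denom)


def _solve_simplex_lsq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||Ax - b|| over the probability simplex.

    SLSQP for the active set, then an exact equality-constrained
    refit on the support so interior solutions reach machine precision.
    """
    n = a.shape[1]
    x0 = np.full(n, 1.0 / n)
    res = minimize(
        lambda x: 0.5 * np.sum((a @ x - b) ** 2),
        x0,
        jac=lambda x: a.T @ (a @ x - b),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0, "jac": lambda x: np.ones(n)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    x = np.clip(res.x, 0.0, None)
    # polish: exact KKT solve on the active support
    support = x > 1e-9
    if support.any():
        a_s = a[:, support]
        k = a_s.shape[1]
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = a_s.T @ a_s
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([a_s.T @ b, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)[:k]
            if np.all(sol >= -1e-12):
                x_pol = np.zeros(n)
                x_pol[support] = np.clip(sol, 0.0, None)
                if np.linalg.norm(a @ x_pol - b) <= np.linalg.norm(a @ x - b) + 1e-12:
                    x = x_pol
        except np.linalg.LinAlgError:
            pass
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def mmm_fit(region_fractions, signatures: SignatureMatrix) -> "MmmResults":
    """Unmix observed MMM-region fractions into compound classes.

    Parameters
    ----------
    region_fractions : Series or array
        Observed fractions in the order of ``signatures.regions`` (a
        Series is reindexed by name). Need not be normalised.
    signatures : SignatureMatrix

    Returns
    -------
    MmmResults
        Class fractions on the simplex plus the residual norm.
    """
    if isinstance(region_fractions, pd.Series):
        b = region_fractions.reindex(list(signatures.regions)).to_numpy(dtype=float)
        if np.any(np.isnan(b)):
            raise ValueError("region fractions missing required MMM regions")
    else:
        b = np.asarray(region_fractions, dtype=float)
    if b.sum() <= 0:
        raise ValueError("region fractions must have positive total")
    b = b / b.sum()
    a = signatures.matrix
    x = _solve_simplex_lsq(a, b)
    resid = float(np.linalg.norm(a @ x - b))
    rank = np.linalg.matrix_rank(a)
    return MmmResults(
        params=pd.Series(x, index=list(signatures.classes)),
        resid_norm=resid,
        observed=pd.Series(b, index=list(signatures.regions)),
        fitted=pd.Series(a @ x, index=list(signatures.regions)),
        rank_deficient=rank < a.shape[1],
    )


@dataclass
class MmmResults:
    """Molecular-mixing-model composition estimate."""

    params: pd.Series
    resid_norm: float
    observed: pd.Series
    fitted: pd.Series
    rank_deficient: bool = False

    def summary(self) -> str:
        lines = ["Molecular mixing model fit", "=" * 40]
        lines.append(f"{'class':<14}{'fraction':>10}{'percent':>10}")
        for name, val in self.params.items():
            lines.append(f"{name:<14}{val:>10.4f}{100 * val:>9.1f}%")
        lines.append("-" * 40)
        lines.append(f"residual norm (region fractions): {self.resid_norm:.3e}")
        if self.rank_deficient:
            lines.append("warning: signature matrix is rank deficient")
        return "\n".join(lines)


class MolecularMixingModel:
    """Model object tying a spectrum to a signature matrix.

    Examples
    --------
    >>> model = MolecularMixingModel.from_spectrum(ppm, intensity)
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, region_fractions: pd.Series, signatures: SignatureMatrix | None = None):
        self.signatures = signatures if signatures is not None else load_signatures()
        self.region_fractions = region_fractions

    @classmethod
    def from_spectrum(cls, ppm, intensity, signatures: SignatureMatrix | None = None, **kw):
        sig = signatures if signatures is not None else load_signatures()
        regions = {r: MMM_REGIONS[r] for r in sig.regions}
        return cls(integrate_regions(ppm, intensity, regions, **kw), sig)

    def fit(self) -> MmmResults:
        return mmm_fit(self.region_fractions, self.signatures)
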