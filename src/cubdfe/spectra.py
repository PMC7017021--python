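"""Core Wright-Fisher equilibrium spectrum machinery.

Everything downstream (simulation, likelihood fitting, summaries) is built
on the quantities defined here:

* the expected sojourn density of a derived allele segregating at
  population frequency ``z`` under genic selection with scaled coefficient
  ``gamma = Ne*s`` (codominant, derived fitness ``1 + 2s``);
* its projection onto a finite sample of ``Ns`` haplotypes through
  binomial sampling over the discrete population-frequency grid
  ``z = j/(2*Ne)``, ``j = 1..2*Ne-1``;
* folded sample spectra, per-frequency-bin demographic correction
  factors (``alpha``), and the expected folded spectrum of a categorical
  DFE including an optional "lethal" class that contributes no
  polymorphism at all.

All per-site probabilities use the class weight ``f_c`` (fraction of
sites in class ``c``) so that the expected spectrum is a proper
probability distribution over {monomorphic, folded frequency classes};
multiplying by the number of sites ``L`` gives expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.stats import binom as _binom

from .errors import DomainError, ModelInvalidError

__all__ = [
    "LETHAL",
    "DFEClass",
    "DFEModel",
    "PopulationModel",
    "AlphaCorrection",
    "FoldedSFS",
    "sojourn_density",
    "sample_frequency_probs",
    "expected_folded_sfs",
    "fold",
    "default_alpha_bins",
]

#: Sentinel for the lethal selection class (no polymorphism contribution).
LETHAL = "lethal"

Gamma = Union[float, str]

# Direct evaluation of (1 - exp(-4g(1-z))) / (1 - exp(-4g)) overflows once
# 4|gamma| exceeds ~700; beyond that we switch to a log-space evaluation.
_LOG_BRANCH_THRESHOLD = 700.0


def _is_lethal(gamma: Gamma) -> bool:
    if isinstance(gamma, str):
        if gamma != LETHAL:
            raise DomainError(f"unknown selection coefficient sentinel: {gamma!r}")
        return True
    return bool(np.isinf(gamma) and gamma < 0)


def _ratio(z: np.ndarray, gamma: float) -> np.ndarray:
    """(1 - e^{-4g(1-z)}) / (1 - e^{-4g}) for g != 0, and (1-z) at g = 0.

    Continuous in gamma at 0 and overflow-safe for large |gamma|.
    """
    if gamma == 0.0:
        return 1.0 - np.asarray(z, dtype=float)
    z = np.asarray(z, dtype=float)
    a = -4.0 * gamma * (1.0 - z)
    b = -4.0 * gamma
    if abs(b) <= _LOG_BRANCH_THRESHOLD:
        return np.expm1(a) / np.expm1(b)
    if b > 0:  # strongly deleterious: work with log(e^a - 1) = a + log(1 - e^-a)
        log_num = a + np.log(-np.expm1(-a))
        log_den = b + np.log(-np.expm1(-b))
        return np.exp(log_num - log_den)
    # strongly beneficial (outside the purifying convention, but defined):
    # both expm1 terms are ~ -1, ratio -> 1 smoothly.
    return np.expm1(a) / np.expm1(b)


def sojourn_density(z, mu: float, gamma: Gamma, L_c: float = 1.0):
    """Expected density g_c(z) of sites with a derived allele at population
    frequency ``z`` under the standard Wright-Fisher mutation-selection model.

    Parameters
    ----------
    z : float or array-like, strictly inside (0, 1).
    mu : per-site mutation rate per generation.
    gamma : scaled selection coefficient Ne*s (<= 0 for purifying selection),
        or the sentinel ``"lethal"``.
    L_c : number of sites in the class (use the class fraction ``f_c`` for a
        per-site density).

    Returns
    -------
    ``2*mu*L_c * (1 - e^{-4g(1-z)}) / (z(1-z)(1 - e^{-4g}))`` for g != 0 and
    ``2*mu*L_c / z`` for g = 0 (the continuous limit). The lethal sentinel
    returns 0 everywhere.
    """
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    z_arr = np.atleast_1d(z_arr)
    if np.any((z_arr <= 0.0) | (z_arr >= 1.0)):
        raise DomainError("population frequency z must lie strictly in (0, 1)")
    if L_c < 0:
        raise DomainError("L_c must be non-negative")
    if _is_lethal(gamma):
        out = np.zeros_like(z_arr)
    else:
        if not np.isfinite(gamma):
            raise DomainError("gamma must be finite or the lethal sentinel")
        out = 2.0 * mu * L_c * _ratio(z_arr, float(gamma)) / (z_arr * (1.0 - z_arr))
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class PopulationModel:
    """Population-scale parameters shared by simulation and inference.

    ``ne`` is the diploid effective size defining the frequency grid,
    ``ns`` the number of sampled haplotypes, ``theta = 4*Ne*mu`` the
    scaled per-site mutation rate and ``L`` the number of sites.
    """

    ne: int = 2000
    ns: int = 160
    theta: float = 0.01
    L: int = 1

    def __post_init__(self):
        if self.ns < 2:
            raise DomainError("ns must be at least 2")
        if self.ne < 1:
            raise DomainError("ne must be positive")
        if not self.theta > 0:
            raise DomainError("theta must be positive")
        if self.L < 1:
            raise DomainError("L must be at least 1")

    @property
    def mu(self) -> float:
        return self.theta / (4.0 * self.ne)

    @property
    def n_folded(self) -> int:
        return self.ns // 2


@dataclass(frozen=True)
class DFEClass:
    gamma: Gamma
    f: float

    @property
    def is_lethal(self) -> bool:
        return _is_lethal(self.gamma)


@dataclass(frozen=True)
class DFEModel:
    """Categorical distribution of fitness effects.

    ``classes`` lists the non-neutral classes as (gamma, fraction) pairs;
    the neutral class is implicit with ``f0 = 1 - sum(f_c)`` and gamma 0.
    """

    classes: tuple = ()

    def __post_init__(self):
        cls = tuple(
            c if isinstance(c, DFEClass) else DFEClass(*c) for c in self.classes
        )
        object.__setattr__(self, "classes", cls)
        total = 0.0
        n_lethal = 0
        for c in cls:
            if c.f < 0:
                raise DomainError("class fractions must be non-negative")
            total += c.f
            if c.is_lethal:
                n_lethal += 1
            else:
                if not np.isfinite(c.gamma):
                    raise DomainError("gamma must be finite or lethal")
                if c.gamma > 0:
                    raise DomainError("purifying convention requires gamma <= 0")
        if total > 1.0 + 1e-12:
            raise DomainError(f"class fractions sum to {total} > 1")
        if n_lethal > 1:
            raise DomainError("at most one lethal class is allowed")

    @property
    def f0(self) -> float:
        return max(0.0, 1.0 - sum(c.f for c in self.classes))

    @classmethod
    def neutral(cls) -> "DFEModel":
        return cls(())


# ---------------------------------------------------------------------------
# cached grids
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _grid(ne: int, ns: int):
    """Precomputed sampling matrices for a (Ne, Ns) pair.

    Returns (z, B, Bf, shape0) where
      z      : population frequency grid j/(2Ne), j = 1..2Ne-1
      B      : B[j, k-1] = Binom(k; Ns, z_j) for k = 1..Ns-1
      Bf     : folded projection, Bf[j, m-1] = B[j, m] + B[j, Ns-m]
               (the Ns/2 class counted once)
      shape0 : neutral per-(theta*f) sojourn shape, shape0[j] = 1/j
    """
    j = np.arange(1, 2 * ne)
    z = j / (2.0 * ne)
    k = np.arange(1, ns)
    B = _binom.pmf(k[None, :], ns, z[:, None])
    nf = ns // 2
    Bf = B[:, :nf].copy()
    for m in range(1, nf + 1):
        if ns - m != m:
            Bf[:, m - 1] += B[:, ns - m - 1]
    shape0 = 1.0 / j
    B.setflags(write=False)
    Bf.setflags(write=False)
    shape0.setflags(write=False)
    return z, B, Bf, shape0


def _shape(ne: int, ns: int, gamma: float) -> np.ndarray:
    """Per-(theta*f_c) sojourn weights over the grid: g_c(z_j)/(theta*f_c)."""
    z, _, _, shape0 = _grid(ne, ns)
    if gamma == 0.0:
        return shape0
    return _ratio(z, gamma) / (z * (1.0 - z)) / (2.0 * ne)


def _unit_sample_probs(ne: int, ns: int, gamma: Gamma) -> np.ndarray:
    """Unfolded sample-frequency probabilities per unit (theta * f_c)."""
    _, B, _, _ = _grid(ne, ns)
    if _is_lethal(gamma):
        return np.zeros(ns - 1)
    return _shape(ne, ns, float(gamma)) @ B


def _unit_folded_probs(ne: int, ns: int, gamma: Gamma) -> np.ndarray:
    """Folded polymorphic probabilities (classes 1..Ns//2) per unit (theta*f_c)."""
    _, _, Bf, _ = _grid(ne, ns)
    if _is_lethal(gamma):
        return np.zeros(ns // 2)
    return _shape(ne, ns, float(gamma)) @ Bf


@lru_cache(maxsize=8)
def _unit_folded_neutral(ne: int, ns: int) -> np.ndarray:
    out = _unit_folded_probs(ne, ns, 0.0)
    out.setflags(write=False)
    return out


@lru_cache(maxsize=8)
def _fold_kernel(ne: int, ns: int):
    """(z, 1/(2Ne z(1-z)), Bf) for the hot fitting path."""
    z, _, Bf, _ = _grid(ne, ns)
    zz = 1.0 / (z * (1.0 - z) * (2.0 * ne))
    zz.setflags(write=False)
    return z, zz, Bf


def sample_frequency_probs(
    model: PopulationModel, gamma: Gamma, f_c: float = 1.0
) -> np.ndarray:
    """Per-site probability of observing k = 1..Ns-1 derived copies in the
    sample, for a selection class with coefficient ``gamma`` occupying a
    fraction ``f_c`` of sites.

    Sums the sojourn density over the full population frequency grid
    ``z = j/(2Ne)`` against the binomial sampling kernel. The lethal class
    returns the all-zero vector.
    """
    if f_c < 0:
        raise DomainError("f_c must be non-negative")
    return model.theta * f_c * _unit_sample_probs(model.ne, model.ns, gamma)


def _folded_poly_probs(
    ne: int,
    ns: int,
    theta: float,
    dfe: DFEModel,
    alpha_vec: np.ndarray | None = None,
) -> np.ndarray:
    """alpha-corrected folded polymorphic class probabilities (m = 1..Ns//2)."""
    poly = dfe.f0 * _unit_folded_neutral(ne, ns).copy()
    for c in dfe.classes:
        if c.is_lethal or c.f == 0.0:
            continue
        poly += c.f * _unit_folded_probs(ne, ns, c.gamma)
    poly *= theta
    if alpha_vec is not None:
        poly = poly * alpha_vec
    return poly


def expected_folded_sfs(
    model: PopulationModel,
    dfe: DFEModel,
    alpha: "AlphaCorrection | None" = None,
) -> np.ndarray:
    """Expected per-site folded spectrum under a categorical DFE.

    Returns a vector of length ``Ns//2 + 1``: entry 0 is the monomorphic
    class probability, entries ``m = 1..Ns//2`` the alpha-corrected folded
    polymorphic classes ``alpha_m * sum_c [p_c(m) + p_c(Ns-m)]`` (the
    ``Ns/2`` class counted once). Raises :class:`ModelInvalidError` when
    the implied monomorphic probability is negative.
    """
    alpha_vec = None if alpha is None else alpha.expand(model.n_folded)
    poly = _folded_poly_probs(model.ne, model.ns, model.theta, dfe, alpha_vec)
    mono = 1.0 - poly.sum()
    if mono < 0:
        raise ModelInvalidError(
            f"monomorphic probability {mono:g} < 0; theta and/or alpha too large"
        )
    return np.concatenate(([mono], poly))


# ---------------------------------------------------------------------------
# folded spectra and alpha corrections
# ---------------------------------------------------------------------------


@dataclass
class FoldedSFS:
    """A folded sample spectrum: polymorphic class counts plus monomorphic.

    ``counts[m-1]`` holds the number of sites in folded class ``m`` for
    ``m = 1..Ns//2``; ``k0`` the monomorphic sites.
    """

    counts: np.ndarray
    k0: int
    ns: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) != self.ns // 2:
            raise DomainError(
                f"expected {self.ns // 2} folded classes for ns={self.ns}, "
                f"got {len(self.counts)}"
            )
        if self.k0 < 0 or np.any(self.counts < 0):
            raise DomainError("counts must be non-negative")
        if self.L < 1:
            raise DomainError("spectrum must contain at least one site")

    @property
    def L(self) -> int:
        return int(self.k0 + self.counts.sum())

    @property
    def n_polymorphic(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "FoldedSFS") -> "FoldedSFS":
        if other.ns != self.ns:
            raise DomainError("cannot add spectra with different ns")
        return FoldedSFS(self.counts + other.counts, self.k0 + other.k0, self.ns)


def fold(raw: Sequence[float]) -> FoldedSFS:
    """Fold a raw spectrum over derived counts 0..Ns into a :class:`FoldedSFS`.

    ``raw[k]`` is the number of sites with k derived copies; classes k and
    Ns-k are combined, the Ns/2 class (even Ns) is kept as is, and classes
    0 and Ns jointly form the monomorphic count.
    """
    raw = np.asarray(raw)
    if np.any(raw < 0):
        raise DomainError("negative counts in raw spectrum")
    ns = len(raw) - 1
    if ns < 2:
        raise DomainError("raw spectrum must cover derived counts 0..Ns with Ns >= 2")
    nf = ns // 2
    counts = np.empty(nf, dtype=np.int64)
    for m in range(1, nf + 1):
        counts[m - 1] = raw[m] + (raw[ns - m] if ns - m != m else 0)
    return FoldedSFS(counts, int(raw[0] + raw[ns]), ns)


def default_alpha_bins(ns: int, n_bins: int = 6) -> tuple:
    """Power-law partition of folded classes 1..Ns//2 into frequency bins.

    For the canonical Ns=160 design the edges are
    {1},{2-3},{4-8},{9-20},{21-44},{45-80}; other sample sizes use a
    geometric progression of lower edges.
    """
    nf = ns // 2
    if ns == 160 and n_bins == 6:
        lowers = [1, 2, 4, 9, 21, 45]
    else:
        lowers = sorted({int(round(nf ** (i / n_bins))) for i in range(n_bins)})
        lowers = [lo for lo in lowers if lo <= nf]
    bins = []
    for i, lo in enumerate(lowers):
        hi = (lowers[i + 1] - 1) if i + 1 < len(lowers) else nf
        bins.append((lo, hi))
    return tuple(bins)


@dataclass(frozen=True)
class AlphaCorrection:
    """Per-frequency-bin multiplicative corrections to folded class
    probabilities. ``bins`` is a tuple of inclusive (lo, hi) folded-class
    ranges partitioning 1..Ns//2; the bin containing the singleton class
    is constrained to multiplier 1.
    """

    bins: tuple
    values: tuple

    def __post_init__(self):
        bins = tuple((int(lo), int(hi)) for lo, hi in self.bins)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "bins", bins)
        object.__setattr__(self, "values", values)
        if len(bins) != len(values):
            raise DomainError("one alpha value per bin required")
        if any(v <= 0 for v in values):
            raise DomainError("alpha values must be positive")
        prev_hi = 0
        for lo, hi in bins:
            if lo != prev_hi + 1 or hi < lo:
                raise DomainError("bins must partition 1..Ns//2 contiguously")
            prev_hi = hi
        # singleton bin anchored at 1
        if abs(values[0] - 1.0) > 1e-12:
            raise DomainError("the bin containing the singleton class is fixed at 1")

    @classmethod
    def identity(cls, ns: int, n_bins: int = 6) -> "AlphaCorrection":
        bins = default_alpha_bins(ns, n_bins)
        return cls(bins, (1.0,) * len(bins))

    @property
    def n_folded(self) -> int:
        return self.bins[-1][1]

    def expand(self, nf: int) -> np.ndarray:
        """Per-folded-class multiplier vector of length ``nf``."""
        if nf != self.n_folded:
            raise DomainError(
                f"alpha bins cover classes 1..{self.n_folded}, need 1..{nf}"
            )
        out = np.empty(nf)
        for (lo, hi), v in zip(self.bins, self.values):
            out[lo - 1 : hi] = v
        return out

    def bin_of(self, m: int) -> int:
        for i, (lo, hi) in enumerate(self.bins):
            if lo <= m <= hi:
                return i
        raise DomainError(f"folded class {m} outside alpha bins")
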