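"""Analytic single-fragment coverage model for paired-end libraries.

Sequencing one paired-end fragment (insert size ``L``, read length ``r``)
from a genome of ``n`` bases contributes coverage to a random position.
For a *short-insert* library (``L < 2r``, the cell-free DNA regime) the
two reads overlap, so a base either receives no coverage or the
concentrated per-base contribution ``2r/L``; for a *long-insert* library
(``L > 2r``, sheared genomic DNA) a base is covered at most once.  Both
two-point distributions share the expectation ``2r/n`` but differ in
variance, which is why short-insert coverage is less uniform across the
genome at matched mean depth.

The model is derived for a single fragment (``k = 1``); the read-count
field ``k`` is carried in the parameter set but values above one are not
implemented.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LibraryKind",
    "CoverageModelParams",
    "CoveragePMF",
    "KindInsertMismatchError",
    "pmf",
    "expectation",
    "variance",
    "variance_difference",
    "simulate_coverage",
]

#: Absolute tolerance used for analytic equality checks throughout.
ATOL = 1e-12


class LibraryKind(str, enum.Enum):
    """Library regime: short inserts (reads overlap) or long inserts."""

    SHORT_INSERT = "short_insert"
    LONG_INSERT = "long_insert"


class KindInsertMismatchError(ValueError):
    """The insert size is incompatible with the requested library kind."""


@dataclass(frozen=True)
class CoverageModelParams:
    """Parameters of the analytic coverage model.

    Parameters
    ----------
    n
        Genome size in bases.
    L
        Insert size (fragment length) in bases.
    r
        Read length in bases; paired-end, so ``2r`` bases are sequenced
        per fragment.
    k
        Number of fragments; the model is derived for ``k = 1`` only.
    """

    n: int
    L: int
    r: int
    k: int = 1

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"read length r must be >= 1, got {self.r}")
        if self.L < 1:
            raise ValueError(f"insert size L must be >= 1, got {self.L}")
        if self.n <= self.L:
            raise ValueError(f"genome size n={self.n} must exceed insert size L={self.L}")
        if self.n <= 2 * self.r:
            raise ValueError(f"genome size n={self.n} must exceed 2r={2 * self.r}")
        if self.k < 1:
            raise ValueError(f"read count k must be >= 1, got {self.k}")

    @property
    def p1(self) -> float:
        """Probability that a base falls within the (short) fragment, L/n."""
        return self.L / self.n

    @property
    def p2(self) -> float:
        """Probability that a base falls within a read, 2r/n."""
        return 2 * self.r / self.n


@dataclass(frozen=True)
class CoveragePMF:
    """Two-point probability mass function of per-base coverage."""

    support: tuple[float, ...]
    probabilities: tuple[float, ...]
    kind: LibraryKind

    def __post_init__(self) -> None:
        if abs(sum(self.probabilities) - 1.0) > ATOL:
            raise ValueError("probabilities must sum to 1")
        if any(p < 0 or p > 1 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(x < 0 for x in self.support):
            raise ValueError("support values must be non-negative")

    def moment(self, order: int, central: bool = False) -> float:
        """Moment of the distribution by direct summation over the support."""
        s = np.asarray(self.support, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if central:
            s = s - float(np.sum(s * p))
        return float(np.sum(s**order * p))


def _require_k1(params: CoverageModelParams) -> None:
    if params.k != 1:
        raise NotImplementedError(
            "the analytic coverage model is derived for a single fragment (k = 1); "
            f"got k = {params.k}"
        )


def _check_kind(params: CoverageModelParams, kind: LibraryKind) -> LibraryKind:
    kind = LibraryKind(kind)
    # L == 2r is the boundary where both regimes coincide and either kind
    # is accepted.
    if kind is LibraryKind.SHORT_INSERT and params.L > 2 * params.r:
        raise KindInsertMismatchError(
            f"short_insert requires L <= 2r, got L={params.L}, 2r={2 * params.r}"
        )
    if kind is LibraryKind.LONG_INSERT and params.L < 2 * params.r:
        raise KindInsertMismatchError(
            f"long_insert requires L >= 2r, got L={params.L}, 2r={2 * params.r}"
        )
    return kind


def pmf(params: CoverageModelParams, kind: LibraryKind) -> CoveragePMF:
    """Coverage PMF of a single fragment for the given library kind.

    Short-insert: support ``{0, 2r/L}`` with masses ``{1 - L/n, L/n}``.
    Long-insert: support ``{0, 1}`` with masses ``{1 - 2r/n, 2r/n}``.
    """
    _require_k1(params)
    kind = _check_kind(params, kind)
    if kind is LibraryKind.SHORT_INSERT:
        return CoveragePMF(
            support=(0.0, 2 * params.r / params.L),
            probabilities=(1.0 - params.p1, params.p1),
            kind=kind,
        )
    return CoveragePMF(
        support=(0.0, 1.0),
        probabilities=(1.0 - params.p2, params.p2),
        kind=kind,
    )


def expectation(params: CoverageModelParams, kind: LibraryKind) -> float:
    """Expected per-base coverage, ``2r/n`` — identical for both kinds."""
    _require_k1(params)
    LibraryKind(kind)
    return 2 * params.r / params.n


def variance(params: CoverageModelParams, kind: LibraryKind) -> float:
    """Analytic coverage variance for the given library kind.

    Short-insert: ``4 r^2 (1/(L n) - 1/n^2)``.
    Long-insert: ``(2r/n)(1 - 2r/n)``.
    """
    _require_k1(params)
    kind = _check_kind(params, kind)
    n, L, r = params.n, params.L, params.r
    if kind is LibraryKind.SHORT_INSERT:
        return 4 * r**2 * (1.0 / (L * n) - 1.0 / n**2)
    return (2 * r / n) * (1.0 - 2 * r / n)


def variance_difference(params: CoverageModelParams) -> float:
    """Var(short) - Var(long) in closed form: ``(2r/n)(2r/L - 1)``.

    Strictly positive when ``L < 2r``; zero at the ``L = 2r`` boundary.
    Raises for ``L > 2r``, where the short-insert regime does not apply.
    """
    _require_k1(params)
    if params.L > 2 * params.r:
        raise KindInsertMismatchError(
            f"variance_difference requires L <= 2r, got L={params.L}, 2r={2 * params.r}"
        )
    return (2 * params.r / params.n) * (2 * params.r / params.L - 1.0)


def simulate_coverage(
    params: CoverageModelParams,
    kind: LibraryKind,
    draws: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo sample of the coverage PMF.

    Returns the sample mean and (population, ``ddof=0``) sample variance
    of ``draws`` i.i.d. draws; reproducible for a fixed ``seed``.
    """
    if draws < 1:
        raise ValueError(f"draws must be >= 1, got {draws}")
    dist = pmf(params, kind)
    rng = np.random.default_rng(seed)
    hit = rng.random(draws) < dist.probabilities[1]
    values = np.where(hit, dist.support[1], dist.support[0])
    return float(values.mean()), float(values.var())
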