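"""Symbolic derivation of the virtual-hexagonal-trellis (VHT) gradient kernels.

A hexagonal neighborhood is overlaid on the native 3x3 square pixel grid by
introducing four *virtual elements* ``h1..h4``, each the average of a corner
pixel and the central pixel ``fc``.  Directional intensity differences across
the resulting hexagon expand, after substitution of the virtual elements, into
linear combinations of the nine real pixels; those combinations are the x- and
y-gradient kernels.  A 45-degree diagonal kernel arises from summing the two
bracket matrices, and the 135-degree kernel is its column mirror.

All symbolic work is done with exact rational coefficients
(:class:`fractions.Fraction`) so that the cancellation of the central pixel is
exact rather than a floating-point near-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, Mapping

import numpy as np

#: The nine real-pixel symbols of the 3x3 neighborhood.
SYMBOLS = ("f1", "f2", "f3", "f4", "fc", "f6", "f7", "f8", "f9")

#: Row-major symbol layout of the 3x3 neighborhood, origin top-left.
#: This is the unique layout under which the x-direction expansion maps onto
#: the half-Sobel x matrix.
LAYOUT = (
    ("f1", "f2", "f3"),
    ("f4", "fc", "f6"),
    ("f7", "f8", "f9"),
)


@dataclass(frozen=True)
class VirtualElementExpr:
    """Exact linear combination of the 3x3 neighborhood symbols.

    Coefficients are :class:`~fractions.Fraction`; symbols with coefficient
    zero may be omitted from the mapping.
    """

    coefficients: Mapping[str, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.coefficients) - set(SYMBOLS)
        if bad:
            raise ValueError(f"unknown neighborhood symbols: {sorted(bad)}")
        object.__setattr__(
            self,
            "coefficients",
            {s: Fraction(c) for s, c in self.coefficients.items() if c != 0},
        )

    def coeff(self, symbol: str) -> Fraction:
        if symbol not in SYMBOLS:
            raise ValueError(f"unknown neighborhood symbol: {symbol}")
        return self.coefficients.get(symbol, Fraction(0))

    def __add__(self, other: "VirtualElementExpr") -> "VirtualElementExpr":
        out = dict(self.coefficients)
        for s, c in other.coefficients.items():
            out[s] = out.get(s, Fraction(0)) + c
        return VirtualElementExpr(out)

    def __sub__(self, other: "VirtualElementExpr") -> "VirtualElementExpr":
        return self + (other * -1)

    def __mul__(self, scalar) -> "VirtualElementExpr":
        k = Fraction(scalar)
        return VirtualElementExpr({s: c * k for s, c in self.coefficients.items()})

    __rmul__ = __mul__

    def evaluate(self, neighborhood: Mapping[str, float] | np.ndarray) -> float:
        """Numeric value of the expression on a concrete 3x3 neighborhood.

        ``neighborhood`` is either a symbol->value mapping or a 3x3 array laid
        out as :data:`LAYOUT`.
        """
        if isinstance(neighborhood, np.ndarray):
            arr = np.asarray(neighborhood, dtype=float)
            if arr.shape != (3, 3):
                raise ValueError("neighborhood array must be 3x3")
            neighborhood = {
                LAYOUT[r][c]: arr[r, c] for r in range(3) for c in range(3)
            }
        return float(
            sum(float(c) * float(neighborhood[s]) for s, c in self.coefficients.items())
        )

    def coefficient_sum(self) -> Fraction:
        return sum(self.coefficients.values(), Fraction(0))


def _sym(symbol: str) -> VirtualElementExpr:
    return VirtualElementExpr({symbol: Fraction(1)})


def build_virtual_elements() -> Dict[str, VirtualElementExpr]:
    """The four virtual elements: mean of one corner pixel and ``fc``.

    ``h1`` pairs ``f1`` with the center, ``h2`` pairs ``f3``, ``h3`` pairs
    ``f7`` and ``h4`` pairs ``f9``.
    """
    half = Fraction(1, 2)
    return {
        "h1": VirtualElementExpr({"f1": half, "fc": half}),
        "h2": VirtualElementExpr({"f3": half, "fc": half}),
        "h3": VirtualElementExpr({"f7": half, "fc": half}),
        "h4": VirtualElementExpr({"f9": half, "fc": half}),
    }


def expand_directional_difference(axis: str) -> VirtualElementExpr:
    """Directional hexagon difference with the virtual elements substituted.

    ``axis='x'``: (f6 + h2 + h4) - (f4 + h1 + h3), the right column of the
    hexagon minus the left; expands to (2f6 + f3 + f9 - 2f4 - f1 - f7) / 2.
    ``axis='y'``: (h3 + h4) - (h1 + h2), the lower virtual pair minus the
    upper; expands to (f7 + f9 - f1 - f3) / 2.  The central pixel cancels in
    both expansions.
    """
    h = build_virtual_elements()
    if axis == "x":
        return (_sym("f6") + h["h2"] + h["h4"]) - (_sym("f4") + h["h1"] + h["h3"])
    if axis == "y":
        return (h["h3"] + h["h4"]) - (h["h1"] + h["h2"])
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


def kernel_from_expression(
    expr: VirtualElementExpr, layout: Iterable[Iterable[str]] = LAYOUT
) -> np.ndarray:
    """Map symbolic coefficients onto a 3x3 matrix of Fractions.

    Cell (r, c) holds the coefficient of the symbol at that layout position,
    so evaluating the expression on a neighborhood equals the elementwise
    product-sum of this matrix with the neighborhood array.
    """
    layout = tuple(tuple(row) for row in layout)
    out = np.empty((3, 3), dtype=object)
    for r in range(3):
        for c in range(3):
            out[r, c] = expr.coeff(layout[r][c])
    return out


def expression_from_kernel(
    kernel: np.ndarray, layout: Iterable[Iterable[str]] = LAYOUT
) -> VirtualElementExpr:
    """Inverse of :func:`kernel_from_expression`."""
    layout = tuple(tuple(row) for row in layout)
    coeffs: Dict[str, Fraction] = {}
    for r in range(3):
        for c in range(3):
            coeffs[layout[r][c]] = coeffs.get(layout[r][c], Fraction(0)) + Fraction(
                kernel[r, c]
            )
    return VirtualElementExpr(coeffs)


def _frac_matrix(rows, scale=Fraction(1)) -> np.ndarray:
    out = np.empty((3, 3), dtype=object)
    for r in range(3):
        for c in range(3):
            out[r, c] = Fraction(rows[r][c]) * scale
    return out


@dataclass(frozen=True)
class KernelSet:
    """The four numeric VHT gradient kernels (exact rational entries).

    ``kx``/``ky`` are the derived half-Sobel operators; ``k45`` is the
    unit-scaled diagonal kernel obtained from the bracket-matrix sum, and
    ``k135`` is its mirror across the vertical axis.  Every kernel sums to
    zero, so constant image regions produce zero response.
    """

    kx: np.ndarray
    ky: np.ndarray
    k45: np.ndarray
    k135: np.ndarray
    #: the integer prefactor the combined diagonal kernel was factored by
    diagonal_factor: int = 2

    def __iter__(self):
        return iter((self.kx, self.ky, self.k45, self.k135))

    def as_float(self) -> Dict[str, np.ndarray]:
        """Kernels as float arrays, keyed by direction name."""
        return {
            name: np.array([[float(v) for v in row] for row in k])
            for name, k in zip(("x", "y", "45", "135"), self)
        }


def canonical_kernels() -> KernelSet:
    """The four canonical VHT kernels.

    ``kx`` is derived symbolically; ``ky`` is the half-Sobel y matrix
    (see the methods note for why it is not the raw y-expansion); ``k45`` is
    the bracket-matrix sum factored to unit scale; ``k135`` its column mirror.
    """
    half = Fraction(1, 2)
    kx = _frac_matrix([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], half)
    ky = _frac_matrix([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], half)
    k45 = _frac_matrix([[0, 1, 1], [-1, 0, 1], [-1, -1, 0]])
    k135 = k45[:, ::-1].copy()
    return KernelSet(kx=kx, ky=ky, k45=k45, k135=k135, diagonal_factor=2)


def bracket_sum() -> np.ndarray:
    """Elementwise sum of the integer bracket matrices of kx and ky.

    The half prefactors of both kernels are dropped before summing, matching
    the combination step that precedes the diagonal-kernel factoring."""
    ks = canonical_kernels()
    out = np.empty((3, 3), dtype=object)
    for r in range(3):
        for c in range(3):
            out[r, c] = (ks.kx[r, c] + ks.ky[r, c]) * 2
    return out


def gcd_factor(m: np.ndarray) -> int:
    """GCD of the absolute values of the nonzero entries of an integer matrix."""
    vals = [int(v) for v in np.asarray(m, dtype=object).ravel() if int(v) != 0]
    if not vals:
        raise ValueError("all-zero matrix has no GCD factor")
    return math.gcd(*(abs(v) for v in vals)) if len(vals) > 1 else abs(vals[0])
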