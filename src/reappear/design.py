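"""Design matrices for the rating-polynomial model family.

The predictor is the five-level fact-checking rating x in
{-2, -1, 0, 1, 2}.  Model structures range from an intercept-only
null model to a saturated model that treats the rating as a
categorical variable.  Raw polynomial columns (x, x^2, x^3) can be
replaced by orthogonal polynomial contrasts built against the
empirical rating distribution, which decorrelates the linear
("falsehood") and quadratic ("ambiguity") terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRUCTURES = (
    "intercept",
    "linear",
    "quadratic_constrained",
    "quadratic_unconstrained",
    "cubic",
    "saturated",
)

# number of design columns (incl. intercept) per structure
_K_DESIGN = {
    "intercept": 1,
    "linear": 2,
    "quadratic_constrained": 2,
    "quadratic_unconstrained": 3,
    "cubic": 4,
    "saturated": 5,
}

#: reference level for the saturated (categorical) coding
SATURATED_REFERENCE = -2


@dataclass(frozen=True)
class DesignSpec:
    """Specification of one model structure over the rating predictor."""

    structure: str = "quadratic_unconstrained"
    orthogonal: bool = False
    predictor: str = "rating"

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )

    @property
    def k_design(self) -> int:
        return _K_DESIGN[self.structure]

    def is_nested_in(self, other: "DesignSpec") -> bool:
        """True when this structure's column space is contained in *other*'s.

        Nesting is judged on the raw polynomial/categorical spans; the
        orthogonal flag does not change spans, only the basis.
        """
        spans = {
            "intercept": frozenset(),
            "linear": frozenset({1}),
            "quadratic_constrained": frozenset({2}),
            "quadratic_unconstrained": frozenset({1, 2}),
            "cubic": frozenset({1, 2, 3}),
        }
        if other.structure == "saturated":
            # 5 rating levels: the saturated span contains every polynomial
            # of degree <= 4, hence all other structures.
            return self.structure != "saturated"
        if self.structure == "saturated":
            return False
        return spans[self.structure] <= spans[other.structure]


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthogonal polynomial columns of ``x`` up to ``degree``.

    Gram–Schmidt against the empirical distribution of ``x`` (via QR of
    the centred Vandermonde matrix): each returned column has zero mean,
    unit Euclidean norm and is orthogonal to all lower-degree columns.
    Column ``j`` (0-based) is the degree ``j+1`` contrast.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.unique(x).size <= degree:
        raise ValueError(
            f"need more than {degree} distinct predictor values for degree-{degree} "
            "orthogonal polynomials"
        )
    V = np.vander(x, N=degree + 1, increasing=True)  # [1, x, x^2, ...]
    Q, R = np.linalg.qr(V)
    # fix sign so each contrast correlates positively with x^degree
    for j in range(1, degree + 1):
        if R[j, j] < 0:
            Q[:, j] *= -1.0
    return Q[:, 1:]


def build_design(ratings: np.ndarray, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Build the (n, k_design) design matrix and its column names."""
    x = np.asarray(ratings, dtype=float)
    n = x.shape[0]
    ones = np.ones(n)

    if spec.structure == "saturated":
        levels = [-2, -1, 0, 1, 2]
        cols = [ones]
        names = ["beta0"]
        for lv in levels:
            if lv == SATURATED_REFERENCE:
                continue
            cols.append((x == lv).astype(float))
            names.append(f"rating[{lv:+d}]")
        return np.column_stack(cols), names

    max_degree = {"intercept": 0, "linear": 1, "quadratic_constrained": 2,
                  "quadratic_unconstrained": 2, "cubic": 3}[spec.structure]
    if spec.structure == "intercept":
        return ones[:, None], ["beta0"]

    if spec.orthogonal:
        P = orthogonal_poly(x, max_degree)
        poly_cols = {d: P[:, d - 1] for d in range(1, max_degree + 1)}
        tag = "o"
    else:
        poly_cols = {d: x**d for d in range(1, max_degree + 1)}
        tag = ""

    degrees = {
        "linear": [1],
        "quadratic_constrained": [2],
        "quadratic_unconstrained": [1, 2],
        "cubic": [1, 2, 3],
    }[spec.structure]
    cols = [ones] + [poly_cols[d] for d in degrees]
    names = ["beta0"] + [f"beta{d}{tag}" for d in degrees]
    return np.column_stack(cols), names
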