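"""Natural cubic spline basis for time since disease onset.

The trajectory model represents time through a natural cubic spline:
cubic between knots, continuous second derivative, and *linear* outside
the boundary knots, so extrapolation a little past the observation
window stays tame.  The default configuration uses 2 basis columns with
one interior knot at 5 years and boundary knots at 0 and 10 years.

Every basis column is shifted to equal 0 at the left boundary knot
(disease onset), so a cluster's intercept coefficient is its mean
biomarker level at onset.  Which particular columns span the spline
space is a convention; fitted curves are invariant to it, individual
coefficients are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineConfig", "spline_basis"]


@dataclass(frozen=True)
class SplineConfig:
    """Configuration of the time spline.

    ``df`` is the number of basis columns (excluding the intercept,
    which the design matrices carry separately); it must equal
    ``1 + len(interior_knots)`` for a natural cubic spline space.
    """

    df: int = 2
    interior_knots: tuple[float, ...] = (5.0,)
    boundary: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self):
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary knots must be increasing")
        if any(not lo < k < hi for k in self.interior_knots):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if list(self.interior_knots) != sorted(self.interior_knots):
            raise ValueError("interior knots must be sorted")
        if self.df != len(self.interior_knots) + 1:
            raise ValueError(
                "df must equal 1 + number of interior knots "
                f"(got df={self.df}, {len(self.interior_knots)} interior knots)"
            )

    @property
    def all_knots(self) -> np.ndarray:
        return np.array([self.boundary[0], *self.interior_knots, self.boundary[1]])

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "interior_knots": list(self.interior_knots),
            "boundary": list(self.boundary),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineConfig":
        return cls(df=int(d["df"]),
                   interior_knots=tuple(float(k) for k in d["interior_knots"]),
                   boundary=(float(d["boundary"][0]), float(d["boundary"][1])))


def _cubed_plus(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0) ** 3


def spline_basis(t, cfg: SplineConfig = SplineConfig()) -> np.ndarray:
    """Evaluate the natural cubic spline basis at times ``t``.

    Returns an array of shape ``(len(t), cfg.df)``.  Rows at the left
    boundary knot are identically zero; beyond either boundary knot the
    columns continue linearly.

    The construction is the classical reduced truncated-power one: with
    knots ``xi_1 < ... < xi_m`` (boundary knots included), the non-linear
    columns are differences

        d_k(t) - d_{m-1}(t),   d_k(t) = [(t-xi_k)^3_+ - (t-xi_m)^3_+] / (xi_m - xi_k)

    whose cubic and quadratic terms cancel beyond ``xi_m``; the linear
    column is ``t - xi_1``.  Columns are rescaled by the knot range
    (linear column by ``1/range``, the rest by ``1/range^2``) so all
    basis values are O(1) over the window and coefficient priors of a
    few units are weakly informative on standardized biomarker scales.
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("non-finite time values")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    xi = cfg.all_knots
    m = len(xi)

    def d(k):
        return (_cubed_plus(t - xi[k]) - _cubed_plus(t - xi[m - 1])) / (xi[m - 1] - xi[k])

    rng = xi[-1] - xi[0]
    cols = [(t - xi[0]) / rng]
    dm1 = d(m - 2)
    for k in range(m - 2):
        cols.append((d(k) - dm1) / rng ** 2)
    # every column vanishes at xi_1 already (truncated powers are zero
    # at or below their own knot), which is the at-onset convention
    out = np.column_stack(cols)
    return out[0] if scalar else out
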