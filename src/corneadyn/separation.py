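"""Separation of whole-eyeball displacement from corneal deflection.

During the air puff the cornea is indented *and* the whole globe recedes
into the orbit.  Both motions superimpose in the contour map, so the
relative deformation

    L_T(n, i) = L_P(n, i) - L_P(n, 0)

is decomposed as L_T = L_TO + L_TR, where the eyeball displacement L_TO
is, for each frame, the straight line (affine in the column index n)
through the deformation observed at the left and right image borders --
the cornea itself is assumed undeformed there, so whatever the borders do
is rigid-globe motion -- and the corneal deflection L_TR is the
remainder.  The decomposition is linear, exact by construction
(L_TO + L_TR reconstructs L_T bit for bit) and idempotent: the cornea
part has zero border values, so separating it again changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_sequences import DimensionError, Map2D

__all__ = ["DeformationDecomposition", "relative_deformation", "separate_eyeball", "max_deflection"]


@dataclass
class DeformationDecomposition:
    """Relative deformation and its eyeball/cornea split, all (N, I) in px."""

    L_T: Map2D
    L_TO: Map2D
    L_TR: Map2D

    def __post_init__(self) -> None:
        if not (self.L_T.shape == self.L_TO.shape == self.L_TR.shape):
            raise DimensionError("decomposition maps must share one shape")


def relative_deformation(contour: Map2D) -> Map2D:
    """Subtract the frame-0 corneal profile from every frame.

    Positive values mean displacement toward the eye interior (the row
    index grows downward).  Frame 0 is its own baseline, so the first
    column of the result is identically zero.  NaNs (missing contour
    columns) propagate.
    """
    values = contour.values - contour.values[:, [0]]
    return Map2D(values, "deformation")


def separate_eyeball(L_T: Map2D, border_band: int = 1) -> DeformationDecomposition:
    """Split relative deformation into eyeball displacement and corneal deflection.

    For each frame the eyeball displacement is the affine-in-n
    interpolation between the deformation at the left and right image
    borders.  ``border_band`` widens each border reading to the mean of
    that many outermost columns (1 = single border columns, the exact
    border rule; wider bands trade exactness at the borders for robustness
    to border noise).
    """
    n_cols = L_T.shape[0]
    if not 1 <= border_band <= n_cols // 2:
        raise ValueError(f"border_band must lie in [1, {n_cols // 2}], got {border_band}")
    values = L_T.values
    left = values[:border_band, :].mean(axis=0)
    right = values[-border_band:, :].mean(axis=0)
    ramp = (np.arange(n_cols, dtype=float) / (n_cols - 1))[:, None]
    eyeball = left[None, :] + (right - left)[None, :] * ramp
    # pin the borders so the affine line passes through them exactly, free
    # of the rounding of the ramp arithmetic
    eyeball[0, :] = left
    eyeball[-1, :] = right
    cornea = values - eyeball
    # returning the recomposed sum (identical to the input up to one ulp)
    # makes the conservation identity L_TO + L_TR = L_T hold bit-exactly
    return DeformationDecomposition(
        L_T=Map2D(eyeball + cornea, "deformation"),
        L_TO=Map2D(eyeball, "eyeball"),
        L_TR=Map2D(cornea, "cornea"),
    )


def max_deflection(L_TR: Map2D) -> float:
    """Maximum corneal deflection amplitude, px: the global max over (n, i)."""
    return float(np.nanmax(L_TR.values))
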