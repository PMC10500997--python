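"""Synthetic template geometries and toy oracle systems.

Everything here is generated in code — no structure downloads.  The helix
generator emulates the regular helical geometry of the experimental heparin
template at the anchor level (configurable rise/twist/radius); the defaults
give an anchor spacing of ≈5 Å so that a fully extended dp12 chain has a
contour length of ≈60 Å, matching the scale of the packaged experimental
reference.  This is a fixture convention, not a claim about the true atomic
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .params import CGParameters

__all__ = ["HelixSpec", "make_helix_template", "ToyDimer", "make_toy_dimer"]


@dataclass
class HelixSpec:
    """Regular helix through the anchor points."""

    rise: float = 4.5        # Å per residue along the helix axis
    twist: float = 174.0     # degrees per residue (~2-fold screw)
    radius: float = 1.1      # Å, anchor distance from the helix axis
    dp: int = 12

    def __post_init__(self):
        if self.rise <= 0:
            raise ParameterError(f"rise must be > 0, got {self.rise}")
        if self.dp < 2:
            raise ParameterError(f"dp must be >= 2, got {self.dp}")
        if self.radius < 0:
            raise ParameterError("radius must be >= 0")

    @property
    def anchor_spacing(self) -> float:
        """Closed-form chord length between consecutive anchors, Å."""
        half = np.radians(self.twist) / 2.0
        return float(np.sqrt(self.rise**2 + (2.0 * self.radius * np.sin(half)) ** 2))


def make_helix_template(spec: HelixSpec) -> np.ndarray:
    """(dp+1, 3) anchor coordinates of a regular helix.

    All virtual bonds have the same length (:attr:`HelixSpec.anchor_spacing`)
    and the internal coordinates are periodic with period one in the residue
    index.  twist=0, radius=0 degenerates to a straight chain with
    EED = dp·rise.
    """
    k = np.arange(spec.dp + 1)
    phi = np.radians(spec.twist) * k
    return np.column_stack(
        [spec.radius * np.cos(phi), spec.radius * np.sin(phi), spec.rise * k]
    ).astype(float)


@dataclass
class ToyDimer:
    """Two isolated interaction sites with explicit head/tail geometry.

    Oracle substrate for the pairwise energy terms; not a bonded chain, so
    the pair is evaluated directly by the term functions of
    :mod:`hepcg.energy`.
    """

    heads: np.ndarray        # (2, 3)
    tails: np.ndarray        # (2, 3)
    orientations: np.ndarray  # (2, 3) unit tail->head axes
    charges: np.ndarray      # (2,)


def make_toy_dimer(
    arrangement: str = "side_to_side",
    separation: float = 5.0,
    params: CGParameters | None = None,
    seed: int | None = None,
) -> ToyDimer:
    """Build a two-site system in a controlled mutual orientation.

    arrangement:
        ``"side_to_side"`` — parallel site axes, both perpendicular to the
        separation vector; ``"end_to_end"`` — both axes along the separation
        vector; ``"random"`` — reproducible random orientations from ``seed``.
    separation:
        Distance between the two site centers, Å.
    """
    params = params or CGParameters()
    sep = np.array([separation, 0.0, 0.0])
    if arrangement == "side_to_side":
        axes = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
    elif arrangement == "end_to_end":
        axes = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    elif arrangement == "random":
        rng = np.random.default_rng(0 if seed is None else seed)
        axes = rng.normal(size=(2, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    else:
        raise ParameterError(f"unknown arrangement {arrangement!r}")
    centers = np.array([[0.0, 0.0, 0.0], sep])
    heads = centers + params.head_offset * axes
    tails = centers + params.tail_offset * axes
    charges = params.site_charges(2)
    return ToyDimer(heads=heads, tails=tails, orientations=axes, charges=charges)
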