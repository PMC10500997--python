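"""Reduced heparin chain representation.

A chain of ``dp`` sugar residues is described by ``dp + 1`` glycosidic-oxygen
anchor points.  Each residue carries one interaction site located exactly
midway between its two flanking anchors; the site is split into a charged
"head" and an uncharged "tail", displaced from the site center along the
virtual-bond axis by the parameterized offsets.  The internal geometry is a
virtual-bond chain: bond lengths d_i, bond angles θ_i and dihedrals γ_i.

Angles are stored in degrees, θ ∈ (0°, 180°] (180° = collinear) and
γ ∈ (−180°, 180°] (180° = trans/extended).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidChainError, InvalidGeometryError, TopologyMismatchError
from .params import CGParameters

RESIDUE_TYPES = ("IdoA2S", "GlcNS6S")

#: Tolerance below which a bond-angle sine is treated as a degenerate
#: (collinear) triple when computing dihedrals.
_DEGENERATE_SIN = 1e-8


@dataclass
class HeparinChain:
    """Topology + geometry of one coarse-grained heparin chain."""

    dp: int
    anchors: np.ndarray      # (dp+1, 3) glycosidic-oxygen positions, Å
    sites: np.ndarray        # (dp, 3) geometric site centers, Å
    heads: np.ndarray        # (dp, 3) charged-center positions, Å
    tails: np.ndarray        # (dp, 3) uncharged-center positions, Å
    charges: np.ndarray      # (dp,) residue charges, e
    d: np.ndarray            # (dp,) virtual-bond lengths, Å
    theta: np.ndarray        # (dp-1,) virtual-bond angles, degrees
    gamma: np.ndarray        # (dp-2,) virtual-bond dihedrals, degrees
    residue_types: tuple = ()

    @property
    def orientations(self) -> np.ndarray:
        """Unit tail→head axis of every site (= virtual-bond direction)."""
        b = self.anchors[1:] - self.anchors[:-1]
        return b / np.linalg.norm(b, axis=1, keepdims=True)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def contour_length(self) -> float:
        """Sum of virtual-bond lengths, Å (upper bound on the EED)."""
        return float(self.d.sum())

    def with_anchors(self, anchors: np.ndarray, params: CGParameters) -> "HeparinChain":
        """New chain with the same residues at updated anchor positions."""
        return chain_from_anchors(anchors, params, charges=self.charges)


def build_chain(dp: int, params: CGParameters, template="extended") -> HeparinChain:
    """Build a heparin chain of ``dp`` residues.

    Parameters
    ----------
    dp:
        Degree of polymerization (number of monosaccharide residues), >= 2.
        Residues alternate IdoA2S / GlcNS6S with charges from
        ``params.charge_split`` (default −2 e each, −4 e per disaccharide).
    template:
        ``"extended"`` for a fully extended (collinear) start with anchor
        spacing ``params.bond_d0``, or an explicit ``(dp+1, 3)`` array of
        anchor coordinates (e.g. from :func:`hepcg.fixtures.make_helix_template`).
    """
    if dp < 2:
        raise InvalidChainError(f"dp must be >= 2, got {dp}")
    if isinstance(template, str):
        if template != "extended":
            raise InvalidChainError(f"unknown template {template!r}")
        anchors = np.zeros((dp + 1, 3))
        anchors[:, 0] = params.bond_d0 * np.arange(dp + 1)
    else:
        anchors = np.asarray(template, dtype=float)
        if anchors.shape != (dp + 1, 3):
            raise TopologyMismatchError(
                f"template must provide {dp + 1} anchors for dp={dp}, "
                f"got shape {anchors.shape}"
            )
    return chain_from_anchors(anchors, params)


def chain_from_anchors(
    anchors: np.ndarray, params: CGParameters, charges: np.ndarray | None = None
) -> HeparinChain:
    """Derive the full chain (sites, heads, tails, internal coordinates)
    from anchor coordinates."""
    anchors = np.ascontiguousarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 3 or anchors.shape[0] < 3:
        raise InvalidChainError(f"need (dp+1, 3) anchors with dp >= 2, got {anchors.shape}")
    dp = anchors.shape[0] - 1
    if charges is None:
        charges = params.site_charges(dp)
    sites = 0.5 * (anchors[:-1] + anchors[1:])
    heads, tails = _place_points(anchors, params.head_offset, params.tail_offset)
    d, theta, gamma = internal_coordinates_from_anchors(anchors)
    types = tuple(RESIDUE_TYPES[i % 2] for i in range(dp))
    return HeparinChain(
        dp=dp,
        anchors=anchors,
        sites=sites,
        heads=heads,
        tails=tails,
        charges=np.asarray(charges, dtype=float),
        d=d,
        theta=theta,
        gamma=gamma,
        residue_types=types,
    )


def _place_points(anchors: np.ndarray, head_offset: float, tail_offset: float):
    b = anchors[1:] - anchors[:-1]
    u = b / np.linalg.norm(b, axis=1, keepdims=True)
    mid = 0.5 * (anchors[:-1] + anchors[1:])
    return mid + head_offset * u, mid + tail_offset * u


def place_head_tail(chain: HeparinChain, params: CGParameters) -> HeparinChain:
    """Recompute head/tail positions from the current anchors and offsets.

    Zero offsets collapse head = tail = site center (isotropic mode).  The
    placement is a deterministic function of the local frame, so heads and
    tails co-rotate with any rigid-body transform of the anchors.
    """
    heads, tails = _place_points(chain.anchors, params.head_offset, params.tail_offset)
    return replace(chain, heads=heads, tails=tails)


# ----------------------------------------------------------------------
# internal coordinates
# ----------------------------------------------------------------------

def internal_coordinates(chain: HeparinChain):
    """Return (d, theta, gamma) of a chain; see module docstring for conventions."""
    return internal_coordinates_from_anchors(chain.anchors)


def internal_coordinates_from_anchors(anchors: np.ndarray):
    anchors = np.asarray(anchors, dtype=float)
    if anchors.shape[0] < 2:
        raise InvalidChainError("need at least 2 anchors")
    b = anchors[1:] - anchors[:-1]
    d = np.linalg.norm(b, axis=1)
    if np.any(d == 0):
        raise InvalidGeometryError("coincident consecutive anchors")

    n_b = b.shape[0]
    theta = np.empty(max(n_b - 1, 0))
    for i in range(n_b - 1):
        # angle at anchor i+1 between the back and forward bond vectors
        c = float(np.dot(-b[i], b[i + 1]) / (d[i] * d[i + 1]))
        theta[i] = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    gamma = np.empty(max(n_b - 2, 0))
    degenerate = False
    for i in range(n_b - 2):
        n1 = np.cross(b[i], b[i + 1])
        n2 = np.cross(b[i + 1], b[i + 2])
        m1 = np.linalg.norm(n1)
        m2 = np.linalg.norm(n2)
        if m1 < _DEGENERATE_SIN * d[i] * d[i + 1] or m2 < _DEGENERATE_SIN * d[i + 1] * d[i + 2]:
            # collinear triple: dihedral undefined; 180° is continuous with
            # the extended conformation
            gamma[i] = 180.0
            degenerate = True
            continue
        b2u = b[i + 1] / d[i + 1]
        ang = np.degrees(np.arctan2(float(np.dot(np.cross(n1, n2), b2u)),
                                    float(np.dot(n1, n2))))
        gamma[i] = 180.0 if ang <= -180.0 + 1e-12 else ang
    if degenerate:
        warnings.warn(
            "collinear anchor triple: dihedral undefined, set to 180° by convention",
            RuntimeWarning,
            stacklevel=2,
        )
    return d, theta, gamma


def rebuild_cartesian(d, theta, gamma, params: CGParameters | None = None) -> HeparinChain:
    """Rebuild anchor Cartesians from internal coordinates (NeRF chain growth).

    The first anchor is placed at the origin, the first bond along +x and the
    second bond in the xy half-plane with positive y.  Inverse of
    :func:`internal_coordinates` up to a rigid-body transform (exact in the
    chosen frame).

    Parameters
    ----------
    d, theta, gamma:
        Arrays of n bond lengths (Å), n−1 bond angles and n−2 dihedrals
        (degrees); θ must lie in (0°, 180°].
    params:
        Force-field parameters used to dress the rebuilt anchors with sites,
        heads, tails and charges (defaults to ``CGParameters()``).
    """
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    n = d.shape[0]
    if theta.shape[0] != max(n - 1, 0) or gamma.shape[0] != max(n - 2, 0):
        raise InvalidGeometryError(
            f"inconsistent array lengths: {n} bonds need {n - 1} angles and {n - 2} dihedrals"
        )
    if np.any(d <= 0):
        raise InvalidGeometryError("bond lengths must be > 0")
    if n and theta.size and (np.any(theta <= 0) or np.any(theta > 180)):
        raise InvalidGeometryError("bond angles must lie in (0°, 180°]")

    anchors = np.zeros((n + 1, 3))
    anchors[1] = (d[0], 0.0, 0.0)
    th = np.radians(theta)
    ga = np.radians(gamma)
    for k in range(2, n + 1):
        u = anchors[k - 1] - anchors[k - 2]
        u /= np.linalg.norm(u)
        if k == 2:
            normal = np.array([0.0, 1.0, 0.0])
            # bond angle θ between the back vector (−u) and the new bond
            v = -np.cos(th[0]) * u + np.sin(th[0]) * normal
        else:
            w = anchors[k - 2] - anchors[k - 3]
            nvec = np.cross(w, u)
            m = np.linalg.norm(nvec)
            if m < 1e-12:
                # previous triple collinear: pick any perpendicular reference
                nvec = np.cross(u, [1.0, 0.0, 0.0])
                if np.linalg.norm(nvec) < 1e-12:
                    nvec = np.cross(u, [0.0, 1.0, 0.0])
                m = np.linalg.norm(nvec)
            nvec /= m
            mvec = np.cross(nvec, u)
            t = th[k - 2]
            g = ga[k - 3]
            v = (
                -np.cos(t) * u
                + np.sin(t) * np.cos(g) * mvec
                + np.sin(t) * np.sin(g) * nvec
            )
        anchors[k] = anchors[k - 1] + d[k - 1] * v
    return chain_from_anchors(anchors, params or CGParameters())
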