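"""Force-field parameters for the one-site-per-residue heparin model.

Units are Å (length), kcal/mol (energy), elementary charges e, K (temperature)
and amu (mass) throughout the package.  ``kappa`` is the inverse Debye
screening length in Å⁻¹ that enters the ``exp(-kappa*r)`` factors of the
charge-sourced nonbonded terms; :mod:`hepcg.electrolyte` converts it to/from
ionic strength.

The numeric defaults below are a documented placeholder parameterization of
the IdoA2S–GlcNS6S repeat (the published tables they would normally come from
are not shipped); :meth:`CGParameters.from_file` loads user-supplied tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Electrostatic conversion constant, kcal·Å/(mol·e²).
C_ELEC = 332.063713

#: Boltzmann constant, kcal/(mol·K).
K_B = 0.0019872041

#: Canonical energy-term order used for weights, temperature factors and
#: per-term reports.
TERM_NAMES = (
    "bond",
    "angle",
    "torsion",
    "gberne",
    "polGB",
    "pol",
    "caviso",
    "cavtail",
    "vdw",
    "eel",
)

#: Default order n of the temperature factor f_n for each term.  n=1 makes
#: f_n ≡ 1 (athermal term); local bonded terms are athermal, mean-field
#: (solvent-averaged) terms carry n=2.
DEFAULT_FN_ORDERS = {
    "bond": 1,
    "angle": 1,
    "torsion": 2,
    "gberne": 1,
    "polGB": 2,
    "pol": 2,
    "caviso": 2,
    "cavtail": 2,
    "vdw": 1,
    "eel": 2,
}


@dataclass
class Weights:
    """Dimensionless multiplier for each effective-energy term."""

    w_bond: float = 1.0
    w_ang: float = 1.0
    w_tor: float = 1.0
    w_GBerne: float = 1.0
    w_polGB: float = 1.0
    w_pol: float = 1.0
    w_caviso: float = 1.0
    w_cavtail: float = 1.0
    w_vdw: float = 1.0
    w_eel: float = 1.0

    _FIELD_BY_TERM = {
        "bond": "w_bond",
        "angle": "w_ang",
        "torsion": "w_tor",
        "gberne": "w_GBerne",
        "polGB": "w_polGB",
        "pol": "w_pol",
        "caviso": "w_caviso",
        "cavtail": "w_cavtail",
        "vdw": "w_vdw",
        "eel": "w_eel",
    }

    def as_array(self) -> np.ndarray:
        """Weights as a vector in :data:`TERM_NAMES` order."""
        return np.array(
            [getattr(self, self._FIELD_BY_TERM[t]) for t in TERM_NAMES], dtype=float
        )

    def validate(self) -> None:
        for name in TERM_NAMES:
            w = getattr(self, self._FIELD_BY_TERM[name])
            if w < 0:
                raise ParameterError(f"weight for term {name!r} must be >= 0, got {w}")

    def replace(self, **kwargs) -> "Weights":
        return dataclasses.replace(self, **kwargs)


def temperature_factor(term: str, T: float, T0: float = 300.0, order: int | None = None) -> float:
    """Temperature factor f_n(T) multiplying an effective-energy term.

    f_n(T) = ln(e + 1/e) / ln(exp(x) + exp(-x)) with x = (T/T0)^(n-1), so
    f_n(T0) = 1 for every order n and f_1 ≡ 1.

    Parameters
    ----------
    term:
        One of :data:`TERM_NAMES` (used to look up the default order).
    T:
        Absolute temperature, K.
    T0:
        Reference temperature, K (default 300).
    order:
        Override the term's default cumulant order n.
    """
    if T <= 0:
        raise ParameterError(f"temperature must be > 0 K, got {T}")
    if term not in TERM_NAMES:
        raise ParameterError(f"unknown energy term {term!r}")
    n = DEFAULT_FN_ORDERS[term] if order is None else int(order)
    x = (T / T0) ** (n - 1)
    return math.log(math.e + 1.0 / math.e) / math.log(math.exp(x) + math.exp(-x))


@dataclass
class CGParameters:
    """Every numeric constant of the effective energy function.

    Geometry / topology
    -------------------
    head_offset, tail_offset : Å, signed displacement of the charged head and
        the uncharged tail from the site center along the virtual-bond axis.
        Setting both to 0 collapses head = tail = site ("collapsed" isotropic
        mode).
    charge_split : e, charges of the two residues of one disaccharide
        (IdoA2S, GlcNS6S); must sum to the net disaccharide charge (−4 e).
    site_mass : amu, mass assigned to each dynamical anchor point.
    """

    # --- bonded terms ---
    bond_k: float = 50.0           # kcal/mol/Å², U_bond = k (d - d0)²
    bond_d0: float = 5.0           # Å, equilibrium virtual-bond length
    angle_k: float = 20.0          # kcal/mol, U_b = k/2 (cosθ - cosθ0)²
    angle_theta0: float = 150.0    # degrees
    torsion_coeffs: tuple = (0.5, 0.0, 0.2)  # kcal/mol, Fourier c1..c3

    # --- tails: anisotropic (Gay–Berne) van der Waals ---
    sigma0_tail: float = 5.0       # Å, side-to-side zero-energy distance σ_ij^0
    eps_tail: float = 0.3          # kcal/mol, well depth ϵ_ij
    chi_gb_sigma: float = 0.25     # shape anisotropy of the contact distance
    chi_gb_eps: float = 0.15       # anisotropy of the well depth

    # --- heads: isotropic Lennard-Jones ---
    sigma_head: float = 4.0        # Å, σ_ij′
    eps_head: float = 0.2          # kcal/mol, ϵ_ij′

    # --- generalized Born solvation ---
    born_radii: tuple = (3.0, 3.0)  # Å, a_i per residue type (IdoA2S, GlcNS6S)
    eps_in: float = 2.0             # dielectric inside the particles
    eps_out: float = 80.0           # solvent dielectric

    # --- head–tail polarization ---
    alpha1: float = 1.5            # kcal·Å⁴/(mol·e²), solvation factor, tail i
    alpha2: float = 1.5            # kcal·Å⁴/(mol·e²), solvation factor, tail j

    # --- cavity terms ---
    sigma_iso: float = 2.0         # Å, σ_i^iso per charged head
    eps_cav_iso: float = 0.5       # kcal/mol, amplitude of the head cavity term
    sigma_cav_tail: float = 2.5    # Å, per-tail cavity radius
    eps_cav_tail: float = 0.5      # kcal/mol, amplitude of the tail cavity term
    chi_cav_1: float = 0.2         # χ_ij″^(1), cavity contact-distance anisotropy
    chi_cav_2: float = 0.2         # χ_ij″^(2), cavity orientational coupling

    # --- electrostatics / screening ---
    eel_dielectric: float | None = None  # dielectric of the eel term; None -> eps_in
    kappa: float = 0.0             # Å⁻¹, inverse Debye screening length
    screen_gb_pol: bool = True     # apply exp(-κr) screening to the GB polarization
    screen_pol: bool = True        # ... to the head–tail polarization
    screen_eel: bool = True        # ... to the Coulomb term

    # --- site placement / charges / mass ---
    head_offset: float = 1.0       # Å
    tail_offset: float = -1.0      # Å
    charge_split: tuple = (-2.0, -2.0)  # e per residue of a disaccharide
    site_mass: float = 288.0       # amu

    # --- thermodynamic state ---
    T: float = 300.0               # K
    T0: float = 300.0              # K, reference temperature of f_n
    weights: Weights = field(default_factory=Weights)
    fn_orders: dict = field(default_factory=lambda: dict(DEFAULT_FN_ORDERS))

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ParameterError` on any violated invariant."""
        positive = {
            "bond_k": self.bond_k,
            "bond_d0": self.bond_d0,
            "sigma0_tail": self.sigma0_tail,
            "eps_tail": self.eps_tail,
            "sigma_head": self.sigma_head,
            "eps_head": self.eps_head,
            "sigma_iso": self.sigma_iso,
            "sigma_cav_tail": self.sigma_cav_tail,
            "site_mass": self.site_mass,
            "T": self.T,
            "T0": self.T0,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value}")
        if any(a <= 0 for a in self.born_radii):
            raise ParameterError(f"Born radii must be > 0, got {self.born_radii}")
        if not (self.eps_out > self.eps_in > 0):
            raise ParameterError(
                f"need eps_out > eps_in > 0, got eps_out={self.eps_out}, eps_in={self.eps_in}"
            )
        if self.eel_dielectric is not None and self.eel_dielectric <= 0:
            raise ParameterError(f"eel_dielectric must be > 0, got {self.eel_dielectric}")
        if self.kappa < 0:
            raise ParameterError(f"kappa must be >= 0, got {self.kappa}")
        for chi in (self.chi_gb_sigma, self.chi_gb_eps, self.chi_cav_1, self.chi_cav_2):
            if not (0 <= chi < 1):
                raise ParameterError(f"anisotropies must lie in [0, 1), got {chi}")
        if not (0 <= self.angle_theta0 <= 180):
            raise ParameterError(f"angle_theta0 must be in [0, 180] deg, got {self.angle_theta0}")
        self.weights.validate()

    # ------------------------------------------------------------------
    @property
    def eel_eps(self) -> float:
        """Resolved dielectric constant of the Coulomb term."""
        return self.eps_in if self.eel_dielectric is None else self.eel_dielectric

    def fn_array(self, T: float | None = None) -> np.ndarray:
        """Temperature factors f_n for all terms in :data:`TERM_NAMES` order."""
        T = self.T if T is None else T
        return np.array(
            [
                temperature_factor(t, T, self.T0, self.fn_orders.get(t))
                for t in TERM_NAMES
            ]
        )

    def site_charges(self, dp: int) -> np.ndarray:
        """Per-residue charges (e) for a dp-residue chain, alternating types."""
        q = np.empty(dp)
        q[0::2] = self.charge_split[0]
        q[1::2] = self.charge_split[1]
        return q

    def site_born_radii(self, dp: int) -> np.ndarray:
        a = np.empty(dp)
        a[0::2] = self.born_radii[0]
        a[1::2] = self.born_radii[1]
        return a

    def kernel_vector(self) -> np.ndarray:
        """Scalar parameters packed for the compiled energy kernel."""
        return np.array(
            [
                self.bond_k,
                self.bond_d0,
                self.angle_k,
                math.cos(math.radians(self.angle_theta0)),
                self.torsion_coeffs[0],
                self.torsion_coeffs[1] if len(self.torsion_coeffs) > 1 else 0.0,
                self.torsion_coeffs[2] if len(self.torsion_coeffs) > 2 else 0.0,
                self.sigma0_tail,
                self.eps_tail,
                self.chi_gb_sigma,
                self.chi_gb_eps,
                self.sigma_head,
                self.eps_head,
                self.eps_in,
                self.eps_out,
                self.alpha1,
                self.alpha2,
                self.eps_cav_iso,
                self.sigma_iso,
                self.eps_cav_tail,
                self.sigma_cav_tail,
                self.chi_cav_1,
                self.chi_cav_2,
                self.eel_eps,
                self.kappa,
                self.head_offset,
                self.tail_offset,
                1.0 if self.screen_gb_pol else 0.0,
                1.0 if self.screen_pol else 0.0,
                1.0 if self.screen_eel else 0.0,
            ],
            dtype=np.float64,
        )

    def replace(self, **kwargs) -> "CGParameters":
        """Return a copy with the given fields replaced (weights may be a dict)."""
        w = kwargs.pop("weights", None)
        new = dataclasses.replace(self, **kwargs)
        if w is not None:
            new.weights = w if isinstance(w, Weights) else Weights(**w)
            new.validate()
        return new

    def param_hash(self) -> str:
        """Short stable hash of all parameters, for run logs."""
        payload = repr(sorted(self.to_dict().items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "weights":
                v = dataclasses.asdict(v)
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    def to_file(self, path) -> None:
        """Write a flat ``key = value`` parameter file (documented schema).

        Units: Å, kcal/mol, e, K, amu; sequences comma-separated; weights and
        fn orders are flattened as ``weights.w_eel`` / ``fn_orders.eel`` keys.
        """
        lines = ["# hepcg parameter file (Å / kcal/mol / e / K / amu)"]
        for key, value in self.to_dict().items():
            if isinstance(value, dict):
                for k2, v2 in value.items():
                    lines.append(f"{key}.{k2} = {v2}")
            elif isinstance(value, list):
                lines.append(f"{key} = " + ", ".join(str(x) for x in value))
            else:
                lines.append(f"{key} = {value}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "CGParameters":
        """Load a parameter file written by :meth:`to_file` (missing keys keep defaults)."""
        scalars: dict = {}
        weights: dict = {}
        fn_orders: dict = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParameterError(f"malformed parameter line: {raw!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                if key.startswith("weights."):
                    weights[key.split(".", 1)[1]] = float(value)
                elif key.startswith("fn_orders."):
                    fn_orders[key.split(".", 1)[1]] = int(value)
                else:
                    scalars[key] = _parse_value(value)
        for tup_key in ("torsion_coeffs", "born_radii", "charge_split"):
            if tup_key in scalars and not isinstance(scalars[tup_key], tuple):
                scalars[tup_key] = (scalars[tup_key],)
        params = cls(**scalars)
        if weights:
            params.weights = Weights(**{**dataclasses.asdict(params.weights), **weights})
        if fn_orders:
            params.fn_orders.update(fn_orders)
        params.validate()
        return params


def _parse_value(text: str):
    if "," in text:
        return tuple(_parse_value(t.strip()) for t in text.split(","))
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low == "none":
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text
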