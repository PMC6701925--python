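"""Parameter containers for the MukBEF/ori positioning model.

Three groups of parameters are used throughout the package:

* :class:`TuringParams` — kinetics and diffusion of the three MukBEF species
  (u: mobile DNA-associated, v: slow clustered, w: well-mixed cytosolic) on a
  1-D compartment lattice along the long cell axis.
* :class:`OriParams` — the *ori* particle: its diffusion on a finer
  sub-compartment lattice, the strength of its drift up the v-gradient,
  preferential MukBEF loading at *ori*, entropic sister repulsion and the
  length-triggered duplication rule.
* :class:`GrowthParams` — exponential cell growth from birth to division
  length by stochastic compartment insertion.

Defaults correspond to slow-growing *E. coli* (2.5 µm birth length,
120 min doubling time, 520 nM total MukBEF).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
import math

#: Avogadro constant, mol^-1.
N_A = 6.02214076e23

#: Thermal energy at 30 C, J (used to express restoring forces in pN).
KT_30C = 4.19e-21

LOG2 = math.log(2.0)


class InvalidParameterError(ValueError):
    """A parameter value violates its documented constraint."""


@dataclass(frozen=True)
class TuringParams:
    """Kinetic constants of the three-species MukBEF reaction-diffusion model.

    Rates describe, per molecule: basal (``alpha``) and cooperative
    (``beta``) conversion of the mobile DNA-bound state u into the slow
    clustered state v, the reverse conversion (``gamma``), unbinding of u
    into the cytosol (``delta``) and rebinding from the cytosol
    (``epsilon``).  ``beta`` is a deterministic mass-action constant in
    nM^-2 s^-1; it is rescaled to per-molecule units by the compartment
    volume at simulation time (see :func:`oriseg.model_core.build_propensities`).
    """

    alpha: float = 0.5            # s^-1, basal u -> v
    beta: float = 1.5e-4          # nM^-2 s^-1, cooperative u + 2v -> 3v
    gamma: float = 3.6            # s^-1, v -> u
    delta: float = LOG2 / 50.0    # s^-1, u -> w (cytosol)
    epsilon: float = 3.0 * LOG2 / 50.0  # s^-1, w -> u (loading)
    D_u: float = 0.3              # um^2 s^-1
    D_v: float = 0.012            # um^2 s^-1
    h: float = 0.1                # um, compartment width
    C: float = 520.0              # nM, total MukBEF concentration
    V_birth: float = 1.25e-15     # L, cell volume at birth length
    L_birth: float = 2.5          # um, birth length
    #: whether the slow clustered state also unbinds directly to the cytosol
    #: (v -> w at rate delta) in addition to u -> w.  Both DNA-associated
    #: states exchanging with the cytosol is required for flux-balance
    #: positioning: with u -> w only, the nucleoid-bound pool equilibrates
    #: through u and the self-organised v cluster receives no net
    #: length-proportional flux, leaving it pinned near a pole instead of
    #: mid-cell.
    v_to_w: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "epsilon",
                     "D_u", "D_v", "h", "C", "V_birth", "L_birth"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.D_u < self.D_v:
            raise InvalidParameterError(
                "D_u must not be smaller than D_v (differential diffusion)")

    def volume_at_length(self, L: float) -> float:
        """Cell volume in litres; scales linearly with cell length."""
        return self.V_birth * L / self.L_birth

    def n_comp_at_length(self, L: float) -> int:
        n = L / self.h
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError("cell length must be a multiple of h")
        return int(round(n))

    def c1(self, V: float, n_comp: int) -> float:
        """Concentration (nM) of a single molecule in one compartment."""
        return 1e9 / (N_A * (V / n_comp))

    def beta_hat(self, V: float, n_comp: int) -> float:
        """Per-molecule cooperative rate: beta rescaled by compartment volume."""
        return self.beta * self.c1(V, n_comp) ** 2

    def replace(self, **kw) -> "TuringParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OriParams:
    """Parameters of the *ori* particle and its coupling to MukBEF.

    ``mu`` sets the strength of the drift up the gradient of the clustered
    species v; ``loading_ratio`` elevates the w -> u loading rate in
    compartments containing an *ori* (total loading rate unchanged);
    ``k_rep``/``sigma_rep`` parameterise the Gaussian-potential entropic
    repulsion between sister *ori*s; duplication is triggered at a cell
    length drawn from a truncated normal distribution.

    The defaults are the fixed-length-cell fit (D_ori = 5.4e-5 um^2/s,
    mu = 0.026 um); :data:`ORI_GROWTH` holds the growing-cell fit obtained
    with 6x preferential loading (D_ori = 5.1e-5, mu = 0.052).
    """

    D_ori: float = 5.4e-5         # um^2 s^-1
    mu: float = 0.026             # um, drift strength
    n_sub: int = 21               # odd; sub-compartments per compartment
    loading_ratio: float = 1.0    # >= 1; 1 disables preferential loading
    k_rep: float = 0.0            # s^-1, sister repulsion strength (0 = off)
    sigma_rep: float = 0.2        # um, repulsion range
    dup_mean_length: float = 3.0  # um, mean duplication length
    dup_cv: float = 0.16          # coefficient of variation
    dup_range: tuple = (2.5, 5.0)  # um, truncation range

    def __post_init__(self) -> None:
        if self.n_sub < 1 or self.n_sub % 2 == 0:
            raise InvalidParameterError("n_sub must be odd and >= 1")
        if self.D_ori <= 0:
            raise InvalidParameterError("D_ori must be positive")
        for name in ("mu", "k_rep", "sigma_rep", "dup_mean_length", "dup_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.loading_ratio < 1:
            raise InvalidParameterError("loading_ratio must be >= 1")

    @property
    def dup_sd_length(self) -> float:
        return self.dup_mean_length * self.dup_cv

    def h_sub(self, h: float) -> float:
        """Sub-compartment width in um."""
        return h / self.n_sub

    def replace(self, **kw) -> "OriParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dup_range"] = list(self.dup_range)
        return d


#: Growing-cell ori parameters (fit with 6x preferential loading).
ORI_GROWTH = OriParams(D_ori=5.1e-5, mu=0.052)


@dataclass(frozen=True)
class GrowthParams:
    """Exponential growth from birth to division length.

    The cell grows exponentially with doubling time ``T_double`` (minutes);
    geometrically this is realised by inserting one empty compartment of
    width ``h`` at a uniformly random position whenever the length has grown
    by ``h`` (see :mod:`oriseg.cell_growth`).
    """

    L_birth: float = 2.5   # um
    L_div: float = 5.0     # um
    T_double: float = 120.0  # min
    h: float = 0.1         # um

    def __post_init__(self) -> None:
        if self.T_double <= 0:
            raise InvalidParameterError("T_double must be positive")
        if self.L_div <= self.L_birth:
            raise InvalidParameterError("L_div must exceed L_birth")
        n = (self.L_div - self.L_birth) / self.h
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                "L_div - L_birth must be an integer multiple of h")

    @property
    def n_insertions(self) -> int:
        return int(round((self.L_div - self.L_birth) / self.h))

    def length_to_time(self, L: float) -> float:
        """Time (min since birth) at which the cell reaches length L."""
        return self.T_double * math.log2(L / self.L_birth)

    def replace(self, **kw) -> "GrowthParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)
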