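"""Mass-conserved activator-substrate (MCAS) polarity models.

Four reaction-diffusion models of Rho-GTPase polarity circuits:

* ``minimal`` -- two species: a slow membrane activator ``u`` (GTP-bound
  GTPase) and a fast cytosolic substrate ``v`` (GDP-bound GTPase), coupled
  by an autocatalytic activation term ``a u^2 v`` and first-order
  inactivation ``b u``.  Total protein ``u + v`` is conserved.
* ``indirect`` -- the minimal model plus an indirect substrate ``v_i``:
  ``u`` converts to ``v_i`` (rate ``c``) which converts back to ``v``
  (rate ``d``).  The indirect route is what permits equalization of
  unequal peaks when ``v_i`` is mobile.
* ``mechanistic`` -- six-species model of the budding-yeast circuit
  (Cdc42 in GTP/GDP membrane/cytosol forms plus a scaffold-GEF complex
  "BemGEF" that binds GTP-Cdc42 to close the positive feedback loop).
* ``mechanistic_nfb`` -- nine-species extension with negative feedback
  via ultrasensitive multi-site phosphorylation of the GEF (phosphorylated
  species carry a ``_p`` suffix; only unphosphorylated complexes act as
  GEFs, but both act as kinases).

All reaction kinetics conserve mass within each conservation group: the
weighted sum of reaction rates is zero at every state (weights are 1 for
membrane species and ``1/eta`` for cytosolic species in the mechanistic
models, where ``eta`` is the membrane-to-cytoplasm volume ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpeciesSpec",
    "ModelSpec",
    "HomogeneousState",
    "ModelValidationError",
    "make_minimal_model",
    "make_indirect_model",
    "make_mechanistic_model",
    "make_model",
    "homogeneous_steady_state",
    "linear_growth_rate",
    "linear_stability_eigenvalues",
]


class ModelValidationError(ValueError):
    """Raised for invalid model parameters or malformed states."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species: its compartment and diffusivity.

    ``diffusivity`` is dimensionless for the minimal/indirect models and
    in um^2/s for the mechanistic models.
    """

    name: str
    compartment: str  # "membrane" | "cytoplasm"
    diffusivity: float

    def __post_init__(self) -> None:
        if self.compartment not in ("membrane", "cytoplasm"):
            raise ModelValidationError(
                f"unknown compartment {self.compartment!r} for species {self.name}"
            )
        if self.diffusivity < 0:
            raise ModelValidationError(f"negative diffusivity for species {self.name}")


@dataclass(frozen=True)
class ModelSpec:
    """A named reaction-diffusion model.

    ``reaction`` maps a concentration array of shape ``(n_species, ...)``
    to per-species reaction rates of the same shape (pure function, no
    spatial coupling).  ``conservation_groups`` lists, per conserved pool,
    ``(group_name, ((species_name, weight), ...))``.
    """

    name: str
    species: tuple[SpeciesSpec, ...]
    parameters: dict[str, float]
    reaction: Callable[[np.ndarray], np.ndarray]
    conservation_groups: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    derived_sums: dict[str, tuple[str, ...]] = field(default_factory=dict)
    # analytic reaction Jacobian: (n_species, ...) -> (n_species, n_species, ...)
    # with J[i, j] = dR_i/dc_j; used by the implicit reaction solver
    jacobian: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([s.diffusivity for s in self.species])

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"model {self.name!r} has no species {name!r}") from None

    def group_weights(self, group_name: str) -> np.ndarray:
        """Weight vector over all species for one conservation group."""
        for gname, members in self.conservation_groups:
            if gname == group_name:
                w = np.zeros(self.n_species)
                for sp, weight in members:
                    w[self.index(sp)] = weight
                return w
        raise KeyError(f"model {self.name!r} has no conservation group {group_name!r}")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.conservation_groups)

    def validate(self) -> None:
        # complexes (e.g. GTPase-GEF) legitimately count toward several pools,
        # so only coverage is enforced here
        seen: set[str] = set()
        for _gname, members in self.conservation_groups:
            seen.update(sp for sp, _ in members)
        missing = set(self.species_names) - seen
        if missing:
            raise ModelValidationError(f"species outside any conservation group: {missing}")
        dm = [s.diffusivity for s in self.species if s.compartment == "membrane"]
        dc = [s.diffusivity for s in self.species if s.compartment == "cytoplasm"]
        if dm and dc and max(dm) >= min(dc):
            raise ModelValidationError(
                "membrane diffusivity must be below cytoplasmic diffusivity"
            )


@dataclass(frozen=True)
class HomogeneousState:
    """A spatially uniform steady state: per-species concentrations."""

    concentrations: dict[str, float]

    def as_array(self, model: ModelSpec) -> np.ndarray:
        return np.array([self.concentrations[s] for s in model.species_names])


def _require_positive(**params: float) -> None:
    for name, value in params.items():
        if not np.isfinite(value) or value <= 0:
            raise ModelValidationError(f"parameter {name} must be positive, got {value}")


# ---------------------------------------------------------------------------
# minimal model: du/dt = a u^2 v - b u,  dv/dt = -a u^2 v + b u


def make_minimal_model(a: float = 1.0, b: float = 1.0,
                       Dm: float = 0.01, Dc: float = 1.0) -> ModelSpec:
    """Two-species MCAS model (dimensionless units)."""
    _require_positive(a=a, b=b, Dm=Dm, Dc=Dc)

    def reaction(c: np.ndarray) -> np.ndarray:
        u, v = c[0], c[1]
        f = a * u * u * v - b * u
        return np.stack([f, -f])

    def jacobian(c: np.ndarray) -> np.ndarray:
        u, v = c[0], c[1]
        fu = 2 * a * u * v - b
        fv = a * u * u
        return np.stack([np.stack([fu, fv]), np.stack([-fu, -fv])])

    return ModelSpec(
        name="minimal",
        species=(
            SpeciesSpec("u", "membrane", Dm),
            SpeciesSpec("v", "cytoplasm", Dc),
        ),
        parameters={"a": a, "b": b, "Dm": Dm, "Dc": Dc},
        reaction=reaction,
        conservation_groups=(("total", (("u", 1.0), ("v", 1.0))),),
        jacobian=jacobian,
    )


# ---------------------------------------------------------------------------
# indirect-substrate model: u -> v_i (rate c), v_i -> v (rate d)


def make_indirect_model(a: float = 1.0, b: float = 1.0, c: float = 0.01,
                        d: float = 1.0, Dm: float = 0.01, Dc: float = 1.0,
                        Dvi: float = 1.0) -> ModelSpec:
    """Three-species MCAS model with an indirect substrate ``v_i``."""
    _require_positive(a=a, b=b, c=c, d=d, Dm=Dm, Dc=Dc, Dvi=Dvi)

    def reaction(conc: np.ndarray) -> np.ndarray:
        u, v, vi = conc[0], conc[1], conc[2]
        auv = a * u * u * v
        du = auv - b * u - c * u
        dvi = c * u - d * vi
        dv = -auv + b * u + d * vi
        return np.stack([du, dv, dvi])

    def jacobian(conc: np.ndarray) -> np.ndarray:
        u, v = conc[0], conc[1]
        z = np.zeros_like(u)
        g_u = 2 * a * u * v  # d(a u^2 v)/du
        g_v = a * u * u
        return np.stack([
            np.stack([g_u - b - c, g_v, z]),
            np.stack([-g_u + b, -g_v, z + d]),
            np.stack([z + c, z, z - d]),
        ])

    return ModelSpec(
        name="indirect",
        species=(
            SpeciesSpec("u", "membrane", Dm),
            SpeciesSpec("v", "cytoplasm", Dc),
            SpeciesSpec("v_i", "cytoplasm", Dvi),
        ),
        parameters={"a": a, "b": b, "c": c, "d": d, "Dm": Dm, "Dc": Dc, "Dvi": Dvi},
        reaction=reaction,
        conservation_groups=(("total", (("u", 1.0), ("v", 1.0), ("v_i", 1.0))),),
        jacobian=jacobian,
    )


# ---------------------------------------------------------------------------
# mechanistic yeast-circuit models

MECHANISTIC_DEFAULTS: dict[str, float] = {
    "k1a": 10.0,   # 1/s   BemGEF_c -> BemGEF_m
    "k1b": 10.0,   # 1/s   BemGEF_m -> BemGEF_c
    "k2a": 0.16,   # 1/(uM s)  GEF-catalysed Cdc42 activation
    "k2b": 1.75,   # 1/s   GAP-mediated Cdc42 inactivation
    "k3": 0.35,    # 1/(uM s)  BemGEF42-catalysed activation
    "k4a": 10.0,   # 1/(uM s)  BemGEF_m + Cdc42T -> BemGEF42
    "k4b": 10.0,   # 1/s   BemGEF42 dissociation
    "k5a": 36.0,   # 1/s   Cdc42D_c -> Cdc42D_m
    "k5b": 0.65,   # 1/s   Cdc42D_m -> Cdc42D_c
    "k7": 10.0,    # 1/(uM s)  BemGEF_c + Cdc42T -> BemGEF42
    "Dm": 0.0025,  # um^2/s membrane diffusion
    "Dc": 10.0,    # um^2/s cytoplasmic diffusion
    "eta": 0.01,   # membrane/cytoplasm volume ratio
}

NFB_EXTRA_DEFAULTS: dict[str, float] = {
    "k2b": 0.35,      # slower GAP activity in the negative-feedback variant
    "k8max": 0.0063,  # 1/(uM s)  max phosphorylation rate
    "k8n": 6.0,
    "k8h": 10.0,      # uM
    "k9max": 0.0044,  # 1/s  max dephosphorylation rate
    "k9n": 6.0,
    "k9h": 0.003,     # uM
}

# species orderings (membrane species first, then cytoplasmic)
MECH_SPECIES = ("Cdc42T", "Cdc42Dm", "BemGEF42", "BemGEFm", "Cdc42Dc", "BemGEFc")
MECH_NFB_SPECIES = (
    "Cdc42T", "Cdc42Dm", "BemGEF42", "BemGEFm", "BemGEFm_p", "BemGEF42_p",
    "Cdc42Dc", "BemGEFc", "BemGEFc_p",
)


def hill(x: np.ndarray, vmax: float, n: float, h: float) -> np.ndarray:
    """Saturating Hill function ``vmax x^n / (h^n + x^n)``.

    Monotone nondecreasing in ``x`` and bounded by ``vmax``.
    """
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = x ** n
    return vmax * xn / (h ** n + xn)


def hill_derivative(x: np.ndarray, vmax: float, n: float, h: float) -> np.ndarray:
    """d/dx of :func:`hill`."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = x ** n
    hn = h ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vmax * n * hn * np.where(x > 0, xn / x, 0.0) / (hn + xn) ** 2
    return out


def make_mechanistic_model(
    params: dict[str, float] | None = None,
    negative_feedback: bool = False,
    k8_argument: str = "BemGEF42_t",
    k9_argument: str = "BemGEFm_p",
) -> ModelSpec:
    """Mechanistic yeast polarity model, with or without GEF phosphorylation.

    The phosphorylation (``k8``) and dephosphorylation (``k9``) rates are
    ultrasensitive Hill functions.  Their arguments are configurable:
    ``k8_argument`` in {"BemGEF42_t", "BemGEFm_t"} (default: the total
    membrane-bound GTPase-GEF complex, consistent with phosphorylation
    requiring both kinase and target complexes bound to GTP-Cdc42) and
    ``k9_argument`` in {"BemGEFm_p", "BemGEFc_p"} (default: the
    phosphorylated membrane GEF pool, whose scale matches the half-maximal
    constant k9h; the cytosolic phosphorylated pool sits orders of
    magnitude below k9h, which would silence dephosphorylation entirely).
    """
    table = dict(MECHANISTIC_DEFAULTS)
    if negative_feedback:
        table.update(NFB_EXTRA_DEFAULTS)
    if params:
        unknown = set(params) - set(table)
        if unknown:
            raise ModelValidationError(f"unknown mechanistic parameters: {sorted(unknown)}")
        table.update(params)
    if negative_feedback:
        missing = [k for k in NFB_EXTRA_DEFAULTS if k not in table]
        if missing:
            raise ModelValidationError(f"negative feedback requires parameters {missing}")
    if not (0 < table["eta"] <= 1):
        raise ModelValidationError("eta must be in (0, 1]")
    for k, v in table.items():
        if k != "eta" and v < 0:
            raise ModelValidationError(f"rate constant {k} must be >= 0")
    if k8_argument not in ("BemGEF42_t", "BemGEFm_t"):
        raise ModelValidationError(f"unsupported k8 argument {k8_argument!r}")
    if k9_argument not in ("BemGEFm_p", "BemGEFc_p"):
        raise ModelValidationError(f"unsupported k9 argument {k9_argument!r}")

    p = table
    eta = p["eta"]

    if not negative_feedback:

        def reaction(c: np.ndarray) -> np.ndarray:
            T, Dm42, B42, Bm, Dc42, Bc = c
            act = (p["k2a"] * Bm + p["k3"] * B42) * Dm42
            dT = act - (p["k2b"] + p["k4a"] * Bm + p["k7"] * Bc) * T + p["k4b"] * B42
            dDm42 = p["k2b"] * T - act - p["k5b"] * Dm42 + p["k5a"] * Dc42
            dB42 = (p["k4a"] * Bm + p["k7"] * Bc) * T - p["k4b"] * B42
            dBm = p["k1a"] * Bc - p["k1b"] * Bm + p["k4b"] * B42 - p["k4a"] * Bm * T
            dDc42 = eta * (p["k5b"] * Dm42 - p["k5a"] * Dc42)
            dBc = eta * (p["k1b"] * Bm - p["k1a"] * Bc - p["k7"] * Bc * T)
            out = np.empty_like(c)
            out[0], out[1], out[2] = dT, dDm42, dB42
            out[3], out[4], out[5] = dBm, dDc42, dBc
            return out

        def jacobian(c: np.ndarray) -> np.ndarray:
            T, Dm42, B42, Bm, Dc42, Bc = c
            k2a, k2b, k3 = p["k2a"], p["k2b"], p["k3"]
            k4a, k4b, k7 = p["k4a"], p["k4b"], p["k7"]
            k1a, k1b, k5a, k5b = p["k1a"], p["k1b"], p["k5a"], p["k5b"]
            gef = k2a * Bm + k3 * B42          # GEF activity on Cdc42Dm
            bind = k4a * Bm + k7 * Bc          # BemGEF binding to Cdc42T
            J = np.zeros((6, 6) + np.shape(T))
            J[0, 0] = -(k2b + bind); J[0, 1] = gef
            J[0, 2] = k3 * Dm42 + k4b; J[0, 3] = k2a * Dm42 - k4a * T
            J[0, 5] = -k7 * T
            J[1, 0] = k2b; J[1, 1] = -gef - k5b
            J[1, 2] = -k3 * Dm42; J[1, 3] = -k2a * Dm42; J[1, 4] = k5a
            J[2, 0] = bind; J[2, 2] = -k4b; J[2, 3] = k4a * T; J[2, 5] = k7 * T
            J[3, 0] = -k4a * Bm; J[3, 2] = k4b
            J[3, 3] = -k1b - k4a * T; J[3, 5] = k1a
            J[4, 1] = eta * k5b; J[4, 4] = -eta * k5a
            J[5, 0] = -eta * k7 * Bc; J[5, 3] = eta * k1b
            J[5, 5] = -eta * (k1a + k7 * T)
            return J

        species = (
            SpeciesSpec("Cdc42T", "membrane", p["Dm"]),
            SpeciesSpec("Cdc42Dm", "membrane", p["Dm"]),
            SpeciesSpec("BemGEF42", "membrane", p["Dm"]),
            SpeciesSpec("BemGEFm", "membrane", p["Dm"]),
            SpeciesSpec("Cdc42Dc", "cytoplasm", p["Dc"]),
            SpeciesSpec("BemGEFc", "cytoplasm", p["Dc"]),
        )
        groups = (
            ("Cdc42", (("Cdc42T", 1.0), ("Cdc42Dm", 1.0), ("BemGEF42", 1.0),
                       ("Cdc42Dc", 1.0 / eta))),
            ("BemGEF", (("BemGEF42", 1.0), ("BemGEFm", 1.0), ("BemGEFc", 1.0 / eta))),
        )
        return ModelSpec(
            name="mechanistic",
            species=species,
            parameters=dict(p),
            reaction=reaction,
            conservation_groups=groups,
            derived_sums={},
            jacobian=jacobian,
        )

    def reaction_nfb(c: np.ndarray) -> np.ndarray:
        T, Dm42, B42, Bm, Bm_p, B42_p, Dc42, Bc, Bc_p = c
        Bmt = Bm + Bm_p
        Bct = Bc + Bc_p
        B42t = B42 + B42_p
        k8 = hill(B42t if k8_argument == "BemGEF42_t" else Bmt,
                  p["k8max"], p["k8n"], p["k8h"])
        k9 = hill(Bc_p if k9_argument == "BemGEFc_p" else Bm_p,
                  p["k9max"], p["k9n"], p["k9h"])
        act = (p["k2a"] * Bm + p["k3"] * B42) * Dm42
        phos = k8 * B42t * B42  # kinases: all membrane complexes; targets: unphos.
        dT = act - (p["k2b"] + p["k4a"] * Bmt + p["k7"] * Bct) * T + p["k4b"] * B42t
        dDm42 = p["k2b"] * T - act - p["k5b"] * Dm42 + p["k5a"] * Dc42
        dB42 = (p["k4a"] * Bm + p["k7"] * Bc) * T - p["k4b"] * B42 - phos
        dBm = p["k1a"] * Bc - p["k1b"] * Bm + p["k4b"] * B42 - p["k4a"] * Bm * T
        dDc42 = eta * (p["k5b"] * Dm42 - p["k5a"] * Dc42)
        dBc = eta * (p["k1b"] * Bm - p["k1a"] * Bc - p["k7"] * Bc * T) + k9 * Bc_p
        dBm_p = (p["k1a"] * Bc_p - p["k1b"] * Bm_p + p["k4b"] * B42_p
                 - p["k4a"] * Bm_p * T)
        dBc_p = eta * (p["k1b"] * Bm_p - p["k1a"] * Bc_p - p["k7"] * Bc_p * T) - k9 * Bc_p
        dB42_p = (p["k4a"] * Bm_p + p["k7"] * Bc_p) * T - p["k4b"] * B42_p + phos
        out = np.empty_like(c)
        out[0], out[1], out[2] = dT, dDm42, dB42
        out[3], out[4], out[5] = dBm, dBm_p, dB42_p
        out[6], out[7], out[8] = dDc42, dBc, dBc_p
        return out

    def jacobian_nfb(c: np.ndarray) -> np.ndarray:
        T, Dm42, B42, Bm, Bm_p, B42_p, Dc42, Bc, Bc_p = c
        z = np.zeros(np.shape(T))
        k2a, k2b, k3 = p["k2a"], p["k2b"], p["k3"]
        k4a, k4b, k7 = p["k4a"], p["k4b"], p["k7"]
        k1a, k1b, k5a, k5b = p["k1a"], p["k1b"], p["k5a"], p["k5b"]
        Bmt = Bm + Bm_p
        Bct = Bc + Bc_p
        B42t = B42 + B42_p
        A8 = B42t if k8_argument == "BemGEF42_t" else Bmt
        k8 = hill(A8, p["k8max"], p["k8n"], p["k8h"])
        dk8 = hill_derivative(A8, p["k8max"], p["k8n"], p["k8h"])
        Y9 = Bc_p if k9_argument == "BemGEFc_p" else Bm_p
        k9 = hill(Y9, p["k9max"], p["k9n"], p["k9h"])
        dk9 = hill_derivative(Y9, p["k9max"], p["k9n"], p["k9h"])
        # phos = k8(A8) * B42t * B42 partials
        a8_is_b42t = k8_argument == "BemGEF42_t"
        P_B42 = (dk8 * B42t * B42 if a8_is_b42t else z) + k8 * (B42 + B42t)
        P_B42p = (dk8 * B42t * B42 if a8_is_b42t else z) + k8 * B42
        P_Bm = z if a8_is_b42t else dk8 * B42t * B42
        # q = k9(Y9) * Bc_p partials
        y_is_bcp = k9_argument == "BemGEFc_p"
        q_Bcp = k9 + (dk9 * Bc_p if y_is_bcp else z)
        q_Bmp = z if y_is_bcp else dk9 * Bc_p  # via Y9 = Bm_p only
        gef = k2a * Bm + k3 * B42
        J = np.zeros((9, 9) + np.shape(T))
        J[0, 0] = -(k2b + k4a * Bmt + k7 * Bct); J[0, 1] = gef
        J[0, 2] = k3 * Dm42 + k4b; J[0, 3] = k2a * Dm42 - k4a * T
        J[0, 4] = -k4a * T; J[0, 5] = k4b; J[0, 7] = -k7 * T; J[0, 8] = -k7 * T
        J[1, 0] = k2b; J[1, 1] = -gef - k5b
        J[1, 2] = -k3 * Dm42; J[1, 3] = -k2a * Dm42; J[1, 6] = k5a
        J[2, 0] = k4a * Bm + k7 * Bc; J[2, 2] = -k4b - P_B42
        J[2, 3] = k4a * T - P_Bm; J[2, 4] = -P_Bm
        J[2, 5] = -P_B42p; J[2, 7] = k7 * T
        J[3, 0] = -k4a * Bm; J[3, 2] = k4b
        J[3, 3] = -k1b - k4a * T; J[3, 7] = k1a
        J[4, 0] = -k4a * Bm_p; J[4, 4] = -k1b - k4a * T
        J[4, 5] = k4b; J[4, 8] = k1a
        J[5, 0] = k4a * Bm_p + k7 * Bc_p; J[5, 2] = P_B42; J[5, 3] = P_Bm
        J[5, 4] = k4a * T + P_Bm; J[5, 5] = -k4b + P_B42p; J[5, 8] = k7 * T
        J[6, 1] = eta * k5b; J[6, 6] = -eta * k5a
        J[7, 0] = -eta * k7 * Bc; J[7, 3] = eta * k1b; J[7, 4] = q_Bmp
        J[7, 7] = -eta * (k1a + k7 * T); J[7, 8] = q_Bcp
        J[8, 0] = -eta * k7 * Bc_p
        J[8, 4] = eta * k1b - q_Bmp
        J[8, 8] = -eta * (k1a + k7 * T) - q_Bcp
        return J

    species = (
        SpeciesSpec("Cdc42T", "membrane", p["Dm"]),
        SpeciesSpec("Cdc42Dm", "membrane", p["Dm"]),
        SpeciesSpec("BemGEF42", "membrane", p["Dm"]),
        SpeciesSpec("BemGEFm", "membrane", p["Dm"]),
        SpeciesSpec("BemGEFm_p", "membrane", p["Dm"]),
        SpeciesSpec("BemGEF42_p", "membrane", p["Dm"]),
        SpeciesSpec("Cdc42Dc", "cytoplasm", p["Dc"]),
        SpeciesSpec("BemGEFc", "cytoplasm", p["Dc"]),
        SpeciesSpec("BemGEFc_p", "cytoplasm", p["Dc"]),
    )
    groups = (
        ("Cdc42", (("Cdc42T", 1.0), ("Cdc42Dm", 1.0), ("BemGEF42", 1.0),
                   ("BemGEF42_p", 1.0), ("Cdc42Dc", 1.0 / eta))),
        ("BemGEF", (("BemGEF42", 1.0), ("BemGEF42_p", 1.0), ("BemGEFm", 1.0),
                    ("BemGEFm_p", 1.0), ("BemGEFc", 1.0 / eta),
                    ("BemGEFc_p", 1.0 / eta))),
    )
    return ModelSpec(
        name="mechanistic_nfb",
        species=species,
        parameters=dict(p),
        reaction=reaction_nfb,
        conservation_groups=groups,
        derived_sums={
            "BemGEFm_t": ("BemGEFm", "BemGEFm_p"),
            "BemGEFc_t": ("BemGEFc", "BemGEFc_p"),
            "BemGEF42_t": ("BemGEF42", "BemGEF42_p"),
        },
        jacobian=jacobian_nfb,
    )


def make_model(name: str, params: dict[str, float] | None = None, **kwargs) -> ModelSpec:
    """Factory by model name: minimal | indirect | mechanistic | mechanistic_nfb."""
    params = params or {}
    if name == "minimal":
        return make_minimal_model(**params, **kwargs)
    if name == "indirect":
        return make_indirect_model(**params, **kwargs)
    if name == "mechanistic":
        return make_mechanistic_model(params, negative_feedback=False, **kwargs)
    if name == "mechanistic_nfb":
        return make_mechanistic_model(params, negative_feedback=True, **kwargs)
    raise ModelValidationError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# homogeneous steady states and linear stability


def homogeneous_steady_state(
    model: ModelSpec, totals: dict[str, float] | float
) -> list[HomogeneousState]:
    """All homogeneous steady states compatible with the requested totals.

    ``totals`` maps conservation-group name to the weighted uniform total
    concentration (for the minimal model this is simply ``u + v``); a bare
    float is accepted for single-group models.  For the minimal and
    indirect models the roots are closed-form; for the mechanistic models
    the well-mixed kinetics are relaxed numerically to steady state.
    """
    if not isinstance(totals, dict):
        if len(model.conservation_groups) != 1:
            raise ModelValidationError("scalar total requires a single-group model")
        totals = {model.conservation_groups[0][0]: float(totals)}
    for g, T in totals.items():
        if T < 0:
            raise ModelValidationError(f"total for group {g} must be >= 0")

    p = model.parameters
    states: list[HomogeneousState] = []

    if model.name == "minimal":
        T = totals["total"]
        states.append(HomogeneousState({"u": 0.0, "v": T}))
        disc = T * T - 4.0 * p["b"] / p["a"]
        if disc >= 0:
            for u in ((T + np.sqrt(disc)) / 2.0, (T - np.sqrt(disc)) / 2.0):
                if u > 0:
                    states.append(HomogeneousState({"u": u, "v": T - u}))
        return _dedupe(states)

    if model.name == "indirect":
        T = totals["total"]
        states.append(HomogeneousState({"u": 0.0, "v": T, "v_i": 0.0}))
        # a u v = b + c with v_i = (c/d) u and u + v + v_i = T
        alpha = 1.0 + p["c"] / p["d"]
        disc = T * T - 4.0 * alpha * (p["b"] + p["c"]) / p["a"]
        if disc >= 0:
            for u in ((T + np.sqrt(disc)) / (2 * alpha), (T - np.sqrt(disc)) / (2 * alpha)):
                if u > 0:
                    vi = p["c"] / p["d"] * u
                    states.append(HomogeneousState({"u": u, "v": T - u - vi, "v_i": vi}))
        return _dedupe(states)

    # mechanistic models: relax the well-mixed ODE (conservation is built in)
    from scipy.integrate import solve_ivp

    eta = p["eta"]
    c0 = np.zeros(model.n_species)
    c0[model.index("Cdc42Dc")] = eta * totals["Cdc42"]
    c0[model.index("BemGEFc")] = eta * totals["BemGEF"]

    def rhs(_t, y):
        return model.reaction(y)

    sol = solve_ivp(rhs, (0.0, 2e4), c0, method="LSODA", rtol=1e-12, atol=1e-14)
    y = sol.y[:, -1]
    rate = model.reaction(y)
    scale = max(np.max(np.abs(y)), 1.0)
    if np.max(np.abs(rate)) > 1e-9 * scale:
        raise ModelValidationError("well-mixed relaxation did not reach steady state")
    states.append(HomogeneousState(dict(zip(model.species_names, map(float, y)))))
    return states


def _dedupe(states: Sequence[HomogeneousState]) -> list[HomogeneousState]:
    out: list[HomogeneousState] = []
    for s in states:
        vec = np.array(sorted(s.concentrations.values()))
        if not any(
            np.allclose(vec, np.array(sorted(o.concentrations.values())), atol=1e-12)
            and s.concentrations.keys() == o.concentrations.keys()
            and np.allclose(
                np.array(list(s.concentrations.values())),
                np.array(list(o.concentrations.values())), atol=1e-12)
            for o in out
        ):
            out.append(s)
    return out


def reaction_jacobian(model: ModelSpec, state: np.ndarray) -> np.ndarray:
    """Jacobian of the reaction term at a uniform state (central differences)."""
    state = np.asarray(state, dtype=float)
    n = model.n_species
    J = np.zeros((n, n))
    scale = max(np.max(np.abs(state)), 1.0)
    h = 1e-6 * scale
    for j in range(n):
        plus = state.copy(); plus[j] += h
        minus = state.copy(); minus[j] -= h
        J[:, j] = (model.reaction(plus) - model.reaction(minus)) / (2 * h)
    return J


def linear_stability_eigenvalues(
    model: ModelSpec, hss: HomogeneousState | np.ndarray, q: float,
    check_steady: bool = True,
) -> np.ndarray:
    """Eigenvalues of the linearized model at wavenumber ``q``.

    Returns the eigenvalues of ``J - q^2 diag(D)`` where ``J`` is the
    reaction Jacobian at the homogeneous steady state.  At ``q = 0``
    each conservation group contributes an exactly zero eigenvalue.
    """
    state = hss.as_array(model) if isinstance(hss, HomogeneousState) else np.asarray(hss)
    if check_steady:
        rate = model.reaction(state.astype(float))
        scale = max(np.max(np.abs(state)), 1.0)
        if np.max(np.abs(rate)) > 1e-8 * scale:
            raise ModelValidationError("state is not a homogeneous steady state")
    J = reaction_jacobian(model, state)
    A = J - (q * q) * np.diag(model.diffusivities)
    return np.linalg.eigvals(A)


def linear_growth_rate(model: ModelSpec, hss: HomogeneousState | np.ndarray,
                       q: float, check_steady: bool = True) -> float:
    """Leading growth rate Re(lambda_max) of a perturbation at wavenumber ``q``."""
    return float(np.max(np.real(linear_stability_eigenvalues(model, hss, q, check_steady))))
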