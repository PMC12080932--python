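"""Donor-specific platelet calcium signaling and activation state.

Each platelet's intracellular calcium [Ca²⁺]ᵢ is predicted one second at
a time by a donor-specific feed-forward network whose 14 inputs are the
six agonist concentrations at time t (ADP, convulxin, thrombin, U46619,
iloprost, GSNO) and the platelet's own calcium at the eight feedback
lags t-1, t-2, t-4, t-8, t-16, t-32, t-64 and t-128 s (padded with the
basal level before the platelet entered the domain).

Collagen contact is presented to the network as the GPVI agonist
convulxin at an effective 10 nM; local TXA2 enters as the TP agonist
U46619 at 15x the TXA2 concentration. Pharmacological scenarios act by
transforming this input vector (e.g. ADP inhibition zeroes the ADP
entry), and the tissue-factor scenario supplies an intra-clot thrombin
concentration from a reduced generation curve.

The activation state is the running integral of supra-basal calcium,
``xi(t) = ∫ ([Ca]_i - [Ca]_0) dt`` (negative excursions subtract, as
written — no rectification), and maps to adhesiveness through a Hill
function ``F(xi) = a_min + (a_max - a_min) xi^n / (xi^n + xi50^n)``.
Crossing ``xi_crit`` triggers dense-granule release (irreversible).

Units: ADP μM, convulxin nM, thrombin nM, U46619 μM-equivalents,
iloprost nM, GSNO μM; calcium μM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationError

__all__ = [
    "AGONIST_NAMES",
    "SCENARIOS",
    "LAGS",
    "CONVULXIN_CONTACT_NM",
    "U46619_PER_TXA2",
    "HillParams",
    "hill_adhesiveness",
    "AgonistVector",
    "assemble_agonist_inputs",
    "DonorModel",
    "CalciumTrace",
    "ActivationState",
    "update_activation",
    "ThrombinParams",
    "thrombin_curve",
]

AGONIST_NAMES = ("ADP", "convulxin", "thrombin", "U46619", "iloprost", "GSNO")
SCENARIOS = ("control", "no-adp", "no-txa2", "no-both", "gsno", "iloprost", "tf")
LAGS = (1, 2, 4, 8, 16, 32, 64, 128)

CONVULXIN_CONTACT_NM = 10.0   # effective GPVI input for collagen contact
U46619_PER_TXA2 = 15.0        # U46619 equivalents per μM TXA2

# default antagonist doses applied by the endothelial scenarios
ILOPROST_SCENARIO_NM = 10.0
GSNO_SCENARIO_UM = 1.0


@dataclass(frozen=True)
class HillParams:
    """Adhesiveness Hill map and the release threshold.

    ``xi50`` (μM·s) gives half-maximal adhesiveness, ``n`` the response
    sharpness, and ``xi_crit`` (μM·s) the dense-granule release
    threshold; ``xi50``/``xi_crit`` come from cohort calibration.
    """

    alpha_min: float = 0.01
    alpha_max: float = 1.0
    n: float = 2.0
    xi50: float = 10.0
    xi_crit: float = 20.0


def hill_adhesiveness(xi, p: HillParams):
    """F(xi): bounded, monotone in xi; xi <= 0 maps to alpha_min."""
    xi = np.asarray(xi, dtype=float)
    xp = np.clip(xi, 0.0, None) ** p.n
    F = p.alpha_min + (p.alpha_max - p.alpha_min) * xp / (xp + p.xi50 ** p.n)
    return F if F.ndim else float(F)


@dataclass
class AgonistVector:
    """The six network inputs, in network units (see module docstring)."""

    adp: float = 0.0
    convulxin: float = 0.0
    thrombin: float = 0.0
    u46619: float = 0.0
    iloprost: float = 0.0
    gsno: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.adp, self.convulxin, self.thrombin,
                         self.u46619, self.iloprost, self.gsno])


def assemble_agonist_inputs(adp_uM: float, txa2_uM: float,
                            collagen_contact: bool,
                            thrombin_nM: float,
                            scenario: str,
                            iloprost_nM: float = ILOPROST_SCENARIO_NM,
                            gsno_uM: float = GSNO_SCENARIO_UM) -> AgonistVector:
    """Map local fields to the network input vector, then apply the scenario.

    Scenario transforms are applied last: agonist-inhibition scenarios
    zero the corresponding entries (mimicking P2Y12 blockade and TXA2
    synthesis inhibition), the antagonist scenarios add a constant
    endothelial inhibitor dose, and the tissue-factor scenario passes
    the supplied thrombin level (zero otherwise).
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    if min(adp_uM, txa2_uM, thrombin_nM) < 0:
        raise ValueError("agonist concentrations must be non-negative")
    v = AgonistVector(
        adp=adp_uM,
        convulxin=CONVULXIN_CONTACT_NM if collagen_contact else 0.0,
        thrombin=0.0,
        u46619=U46619_PER_TXA2 * txa2_uM,
    )
    if scenario in ("no-adp", "no-both"):
        v.adp = 0.0
    if scenario in ("no-txa2", "no-both"):
        v.u46619 = 0.0
    if scenario == "iloprost":
        v.iloprost = iloprost_nM
    if scenario == "gsno":
        v.gsno = gsno_uM
    if scenario == "tf":
        v.thrombin = thrombin_nM
    return v


@dataclass
class DonorModel:
    """Trained feed-forward calcium model for one (synthetic) donor.

    ``weights``/``biases`` hold the hidden layers (tanh) and the linear
    scalar output; inputs are standardized by ``x_mean``/``x_scale``.
    ``ca0`` is the donor's basal calcium (μM). ``provenance`` records
    the synthetic-donor parameter set and training seed.
    """

    weights: list          # [W1 (nin x h), W2, ..., Wout (h x 1)]
    biases: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    ca0: float
    hill: HillParams = field(default_factory=HillParams)
    provenance: dict = field(default_factory=dict)
    # agonist inputs enter through log1p (monotone reparameterization that
    # resolves the decade-spanning dose grid); standardization constants
    # are stored in transformed coordinates
    log_dose: bool = True

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Next-second calcium (μM, clamped >= 0) for rows of 14 inputs."""
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs")
        if self.log_dose:
            X = X.copy()
            X[:, :6] = np.log1p(X[:, :6])
        h = (X - self.x_mean) / self.x_scale
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ W + b)
        y = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return np.clip(y, 0.0, None)

    # -- serialization ----------------------------------------------
    def save(self, h5group) -> None:
        h5group.attrs["ca0"] = self.ca0
        h5group.attrs["n_layers"] = len(self.weights)
        h5group.attrs["log_dose"] = self.log_dose
        for k in ("alpha_min", "alpha_max", "n", "xi50", "xi_crit"):
            h5group.attrs[k] = getattr(self.hill, k)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h5group.create_dataset(f"W{i}", data=W)
            h5group.create_dataset(f"b{i}", data=b)
        h5group.create_dataset("x_mean", data=self.x_mean)
        h5group.create_dataset("x_scale", data=self.x_scale)
        prov = h5group.create_group("provenance")
        for k, v in self.provenance.items():
            prov.attrs[k] = v

    @classmethod
    def load(cls, h5group) -> "DonorModel":
        n = int(h5group.attrs["n_layers"])
        weights = [h5group[f"W{i}"][()] for i in range(n)]
        biases = [h5group[f"b{i}"][()] for i in range(n)]
        hill = HillParams(**{k: float(h5group.attrs[k]) for k in
                             ("alpha_min", "alpha_max", "n", "xi50", "xi_crit")})
        prov = dict(h5group["provenance"].attrs) if "provenance" in h5group else {}
        return cls(weights=weights, biases=biases,
                   x_mean=h5group["x_mean"][()], x_scale=h5group["x_scale"][()],
                   ca0=float(h5group.attrs["ca0"]), hill=hill, provenance=prov,
                   log_dose=bool(h5group.attrs.get("log_dose", True)))


class CalciumTrace:
    """Per-platelet calcium history at 1 s resolution.

    Lag lookups for times before the platelet entered the domain return
    the basal level.
    """

    def __init__(self, ca0: float, t_entry: float = 0.0):
        self.ca0 = ca0
        self.t_entry = float(t_entry)
        self.values: list[float] = []

    def append(self, ca: float) -> None:
        self.values.append(max(float(ca), 0.0))

    def at(self, t: float) -> float:
        """Calcium at integer second ``t`` (basal before entry)."""
        k = int(round(t - self.t_entry))
        if k < 0 or k >= len(self.values):
            return self.ca0
        return self.values[k]

    def lag_vector(self, t: float) -> np.ndarray:
        return np.array([self.at(t - lag) for lag in LAGS])


def predict_calcium(model: DonorModel, trace: CalciumTrace,
                    agonists: AgonistVector, t: float) -> float:
    """[Ca²⁺]ᵢ(t + 1 s) from the 6 agonists at t and the 8 lagged values."""
    x = np.concatenate([agonists.as_array(), trace.lag_vector(t)])
    return float(model.predict(x[None, :])[0])


@dataclass
class ActivationState:
    """Integrated activation xi, adhesiveness F, and the release flag."""

    xi: float = 0.0
    F: float = None
    released: bool = False
    t_release: float | None = None

    def __post_init__(self):
        if self.F is None:
            self.F = None  # set on first update


def update_activation(state: ActivationState, ca: float, ca0: float,
                      t: float, dt: float, hill: HillParams) -> ActivationState:
    """Accumulate xi by (ca - ca0) dt, update F and the release flag.

    The integrand is applied exactly as written: calcium excursions
    below basal reduce xi. The released flag is monotone.
    """
    state.xi += (ca - ca0) * dt
    state.F = hill_adhesiveness(state.xi, hill)
    if not state.released and state.xi >= hill.xi_crit:
        state.released = True
        state.t_release = t
    return state


@dataclass(frozen=True)
class ThrombinParams:
    """Reduced intra-clot thrombin generation curve.

    A lag phase of duration ``t_lag`` is followed by a saturating
    (logistic-type) rise to a plateau; both the plateau and the rise
    speed increase with the wall tissue-factor density. ``t_max_ref``
    is the plateau at saturating TF, ``rho_half`` the TF density of
    half-maximal plateau (molecules/μm²).
    """

    t_max_ref: float = 30.0    # nM
    rho_half: float = 0.5      # molecules/μm²
    t_lag_ref: float = 50.0    # s at rho = rho_half
    tau_rise: float = 30.0     # s


def thrombin_curve(t: float, tf_density: float,
                   params: ThrombinParams | None = None) -> float:
    """Spatially uniform intra-clot thrombin (nM) at time ``t``.

    Zero for ``tf_density == 0`` and at ``t == 0``; non-decreasing in
    both ``t`` and ``tf_density``.
    """
    if tf_density < 0:
        raise ValueError("tf_density must be non-negative")
    p = params or ThrombinParams()
    if tf_density == 0.0:
        return 0.0
    t_max = p.t_max_ref * tf_density / (tf_density + p.rho_half)
    t_lag = p.t_lag_ref * 2.0 * p.rho_half / (tf_density + p.rho_half)
    tt = t - t_lag
    if tt <= 0:
        return 0.0
    # logistic-type rise starting from zero at the end of the lag phase
    return t_max * (2.0 / (1.0 + np.exp(-tt / p.tau_rise)) - 1.0)
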