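"""Model parameters, type/field enumerations, units and configuration I/O.

Every constant of the wound-healing model lives here: the Cellular Potts
energy coefficients, the reaction-diffusion coefficients of the four
diffusible species (PDGF, CSF1, MMP, inflammatory SASP), and the thresholds
and rates of the cell-behaviour rule system.  Values are in model units
(pixels, Monte-Carlo steps, arbitrary concentration units); the
:class:`UnitSystem` gives the conversions to micrometres and seconds.

The packaged defaults are the calibrated healthy-healing baseline; see
``docs/methods.md`` for how each value was chosen.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

log = logging.getLogger("woundcpm")

# --------------------------------------------------------------------------
# enumerations
# --------------------------------------------------------------------------

MEDIUM = 0
FIBROBLAST = 1
MYOFIBROBLAST = 2
MACROPHAGE = 3
SENESCENT = 4          # senescent myofibroblast
PRE_SENESCENT = 5      # pre-existing inflammatory senescent cell
ECM = 6                # one-pixel, immobile matrix "cell"
N_TYPES = 7

CELL_TYPE_NAMES = (
    "Medium",
    "Fibroblast",
    "Myofibroblast",
    "Macrophage",
    "SenescentMyofibroblast",
    "InflammatorySenescent",
    "ECM",
)

PDGF = 0
CSF1 = 1
MMP = 2
INF = 3
N_FIELDS = 4
FIELD_NAMES = ("pdgf", "csf1", "mmp", "inf")

# senescence-induction mechanisms
MECH_NONE = 0
MECH_PRIMARY = 1       # CCN1-mediated, probabilistic gate
MECH_JUXTACRINE = 2    # contact with fibrogenic-phase senescent cell
MECH_PARACRINE = 3     # inflammatory field from fibrolytic-phase senescent cell
MECH_PREEXISTING = 4
MECHANISM_NAMES = ("none", "primary", "juxtacrine", "paracrine", "preexisting")


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


# --------------------------------------------------------------------------
# units
# --------------------------------------------------------------------------

@dataclass
class UnitSystem:
    """Pixel/MCS to physical-unit conversions.

    One lattice pixel is 3 µm.  One Monte-Carlo step is 27 s, anchored on a
    reference free-cell displacement of 0.3 µm/MCS against a peak fibroblast
    migration speed of 40 µm/h (0.3 * 3600 / 40 = 27).
    """

    pixel_size_um: float = 3.0
    seconds_per_mcs: float = 27.0
    reference_displacement_um_per_mcs: float = 0.3
    reference_speed_um_per_h: float = 40.0

    @property
    def mcs_per_day(self) -> float:
        return 86400.0 / self.seconds_per_mcs

    def mcs_to_seconds(self, n_mcs: float) -> float:
        if n_mcs < 0:
            raise ValueError("number of MCS must be non-negative")
        return n_mcs * self.seconds_per_mcs

    def mcs_to_days(self, n_mcs: float) -> float:
        return self.mcs_to_seconds(n_mcs) / 86400.0

    def days_to_mcs(self, days: float) -> int:
        return int(round(days * self.mcs_per_day))

    def pixels_to_um(self, px: float) -> float:
        return px * self.pixel_size_um

    def validate(self) -> None:
        derived = (self.reference_displacement_um_per_mcs * 3600.0
                   / self.reference_speed_um_per_h)
        if abs(derived - self.seconds_per_mcs) > 1e-9:
            raise ConfigError(
                "units: seconds_per_mcs must equal "
                "reference_displacement * 3600 / reference_speed "
                f"({derived} != {self.seconds_per_mcs})")


# --------------------------------------------------------------------------
# CPM effective-energy parameters
# --------------------------------------------------------------------------

def _default_contact() -> np.ndarray:
    """Symmetric contact-energy matrix J(tau, tau') over the 7 types.

    Higher J = weaker adhesion.  Motile cells prefer cell-cell and cell-ECM
    contact over medium contact; ECM-ECM is strongly cohesive so the matrix
    scaffold stays compact.
    """
    J = np.zeros((N_TYPES, N_TYPES))
    cells = (FIBROBLAST, MYOFIBROBLAST, MACROPHAGE, SENESCENT, PRE_SENESCENT)
    for a in cells:
        J[MEDIUM, a] = J[a, MEDIUM] = 8.0
        J[ECM, a] = J[a, ECM] = 6.0
        for b in cells:
            J[a, b] = 11.0
    J[MEDIUM, ECM] = J[ECM, MEDIUM] = 4.0
    J[ECM, ECM] = 2.0
    return J


@dataclass
class EnergyParams:
    """Coefficients of the CPM effective energy and Metropolis dynamics."""

    temperature: float = 4.2
    contact: np.ndarray = field(default_factory=_default_contact)
    # per-type volume constraint; ECM stiffness is the immobilization barrier
    lambda_volume: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 2.0, 2.0, 2.0, 2.0, 2.0, 500.0]))
    target_volume: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 64.0, 64.0, 64.0, 64.0, 64.0, 1.0]))
    lambda_surface: np.ndarray = field(default_factory=lambda: np.zeros(N_TYPES))
    target_surface: np.ndarray = field(default_factory=lambda: np.zeros(N_TYPES))
    # chemotaxis: field index per type (-1 = none), strength, strength on ECM
    chem_field: np.ndarray = field(default_factory=lambda: np.array(
        [-1, PDGF, PDGF, INF, -1, -1, -1], dtype=np.int64))
    chem_lambda: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 1000.0, 1000.0, 1500.0, 0.0, 0.0, 0.0]))
    chem_lambda_ecm: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 2000.0, 2000.0, 1500.0, 0.0, 0.0, 0.0]))
    contact_order: int = 2   # Moore neighbourhood for contact energy / surfaces
    copy_order: int = 1      # von Neumann neighbourhood for copy attempts

    def validate(self) -> None:
        J = np.asarray(self.contact, float)
        if J.shape != (N_TYPES, N_TYPES):
            raise ConfigError("energy.contact: must be a 7x7 matrix")
        if not np.allclose(J, J.T):
            raise ConfigError("energy.contact: matrix must be symmetric")
        if self.temperature <= 0:
            raise ConfigError("energy.temperature: must be > 0")
        for name in ("lambda_volume", "target_volume", "lambda_surface",
                     "target_surface", "chem_lambda", "chem_lambda_ecm",
                     "chem_field"):
            if len(np.asarray(getattr(self, name))) != N_TYPES:
                raise ConfigError(f"energy.{name}: must have {N_TYPES} entries")
        chem = np.asarray(self.chem_field)
        lam, lam_e = np.asarray(self.chem_lambda), np.asarray(self.chem_lambda_ecm)
        if np.any(lam_e[chem >= 0] < lam[chem >= 0]):
            raise ConfigError(
                "energy.chem_lambda_ecm: ECM-contact chemotaxis strength must "
                "be >= the base strength")
        if self.contact_order not in (1, 2) or self.copy_order not in (1, 2):
            raise ConfigError("energy.contact_order/copy_order: must be 1 or 2")


# --------------------------------------------------------------------------
# reaction-diffusion parameters
# --------------------------------------------------------------------------

@dataclass
class SecretionRates:
    """Per-cell secretion rates (concentration units per MCS, spread over the
    secreting cell's pixels).  Which cells secrete what, and when, is encoded
    in :func:`woundcpm.fields.build_secretion_map`."""

    mac_pdgf: float = 0.03    # M2 macrophage -> PDGF
    mac_mmp: float = 0.010    # M1 macrophage, or macrophage touching ECM -> MMP
    fib_csf1: float = 0.015   # activated fibroblast (macrophage contact) -> CSF1
    myo_pdgf: float = 0.010   # myofibroblast autocrine PDGF
    myo_csf1: float = 0.015   # myofibroblast (macrophage contact) -> CSF1
    sen_pdgf: float = 0.020   # fibrogenic-phase senescent -> PDGF
    sen_csf1: float = 0.008   # fibrolytic-phase / pre-existing senescent
    sen_inf: float = 0.010
    sen_mmp: float = 0.007


@dataclass
class FieldParams:
    """Explicit finite-difference parameters for the four diffusible fields.

    ``diffusion`` is in pixel^2/MCS, ``decay`` in 1/MCS.  ``substeps=0`` lets
    the solver pick the smallest count satisfying the forward-Euler stability
    bound D*dt <= 1/4.
    """

    diffusion: np.ndarray = field(default_factory=lambda: np.full(N_FIELDS, 0.2))
    decay: np.ndarray = field(default_factory=lambda: np.array(
        [1.0e-3, 5.0e-4, 1.0e-3, 1.0e-3]))
    secretion: SecretionRates = field(default_factory=SecretionRates)
    substeps: int = 0

    def resolved_substeps(self) -> int:
        dmax = float(np.max(self.diffusion))
        needed = max(1, int(np.ceil(dmax / 0.25)))
        if self.substeps == 0:
            return needed
        if self.substeps < needed:
            raise ConfigError(
                f"fields.substeps: {self.substeps} sub-steps violate the "
                f"stability bound D*dt <= 1/4 (need >= {needed})")
        return self.substeps

    def validate(self) -> None:
        for name in ("diffusion", "decay"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (N_FIELDS,):
                raise ConfigError(f"fields.{name}: must have {N_FIELDS} entries")
            if np.any(arr < 0):
                raise ConfigError(f"fields.{name}: must be non-negative")
        if np.any(np.asarray(self.decay, float) >= 1.0):
            raise ConfigError("fields.decay: per-MCS decay must be < 1")
        for f_ in dataclasses.fields(SecretionRates):
            if getattr(self.secretion, f_.name) < 0:
                raise ConfigError(f"fields.secretion.{f_.name}: must be >= 0")
        self.resolved_substeps()


# --------------------------------------------------------------------------
# cell-behaviour parameters
# --------------------------------------------------------------------------

@dataclass
class BehaviorParams:
    """Thresholds, probabilities and rates of the cell-state rule system.

    Probabilities (``p_mf``, ``p_snc``, ``p_clear``) are per behaviour sweep
    (one sweep every ``sweep_period_mcs`` MCS).  ``t_sen`` is expressed in
    units of 1000 MCS: the baseline 12 corresponds to 12,000 MCS = 3.75 days,
    the time at which the primary (CCN1) senescence gate opens, matching the
    observed day-4 onset of senescence in healthy healing.  ``t_sen_mode``
    switches between the gate-opens-at-t_sen reading ("open_after", default)
    and the literal printed rule ("closed_before": induction only while
    t < t_sen).
    """

    # growth (pixels of target volume per MCS) and half-saturation constants
    gmax_f: float = 0.025
    gmax_mf: float = 0.03
    gmax_m: float = 0.011
    pdgf0: float = 0.02
    csf0: float = 0.015
    t_ci: float = 0.08          # contact-inhibition threshold on Rs
    # state-transition probabilities (per sweep)
    p_mf: float = 0.1
    p_snc: float = 0.15
    p_clear: float = 0.05
    # senescence timing
    t_sen: float = 12.0         # units of 1000 MCS (12 -> 3.75 days)
    t_sen_mode: str = "open_after"
    t_nis_days: float = 3.0     # fibrogenic SASP phase duration
    # concentration / contact-area thresholds
    pdgf_f: float = 0.01
    snc_thr: float = 0.03
    mmp_thr: float = 0.03
    ecm_thr: float = 3.0        # contact pixel-pairs with ECM
    inf_thr: float = 0.02
    csf1_thr: float = 0.002
    # removal and matrix production
    mu_per_day: float = 0.05    # background removal rate (1/day)
    ecm_fib: int = 2            # ECM pixels per producing fibroblast per sweep
    ecm_myof: int = 4           # always 2 * ecm_fib
    sweep_period_mcs: int = 500
    fate_period_mcs: int = 2000  # cadence of myofibroblast fate / senescence draws

    @property
    def t_sen_mcs(self) -> float:
        return self.t_sen * 1000.0

    def validate(self) -> None:
        for name in ("p_mf", "p_snc", "p_clear"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"behavior.{name}: probability must be in [0, 1]")
        for name in ("gmax_f", "gmax_mf", "gmax_m", "pdgf0", "csf0", "t_ci",
                     "t_sen", "t_nis_days", "pdgf_f", "snc_thr", "mmp_thr",
                     "ecm_thr", "inf_thr", "csf1_thr", "mu_per_day"):
            if getattr(self, name) < 0:
                raise ConfigError(f"behavior.{name}: must be >= 0")
        if self.t_sen_mode not in ("open_after", "closed_before"):
            raise ConfigError(
                "behavior.t_sen_mode: must be 'open_after' or 'closed_before'")
        if self.sweep_period_mcs < 1:
            raise ConfigError("behavior.sweep_period_mcs: must be >= 1")
        if self.fate_period_mcs % self.sweep_period_mcs != 0:
            raise ConfigError(
                "behavior.fate_period_mcs: must be a multiple of "
                "sweep_period_mcs")
        if self.ecm_fib < 0 or self.ecm_myof < 0:
            raise ConfigError("behavior.ecm_fib/ecm_myof: must be >= 0")
        if self.ecm_myof != 2 * self.ecm_fib:
            warnings.warn(
                "behavior.ecm_myof overridden away from 2 * ecm_fib "
                f"({self.ecm_myof} != 2*{self.ecm_fib})", stacklevel=2)
            log.warning("ecm_myof != 2 * ecm_fib (override allowed)")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass
class GridParams:
    """Domain geometry and initial seeding.

    The wound is a central square of side ``wound_size``; the surrounding
    dermal margin is tiled with ``cell_size`` x ``cell_size`` fibroblasts in a
    checkerboard with blocks of one-pixel ECM cells.  The wound is seeded with
    ``macrophage_count`` M2 macrophages (and, in the pre-existing-senescence
    scenario, ``preexisting_count`` inflammatory senescent cells).
    """

    width: int = 200
    height: int = 200
    wound_size: int = 120
    cell_size: int = 8
    macrophage_count: int = 30
    preexisting_count: int = 12
    preexisting_inf_value: float = 0.08   # initial INF level on seeded senescent cells
    wound_csf1_init: float = 0.15         # inflammatory-phase CSF1 carry-over in the wound

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ConfigError("grid.width/height: lattice too small")
        if not 0 < self.wound_size <= min(self.width, self.height) - 2 * self.cell_size:
            raise ConfigError(
                "grid.wound_size: wound must leave a dermal margin of at "
                "least one cell on every side")
        if self.macrophage_count < 0 or self.preexisting_count < 0:
            raise ConfigError("grid: seeding counts must be >= 0")

    def scaled(self, width: int, height: int | None = None) -> "GridParams":
        """Proportionally rescaled geometry for reduced-size runs."""
        height = width if height is None else height
        f = width / self.width
        wound = max(self.cell_size, int(round(self.wound_size * f)))
        wound = min(wound, min(width, height) - 2 * self.cell_size)
        return dataclasses.replace(
            self, width=width, height=height,
            wound_size=wound,
            macrophage_count=max(1, int(round(self.macrophage_count * f * f))),
            preexisting_count=max(1, int(round(self.preexisting_count * f * f))),
        )


# --------------------------------------------------------------------------
# top-level container
# --------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Everything needed to run one simulation replicate."""

    units: UnitSystem = field(default_factory=UnitSystem)
    grid: GridParams = field(default_factory=GridParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    fields: FieldParams = field(default_factory=FieldParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)

    def validate(self) -> "SimulationParams":
        self.units.validate()
        self.grid.validate()
        self.energy.validate()
        self.fields.validate()
        self.behavior.validate()
        return self

    # ---- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return _fromdict(cls, d, "")


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _fromdict(cls, d, prefix):
    if not isinstance(d, dict):
        raise ConfigError(f"{prefix or 'config'}: expected a mapping")
    fields_ = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields_)
    if unknown:
        raise ConfigError(f"{prefix or 'config'}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, f in fields_.items():
        if name not in d:
            continue
        val = d[name]
        typ = f.type if not isinstance(f.type, str) else f.type
        default = getattr(cls(), name) if dataclasses.is_dataclass(cls) else None
        if dataclasses.is_dataclass(default.__class__) and isinstance(val, dict) \
                and not isinstance(default, (int, float, str)):
            kwargs[name] = _fromdict(default.__class__, val,
                                     f"{prefix}{name}." if prefix else f"{name}.")
        elif isinstance(default, np.ndarray):
            kwargs[name] = np.asarray(val, dtype=default.dtype)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def load_config(path) -> SimulationParams:
    """Load and validate a YAML configuration file.

    Unknown keys are rejected; validation errors name the offending key.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    params = SimulationParams.from_dict(raw)
    params.validate()
    return params


def save_config(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def baseline_params() -> SimulationParams:
    """The calibrated healthy-healing baseline parameter set."""
    return SimulationParams().validate()
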