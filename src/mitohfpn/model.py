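"""Mitochondrial HFPN model of thiacalix[4]arene C-1193 action.

Encodes the myometrial-mitochondria network — electron transport chain
complexes I–IV energized by succinate and pyruvate, electric potential (EP)
on the inner membrane driving electrophoretic Ca2+ uptake, Ca2+-dependent
NO synthase, superoxide/ROS formation, and the cyclosporin-A-blocked
permeability transition pore — as a ready-to-simulate net whose observable
places carry the fluorescence reporters:

=========  ===============================  =====================
observable reporter                          units
=========  ===============================  =====================
NADH       NADH autofluorescence *change*    rel. units x1000
EP         inner-membrane potential          mV
Ca_Fluo4   Fluo-4 (matrix Ca2+)              rel. units x1000
NO_DAFFM   DAF-FM-T (nitric oxide)           rel. units x1000
ROS_DCF    DCF* (reactive oxygen species)    rel. units x1000
=========  ===============================  =====================

Each observable's dynamics F(t) is a fitted polynomial of time (minutes,
valid on [0, 15]); the corresponding continuous transition fires at the
analytic derivative dF/dt. The inhibitor acts through a transition pair:
the control-rate transition is gated by an inhibitory arc from the C1193
place and the inhibited-rate transition by a test arc at the same 1 nM
threshold, so exactly one of the pair is enabled at any concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fitting import PolyModel, LinearModel
from .hfpn import ArcSpec, NetSpec, PlaceSpec, RateLaw, TransitionSpec, ensure_valid, logger

#: inhibitory/test-arc threshold on the C1193 place, molar (1 nM, well below
#: the 10 uM experimental dose)
C1193_THRESHOLD_M = 1e-9
#: experimental inhibitor dose, molar
C1193_DOSE_M = 10e-6
#: constant offset relating EP (mV) to the NADH fluorescence-change dynamics
EP_OFFSET_MV = -40.00

CONTROL = "control"
C1193 = "c1193"

OBSERVABLES = ("NADH", "EP", "Ca_Fluo4", "NO_DAFFM", "ROS_DCF")


@dataclass(frozen=True)
class Condition:
    """Experimental condition: vehicle control or 10 uM C-1193."""

    name: str = CONTROL
    c1193_concentration: float = 0.0  # molar

    def __post_init__(self) -> None:
        if self.name not in (CONTROL, C1193):
            raise ValueError(f"unknown condition {self.name!r}")
        if self.c1193_concentration < 0:
            raise ValueError("concentration must be >= 0")
        if (self.name == CONTROL) != (self.c1193_concentration == 0):
            raise ValueError("control means zero C-1193 concentration and vice versa")

    @classmethod
    def control(cls) -> "Condition":
        return cls(CONTROL, 0.0)

    @classmethod
    def c1193(cls, concentration: float = C1193_DOSE_M) -> "Condition":
        return cls(C1193, concentration)


# ---------------------------------------------------------------------------
# fitted dynamics, coefficients in ascending order (c0, c1, ..., cd)
# ---------------------------------------------------------------------------

_DYNAMICS: dict[str, dict[str, tuple[float, ...]]] = {
    # NADH fluorescence change: cubic, zero intercept
    "NADH": {
        CONTROL: (0.0, -49.20, 7.44, -0.38),
        C1193: (0.0, -30.80, 3.81, -0.16),
    },
    # DCF* (ROS): linear
    "ROS_DCF": {
        CONTROL: (1000.0, 13.9),
        C1193: (1000.0, 1.3),
    },
    # DAF-FM-T (NO): linear
    "NO_DAFFM": {
        CONTROL: (16.91, 17.39),
        C1193: (-8.23, 13.12),
    },
    # Fluo-4 (Ca2+): quartic
    "Ca_Fluo4": {
        CONTROL: (1.57, 106.15, -28.68, 4.06, -0.20),
        C1193: (3.26, 61.15, -19.58, 2.80, -0.14),
    },
}

#: two-component linearization of the Fluo-4 dynamics around the 2.5-min
#: breakpoint: (slope, intercept) for the early [0, 2.5] and late (2.5, 15]
#: intervals
PIECEWISE_CA: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    CONTROL: ((27.68, -11.41), (20.44, 116.03)),
    C1193: ((12.86, 1.01), (4.17, 66.43)),
}

CA_BREAKPOINT_MIN = 2.5


@dataclass(frozen=True)
class DynamicsSet:
    """Per-observable fluorescence-vs-time models for one condition."""

    condition: Condition
    models: dict[str, PolyModel]
    piecewise_ca: tuple[LinearModel, LinearModel]
    ep_offset: float = EP_OFFSET_MV

    def __getitem__(self, observable: str) -> PolyModel:
        return self.models[observable]


def piecewise_ca_models(condition_name: str) -> tuple[LinearModel, LinearModel]:
    """The two-component linear Ca2+ (Fluo-4) representation for a condition."""
    (s0, b0), (s1, b1) = PIECEWISE_CA[condition_name]
    return (
        LinearModel(slope=s0, intercept=b0, interval=(0.0, CA_BREAKPOINT_MIN)),
        LinearModel(slope=s1, intercept=b1, interval=(CA_BREAKPOINT_MIN, 15.0)),
    )


def dynamics_polynomials(condition: Condition) -> DynamicsSet:
    """Fitted dynamics polynomials for every observable under a condition.

    EP (mV) is the NADH fluorescence-change dynamics shifted by −40.00 mV.
    """
    name = condition.name
    models = {obs: PolyModel(coefficients=coeffs[name]) for obs, coeffs in _DYNAMICS.items()}
    nadh = models["NADH"].coefficients
    models["EP"] = PolyModel(coefficients=(nadh[0] + EP_OFFSET_MV,) + tuple(nadh[1:]))
    return DynamicsSet(condition=condition, models=models, piecewise_ca=piecewise_ca_models(name))


def rate_from_dynamics(dynamics: PolyModel) -> RateLaw:
    """Transition speed = analytic time derivative of the dynamics polynomial."""
    if dynamics.degree > 4:
        raise ValueError(f"dynamics degree {dynamics.degree} exceeds 4")
    deriv = dynamics.derivative()
    return RateLaw(coefficients=deriv.coefficients, valid_interval=dynamics.valid_interval)


def ep_from_nadh(nadh_dynamics_value: float) -> float:
    """EP (mV) implied by a NADH fluorescence-change value."""
    return nadh_dynamics_value + EP_OFFSET_MV


# ---------------------------------------------------------------------------
# net construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservableMap:
    """Observable name -> place id, with units."""

    places: dict[str, str] = field(default_factory=lambda: {
        "NADH": "NADH", "EP": "EP", "Ca_Fluo4": "Ca_Fluo4",
        "NO_DAFFM": "NO_DAFFM", "ROS_DCF": "ROS_DCF", "C1193": "C1193",
    })
    units: dict[str, str] = field(default_factory=lambda: {
        "NADH": "rel. units x1000", "EP": "mV", "Ca_Fluo4": "rel. units x1000",
        "NO_DAFFM": "rel. units x1000", "ROS_DCF": "rel. units x1000", "C1193": "M",
    })

    def __getitem__(self, observable: str) -> str:
        return self.places[observable]


#: structural test arcs gating each observable's transition pair; complexes
#: and NOS are catalytic elements with no dynamics of their own
_CATALYSTS: dict[str, tuple[str, ...]] = {
    "NADH": ("complex_I",),
    "EP": ("complex_I", "complex_III", "complex_IV"),
    "Ca_Fluo4": ("uniporter",),
    "NO_DAFFM": ("NOS",),
    "ROS_DCF": ("complex_III",),
}


def build_model(condition: Condition) -> tuple[NetSpec, ObservableMap]:
    """Assemble and validate the mitochondrial net for one condition.

    The net's structure is condition-independent; the condition sets the
    C1193 place marking (which selects one transition of each gated pair)
    and the observable places' initial markings (the dynamics intercepts).
    """
    dyn = dynamics_polynomials(condition)

    places = [
        PlaceSpec("Sc", "continuous", 5.0, "sodium succinate, mM"),
        PlaceSpec("Pyr", "continuous", 5.0, "sodium pyruvate, mM"),
        PlaceSpec("complex_I", "generic", 1.0, "electron transport chain complex I"),
        PlaceSpec("complex_II", "generic", 1.0, "electron transport chain complex II"),
        PlaceSpec("complex_III", "generic", 1.0, "electron transport chain complex III"),
        PlaceSpec("complex_IV", "generic", 1.0, "electron transport chain complex IV"),
        PlaceSpec("NOS", "generic", 1.0, "mitochondrial NO synthase"),
        PlaceSpec("uniporter", "generic", 1.0, "Ca2+ uniporter"),
        PlaceSpec("CsA", "continuous", 0.005, "cyclosporin A, mM (MPTP blocker)"),
        PlaceSpec("C1193", "continuous", condition.c1193_concentration, "thiacalix[4]arene C-1193, M"),
        PlaceSpec("mito_intact", "discrete", 1, "organelle with closed MPTP"),
        PlaceSpec("mito_swollen", "discrete", 0, "organelle swollen after MPTP opening"),
    ]
    for obs in OBSERVABLES:
        intercept = dyn[obs].coefficients[0]
        init = intercept
        allow_negative = obs in ("NADH", "EP")
        if not allow_negative and intercept < 0:
            init = 0.0
            logger.info(
                "observable %s: fitted intercept %.2f is negative; initial marking set to 0 "
                "(fluorescence cannot be negative; the analytic model is kept for fitting)",
                obs, intercept,
            )
        label = {
            "NADH": "NADH autofluorescence change, rel. units x1000",
            "EP": "inner-membrane electric potential, mV",
            "Ca_Fluo4": "Fluo-4 fluorescence (matrix Ca2+), rel. units x1000",
            "NO_DAFFM": "DAF-FM-T fluorescence (NO), rel. units x1000",
            "ROS_DCF": "DCF* fluorescence (ROS), rel. units x1000",
        }[obs]
        places.append(PlaceSpec(obs, "continuous", init, label, allow_negative=allow_negative))

    transitions = [
        TransitionSpec("MPTP", "discrete", delay=1.0,
                       label="cyclosporin-sensitive permeability transition pore"),
    ]
    arcs = [
        ArcSpec("CsA", "MPTP", "inhibitory", 0.001),  # CsA present => pore never opens
        ArcSpec("mito_intact", "MPTP", "normal", 1.0),
        ArcSpec("MPTP", "mito_swollen", "normal", 1.0),
    ]

    control_dyn = dynamics_polynomials(Condition.control())
    c1193_dyn = dynamics_polynomials(Condition.c1193())
    for obs in OBSERVABLES:
        for cond_name, d in ((CONTROL, control_dyn), (C1193, c1193_dyn)):
            tid = f"{obs}_{cond_name}_rate"
            transitions.append(
                TransitionSpec(tid, "continuous", rate=rate_from_dynamics(d[obs]),
                               label=f"{obs} {cond_name} dynamics")
            )
            gate = "inhibitory" if cond_name == CONTROL else "test"
            arcs.append(ArcSpec("C1193", tid, gate, C1193_THRESHOLD_M))
            arcs.append(ArcSpec("Sc", tid, "test", 0.1))
            arcs.append(ArcSpec("Pyr", tid, "test", 0.1))
            for cat in _CATALYSTS[obs]:
                arcs.append(ArcSpec(cat, tid, "test", 1.0))
            arcs.append(ArcSpec(tid, obs, "normal", 1.0))

    net = NetSpec(places=tuple(places), transitions=tuple(transitions), arcs=tuple(arcs))
    return ensure_valid(net), ObservableMap()


def bundled_model_path(condition_name: str):
    """Path to the shipped net YAML (``mito_control.yaml`` / ``mito_c1193.yaml``)."""
    from importlib import resources

    if condition_name not in (CONTROL, C1193):
        raise ValueError(f"unknown condition {condition_name!r}")
    return resources.files("mitohfpn") / "models" / f"mito_{condition_name}.yaml"
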