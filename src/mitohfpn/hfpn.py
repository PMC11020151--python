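"""Hybrid functional Petri net (HFPN) engine.

An HFPN is a bipartite graph of *places* (resources: token counts, real
amounts, or opaque generic payloads) and *transitions* (processes: discrete
token-firing events with a delay, or continuous flows with a real-valued
speed), connected by *normal*, *test*, and *inhibitory* arcs. Test arcs read
a marking without consuming it; inhibitory arcs disable a transition once
the source marking reaches a threshold.

This engine supports the restricted semantics needed for the mitochondrial
fluorescence model: continuous transition speeds are polynomials of
simulation time t (minutes), not of markings, and every trajectory lives in
the validity window [0, 15] min of those polynomials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from numpy.polynomial import polynomial as npoly

logger = logging.getLogger("mitohfpn")

#: hard cap of the rate-law validity window, minutes
T_MAX = 15.0

PLACE_KINDS = ("discrete", "continuous", "generic")
TRANSITION_KINDS = ("discrete", "continuous", "generic")
ARC_KINDS = ("normal", "test", "inhibitory")


# ---------------------------------------------------------------------------
# net specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateLaw:
    """Polynomial transition speed c0 + c1*t + ... + cd*t**d.

    Units: relative fluorescence units (x1000) per minute; t in minutes.
    Degree at most 4; validity interval within [0, 15] min.
    """

    coefficients: tuple[float, ...]
    valid_interval: tuple[float, float] = (0.0, T_MAX)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "valid_interval", tuple(float(v) for v in self.valid_interval))

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t: float) -> float:
        return float(npoly.polyval(t, self.coefficients))


@dataclass(frozen=True)
class PlaceSpec:
    id: str
    kind: str = "continuous"
    initial_marking: float = 0.0
    label: str = ""
    #: continuous places carrying signed observables (NADH change, EP) may
    #: go below zero; all others are clamped at 0 during simulation.
    allow_negative: bool = False


@dataclass(frozen=True)
class TransitionSpec:
    id: str
    kind: str = "continuous"
    rate: RateLaw | None = None
    delay: float | None = None
    label: str = ""


@dataclass(frozen=True)
class ArcSpec:
    source: str
    target: str
    kind: str = "normal"
    weight_or_threshold: float = 1.0


@dataclass(frozen=True)
class NetSpec:
    places: tuple[PlaceSpec, ...]
    transitions: tuple[TransitionSpec, ...]
    arcs: tuple[ArcSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "places", tuple(self.places))
        object.__setattr__(self, "transitions", tuple(self.transitions))
        object.__setattr__(self, "arcs", tuple(self.arcs))

    def place(self, pid: str) -> PlaceSpec:
        for p in self.places:
            if p.id == pid:
                return p
        raise KeyError(f"unknown place id: {pid!r}")

    def transition(self, tid: str) -> TransitionSpec:
        for t in self.transitions:
            if t.id == tid:
                return t
        raise KeyError(f"unknown transition id: {tid!r}")


@dataclass
class SimulationState:
    """Time-stamped marking vector plus the discrete-event log."""

    time: float
    marking: dict[str, float]
    event_log: list[tuple[float, str]] = field(default_factory=list)
    clamp_events: list[tuple[float, str]] = field(default_factory=list)
    # bookkeeping: when each discrete transition last became enabled / fired
    _enabled_since: dict[str, float] = field(default_factory=dict)
    _clamp_seen: set[str] = field(default_factory=set)

    @classmethod
    def initial(cls, net: NetSpec) -> "SimulationState":
        return cls(time=0.0, marking={p.id: float(p.initial_marking) for p in net.places})


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """One invariant violation, naming the offending element."""

    element: str
    message: str

    def __str__(self) -> str:
        return f"{self.element}: {self.message}"


def validate_net(net: NetSpec) -> list[Diagnostic]:
    """Check every structural invariant; empty list means the net is valid.

    Violations are reported as diagnostics (one per violation), never raised.
    """
    diags: list[Diagnostic] = []
    place_ids = [p.id for p in net.places]
    trans_ids = [t.id for t in net.transitions]

    for seq, what in ((place_ids, "place"), (trans_ids, "transition")):
        seen: set[str] = set()
        for eid in seq:
            if eid in seen:
                diags.append(Diagnostic(eid, f"duplicate {what} id {eid!r}"))
            seen.add(eid)
    shared = set(place_ids) & set(trans_ids)
    for eid in sorted(shared):
        diags.append(Diagnostic(eid, f"id {eid!r} used for both a place and a transition"))

    for p in net.places:
        if p.kind not in PLACE_KINDS:
            diags.append(Diagnostic(p.id, f"unknown place kind {p.kind!r}"))
        if not np.isfinite(p.initial_marking) or p.initial_marking < 0:
            if not (p.allow_negative and np.isfinite(p.initial_marking)):
                diags.append(Diagnostic(p.id, f"initial marking {p.initial_marking} must be finite and >= 0"))
        if p.kind == "discrete" and float(p.initial_marking) != int(p.initial_marking):
            diags.append(Diagnostic(p.id, "discrete place requires an integer token count"))

    for t in net.transitions:
        if t.kind not in TRANSITION_KINDS:
            diags.append(Diagnostic(t.id, f"unknown transition kind {t.kind!r}"))
        if t.kind == "continuous":
            if t.rate is None:
                diags.append(Diagnostic(t.id, "continuous transition requires a rate law"))
            else:
                if t.rate.degree > 4:
                    diags.append(Diagnostic(t.id, f"rate degree {t.rate.degree} exceeds 4"))
                lo, hi = t.rate.valid_interval
                if not (0.0 <= lo < hi <= T_MAX):
                    diags.append(Diagnostic(t.id, f"rate valid_interval {t.rate.valid_interval} not within [0, {T_MAX}]"))
            if t.delay is not None:
                diags.append(Diagnostic(t.id, "continuous transition must not carry a delay"))
        elif t.kind == "discrete":
            if t.delay is None or t.delay < 0:
                diags.append(Diagnostic(t.id, "discrete transition requires a nonnegative delay"))
            if t.rate is not None:
                diags.append(Diagnostic(t.id, "discrete transition must not carry a rate law"))

    pset, tset = set(place_ids), set(trans_ids)
    if not net.transitions:
        diags.append(Diagnostic("<net>", "net has no transitions"))
    for a in net.arcs:
        aid = f"arc {a.source}->{a.target}"
        if a.kind not in ARC_KINDS:
            diags.append(Diagnostic(aid, f"unknown arc kind {a.kind!r}"))
        src_p, src_t = a.source in pset, a.source in tset
        dst_p, dst_t = a.target in pset, a.target in tset
        if not (src_p or src_t):
            diags.append(Diagnostic(aid, f"unknown arc source {a.source!r}"))
        if not (dst_p or dst_t):
            diags.append(Diagnostic(aid, f"unknown arc target {a.target!r}"))
        if (src_p and dst_p) or (src_t and dst_t):
            diags.append(Diagnostic(aid, "arc must connect a place with a transition (bipartite)"))
        if a.kind in ("test", "inhibitory") and not (src_p and dst_t):
            diags.append(Diagnostic(aid, f"{a.kind} arc must point place -> transition"))
        if not np.isfinite(a.weight_or_threshold) or a.weight_or_threshold < 0:
            diags.append(Diagnostic(aid, f"weight/threshold {a.weight_or_threshold} must be finite and >= 0"))
    return diags


def ensure_valid(net: NetSpec) -> NetSpec:
    """Raise ValueError listing every diagnostic if the net is invalid."""
    diags = validate_net(net)
    if diags:
        raise ValueError("invalid net:\n" + "\n".join(str(d) for d in diags))
    return net


# ---------------------------------------------------------------------------
# enablement and stepping
# ---------------------------------------------------------------------------

def _input_arcs(net: NetSpec, tid: str) -> list[ArcSpec]:
    return [a for a in net.arcs if a.target == tid]


def _output_arcs(net: NetSpec, tid: str) -> list[ArcSpec]:
    return [a for a in net.arcs if a.source == tid]


def is_enabled(net: NetSpec, state: SimulationState, transition_id: str) -> bool:
    """True iff every normal/test input arc is satisfied (marking >= weight
    or threshold) and every inhibitory input arc is below its threshold."""
    net.transition(transition_id)  # raises KeyError naming an unknown id
    for a in _input_arcs(net, transition_id):
        m = state.marking[a.source]
        if a.kind == "inhibitory":
            if m >= a.weight_or_threshold:
                return False
        else:  # normal or test both require availability
            if m < a.weight_or_threshold:
                return False
    return True


def _fire_discrete(net: NetSpec, state: SimulationState, tid: str) -> None:
    for a in _input_arcs(net, tid):
        if a.kind == "normal":
            state.marking[a.source] -= a.weight_or_threshold
    for a in _output_arcs(net, tid):
        state.marking[a.target] += a.weight_or_threshold
    state.event_log.append((state.time, tid))


def _continuous_flow(net: NetSpec, state: SimulationState, t0: float, dt: float) -> dict[str, float]:
    """Net marking change over [t0, t0+dt] from enabled continuous transitions.

    The per-step flux uses the trapezoid rule dt*(rate(t0)+rate(t0+dt))/2,
    which is exact for linear speeds and second-order accurate in general
    (time-dependent speeds only, so this is plain quadrature).
    """
    delta: dict[str, float] = {}
    for t in net.transitions:
        if t.kind != "continuous" or not is_enabled(net, state, t.id):
            continue
        r0, r1 = t.rate(t0), t.rate(t0 + dt)
        if not (np.isfinite(r0) and np.isfinite(r1)):
            raise ArithmeticError(f"nonfinite rate for transition {t.id!r} at t={t0}")
        flux = 0.5 * (r0 + r1) * dt
        for a in _input_arcs(net, t.id):
            if a.kind == "normal":
                delta[a.source] = delta.get(a.source, 0.0) - a.weight_or_threshold * flux
        for a in _output_arcs(net, t.id):
            delta[a.target] = delta.get(a.target, 0.0) + a.weight_or_threshold * flux
    return delta


def step(net: NetSpec, state: SimulationState, dt: float) -> SimulationState:
    """Advance the state by dt minutes (in place semantics on a copy).

    Discrete transitions whose delay has elapsed while continuously enabled
    fire atomically first, in lexicographic id order; then every enabled
    continuous transition moves marking according to its speed. Markings of
    places without ``allow_negative`` are clamped at 0 (clamp logged).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    state = replace(
        state,
        marking=dict(state.marking),
        event_log=list(state.event_log),
        clamp_events=list(state.clamp_events),
        _enabled_since=dict(state._enabled_since),
        _clamp_seen=set(state._clamp_seen),
    )

    discrete = sorted(t.id for t in net.transitions if t.kind == "discrete")
    for tid in discrete:
        if is_enabled(net, state, tid):
            since = state._enabled_since.setdefault(tid, state.time)
            if state.time - since >= net.transition(tid).delay:
                _fire_discrete(net, state, tid)
                state._enabled_since[tid] = state.time
        else:
            state._enabled_since.pop(tid, None)

    delta = _continuous_flow(net, state, state.time, dt)
    for pid, d in delta.items():
        state.marking[pid] += d
    state.time += dt

    for p in net.places:
        if not p.allow_negative and state.marking[p.id] < 0:
            state.marking[p.id] = 0.0
            first = p.id not in state._clamp_seen
            state._clamp_seen.add(p.id)
            state.clamp_events.append((state.time, p.id))
            # every clamp is recorded in clamp_events; repeat clamps of the
            # same place go to debug to keep run logs readable
            log = logger.warning if first else logger.debug
            log("clamped place %r at 0 (t=%.4f min)", p.id, state.time)
    return state


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Sampled trajectory of every place plus the run's event bookkeeping."""

    times: np.ndarray
    marking: dict[str, np.ndarray]  # place id -> sampled amounts
    event_log: list[tuple[float, str]]
    clamp_events: list[tuple[float, str]]

    def __getitem__(self, place_id: str) -> np.ndarray:
        return self.marking[place_id]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, **self.marking})


def simulate(
    net: NetSpec,
    t_end: float,
    dt: float = 0.001,
    sample_every: float = 0.5,
    allow_beyond_validity: bool = False,
) -> SimulationResult:
    """Run the net over [0, t_end] minutes, sampling every ``sample_every``.

    Preconditions: 0 < dt <= sample_every <= max(t_end, dt); t_end <= 15
    (the rate-law validity window) unless ``allow_beyond_validity``.
    ``sample_every`` must be an integer multiple of dt and ``t_end`` of
    ``sample_every`` (within floating-point rounding).
    """
    ensure_valid(net)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end}")
    if t_end > 0 and not (dt <= sample_every <= t_end):
        raise ValueError(f"need dt <= sample_every <= t_end, got dt={dt}, sample_every={sample_every}, t_end={t_end}")
    if t_end > T_MAX:
        if not allow_beyond_validity:
            raise ValueError(f"t_end={t_end} outside the [0, {T_MAX}] min validity window of the rate laws")
        logger.warning("simulating to t=%.3f min, beyond the [0, %.0f] min validity window", t_end, T_MAX)

    n_samples = int(round(t_end / sample_every)) if t_end > 0 else 0
    if n_samples and abs(n_samples * sample_every - t_end) > 1e-9:
        raise ValueError(f"t_end={t_end} is not a multiple of sample_every={sample_every}")
    steps_per_sample = max(int(round(sample_every / dt)), 1) if n_samples else 0
    if n_samples and abs(steps_per_sample * dt - sample_every) > 1e-9:
        raise ValueError(f"sample_every={sample_every} is not a multiple of dt={dt}")

    state = SimulationState.initial(net)
    times = [0.0]
    samples = {p.id: [state.marking[p.id]] for p in net.places}
    for k in range(1, n_samples + 1):
        for j in range(steps_per_sample):
            state = step(net, state, dt)
            # keep time exact on the grid against float drift
            state.time = (k - 1) * sample_every + (j + 1) * dt
        state.time = k * sample_every
        times.append(state.time)
        for pid in samples:
            samples[pid].append(state.marking[pid])
    return SimulationResult(
        times=np.asarray(times),
        marking={pid: np.asarray(v) for pid, v in samples.items()},
        event_log=state.event_log,
        clamp_events=state.clamp_events,
    )


# ---------------------------------------------------------------------------
# YAML serialization (lossless round-trip)
# ---------------------------------------------------------------------------

def net_to_dict(net: NetSpec) -> dict:
    def place(p: PlaceSpec) -> dict:
        d = {"id": p.id, "kind": p.kind, "initial_marking": p.initial_marking, "label": p.label}
        if p.allow_negative:
            d["allow_negative"] = True
        return d

    def transition(t: TransitionSpec) -> dict:
        d: dict = {"id": t.id, "kind": t.kind, "label": t.label}
        if t.rate is not None:
            d["rate"] = {
                "coefficients": list(t.rate.coefficients),
                "valid_interval": list(t.rate.valid_interval),
            }
        if t.delay is not None:
            d["delay"] = t.delay
        return d

    def arc(a: ArcSpec) -> dict:
        return {"source": a.source, "target": a.target, "kind": a.kind,
                "weight_or_threshold": a.weight_or_threshold}

    return {
        "places": [place(p) for p in net.places],
        "transitions": [transition(t) for t in net.transitions],
        "arcs": [arc(a) for a in net.arcs],
    }


def net_from_dict(doc: dict) -> NetSpec:
    places = tuple(
        PlaceSpec(
            id=d["id"], kind=d.get("kind", "continuous"),
            initial_marking=float(d.get("initial_marking", 0.0)),
            label=d.get("label", ""), allow_negative=bool(d.get("allow_negative", False)),
        )
        for d in doc.get("places", [])
    )
    transitions = []
    for d in doc.get("transitions", []):
        rate = None
        if "rate" in d and d["rate"] is not None:
            rate = RateLaw(
                coefficients=tuple(d["rate"]["coefficients"]),
                valid_interval=tuple(d["rate"].get("valid_interval", (0.0, T_MAX))),
            )
        transitions.append(
            TransitionSpec(id=d["id"], kind=d.get("kind", "continuous"), rate=rate,
                           delay=d.get("delay"), label=d.get("label", ""))
        )
    arcs = tuple(
        ArcSpec(source=d["source"], target=d["target"], kind=d.get("kind", "normal"),
                weight_or_threshold=float(d.get("weight_or_threshold", 1.0)))
        for d in doc.get("arcs", [])
    )
    return NetSpec(places=places, transitions=tuple(transitions), arcs=arcs)


def write_net_yaml(net: NetSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(net_to_dict(net), fh, sort_keys=False)


def read_net_yaml(path) -> NetSpec:
    with open(path) as fh:
        return net_from_dict(yaml.safe_load(fh))
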