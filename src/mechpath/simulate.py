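"""Kinetic Monte Carlo simulation of mechanical protein unfolding.

The generator emulates force-clamp / force-ramp / constant-velocity AFM
experiments on a small two-state protein that unfolds through a set of
structural elements (default: five beta-strands plus an ordered loop, ~3 nm
of extension each at 40 pN, ~19 nm total).  Each element unfolds with a
Bell-type force-dependent rate

    rate(F) = alpha0 * exp(F * dx / kT)

where ``alpha0`` is the zero-force rate (1/s) and ``dx`` the distance to the
transition state (nm).  The trajectory over the lattice of folded-element
subsets is sampled with the Gillespie algorithm (clamp), by inverting the
integrated time-inhomogeneous hazard (ramp), or by per-sample thinning along
a quasi-static retraction (constant velocity).  Observable extension follows
worm-like-chain equilibrium elasticity of the cumulative unfolded contour,
with i.i.d. Gaussian instrument noise.

Pathway heterogeneity in the default network arises from a kinetic branch at
the first (nucleating, strand-5) unfolding event: a "sweep" channel whose
downstream rates are strongly accelerated (all later dwells fall below the
instrument resolution, producing apparent single-step unfolding) competes
with a "trapped" channel that proceeds at base rates and populates
long-lived intermediates in stochastic order.  The two channels carry
different ``dx``, so their Bell competition shifts flux with force; see
docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .trace import EventTable, Trace
from .wlc import KT_ROOM, WLCParams, wlc_force, wlc_fractional_extension

__all__ = [
    "BellModel",
    "Element",
    "PathwayChannel",
    "UnfoldingNetwork",
    "SimConfig",
    "StatePath",
    "default_network",
    "gillespie_clamp",
    "gillespie_ramp",
    "simulate_clamp",
    "simulate_ramp",
    "simulate_extension",
    "generate_ensemble",
    "observed_multiplicity",
]


@dataclass(frozen=True)
class BellModel:
    """Bell force-dependent rate law rate(F) = alpha0 * exp(F * dx / kT)."""

    alpha0: float  # 1/s, zero-force rate
    dx: float  # nm, distance to the transition state
    kT: float = KT_ROOM

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")

    def rate(self, F) -> float | np.ndarray:
        return self.alpha0 * np.exp(np.asarray(F, dtype=float) * self.dx / self.kT)


@dataclass(frozen=True)
class Element:
    """One structural element: contour gained on unfolding + Bell kinetics."""

    name: str
    contour_gain: float  # nm of contour released when this element unfolds
    alpha0: float  # 1/s
    dx: float  # nm

    def bell(self, kT: float = KT_ROOM) -> BellModel:
        return BellModel(self.alpha0, self.dx, kT)


@dataclass(frozen=True)
class PathwayChannel:
    """One competing unfolding channel of the branching (nucleating) element.

    ``post_rate_scale`` multiplies the rates of every later transition once
    the molecule has committed to this channel.
    """

    name: str
    alpha0: float
    dx: float
    post_rate_scale: float = 1.0


class ParameterError(ValueError):
    """Invalid generator parameter."""


@dataclass(frozen=True)
class UnfoldingNetwork:
    """Generative kinetic model of stepwise unfolding.

    ``prerequisites`` is a partial order: an element may unfold only after
    all of its prerequisites have.  ``branch_element`` optionally names the
    element whose unfolding commits the molecule to one of several
    :class:`PathwayChannel` s (its own alpha0/dx are then unused).
    """

    elements: tuple[Element, ...]
    prerequisites: dict = field(default_factory=dict)
    branch_element: str | None = None
    channels: tuple[PathwayChannel, ...] = ()
    rho: float = 0.4  # nm, persistence length of the unfolded chain
    kT: float = KT_ROOM

    def __post_init__(self) -> None:
        names = [e.name for e in self.elements]
        if len(self.elements) < 1:
            raise ParameterError("network needs at least one element")
        if len(set(names)) != len(names):
            raise ParameterError("duplicate element names")
        for e in self.elements:
            if e.contour_gain <= 0:
                raise ParameterError(f"contour gain of {e.name} must be positive")
        for el, pres in self.prerequisites.items():
            if el not in names or any(p not in names for p in pres):
                raise ParameterError(f"unknown element in prerequisites: {el}")
        if self.branch_element is not None:
            if self.branch_element not in names:
                raise ParameterError(f"unknown branch element {self.branch_element}")
            if len(self.channels) < 1:
                raise ParameterError("branch element declared without channels")
        self._check_acyclic(names)

    def _check_acyclic(self, names: list[str]) -> None:
        order: list[str] = []
        marked: set[str] = set()
        pres = {n: set(self.prerequisites.get(n, ())) for n in names}
        while len(order) < len(names):
            free = [n for n in names if n not in marked and pres[n] <= marked]
            if not free:
                raise ParameterError("dependency relation is cyclic")
            for n in free:
                marked.add(n)
                order.append(n)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.elements)

    @property
    def total_contour(self) -> float:
        return float(sum(e.contour_gain for e in self.elements))

    def fractional_extension(self, F: float) -> float:
        """WLC relative extension of unfolded contour at force F (pN)."""
        return float(wlc_fractional_extension(F, self.rho, self.kT))

    def total_length_at(self, F: float) -> float:
        """Equilibrium extension (nm) of the fully unfolded chain at force F."""
        return self.total_contour * self.fractional_extension(F)

    def extension_gains_at(self, F: float) -> dict:
        """Per-element equilibrium extension gain (nm) at force F."""
        z = self.fractional_extension(F)
        return {e.name: e.contour_gain * z for e in self.elements}


def default_network(
    n_elements: int = 6,
    total_length: float = 19.0,
    calibration_force: float = 40.0,
    rho: float = 0.4,
    kT: float = KT_ROOM,
) -> UnfoldingNetwork:
    """Default unfolding network calibrated to the emulated experiments.

    Per-element contour gains are equal and chosen so that the
    WLC-equilibrated extension of the fully unfolded chain at
    ``calibration_force`` equals ``total_length`` (default: 19 nm at 40 pN,
    i.e. ~3.17 nm of observable extension per element).

    For the canonical ``n_elements=6`` network the kinetic defaults encode
    the heterogeneous multi-pathway behaviour described in the module
    docstring: nucleation at strand s5 branches between a fast "sweep"
    channel and a "trapped" channel, the loop and remaining strands unfold
    in stochastic order afterwards, and strand s3 follows s2 near-instantly
    (capping the number of resolvable intermediates at four).  Other sizes
    get prerequisite-free elements with geometrically spread zero-force
    rates (a single element uses the experimental global rate scale).
    """
    if n_elements < 1:
        raise ParameterError(f"n_elements must be >= 1, got {n_elements}")
    if total_length <= 0:
        raise ParameterError(f"total_length must be positive, got {total_length}")
    z = float(wlc_fractional_extension(calibration_force, rho, kT))
    gain = (total_length / n_elements) / z

    if n_elements == 6:
        elements = (
            Element("s5", gain, alpha0=0.0, dx=0.0),  # kinetics via channels
            Element("s4", gain, alpha0=0.28, dx=0.2),
            Element("loop", gain, alpha0=0.20, dx=0.2),
            Element("s1", gain, alpha0=0.14, dx=0.2),
            Element("s2", gain, alpha0=0.055, dx=0.2),
            Element("s3", gain, alpha0=30.0, dx=0.2),
        )
        prerequisites = {
            "s4": ("s5",),
            "loop": ("s5",),
            "s1": ("s5",),
            "s2": ("s5",),
            "s3": ("s5", "s2"),
        }
        channels = (
            PathwayChannel("sweep", alpha0=0.20, dx=0.05, post_rate_scale=400.0),
            PathwayChannel("trapped", alpha0=0.005, dx=0.5, post_rate_scale=1.0),
        )
        return UnfoldingNetwork(
            elements=elements,
            prerequisites=prerequisites,
            branch_element="s5",
            channels=channels,
            rho=rho,
            kT=kT,
        )

    if n_elements == 1:
        alphas = np.array([0.07])
    else:
        alphas = np.geomspace(0.3, 0.03, n_elements)
    elements = tuple(
        Element(f"e{i + 1}", gain, alpha0=float(alphas[i]), dx=0.2)
        for i in range(n_elements)
    )
    return UnfoldingNetwork(elements=elements, rho=rho, kT=kT)


@dataclass
class StatePath:
    """One stochastic unfolding path: which element unfolded when.

    ``times`` are absolute event times (s) from force application;
    ``elements`` the unfolding order; ``pathway`` the committed branch
    channel (or None); ``completed`` is False when a time cap truncated the
    path before full unfolding.
    """

    elements: list[str]
    times: np.ndarray  # s, one per event
    pathway: str | None
    completed: bool
    t_end: float  # cap applied during simulation (inf when uncapped)

    @property
    def dwells(self) -> np.ndarray:
        """Dwell in each visited state (N first), as observed up to t_end."""
        t = np.concatenate(([0.0], self.times))
        end = self.t_end if np.isfinite(self.t_end) else (t[-1] if t.size else 0.0)
        edges = np.concatenate((t, [max(end, t[-1])]))
        return np.diff(edges)

    def states(self) -> list[tuple[frozenset, float]]:
        """(unfolded-subset, dwell) pairs, starting from the folded state."""
        out = []
        unfolded: set[str] = set()
        dwells = self.dwells
        for i, dwell in enumerate(dwells[:-1]):
            out.append((frozenset(unfolded), float(dwell)))
            unfolded.add(self.elements[i])
        out.append((frozenset(unfolded), float(dwells[-1])))
        return out


def _candidates(
    network: UnfoldingNetwork, unfolded: set, scale: float
) -> list[tuple[str, float | None, float, float]]:
    """Eligible transitions as (element, channel, alpha0_eff, dx)."""
    cands = []
    for e in network.elements:
        if e.name in unfolded:
            continue
        pres = network.prerequisites.get(e.name, ())
        if not all(p in unfolded for p in pres):
            continue
        if e.name == network.branch_element:
            for ch in network.channels:
                cands.append((e.name, ch.name, ch.alpha0 * scale, ch.dx))
        else:
            cands.append((e.name, None, e.alpha0 * scale, e.dx))
    return cands


def gillespie_clamp(
    network: UnfoldingNetwork,
    F: float,
    seed=None,
    t_max: float = math.inf,
) -> StatePath:
    """Stochastic simulation of the unfolding path at constant force F (pN).

    At each step the candidate transitions are the unfolding of any folded
    element whose prerequisites are met; the dwell is exponential with rate
    equal to the summed Bell rates and the element is chosen proportionally
    to its rate.  Terminates at the all-unfolded state or at ``t_max``.
    """
    if F < 0:
        raise ParameterError(f"force must be >= 0, got {F}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    unfolded: set[str] = set()
    scale = 1.0
    pathway: str | None = None
    t = 0.0
    order: list[str] = []
    times: list[float] = []
    completed = True
    while len(unfolded) < len(network.elements):
        cands = _candidates(network, unfolded, scale)
        rates = np.array(
            [a0 * math.exp(F * dx / network.kT) for (_, _, a0, dx) in cands]
        )
        total = float(rates.sum())
        if total <= 0.0:
            completed = False
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            completed = False
            break
        k = int(rng.choice(len(cands), p=rates / total))
        name, channel, _, _ = cands[k]
        if channel is not None:
            pathway = channel
            scale *= next(
                ch.post_rate_scale for ch in network.channels if ch.name == channel
            )
        unfolded.add(name)
        order.append(name)
        times.append(t)
    return StatePath(
        elements=order,
        times=np.asarray(times),
        pathway=pathway,
        completed=completed,
        t_end=t_max,
    )


def observed_multiplicity(path: StatePath, t_res: float) -> int:
    """Number of resolvable intermediates in a path at time resolution t_res.

    An intermediate (partially unfolded state between two steps, or the
    state occupied when a truncated pulse ends) counts as observed when its
    dwell is at least ``t_res`` s.  Mirrors the "number of intermediates =
    number of steps - 1" bookkeeping of the detector.
    """
    dwells = path.dwells
    inter = dwells[1:-1] if path.completed else dwells[1:]
    return int(np.sum(inter >= t_res))


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings for one batch of traces.

    Defaults mirror the emulated experimental protocols: 20-80 pN clamps
    held for 5-20 s (10 s default) sampled at 1 kHz, ramps at 20-800 pN/s
    capped at 300 pN, 400 nm/s retractions, Gaussian extension noise of
    0.5 nm and a resolvable-dwell floor ``t_res`` of 50 ms (feedback
    response scale).  ``include_fingerprint`` appends a decorative 150 pN
    segment with six ~24 nm titin-I27-like steps.
    """

    protocol: str = "clamp"
    force: float | None = 40.0  # pN, clamp setpoint
    ramp_rate: float | None = None  # pN/s
    pull_speed: float | None = None  # nm/s
    force_cap: float = 300.0  # pN, ramp cap
    duration: float = 10.0  # s
    sampling_rate: float = 1000.0  # Hz
    noise_sd: float = 0.5  # nm, extension channel
    force_noise_sd: float = 0.0  # pN, force channel (extension protocol)
    n_traces: int = 1
    seed: int | None = None
    t_res: float = 0.05  # s, resolution floor used for ground-truth bookkeeping
    include_fingerprint: bool = False
    fingerprint_force: float = 150.0  # pN
    fingerprint_duration: float = 4.0  # s
    handle_contour: float = 40.0  # nm, folded construct + linker offset (extension)
    quench_duration: float = 10.0  # s, cycles protocol
    cycle_forces: tuple = (20.0, 40.0, 60.0, 80.0)  # pN, cycles protocol

    def __post_init__(self) -> None:
        if self.protocol not in ("clamp", "ramp", "extension", "cycles"):
            raise ParameterError(f"unknown protocol {self.protocol!r}")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ParameterError("duration and sampling_rate must be positive")
        if self.t_res <= 0:
            raise ParameterError("t_res must be positive")
        if self.protocol == "ramp" and (self.ramp_rate is None or self.ramp_rate <= 0):
            raise ParameterError("ramp protocol requires positive ramp_rate")
        if self.protocol == "extension" and (
            self.pull_speed is None or self.pull_speed <= 0
        ):
            raise ParameterError("extension protocol requires positive pull_speed")
        if self.protocol in ("clamp",) and (self.force is None or self.force < 0):
            raise ParameterError("clamp protocol requires non-negative force")


def _fingerprint_segment(
    config: SimConfig, rng: np.random.Generator, t_start: float, x_start: float
):
    """Decorative I27-like staircase at the fingerprint force (not analysed)."""
    n = int(round(config.fingerprint_duration * config.sampling_rate))
    t = t_start + (np.arange(n) + 1) / config.sampling_rate
    dwells = rng.exponential(1.0 / 2.0, size=6)  # ~2 /s per I27 at 150 pN
    times = t_start + np.cumsum(dwells)
    levels = x_start + 24.0 * np.searchsorted(times, t, side="right")
    force = np.full(n, config.fingerprint_force)
    return t, levels, force


def simulate_clamp(
    network: UnfoldingNetwork,
    config: SimConfig,
    seed=None,
) -> tuple[Trace, StatePath]:
    """Render one constant-force trace (extension staircase + noise).

    The extension level after each unfolding event is the WLC-equilibrated
    extension of the cumulative unfolded contour at the clamp force.  When
    the pulse ends before full unfolding the trace is truncated and flagged
    in metadata.  Returns the trace together with its ground-truth path.
    """
    if config.protocol not in ("clamp", "cycles"):
        raise ParameterError("simulate_clamp requires clamp or cycles protocol")
    if config.protocol == "cycles":
        return _simulate_cycles(network, config, seed)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    F = float(config.force)
    path = gillespie_clamp(network, F, rng, t_max=config.duration)
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    z = network.fractional_extension(F)
    gains = np.array([z * g for g in _gains_in_order(network, path)])
    cum = np.concatenate(([0.0], np.cumsum(gains)))
    level = cum[np.searchsorted(path.times, t, side="right")]
    force = np.full(n, F)
    if config.include_fingerprint:
        tf, xf, ff = _fingerprint_segment(config, rng, t[-1] if n else 0.0, cum[-1])
        t = np.concatenate((t, tf))
        level = np.concatenate((level, xf))
        force = np.concatenate((force, ff))
    ext = level + (rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd else 0.0)
    trace = Trace(
        time=t,
        extension=ext,
        force=force,
        protocol="clamp",
        sampling_rate=config.sampling_rate,
        setpoint=F,
        meta={"truncated": not path.completed, "pathway": path.pathway or ""},
    )
    return trace, path


def _gains_in_order(network: UnfoldingNetwork, path: StatePath) -> list[float]:
    by_name = {e.name: e.contour_gain for e in network.elements}
    return [by_name[name] for name in path.elements]


def _simulate_cycles(network, config: SimConfig, seed):
    """Alternating force pulses and zero-force quenches; instantaneous refolding."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    fs = config.sampling_rate
    t_parts, x_parts, f_parts = [], [], []
    t0 = 0.0
    paths = []
    for F in config.cycle_forces:
        sub = replace(config, protocol="clamp", force=float(F), include_fingerprint=False)
        trace, path = simulate_clamp(network, sub, rng)
        t_parts.append(t0 + trace.time)
        x_parts.append(trace.extension)
        f_parts.append(trace.force)
        paths.append(path)
        t0 += config.duration
        nq = int(round(config.quench_duration * fs))
        tq = t0 + np.arange(nq) / fs
        # refolding at zero force is instantaneous and complete
        xq = rng.normal(0.0, config.noise_sd, size=nq) if config.noise_sd else np.zeros(nq)
        t_parts.append(tq)
        x_parts.append(xq)
        f_parts.append(np.zeros(nq))
        t0 += config.quench_duration
    t = np.concatenate(t_parts)
    ext = np.concatenate(x_parts)
    force = np.concatenate(f_parts)
    if config.include_fingerprint:
        tf, xf, ff = _fingerprint_segment(config, rng, t[-1], float(ext[-1]))
        noise = rng.normal(0.0, config.noise_sd, size=tf.size) if config.noise_sd else 0.0
        t = np.concatenate((t, tf))
        ext = np.concatenate((ext, xf + noise))
        force = np.concatenate((force, ff))
    trace = Trace(
        time=t,
        extension=ext,
        force=force,
        protocol="cycles",
        sampling_rate=fs,
        setpoint=None,
        meta={"cycle_forces": ",".join(f"{f:g}" for f in config.cycle_forces)},
    )
    return trace, paths


def _ramp_force(t, rate: float, cap: float):
    return np.minimum(rate * np.asarray(t, dtype=float), cap)


def _integrated_hazard(cands, t0: float, t, rate: float, cap: float, kT: float):
    """Integral of the summed Bell hazard from t0 to t under F(s)=min(rate*s, cap)."""
    t_cap = cap / rate
    total = 0.0
    for (_, _, a0, dx) in cands:
        if a0 <= 0:
            continue
        if dx <= 0:
            total += a0 * (t - t0)
            continue
        c = rate * dx / kT
        lo, hi = min(t0, t_cap), min(t, t_cap)
        if hi > lo:
            total += (a0 / c) * (math.exp(c * hi) - math.exp(c * lo))
        if t > t_cap:
            lo2 = max(t0, t_cap)
            if t > lo2:
                total += a0 * math.exp(cap * dx / kT) * (t - lo2)
    return total


def gillespie_ramp(
    network: UnfoldingNetwork,
    ramp_rate: float,
    seed=None,
    force_cap: float = 300.0,
    t_max: float = math.inf,
) -> StatePath:
    """Sample an unfolding path under a linear force ramp F(t) = rate*t (cap).

    Event times are drawn exactly by inverting the integrated
    time-inhomogeneous hazard of the eligible Bell transitions (root
    bracketing on the monotone cumulative hazard); the element is chosen
    proportionally to its instantaneous rate at the transition time.
    """
    if ramp_rate <= 0:
        raise ParameterError("ramp_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate, cap, kT = float(ramp_rate), float(force_cap), network.kT
    # with a finite cap the post-cap hazard is constant, so a finite horizon
    # always exists; default to reaching the cap plus ten mean lifetimes
    horizon = t_max if math.isfinite(t_max) else cap / rate + 1e6

    unfolded: set[str] = set()
    scale = 1.0
    pathway = None
    t_now = 0.0
    order, times = [], []
    completed = True
    while len(unfolded) < len(network.elements):
        cands = _candidates(network, unfolded, scale)
        if not any(a0 > 0 for (_, _, a0, _) in cands):
            completed = False
            break
        u = rng.exponential(1.0)
        lam_end = _integrated_hazard(cands, t_now, horizon, rate, cap, kT)
        if lam_end < u:
            completed = False
            break
        t_next = optimize.brentq(
            lambda tt: _integrated_hazard(cands, t_now, tt, rate, cap, kT) - u,
            t_now,
            horizon,
            xtol=1e-10,
        )
        F_now = min(rate * t_next, cap)
        rates = np.array([a0 * math.exp(F_now * dx / kT) for (_, _, a0, dx) in cands])
        k = int(rng.choice(len(cands), p=rates / rates.sum()))
        name, channel, _, _ = cands[k]
        if channel is not None:
            pathway = channel
            scale *= next(
                ch.post_rate_scale for ch in network.channels if ch.name == channel
            )
        unfolded.add(name)
        order.append(name)
        times.append(t_next)
        t_now = t_next
    return StatePath(
        elements=order,
        times=np.asarray(times),
        pathway=pathway,
        completed=completed,
        t_end=t_max if math.isfinite(t_max) else (times[-1] if times else 0.0),
    )


_Z_GRID_CACHE: dict = {}


def _z_interpolator(rho: float, kT: float, cap: float):
    key = (round(rho, 9), round(kT, 9), round(cap, 6))
    if key not in _Z_GRID_CACHE:
        f_grid = np.linspace(0.0, cap, 1024)
        _Z_GRID_CACHE[key] = (f_grid, wlc_fractional_extension(f_grid, rho, kT))
    return _Z_GRID_CACHE[key]


def simulate_ramp(
    network: UnfoldingNetwork,
    config: SimConfig,
    seed=None,
) -> tuple[Trace, StatePath]:
    """Render one force-ramp trace: F(t) = ramp_rate * t capped at force_cap.

    The unfolding path comes from :func:`gillespie_ramp`; the extension
    channel tracks the WLC extension of the unfolded contour at the
    instantaneous force (fractional extension interpolated on a cached
    force grid, accurate to <1e-3).
    """
    if config.protocol != "ramp":
        raise ParameterError("simulate_ramp requires ramp protocol")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    rate, cap = float(config.ramp_rate), float(config.force_cap)
    duration = config.duration
    path = gillespie_ramp(network, rate, rng, force_cap=cap, t_max=duration)
    pathway = path.pathway

    n = int(round(duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    force = _ramp_force(t, rate, cap)
    f_grid, z_grid = _z_interpolator(network.rho, network.kT, cap)
    z_t = np.interp(force, f_grid, z_grid)
    gains = np.array(_gains_in_order(network, path))
    cum = np.concatenate(([0.0], np.cumsum(gains)))
    contour = cum[np.searchsorted(path.times, t, side="right")]
    level = z_t * contour
    ext = level + (rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0)
    trace = Trace(
        time=t,
        extension=ext,
        force=force,
        protocol="ramp",
        sampling_rate=config.sampling_rate,
        ramp_rate=rate,
        meta={"truncated": not path.completed, "force_cap": cap,
              "pathway": pathway or ""},
    )
    return trace, path


def simulate_extension(
    network: UnfoldingNetwork,
    config: SimConfig,
    seed=None,
) -> tuple[Trace, StatePath]:
    """Render one constant-velocity (force-extension) trace.

    Quasi-static model: the tip-surface separation is ramped at
    ``pull_speed``; the force follows the WLC of the currently available
    contour (folded construct offset ``handle_contour`` plus unfolded
    gains); unfolding hazards are integrated along the trajectory by
    per-sample thinning.  Output is the sawtooth force-versus-time signal
    with the extension channel holding the separation.
    """
    if config.protocol != "extension":
        raise ParameterError("simulate_extension requires extension protocol")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else config.seed
    )
    v = float(config.pull_speed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    dt = 1.0 / fs
    kT = network.kT

    unfolded: set[str] = set()
    scale = 1.0
    pathway = None
    order, times = [], []
    contour = config.handle_contour
    force = np.empty(n)
    t = np.arange(n) / fs
    z_sep = v * t
    for i in range(n):
        x_eff = min(z_sep[i], 0.995 * contour)
        F = wlc_force(x_eff, WLCParams(Lc=contour, rho=network.rho, kT=kT))
        force[i] = F
        cands = _candidates(network, unfolded, scale)
        if not cands:
            continue
        rates = np.array([a0 * math.exp(min(F * dx / kT, 700.0)) for (_, _, a0, dx) in cands])
        total = rates.sum()
        if total <= 0:
            continue
        if rng.random() < -math.expm1(-total * dt):
            k = int(rng.choice(len(cands), p=rates / total))
            name, channel, _, _ = cands[k]
            if channel is not None:
                pathway = channel
                scale *= next(
                    ch.post_rate_scale for ch in network.channels if ch.name == channel
                )
            unfolded.add(name)
            order.append(name)
            times.append(t[i])
            contour += dict((e.name, e.contour_gain) for e in network.elements)[name]
    completed = len(unfolded) == len(network.elements)
    if config.force_noise_sd:
        force = force + rng.normal(0.0, config.force_noise_sd, size=n)
    path = StatePath(
        elements=order,
        times=np.asarray(times),
        pathway=pathway,
        completed=completed,
        t_end=config.duration,
    )
    trace = Trace(
        time=t,
        extension=z_sep,
        force=force,
        protocol="extension",
        sampling_rate=fs,
        pull_speed=v,
        meta={"truncated": not completed, "handle_contour": config.handle_contour,
              "pathway": pathway or ""},
    )
    return trace, path


def generate_ensemble(
    network: UnfoldingNetwork,
    configs: Sequence[SimConfig] | SimConfig,
    seed: int,
) -> tuple[list[Trace], EventTable]:
    """Generate a deterministic batch of traces plus ground-truth events.

    ``configs`` is one :class:`SimConfig` or a list (one batch per config;
    ``n_traces`` traces each).  All randomness derives from ``seed`` through
    a spawned generator hierarchy, so batches are bit-reproducible.  The
    returned :class:`EventTable` holds the TRUE step events (equilibrium
    extension gains and exact times), for detector validation; its traces
    frame carries ``pathway`` and ``censored`` (pulse ended early) columns.
    """
    if seed is None:
        raise ParameterError("generate_ensemble requires an explicit seed")
    if isinstance(configs, SimConfig):
        configs = [configs]
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(configs))

    traces: list[Trace] = []
    event_rows = []
    trace_rows = []
    for cfg, stream in zip(configs, streams):
        child_seeds = stream.spawn(cfg.n_traces)
        for i in range(cfg.n_traces):
            rng = np.random.default_rng(child_seeds[i])
            cond = {
                "clamp": cfg.force,
                "ramp": cfg.ramp_rate,
                "extension": cfg.pull_speed,
                "cycles": None,
            }[cfg.protocol]
            tid = f"{cfg.protocol}_{cond:g}_{i:04d}" if cond is not None else f"cycles_{i:04d}"
            if cfg.protocol == "clamp":
                trace, path = simulate_clamp(network, cfg, rng)
            elif cfg.protocol == "ramp":
                trace, path = simulate_ramp(network, cfg, rng)
            elif cfg.protocol == "extension":
                trace, path = simulate_extension(network, cfg, rng)
            else:
                trace, path = _simulate_cycles(network, cfg, rng)
            trace.trace_id = tid
            trace.seed = seed
            traces.append(trace)
            if cfg.protocol == "cycles":
                trace_rows.append(
                    {"trace_id": tid, "protocol": cfg.protocol, "force_condition": np.nan,
                     "n_steps": 0, "n_intermediates": 0, "total_length": 0.0,
                     "first_passage_time": np.nan, "censored": True, "pathway": ""}
                )
                continue
            if cfg.protocol == "clamp":
                z = network.fractional_extension(float(cfg.force))
            gains = _gains_in_order(network, path)
            cum = 0.0
            prev_t = 0.0
            for j, (name, t_ev) in enumerate(zip(path.elements, path.times)):
                if cfg.protocol == "clamp":
                    length = z * gains[j]
                elif cfg.protocol == "ramp":
                    F_ev = min(cfg.ramp_rate * t_ev, cfg.force_cap)
                    length = network.fractional_extension(F_ev) * gains[j]
                else:
                    length = gains[j]
                cum += length
                event_rows.append(
                    {
                        "trace_id": tid,
                        "step_index": j,
                        "step_length": length,
                        "cumulative_length": cum,
                        "dwell_before": t_ev - prev_t,
                        "force_at_step": (
                            float(cfg.force)
                            if cfg.protocol == "clamp"
                            else float(min(cfg.ramp_rate * t_ev, cfg.force_cap))
                            if cfg.protocol == "ramp"
                            else np.nan
                        ),
                        "t_step": t_ev,
                        "element": name,
                    }
                )
                prev_t = t_ev
            n_steps = len(path.elements)
            trace_rows.append(
                {
                    "trace_id": tid,
                    "protocol": cfg.protocol,
                    "force_condition": cond,
                    "n_steps": n_steps,
                    "n_intermediates": max(n_steps - 1, 0),
                    "total_length": cum,
                    "first_passage_time": (
                        float(path.times[-1]) if path.completed and n_steps else np.nan
                    ),
                    "censored": not path.completed,
                    "pathway": path.pathway or "",
                    "n_visible": observed_multiplicity(path, cfg.t_res),
                }
            )
    events = pd.DataFrame(event_rows)
    table = EventTable(events=events, traces=pd.DataFrame(trace_rows))
    return traces, table
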