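"""In-silico genetic perturbations expressed as timed schedules.

A :class:`Schedule` is a list of :class:`PerturbationEvent`; the integrator
resolves the active events at each time step.  Modes:

``clamp_zero``
    exact knockout: the gene is held at zero for the window.
``null_production``
    noisy knockout: production is removed but degradation and noise remain,
    so expression is zero on average with fluctuations.
``gain``
    ectopic over-expression: a constant extra production rate g.
``extra_degradation``
    inhibition: an extra decay term -d * x.
``noise_boost``
    raises the noise magnitude to D_high (applied to all genes; the
    per-gene-only variant is available via ``global_noise=False``).

Clamps take precedence over gains and degradation on the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .network import GENE_INDEX, N_TF

__all__ = [
    "PerturbationEvent",
    "Schedule",
    "knockout",
    "noisy_knockout",
    "overexpress",
    "inhibit",
    "staggered_protocol",
    "preset",
    "PRESETS",
    "DEFAULT_WINDOW",
    "DEFAULT_GAIN",
    "MARKER_GAIN",
]

MODES = ("clamp_zero", "null_production", "gain", "extra_degradation", "noise_boost")

#: Default reprogramming window (model-time units).
DEFAULT_WINDOW = (0.0, 40.0)
#: Default ectopic gain for relay transcription factors.
DEFAULT_GAIN = 5.0
#: Sub-latch boost applied when over-expressing a self-latching marker gene.
MARKER_GAIN = 0.3
_SELF_LATCHED = ("Ptf1a", "MafA", "DeltaGene", "Brn4")
#: Calibrated preset doses for the reprogramming recipes.
PRESET_DOSE = {"Pdx1": 0.5, "Ngn3": 4.0, "Pax4": 4.0}

_WHOLE_RUN = (0.0, np.inf)


@dataclass(frozen=True)
class PerturbationEvent:
    gene: str
    mode: str
    magnitude: float = 0.0
    window: tuple[float, float] = _WHOLE_RUN

    def __post_init__(self) -> None:
        if self.gene not in GENE_INDEX:
            raise KeyError(f"unknown gene {self.gene!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")
        t0, t1 = self.window
        if not t0 < t1:
            raise ValueError("window must satisfy t_on < t_off")

    def active(self, t: float) -> bool:
        return self.window[0] <= t < self.window[1]

    def to_dict(self) -> dict:
        t0, t1 = self.window
        return {
            "gene": self.gene,
            "mode": self.mode,
            "magnitude": self.magnitude,
            "window": [t0, None if np.isinf(t1) else t1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationEvent":
        t0, t1 = d.get("window", [0.0, None])
        return cls(d["gene"], d["mode"], float(d.get("magnitude", 0.0)),
                   (float(t0), np.inf if t1 is None else float(t1)))


@dataclass(frozen=True)
class Schedule:
    events: tuple[PerturbationEvent, ...] = ()
    label: str = "unperturbed"

    def __add__(self, other: "Schedule") -> "Schedule":
        return Schedule(self.events + other.events, f"{self.label}+{other.label}")

    def modifiers(self, t: float) -> "Modifiers":
        """Resolve the schedule at time t into per-gene modifier vectors."""
        clamp = np.zeros(N_TF, dtype=bool)
        nullprod = np.zeros(N_TF, dtype=bool)
        gain = np.zeros(N_TF)
        deg = np.zeros(N_TF)
        noise = 1.0
        d_abs = None
        for e in self.events:
            if not e.active(t):
                continue
            i = GENE_INDEX[e.gene]
            if e.mode == "clamp_zero":
                clamp[i] = True
            elif e.mode == "null_production":
                nullprod[i] = True
            elif e.mode == "gain":
                gain[i] += e.magnitude
            elif e.mode == "extra_degradation":
                deg[i] += e.magnitude
            elif e.mode == "noise_boost":
                d_abs = max(d_abs or 0.0, e.magnitude)
        gain[clamp] = 0.0
        deg[clamp] = 0.0
        return Modifiers(clamp, nullprod, gain, deg, d_abs)

    def boundaries(self) -> list[float]:
        ts: set[float] = set()
        for e in self.events:
            ts.add(e.window[0])
            if np.isfinite(e.window[1]):
                ts.add(e.window[1])
        return sorted(ts)

    def validate_horizon(self, t_end: float) -> None:
        for e in self.events:
            if e.window[0] > t_end:
                raise ValueError(
                    f"event on {e.gene} opens at t={e.window[0]} after t_end={t_end}")

    def to_dict(self) -> dict:
        return {"events": [e.to_dict() for e in self.events], "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "Schedule":
        return cls(tuple(PerturbationEvent.from_dict(e) for e in d.get("events", ())),
                   d.get("label", "schedule"))


@dataclass(frozen=True)
class Modifiers:
    clamp: np.ndarray
    null_production: np.ndarray
    gain: np.ndarray
    extra_degradation: np.ndarray
    noise_override: float | None


def knockout(gene: str) -> Schedule:
    """Whole-run deletion: the gene's expression is held at zero."""
    return Schedule((PerturbationEvent(gene, "clamp_zero"),), f"{gene.lower()}_ko")


def noisy_knockout(gene: str, D_high: float) -> Schedule:
    """Zero-mean knockout with boosted stochastic fluctuations.

    Production of ``gene`` is removed (expression relaxes to zero on
    average) while the noise magnitude of the whole system is raised to
    ``D_high``, revealing attractors that persist without the gene.
    """
    return Schedule(
        (
            PerturbationEvent(gene, "null_production"),
            PerturbationEvent(gene, "noise_boost", D_high),
        ),
        f"{gene.lower()}_noisy_ko",
    )


def _dose(gene: str, g: float | None) -> float:
    if g is not None:
        return g
    if gene in _SELF_LATCHED:
        return MARKER_GAIN
    return PRESET_DOSE.get(gene, DEFAULT_GAIN)


def overexpress(
    genes: Sequence[str], g: float | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    label: str = "overexpress",
) -> Schedule:
    """Ectopic over-expression: +g production on each gene inside window.

    When ``g`` is None each gene receives its calibrated preset dose
    (sub-latch boost for self-latching marker genes, full dose otherwise).
    """
    events = tuple(PerturbationEvent(x, "gain", _dose(x, g), window) for x in genes)
    return Schedule(events, label)


def inhibit(
    gene: str, d: float = 5.0, window: tuple[float, float] = DEFAULT_WINDOW,
) -> Schedule:
    """Targeted inhibition: extra first-order degradation -d*x in window."""
    return Schedule((PerturbationEvent(gene, "extra_degradation", d, window),),
                    f"{gene.lower()}_inhib")


def staggered_protocol(
    order: Sequence[str], stagger: float = 10.0, g: float | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    label: str | None = None,
) -> Schedule:
    """Open each gene's gain window at t_on + rank * stagger; common close.

    ``stagger=0`` reproduces the simultaneous protocol.
    """
    if len(set(order)) != len(order):
        raise ValueError("genes in a staggered protocol must be distinct")
    if stagger < 0:
        raise ValueError("stagger must be nonnegative")
    t0, t1 = window
    events = []
    for rank, gene in enumerate(order):
        on = t0 + rank * stagger
        if on >= t1:
            raise ValueError(f"stagger pushes {gene} outside the window")
        events.append(PerturbationEvent(gene, "gain", _dose(gene, g), (on, t1)))
    return Schedule(tuple(events), label or ("seq_" + "_".join(order)))


def preset(name: str) -> Schedule:
    """Look up a named protocol preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}") from None


_PNM = ("Pdx1", "Ngn3", "MafA")
PRESETS: dict[str, Schedule] = {
    "pax4_ko": knockout("Pax4"),
    "arx_ko": knockout("Arx"),
    "pdx1_noisy_ko": noisy_knockout("Pdx1", 0.2),
    "melton_pnm": overexpress(_PNM, label="melton_pnm"),
    "pnm_plus_pax4": overexpress(_PNM + ("Pax4",), label="pnm_plus_pax4"),
    "pnm_pax4_ptf1a_inhib": overexpress(_PNM + ("Pax4",), label="pnm_pax4") + inhibit("Ptf1a"),
    "sequence_A": staggered_protocol(("Pdx1", "Ngn3", "MafA"), label="sequence_A"),
    "sequence_B": staggered_protocol(("Ngn3", "Pdx1", "MafA"), label="sequence_B"),
    "sequence_C": staggered_protocol(("MafA", "Ngn3", "Pdx1"), label="sequence_C"),
    "sequence_D": staggered_protocol(("MafA", "Ptf1a", "Ngn3"), label="sequence_D"),
}
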