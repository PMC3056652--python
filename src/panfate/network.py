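"""Topology and rate law of the pancreas cell-fate gene regulatory network.

The circuit couples three cross-inhibition toggle switches in a hierarchy:
Ptf1a–Ngn3 (exocrine vs. endocrine), Pax4–Arx (beta/delta vs. alpha) and
MafA–DeltaGene (beta vs. delta), triggered by Hnf6 and fed back through a
cumulative "maturation" variable that eventually shuts Hnf6 down.  State is
an 11-vector: ten transcription factors plus the maturation node.

Production of gene *i* is a rational sigmoid of its regulators,

    prod_i = a_i * N_i / (1 + N_i + I_i),

where ``N_i`` collects activator terms ``eta_i * (x_j / chi_e)^m_e`` plus a
steep self-activation latch ``(x_i / x0)^{m_self}`` for autoregulated genes,
and ``I_i`` collects inhibitor terms ``(x_j / chi_e)^4``.  Weakening
coefficients eta follow the single-input / multi-input convention.  Each
edge carries an input scale (half-saturation) ``chi`` and a Hill exponent;
the defaults encode the calibrated wild-type model (see docs/methods.md for
the rationale of every non-unit scale).  Degradation is first order with
uniform rate ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np

__all__ = [
    "GENES",
    "MARKER_GENES",
    "MATURATION",
    "RegulatoryEdge",
    "GeneNetwork",
    "ParameterSet",
    "build_master_network",
    "build_alternative_network",
    "RateKernel",
    "compile_kernel",
    "production_rate",
    "drift",
    "maturity_input",
]

#: Transcription-factor nodes, in state-vector order.
GENES = (
    "Hnf6",
    "Pdx1",
    "Ptf1a",
    "Ngn3",
    "Pax4",
    "Arx",
    "MafA",
    "DeltaGene",
    "Pax6",
    "Brn4",
)

#: Name of the bookkeeping node occupying state index 10.
MATURATION = "maturation"

#: Terminal lineage markers (exocrine, beta, delta, alpha respectively).
MARKER_GENES = ("Ptf1a", "MafA", "DeltaGene", "Brn4")

GENE_INDEX = {g: i for i, g in enumerate(GENES)}
MARKER_INDEX = tuple(GENE_INDEX[g] for g in MARKER_GENES)
N_TF = len(GENES)
N_STATE = N_TF + 1


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed, directed regulatory interaction.

    ``input_scale`` is the half-saturation level of the source read by this
    edge and ``hill`` its sigmoid exponent; both default to the generic
    values (1.0 and 4) and are overridden for the calibrated edges.
    """

    source: str
    target: str
    sign: int
    input_scale: float = 1.0
    hill: int = 4

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")

    @property
    def is_self(self) -> bool:
        return self.source == self.target


# Calibrated per-edge input scales / exponents of the wild-type model.
# Chain activations not listed here run at scale 1 (deeply saturated at the
# source's high level); switch->marker and Pdx1-outgoing edges are
# high-threshold so that race transients and physiological Pdx1 do not
# ignite downstream latches; Hnf6->Ptf1a is a sharp trigger that arms at the
# Hnf6 plateau (2.2) and disarms during its decay.
EDGE_TUNING: dict[tuple[str, str], tuple[float, int]] = {
    ("Hnf6", "Ptf1a"): (1.55, 8),
    ("Pdx1", "Pax4"): (3.0, 4),
    ("Pdx1", "Arx"): (3.0, 4),
    ("Pdx1", "MafA"): (3.0, 4),
    ("Pax4", "MafA"): (2.9, 4),
    ("Pax4", "DeltaGene"): (2.9, 4),
    ("Arx", "Brn4"): (2.9, 4),
    # within-switch cross-inhibitions
    ("Ptf1a", "Ngn3"): (1.2, 4),
    ("Ngn3", "Ptf1a"): (1.2, 4),
    ("Pax4", "Arx"): (1.2, 4),
    ("Arx", "Pax4"): (1.2, 4),
    ("MafA", "DeltaGene"): (1.2, 4),
    ("DeltaGene", "MafA"): (1.2, 4),
    # alternative-variant inhibitions
    ("Pdx1", "Ptf1a"): (2.5, 4),
    ("Pdx1", "Ngn3"): (2.5, 4),
}

# Table-1 interactions plus the circuit completions (first-switch trigger,
# mutual inhibition of the third switch, delta-gene symmetry, and
# self-activation of every terminal marker and Pax6).
_MASTER_EDGES: tuple[tuple[str, str, int], ...] = (
    ("Hnf6", "Ngn3", +1),
    ("Hnf6", "Pdx1", +1),
    ("Ngn3", "Ptf1a", -1),
    ("Ngn3", "Pax6", +1),
    ("Ngn3", "Pax4", +1),
    ("Ngn3", "Arx", +1),
    ("Pax4", "Arx", -1),
    ("Pax4", "MafA", +1),
    ("Arx", "Pax4", -1),
    ("MafA", "Pdx1", +1),
    ("Pax6", "Pdx1", +1),
    ("Pdx1", "Pax4", +1),
    ("Pdx1", "Arx", +1),
    ("Pdx1", "MafA", +1),
    ("MafA", "MafA", +1),
    ("Arx", "Brn4", +1),
    ("Brn4", "Brn4", +1),
    ("Hnf6", "Ptf1a", +1),
    ("Ptf1a", "Ngn3", -1),
    ("MafA", "DeltaGene", -1),
    ("DeltaGene", "MafA", -1),
    ("Pax4", "DeltaGene", +1),
    ("Ptf1a", "Ptf1a", +1),
    ("DeltaGene", "DeltaGene", +1),
    ("Pax6", "Pax6", +1),
)

_ALTERNATIVE_EXTRA: tuple[tuple[str, str, int], ...] = (
    ("Pdx1", "Ptf1a", -1),
    ("Pdx1", "Ngn3", -1),
)

# Feedbacks the literature mentions but Table 1 omits; off by default.
OPTIONAL_TOGGLES = ("pdx1_auto", "pax4_to_pdx1", "ngn3_to_mafa")
_TOGGLE_EDGES = {
    "pdx1_auto": ("Pdx1", "Pdx1", +1),
    "pax4_to_pdx1": ("Pax4", "Pdx1", +1),
    "ngn3_to_mafa": ("Ngn3", "MafA", +1),
}


@dataclass(frozen=True)
class GeneNetwork:
    """The regulatory graph: ten TFs, one maturation node, signed edges."""

    gene_names: tuple[str, ...]
    edges: tuple[RegulatoryEdge, ...]
    variant: str
    marker_genes: tuple[str, ...] = MARKER_GENES
    toggles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.variant not in ("master", "alternative"):
            raise ValueError(f"unknown variant {self.variant!r}")
        names = set(self.gene_names)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise ValueError(f"edge {e.source}->{e.target} names an undeclared gene")
            if e.target == "Hnf6":
                raise ValueError("no transcription factor may regulate Hnf6")
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_state(self) -> int:
        return len(self.gene_names) + 1

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {(e.source, e.target, e.sign) for e in self.edges}

    def has_edge(self, source: str, target: str, sign: int | None = None) -> bool:
        for e in self.edges:
            if e.source == source and e.target == target:
                return sign is None or e.sign == sign
        return False

    def in_degree(self, gene: str) -> int:
        return sum(1 for e in self.edges if e.target == gene)

    def regulators(self, gene: str) -> list[RegulatoryEdge]:
        return [e for e in self.edges if e.target == gene]

    def to_dict(self) -> dict:
        return {
            "genes": list(self.gene_names),
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "sign": e.sign,
                    "input_scale": e.input_scale,
                    "hill": e.hill,
                }
                for e in self.edges
            ],
            "variant": self.variant,
            "toggles": list(self.toggles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneNetwork":
        return cls(
            gene_names=tuple(d["genes"]),
            edges=tuple(
                RegulatoryEdge(
                    e["source"],
                    e["target"],
                    int(e["sign"]),
                    float(e.get("input_scale", 1.0)),
                    int(e.get("hill", 4)),
                )
                for e in d["edges"]
            ),
            variant=d.get("variant", "master"),
            toggles=tuple(d.get("toggles", ())),
        )


def _build(variant: str, toggles: Iterable[str]) -> GeneNetwork:
    raw = list(_MASTER_EDGES)
    if variant == "alternative":
        raw += list(_ALTERNATIVE_EXTRA)
    toggles = tuple(toggles)
    for t in toggles:
        if t not in _TOGGLE_EDGES:
            raise ValueError(f"unknown toggle {t!r}; options: {OPTIONAL_TOGGLES}")
        raw.append(_TOGGLE_EDGES[t])
    edges = []
    for s, t, sign in raw:
        scale, hill = EDGE_TUNING.get((s, t), (1.0, 4))
        edges.append(RegulatoryEdge(s, t, sign, scale, hill))
    return GeneNetwork(gene_names=GENES, edges=tuple(edges), variant=variant, toggles=toggles)


def build_master_network(toggles: Iterable[str] = ()) -> GeneNetwork:
    """The wild-type (master) network of Table 1 plus circuit completions."""
    return _build("master", toggles)


def build_alternative_network(toggles: Iterable[str] = ()) -> GeneNetwork:
    """Master network plus direct inhibition of Ptf1a and Ngn3 by Pdx1."""
    return _build("alternative", toggles)


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants (defaults are the published values) and settings.

    a: per-gene maximal production rate; k: uniform first-order degradation;
    eta_single / eta_multi: weakening coefficients for genes with one vs.
    several regulatory inputs; n: Hill exponent of regulatory inputs;
    lambda_mat: maturity accumulation rate; D: noise magnitude with
    autocorrelation <xi_i(t) xi_j(t')> = 2 D delta_ij delta(t - t').

    self_hill / self_scale shape the autoregulation latch; mat_gate_scale /
    mat_gate_hill shape the maturation gate on Hnf6.  hnf6_mode selects how
    maturity shuts Hnf6 down ("gate": production gate, "degradation": extra
    first-order decay term x11 * Hnf6).
    """

    a: dict[str, float] = field(
        default_factory=lambda: {
            g: (2.2 if g in ("Pdx1", "Hnf6") else 6.0 if g in ("Pax4", "Arx") else 4.0)
            for g in GENES
        }
    )
    k: float = 1.0
    eta_single: float = 0.25
    eta_multi: float = 0.125
    n: int = 4
    lambda_mat: float = 0.01
    D: float = 0.05
    dt: float = 0.01
    t_end: float = 400.0
    save_interval: float = 0.5
    n_cells: int = 100
    seed: int = 1
    self_hill: int = 10
    self_scale: float = 2.0
    mat_gate_scale: float = 0.7
    mat_gate_hill: int = 8
    hnf6_mode: str = "gate"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.a.values()) or self.k < 0 or self.D < 0:
            raise ValueError("rates must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("Hill exponent n must be a positive integer")
        if self.hnf6_mode not in ("gate", "degradation"):
            raise ValueError("hnf6_mode must be 'gate' or 'degradation'")

    def with_(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        if "a" in d:
            d["a"] = {str(k): float(v) for k, v in d["a"].items()}
        return cls(**d)


class RateKernel:
    """Vectorised evaluator of the deterministic rate law.

    Precompiles the network into weight matrices grouped by Hill exponent so
    the drift of an (m, 11) ensemble state costs a few matrix products.
    """

    def __init__(self, network: GeneNetwork, params: ParameterSet):
        self.network = network
        self.params = params
        n4 = params.n
        self.a = np.array([params.a[g] for g in GENES])
        self.k = params.k

        n_inputs = np.zeros(N_TF)
        for e in network.edges:
            n_inputs[GENE_INDEX[e.target]] += 1
        n_inputs[GENE_INDEX["Hnf6"]] += 1  # the maturation input
        eta = np.where(n_inputs > 1, params.eta_multi, params.eta_single)

        self.act_w: dict[int, np.ndarray] = {}
        self.inh_w: dict[int, np.ndarray] = {}
        self.self_mask = np.zeros(N_TF)
        for e in network.edges:
            ti, si = GENE_INDEX[e.target], GENE_INDEX[e.source]
            if e.is_self:
                self.self_mask[ti] = 1.0
                continue
            w = 1.0 / e.input_scale ** e.hill
            if e.sign > 0:
                mat = self.act_w.setdefault(e.hill, np.zeros((N_TF, N_TF)))
                mat[ti, si] = w * eta[ti]
            else:
                mat = self.inh_w.setdefault(e.hill, np.zeros((N_TF, N_TF)))
                mat[ti, si] = w
        self.eta = eta
        self.hnf6 = GENE_INDEX["Hnf6"]

    def sigmoid(self, x: np.ndarray) -> np.ndarray:
        """Transfer S(x) in [0, 1] for TF production; x is (m, 11)."""
        p = self.params
        g = x[:, :N_TF]
        num = np.zeros_like(g)
        den = np.zeros_like(g)
        for hill, w in self.act_w.items():
            num += (w @ (g ** hill).T).T
        for hill, w in self.inh_w.items():
            den += (w @ (g ** hill).T).T
        num += self.self_mask * (g / p.self_scale) ** p.self_hill
        S = num / (1.0 + num + den)
        mat_term = (x[:, N_TF] / p.mat_gate_scale) ** p.mat_gate_hill
        if p.hnf6_mode == "gate":
            S[:, self.hnf6] = 1.0 / (1.0 + mat_term)
        else:
            S[:, self.hnf6] = 1.0
        return S

    def drift(self, x: np.ndarray) -> np.ndarray:
        """Deterministic rate of change of an (m, 11) ensemble state."""
        p = self.params
        d = np.empty_like(x)
        d[:, :N_TF] = self.a * self.sigmoid(x) - self.k * x[:, :N_TF]
        if p.hnf6_mode == "degradation":
            d[:, self.hnf6] -= x[:, N_TF] * x[:, self.hnf6]
        d[:, N_TF] = self.maturity_input(x)
        return d

    def maturity_input(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        m = x[:, MARKER_INDEX] ** p.n
        return p.lambda_mat * (m / (1.0 + m)).sum(axis=1)


def compile_kernel(network: GeneNetwork, params: ParameterSet) -> RateKernel:
    return RateKernel(network, params)


def _as_batch(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.ndim == 1:
        return state[None, :]
    return state


def production_rate(
    gene: str, state: np.ndarray, network: GeneNetwork, params: ParameterSet,
    kernel: RateKernel | None = None,
) -> float:
    """Production rate a_gene * S of one TF at a single state (length 11)."""
    if gene not in GENE_INDEX:
        raise KeyError(f"unknown gene {gene!r}")
    kernel = kernel or compile_kernel(network, params)
    S = kernel.sigmoid(_as_batch(state))
    return float(params.a[gene] * S[0, GENE_INDEX[gene]])


def drift(
    state: np.ndarray, network: GeneNetwork, params: ParameterSet,
    kernel: RateKernel | None = None,
) -> np.ndarray:
    """Deterministic drift of a single length-11 state (no perturbations)."""
    kernel = kernel or compile_kernel(network, params)
    return kernel.drift(_as_batch(state))[0]


def maturity_input(state: np.ndarray, params: ParameterSet) -> float:
    """Rate of maturity accumulation: lambda * sum of marker Hill readouts."""
    x = _as_batch(state)
    m = x[:, MARKER_INDEX] ** params.n
    return float(params.lambda_mat * (m / (1.0 + m)).sum(axis=1)[0])
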