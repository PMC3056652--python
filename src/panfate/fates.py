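"""Terminal-state classification, attractor census and robustness scans.

A cell type is read off the binarized pattern of the four terminal marker
genes (Ptf1a = exocrine, MafA = beta, DeltaGene = delta, Brn4 = alpha).
Marker thresholds default to 50% of each gene's wild-type attractor level
(computed once by deterministic relaxation), with an absolute fallback of
1.0 for genes that are off in every attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .engine import Ensemble, find_attractor, simulate_ensemble
from .network import (
    GENES,
    GENE_INDEX,
    MARKER_GENES,
    N_TF,
    GeneNetwork,
    ParameterSet,
    build_master_network,
)

__all__ = [
    "CELL_TYPES",
    "CellTypeCall",
    "BranchingReport",
    "ScanResult",
    "reference_attractors",
    "marker_thresholds",
    "classify_cell",
    "classify_ensemble",
    "count_attractors",
    "detect_branchings",
    "pca_embed",
    "noise_threshold_scan",
    "parameter_robustness_scan",
]

CELL_TYPES = ("exocrine", "alpha", "beta", "delta", "progenitor", "abnormal")

#: Marker on-pattern (Ptf1a, MafA, DeltaGene, Brn4) per pure cell type.
_PATTERNS = {
    (1, 0, 0, 0): "exocrine",
    (0, 1, 0, 0): "beta",
    (0, 0, 1, 0): "delta",
    (0, 0, 0, 1): "alpha",
    (0, 0, 0, 0): "progenitor",
}

# Archetype seeds used to locate the four wild-type attractors by
# deterministic relaxation: marker high plus the lineage's support genes.
_ARCHETYPES = {
    "exocrine": {"Ptf1a": 4.0},
    "alpha": {"Brn4": 4.0, "Pax6": 4.0, "Pdx1": 2.0},
    "beta": {"MafA": 4.0, "Pax6": 4.0, "Pdx1": 2.0},
    "delta": {"DeltaGene": 4.0, "Pax6": 4.0, "Pdx1": 2.0},
}


@dataclass(frozen=True)
class CellTypeCall:
    label: str
    marker_vector: tuple[int, ...]
    terminal_state: np.ndarray


@dataclass(frozen=True)
class BranchingReport:
    switch_pair: tuple[str, str]
    split_detected: bool
    subpopulation_sizes: tuple[int, int]
    detection_time: float | None


@dataclass(frozen=True)
class ScanResult:
    factors: np.ndarray          # (n_samples, 3) multipliers on (a, k, eta)
    success: np.ndarray          # (n_samples,) bool
    success_fraction: float
    seed: int


_ATTRACTOR_CACHE: dict[str, dict[str, np.ndarray]] = {}


def reference_attractors(
    network: GeneNetwork | None = None,
    params: ParameterSet | None = None,
) -> dict[str, np.ndarray]:
    """The four wild-type attractors, found by deterministic relaxation."""
    import json

    network = network or build_master_network()
    params = params or ParameterSet()
    key = json.dumps([network.to_dict(), params.to_dict()], sort_keys=True)
    if key in _ATTRACTOR_CACHE:
        return {k: v.copy() for k, v in _ATTRACTOR_CACHE[key].items()}
    out = {}
    for name, levels in _ARCHETYPES.items():
        x0 = np.zeros(network.n_state)
        x0[N_TF] = 3.0  # matured tissue: Hnf6 gate closed
        for g, v in levels.items():
            x0[GENE_INDEX[g]] = v
        res = find_attractor(network, params, x0)
        out[name] = res.state
    _ATTRACTOR_CACHE[key] = {k: v.copy() for k, v in out.items()}
    return out


def marker_thresholds(
    network: GeneNetwork | None = None,
    params: ParameterSet | None = None,
    fraction: float = 0.5,
    fallback: float = 1.0,
) -> dict[str, float]:
    """Per-gene on/off thresholds: ``fraction`` of the highest wild-type
    attractor level, or ``fallback`` for genes off in every attractor."""
    atts = reference_attractors(network, params)
    peak = np.max(np.stack(list(atts.values())), axis=0)[:N_TF]
    return {
        g: (fraction * peak[i] if peak[i] * fraction > fallback / 2 else fallback)
        for i, g in enumerate(GENES)
    }


def _threshold_vector(thresholds: Mapping[str, float]) -> np.ndarray:
    return np.array([thresholds[g] for g in MARKER_GENES])


def classify_cell(
    state: np.ndarray, thresholds: Mapping[str, float]
) -> CellTypeCall:
    """Binarize the marker genes and apply the cell-type pattern table."""
    state = np.asarray(state, float)
    idx = [GENE_INDEX[g] for g in MARKER_GENES]
    on = tuple((state[idx] > _threshold_vector(thresholds)).astype(int))
    label = _PATTERNS.get(on, "abnormal") if sum(on) < 2 else "abnormal"
    return CellTypeCall(label, on, state)


def classify_ensemble(
    ens: Ensemble, thresholds: Mapping[str, float] | None = None
) -> list[CellTypeCall]:
    thresholds = thresholds or marker_thresholds(ens.network, ens.params)
    return [classify_cell(s, thresholds) for s in ens.terminal_states()]


def count_attractors(
    ens: Ensemble,
    thresholds: Mapping[str, float] | None = None,
    stationarity_window: int = 20,
    stationarity_tol: float = 1.0,
) -> tuple[int, dict[tuple[int, ...], np.ndarray]]:
    """Number of distinct binarized terminal marker patterns.

    Cells whose marker pattern is still changing over the last saved window
    are flagged non-stationary and excluded (with a warning).
    Returns (count, {pattern: representative terminal state}).
    """
    import warnings

    thresholds = thresholds or marker_thresholds(ens.network, ens.params)
    thr = _threshold_vector(thresholds)
    idx = [GENE_INDEX[g] for g in MARKER_GENES]
    patterns: dict[tuple[int, ...], np.ndarray] = {}
    n_dropped = 0
    for tr in ens.trajectories:
        tail = tr.states[-stationarity_window:, idx]
        pat_tail = tail > thr
        if not (pat_tail == pat_tail[-1]).all():
            # a marker is crossing its threshold at the end of the run
            drift_span = np.abs(tail[-1] - tail[0]).max()
            if drift_span > stationarity_tol:
                n_dropped += 1
                continue
        pat = tuple(int(v) for v in pat_tail[-1])
        patterns.setdefault(pat, tr.final_state)
    if n_dropped:
        warnings.warn(f"{n_dropped} non-stationary cells excluded from the census")
    return len(patterns), patterns


SWITCH_PAIRS = (("Ptf1a", "Ngn3"), ("Pax4", "Arx"), ("MafA", "DeltaGene"))


def detect_branchings(
    ens: Ensemble, thresholds: Mapping[str, float] | None = None
) -> list[BranchingReport]:
    """Detect lineage splits at the three cross-inhibition switches.

    A cell *engages* a switch if either member ever exceeds its threshold;
    its dominance is the member with the larger running maximum.  A split
    is detected when both dominance groups are non-empty among engaged
    cells; the detection time is the first save time at which that holds.
    """
    thresholds = thresholds or marker_thresholds(ens.network, ens.params)
    states = ens.states_array()           # (m, T, 11)
    times = ens.times
    reports = []
    for ga, gb in SWITCH_PAIRS:
        ia, ib = GENE_INDEX[ga], GENE_INDEX[gb]
        tha, thb = thresholds[ga], thresholds[gb]
        amax = np.maximum.accumulate(states[:, :, ia], axis=1)
        bmax = np.maximum.accumulate(states[:, :, ib], axis=1)
        engaged = (amax[:, -1] > tha) | (bmax[:, -1] > thb)
        a_dom = engaged & (amax[:, -1] >= bmax[:, -1])
        b_dom = engaged & ~a_dom
        n_a, n_b = int(a_dom.sum()), int(b_dom.sum())
        split = n_a > 0 and n_b > 0
        t_det = None
        if split:
            a_on = (amax > tha) & (amax >= bmax)
            b_on = (bmax > thb) & (bmax > amax)
            both = a_on.any(axis=0) & b_on.any(axis=0)
            if both.any():
                t_det = float(times[int(np.argmax(both))])
        reports.append(BranchingReport((ga, gb), split, (n_a, n_b), t_det))
    return reports


def pca_embed(
    ens: Ensemble, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, float]]]:
    """PCA of all saved states pooled across cells (centered, unscaled).

    Returns (coordinates (N, c), explained_variance_ratio (c,), keys) where
    keys[i] = (cell_id, time) of row i.
    """
    import warnings

    X, keys = [], []
    for tr in ens.trajectories:
        X.append(tr.states[:, :N_TF])
        keys.extend((tr.cell_id, float(t)) for t in tr.times)
    X = np.concatenate(X)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two state samples")
    max_c = int(min(X.shape[0] - 1, X.shape[1]))
    if n_components > max_c:
        warnings.warn(f"reducing n_components from {n_components} to {max_c}")
        n_components = max_c
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_, keys


DEFAULT_D_GRID = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4)


def noise_threshold_scan(
    D_grid: Sequence[float] = DEFAULT_D_GRID,
    n_cells: int = 25,
    network: GeneNetwork | None = None,
    params: ParameterSet | None = None,
    observation_window: float | None = None,
    master_seed: int = 0,
) -> dict:
    """Smallest noise magnitude at which cell-type attractors destabilize.

    Cohorts of ``n_cells`` are placed at each of the four wild-type
    attractors and simulated for one observation window (default t_end) at
    each D on the grid; any change of classified type counts as a switch.
    Returns {"D_star": smallest grid D with >= 1 switch (or None),
    "switch_counts": {D: count}, "switch_fractions": {D: fraction}}.
    """
    if list(D_grid) != sorted(D_grid):
        raise ValueError("D_grid must be increasing")
    network = network or build_master_network()
    params = params or ParameterSet()
    window = observation_window if observation_window is not None else params.t_end
    atts = reference_attractors(network, params)
    thr = marker_thresholds(network, params)
    ss = np.random.SeedSequence(master_seed)
    counts: dict[float, int] = {}
    total = 4 * n_cells
    for D, child in zip(D_grid, ss.spawn(len(D_grid))):
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4)]
        n_switch = 0
        for (name, a0), sd in zip(atts.items(), seeds):
            ens = simulate_ensemble(
                n_cells, network, params.with_(D=D), master_seed=sd,
                initial=a0, t_end=window,
            )
            for s in ens.terminal_states():
                if classify_cell(s, thr).label != name:
                    n_switch += 1
        counts[float(D)] = n_switch
    D_star = next((D for D, c in counts.items() if c > 0), None)
    return {
        "D_star": D_star,
        "switch_counts": counts,
        "switch_fractions": {D: c / total for D, c in counts.items()},
    }


def parameter_robustness_scan(
    n_samples: int = 100,
    master_seed: int = 0,
    decades: float = 1.0,
    n_cells: int = 30,
    network: GeneNetwork | None = None,
    params: ParameterSet | None = None,
    include_default: bool = True,
) -> ScanResult:
    """Log-uniform scan of (a, k, eta) over +/- ``decades`` orders.

    Each sample multiplies all production rates, the degradation rate and
    both weakening coefficients by independent log-uniform factors and runs
    a reduced ensemble; success means all four cell types are produced.
    Sample 0 is the default parameter set when ``include_default``.
    """
    network = network or build_master_network()
    params = params or ParameterSet()
    rng = np.random.default_rng(master_seed)
    n_random = n_samples - (1 if include_default else 0)
    factors = 10.0 ** rng.uniform(-decades, decades, size=(n_random, 3))
    if include_default:
        factors = np.vstack([[1.0, 1.0, 1.0], factors])
    thr = marker_thresholds(network, params)
    seeds = np.random.SeedSequence(master_seed).spawn(len(factors))
    success = np.zeros(len(factors), dtype=bool)
    for i, ((fa, fk, fe), child) in enumerate(zip(factors, seeds)):
        p_i = params.with_(
            a={g: v * fa for g, v in params.a.items()},
            k=params.k * fk,
            eta_single=params.eta_single * fe,
            eta_multi=params.eta_multi * fe,
            n_cells=n_cells,
        )
        sd = int(child.generate_state(1)[0] % (2**31))
        try:
            ens = simulate_ensemble(n_cells, network, p_i, master_seed=sd)
        except FloatingPointError:
            continue
        labels = {classify_cell(s, thr).label for s in ens.terminal_states()}
        success[i] = {"exocrine", "alpha", "beta", "delta"} <= labels
    return ScanResult(factors, success, float(success.mean()), master_seed)
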