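"""Simulated-annealing minimization of the cost-efficiency objective.

The objective is ``L = (1 - alpha) * l_g / lg_max + alpha * l_p / lp_max``:
a convex mix of normalized graph length (processing inefficiency) and
normalized wiring cost.  Candidate moves are directed double-edge swaps, so
the in/out degree sequence of the real network is conserved at every step;
moves that disconnect the network are discarded without counting toward
acceptance statistics.

The temperature drops as ``T_{n+1} = T_n / n`` (n = 1, 2, ...), i.e. a
brief hot phase followed by a factorially fast quench; each level rewires
for a fixed number of steps and the run terminates when the best objective
improves by no more than ``tol`` between consecutive levels.

Independent realizations from different random initial rewirings are
aggregated into a link-frequency matrix ``P`` and thresholded into a
consensus network whose link count matches the real network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from cortnet._graph import (
    efficiency_from_dist,
    hop_distances,
    is_strongly_connected,
)
from cortnet.data import SpatialNetwork, randomize_preserving_degrees
from cortnet.metrics import wiring_cost


@dataclass
class ObjectiveSpec:
    """Weight and normalizers of the cost-efficiency objective."""

    alpha: float
    lp_max: float = 1.0
    lg_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lp_max <= 0 or self.lg_max <= 0:
            raise ValueError("normalizers must be positive")


@dataclass
class AnnealSchedule:
    """Annealing protocol parameters.

    ``T0=None`` triggers calibration: T0 is set so that ~50% of uphill
    moves in a 200-swap probe from the initial state would be accepted,
    which places the few effective levels of the factorial quench inside
    the temperature window where escaping local optima still matters.
    ``min_levels`` keeps the quench from terminating during the hot phase,
    where the best objective can stagnate for a level by chance; by level
    ~12 the factorial schedule has already cooled T below T0/10^7.
    """

    T0: float | None = None
    steps_per_level: int = 1000
    tol: float = 1e-5
    max_levels: int = 10_000
    min_levels: int = 12


@dataclass
class AnnealResult:
    A: np.ndarray
    L: float
    lp: float
    lg: float
    T0: float
    n_levels: int
    accept_rate: float
    converged: bool


@dataclass
class ReconstructionEnsemble:
    """Link frequencies across realizations and the thresholded consensus."""

    realizations: list[np.ndarray]
    P: np.ndarray
    P_T: float
    A_recon: np.ndarray
    K_target: int

    @property
    def K_achieved(self) -> int:
        return int(self.A_recon.sum())


def _lg_of(A: np.ndarray) -> tuple[float, bool]:
    """Graph length and a strong-connectivity flag from one BFS sweep."""
    dist = hop_distances(A)
    eg = efficiency_from_dist(dist)
    connected = not np.isinf(dist).any()
    if eg == 0.0:
        return math.inf, connected
    return 1.0 / eg, connected


def objective(A: np.ndarray, D: np.ndarray, spec: ObjectiveSpec) -> float:
    """Evaluate L = (1-alpha) l_g/lg_max + alpha l_p/lp_max.

    Disconnected networks are penalized through the efficiency convention
    (unreachable pairs contribute 0 to e_g), keeping L finite whenever any
    pair is reachable.
    """
    lp = wiring_cost(A, D)
    lg, _ = _lg_of(A)
    return (1.0 - spec.alpha) * lg / spec.lg_max + spec.alpha * lp / spec.lp_max


def _propose_swap(edges: np.ndarray, A: np.ndarray,
                  rng: np.random.Generator) -> tuple | None:
    """Pick two directed links and propose the degree-preserving exchange
    (s1->t1, s2->t2) => (s1->t2, s2->t1); None when invalid."""
    k = len(edges)
    e1 = rng.integers(0, k)
    e2 = rng.integers(0, k)
    if e1 == e2:
        return None
    s1, t1 = edges[e1]
    s2, t2 = edges[e2]
    if s1 == t2 or s2 == t1 or t1 == t2 or s1 == s2:
        return None
    if A[t2, s1] or A[t1, s2]:
        return None
    return e1, e2, s1, t1, s2, t2


def _apply(A, edges, e1, e2, s1, t1, s2, t2) -> None:
    A[t1, s1] = 0
    A[t2, s2] = 0
    A[t2, s1] = 1
    A[t1, s2] = 1
    edges[e1] = (s1, t2)
    edges[e2] = (s2, t1)


def _revert(A, edges, e1, e2, s1, t1, s2, t2) -> None:
    A[t2, s1] = 0
    A[t1, s2] = 0
    A[t1, s1] = 1
    A[t2, s2] = 1
    edges[e1] = (s1, t1)
    edges[e2] = (s2, t2)


def _calibrate_T0(A, edges, D, spec, rng, target=0.5, n_probe=200) -> float:
    """T0 such that an average uphill move is accepted with prob ~target."""
    need_lg = spec.alpha < 1.0
    lp = wiring_cost(A, D)
    lg, _ = _lg_of(A) if need_lg else (0.0, True)
    L0 = (1 - spec.alpha) * lg / spec.lg_max + spec.alpha * lp / spec.lp_max
    ups = []
    tried = 0
    while len(ups) < n_probe and tried < 20 * n_probe:
        tried += 1
        prop = _propose_swap(edges, A, rng)
        if prop is None:
            continue
        e1, e2, s1, t1, s2, t2 = prop
        dlp = (D[t2, s1] + D[t1, s2] - D[t1, s1] - D[t2, s2])
        _apply(A, edges, e1, e2, s1, t1, s2, t2)
        if need_lg:
            lg_new, _ = _lg_of(A)
        else:
            lg_new = 0.0
        L1 = ((1 - spec.alpha) * lg_new / spec.lg_max
              + spec.alpha * (lp + dlp) / spec.lp_max)
        _revert(A, edges, e1, e2, s1, t1, s2, t2)
        if L1 > L0:
            ups.append(L1 - L0)
    if not ups:
        return 1.0
    return float(np.mean(ups) / (-math.log(target)))


def anneal(
    net: SpatialNetwork | np.ndarray,
    D: np.ndarray,
    spec: ObjectiveSpec,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | None = None,
    A_init: np.ndarray | None = None,
) -> AnnealResult:
    """Minimize the cost-efficiency objective under fixed degrees.

    Starts from a degree-preserving randomization of the input network
    (``A_init`` overrides), performs Metropolis-accepted double-edge swaps
    with the quench schedule, and returns the best state seen.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(rng)
    A_real = (net.A if isinstance(net, SpatialNetwork) else np.asarray(net))
    if A_init is None:
        A = None
        for _ in range(50):
            cand = randomize_preserving_degrees(A_real, 10, rng)
            if is_strongly_connected(cand):
                A = cand
                break
        if A is None:  # fall back to the real network itself
            A = A_real.copy().astype(np.int8)
    else:
        A = np.asarray(A_init).copy().astype(np.int8)
    tgt, src = np.nonzero(A)
    edges = np.column_stack([src, tgt])

    alpha = spec.alpha
    need_lg = alpha < 1.0
    T0 = schedule.T0
    if T0 is None:
        T0 = _calibrate_T0(A, edges, D, spec, rng)

    lp = wiring_cost(A, D)
    lg, _ = _lg_of(A)
    L = (1 - alpha) * lg / spec.lg_max + alpha * lp / spec.lp_max
    best_A = A.copy()
    best = (L, lp, lg)

    T = T0
    divisor = 1
    n_accept = 0
    n_counted = 0
    converged = False
    level = 0
    for level in range(1, schedule.max_levels + 1):
        best_before = best[0]
        for _ in range(schedule.steps_per_level):
            prop = _propose_swap(edges, A, rng)
            if prop is None:
                continue
            e1, e2, s1, t1, s2, t2 = prop
            dlp = D[t2, s1] + D[t1, s2] - D[t1, s1] - D[t2, s2]
            if need_lg:
                _apply(A, edges, e1, e2, s1, t1, s2, t2)
                lg_new, connected = _lg_of(A)
                if not connected:
                    # disconnected candidate: discard, do not count
                    _revert(A, edges, e1, e2, s1, t1, s2, t2)
                    continue
                L_new = ((1 - alpha) * lg_new / spec.lg_max
                         + alpha * (lp + dlp) / spec.lp_max)
                dL = L_new - L
                n_counted += 1
                if dL < 0 or rng.random() < math.exp(-dL / T):
                    n_accept += 1
                    L, lp, lg = L_new, lp + dlp, lg_new
                    if L < best[0]:
                        best = (L, lp, lg)
                        best_A[:] = A
                else:
                    _revert(A, edges, e1, e2, s1, t1, s2, t2)
            else:
                dL = alpha * dlp / spec.lp_max
                n_counted += 1
                if dL < 0 or rng.random() < math.exp(-dL / T):
                    _apply(A, edges, e1, e2, s1, t1, s2, t2)
                    if not is_strongly_connected(A):
                        _revert(A, edges, e1, e2, s1, t1, s2, t2)
                        n_counted -= 1
                        continue
                    n_accept += 1
                    L, lp = L + dL, lp + dlp
                    if L < best[0]:
                        best = (L, lp, lg)
                        best_A[:] = A
        if (level >= schedule.min_levels
                and best_before - best[0] <= schedule.tol):
            converged = True
            break
        T = T / divisor
        divisor += 1

    L_best, lp_best, lg_best = best
    if not need_lg:
        lg_best, _ = _lg_of(best_A)
    return AnnealResult(
        A=best_A, L=L_best, lp=lp_best, lg=lg_best, T0=T0, n_levels=level,
        accept_rate=(n_accept / n_counted if n_counted else 0.0),
        converged=converged,
    )


def calibrate_normalizers(
    net: SpatialNetwork,
    D: np.ndarray,
    schedule: AnnealSchedule | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, dict]:
    """Obtain lp_max and lg_max from the two single-factor optimizations.

    lp_max is the wiring cost of the pure-efficiency optimum (alpha = 0)
    and lg_max the graph length of the pure-cost optimum (alpha = 1).
    Returns (lp_max, lg_max, diagnostics) where diagnostics carry the
    endpoint ratios relative to the real network.
    """
    rng = np.random.default_rng(rng)
    from cortnet.metrics import graph_length

    lp_real = wiring_cost(net.A, D)
    lg_real, _ = graph_length(net.A)
    res0 = anneal(net, D, ObjectiveSpec(alpha=0.0), schedule, rng)
    res1 = anneal(net, D, ObjectiveSpec(alpha=1.0), schedule, rng)
    diag = {
        "lp_real": lp_real, "lg_real": lg_real,
        "lp_at_alpha0": res0.lp, "lg_at_alpha0": res0.lg,
        "lp_at_alpha1": res1.lp, "lg_at_alpha1": res1.lg,
        "lp_ratio_alpha1": res1.lp / lp_real,
        "lg_ratio_alpha0": res0.lg / lg_real,
        "lp_ratio_alpha0": res0.lp / lp_real,
        "lg_ratio_alpha1": res1.lg / lg_real,
    }
    return res0.lp, res1.lg, diag


def build_consensus(
    realizations: list[np.ndarray],
    K_target: int,
    D: np.ndarray | None = None,
) -> ReconstructionEnsemble:
    """Threshold the link-frequency matrix to the real link count.

    Links are ranked by occurrence frequency P_ij (descending); ties at the
    threshold frequency are broken by shorter Euclidean distance first
    (stable index order when D is not given). Links with P_ij = 0 are never
    added, so the achieved count is the closest possible to ``K_target``.
    """
    if not realizations:
        raise ValueError("need at least one realization")
    stack = np.stack([np.asarray(r) for r in realizations])
    P = stack.mean(axis=0)
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(off & (P > 0))
    p = P[ii, jj]
    d = (D[ii, jj] if D is not None else np.zeros_like(p))
    order = np.lexsort((np.arange(len(p)), d, -p))
    take = order[:K_target]
    A_recon = np.zeros_like(P, dtype=np.int8)
    A_recon[ii[take], jj[take]] = 1
    P_T = float(p[take].min()) if len(take) else 1.0
    return ReconstructionEnsemble(
        realizations=[np.asarray(r) for r in realizations],
        P=P, P_T=P_T, A_recon=A_recon, K_target=K_target,
    )


def alpha_sweep(
    net: SpatialNetwork,
    D: np.ndarray,
    alphas: list[float],
    n_realizations: int = 50,
    rng: np.random.Generator | None = None,
    schedule: AnnealSchedule | None = None,
    normalizers: tuple[float, float] | None = None,
) -> dict:
    """Consensus reconstruction and recovery rates across alpha values.

    Returns a dict with per-alpha ensembles and (r1, r0) curves plus the
    argmax-alpha by r1.
    """
    from cortnet.recovery import recovery_rates

    rng = np.random.default_rng(rng)
    if normalizers is None:
        lp_max, lg_max, diag = calibrate_normalizers(net, D, schedule, rng)
    else:
        lp_max, lg_max = normalizers
        diag = {}
    results = {}
    curves = []
    for alpha in alphas:
        spec = ObjectiveSpec(alpha=alpha, lp_max=lp_max, lg_max=lg_max)
        reals = [anneal(net, D, spec, schedule, rng).A
                 for _ in range(n_realizations)]
        ens = build_consensus(reals, net.n_links, D)
        r1, r0 = recovery_rates(net.A, ens.A_recon)
        results[alpha] = ens
        curves.append((alpha, r1, r0))
    best_alpha = max(curves, key=lambda t: t[1])[0]
    return {
        "ensembles": results,
        "curves": curves,
        "best_alpha": best_alpha,
        "lp_max": lp_max,
        "lg_max": lg_max,
        "calibration": diag,
    }
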