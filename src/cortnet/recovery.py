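"""Link- and region-level recovery statistics and LDC identification.

Recovery compares a model (reconstructed) adjacency with the real one:
``r1`` is the fraction of real links present in the model and ``r0`` the
fraction of real non-links (off-diagonal) absent from it.  Per-region
recovery pools a region's input and output links; its significance is a
Z-score against the coincident recovery of degree-preserving null
networks.  Regions whose links the best trade-off model recovers
significantly *worse* than chance (Z < -1.65, p < 0.05) concentrate
long-range connections and are flagged as long-distance connectors (LDCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cortnet.data import NullEnsemble, SpatialNetwork

Z_CRIT = 1.65  # one-sided 5% normal quantile


@dataclass
class WiringCostProfile:
    lp_node: np.ndarray        # per-area summed link distance, mm
    lp_ratio: np.ndarray       # lp_node / mean over null ensemble
    long_frac: np.ndarray      # per-area fraction of links > long_cut


def _check_pair(A_real, A_model):
    A_real = np.asarray(A_real)
    A_model = np.asarray(A_model)
    if A_real.shape != A_model.shape:
        raise ValueError("adjacency shapes differ")
    return A_real.astype(bool), A_model.astype(bool)


def recovery_rates(A_real: np.ndarray, A_model: np.ndarray) -> tuple[float, float]:
    """Global recovery rates (r1, r0) of links and non-links."""
    A_real, A_model = _check_pair(A_real, A_model)
    off = ~np.eye(A_real.shape[0], dtype=bool)
    ones = A_real & off
    zeros = ~A_real & off
    r1 = float((A_model & ones).sum() / ones.sum()) if ones.any() else np.nan
    r0 = float((~A_model & zeros).sum() / zeros.sum()) if zeros.any() else np.nan
    return r1, r0


def binned_recovery(
    A_real: np.ndarray,
    A_model: np.ndarray,
    D: np.ndarray,
    bin_width: float = 5.0,
) -> dict:
    """Recovery rates within Euclidean-distance bins.

    Returns bin edges plus per-bin (r1, r0); bins with no real links (or no
    real non-links) report NaN for the corresponding rate.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    A_real, A_model = _check_pair(A_real, A_model)
    off = ~np.eye(A_real.shape[0], dtype=bool)
    d = np.asarray(D)[off]
    real = A_real[off]
    model = A_model[off]
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    idx = np.digitize(d, edges) - 1
    r1 = np.full(len(edges) - 1, np.nan)
    r0 = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        m = idx == b
        ones = m & real
        zeros = m & ~real
        if ones.any():
            r1[b] = (model & ones).sum() / ones.sum()
        if zeros.any():
            r0[b] = (~model & zeros).sum() / zeros.sum()
    return {"edges": edges, "r1": r1, "r0": r0}


def node_recovery(A_real: np.ndarray, A_model: np.ndarray) -> np.ndarray:
    """Per-area recovery of pooled input+output links.

    Areas without any link in the real network get NaN.
    """
    A_real, A_model = _check_pair(A_real, A_model)
    hit = A_real & A_model
    k = A_real.sum(0) + A_real.sum(1)
    got = hit.sum(0) + hit.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(k > 0, got / np.maximum(k, 1), np.nan)
    return R


def node_zscores(
    A_real: np.ndarray,
    A_model: np.ndarray,
    null: NullEnsemble,
) -> np.ndarray:
    """Z-score of per-area recovery against coincident recovery in nulls.

    For each null member the same pooled input+output overlap with the real
    links is computed; Z(i) = (R_model(i) - mean_null(i)) / std_null(i).
    Areas with zero null variance get NaN.
    """
    R = node_recovery(A_real, A_model)
    null_R = np.stack([node_recovery(A_real, m) for m in null.members])
    mu = null_R.mean(axis=0)
    sd = null_R.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (R - mu) / sd, np.nan)
    return Z


def identify_ldcs(
    Z: np.ndarray,
    total_degree: np.ndarray,
    degree_cut: float = 20.0,
    extended_candidates: np.ndarray | list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Core and extended long-distance connector sets.

    Core: areas recovered significantly worse than chance (Z < -1.65).
    Extended: areas with insignificant recovery (|Z| < 1.65) and
    intermediate-to-large total degree (>= ``degree_cut``); when
    ``extended_candidates`` (area indices) is given, the extended set is
    restricted to it.  Returns (core_idx, extended_idx).
    """
    Z = np.asarray(Z, dtype=float)
    deg = np.asarray(total_degree)
    core = np.flatnonzero(Z < -Z_CRIT)
    ext_mask = (np.abs(Z) < Z_CRIT) & (deg >= degree_cut)
    ext = np.flatnonzero(ext_mask)
    if extended_candidates is not None:
        ext = np.intersect1d(ext, np.asarray(extended_candidates))
    ext = np.setdiff1d(ext, core)
    return core, ext


def links_involving(A: np.ndarray, node_set) -> int:
    """Number of directed links with either endpoint in ``node_set``
    (each directed link counted once)."""
    A = np.asarray(A, dtype=bool)
    mask = np.zeros(A.shape[0], dtype=bool)
    mask[np.asarray(list(node_set), dtype=int)] = True
    involve = mask[:, None] | mask[None, :]
    return int((A & involve).sum())


def long_link_share(
    A: np.ndarray,
    D: np.ndarray,
    node_set,
    long_cut: float = 30.0,
) -> float:
    """Fraction of all links longer than ``long_cut`` that touch the set."""
    A = np.asarray(A, dtype=bool)
    long_links = A & (np.asarray(D) > long_cut)
    total = long_links.sum()
    if total == 0:
        return np.nan
    mask = np.zeros(A.shape[0], dtype=bool)
    mask[np.asarray(list(node_set), dtype=int)] = True
    involve = mask[:, None] | mask[None, :]
    return float((long_links & involve).sum() / total)


def wiring_cost_profile(
    net: SpatialNetwork,
    D: np.ndarray,
    null: NullEnsemble,
    long_cut: float = 30.0,
) -> WiringCostProfile:
    """Per-area wiring cost, its ratio to the null mean, and the fraction
    of each area's links longer than ``long_cut``."""
    A = net.A.astype(bool)
    D = np.asarray(D)

    def node_lp(M):
        M = np.asarray(M, dtype=bool)
        return (M * D).sum(0) + (M * D).sum(1)

    lp = node_lp(A)
    null_lp = np.stack([node_lp(m) for m in null.members]).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(null_lp > 0, lp / np.maximum(null_lp, 1e-300), np.nan)
    k = A.sum(0) + A.sum(1)
    long_links = A & (D > long_cut)
    n_long = long_links.sum(0) + long_links.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        long_frac = np.where(k > 0, n_long / np.maximum(k, 1), np.nan)
    return WiringCostProfile(lp_node=lp, lp_ratio=ratio, long_frac=long_frac)
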