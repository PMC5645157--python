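"""Data model and I/O for spatially embedded directed cortical networks.

File dialects match the plain-text supplements the analysis was designed
around: a whitespace-delimited 0/1 adjacency matrix (columns = source
areas, rows = target areas), a 3-column coordinate table in millimetres in
the same area order, and an optional side-car label map assigning each area
to one of five functional systems (visual V, somatosensory S, motor M,
temporal T, frontal F) or UNKNOWN.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

SYSTEMS = ("V", "S", "M", "T", "F")
UNKNOWN = "UNKNOWN"

_LABEL_ALIASES = {
    "V": "V", "VISUAL": "V",
    "S": "S", "SOMATOSENSORY": "S",
    "M": "M", "MOTOR": "M",
    "T": "T", "TEMPORAL": "T",
    "F": "F", "FRONTAL": "F",
    UNKNOWN: UNKNOWN,
}


@dataclass
class SpatialNetwork:
    """A directed binary graph with 3-D node coordinates and system labels.

    ``A[i, j] == 1`` means a projection from area ``j`` to area ``i``.
    """

    area_ids: list[str]
    coords: np.ndarray          # (N, 3), mm
    A: np.ndarray               # (N, N), int8 in {0, 1}
    system: np.ndarray = field(default=None)  # (N,) of str

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.area_ids)
        if self.A.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match {n} areas")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} areas")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diagonal(self.A).any():
            raise ValueError("self-connections are not allowed")
        self.A = self.A.astype(np.int8)
        if self.system is None:
            self.system = np.array([UNKNOWN] * n)
        else:
            self.system = np.asarray(self.system, dtype=object)
            if self.system.shape != (n,):
                raise ValueError("system labels must match area count")
            bad = set(self.system) - set(SYSTEMS) - {UNKNOWN}
            if bad:
                raise ValueError(f"unknown system labels: {sorted(bad)}")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_links(self) -> int:
        return int(self.A.sum())

    def total_degrees(self) -> np.ndarray:
        """In-degree + out-degree per area."""
        return self.A.sum(axis=1) + self.A.sum(axis=0)


@dataclass
class NullEnsemble:
    """Degree-preserving randomizations of a source network."""

    members: list[np.ndarray]

    @property
    def n(self) -> int:
        return len(self.members)


def _read_labels(path: str | Path, n: int) -> tuple[list[str], np.ndarray]:
    """Label map: YAML mapping or 2-column CSV/whitespace (name, system)."""
    path = Path(path)
    names: list[str] = []
    labels: list[str] = []
    if path.suffix in (".yml", ".yaml"):
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ValueError("label YAML must be a name -> system mapping")
        for name, lab in mapping.items():
            names.append(str(name))
            labels.append(str(lab))
    else:
        with open(path, newline="") as fh:
            sample = fh.read()
        dialect_delim = "," if "," in sample.splitlines()[0] else None
        for line in sample.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = (line.split(",") if dialect_delim else line.split())
            if len(parts) != 2:
                raise ValueError(f"bad label line: {line!r}")
            names.append(parts[0].strip())
            labels.append(parts[1].strip())
    if len(names) != n:
        raise ValueError(
            f"label file has {len(names)} rows but network has {n} areas")
    canon = []
    for lab in labels:
        key = lab.strip().upper()
        if key not in _LABEL_ALIASES:
            raise ValueError(f"unknown system label {lab!r}")
        canon.append(_LABEL_ALIASES[key])
    return names, np.array(canon, dtype=object)


def read_network(
    adjacency_path: str | Path,
    coords_path: str | Path,
    labels_path: str | Path | None = None,
) -> SpatialNetwork:
    """Load a network from adjacency + coordinate (+ optional label) files.

    The adjacency file is a whitespace-delimited square 0/1 matrix with
    columns as sources and rows as targets; the coordinate file carries one
    ``x y z`` triple (mm) per area in matching row order.
    """
    A = np.loadtxt(adjacency_path)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency matrix is not square: {A.shape}")
    coords = np.loadtxt(coords_path, dtype=float)
    coords = np.atleast_2d(coords)
    if coords.shape[0] != A.shape[0]:
        raise ValueError(
            f"coordinate rows ({coords.shape[0]}) do not match "
            f"adjacency size ({A.shape[0]})")
    if coords.shape[1] != 3:
        raise ValueError("coordinate file must have exactly 3 columns")
    n = A.shape[0]
    names = [f"area{i:03d}" for i in range(n)]
    system = None
    if labels_path is not None:
        names, system = _read_labels(labels_path, n)
    return SpatialNetwork(area_ids=names, coords=coords, A=A, system=system)


def write_network(net: SpatialNetwork, out_dir: str | Path,
                  prefix: str = "network") -> dict[str, Path]:
    """Write adjacency / coordinates / labels in the same plain-text dialect
    that :func:`read_network` reads; round-trips bit-exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adj = out_dir / f"{prefix}_adjacency.txt"
    coo = out_dir / f"{prefix}_coords.txt"
    lab = out_dir / f"{prefix}_labels.csv"
    np.savetxt(adj, net.A, fmt="%d")
    np.savetxt(coo, net.coords, fmt="%.6f")
    with open(lab, "w", newline="") as fh:
        writer = csv.writer(fh)
        for name, system in zip(net.area_ids, net.system):
            writer.writerow([name, system])
    return {"adjacency": adj, "coords": coo, "labels": lab}


def distance_matrix(net: SpatialNetwork) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between area coordinates."""
    return cdist(net.coords, net.coords)


def _edges_of(A: np.ndarray) -> np.ndarray:
    """Directed edges as (source, target) pairs; A[t, s] == 1."""
    tgt, src = np.nonzero(A)
    return np.column_stack([src, tgt])


def randomize_preserving_degrees(
    net: SpatialNetwork | np.ndarray,
    n_swap_per_link: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Degree-preserving randomization by directed double-edge swaps.

    Two random directed links (s1 -> t1), (s2 -> t2) are exchanged to
    (s1 -> t2), (s2 -> t1) whenever this creates neither a self-loop nor a
    duplicate link; ``n_swap_per_link * K`` swaps are attempted.  In- and
    out-degree sequences are conserved exactly.
    """
    if n_swap_per_link < 1:
        raise ValueError("n_swap_per_link must be >= 1")
    rng = np.random.default_rng(rng)
    A = (net.A if isinstance(net, SpatialNetwork) else np.asarray(net)).copy()
    A = A.astype(np.int8)
    edges = _edges_of(A)
    k = len(edges)
    if k < 2:
        return A
    attempts = n_swap_per_link * k
    idx = rng.integers(0, k, size=(attempts, 2))
    for e1, e2 in idx:
        if e1 == e2:
            continue
        s1, t1 = edges[e1]
        s2, t2 = edges[e2]
        if s1 == t2 or s2 == t1:
            continue
        if A[t2, s1] or A[t1, s2]:
            continue
        A[t1, s1] = 0
        A[t2, s2] = 0
        A[t2, s1] = 1
        A[t1, s2] = 1
        edges[e1] = (s1, t2)
        edges[e2] = (s2, t1)
    return A


def make_null_ensemble(
    net: SpatialNetwork | np.ndarray,
    n: int = 100,
    rng: np.random.Generator | None = None,
    n_swap_per_link: int = 10,
) -> NullEnsemble:
    """Ensemble of ``n`` independent degree-preserving randomizations."""
    if n < 2:
        raise ValueError("ensemble size must be >= 2")
    rng = np.random.default_rng(rng)
    members = [
        randomize_preserving_degrees(net, n_swap_per_link, rng)
        for _ in range(n)
    ]
    return NullEnsemble(members=members)
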