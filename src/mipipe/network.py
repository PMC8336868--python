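"""Pearson functional connectivity of trial-block ERPs and graph indicators.

A trial-block ERP (channels x samples) yields a symmetric channel-by-
channel Pearson correlation matrix per analysis window (task [0, 1) s or
rest [-1, 0) s).  Three indicator families read the brain network at
increasing scale:

* node degree      — sum of signed correlation weights at one channel;
* regional degree  — sum of edge weights inside a channel set (left
  hemisphere LnL, right hemisphere LnR) or across hemispheres excluding
  the midline (EX);
* transitivity     — global clustering 3*G_tri / (3*G_tri + G_open) of
  the graph binarized at a correlation threshold (0.6 by default, signed
  comparison: strong negative correlations do not create edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .montage import Montage, standard_montage
from .preprocessing import TrialBlockERP, bandpass, make_trial_blocks, FIVE_BAND_GRID
from .recording import EpochedRecording, select_trials

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6

#: single-node report targets by imagery side (contralateral set first)
TARGET_NODES = {
    "left": {"contra": ("C4", "O2", "Fp2"), "ipsi": ("C3", "O1", "Fp1")},
    "right": {"contra": ("C3", "O1", "Fp1"), "ipsi": ("C4", "O2", "Fp2")},
}
ALL_TARGET_NODES = ("C3", "C4", "Fp1", "Fp2", "O1", "O2")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel Pearson matrix with block provenance."""

    values: np.ndarray
    channels: tuple[str, ...]
    window_role: str
    session: int = 0
    day: int = 1
    block_index: int = 0
    task_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigurationError("connectivity matrix must be square")
        if v.shape[0] != len(self.channels):
            raise ConfigurationError("matrix size must match channel count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ConfigurationError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ConfigurationError("connectivity diagonal must be 1")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ConfigurationError("correlations must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    def index(self, label: str) -> int:
        return self.channels.index(label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channels,
                            columns=self.channels)


@dataclass
class BinaryGraph:
    """Undirected unweighted graph from thresholded connectivity."""

    adjacency: np.ndarray
    channels: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ConfigurationError("adjacency must be symmetric, zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ConfigurationError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int64)

    def to_edge_list(self) -> pd.DataFrame:
        """Edges as a two-column frame (each undirected edge once)."""
        rows = [
            {"source": self.channels[i], "target": self.channels[j]}
            for i, j in zip(*np.nonzero(np.triu(self.adjacency, 1)))
        ]
        return pd.DataFrame(rows, columns=["source", "target"])


def pearson_connectivity(block: TrialBlockERP, window_role: str = "task"
                         ) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over the selected window's samples.

    Channels with zero variance in the window are flagged with a warning
    and contribute zero-weight edges (diagonal stays 1).
    """
    window = block.window_slice(window_role)
    if window.shape[1] < 3:
        raise ConfigurationError("window must contain at least 3 samples")
    sd = window.std(axis=1)
    # flatness is judged relative to the channel's amplitude scale, since a
    # numerically constant channel can carry an O(1e-14) rounding std
    scale = np.maximum(np.abs(window).max(axis=1), 1.0)
    flat = sd <= 1e-12 * scale
    if flat.any():
        labels = [c for c, f in zip(block.channels, flat) if f]
        logger.warning("zero-variance channel(s) %s: edges set to 0", labels)
        rho = np.eye(len(block.channels))
        ok = ~flat
        if ok.sum() >= 2:
            rho[np.ix_(ok, ok)] = np.corrcoef(window[ok])
    else:
        rho = np.corrcoef(window)
    np.fill_diagonal(rho, 1.0)
    return ConnectivityMatrix(
        values=rho, channels=tuple(block.channels), window_role=window_role,
        session=block.session, day=block.day, block_index=block.block_index,
        task_label=block.task_label,
    )


def node_degree(conn: ConnectivityMatrix, node: str) -> float:
    """Weighted degree: sum of signed correlation weights at ``node``."""
    i = conn.index(node)
    return float(conn.values[i].sum() - conn.values[i, i])


def node_degrees(conn: ConnectivityMatrix) -> np.ndarray:
    return conn.values.sum(axis=1) - np.diag(conn.values)


def region_degree(conn: ConnectivityMatrix, region) -> float:
    """Sum of edge weights over unordered channel pairs inside ``region``."""
    labels = [lb for lb in region]
    if len(labels) < 2:
        raise ConfigurationError("region needs at least 2 nodes")
    idx = [conn.index(lb) for lb in labels]
    total = 0.0
    for a, b in combinations(idx, 2):
        total += conn.values[a, b]
    return float(total)


def ex_degree(conn: ConnectivityMatrix, montage: Montage) -> float:
    """Cross-hemisphere edge-weight sum, midline channels excluded."""
    left = [conn.index(c) for c in montage.channels if c in montage.left_set]
    right = [conn.index(c) for c in montage.channels if c in montage.right_set]
    return float(conn.values[np.ix_(left, right)].sum())


def binarize(conn: ConnectivityMatrix, threshold: float = DEFAULT_THRESHOLD,
             use_absolute: bool = False) -> BinaryGraph:
    """Edges where rho >= threshold (or |rho| with ``use_absolute``)."""
    if not (-1.0 < threshold < 1.0):
        raise ConfigurationError("threshold must lie strictly inside (-1, 1)")
    values = np.abs(conn.values) if use_absolute else conn.values
    adjacency = (values >= threshold).astype(np.int64)
    np.fill_diagonal(adjacency, 0)
    return BinaryGraph(adjacency=adjacency, channels=conn.channels,
                       threshold=threshold)


def transitivity(graph: BinaryGraph, node_subset=None) -> float:
    """Global clustering: 3*triangles / connected triples on a subgraph.

    Counted in integer arithmetic (trace(A^3)/6 triangles, sum of
    k(k-1)/2 connected triples); returns 0.0 when the subgraph has no
    connected triple.
    """
    if node_subset is None:
        a = graph.adjacency
    else:
        idx = [graph.channels.index(lb) for lb in node_subset]
        if len(idx) < 3:
            raise ConfigurationError("node subset needs at least 3 nodes")
        a = graph.adjacency[np.ix_(idx, idx)]
    if a.shape[0] < 3:
        raise ConfigurationError("graph needs at least 3 nodes")
    triangles = int(np.trace(a @ a @ a)) // 6
    k = a.sum(axis=1)
    triples = int((k * (k - 1)).sum()) // 2
    if triples == 0:
        return 0.0
    return 3.0 * triangles / triples


@dataclass
class NetworkMetrics:
    """All indicators of one trial-block at one analysis window."""

    window_role: str
    node_degree: dict[str, float]
    lnl: float
    lnr: float
    ex: float
    clustering_all: float
    clustering_left: float
    clustering_right: float
    session: int = 0
    day: int = 1
    block_index: int = 0
    task_label: str = ""


def network_metrics(block: TrialBlockERP, montage: Montage | None = None,
                    threshold: float = DEFAULT_THRESHOLD,
                    use_absolute: bool = False) -> dict[str, NetworkMetrics]:
    """Node / hemisphere / whole-brain indicators for both windows."""
    montage = montage or standard_montage()
    left = [c for c in montage.channels if c in montage.left_set]
    right = [c for c in montage.channels if c in montage.right_set]
    out = {}
    for role in ("task", "rest"):
        conn = pearson_connectivity(block, role)
        graph = binarize(conn, threshold, use_absolute)
        degrees = node_degrees(conn)
        out[role] = NetworkMetrics(
            window_role=role,
            node_degree={c: float(d) for c, d in zip(conn.channels, degrees)},
            lnl=region_degree(conn, left),
            lnr=region_degree(conn, right),
            ex=ex_degree(conn, montage),
            clustering_all=transitivity(graph),
            clustering_left=transitivity(graph, left),
            clustering_right=transitivity(graph, right),
            session=block.session, day=block.day,
            block_index=block.block_index, task_label=block.task_label,
        )
    return out


def metrics_table(blocks: list[TrialBlockERP], montage: Montage | None = None,
                  threshold: float = DEFAULT_THRESHOLD,
                  use_absolute: bool = False) -> pd.DataFrame:
    """Tidy indicator table: one row per block x window x indicator."""
    montage = montage or standard_montage()
    rows = []
    for blk in blocks:
        for role, m in network_metrics(blk, montage, threshold,
                                       use_absolute).items():
            base = {"day": m.day, "session": m.session,
                    "task_label": m.task_label, "block": m.block_index,
                    "start_trial": blk.start_trial, "window_role": role}
            scalars = {
                "lnl": m.lnl, "lnr": m.lnr, "ex": m.ex,
                "clustering_all": m.clustering_all,
                "clustering_left": m.clustering_left,
                "clustering_right": m.clustering_right,
                "mean_degree": float(np.mean(list(m.node_degree.values()))),
                "mean_target_degree": float(np.mean(
                    [m.node_degree[c] for c in ALL_TARGET_NODES])),
            }
            for ch, d in m.node_degree.items():
                scalars[f"degree_{ch}"] = d
            for name, value in scalars.items():
                rows.append({**base, "indicator": name, "value": value})
    return pd.DataFrame(rows)


def band_scan_degree(rec: EpochedRecording, bands=FIVE_BAND_GRID,
                     montage: Montage | None = None, block_size: int = 20,
                     target_nodes=ALL_TARGET_NODES) -> pd.DataFrame:
    """Per-band, per-session mean node degree over the target nodes.

    For each screening band the non-hold trials are band-passed, blocked
    and correlated (task window); each block contributes the mean
    weighted degree over ``target_nodes``.  Returns the scan table with
    per-session mean, SD and block count.
    """
    montage = montage or standard_montage()
    nonhold = select_trials(rec, tasks=("left", "right"))
    rows = []
    for band in bands:
        filtered = bandpass(nonhold, band)
        blocks = make_trial_blocks(filtered, block_size)
        per_block = []
        for blk in blocks:
            conn = pearson_connectivity(blk, "task")
            degs = [node_degree(conn, c) for c in target_nodes]
            per_block.append((blk.session, float(np.mean(degs))))
        frame = pd.DataFrame(per_block, columns=["session", "degree"])
        for session, grp in frame.groupby("session"):
            rows.append({
                "band": band.label(), "lo": band.lo, "hi": band.hi,
                "session": int(session),
                "mean": float(grp["degree"].mean()),
                "sd": float(grp["degree"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "n_blocks": int(len(grp)),
            })
    return pd.DataFrame(rows)
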