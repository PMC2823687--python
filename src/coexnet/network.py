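"""Weighted co-expression network construction and module detection.

The network is unsigned: pairwise Pearson correlations are raised elementwise
to a soft-threshold power beta, giving continuous connection strengths
``a_ij = |r_ij|**beta`` instead of a hard edge cutoff.  Module detection
clusters probes by topological-overlap dissimilarity (average linkage) and
cuts the tree into branches of at least ``min_module_size`` probes; the
remainder is labelled grey.  Modules are named with the conventional ordered
color palette by decreasing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

#: WGCNA-conventional module colors, assigned by decreasing module size.
#: "grey" is reserved for unassigned probes.
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
GREY = "grey"


@dataclass(frozen=True)
class NetworkConfig:
    beta: int = 8
    connectivity_tau: float = 0.1
    min_module_size: int = 50
    cut_method: str = "dynamic_tree"  # or "static_height"
    cut_height: float = 0.99  # absolute top cut on the 1 - TOM scale
    static_height: float = 0.99  # absolute cut for cut_method="static_height"
    branch_cut_frac: float = 0.99  # recursive re-cut, fraction of branch range
    separation: float = 0.75  # accept a branch split only if mean cross-branch
    #   TOM < separation * min(mean within-branch TOM) of the parts
    tau_scaled: bool = True  # tau applies to k / max(k); False = raw k

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 <= self.connectivity_tau < 1.0:
            raise ValueError("connectivity_tau must be in [0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.cut_method not in ("dynamic_tree", "static_height"):
            raise ValueError(f"unknown cut_method {self.cut_method!r}")
        if not 0.0 < self.static_height <= 1.0:
            raise ValueError("static_height must be in (0, 1]")
        if not 0.0 < self.cut_height <= 1.0 or not 0.0 < self.branch_cut_frac <= 1.0:
            raise ValueError("cut_height and branch_cut_frac must be in (0, 1]")


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between probes (complete cases only)."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    if expr.isna().any().any():
        raise ValueError("missing values are not supported; impute or drop first")
    sd = expr.to_numpy().std(axis=1)
    bad = expr.index[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance probes have undefined correlations: {list(bad[:10])}")
    r = np.corrcoef(expr.to_numpy())
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def soft_threshold_adjacency(cor: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency ``a_ij = |r_ij|**beta``, zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(cor.to_numpy()) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Per-probe connectivity k_i = sum of connection strengths to others."""
    return pd.Series(adj.to_numpy().sum(axis=1), index=adj.index, name="k")


def filter_by_scaled_connectivity(
    expr: pd.DataFrame, adj: pd.DataFrame, tau: float, scaled: bool = True
) -> tuple[pd.DataFrame, list]:
    """Drop weakly connected probes: keep k_i / max(k) >= tau (or raw k >= tau).

    Module probes are densely interconnected, so this concentrates the
    clustering on candidate module members.  Returns the expression subset
    and the kept probe IDs; TOM should be recomputed on the subset.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must be in [0, 1)")
    k = connectivity(adj)
    kmax = float(k.max())
    if kmax == 0.0:
        raise ValueError("degenerate network: all connectivities are zero")
    score = k / kmax if scaled else k
    kept = list(k.index[score >= tau])
    log.info("connectivity filter kept %d of %d probes", len(kept), len(k))
    return expr.loc[kept], kept


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j,
    TOM_ii = 1.  Shared neighbours raise the overlap above the direct
    connection strength, making the measure robust to single spurious edges.
    """
    a = adj.to_numpy()
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _cut_tree(z: np.ndarray, n: int, height_frac: float, min_size: int) -> np.ndarray:
    """Cut a linkage at ``height_frac`` of the merge-height range; clusters
    below ``min_size`` go to 0 (grey)."""
    heights = z[:, 2]
    lo, hi = float(heights.min()), float(heights.max())
    cut = lo + height_frac * (hi - lo)
    labels = fcluster(z, t=cut, criterion="distance")
    out = np.zeros(n, dtype=int)
    nxt = 1
    for lab, size in pd.Series(labels).value_counts().items():
        if size >= min_size:
            out[labels == lab] = nxt
            nxt += 1
    return out


def detect_modules(
    tom: pd.DataFrame, cfg: NetworkConfig
) -> tuple[pd.Series, np.ndarray]:
    """Cluster probes on 1 - TOM and cut branches into color-labelled modules.

    Average-linkage hierarchical clustering, then dynamic branch
    decomposition: the dendrogram is first cut at the absolute height
    ``cut_height`` (default 0.99 — uncorrelated probes merge essentially at
    1, so they fragment and fall to grey), and each surviving branch is
    recursively re-cut within its own merge-height range.  A split is
    accepted only when the parts are topologically separated — the mean
    between-part TOM must fall below ``separation`` times the smallest mean
    within-part TOM — so coherent modules are never fragmented, while
    nested but distinct modules (for example two modules sharing a trait
    response) are pulled apart.  Sub-``min_module_size`` remnants go to
    "grey".  With ``cut_method="static_height"`` a single absolute-height
    cut is used instead.  Labels are colors by decreasing module size.
    Returns (assignment, linkage matrix).
    """
    cfg.validate()
    n = len(tom)
    probes = tom.index
    if n < cfg.min_module_size:
        log.warning("fewer probes (%d) than min_module_size; all grey", n)
        z = linkage(np.zeros(max(n * (n - 1) // 2, 1)), method="average") if n > 1 else np.empty((0, 4))
        return pd.Series(GREY, index=probes, name="module"), z

    d = 1.0 - tom.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize away rounding noise
    z = linkage(squareform(d, checks=False), method="average")

    if cfg.cut_method == "static_height":
        labels = fcluster(z, t=cfg.static_height, criterion="distance")
        raw = np.zeros(n, dtype=int)
        nxt = 1
        for lab, size in pd.Series(labels).value_counts().items():
            if size >= cfg.min_module_size:
                raw[labels == lab] = nxt
                nxt += 1
    else:
        tom_arr = tom.to_numpy()
        raw = np.zeros(n, dtype=int)
        counter = [0]
        for branch in _branches(z, n, cfg.cut_height, cfg.min_module_size):
            _decompose(branch, d, tom_arr, cfg, raw, counter)

    assignment = _color_labels(raw, probes)
    return assignment, z


def _branches(z: np.ndarray, n: int, cut_height: float, min_size: int) -> list[np.ndarray]:
    """Member index sets of all branches >= min_size below the absolute cut."""
    labels = fcluster(z, t=cut_height, criterion="distance")
    keep = [lab for lab, size in pd.Series(labels).value_counts().items() if size >= min_size]
    return [np.flatnonzero(labels == lab) for lab in keep]


def _mean_offdiag(tom: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    block = tom[np.ix_(rows, cols)]
    if rows is cols or np.array_equal(rows, cols):
        m = block.shape[0]
        return float((block.sum() - np.trace(block)) / (m * (m - 1)))
    return float(block.mean())


def _decompose(members: np.ndarray, d: np.ndarray, tom: np.ndarray,
               cfg: NetworkConfig, raw: np.ndarray, counter: list) -> None:
    """Recursively re-cut one branch; write accepted modules into ``raw``."""
    parts = []
    if members.size >= 2 * cfg.min_module_size:
        sub = d[np.ix_(members, members)]
        z = linkage(squareform(sub, checks=False), method="average")
        labels = _cut_tree(z, members.size, cfg.branch_cut_frac, cfg.min_module_size)
        parts = [members[labels == lab] for lab in np.unique(labels) if lab != 0]
    if len(parts) >= 2 and _separated(parts, tom, cfg.separation):
        for part in parts:
            _decompose(part, d, tom, cfg, raw, counter)
    else:
        counter[0] += 1
        raw[members] = counter[0]


def _separated(parts: list[np.ndarray], tom: np.ndarray, separation: float) -> bool:
    """True when every pair of parts has mean cross-TOM well below the
    smaller of the two mean within-TOMs."""
    within = [_mean_offdiag(tom, p, p) for p in parts]
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            cross = _mean_offdiag(tom, parts[i], parts[j])
            if cross >= separation * min(within[i], within[j]):
                return False
    return True


def _color_labels(raw: np.ndarray, probes: pd.Index) -> pd.Series:
    sizes = pd.Series(raw[raw > 0]).value_counts()
    # decreasing size; ties by first appearance for determinism
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    palette = {}
    for i, lab in enumerate(order):
        palette[lab] = COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module{i + 1}"
    labels = [palette.get(lab, GREY) if lab > 0 else GREY for lab in raw]
    return pd.Series(labels, index=probes, name="module")
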