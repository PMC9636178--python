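"""Lap-wise population-vector correlations and the Rewarded-cluster trace.

Each analyzed lap is summarized by a population vector: for every 5 cm bin
the mean dF/F of every R-defined place cell.  The lap-by-lap correlation
matrix averages, over positions, the Pearson correlation between the two
laps' cell vectors at that position.  To quantify transitions in the map,
k-means is run many times on the flattened lap vectors; on each run the
"Rewarded cluster" is the modal cluster of R laps, and each lap's
probability of belonging to it across runs traces when the map leaves and
returns to the rewarded configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .session import SessionRecord, BinningSpec
from .behavior import Lap
from .placefields import bin_activity


@dataclass
class PopulationVectorSet:
    """Laps x (cells * 40) matrix of per-lap, per-cell, per-bin mean dF/F,
    restricted to R-defined place cells; column blocks ordered by cell then
    bin."""

    matrix: np.ndarray
    lap_conditions: list[str]
    lap_indices: list[int]
    cells: list[int]
    n_bins: int = 40

    @property
    def n_laps(self) -> int:
        return self.matrix.shape[0]

    def tensor(self) -> np.ndarray:
        """View as laps x cells x bins."""
        return self.matrix.reshape(self.n_laps, len(self.cells), self.n_bins)


def build_population_vectors(session: SessionRecord, laps: list[Lap],
                             cells, spec: BinningSpec | None = None
                             ) -> PopulationVectorSet:
    """Assemble the lap-wise population-vector matrix for the given cells
    (typically the place cells defined in R) over the given laps."""
    spec = spec or BinningSpec()
    cells = list(cells)
    per_cell = []
    for cell in cells:
        rate_map = bin_activity(session, laps, cell, spec)
        per_cell.append(rate_map.matrix)           # L x 40
    tensor = np.stack(per_cell, axis=1)            # L x cells x 40
    return PopulationVectorSet(
        matrix=tensor.reshape(len(laps), -1),
        lap_conditions=[l.condition for l in laps],
        lap_indices=[l.lap_index for l in laps],
        cells=cells,
        n_bins=spec.n_bins,
    )


def pv_correlation_matrix(pv_set: PopulationVectorSet) -> np.ndarray:
    """L x L matrix of lap-pair population-vector correlations.

    Entry (i, j) averages, over the 40 positions, the Pearson correlation
    between lap i's and lap j's cell vectors at that position; positions
    where either lap's cell vector has zero variance are skipped for that
    pair (the skip count is warned once).  Symmetric with unit diagonal.
    """
    tensor = pv_set.tensor()               # L x C x B
    L, C, B = tensor.shape
    if L < 2:
        raise ValueError("need at least 2 laps")
    # center/normalize cell vectors per lap per position
    x = tensor - tensor.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1)       # L x B
    valid = norm > 0
    skipped = 0
    out = np.eye(L)
    for i in range(L):
        for j in range(i + 1, L):
            ok = valid[i] & valid[j]
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                skipped += B
                continue
            skipped += int(B - ok.sum())
            r = (x[i, :, ok] * x[j, :, ok]).sum(axis=1) \
                / (norm[i, ok] * norm[j, ok])
            out[i, j] = out[j, i] = r.mean()
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance position-vectors")
    return out


def choose_k_elbow(pv_set: PopulationVectorSet, k_range=range(2, 9),
                   fixed_k: int | None = None,
                   rng: np.random.Generator | None = None,
                   min_reduction: float = 0.2) -> int:
    """Elbow choice of k: the k with maximum second difference of the
    within-cluster sum of squares over ``k_range`` (the k=1 total sum of
    squares anchors the curve so an elbow at the smallest k is
    detectable).  When clustering barely reduces the WCSS — relative
    reduction below ``min_reduction`` at the first k, i.e. no real cluster
    structure — the elbow is flagged unstable and ``fixed_k`` (when given)
    is returned."""
    rng = rng or np.random.default_rng(0)
    ks = [k for k in k_range if k < pv_set.n_laps]
    X = pv_set.matrix
    wcss1 = float(((X - X.mean(axis=0)) ** 2).sum())
    wcss = [wcss1]
    for k in ks:
        km = KMeans(n_clusters=k, n_init=5,
                    random_state=int(rng.integers(2 ** 31)))
        km.fit(X)
        wcss.append(km.inertia_)
    wcss = np.asarray(wcss)
    all_ks = [1] + ks
    if wcss1 <= 0 or (wcss1 - wcss[1]) / wcss1 < min_reduction:
        warnings.warn("elbow unstable (no cluster structure); "
                      "falling back to fixed k")
        return fixed_k or ks[0]
    if len(all_ks) < 3:
        return fixed_k or ks[-1]
    curvature = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]
    return all_ks[1 + int(np.argmax(curvature))]


def rewarded_cluster_probability(pv_set: PopulationVectorSet, k: int = 3,
                                 n_runs: int = 1000,
                                 rng: np.random.Generator | None = None
                                 ) -> np.ndarray:
    """Per-lap probability of belonging to the Rewarded cluster.

    k-means is run ``n_runs`` times with fresh random initialization; each
    run's Rewarded cluster is the modal cluster of R laps (ties broken
    toward the larger cluster), and each lap's probability is the fraction
    of runs assigning it to that cluster.
    """
    rng = rng or np.random.default_rng(0)
    r_laps = np.asarray([c == "R" for c in pv_set.lap_conditions])
    if not r_laps.any():
        raise ValueError("no R laps in the population-vector set")
    X = pv_set.matrix
    k = min(k, pv_set.n_laps)
    counts = np.zeros(pv_set.n_laps)
    for _ in range(n_runs):
        km = KMeans(n_clusters=k, n_init=1, init="random",
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(X)
        r_counts = np.bincount(labels[r_laps], minlength=k)
        best = np.flatnonzero(r_counts == r_counts.max())
        if best.size > 1:   # tie: prefer the larger cluster overall
            sizes = np.bincount(labels, minlength=k)[best]
            best = best[np.argmax(sizes)]
        else:
            best = best[0]
        counts += labels == best
    return counts / n_runs
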