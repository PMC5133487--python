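"""Batch self-organizing map on a rectangular grid.

A SOM quantizes the gene profiles onto a small grid of codebook vectors while
preserving topology: neighboring units hold similar profiles.  Training is
the classical batch scheme — every epoch each profile is assigned to its
best-matching unit (BMU, nearest codebook vector in Euclidean distance) and
each codebook vector is replaced by the neighborhood-weighted mean of all
profiles, with a Gaussian neighborhood on the grid whose radius shrinks
linearly over the epochs.  The codebook is initialized from a seeded random
sample of the input rows, so training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SOMTrainingParams", "SOMPatternModel", "train_som"]


@dataclass
class SOMTrainingParams:
    n_epochs: int = 100
    radius_start: float | None = None  # default max(rows, cols) / 2
    radius_end: float = 0.5
    seed: int = 0


@dataclass
class SOMPatternModel:
    """Trained SOM: grid geometry, codebook, and gene assignments.

    ``codebook`` is (rows*cols) x n with unit u at grid position
    (u // cols, u % cols).  ``assignments`` maps each gene id to its BMU
    (distance ties broken toward the lowest unit index).
    """

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray
    assignments: dict[str, int]
    training_params: SOMTrainingParams
    topology: str = "rectangular"
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def unit_sizes(self) -> np.ndarray:
        sizes = np.zeros(self.n_units, dtype=int)
        for u in self.assignments.values():
            sizes[u] += 1
        return sizes

    def members(self, unit: int) -> list[str]:
        return [g for g, u in self.assignments.items() if u == unit]


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _bmu(data: np.ndarray, codebook: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(data, codebook)
    bmu = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    return bmu, d[np.arange(len(data)), bmu]


def train_som(
    profiles: np.ndarray,
    gene_ids: list[str],
    grid: tuple[int, int] = (3, 3),
    params: SOMTrainingParams | None = None,
    rng: np.random.Generator | None = None,
) -> SOMPatternModel:
    """Train a batch SOM on a genes x n profile matrix.

    Fewer genes than grid units is allowed (units may end up empty); zero
    genes is an error.  The quantization error (mean BMU distance) is
    recorded per epoch in ``qe_history``.
    """
    data = np.asarray(profiles, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D matrix")
    if data.shape[1] < 2:
        raise ValueError("profiles need at least 2 coordinates")
    if len(gene_ids) != data.shape[0]:
        raise ValueError("gene_ids length must match number of profile rows")
    params = params or SOMTrainingParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    n_units = rows * cols
    coords = _grid_coords(rows, cols)
    grid_d2 = cdist(coords, coords) ** 2

    n_genes = data.shape[0]
    init_idx = rng.choice(n_genes, size=n_units, replace=n_genes < n_units)
    codebook = data[init_idx].copy()

    r0 = params.radius_start if params.radius_start is not None else max(rows, cols) / 2.0
    r1 = params.radius_end
    epochs = params.n_epochs
    qe_history: list[float] = []
    for e in range(epochs):
        frac = e / (epochs - 1) if epochs > 1 else 1.0
        radius = r0 + frac * (r1 - r0)
        bmu, dist = _bmu(data, codebook)
        qe_history.append(float(dist.mean()))
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))  # genes x units
        weight = h.sum(axis=0)
        num = h.T @ data
        nz = weight > 1e-12
        codebook[nz] = num[nz] / weight[nz, None]

    bmu, dist = _bmu(data, codebook)
    qe_history.append(float(dist.mean()))
    assignments = {g: int(u) for g, u in zip(gene_ids, bmu)}
    return SOMPatternModel(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook,
        assignments=assignments,
        training_params=params,
        qe_history=qe_history,
    )
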