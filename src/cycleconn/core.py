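"""Core containers shared across the package.

A *connectome* is a symmetric region-by-region matrix of functional
connectivity (Pearson correlations between regional BOLD signals, or
synthetic analogues thereof).  Throughout the package an edge is an
unordered region pair ``(i, j)`` with ``i < j``, and edge vectors flatten
the strict upper triangle in row-major order — the same order returned by
``numpy.triu_indices(n, 1)``.  This ordering is a package-wide total order:
every module that maps between matrices and edge vectors uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every session table must carry.
SESSION_COLUMNS = (
    "subject_id",
    "dataset_id",
    "session_id",
    "hc_use",
    "cycle_day",
    "e2",
    "p4",
    "mean_fd",
)


def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the canonical edge ordering for ``n_regions``."""
    return np.triu_indices(n_regions, k=1)


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs, ``n (n - 1) / 2``."""
    return n_regions * (n_regions - 1) // 2


@dataclass
class Connectome:
    """A symmetric connectivity matrix with ordered region labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} region labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10, equal_nan=True):
            raise ValueError("connectome matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def edge_vector(self) -> np.ndarray:
        """Strict upper triangle in canonical (row-major, i<j) order."""
        iu, ju = edge_index(self.n_regions)
        return self.matrix[iu, ju]


@dataclass
class Study:
    """A session table plus one connectome per session, in table order.

    ``sessions`` carries one row per scan session with the columns in
    :data:`SESSION_COLUMNS`; ``connectomes[k]`` belongs to ``sessions``
    row ``k``.  ``regions`` optionally maps regions to canonical
    functional networks (columns ``region_id``, ``region_name``,
    ``network_name``).
    """

    sessions: pd.DataFrame
    connectomes: list[Connectome]
    regions: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.sessions) != len(self.connectomes):
            raise ValueError(
                f"{len(self.sessions)} session rows but "
                f"{len(self.connectomes)} connectomes"
            )
        if self.connectomes:
            ref = self.connectomes[0].labels
            for c in self.connectomes[1:]:
                if c.labels != ref:
                    raise ValueError("region labels differ across sessions")
        self.sessions = self.sessions.reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return self.connectomes[0].labels

    @property
    def n_sessions(self) -> int:
        return len(self.connectomes)

    def edge_matrix(self) -> np.ndarray:
        """Sessions × edges matrix of edge vectors in canonical order."""
        return np.vstack([c.edge_vector for c in self.connectomes])

    def subset(self, mask) -> "Study":
        """New study restricted to the boolean/positional row selection."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Study(
            sessions=self.sessions.iloc[idx].reset_index(drop=True),
            connectomes=[self.connectomes[k] for k in idx],
            regions=self.regions,
        )
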