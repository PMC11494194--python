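"""Larval exchange between sites: fertilisation, dispersal, settlement.

A connectivity matrix M gives the probability that a larva released at
site j (column) settles at site i (row). Columns may sum to less than one;
the deficit is larvae advected out of the reef cluster and lost (or
settling elsewhere). Matrices from multiple spawning days/years are
averaged into a single mean matrix. Larvae supplied from outside the
cluster are distributed to a reef's sites in proportion to site area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "mean_connectivity",
    "fertilise",
    "disperse",
    "distribute_external",
    "settle",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Site-to-site larval transfer probabilities (columns = origin)."""

    site_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        n = len(self.site_ids)
        if M.shape != (n, n):
            raise ValueError("matrix must be square over site_ids")
        if np.any(M < 0) or np.any(M > 1):
            raise ValueError("connectivity entries must be probabilities in [0, 1]")
        colsums = M.sum(axis=0)
        bad = np.where(colsums > 1 + 1e-9)[0]
        if bad.size:
            raise ValueError(
                f"connectivity column sums exceed 1 for sites: "
                f"{[self.site_ids[i] for i in bad]}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def loss_fractions(self) -> np.ndarray:
        """Per-origin fraction of larvae lost outside the cluster."""
        return 1.0 - self.matrix.sum(axis=0)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ConnectivityMatrix":
        """Dense CSV layout: site-id index and columns."""
        ids = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != ids:
            raise ValueError("connectivity row and column site ids must match")
        return ConnectivityMatrix(site_ids=ids, matrix=df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.site_ids), columns=list(self.site_ids))


def mean_connectivity(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Average matrices across spawning days and years into one matrix."""
    if not matrices:
        raise ValueError("no matrices to average")
    ids = matrices[0].site_ids
    for m in matrices[1:]:
        if m.site_ids != ids:
            raise ValueError("all matrices must share the same site ids")
    stack = np.stack([m.matrix for m in matrices])
    return ConnectivityMatrix(site_ids=ids, matrix=stack.mean(axis=0))


def fertilise(eggs: np.ndarray, fertilisation_prob: float) -> np.ndarray:
    """Eggs -> larvae released, at a fixed fertilisation probability."""
    if not 0.0 <= fertilisation_prob <= 1.0:
        raise ValueError("fertilisation_prob must be in [0, 1]")
    eggs = np.asarray(eggs, dtype=float)
    if np.any(eggs < 0):
        raise ValueError("egg counts must be >= 0")
    return eggs * fertilisation_prob


def disperse(released: np.ndarray, M: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Transport released larvae across the cluster.

    Returns (arriving per site, larvae lost outside the cluster); mass
    balance released = arriving + lost holds exactly.
    """
    released = np.asarray(released, dtype=float)
    if released.size != M.n_sites:
        raise ValueError("released vector length must equal matrix dimension")
    arriving = M.matrix @ released
    lost = float(M.loss_fractions() @ released)
    return arriving, lost


def distribute_external(supply: float, site_areas: pd.Series) -> pd.Series:
    """Share a reef's external larval supply among its sites by area."""
    if len(site_areas) == 0:
        raise ValueError("reef has no sites")
    areas = site_areas.astype(float)
    if (areas <= 0).any():
        raise ValueError("site areas must be positive")
    return supply * areas / areas.sum()


def settle(arriving: np.ndarray, settlement_prob: float) -> np.ndarray:
    """Arriving larvae -> new settlers (added to the settler pool).

    Settlers enter the smallest size class the following year via the
    kernel's settler column (first-year post-settlement survival).
    """
    if not 0.0 <= settlement_prob <= 1.0:
        raise ValueError("settlement_prob must be in [0, 1]")
    arriving = np.asarray(arriving, dtype=float)
    return arriving * settlement_prob
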