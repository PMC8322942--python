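"""Weighted brain graph construction and its Laplacian.

The brain's axonal wiring is represented as a weighted, undirected graph with
one node per atlas region. Edge weights are tractography-derived: the number
of reconstructed fibers ``n_ij`` between regions ``i`` and ``j`` divided by
their mean fiber length ``l_ij``, so ``A_ij = n_ij / l_ij`` (units: fibers per
unit length). Diffusive transport of misfolded protein on this graph is
governed by the graph Laplacian ``L = D - A`` with degree matrix
``D_ii = sum_{j != i} A_ij``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "RegionTable",
    "BrainNetwork",
    "build_laplacian",
    "read_edge_list",
    "coarsen_network",
    "write_edge_list",
    "write_adjacency",
    "make_synthetic_connectome",
    "load_default_network",
]

_SYMMETRY_RTOL = 1e-10


@dataclass(frozen=True)
class RegionTable:
    """Atlas region lookup: names, hemisphere and cortical/subcortical flags.

    Region ids are the positions ``0..n-1`` in the three parallel tuples.
    """

    names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    is_cortical: np.ndarray  # bool, shape (n,)

    def __post_init__(self) -> None:
        flags = np.asarray(self.is_cortical, dtype=bool)
        object.__setattr__(self, "is_cortical", flags)
        if not (len(self.names) == len(self.hemisphere) == flags.size):
            raise DataError("region table columns have inconsistent lengths")
        if len(set(self.names)) != len(self.names):
            raise DataError("region names must be unique")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def cortical_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_cortical)

    def index(self, label: str | int) -> int:
        """Resolve a region reference (name or integer id) to its index."""
        if isinstance(label, (int, np.integer)):
            i = int(label)
            if not 0 <= i < self.n:
                raise DataError(f"region id {i} outside 0..{self.n - 1}")
            return i
        text = str(label).strip()
        try:
            return self.names.index(text)
        except ValueError:
            pass
        if text.isdigit():
            return self.index(int(text))
        raise DataError(f"unknown region label {text!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n),
                "name": self.names,
                "hemisphere": self.hemisphere,
                "is_cortical": self.is_cortical.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionTable":
        required = {"region_id", "name", "hemisphere", "is_cortical"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"region table missing columns: {sorted(missing)}")
        df = df.sort_values("region_id").reset_index(drop=True)
        ids = df["region_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(df))):
            raise DataError("region_id must be a contiguous 0-based range")
        return cls(
            names=tuple(str(x) for x in df["name"]),
            hemisphere=tuple(str(x) for x in df["hemisphere"]),
            is_cortical=df["is_cortical"].astype(bool).to_numpy(),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "RegionTable":
        return cls.from_frame(pd.read_csv(path, sep=None, engine="python"))


def build_laplacian(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and graph Laplacian ``L = D - A`` of a weighted graph.

    The input must be square, symmetric, nonnegative and zero on the diagonal.
    Row sums of ``L`` cancel exactly because ``D_ii`` is assembled from the
    same floating-point row sum it is subtracted against.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DataError(f"adjacency must be square, got shape {A.shape}")
    if np.any(A < 0):
        raise DataError("adjacency has negative weights")
    scale = max(float(np.abs(A).max()), 1.0)
    if np.max(np.abs(A - A.T)) > _SYMMETRY_RTOL * scale:
        raise DataError("adjacency is not symmetric")
    if np.any(np.diag(A) != 0):
        raise DataError("adjacency diagonal must be zero (no self-loops)")
    degree = np.diag(A.sum(axis=1))
    laplacian = degree - A
    return degree, laplacian


@dataclass(frozen=True)
class BrainNetwork:
    """Weighted undirected brain graph with precomputed degree and Laplacian.

    ``fiber_count`` / ``fiber_length`` keep the raw tractography quantities
    when the network was read from an edge list; they are needed to coarsen
    the graph and are ``None`` for networks built directly from an adjacency
    matrix.
    """

    regions: RegionTable
    adjacency: np.ndarray
    degree: np.ndarray = field(repr=False)
    laplacian: np.ndarray = field(repr=False)
    edge_count: int
    fiber_count: np.ndarray | None = field(default=None, repr=False)
    fiber_length: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.regions.n

    @classmethod
    def from_adjacency(
        cls,
        regions: RegionTable,
        adjacency: np.ndarray,
        fiber_count: np.ndarray | None = None,
        fiber_length: np.ndarray | None = None,
    ) -> "BrainNetwork":
        A = np.asarray(adjacency, dtype=float)
        if A.shape != (regions.n, regions.n):
            raise DataError(
                f"adjacency shape {A.shape} does not match region count {regions.n}"
            )
        degree, laplacian = build_laplacian(A)
        edge_count = int(np.count_nonzero(np.triu(A, k=1)))
        return cls(
            regions=regions,
            adjacency=A,
            degree=degree,
            laplacian=laplacian,
            edge_count=edge_count,
            fiber_count=fiber_count,
            fiber_length=fiber_length,
        )


def read_edge_list(path: str | Path, regions: RegionTable) -> BrainNetwork:
    """Build a :class:`BrainNetwork` from a delimited edge-list file.

    Expected columns: ``region_i, region_j, fiber_count, mean_fiber_length``
    (header required; comma or tab delimited, auto-detected). Region
    references may be names or integer ids. Each undirected edge must appear
    exactly once; the adjacency ``A_ij = n_ij / l_ij`` is symmetrized.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = ["region_i", "region_j", "fiber_count", "mean_fiber_length"]
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"edge list missing columns: {sorted(missing)}")
    n = regions.n
    counts = np.zeros((n, n))
    lengths = np.zeros((n, n))
    A = np.zeros((n, n))
    for row in df.itertuples(index=False):
        i = regions.index(getattr(row, "region_i"))
        j = regions.index(getattr(row, "region_j"))
        if i == j:
            raise DataError(f"self-edge on region {regions.names[i]!r}")
        length = float(getattr(row, "mean_fiber_length"))
        if not length > 0:
            raise DataError(
                f"nonpositive fiber length {length} on edge "
                f"({regions.names[i]}, {regions.names[j]})"
            )
        if A[i, j] != 0:
            raise DataError(
                f"duplicate edge ({regions.names[i]}, {regions.names[j]})"
            )
        w = float(getattr(row, "fiber_count")) / length
        A[i, j] = A[j, i] = w
        counts[i, j] = counts[j, i] = float(getattr(row, "fiber_count"))
        lengths[i, j] = lengths[j, i] = length
    return BrainNetwork.from_adjacency(
        regions, A, fiber_count=counts, fiber_length=lengths
    )


def coarsen_network(
    fine: BrainNetwork,
    node_to_region_map: Mapping[int | str, int],
    coarse_regions: RegionTable | None = None,
) -> BrainNetwork:
    """Aggregate a fine parcellation onto a coarser one.

    Fiber counts between two coarse regions are the *sums* of fine fiber
    counts crossing the group boundary; coarse mean fiber lengths are the
    fiber-count-weighted means of the fine lengths (preserving total tract
    mass). Edges internal to a coarse region are dropped. Every fine node
    must be mapped.
    """
    if fine.fiber_count is None or fine.fiber_length is None:
        raise DataError(
            "coarsening requires fiber counts and lengths "
            "(build the fine network with read_edge_list)"
        )
    mapping = np.full(fine.n, -1, dtype=int)
    for node, region in node_to_region_map.items():
        mapping[fine.regions.index(node)] = int(region)
    if np.any(mapping < 0):
        missing = [fine.regions.names[i] for i in np.flatnonzero(mapping < 0)]
        raise DataError(f"unmapped fine nodes: {missing}")
    m = int(mapping.max()) + 1
    if coarse_regions is None:
        coarse_regions = RegionTable(
            names=tuple(f"region_{k}" for k in range(m)),
            hemisphere=("unknown",) * m,
            is_cortical=np.ones(m, dtype=bool),
        )
    if coarse_regions.n != m:
        raise DataError(
            f"coarse region table has {coarse_regions.n} entries, map implies {m}"
        )
    counts = np.zeros((m, m))
    length_mass = np.zeros((m, m))  # sum of n_ij * l_ij per group pair
    iu, ju = np.triu_indices(fine.n, k=1)
    for i, j in zip(iu, ju):
        nij = fine.fiber_count[i, j]
        if nij == 0:
            continue
        gi, gj = mapping[i], mapping[j]
        if gi == gj:
            continue
        counts[gi, gj] += nij
        counts[gj, gi] += nij
        length_mass[gi, gj] += nij * fine.fiber_length[i, j]
        length_mass[gj, gi] += nij * fine.fiber_length[i, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        lengths = np.where(counts > 0, length_mass / np.maximum(counts, 1e-300), 0.0)
        A = np.where(counts > 0, counts / np.where(lengths > 0, lengths, 1.0), 0.0)
    return BrainNetwork.from_adjacency(
        coarse_regions, A, fiber_count=counts, fiber_length=lengths
    )


def write_edge_list(network: BrainNetwork, path: str | Path) -> None:
    """Write the upper-triangle edges as a comma-delimited table."""
    if network.fiber_count is None or network.fiber_length is None:
        raise DataError("network carries no fiber counts/lengths to write")
    rows = []
    iu, ju = np.triu_indices(network.n, k=1)
    for i, j in zip(iu, ju):
        if network.fiber_count[i, j] > 0:
            rows.append(
                (
                    network.regions.names[i],
                    network.regions.names[j],
                    network.fiber_count[i, j],
                    network.fiber_length[i, j],
                )
            )
    pd.DataFrame(
        rows, columns=["region_i", "region_j", "fiber_count", "mean_fiber_length"]
    ).to_csv(path, index=False)


def write_adjacency(network: BrainNetwork, path: str | Path) -> None:
    """Export the adjacency matrix with region-name header and index."""
    pd.DataFrame(
        network.adjacency,
        index=network.regions.names,
        columns=network.regions.names,
    ).to_csv(path)


# ---------------------------------------------------------------------------
# Synthetic default connectome
# ---------------------------------------------------------------------------

_CORTICAL_LABELS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "transversetemporal",
]
_SUBCORTICAL_LABELS = [
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens", "ventraldc",
]

# Crude lobe grouping used to give the synthetic connectome a block structure
# (stronger within-lobe than between-lobe connectivity).
_LOBE = {
    "frontal": {
        "caudalmiddlefrontal", "frontalpole", "lateralorbitofrontal",
        "medialorbitofrontal", "paracentral", "parsopercularis",
        "parsorbitalis", "parstriangularis", "precentral",
        "rostralmiddlefrontal", "superiorfrontal",
    },
    "temporal": {
        "bankssts", "entorhinal", "fusiform", "inferiortemporal",
        "middletemporal", "parahippocampal", "superiortemporal",
        "transversetemporal", "insula",
    },
    "parietal": {
        "inferiorparietal", "postcentral", "precuneus", "superiorparietal",
        "supramarginal",
    },
    "occipital": {"cuneus", "lateraloccipital", "lingual", "pericalcarine"},
    "cingulate": {
        "caudalanteriorcingulate", "isthmuscingulate", "posteriorcingulate",
        "rostralanteriorcingulate",
    },
}


def _lobe_of(label: str) -> str:
    for lobe, members in _LOBE.items():
        if label in members:
            return lobe
    return "subcortical"


def make_synthetic_connectome(seed: int = 83) -> tuple[RegionTable, pd.DataFrame]:
    """Generate a synthetic 83-region connectome (region table + edge list).

    This is *not* real tractography: it emulates the qualitative structure of
    an averaged human structural connectome — 66 cortical regions (33 per
    hemisphere), 16 subcortical regions and the brainstem; moderate-to-strong
    within-hemisphere connectivity organised in lobe blocks, and only few,
    weak interhemispheric edges (mostly homologous). Fiber counts are drawn
    from log-normal distributions scaled by block affinity; mean fiber
    lengths grow with topological distance.
    """
    rng = np.random.default_rng(seed)
    names: list[str] = []
    hemis: list[str] = []
    cortical: list[bool] = []
    for hemi in ("lh", "rh"):
        for lab in _CORTICAL_LABELS:
            names.append(f"{hemi}-{lab}")
            hemis.append("left" if hemi == "lh" else "right")
            cortical.append(True)
        for lab in _SUBCORTICAL_LABELS:
            names.append(f"{hemi}-{lab}")
            hemis.append("left" if hemi == "lh" else "right")
            cortical.append(False)
    names.append("brainstem")
    hemis.append("midline")
    cortical.append(False)
    regions = RegionTable(tuple(names), tuple(hemis), np.array(cortical))

    def base_label(name: str) -> str:
        return name.split("-", 1)[-1]

    rows = []
    n = regions.n
    for i in range(n):
        for j in range(i + 1, n):
            hi, hj = regions.hemisphere[i], regions.hemisphere[j]
            li, lj = _lobe_of(base_label(names[i])), _lobe_of(base_label(names[j]))
            homologous = base_label(names[i]) == base_label(names[j]) and hi != hj
            if hi == hj or "midline" in (hi, hj):
                if li == lj:
                    p, mu = 0.65, 5.0
                elif "subcortical" in (li, lj):
                    p, mu = 0.35, 4.2
                else:
                    p, mu = 0.18, 3.6
            elif homologous:
                p, mu = 0.8, 3.0
            else:
                p, mu = 0.015, 2.2
            if rng.random() >= p:
                continue
            fibers = max(1, int(np.round(rng.lognormal(mean=mu, sigma=0.6))))
            length = float(np.round(rng.uniform(20.0, 60.0)
                                    + (40.0 if hi != hj else 0.0), 1))
            rows.append((names[i], names[j], fibers, length))
    edges = pd.DataFrame(
        rows, columns=["region_i", "region_j", "fiber_count", "mean_fiber_length"]
    )
    return regions, edges


def load_default_network() -> BrainNetwork:
    """Load the packaged synthetic 83-region connectome.

    The packaged files were produced by :func:`make_synthetic_connectome`
    with its default seed; they stand in for an averaged tractography
    connectome so the pipeline runs with no external download.
    """
    pkg = resources.files(__package__) / "data"
    regions = RegionTable.from_frame(
        pd.read_csv(io.StringIO((pkg / "synthetic_connectome_regions.csv").read_text()))
    )
    edges = pd.read_csv(
        io.StringIO((pkg / "synthetic_connectome_edges.csv").read_text())
    )
    n = regions.n
    A = np.zeros((n, n))
    counts = np.zeros((n, n))
    lengths = np.zeros((n, n))
    for row in edges.itertuples(index=False):
        i, j = regions.index(row.region_i), regions.index(row.region_j)
        counts[i, j] = counts[j, i] = row.fiber_count
        lengths[i, j] = lengths[j, i] = row.mean_fiber_length
        A[i, j] = A[j, i] = row.fiber_count / row.mean_fiber_length
    return BrainNetwork.from_adjacency(regions, A, fiber_count=counts,
                                       fiber_length=lengths)
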