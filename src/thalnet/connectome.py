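"""Structural connectomes: I/O, validation, driver-region variants, graph metrics.

A structural connectome is a pair of square symmetric matrices over brain
regions — streamline counts (coupling weights ``w_ji``) and mean tract lengths
in mm (source of conduction delays) — plus region labels tagged with an
anatomical role (cortical / thalamic / cerebellar / other).
"""

from __future__ import annotations

import csv
import io
import os
import zipfile
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

VALID_ROLES = frozenset({"cortical", "thalamic", "cerebellar", "other"})

_SYMMETRY_TOL = 1e-9


@dataclass
class StructuralConnectome:
    """Weighted undirected brain graph with tract lengths.

    Parameters
    ----------
    labels : list of str
        Unique region names.
    roles : list of str
        Per-region anatomical role, each in ``VALID_ROLES``.
    weights : ndarray, shape (n, n)
        Symmetric nonnegative streamline counts, zero diagonal.
    lengths : ndarray, shape (n, n)
        Symmetric nonnegative mean tract lengths (mm); zero allowed only
        where the corresponding weight is zero.
    subject_id : str
        Free-form identifier.
    """

    labels: list
    roles: list
    weights: np.ndarray
    lengths: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.labels = list(self.labels)
        self.roles = list(self.roles)
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.validate()

    # -- basic protocol -----------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def role_indices(self, role: str) -> np.ndarray:
        """Indices of all regions tagged with ``role``."""
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def validate(self) -> None:
        n = len(self.labels)
        if n == 0:
            raise ValueError("empty connectome (n_regions = 0)")
        if len(self.roles) != n:
            raise ValueError("roles must be defined for every region")
        bad = set(self.roles) - VALID_ROLES
        if bad:
            raise ValueError(f"unknown role tag(s): {sorted(bad)}")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        for name, m in (("weights", self.weights), ("lengths", self.lengths)):
            if m.shape != (n, n):
                raise ValueError(f"{name} shape {m.shape} does not match {n} labels")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite entries in {name}")
            if (m < 0).any():
                raise ValueError(f"negative {name[:-1]}")
            if np.abs(np.diag(m)).max(initial=0.0) != 0:
                raise ValueError(f"{name} diagonal must be zero")
        asym = np.abs(self.weights - self.weights.T).max(initial=0.0)
        asym_l = np.abs(self.lengths - self.lengths.T).max(initial=0.0)
        if asym > _SYMMETRY_TOL or asym_l > _SYMMETRY_TOL:
            raise ValueError("weights/lengths must be symmetric")
        # average away numerically negligible asymmetry
        self.weights = (self.weights + self.weights.T) / 2.0
        self.lengths = (self.lengths + self.lengths.T) / 2.0
        if ((self.lengths == 0) & (self.weights > 0)).any():
            raise ValueError("zero length on an edge with positive weight")

    def __eq__(self, other):
        return (
            isinstance(other, StructuralConnectome)
            and self.labels == other.labels
            and self.roles == other.roles
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.lengths, other.lengths)
        )


def _load_matrix(path) -> np.ndarray:
    with open(path) as fh:
        text = fh.read()
    first = text.splitlines()[0] if text.splitlines() else ""
    delim = "\t" if "\t" in first else ("," if "," in first else None)
    m = np.loadtxt(io.StringIO(text), delimiter=delim)
    if m.ndim == 0:
        m = m.reshape(1, 1)
    elif m.ndim == 1:
        m = m.reshape(1, -1)
    return m


def read_connectome(weights_path, lengths_path, labels_path, subject_id: str = "") -> StructuralConnectome:
    """Read a connectome from delimited-text matrices and a labels CSV.

    Matrix files are header-free, comma- or tab-delimited, one row per
    region; the labels file has one ``name,role`` record per region.
    Inputs asymmetric beyond 1e-9 are rejected; smaller asymmetries are
    symmetrized by averaging.
    """
    w = _load_matrix(weights_path)
    d = _load_matrix(lengths_path)
    if w.shape != d.shape or w.shape[0] != w.shape[1]:
        raise ValueError(f"shape mismatch: weights {w.shape} vs lengths {d.shape}")
    labels, roles = [], []
    with open(labels_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "name":
                continue
            if len(row) < 2:
                raise ValueError(f"labels file row needs name,role: {row!r}")
            labels.append(row[0].strip())
            roles.append(row[1].strip())
    if len(labels) != w.shape[0]:
        raise ValueError(f"{len(labels)} labels for {w.shape[0]}-region matrices")
    return StructuralConnectome(labels, roles, w, d, subject_id=subject_id)


def write_connectome(sc: StructuralConnectome, out_dir) -> dict:
    """Write ``weights.txt``, ``tract_lengths.txt`` and ``labels.txt``.

    Values use repr-precision so that a read/write round trip is exact.
    Returns the mapping of component name to file path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "weights": os.path.join(out_dir, "weights.txt"),
        "lengths": os.path.join(out_dir, "tract_lengths.txt"),
        "labels": os.path.join(out_dir, "labels.txt"),
    }
    np.savetxt(paths["weights"], sc.weights, delimiter="\t", fmt="%.17g")
    np.savetxt(paths["lengths"], sc.lengths, delimiter="\t", fmt="%.17g")
    with open(paths["labels"], "w", newline="") as fh:
        wr = csv.writer(fh)
        for name, role in zip(sc.labels, sc.roles):
            wr.writerow([name, role])
    return paths


def read_bundle(zip_path, subject_id: str = "") -> StructuralConnectome:
    """Read a single-archive bundle (weights.txt, tract_lengths.txt, labels.txt)."""
    with zipfile.ZipFile(zip_path) as zf:
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            zf.extractall(td)
            return read_connectome(
                os.path.join(td, "weights.txt"),
                os.path.join(td, "tract_lengths.txt"),
                os.path.join(td, "labels.txt"),
                subject_id=subject_id,
            )


# -- variants ---------------------------------------------------------------

VARIANT_MODES = ("parceled", "single", "removed")


def build_variant(sc: StructuralConnectome, driver_role: str, mode: str) -> StructuralConnectome:
    """Build the parceled / single-node / removed variant of a driver region.

    ``parceled`` returns the connectome unchanged. ``removed`` deletes all
    rows/columns of the driver role. ``single`` merges the driver-role
    regions into one node: merged weight to any other region is the sum of
    the members' weights (streamline conservation) and merged length is the
    weight-weighted mean of the members' lengths (unweighted mean if all
    contributing weights are zero); edges within the merged group are
    discarded.
    """
    if mode not in VARIANT_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {VARIANT_MODES}")
    drv = sc.role_indices(driver_role)
    if drv.size == 0:
        raise ValueError(f"no region with role {driver_role!r}")
    if mode == "parceled":
        return replace(sc)
    keep = np.array([i for i in range(sc.n_regions) if i not in set(drv.tolist())], dtype=int)
    if mode == "removed":
        if keep.size == 0:
            raise ValueError("removing the driver role would empty the connectome")
        return StructuralConnectome(
            [sc.labels[i] for i in keep],
            [sc.roles[i] for i in keep],
            sc.weights[np.ix_(keep, keep)],
            sc.lengths[np.ix_(keep, keep)],
            subject_id=sc.subject_id,
        )
    # mode == "single": merged node appended after the kept regions
    w_kk = sc.weights[np.ix_(keep, keep)]
    d_kk = sc.lengths[np.ix_(keep, keep)]
    w_mk = sc.weights[np.ix_(drv, keep)]      # driver members x kept
    d_mk = sc.lengths[np.ix_(drv, keep)]
    w_merged = w_mk.sum(axis=0)
    with np.errstate(invalid="ignore"):
        d_merged = np.where(
            w_merged > 0,
            (w_mk * d_mk).sum(axis=0) / np.where(w_merged > 0, w_merged, 1.0),
            d_mk.mean(axis=0),
        )
    # an all-zero column would pair weight 0 with a spurious mean length
    d_merged = np.where(w_merged > 0, d_merged, np.where(d_mk.max(axis=0) > 0, d_mk.mean(axis=0), 0.0))
    n_new = keep.size + 1
    w = np.zeros((n_new, n_new))
    d = np.zeros((n_new, n_new))
    w[: keep.size, : keep.size] = w_kk
    d[: keep.size, : keep.size] = d_kk
    w[-1, : keep.size] = w[: keep.size, -1] = w_merged
    d[-1, : keep.size] = d[: keep.size, -1] = d_merged
    labels = [sc.labels[i] for i in keep] + [f"{driver_role}_merged"]
    roles = [sc.roles[i] for i in keep] + [driver_role]
    return StructuralConnectome(labels, roles, w, d, subject_id=sc.subject_id)


# -- graph metrics ----------------------------------------------------------

def graph_metrics(sc: StructuralConnectome, driver_role: str | None = None) -> pd.DataFrame:
    """Per-region network metrics plus group averages.

    Degree (neighbour count) and node strength (mean streamline count to all
    other regions) are normalized by their maxima over regions. Betweenness
    and average shortest path length use edge distance = 1 / normalized
    weight on the graph of nonzero edges. Rows ``__global__`` and, when
    ``driver_role`` is given, ``__<role>__`` hold column means over the
    corresponding region sets. A ``disconnected`` attribute flags graphs
    whose nonzero-weight skeleton is not connected (path lengths then
    average over reachable nodes only).
    """
    n = sc.n_regions
    w = sc.weights
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("graph has no edges")
    wn = w / wmax
    degree = (w > 0).sum(axis=1).astype(float)
    strength = w.sum(axis=1) / max(n - 1, 1)
    degree_n = degree / degree.max() if degree.max() > 0 else degree
    strength_n = strength / strength.max() if strength.max() > 0 else strength

    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(wn, k=1))
    G.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / wn[i, j]) for i, j in zip(ii, jj)), weight="distance"
    )
    betw = nx.betweenness_centrality(G, weight="distance", normalized=True)
    betweenness = np.array([betw[i] for i in range(n)])

    path_len = np.full(n, np.nan)
    disconnected = not nx.is_connected(G) if n > 1 else False
    for i, dists in nx.all_pairs_dijkstra_path_length(G, weight="distance"):
        others = [v for k, v in dists.items() if k != i]
        if others:
            path_len[i] = float(np.mean(others))

    df = pd.DataFrame(
        {
            "degree": degree_n,
            "strength": strength_n,
            "betweenness": betweenness,
            "path_length": path_len,
        },
        index=sc.labels,
    )
    summary_rows = {"__global__": df.mean()}
    if driver_role is not None:
        idx = sc.role_indices(driver_role)
        if idx.size == 0:
            raise ValueError(f"no region with role {driver_role!r}")
        summary_rows[f"__{driver_role}__"] = df.iloc[idx].mean()
    out = pd.concat([df, pd.DataFrame(summary_rows).T])
    out.attrs["disconnected"] = disconnected
    return out
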