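"""Temporal graphs as stacks of binary snapshots.

A temporal graph is a fixed node set ``0..N-1`` together with a time-indexed
sequence of ``T`` undirected, simple edge sets; a *contact* ``(u, v, t)``
records that the edge ``{u, v}`` is present in snapshot ``t``.  Internally
time and node indices are 0-based and half-open (``t in [0, T)``); the
contact-list file format can read and write 1-based times via a flag.

The dense ``(T, N, N)`` uint8 tensor representation is the universal object
every measure, null model and pipeline stage in this package consumes or
produces.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TemporalGraph",
    "read_contact_list",
    "write_contact_list",
    "load_snapshots",
    "save_snapshots",
]


def _validate_tensor(tensor: np.ndarray) -> None:
    if tensor.ndim != 3 or tensor.shape[1] != tensor.shape[2]:
        raise ValueError(f"snapshot tensor must be (T, N, N), got {tensor.shape}")
    if tensor.shape[0] < 1 or tensor.shape[1] < 1:
        raise ValueError("need at least one snapshot and one node")
    if not np.isin(tensor, (0, 1)).all():
        raise ValueError("adjacency entries must be exactly 0 or 1")
    if (tensor != tensor.transpose(0, 2, 1)).any():
        raise ValueError("every snapshot must be symmetric")
    if any(np.diagonal(tensor[t]).any() for t in range(tensor.shape[0])):
        raise ValueError("self-loops are not allowed (nonzero diagonal)")


class TemporalGraph:
    """Undirected, simple temporal graph on ``n_nodes`` nodes over ``n_steps`` snapshots.

    Parameters
    ----------
    tensor : array_like of shape (T, N, N)
        Binary adjacency per snapshot; must be symmetric with a zero diagonal.
    validate : bool
        Skip invariant checks when the caller guarantees them (internal use).
    """

    __slots__ = ("tensor",)

    def __init__(self, tensor, validate: bool = True):
        tensor = np.ascontiguousarray(np.asarray(tensor), dtype=np.uint8)
        if validate:
            _validate_tensor(tensor)
        self.tensor = tensor

    @property
    def n_nodes(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_steps(self) -> int:
        return self.tensor.shape[0]

    def snapshot(self, t: int) -> np.ndarray:
        """The ``N x N`` binary adjacency of snapshot ``t``."""
        return self.tensor[t]

    @classmethod
    def from_contacts(
        cls,
        contacts: Iterable[tuple[int, int, int]],
        n_nodes: int,
        n_steps: int,
    ) -> "TemporalGraph":
        """Build a temporal graph from ``(u, v, t)`` triples.

        Duplicate contacts collapse silently; ``u == v`` or out-of-range
        indices raise ``ValueError``.
        """
        if n_nodes < 1 or n_steps < 1:
            raise ValueError("n_nodes and n_steps must be positive")
        tensor = np.zeros((n_steps, n_nodes, n_nodes), dtype=np.uint8)
        for u, v, t in contacts:
            u, v, t = int(u), int(v), int(t)
            if u == v:
                raise ValueError(f"self-loop contact ({u}, {v}, {t})")
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise ValueError(f"node id out of range in contact ({u}, {v}, {t})")
            if not (0 <= t < n_steps):
                raise ValueError(f"time out of range in contact ({u}, {v}, {t})")
            tensor[t, u, v] = 1
            tensor[t, v, u] = 1
        return cls(tensor, validate=False)

    def to_contacts(self) -> list[tuple[int, int, int]]:
        """Contacts ``(u, v, t)`` with ``u < v``, sorted by ``(t, u, v)``."""
        out: list[tuple[int, int, int]] = []
        for t in range(self.n_steps):
            us, vs = np.nonzero(np.triu(self.tensor[t], 1))
            out.extend((int(u), int(v), t) for u, v in zip(us, vs))
        return out

    def average_degree(self) -> float:
        """Mean over snapshots of ``2 * |E_t| / N`` (0 for an edgeless graph)."""
        return float(self.tensor.sum()) / (self.n_steps * self.n_nodes)

    def degree_sequence(self, t: int) -> np.ndarray:
        return self.tensor[t].sum(axis=1).astype(np.int64)

    def copy(self) -> "TemporalGraph":
        return TemporalGraph(self.tensor.copy(), validate=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemporalGraph):
            return NotImplemented
        return self.tensor.shape == other.tensor.shape and bool(
            (self.tensor == other.tensor).all()
        )

    def __hash__(self):  # mutable tensor: identity hash only
        return id(self)

    def __repr__(self) -> str:
        return (
            f"TemporalGraph(n_nodes={self.n_nodes}, n_steps={self.n_steps}, "
            f"contacts={int(self.tensor.sum()) // 2})"
        )


# ---------------------------------------------------------------------------
# File I/O


def read_contact_list(
    path,
    n_nodes: int | None = None,
    n_steps: int | None = None,
    one_based_time: bool = False,
) -> TemporalGraph:
    """Read a whitespace/TSV contact list with columns ``u v t``.

    Lines starting with ``#`` and blank lines are skipped; a single
    non-numeric header line is tolerated.  Dimensions are inferred from the
    data when not given.  ``one_based_time`` shifts times down by one on read.
    """
    triples: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                u, v, t = (int(p) for p in parts[:3])
            except ValueError:
                if lineno == 0 or not triples:
                    continue  # header line
                raise ValueError(f"{path}: cannot parse line {lineno + 1}: {line!r}")
            if len(parts) != 3:
                raise ValueError(f"{path}: expected 3 columns on line {lineno + 1}")
            if one_based_time:
                t -= 1
            triples.append((min(u, v), max(u, v), t))
    if n_nodes is None:
        n_nodes = 1 + max((max(u, v) for u, v, _ in triples), default=0)
    if n_steps is None:
        n_steps = 1 + max((t for _, _, t in triples), default=0)
    return TemporalGraph.from_contacts(triples, n_nodes, n_steps)


def write_contact_list(path, g: TemporalGraph, one_based_time: bool = False) -> None:
    """Write ``g`` as a TSV contact list sorted by ``(t, u, v)``."""
    shift = 1 if one_based_time else 0
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={g.n_nodes} n_steps={g.n_steps}\n")
        fh.write("# u\tv\tt\n")
        for u, v, t in g.to_contacts():
            fh.write(f"{u}\t{v}\t{t + shift}\n")


def save_snapshots(path, g: TemporalGraph) -> None:
    """Store the snapshot tensor in a compressed ``.npz`` archive."""
    np.savez_compressed(
        path, tensor=g.tensor, n_nodes=g.n_nodes, n_steps=g.n_steps
    )


def load_snapshots(path) -> TemporalGraph:
    with np.load(path) as data:
        return TemporalGraph(data["tensor"])
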