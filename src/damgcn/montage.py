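"""Electrode montages and the geometric graph the GCN propagates over.

The graph is fixed (not learned): edge weights are inverse 3-D Euclidean
distances between electrodes, the diagonal is 1, and the propagation matrix
is the symmetrically normalized, self-looped adjacency
``D^{-1/2} (A + I) D^{-1/2}``.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "ElectrodeGraph",
    "CoincidentElectrodesError",
    "UnknownMontageError",
    "build_adjacency",
    "normalize_propagation",
    "build_graph",
    "load_standard_montage",
    "read_montage_csv",
    "write_graph_tsv",
    "DEAP32_CHANNELS",
    "SEED62_CHANNELS",
]


class CoincidentElectrodesError(ValueError):
    """Two electrodes share identical coordinates (distance zero)."""


class UnknownMontageError(KeyError):
    """Requested montage name is not bundled."""


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels with 3-D positions (montage-native units)."""

    channel_names: tuple[str, ...]
    coords: np.ndarray  # (C, 3)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(names) < 2:
            raise ValueError("montage needs at least 2 channels")
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        if coords.shape != (len(names), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(names)} channels x 3"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("montage coordinates must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def subset(self, names: list[str] | tuple[str, ...]) -> "Montage":
        """Montage restricted to ``names``, in the given order."""
        idx = [self.channel_names.index(n) for n in names]
        return Montage(tuple(names), self.coords[idx])


@dataclass
class ElectrodeGraph:
    """Distances, inverse-distance adjacency, and normalized propagation."""

    montage: Montage | None
    distances: np.ndarray  # (C, C), d_ii = 0
    adjacency: np.ndarray  # (C, C), w_ii = 1, w_ij = 1/d_ij
    propagation: np.ndarray | None = None
    single_self_loop: bool = False
    _validated: bool = field(default=False, repr=False)

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]


def build_adjacency(montage: Montage) -> ElectrodeGraph:
    """Inverse-distance weighted adjacency from 3-D electrode positions.

    ``w_ij = 1/d_ij`` for ``i != j`` and ``w_ii = 1``, with ``d_ij`` the
    Euclidean distance between electrodes i and j.

    Raises
    ------
    CoincidentElectrodesError
        If any two distinct electrodes occupy the same point.
    """
    xyz = montage.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(len(xyz), dtype=bool)
    if np.any(dist[off] == 0.0):
        i, j = np.argwhere((dist == 0.0) & off)[0]
        raise CoincidentElectrodesError(
            f"electrodes {montage.channel_names[i]!r} and "
            f"{montage.channel_names[j]!r} have identical coordinates"
        )
    adjacency = np.ones_like(dist)
    adjacency[off] = 1.0 / dist[off]
    return ElectrodeGraph(montage=montage, distances=dist, adjacency=adjacency)


def normalize_propagation(
    graph: ElectrodeGraph, single_self_loop: bool = False
) -> ElectrodeGraph:
    """Attach the symmetric propagation matrix ``D^{-1/2} Ã D^{-1/2}``.

    ``Ã = A + I`` (note the adjacency diagonal is already 1, so Ã carries a
    diagonal of 2 by default; ``single_self_loop=True`` keeps it at 1) and
    ``D_ii = Σ_j Ã_ij``.
    """
    a_tilde = graph.adjacency.copy()
    if not single_self_loop:
        a_tilde = a_tilde + np.eye(graph.n_channels)
    deg = a_tilde.sum(axis=1)
    assert np.all(deg > 0), "degree cannot vanish with unit self-weights"
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    graph.propagation = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    graph.single_self_loop = single_self_loop
    return graph


def build_graph(montage: Montage, single_self_loop: bool = False) -> ElectrodeGraph:
    """Convenience: adjacency construction followed by normalization."""
    return normalize_propagation(build_adjacency(montage), single_self_loop)


# ---------------------------------------------------------------------------
# Bundled montages
#
# Idealized unit-sphere positions for the extended 10-20 (10-10) layout:
# head modeled as a unit sphere, Cz at the vertex, nasion-inion and
# ear-to-ear arcs spanning 180 degrees. Outer-ring electrodes sit on the 10%
# circumference circle (72 degrees of inclination from the vertex); interior
# electrodes are great-circle interpolations between the midline electrode
# and the outer-ring electrode of the same row. The source datasets do not
# publish their coordinate tables, so the conventional geometric layout is
# used as the stand-in.
# ---------------------------------------------------------------------------

DEAP32_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4",
    "F8", "FC6", "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
)

SEED62_CHANNELS = (
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ",
    "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2",
    "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4",
    "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "TP8", "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", "CB1", "O1", "OZ",
    "O2", "CB2",
)

_RING_INCLINATION = 72.0  # degrees from vertex for the 10% circle

# azimuth convention: 0 = right ear (+x), 90 = nasion (+y), CCW from above
_RING_AZIMUTH = {
    "FPZ": 90.0, "FP1": 108.0, "FP2": 72.0,
    "AF7": 126.0, "AF8": 54.0,
    "F7": 144.0, "F8": 36.0,
    "FT7": 162.0, "FT8": 18.0,
    "T7": 180.0, "T8": 0.0,
    "TP7": 198.0, "TP8": 342.0,
    "P7": 216.0, "P8": 324.0,
    "PO7": 234.0, "PO8": 306.0,
    "O1": 252.0, "O2": 288.0,
    "OZ": 270.0,
}

# midline electrodes: (inclination from vertex, azimuth)
_MIDLINE = {
    "FPZ": (72.0, 90.0), "AFZ": (54.0, 90.0), "FZ": (36.0, 90.0),
    "FCZ": (18.0, 90.0), "CZ": (0.0, 90.0), "CPZ": (18.0, 270.0),
    "PZ": (36.0, 270.0), "POZ": (54.0, 270.0), "OZ": (72.0, 270.0),
}

# rows with interior electrodes: row prefix -> (midline label, left ring label)
_ROWS = {
    "AF": ("AFZ", "AF7"), "F": ("FZ", "F7"), "FC": ("FCZ", "FT7"),
    "C": ("CZ", "T7"), "CP": ("CPZ", "TP7"), "P": ("PZ", "P7"),
    "PO": ("POZ", "PO7"),
}

# odd index -> fraction of the arc from midline to left ring electrode
_ROW_FRACTION = {1: 0.25, 3: 0.5, 5: 0.75, 7: 1.0}

# cheek/cerebellar leads used by 62-channel caps: below the outer ring
_EXTRA = {"CB1": (100.0, 252.0), "CB2": (100.0, 288.0)}


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    th = math.radians(inclination_deg)
    az = math.radians(azimuth_deg)
    return np.array(
        [math.sin(th) * math.cos(az), math.sin(th) * math.sin(az), math.cos(th)]
    )


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0)))
    if omega < 1e-12:
        return a.copy()
    return (math.sin((1 - t) * omega) * a + math.sin(t * omega) * b) / math.sin(omega)


def _mirror(p: np.ndarray) -> np.ndarray:
    return np.array([-p[0], p[1], p[2]])


def ideal_1010_position(label: str) -> np.ndarray:
    """Unit-sphere position of a 10-10 electrode label (case-insensitive)."""
    key = label.upper()
    if key in _MIDLINE:
        return _sph(*_MIDLINE[key])
    if key in _RING_AZIMUTH:
        return _sph(_RING_INCLINATION, _RING_AZIMUTH[key])
    if key in _EXTRA:
        return _sph(*_EXTRA[key])
    # interior: row prefix + odd (left) / even (right) index
    for prefix in sorted(_ROWS, key=len, reverse=True):
        if key.startswith(prefix) and key[len(prefix):].isdigit():
            idx = int(key[len(prefix):])
            mid_label, ring_label = _ROWS[prefix]
            mid = _sph(*_MIDLINE[mid_label])
            ring = _sph(_RING_INCLINATION, _RING_AZIMUTH[ring_label])
            odd = idx if idx % 2 == 1 else idx - 1
            frac = _ROW_FRACTION.get(odd)
            if frac is None:
                break
            p = _slerp(mid, ring, frac)
            return p if idx % 2 == 1 else _mirror(p)
    raise UnknownMontageError(f"no idealized 10-10 position for label {label!r}")


def load_standard_montage(name: str) -> Montage:
    """Load a bundled montage ('deap32', 'seed62') or a user CSV file path.

    The CSV format is ``name,x,y,z`` with a header row; channel order in the
    file defines channel order in data arrays.
    """
    if name == "deap32":
        channels = DEAP32_CHANNELS
    elif name == "seed62":
        channels = SEED62_CHANNELS
    else:
        import os

        if os.path.exists(name):
            return read_montage_csv(name)
        raise UnknownMontageError(
            f"unknown montage {name!r}: expected 'deap32', 'seed62', or a CSV path"
        )
    coords = np.stack([ideal_1010_position(c) for c in channels])
    return Montage(tuple(channels), coords)


def read_montage_csv(path_or_buf) -> Montage:
    """Read a ``name,x,y,z`` CSV into a Montage."""
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf, newline="") as fh:
            return read_montage_csv(io.StringIO(fh.read()))
    reader = csv.reader(path_or_buf)
    header = next(reader, None)
    if header is None or [h.strip().lower() for h in header[:4]] != ["name", "x", "y", "z"]:
        raise ValueError("montage CSV must have header 'name,x,y,z'")
    names, rows = [], []
    for row in reader:
        if not row:
            continue
        if len(row) < 4:
            raise ValueError(f"malformed montage row: {row!r}")
        names.append(row[0].strip())
        rows.append([float(v) for v in row[1:4]])
    return Montage(tuple(names), np.array(rows))


def write_graph_tsv(graph: ElectrodeGraph, path, matrix: str = "adjacency") -> None:
    """Export a square graph matrix as TSV with channel-name header row/column."""
    mat = getattr(graph, matrix)
    if mat is None:
        raise ValueError(f"graph matrix {matrix!r} not computed")
    names = graph.montage.channel_names
    with open(path, "w") as fh:
        fh.write("\t".join(("",) + names) + "\n")
        for name, row in zip(names, mat):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
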