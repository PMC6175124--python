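"""Orientational trajectories of nitroxide magnetic frames.

The central container is :class:`OrientationTrajectory`: a concatenated,
uniformly sampled record of rotation matrices, one per trajectory frame and
probe, together with the per-probe bilayer directors.  Each rotation matrix
``R`` stores the magnetic axes of the nitroxide moiety as *columns* expressed
in lab coordinates, i.e. ``R`` maps magnetic-frame components to lab-frame
components and a lab-frame tensor with principal values ``diag(T)`` in the
magnetic frame is ``R @ diag(T) @ R.T``.

Frames are either produced synthetically (see :mod:`spinline.synthetic_data`)
or extracted from atomic coordinates of doxyl/cholestane probes: the magnetic
z axis is the normal of the C-N-C nitroxide plane (unit cross product of the
two N-C ring bonds), x is the projection of the N-O bond onto that plane and
y completes the right-handed triad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DirectorFrame",
    "OrientationTrajectory",
    "NitroxideAtomMap",
    "FrameExtractionError",
    "extract_magnetic_frames",
    "concatenate",
    "angle_to_director",
    "assign_leaflets",
    "write_text",
    "read_text",
    "write_hdf5",
    "read_hdf5",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class FrameExtractionError(ValueError):
    """Degenerate nitroxide geometry (e.g. collinear N-C bonds)."""


@dataclass(frozen=True)
class DirectorFrame:
    """Bilayer normal of the probe's leaflet.

    ``director`` points along the outward leaflet normal (+z for the top
    leaflet, -z for the bottom leaflet of a planar bilayer), so that an
    ordered probe yields positive cos(theta) in either leaflet.
    """

    director: np.ndarray
    leaflet_id: str = "top"

    def __post_init__(self) -> None:
        d = np.asarray(self.director, dtype=float)
        if d.shape != (3,):
            raise ValueError("director must be a 3-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("director must be unit norm (within 1e-9)")
        object.__setattr__(self, "director", d)
        if self.leaflet_id not in ("top", "bottom"):
            raise ValueError("leaflet_id must be 'top' or 'bottom'")


@dataclass
class OrientationTrajectory:
    """Concatenated per-probe record of lab-frame magnetic axes.

    Parameters
    ----------
    dt:
        Frame spacing in picoseconds.
    rotations:
        Array of shape ``(n_total, 3, 3)``; columns of each matrix are the
        magnetic x, y, z axes in lab coordinates.
    boundaries:
        Offsets of shape ``(n_probes + 1,)`` partitioning the concatenated
        record into contiguous per-probe blocks; sliding-window consumers
        never span a boundary.
    directors:
        One :class:`DirectorFrame` per probe.
    source:
        ``"synthetic"`` or ``"md"``.
    """

    dt: float
    rotations: np.ndarray
    boundaries: np.ndarray
    directors: list[DirectorFrame]
    source: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotations = np.ascontiguousarray(self.rotations, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n, 3, 3)")
        if self.boundaries[0] != 0 or self.boundaries[-1] != len(self.rotations):
            raise ValueError("boundaries must start at 0 and end at n_total")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.directors) != self.n_probes:
            raise ValueError("need one director per probe")

    @property
    def n_probes(self) -> int:
        return len(self.boundaries) - 1

    @property
    def n_total(self) -> int:
        return len(self.rotations)

    def block_slices(self) -> list[slice]:
        return [
            slice(int(a), int(b))
            for a, b in zip(self.boundaries[:-1], self.boundaries[1:])
        ]

    def blocks(self) -> Iterator[np.ndarray]:
        for s in self.block_slices():
            yield self.rotations[s]

    def axis_vectors(self, axis: str = "z") -> np.ndarray:
        """Lab-frame unit vectors of one magnetic axis, shape (n_total, 3)."""
        return self.rotations[:, :, _AXIS_INDEX[axis]]

    def times(self) -> np.ndarray:
        """Per-frame times in ps, restarting at 0 within each probe block."""
        t = np.empty(self.n_total)
        for s in self.block_slices():
            t[s] = np.arange(s.stop - s.start) * self.dt
        return t

    def check_orthonormal(self, tol: float = 1e-8) -> None:
        R = self.rotations
        err = np.abs(np.einsum("nji,njk->nik", R, R) - np.eye(3)).max()
        if err > tol:
            raise ValueError(f"rotation matrices deviate from orthonormality by {err:.2e}")
        if np.any(np.linalg.det(R) < 0):
            raise ValueError("rotation matrices must have det +1")


@dataclass
class NitroxideAtomMap:
    """Atom indices of the nitroxide moiety, one entry per probe molecule.

    ``c1/c2`` are the two ring carbons bonded to N, ordered by ascending atom
    index so the sign of the cross-product z axis is reproducible.
    """

    n_idx: np.ndarray
    o_idx: np.ndarray
    c1_idx: np.ndarray
    c2_idx: np.ndarray
    selection: str = ""

    def __post_init__(self) -> None:
        self.n_idx = np.asarray(self.n_idx, dtype=np.int64)
        self.o_idx = np.asarray(self.o_idx, dtype=np.int64)
        self.c1_idx = np.asarray(self.c1_idx, dtype=np.int64)
        self.c2_idx = np.asarray(self.c2_idx, dtype=np.int64)
        n = len(self.n_idx)
        if not (len(self.o_idx) == len(self.c1_idx) == len(self.c2_idx) == n):
            raise ValueError("all index arrays must have one entry per probe")
        # enforce deterministic carbon ordering
        swap = self.c1_idx > self.c2_idx
        if np.any(swap):
            c1 = np.where(swap, self.c2_idx, self.c1_idx)
            c2 = np.where(swap, self.c1_idx, self.c2_idx)
            self.c1_idx, self.c2_idx = c1, c2
        for probe in range(n):
            ids = {self.n_idx[probe], self.o_idx[probe], self.c1_idx[probe], self.c2_idx[probe]}
            if len(ids) != 4:
                raise ValueError(f"probe {probe}: N, O, C1, C2 indices must be distinct")

    @property
    def n_probes(self) -> int:
        return len(self.n_idx)


def _minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def _normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


def extract_magnetic_frames(
    coords_stream: Iterable[np.ndarray],
    amap: NitroxideAtomMap,
    dt: float = 20.0,
    box: np.ndarray | Sequence[float] | None = None,
    directors: list[DirectorFrame] | None = None,
    degeneracy_tol: float = 1e-6,
) -> OrientationTrajectory:
    """Build magnetic frames from a stream of coordinate arrays.

    Each element of ``coords_stream`` is either an ``(n_atoms, 3)`` array, or
    a ``(coords, box)`` pair when the box changes per frame (orthorhombic box
    lengths; bond vectors are wrapped by the minimum-image convention before
    normalization).  Per probe and frame: z = unit cross product of the two
    N-C bond unit vectors, x = unit projection of the N-O vector onto the
    plane normal to z, y = z x x.
    """
    box_arr = None if box is None else np.asarray(box, dtype=float)[:3]
    frames: list[np.ndarray] = []
    for f, item in enumerate(coords_stream):
        if isinstance(item, tuple):
            coords, fbox = item
            if fbox is not None:
                fbox = np.asarray(fbox, dtype=float)[:3]
        else:
            coords, fbox = item, box_arr
        coords = np.asarray(coords, dtype=float)
        npos = coords[amap.n_idx]
        v1 = _normalize(_minimum_image(coords[amap.c1_idx] - npos, fbox))
        v2 = _normalize(_minimum_image(coords[amap.c2_idx] - npos, fbox))
        vo = _minimum_image(coords[amap.o_idx] - npos, fbox)
        z = np.cross(v1, v2)
        znorm = np.linalg.norm(z, axis=-1)
        bad = np.nonzero(znorm < degeneracy_tol)[0]
        if bad.size:
            raise FrameExtractionError(
                f"collinear N-C bonds for probe {bad[0]} at frame {f} "
                f"(cross-product norm {znorm[bad[0]]:.2e})"
            )
        z = z / znorm[:, None]
        x = vo - np.sum(vo * z, axis=-1, keepdims=True) * z
        xnorm = np.linalg.norm(x, axis=-1)
        bad = np.nonzero(xnorm < degeneracy_tol)[0]
        if bad.size:
            raise FrameExtractionError(
                f"N-O bond parallel to ring normal for probe {bad[0]} at frame {f}"
            )
        x = x / xnorm[:, None]
        y = np.cross(z, x)
        frames.append(np.stack([x, y, z], axis=-1))  # columns = axes

    if not frames:
        raise ValueError("empty coordinate stream")
    per_frame = np.asarray(frames)  # (n_frames, n_probes, 3, 3)
    n_frames, n_probes = per_frame.shape[:2]
    rotations = np.ascontiguousarray(
        per_frame.transpose(1, 0, 2, 3).reshape(n_frames * n_probes, 3, 3)
    )
    boundaries = np.arange(n_probes + 1, dtype=np.int64) * n_frames
    if directors is None:
        directors = [DirectorFrame(np.array([0.0, 0.0, 1.0]), "top")] * n_probes
    return OrientationTrajectory(
        dt=dt,
        rotations=rotations,
        boundaries=boundaries,
        directors=list(directors),
        source="md",
    )


def assign_leaflets(n_z: np.ndarray, midplane: float | None = None) -> list[DirectorFrame]:
    """Per-probe directors from the nitroxide N z-coordinate.

    Probes above the bilayer midplane belong to the top leaflet (director +z),
    probes below to the bottom leaflet (director -z).  When ``midplane`` is
    omitted it is taken as the mean of ``n_z``.
    """
    n_z = np.asarray(n_z, dtype=float)
    if midplane is None:
        midplane = float(np.mean(n_z))
    out = []
    for z in n_z:
        if z >= midplane:
            out.append(DirectorFrame(np.array([0.0, 0.0, 1.0]), "top"))
        else:
            out.append(DirectorFrame(np.array([0.0, 0.0, -1.0]), "bottom"))
    return out


def concatenate(probes: Sequence[OrientationTrajectory]) -> OrientationTrajectory:
    """Join per-probe records into one concatenated trajectory.

    Block boundaries are retained so downstream sliding windows never span a
    probe junction.  All inputs must share the same frame spacing.
    """
    if not probes:
        raise ValueError("nothing to concatenate")
    dt = probes[0].dt
    for t in probes[1:]:
        if t.dt != dt:
            raise ValueError(f"mismatched frame spacing: {t.dt} ps vs {dt} ps")
    rotations = np.concatenate([t.rotations for t in probes])
    sizes = np.concatenate([np.diff(t.boundaries) for t in probes])
    boundaries = np.concatenate([[0], np.cumsum(sizes)])
    directors = [d for t in probes for d in t.directors]
    source = probes[0].source if len({t.source for t in probes}) == 1 else "mixed"
    return OrientationTrajectory(
        dt=dt,
        rotations=rotations,
        boundaries=boundaries,
        directors=directors,
        source=source,
    )


def angle_to_director(traj: OrientationTrajectory, axis: str = "z") -> list[np.ndarray]:
    """cos(theta) time series of a magnetic axis against the leaflet director.

    Returns one array per probe.  Because the director is per-leaflet (+z top,
    -z bottom) an ordered probe gives positive cos(theta) in either leaflet.
    """
    vecs = traj.axis_vectors(axis)
    out = []
    for probe, s in enumerate(traj.block_slices()):
        out.append(vecs[s] @ traj.directors[probe].director)
    return out


# ---------------------------------------------------------------------------
# file formats: plain columnar text and an HDF5 twin
# ---------------------------------------------------------------------------

def write_text(traj: OrientationTrajectory, path) -> None:
    """Columnar text: probe_id, t [ps], then the 9 row-major matrix entries."""
    with open(path, "w") as fh:
        fh.write(f"# spinline orientation trajectory\n")
        fh.write(f"# dt_ps {traj.dt!r} source {traj.source}\n")
        dirs = " ".join(
            "%s:%.17g,%.17g,%.17g" % (d.leaflet_id, *d.director)
            for d in traj.directors
        )
        fh.write(f"# directors {dirs}\n")
        fh.write("# probe t_ps R00 R01 R02 R10 R11 R12 R20 R21 R22\n")
        times = traj.times()
        for probe, s in enumerate(traj.block_slices()):
            flat = traj.rotations[s].reshape(-1, 9)
            for t, row in zip(times[s], flat):
                fh.write(
                    f"{probe} {t:.6f} " + " ".join(f"{v:.15e}" for v in row) + "\n"
                )


def read_text(path) -> OrientationTrajectory:
    dt = None
    source = "synthetic"
    directors: list[DirectorFrame] = []
    probe_ids = []
    mats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["dt_ps"]:
                    dt = float(parts[1])
                    source = parts[3] if len(parts) > 3 else "synthetic"
                elif parts[:1] == ["directors"]:
                    for tok in parts[1:]:
                        leaflet, vec = tok.split(":")
                        directors.append(
                            DirectorFrame(np.array([float(v) for v in vec.split(",")]), leaflet)
                        )
                continue
            parts = line.split()
            if not parts:
                continue
            probe_ids.append(int(parts[0]))
            mats.append([float(v) for v in parts[2:11]])
    if dt is None:
        raise ValueError("missing dt header")
    probe_ids = np.asarray(probe_ids)
    rotations = np.asarray(mats).reshape(-1, 3, 3)
    boundaries = np.concatenate(
        [[0], np.nonzero(np.diff(probe_ids))[0] + 1, [len(probe_ids)]]
    )
    if not directors:
        directors = [DirectorFrame(np.array([0.0, 0.0, 1.0]))] * (len(boundaries) - 1)
    return OrientationTrajectory(
        dt=dt, rotations=rotations, boundaries=boundaries,
        directors=directors, source=source,
    )


def write_hdf5(traj: OrientationTrajectory, path) -> None:
    import h5py

    with h5py.File(path, "w", track_order=True) as h5:
        for name, data in (
            ("rotations", traj.rotations),
            ("boundaries", traj.boundaries),
            ("directors", np.array([d.director for d in traj.directors])),
        ):
            h5.create_dataset(name, data=data, track_times=False)
        h5.create_dataset(
            "leaflets",
            data=np.array([d.leaflet_id for d in traj.directors], dtype="S6"),
            track_times=False,
        )
        h5.attrs["dt_ps"] = traj.dt
        h5.attrs["source"] = traj.source


def read_hdf5(path) -> OrientationTrajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        directors = [
            DirectorFrame(np.asarray(d), leaflet.decode())
            for d, leaflet in zip(h5["directors"][...], h5["leaflets"][...])
        ]
        return OrientationTrajectory(
            dt=float(h5.attrs["dt_ps"]),
            rotations=h5["rotations"][...],
            boundaries=h5["boundaries"][...],
            directors=directors,
            source=str(h5.attrs["source"]),
        )


# ---------------------------------------------------------------------------
# MDAnalysis adapter (optional dependency) — the core above consumes plain
# coordinate arrays, so MD formats enter only through this thin layer.
# ---------------------------------------------------------------------------

def atom_map_from_universe(universe, n_sel: str, o_sel: str, c_sel: str) -> NitroxideAtomMap:
    """Build a :class:`NitroxideAtomMap` from MDAnalysis selections.

    ``n_sel``/``o_sel`` must select exactly one N and one O per probe residue;
    ``c_sel`` exactly the two N-bonded ring carbons per residue (they are
    ordered by ascending atom index internally).
    """
    n_atoms = universe.select_atoms(n_sel)
    o_atoms = universe.select_atoms(o_sel)
    c_atoms = universe.select_atoms(c_sel)
    if not (len(n_atoms) == len(o_atoms) == len(c_atoms) // 2) or len(c_atoms) % 2:
        raise ValueError(
            "selections must give one N, one O and two ring C atoms per probe"
        )
    c_by_res: dict[int, list[int]] = {}
    for atom in c_atoms:
        c_by_res.setdefault(atom.resindex, []).append(atom.index)
    c1, c2 = [], []
    for atom in n_atoms:
        pair = sorted(c_by_res[atom.resindex])
        c1.append(pair[0])
        c2.append(pair[1])
    return NitroxideAtomMap(
        n_idx=np.array([a.index for a in n_atoms]),
        o_idx=np.array([a.index for a in o_atoms]),
        c1_idx=np.array(c1),
        c2_idx=np.array(c2),
        selection=f"{n_sel} | {o_sel} | {c_sel}",
    )


def extract_from_universe(
    universe,
    amap: NitroxideAtomMap,
    use_box: bool = True,
    assign_directors: bool = True,
) -> OrientationTrajectory:
    """Extract magnetic frames from an MDAnalysis Universe trajectory.

    The director of each probe is the fixed box normal of its leaflet,
    assigned by the sign of the nitroxide N z-coordinate relative to the
    bilayer midplane in the first frame.
    """

    def stream():
        for ts in universe.trajectory:
            box = ts.dimensions[:3] if (use_box and ts.dimensions is not None) else None
            yield np.asarray(ts.positions, dtype=float), box

    dt = float(getattr(universe.trajectory, "dt", 20.0))  # MDAnalysis dt is in ps
    directors = None
    if assign_directors:
        universe.trajectory[0]
        directors = assign_leaflets(universe.atoms.positions[amap.n_idx, 2])
    return extract_magnetic_frames(stream(), amap, dt=dt, directors=directors)
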