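"""Rotational Brownian-dynamics generator for probe-fixed magnetic frames.

A single rigid body carrying the nitroxide magnetic frame diffuses with an
axially symmetric rotational diffusion tensor (D_parallel about the ordering
axis, D_perp about the two transverse axes) in a uniaxial Maier-Saupe
ordering potential

    U / kBT = -lambda_order * P2(cos theta),

where theta is the angle between a chosen body axis and the leaflet director.
This is the minimal stochastic model whose orientational autocorrelation
functions take the biexponential-plus-plateau form used downstream, with the
plateau equal to the square of the equilibrium order parameter S0(lambda).
An optional slow "cage" sub-model lets the local director itself diffuse
about the global one, producing two well-separated decay time scales as seen
for probes whose fast internal motion rides on the slow tumbling of the
surrounding lipids.

Integration is Euler-Maruyama in the body frame: Gaussian angular increments
with variance 2*D_i*dt about each body axis, a deterministic torque term from
the potential, exact rotation composition (Rodrigues) and re-orthonormalized
columns every step.  Each probe consumes an independent child stream of the
master seed, so increasing the probe count never reshuffles existing probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import quad

from .trajectory import DirectorFrame, OrientationTrajectory

__all__ = [
    "CageParams",
    "BrownianModelParams",
    "generate_trajectory",
    "equilibrium_order_parameter",
    "static_isotropic_trajectory",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_NOISE_CHUNK_FRAMES = 4000  # output frames per pre-generated noise block


@dataclass(frozen=True)
class CageParams:
    """Slow-cage sub-model: the local director diffuses about the global one.

    D_cage is an isotropic rotational diffusion coefficient (rad^2/ns) for the
    local director; lambda_cage is the Maier-Saupe strength tying it to the
    global director.
    """

    D_cage: float
    lambda_cage: float

    def validate(self) -> None:
        if self.D_cage <= 0:
            raise ValueError("D_cage must be positive")


@dataclass(frozen=True)
class BrownianModelParams:
    """Parameters of the Brownian-dynamics generator.

    Defaults mirror the trajectory statistics the generator emulates: frames
    every 20 ps, 12 probes (6 per leaflet) of 5000 frames (100 ns) each, so
    the concatenated record is 1.2 us long.  D is in rad^2/ns, time steps in
    ps.  ``ordering_axis`` is the body axis coupled to the director: "z" for
    doxyl chain probes (5/16-PC-like), "y" for cholestane probes (CSL-like).
    """

    D_parallel: float = 0.5
    D_perp: float = 0.05
    lambda_order: float = 2.0
    ordering_axis: str = "z"
    dt_internal: float = 1.0
    dt_output: float = 20.0
    n_frames: int = 5000
    n_probes: int = 12
    seed: int = 0
    burn_in: int = 0
    cage: CageParams | None = None

    def validate(self) -> None:
        if self.D_parallel <= 0 or self.D_perp <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.dt_internal <= 0 or self.dt_output <= 0:
            raise ValueError("time steps must be positive")
        if self.dt_internal > self.dt_output:
            raise ValueError("dt_internal must not exceed dt_output")
        if self.n_frames * self.n_probes <= 0:
            raise ValueError("n_frames and n_probes must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.ordering_axis not in _AXIS_INDEX:
            raise ValueError("ordering_axis must be one of x, y, z")
        if not np.isfinite(self.lambda_order):
            raise ValueError("lambda_order must be finite")
        if self.cage is not None:
            self.cage.validate()

    @property
    def substeps(self) -> int:
        return max(1, int(round(self.dt_output / self.dt_internal)))


def equilibrium_order_parameter(lambda_order: float) -> float:
    """Equilibrium S0 of the Maier-Saupe potential by 1D quadrature.

    S0(lambda) = <P2(cos theta)> under the Boltzmann weight
    exp(lambda * P2(cos theta)) on cos theta in [-1, 1].  Serves as the
    ground truth for parameter-recovery tests.
    """
    lam = float(lambda_order)
    if not np.isfinite(lam):
        raise ValueError("lambda_order must be finite")
    if lam == 0.0:
        return 0.0

    def p2(c):
        return 0.5 * (3.0 * c * c - 1.0)

    # subtract max exponent for numerical stability at large |lambda|
    shift = max(lam, -0.5 * lam)
    num = quad(lambda c: p2(c) * np.exp(lam * p2(c) - shift), -1, 1, limit=200)[0]
    den = quad(lambda c: np.exp(lam * p2(c) - shift), -1, 1, limit=200)[0]
    return num / den


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _orthonormalize(R):
    # modified Gram-Schmidt on columns
    n0 = 0.0
    for i in range(3):
        n0 += R[i, 0] * R[i, 0]
    n0 = np.sqrt(n0)
    for i in range(3):
        R[i, 0] /= n0
    d = 0.0
    for i in range(3):
        d += R[i, 0] * R[i, 1]
    for i in range(3):
        R[i, 1] -= d * R[i, 0]
    n1 = 0.0
    for i in range(3):
        n1 += R[i, 1] * R[i, 1]
    n1 = np.sqrt(n1)
    for i in range(3):
        R[i, 1] /= n1
    # third column = cross of first two (guarantees det +1)
    R[0, 2] = R[1, 0] * R[2, 1] - R[2, 0] * R[1, 1]
    R[1, 2] = R[2, 0] * R[0, 1] - R[0, 0] * R[2, 1]
    R[2, 2] = R[0, 0] * R[1, 1] - R[1, 0] * R[0, 1]


@njit(cache=True)
def _advance_chunk(
    R,
    nloc,
    director,
    noise,
    noise_cage,
    substeps,
    sig,
    three_lam_Ddt,
    a_idx,
    use_cage,
    sig_cage,
    three_lamc_Dcdt,
    out_R,
):
    """Advance ``out_R.shape[0]`` output frames; noise has one row per substep."""
    phi = np.empty(3)
    dR = np.empty((3, 3))
    tmp = np.empty((3, 3))
    k = 0
    n_out = out_R.shape[0]
    for f in range(n_out):
        for _ in range(substeps):
            if use_cage:
                # local director: tangential Euler-Maruyama on the sphere
                cn = nloc[0] * director[0] + nloc[1] * director[1] + nloc[2] * director[2]
                for i in range(3):
                    xi = noise_cage[k, i]
                    drift = three_lamc_Dcdt * cn * (director[i] - cn * nloc[i])
                    nloc[i] += sig_cage * xi + drift
                # project noise tangentially by renormalizing (radial part is
                # removed to O(dt) by the normalization)
                nn = np.sqrt(nloc[0] ** 2 + nloc[1] ** 2 + nloc[2] ** 2)
                for i in range(3):
                    nloc[i] /= nn
            # probe body: angular increment about body axes
            ux = R[0, a_idx]
            uy = R[1, a_idx]
            uz = R[2, a_idx]
            c = ux * nloc[0] + uy * nloc[1] + uz * nloc[2]
            for i in range(3):
                if i == a_idx:
                    phi[i] = sig[i] * noise[k, i]
                else:
                    # d(u.n)/dphi_i = (r_i x u) . n with r_i = column i of R
                    rx = R[0, i]
                    ry = R[1, i]
                    rz = R[2, i]
                    cx = ry * uz - rz * uy
                    cy = rz * ux - rx * uz
                    cz = rx * uy - ry * ux
                    grad = cx * nloc[0] + cy * nloc[1] + cz * nloc[2]
                    phi[i] = sig[i] * noise[k, i] + three_lam_Ddt[i] * c * grad
            k += 1
            # Rodrigues rotation by the body-frame vector phi
            ang = np.sqrt(phi[0] ** 2 + phi[1] ** 2 + phi[2] ** 2)
            if ang < 1e-14:
                continue
            ax = phi[0] / ang
            ay = phi[1] / ang
            az = phi[2] / ang
            ca = np.cos(ang)
            sa = np.sin(ang)
            omc = 1.0 - ca
            dR[0, 0] = ca + ax * ax * omc
            dR[0, 1] = ax * ay * omc - az * sa
            dR[0, 2] = ax * az * omc + ay * sa
            dR[1, 0] = ay * ax * omc + az * sa
            dR[1, 1] = ca + ay * ay * omc
            dR[1, 2] = ay * az * omc - ax * sa
            dR[2, 0] = az * ax * omc - ay * sa
            dR[2, 1] = az * ay * omc + ax * sa
            dR[2, 2] = ca + az * az * omc
            # R <- R @ dR (body-frame increment)
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for m in range(3):
                        s += R[i, m] * dR[m, j]
                    tmp[i, j] = s
            for i in range(3):
                for j in range(3):
                    R[i, j] = tmp[i, j]
            _orthonormalize(R)
        for i in range(3):
            for j in range(3):
                out_R[f, i, j] = R[i, j]


# ---------------------------------------------------------------------------
# equilibrium initial conditions
# ---------------------------------------------------------------------------

def _sample_equilibrium_costheta(lam: float, rng: np.random.Generator) -> float:
    """Rejection-sample cos(theta) from exp(lambda*P2(c)) on [-1, 1]."""
    if lam == 0.0:
        return float(rng.uniform(-1.0, 1.0))
    peak = max(lam, -0.5 * lam)  # max of lam*P2 on [-1, 1]
    while True:
        c = rng.uniform(-1.0, 1.0)
        logw = lam * 0.5 * (3.0 * c * c - 1.0) - peak
        if np.log(rng.uniform(0.0, 1.0) + 1e-300) < logw:
            return float(c)


def _frame_with_axis(u: np.ndarray, a_idx: int, psi: float) -> np.ndarray:
    """Rotation matrix whose column ``a_idx`` equals ``u``; spin angle psi
    about u fixes the remaining gauge freedom."""
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    # rotate v, w about u by psi
    vp = v * np.cos(psi) + w * np.sin(psi)
    wp = np.cross(u, vp)
    cols = [None, None, None]
    cols[a_idx] = u
    other = [i for i in range(3) if i != a_idx]
    cols[other[0]] = vp
    cols[other[1]] = wp
    R = np.stack(cols, axis=-1)
    if np.linalg.det(R) < 0:
        cols[other[1]] = -wp
        R = np.stack(cols, axis=-1)
    return R


def _init_orientation(
    lam: float, director: np.ndarray, a_idx: int, rng: np.random.Generator
) -> np.ndarray:
    c = _sample_equilibrium_costheta(lam, rng)
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal basis around the director
    d = director / np.linalg.norm(director)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    u = np.cos(theta) * d + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return _frame_with_axis(u, a_idx, rng.uniform(0.0, 2.0 * np.pi))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def generate_trajectory(params: BrownianModelParams) -> OrientationTrajectory:
    """Generate seeded Brownian-dynamics magnetic-frame trajectories.

    Returns ``params.n_probes`` independent blocks of ``params.n_frames``
    rotation matrices at ``params.dt_output`` spacing (after discarding
    ``params.burn_in`` output frames; orientations are initialized from the
    equilibrium distribution so the default burn-in is zero).  Identical
    parameters and seed give a bit-identical trajectory.
    """
    params.validate()
    a_idx = _AXIS_INDEX[params.ordering_axis]
    substeps = params.substeps
    dt_ns = params.dt_output / substeps / 1000.0  # effective internal step, ns
    D = np.empty(3)
    D[:] = params.D_perp
    D[a_idx] = params.D_parallel
    sig = np.sqrt(2.0 * D * dt_ns)
    three_lam_Ddt = 3.0 * params.lambda_order * D * dt_ns

    use_cage = params.cage is not None
    if use_cage:
        sig_cage = float(np.sqrt(2.0 * params.cage.D_cage * dt_ns))
        three_lamc = 3.0 * params.cage.lambda_cage * params.cage.D_cage * dt_ns
    else:
        sig_cage = 0.0
        three_lamc = 0.0

    master = np.random.SeedSequence(params.seed)
    children = master.spawn(params.n_probes)

    n_out_total = params.burn_in + params.n_frames
    rotations = np.empty((params.n_probes * params.n_frames, 3, 3))
    directors: list[DirectorFrame] = []
    global_dir = np.array([0.0, 0.0, 1.0])

    for probe in range(params.n_probes):
        rng = np.random.Generator(np.random.PCG64(children[probe]))
        # directors alternate top/bottom (6+6 for the default probe count)
        if probe % 2 == 0:
            directors.append(DirectorFrame(np.array([0.0, 0.0, 1.0]), "top"))
        else:
            directors.append(DirectorFrame(np.array([0.0, 0.0, -1.0]), "bottom"))
        # the potential is P2-symmetric: use the global +z director internally
        if use_cage:
            nloc = np.array(
                [0.0, 0.0, 1.0]
            )
            c0 = _sample_equilibrium_costheta(params.cage.lambda_cage, rng)
            th = np.arccos(np.clip(c0, -1, 1))
            ph = rng.uniform(0, 2 * np.pi)
            nloc = np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
        else:
            nloc = global_dir.copy()
        R = _init_orientation(params.lambda_order, nloc, a_idx, rng)
        out = np.empty((n_out_total, 3, 3))
        done = 0
        while done < n_out_total:
            n_f = min(_NOISE_CHUNK_FRAMES, n_out_total - done)
            n_steps = n_f * substeps
            noise = rng.standard_normal((n_steps, 3))
            noise_cage = (
                rng.standard_normal((n_steps, 3)) if use_cage else np.zeros((1, 3))
            )
            _advance_chunk(
                R,
                nloc,
                global_dir,
                noise,
                noise_cage,
                substeps,
                sig,
                three_lam_Ddt,
                a_idx,
                use_cage,
                sig_cage,
                three_lamc,
                out[done : done + n_f],
            )
            done += n_f
        start = probe * params.n_frames
        rotations[start : start + params.n_frames] = out[params.burn_in :]

    boundaries = np.arange(params.n_probes + 1, dtype=np.int64) * params.n_frames
    return OrientationTrajectory(
        dt=params.dt_output,
        rotations=rotations,
        boundaries=boundaries,
        directors=directors,
        source="synthetic",
        metadata={"params": params},
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit vectors (spherical Fibonacci grid)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)


def static_isotropic_trajectory(
    n_orientations: int = 1024,
    n_frames: int = 1024,
    dt: float = 80.0,
    seed: int = 0,
    grid: str = "fibonacci",
) -> OrientationTrajectory:
    """Frozen isotropically-oriented ensemble (rigid-limit fixture).

    Each "probe" holds a single fixed orientation repeated over ``n_frames``
    frames.  ``grid="fibonacci"`` places the magnetic z axes on a spherical
    Fibonacci grid (with a seeded random spin angle about z), giving a smooth
    powder with modest ensemble sizes; ``grid="random"`` uses fully random
    rotations.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    if grid == "fibonacci":
        # Orientation-dependent resonances are functions of the applied-field
        # direction in the magnetic frame, i.e. the third row of R.  Placing
        # those directions on the Fibonacci grid makes the frozen ensemble a
        # deterministic, nearly uniform powder quadrature.
        us = _fibonacci_sphere(n_orientations)
        mats = np.array(
            [
                _frame_with_axis(u, 2, rng.uniform(0, 2 * np.pi)).T
                for u in us
            ]
        )
    elif grid == "random":
        from scipy.spatial.transform import Rotation

        mats = Rotation.random(n_orientations, random_state=rng).as_matrix()
    else:
        raise ValueError("grid must be 'fibonacci' or 'random'")
    rotations = np.repeat(mats[:, None], n_frames, axis=1).reshape(-1, 3, 3)
    boundaries = np.arange(n_orientations + 1, dtype=np.int64) * n_frames
    directors = [DirectorFrame(np.array([0.0, 0.0, 1.0]), "top")] * n_orientations
    return OrientationTrajectory(
        dt=dt,
        rotations=np.ascontiguousarray(rotations),
        boundaries=boundaries,
        directors=directors,
        source="synthetic",
        metadata={"kind": "static-isotropic", "grid": grid, "seed": seed},
    )
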