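"""Analysis of orientational trajectories, spectra and bilayer structure.

Implements the analysis layer of the pipeline: P2 orientational
autocorrelation functions with sliding-window averaging, biexponential fits
with an order-parameter plateau,

    C(t) = (1 - S0^2) * [w1 exp(-t/tau1) + w2 exp(-t/tau2)] + S0^2,
    tau_eff = w1*tau1 + w2*tau2,

direct order parameters S0 = <(3 cos^2 theta - 1)/2>, the Hubbell-McConnell
spectral estimate

    S0 = (A'par - A'perp) / (Azz - (Axx + Ayy)/2)

from the outer/inner hyperfine splittings of a first-derivative spectrum,
deuterium order profiles, leaflet-projected radial distribution functions
and probe flip-flop detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .spin_dynamics import SpinParameters, Spectrum
from .trajectory import OrientationTrajectory, angle_to_director

__all__ = [
    "AcfResult",
    "AcfFit",
    "SplittingMeasurement",
    "SplittingError",
    "compute_acf",
    "acf_of_axis",
    "fit_biexponential",
    "order_parameter_direct",
    "hm_order_parameter",
    "hubbell_mcconnell",
    "scd_profile",
    "rdf_projected",
    "detect_flip_flop",
]


def _p2(x: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * np.asarray(x) ** 2 - 1.0)


class SplittingError(ValueError):
    """Raised when a spectrum has no resolvable slow-motional outer peaks."""


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class AcfResult:
    """P2 autocorrelation function C(t) on a lag grid (ps)."""

    lag: np.ndarray  # ps
    C: np.ndarray
    n_samples: np.ndarray
    axis: str = ""
    scope: str = "all"
    block_C: np.ndarray | None = None  # per-probe curves, shape (n_blocks, n_lags)

    def standard_error(self) -> np.ndarray | None:
        """Across-probe standard error of C(t), if per-block curves are kept."""
        if self.block_C is None or len(self.block_C) < 2:
            return None
        return np.std(self.block_C, axis=0, ddof=1) / np.sqrt(len(self.block_C))


def _lag_grid(max_lag: int, n_lags: int, log_spaced: bool) -> np.ndarray:
    if log_spaced:
        lags = np.unique(
            np.round(np.geomspace(1, max_lag, n_lags - 1)).astype(np.int64)
        )
        return np.concatenate([[0], lags])
    return np.arange(0, max_lag + 1, max(1, max_lag // n_lags), dtype=np.int64)


def compute_acf(
    series: np.ndarray | Sequence[np.ndarray],
    dt: float,
    boundaries: np.ndarray | None = None,
    max_lag_frac: float = 1.0 / 3.0,
    max_lag: int | None = None,
    n_lags: int = 160,
    log_spaced: bool = True,
    axis_label: str = "",
    keep_blocks: bool = False,
) -> AcfResult:
    """Sliding-window P2 autocorrelation of unit vectors (or a scalar series).

    ``series`` is one ``(n, 3)`` vector array (with optional ``boundaries``
    partitioning it into probe blocks) or a list of per-probe arrays; scalar
    series are accepted and treated as 1-dimensional projections, for which
    ``C(lag) = <P2(s(t) * s(t+lag))>``.  Averaging runs over all start times
    within each block (every pair is a sliding-window start) and over probes.
    The default lag cap is a third of the shortest block; requesting lags
    beyond the cap raises an error.
    """
    if isinstance(series, np.ndarray):
        if boundaries is None:
            blocks = [np.asarray(series, dtype=float)]
        else:
            boundaries = np.asarray(boundaries)
            blocks = [
                np.asarray(series[a:b], dtype=float)
                for a, b in zip(boundaries[:-1], boundaries[1:])
            ]
    else:
        blocks = [np.asarray(b, dtype=float) for b in series]
    shortest = min(len(b) for b in blocks)
    cap = max(1, int(np.floor(shortest * max_lag_frac)))
    if max_lag is None:
        max_lag = cap
    elif max_lag >= shortest:
        raise ValueError(
            f"max_lag {max_lag} exceeds the shortest block ({shortest} frames)"
        )
    lags = _lag_grid(max_lag, n_lags, log_spaced)

    per_block = np.empty((len(blocks), len(lags)))
    counts = np.zeros(len(lags), dtype=np.int64)
    for bi, b in enumerate(blocks):
        for li, lag in enumerate(lags):
            if lag >= len(b):
                per_block[bi, li] = np.nan
                continue
            x, y = b[: len(b) - lag or None], b[lag:]
            dot = np.sum(x * y, axis=-1) if b.ndim == 2 else x * y
            per_block[bi, li] = np.mean(_p2(dot))
            counts[li] += len(dot)
    C = np.nanmean(per_block, axis=0)
    return AcfResult(
        lag=lags * dt,
        C=C,
        n_samples=counts,
        axis=axis_label,
        block_C=per_block if keep_blocks else None,
    )


def acf_of_axis(
    traj: OrientationTrajectory, axis: str = "z", **kwargs
) -> AcfResult:
    """P2 ACF of one magnetic axis of an orientation trajectory."""
    return compute_acf(
        traj.axis_vectors(axis),
        traj.dt,
        boundaries=traj.boundaries,
        axis_label=axis,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# biexponential fit
# ---------------------------------------------------------------------------

@dataclass
class AcfFit:
    """Biexponential-plus-plateau fit of an orientational ACF.

    Times in ns.  ``S0`` carries the sign supplied by the direct order
    parameter (the plateau alone determines only S0^2).  ``tau_eff`` is the
    weight-averaged correlation time w1*tau1 + w2*tau2 by construction.
    """

    w1: float
    w2: float
    tau1: float
    tau2: float
    S0_sq: float
    S0: float
    tau_eff: float
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()
    covariance: np.ndarray | None = None

    @classmethod
    def _from_params(cls, S2, w1, tau1, tau2, rss, converged, flags=(), cov=None):
        if tau1 > tau2:  # canonical ordering
            tau1, tau2 = tau2, tau1
            w1 = 1.0 - w1
        w2 = 1.0 - w1
        return cls(
            w1=w1, w2=w2, tau1=tau1, tau2=tau2, S0_sq=S2,
            S0=float(np.sqrt(max(S2, 0.0))),
            tau_eff=w1 * tau1 + w2 * tau2,
            rss=rss, converged=converged, flags=tuple(flags), covariance=cov,
        )

    def model(self, t_ns: np.ndarray) -> np.ndarray:
        return biexponential(t_ns, self.S0_sq, self.w1, self.tau1, self.tau2)


def biexponential(t_ns, S0_sq, w1, tau1, tau2):
    """Eq.-of-motion model curve C(t) with plateau S0^2 (t in ns)."""
    return (1.0 - S0_sq) * (
        w1 * np.exp(-t_ns / tau1) + (1.0 - w1) * np.exp(-t_ns / tau2)
    ) + S0_sq


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    tail = y[max(1, int(0.9 * len(y))):]
    S2 = float(np.clip(np.mean(tail), 0.0, 0.999))
    decay = (y - S2) / max(1.0 - S2, 1e-9)
    # tau1 from the 1/e crossing of the normalized decay
    below = np.nonzero(decay < np.exp(-1.0))[0]
    tau1 = t[below[0]] if below.size and below[0] > 0 else (t[1] if len(t) > 1 else 1.0)
    # tau2 from the log-slope of the 10%-decay tail
    mask = (decay > 0.02) & (decay < 0.3) & (t > 0)
    if np.count_nonzero(mask) >= 3:
        slope = np.polyfit(t[mask], np.log(decay[mask]), 1)[0]
        tau2 = -1.0 / slope if slope < 0 else 10.0 * tau1
    else:
        tau2 = 10.0 * tau1
    tau2 = max(tau2, 1.5 * tau1)
    return S2, 0.6, float(tau1), float(tau2)


def fit_biexponential(
    acf: AcfResult,
    n_restarts: int = 8,
    sign_source: float | None = None,
    rng_seed: int = 0,
) -> AcfFit:
    """Constrained nonlinear least-squares fit of the biexponential model.

    Constraints: w1 + w2 = 1 (w2 eliminated), 0 <= S0^2 <= 1, tau_i > 0.
    Multi-start initialization (1/e crossing and tail slope, plus
    ``n_restarts`` perturbed restarts; best residual wins) guards against the
    local minima endemic to biexponential fits.  Non-convergence yields a
    flagged result with diagnostics rather than an exception.  If
    ``sign_source`` (a direct <P2> estimate) is given, its sign is applied
    to S0.
    """
    t = np.asarray(acf.lag, dtype=float) / 1000.0  # ns
    y = np.asarray(acf.C, dtype=float)
    if len(t) < 20:
        raise ValueError("need at least 20 lag points spanning both decay regimes")

    S2_0, w1_0, tau1_0, tau2_0 = _initial_guesses(t, y)
    # static ordered limit: no decaying amplitude to fit
    if np.ptp(y) < 1e-12:
        fit = AcfFit._from_params(
            float(np.mean(y)), 1.0, np.nan, np.nan, 0.0, True,
            flags=("tau_unidentifiable",),
        )
        fit = _apply_sign(fit, sign_source)
        return fit

    def residuals(x):
        S2, w1, lt1, lt2 = x
        return biexponential(t, S2, w1, np.exp(lt1), np.exp(lt2)) - y

    rng = np.random.Generator(np.random.PCG64(rng_seed))
    lo = [0.0, 0.0, np.log(1e-4), np.log(1e-4)]
    hi = [1.0, 1.0, np.log(1e5), np.log(1e5)]
    best = None
    x0s = [np.array([S2_0, w1_0, np.log(tau1_0), np.log(tau2_0)])]
    for _ in range(n_restarts):
        x0s.append(
            np.array(
                [
                    np.clip(S2_0 + rng.normal(0, 0.05), 0, 1),
                    rng.uniform(0.2, 0.8),
                    np.log(tau1_0) + rng.normal(0, 1.0),
                    np.log(tau2_0) + rng.normal(0, 1.0),
                ]
            )
        )
    for x0 in x0s:
        try:
            sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return _apply_sign(
            AcfFit._from_params(S2_0, w1_0, tau1_0, tau2_0, np.inf, False,
                                flags=("did_not_converge",)),
            sign_source,
        )
    S2, w1, lt1, lt2 = best.x
    rss = float(2.0 * best.cost)
    flags = [] if best.success else ["did_not_converge"]
    # covariance from the Jacobian in the internal parameterization
    cov = None
    try:
        dof = max(len(t) - 4, 1)
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * rss / dof
    except Exception:
        pass
    fit = AcfFit._from_params(
        float(S2), float(w1), float(np.exp(lt1)), float(np.exp(lt2)),
        rss, best.success, flags=flags, cov=cov,
    )
    return _apply_sign(fit, sign_source)


def _apply_sign(fit: AcfFit, sign_source: float | None) -> AcfFit:
    if sign_source is not None and sign_source < 0:
        fit.S0 = -fit.S0
    return fit


def order_parameter_direct(series) -> float:
    """Time/probe-averaged P2 of a cos(theta) series (or list of series).

    Supplies the sign for the fitted S0: the ACF plateau gives only S0^2.
    """
    if not isinstance(series, np.ndarray):
        series = np.concatenate([np.ravel(s) for s in series])
    if series.size == 0:
        raise ValueError("empty series")
    return float(np.mean(_p2(series)))


def trajectory_order_parameter(traj: OrientationTrajectory, axis: str = "z") -> float:
    """Direct S0 of a magnetic axis against the per-leaflet director."""
    return order_parameter_direct(angle_to_director(traj, axis))


# ---------------------------------------------------------------------------
# Hubbell-McConnell estimate from the line shape
# ---------------------------------------------------------------------------

@dataclass
class SplittingMeasurement:
    """Effective hyperfine splittings read off a first-derivative spectrum.

    ``A_par_eff`` is half the separation of the outermost low-field maximum
    and high-field minimum; ``A_perp_eff`` half the inner splitting.  When
    the inner splitting is unresolved it is derived from trace preservation,
    A'perp = (3*a_iso - A'par)/2, and flagged.
    """

    A_par_eff: float
    A_perp_eff: float
    S0_hm: float
    peaks: dict = field(default_factory=dict)
    inner_resolved: bool = True


def hm_order_parameter(A_par: float, A_perp: float, spin: SpinParameters) -> float:
    """Order parameter from effective splittings (Hubbell-McConnell)."""
    Axx, Ayy, Azz = spin.A_principal
    return (A_par - A_perp) / (Azz - 0.5 * (Axx + Ayy))


def _refine_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic sub-grid refinement of an extremum at index ``i``."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + np.clip(shift, -1, 1) * (x[1] - x[0]))


def hubbell_mcconnell(
    spec: Spectrum,
    spin: SpinParameters,
    prominence: float = 0.03,
    min_inner_offset: float = 3.0,
    refine: bool = False,
) -> SplittingMeasurement:
    """Estimate S0 from the outer/inner hyperfine splittings of a spectrum.

    The outer splitting 2*A'par is the separation between the outermost
    low-field maximum and high-field minimum of the derivative curve
    (prominence-filtered).  The inner splitting 2*A'perp is read from the
    absorption maxima flanking the central line (at least
    ``min_inner_offset`` Gauss from the center); if no flanking maxima are
    resolved, A'perp falls back to trace preservation and the result is
    flagged via ``inner_resolved=False``.
    """
    B = np.asarray(spec.field)
    y = np.asarray(spec.intensity)
    span = float(np.ptp(y))
    peaks, _ = find_peaks(y, prominence=prominence * span)
    troughs, _ = find_peaks(-y, prominence=prominence * span)
    if peaks.size == 0 or troughs.size == 0:
        raise SplittingError("no slow-motional outer peaks")
    p_out, t_out = peaks[0], troughs[-1]
    if B[t_out] <= B[p_out]:
        raise SplittingError("no slow-motional outer peaks")
    if refine:
        b_lo, b_hi = _refine_peak(B, y, p_out), _refine_peak(B, -y, t_out)
    else:
        b_lo, b_hi = float(B[p_out]), float(B[t_out])
    A_par = 0.5 * (b_hi - b_lo)

    # inner splitting from the absorption maxima flanking the central line;
    # the central line is the absorption peak nearest the absorption centroid
    # (robust against g-anisotropy skew of the outer extrema)
    absorption = np.cumsum(y)
    absorption -= absorption.min()
    weights = np.clip(absorption, 0.0, None)
    centroid = float(np.sum(B * weights) / np.sum(weights))
    apk, _ = find_peaks(absorption, prominence=prominence * np.ptp(absorption))
    if apk.size:
        center = float(B[apk[np.argmin(np.abs(B[apk] - centroid))]])
    else:
        center = centroid
    left = [i for i in apk if B[i] < center - min_inner_offset]
    right = [i for i in apk if B[i] > center + min_inner_offset]
    info = {
        "outer_low_G": b_lo,
        "outer_high_G": b_hi,
        "center_G": center,
    }
    if left and right:
        li, ri = left[-1], right[0]
        if refine:
            b_l, b_r = _refine_peak(B, absorption, li), _refine_peak(B, absorption, ri)
        else:
            b_l, b_r = float(B[li]), float(B[ri])
        A_perp = 0.5 * (b_r - b_l)
        info.update(inner_low_G=b_l, inner_high_G=b_r)
        resolved = True
    else:
        A_perp = 0.5 * (3.0 * spin.a_iso - A_par)
        resolved = False
    return SplittingMeasurement(
        A_par_eff=A_par,
        A_perp_eff=A_perp,
        S0_hm=hm_order_parameter(A_par, A_perp, spin),
        peaks=info,
        inner_resolved=resolved,
    )


# ---------------------------------------------------------------------------
# bilayer structural descriptors
# ---------------------------------------------------------------------------

def scd_profile(
    coords_stream: Iterable[np.ndarray],
    chain_map: Sequence[dict[int, tuple[int, Sequence[int]]]],
    normal: Sequence[float] = (0.0, 0.0, 1.0),
    leaflets: Sequence[str] | None = None,
):
    """Deuterium order parameter profile S_CD(n) per acyl carbon.

    ``chain_map`` holds one dict per lipid mapping carbon position ->
    (carbon atom index, hydrogen atom indices).  S_CD(n) is the P2 average of
    the C-H angle against the bilayer normal, over hydrogens, lipids and
    frames; a missing hydrogen list raises (no reconstruction is attempted).
    Returns a pandas DataFrame with columns carbon, leaflet, S_CD, n_samples.
    """
    import pandas as pd

    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    if leaflets is None:
        leaflets = ["all"] * len(chain_map)
    acc: dict[tuple[int, str], list] = {}
    count = 0
    for coords in coords_stream:
        count += 1
        coords = np.asarray(coords, dtype=float)
        for lipid, lmap in enumerate(chain_map):
            for carbon, (c_idx, h_idxs) in lmap.items():
                if h_idxs is None or len(h_idxs) == 0:
                    raise ValueError(
                        f"lipid {lipid} carbon {carbon}: no hydrogens mapped and "
                        "no reconstruction available"
                    )
                vec = coords[list(h_idxs)] - coords[c_idx]
                cos = (vec @ n) / np.linalg.norm(vec, axis=-1)
                acc.setdefault((carbon, leaflets[lipid]), []).append(_p2(cos))
    if count == 0:
        raise ValueError("empty coordinate stream")
    rows = [
        {
            "carbon": carbon,
            "leaflet": leaflet,
            "S_CD": float(np.mean(np.concatenate(vals))),
            "n_samples": int(sum(v.size for v in vals)),
        }
        for (carbon, leaflet), vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def rdf_projected(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    box: Sequence[float],
    mode: str = "2d",
    r_max: float | None = None,
    n_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair radial distribution function, optionally projected on the bilayer
    plane (``mode="2d"``, minimum-image in x/y) or fully 3-dimensional.

    Positions may be single-frame ``(n, 3)`` arrays or multi-frame
    ``(n_frames, n, 3)``; both selections should come from the same leaflet
    in 2d mode.  Normalization is by the ideal-gas expectation (annulus area
    in 2d, shell volume in 3d) and the mean partner density; identical
    selections exclude self-pairs.  Returns (bin centers, g(r)).
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.ndim == 2:
        a = a[None]
    if b.ndim == 2:
        b = b[None]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("empty selection")
    box = np.asarray(box, dtype=float)[:3]
    mode = mode.lower()
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    ndim = 2 if mode == "2d" else 3
    if r_max is None:
        r_max = float(box[:ndim].min()) / 2.0
    edges = np.linspace(0.0, r_max, n_bins + 1)
    same = a.shape == b.shape and np.array_equal(a, b)

    hist = np.zeros(n_bins)
    n_frames = a.shape[0]
    for f in range(n_frames):
        d = a[f][:, None, :ndim] - b[f][None, :, :ndim]
        d -= box[:ndim] * np.round(d / box[:ndim])
        r = np.sqrt(np.sum(d * d, axis=-1))
        if same:
            np.fill_diagonal(r, np.inf)
        hist += np.histogram(r, bins=edges)[0]

    centers = 0.5 * (edges[:-1] + edges[1:])
    if ndim == 2:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        density = b.shape[1] / (box[0] * box[1])
    else:
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        density = b.shape[1] / np.prod(box)
    n_ref = a.shape[1] if not same else a.shape[1]
    ideal = density * shell * n_ref * n_frames
    if same:
        ideal *= (b.shape[1] - 1) / b.shape[1]
    g = hist / ideal
    return centers, g


def detect_flip_flop(
    series: np.ndarray | Sequence[np.ndarray],
    threshold: float = 0.5,
    dwell: int = 5,
) -> list[int] | list[list[int]]:
    """Count leaflet flip-flop events in a cos(theta) series.

    An event is a transition between the states cos(theta) > +threshold and
    cos(theta) < -threshold; the new state registers only once the series has
    stayed in its band for ``dwell`` consecutive frames (hysteresis
    debouncing).  Returns the event frame indices (run starts) per probe,
    a flat list for a single series.
    """
    if not isinstance(series, np.ndarray):
        return [detect_flip_flop(np.asarray(s), threshold, dwell) for s in series]
    s = np.asarray(series, dtype=float)
    events: list[int] = []
    state = 0
    run_band = 0
    run_start = 0
    run_len = 0
    for i, v in enumerate(s):
        band = 1 if v > threshold else (-1 if v < -threshold else 0)
        if band == run_band:
            run_len += 1
        else:
            run_band, run_start, run_len = band, i, 1
        if run_band != 0 and run_len >= dwell and run_band != state:
            if state != 0:
                events.append(run_start)
            state = run_band
    return events
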