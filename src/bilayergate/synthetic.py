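"""Seeded synthetic-data generators with attached ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — lamellar quasi-Bragg scattering from a tri-Gaussian density,
pseudo-membrane leaflets with a radial deformation, ideal α-helices of set
tilt and kink, two-level Markov channel currents with Gaussian noise,
first-order liposome uptake, and two-state carbonyl-flip chains — and
returns its inputs alongside a :class:`SyntheticGroundTruth` recording every
parameter (seed included) so recovery tests can compare estimates against
the truth.  Identical seeds and parameters give byte-identical outputs; all
randomness flows through one ``numpy`` Generator per call.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError
from .gating import CurrentTrace, FluxTimeCourse
from .geometry import Frame, FlipTrace
from .saxs import ScatteringCurve, TriGaussianParams

__all__ = [
    "SyntheticGroundTruth",
    "gen_trigaussian_saxs",
    "gen_ideal_helix",
    "synthetic_kcsa_tetramer",
    "gen_membrane_frames",
    "gen_markov_trace",
    "gen_flux_counts",
    "gen_flip_series",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Provenance record attached to every generated dataset."""

    generator: str
    params: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def __post_init__(self):
        if "seed" not in self.params:
            raise InvalidParameterError("ground truth must record the seed")


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------


def gen_trigaussian_saxs(
    params: TriGaussianParams,
    d_space: float,
    n_orders: int = 2,
    peak_hwhm: float = 0.003,
    noise_sd: float = 0.0,
    seed: int = 0,
    q_step: float = 2e-4,
):
    """Lamellar I(q) with Lorentzian quasi-Bragg peaks from a tri-Gaussian density.

    The cosine coefficients of the profile over one repeat give the true
    form factors: ``c_h = (2/d) ∫ rho(z) cos(2 pi h z / d) dz`` by numerical
    integration; order ``h`` contributes a Lorentzian at ``q_h = 2 pi h / d``
    whose baseline-free area equals ``F_h^2 = c_h^2``.  Gaussian noise of
    ``noise_sd`` is added point-wise.  Phases (signs of ``c_h``) are
    recorded in the ground truth.
    """
    if n_orders < 2:
        raise InvalidParameterError("n_orders must be >= 2")
    if d_space <= 0 or peak_hwhm <= 0:
        raise InvalidParameterError("d_space and peak_hwhm must be > 0")
    rng = np.random.default_rng(seed)
    zfine = np.linspace(-d_space / 2.0, d_space / 2.0, 4001)
    rho = params.density(zfine)
    orders = np.arange(1, n_orders + 1)
    coeffs = np.array(
        [
            (2.0 / d_space)
            * np.trapezoid(rho * np.cos(2.0 * np.pi * h * zfine / d_space), zfine)
            for h in orders
        ]
    )
    F = np.abs(coeffs)
    phases = np.where(coeffs >= 0, 1, -1).astype(int)
    q_h = 2.0 * np.pi * orders / d_space
    q = np.arange(0.55 * q_h[0], q_h[-1] + 0.45 * q_h[0], q_step)
    intensity = np.zeros_like(q)
    for qh, Fh in zip(q_h, F):
        amp = Fh**2 / (math.pi * peak_hwhm)
        intensity += amp * peak_hwhm**2 / ((q - qh) ** 2 + peak_hwhm**2)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=q.size)
    truth = SyntheticGroundTruth(
        "gen_trigaussian_saxs",
        {
            "z_H": params.z_H,
            "sigma_H": params.sigma_H,
            "rho_r": params.rho_r,
            "sigma_C": params.sigma_C,
            "d_space": d_space,
            "n_orders": n_orders,
            "peak_hwhm": peak_hwhm,
            "noise_sd": noise_sd,
            "seed": seed,
            "form_factors": F.tolist(),
            "phases": phases.tolist(),
            "q_peaks": q_h.tolist(),
        },
    )
    return ScatteringCurve(q, intensity, label="synthetic lamellar"), truth


# ---------------------------------------------------------------------------
# helices and the pseudo-channel tetramer
# ---------------------------------------------------------------------------


def gen_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    radius: float = 2.3,
    turn_deg: float = 100.0,
    tilt_deg: float = 0.0,
    kink_after: int | None = None,
    kink_deg: float = 0.0,
) -> np.ndarray:
    """Cα coordinates of an ideal α-helix, optionally tilted and kinked.

    The canonical helix (defaults: 1.5 A rise, 2.3 A radius, 100° per
    residue) is built along +z; with ``kink_after`` set, residues beyond it
    are bent by ``kink_deg`` about the y axis through that residue's Cα;
    finally the whole helix is rotated by ``tilt_deg`` about y.  Note the
    endpoint Cα-to-Cα chord only parallels the helix axis when the two
    endpoints share the helical phase (``(n-1) * turn_deg`` a multiple of
    360°); with ``radius=0`` the construction degenerates to exact axis
    points, useful for angle fixtures.
    """
    if n_res < 4:
        raise InvalidParameterError("n_res must be >= 4")
    i = np.arange(n_res)
    ang = np.radians(turn_deg) * i
    xyz = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
    if kink_after is not None:
        if not (1 <= kink_after < n_res):
            raise InvalidParameterError("kink_after must lie inside the helix span")
        pivot = xyz[kink_after - 1].copy()
        R = _rot_y(np.radians(kink_deg))
        tail = slice(kink_after, n_res)
        xyz[tail] = (xyz[tail] - pivot) @ R.T + pivot
    if tilt_deg:
        xyz = xyz @ _rot_y(np.radians(tilt_deg)).T
    return xyz


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _bent_axis_trace(
    n_lower: int, n_upper: int, bend_deg: float, chord_tilt_deg: float, step: float = 1.5
) -> np.ndarray:
    """Two straight axis segments with a set mutual bend and chord tilt.

    Builds ``n_lower + n_upper`` points: the first segment along direction
    ``(sin a, 0, cos a)``, the second bent by ``bend_deg`` further from z in
    the x-z plane; ``a`` is solved so the end-to-end chord makes
    ``chord_tilt_deg`` with +z.
    """
    bend = math.radians(bend_deg)
    target = math.radians(chord_tilt_deg)
    n1, n2 = n_lower - 1, n_upper  # steps within lower segment, then upper points

    def chord_angle(a):
        d1 = np.array([math.sin(a), 0.0, math.cos(a)])
        d2 = np.array([math.sin(a + bend), 0.0, math.cos(a + bend)])
        c = n1 * step * d1 + n2 * step * d2
        return math.atan2(c[0], c[2]) - target  # signed: monotone in a

    a = brentq(chord_angle, -math.pi / 3, math.pi / 3, xtol=1e-12)
    d1 = np.array([math.sin(a), 0.0, math.cos(a)])
    d2 = np.array([math.sin(a + bend), 0.0, math.cos(a + bend)])
    pts = [np.zeros(3)]
    for _ in range(n1):
        pts.append(pts[-1] + step * d1)
    for _ in range(n2):
        pts.append(pts[-1] + step * d2)
    return np.asarray(pts)


def synthetic_kcsa_tetramer() -> Frame:
    """SYNTHETIC stand-in for a closed-state KcsA pore-domain Cα model.

    Constructed, not experimental: four chains (A-D) of idealised axis
    traces (zero helical radius) reproducing the closed-state pore-domain
    geometry reported for the crystal structure — outer helix M1 (residues
    24-51) with a 20° endpoint tilt and a 140° kink between the 24-42 and
    44-51 segments; inner helix M2 (residues 86-122) with a 33° tilt and a
    169° kink between the 86-103 and 105-121 segments — plus a
    selectivity-filter Cα stub (residues 75-79) defining the pore axis.
    Useful as a worked-example fixture wherever the real coordinates are
    not shipped.
    """
    # M1: residues 24..51 rise from the intracellular side; bend of 40° at
    # residue 43 gives the 140° kink; chord 24->51 tilted 20° from z.
    m1 = _bent_axis_trace(n_lower=20, n_upper=8, bend_deg=40.0, chord_tilt_deg=20.0)
    m1_resids = np.arange(24, 52)
    # M2 descends 86 -> 122; build ascending 122 -> 86 (bend 11° -> 169° kink,
    # chord 33°) then reverse the residue numbering.
    m2_path = _bent_axis_trace(n_lower=18, n_upper=19, bend_deg=11.0, chord_tilt_deg=33.0)
    m2 = m2_path[::-1]
    m2_resids = np.arange(86, 123)
    # place helix tops near z = 0 (the filter level)
    m1 = m1 - m1[-1] + np.array([15.0, 0.0, -2.0])
    m2 = m2 - m2[0] + np.array([8.0, 3.0, 0.0])
    filt = np.column_stack(
        [np.full(5, 4.0), np.linspace(-0.5, 0.5, 5), np.linspace(-1.0, 5.0, 5)]
    )
    filt_resids = np.arange(75, 80)

    names, resnames, resids, chains, coords = [], [], [], [], []
    one = np.vstack([m1, filt, m2])
    one_resids = np.concatenate([m1_resids, filt_resids, m2_resids])
    for ci, chain in enumerate("ABCD"):
        R = _rot_z(math.radians(90.0 * ci))
        xyz = one @ R.T
        coords.append(xyz)
        names += ["CA"] * len(one)
        resnames += ["ALA"] * len(one)
        resids += list(one_resids)
        chains += [chain] * len(one)
    return Frame(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids),
        chains=np.array(chains, dtype=object),
        xyz=np.vstack(coords),
    )


# ---------------------------------------------------------------------------
# pseudo-membranes
# ---------------------------------------------------------------------------


def gen_membrane_frames(
    n_frames: int,
    n_lipids_per_leaflet: int,
    box: float = 140.0,
    leaflet_z: float = 15.0,
    deformation=None,
    atom_noise_sd: float = 0.5,
    seed: int = 0,
    popg_fraction: float = 0.3,
    embed_protein: Frame | None = None,
):
    """Pseudo-membrane trajectory: point first-alkyl-carbon atoms per leaflet.

    Each pseudo-lipid contributes two atoms (C22, C32); xy positions are
    drawn uniformly over the box independently per frame, emulating the
    fast lateral diffusion of lipids between widely spaced analysis frames.
    Leaflet z is ``±(leaflet_z - deformation(r))`` plus per-atom, per-frame
    Gaussian noise; ``deformation`` is a callable of radial distance (A) or
    None for flat leaflets.  Lipid resnames mix POPC/POPG at
    ``popg_fraction``.  An optional protein frame (e.g. the synthetic
    tetramer) is concatenated unchanged into every frame.
    """
    if n_frames < 1 or n_lipids_per_leaflet < 1:
        raise InvalidParameterError("need >= 1 frame and >= 1 lipid per leaflet")
    if box**2 / n_lipids_per_leaflet < 60.0:
        raise InvalidParameterError(
            "overcrowded membrane: need >= 60 A^2 per lipid per leaflet"
        )
    rng = np.random.default_rng(seed)
    n_tot = 2 * n_lipids_per_leaflet  # both leaflets
    leaflet_sign = np.repeat(
        np.concatenate(
            [np.ones(n_lipids_per_leaflet), -np.ones(n_lipids_per_leaflet)]
        ),
        2,
    )
    # sn-2 (C22) at the lipid position, sn-1 (C32) offset within the molecule
    offsets = np.array([[0.0, 0.0], [1.5, 0.0]])
    resids = np.repeat(np.arange(1, n_tot + 1), 2)
    is_pg = rng.random(n_tot) < popg_fraction
    resnames = np.repeat(np.where(is_pg, "POPG", "POPC"), 2).astype(object)
    names = np.tile(np.array(["C22", "C32"], dtype=object), n_tot)
    chains = np.array(["M"] * (2 * n_tot), dtype=object)

    frames = []
    for fi in range(n_frames):
        xy_lipid = rng.uniform(-box / 2.0, box / 2.0, size=(n_tot, 2))
        xy = (xy_lipid[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        r = np.hypot(xy[:, 0], xy[:, 1])
        base_mag = leaflet_z - (deformation(r) if deformation is not None else 0.0)
        z = leaflet_sign * base_mag + rng.normal(0.0, atom_noise_sd, size=xy.shape[0])
        xyz = np.column_stack([xy[:, 0], xy[:, 1], z])
        if embed_protein is not None:
            frame = Frame(
                names=np.concatenate([names, embed_protein.names]),
                resnames=np.concatenate([resnames, embed_protein.resnames]),
                resids=np.concatenate([resids, embed_protein.resids]),
                chains=np.concatenate([chains, embed_protein.chains]),
                xyz=np.vstack([xyz, embed_protein.xyz]),
                box=np.array([box, box, 4 * leaflet_z]),
                time=float(fi),
            )
        else:
            frame = Frame(
                names=names.copy(),
                resnames=resnames.copy(),
                resids=resids.copy(),
                chains=chains.copy(),
                xyz=xyz,
                box=np.array([box, box, 4 * leaflet_z]),
                time=float(fi),
            )
        frames.append(frame)
    truth = SyntheticGroundTruth(
        "gen_membrane_frames",
        {
            "n_frames": n_frames,
            "n_lipids_per_leaflet": n_lipids_per_leaflet,
            "box": box,
            "leaflet_z": leaflet_z,
            "atom_noise_sd": atom_noise_sd,
            "popg_fraction": popg_fraction,
            "seed": seed,
            "flat_thickness": 2.0 * leaflet_z,
            "has_deformation": deformation is not None,
        },
    )
    return frames, truth


# ---------------------------------------------------------------------------
# channel currents
# ---------------------------------------------------------------------------


def gen_markov_trace(
    open_rate: float,
    close_rate,
    i_unitary: float = 2.0,
    noise_sd: float = 0.2,
    fs: float = 50000.0,
    duration: float = 10.0,
    seed: int = 0,
    voltage: float = 100.0,
):
    """Two-level Markov gating current sampled at ``fs`` with Gaussian noise.

    In the plain two-state mode ``open_rate`` (1/s) is the closed→open rate
    (closed dwells exponential with mean ``1/open_rate``) and ``close_rate``
    the open→closed rate (open dwells with mean ``1/close_rate``).
    Alternatively ``close_rate`` may be a closed-dwell mixture spec
    ``{"means_ms": [...], "weights": [...]}``: closed sojourns are then drawn
    from that aggregated multi-state mixture while open dwells stay
    exponential with mean ``1/open_rate`` seconds (``open_rate`` acting as
    the open-state exit rate).  Ground truth records the full event list and
    the stationary open probability.
    """
    if open_rate <= 0:
        raise InvalidParameterError("open_rate must be > 0")
    if duration * fs > 1e8:
        raise InvalidParameterError("duration * fs must be <= 1e8 samples")
    rng = np.random.default_rng(seed)

    mixture = isinstance(close_rate, dict)
    if mixture:
        means_ms = np.asarray(close_rate["means_ms"], dtype=float)
        weights = np.asarray(close_rate["weights"], dtype=float)
        weights = weights / weights.sum()
        mean_closed_s = float(np.sum(weights * means_ms)) / 1000.0
        mean_open_s = 1.0 / open_rate
    else:
        if close_rate <= 0:
            raise InvalidParameterError("close_rate must be > 0")
        mean_closed_s = 1.0 / open_rate
        mean_open_s = 1.0 / close_rate
    p_open = mean_open_s / (mean_open_s + mean_closed_s)

    def draw_closed():
        if mixture:
            j = rng.choice(means_ms.size, p=weights)
            return rng.exponential(means_ms[j] / 1000.0)
        return rng.exponential(mean_closed_s)

    state = bool(rng.random() < p_open)  # True = open, stationary start
    t = 0.0
    ends, states = [], []
    while t < duration:
        dwell = rng.exponential(mean_open_s) if state else draw_closed()
        t += dwell
        ends.append(min(t, duration))
        states.append(state)
        state = not state
    ends = np.asarray(ends)
    states_arr = np.asarray(states, dtype=bool)
    n = int(round(duration * fs))
    sample_t = (np.arange(n) + 0.5) / fs
    idx = np.searchsorted(ends, sample_t, side="right").clip(max=ends.size - 1)
    level = np.where(states_arr[idx], i_unitary, 0.0)
    current = level + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else level
    starts = np.concatenate(([0.0], ends[:-1]))
    events = [
        ("open" if s else "closed", float((e - b) * 1000.0))
        for s, b, e in zip(states_arr, starts, ends)
    ]
    truth = SyntheticGroundTruth(
        "gen_markov_trace",
        {
            "open_rate": open_rate,
            "close_rate": close_rate if not mixture else dict(close_rate),
            "i_unitary": i_unitary,
            "noise_sd": noise_sd,
            "fs": fs,
            "duration": duration,
            "seed": seed,
            "p_open": p_open,
            "events": events,
        },
    )
    return CurrentTrace(current, fs=fs, filter_hz=min(2000.0, fs / 4), voltage=voltage), truth


# ---------------------------------------------------------------------------
# flux and flips
# ---------------------------------------------------------------------------


def gen_flux_counts(
    k_uptake: float,
    capacity_counts: float,
    background_counts: float,
    times,
    poisson_noise: bool = False,
    seed: int = 0,
):
    """First-order liposome uptake: counts(t) = bg + cap (1 - exp(-k t))."""
    if capacity_counts <= 0:
        raise InvalidParameterError("capacity must be > 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    mean = background_counts + capacity_counts * (1.0 - np.exp(-k_uptake * t))
    counts = rng.poisson(mean).astype(float) if poisson_noise else mean
    fc = FluxTimeCourse(
        times=t,
        counts=counts,
        background=background_counts,
        valinomycin=background_counts + capacity_counts,
    )
    truth = SyntheticGroundTruth(
        "gen_flux_counts",
        {
            "k_uptake": k_uptake,
            "capacity_counts": capacity_counts,
            "background_counts": background_counts,
            "poisson_noise": poisson_noise,
            "seed": seed,
        },
    )
    return fc, truth


def gen_flip_series(
    p_leave_inward: float,
    p_leave_flipped: float,
    n_frames: int,
    frame_dt: float = 0.1,
    seed: int = 0,
    residue: str = "V76",
    chain: str = "A",
):
    """Per-frame two-state Markov chain of carbonyl orientations."""
    for p in (p_leave_inward, p_leave_flipped):
        if not 0.0 < p < 1.0:
            raise InvalidParameterError("transition probabilities must be in (0, 1)")
    rng = np.random.default_rng(seed)
    stationary_flipped = p_leave_inward / (p_leave_inward + p_leave_flipped)
    states = np.empty(n_frames, dtype=object)
    flipped = bool(rng.random() < stationary_flipped)
    u = rng.random(n_frames)
    for i in range(n_frames):
        states[i] = "flipped" if flipped else "inward"
        p_leave = p_leave_flipped if flipped else p_leave_inward
        if u[i] < p_leave:
            flipped = not flipped
    trace = FlipTrace(residue=residue, chain=chain, states=states, frame_dt=frame_dt)
    truth = SyntheticGroundTruth(
        "gen_flip_series",
        {
            "p_leave_inward": p_leave_inward,
            "p_leave_flipped": p_leave_flipped,
            "n_frames": n_frames,
            "frame_dt": frame_dt,
            "seed": seed,
            "stationary_flipped": stationary_flipped,
        },
    )
    return trace, truth
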