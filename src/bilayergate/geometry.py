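"""Geometric observables of membrane-protein/bilayer coordinate frames.

Everything here works on :class:`Frame` objects — flat arrays of labelled
atoms — after alignment of the channel's pore axis to +z.  Observables:

* helix tilt: angle between a helix endpoint Cα→Cα vector and the pore axis;
* helix kink: 180° minus the angle between the N→C vectors of the lower and
  upper helix segments (a straight helix reads ≈180°);
* hydrophobic length: |Δz| of the endpoint Cα pair;
* radial hydrophobic thickness: leaflet-resolved mean separation of the
  first acyl-chain carbons after the glycerol ester (CHARMM names C22/C32),
  binned in annuli around the pore axis, with blocking-transform errors;
* carbonyl flip states of selectivity-filter residues, classified from the
  radial projection of the backbone C=O vector with a hysteresis band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .blocking import blocking_stderr
from .errors import InsufficientDataError, InvalidParameterError, SelectionError

__all__ = [
    "Frame",
    "HelixSpec",
    "HELIX_PRESETS",
    "RadialThicknessProfile",
    "FlipTrace",
    "align_to_pore_axis",
    "helix_tilt",
    "helix_kink",
    "hydrophobic_length",
    "first_alkyl_carbons",
    "radial_thickness_profile",
    "bulk_thickness",
    "carbonyl_flip_projection",
    "carbonyl_flip_state",
    "classify_flip_trace",
    "flip_dwells",
    "DEFAULT_FIRST_ALKYL_NAMES",
]

#: First acyl-chain carbon after the glycerol ester linkage, sn-2 and sn-1
#: chains, in the CHARMM36 glycerophospholipid atom-naming convention.
DEFAULT_FIRST_ALKYL_NAMES = ("C22", "C32")

#: Selectivity-filter residues used to centre the pore axis.
DEFAULT_PORE_RESIDUES = (75, 76, 77, 78, 79)


# ---------------------------------------------------------------------------
# frame container
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One set of atomic coordinates with chain/residue/atom labels.

    Arrays are parallel; coordinates in Angstrom.  ``box`` is an optional
    (3,) array of periodic box lengths, ``time`` an optional timestamp in ns.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    xyz: np.ndarray
    box: np.ndarray | None = None
    time: float | None = None

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = self.names.size
        if self.xyz.shape != (n, 3):
            raise InvalidParameterError("xyz must have shape (n_atoms, 3)")
        if not (
            self.resnames.size == n and self.resids.size == n and self.chains.size == n
        ):
            raise InvalidParameterError("label arrays must be parallel")
        if not np.all(np.isfinite(self.xyz)):
            raise InvalidParameterError("coordinates must be finite")

    def __len__(self):
        return self.names.size

    def mask(
        self,
        chain=None,
        resid=None,
        resname=None,
        name=None,
    ) -> np.ndarray:
        """Boolean selection mask; each criterion accepts a scalar or set."""

        def crit(values, wanted):
            if wanted is None:
                return np.ones(len(self), dtype=bool)
            if np.isscalar(wanted) or isinstance(wanted, str):
                wanted = (wanted,)
            return np.isin(values, np.asarray(list(wanted), dtype=values.dtype))

        return (
            crit(self.chains, chain)
            & crit(self.resids, resid)
            & crit(self.resnames, resname)
            & crit(self.names, name)
        )

    def coord(self, chain, resid, name) -> np.ndarray:
        """Coordinates of a single atom; raises SelectionError if absent."""
        m = self.mask(chain=chain, resid=resid, name=name)
        hits = np.flatnonzero(m)
        if hits.size != 1:
            raise SelectionError(
                f"atom {name} of residue {resid} chain {chain}: {hits.size} matches"
            )
        return self.xyz[hits[0]]

    def protein_chains(self) -> list:
        """Chains containing Cα atoms, in order of first appearance."""
        seen = []
        for c in self.chains[self.names == "CA"]:
            if c not in seen:
                seen.append(c)
        return seen

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """New frame with ``xyz -> (xyz + translation) @ rotation.T``."""
        xyz = (self.xyz + translation) @ rotation.T
        return replace(self, xyz=xyz)


@dataclass(frozen=True)
class HelixSpec:
    """Residue spans defining a transmembrane helix's measured vectors.

    ``span`` is the full endpoint pair used for the tilt vector; ``upper``
    and ``lower`` are the kink sub-segments (both taken N→C); ``length_span``
    overrides ``span`` for the hydrophobic-length projection when the two
    conventions differ.  ``chain=None`` means "every protein chain".
    """

    span: tuple
    upper: tuple
    lower: tuple
    chain: str | None = None
    length_span: tuple | None = None
    name: str = ""

    def __post_init__(self):
        for pair in (self.span, self.upper, self.lower, self.length_span):
            if pair is not None and pair[0] >= pair[1]:
                raise InvalidParameterError(f"residue pair {pair} must be ordered")
        lo, hi = self.span
        for pair in (self.upper, self.lower):
            if pair[0] < lo or pair[1] > hi:
                raise InvalidParameterError(
                    f"kink sub-span {pair} falls outside helix span {self.span}"
                )


#: Shipped residue-span presets for the KcsA pore-domain helices.  Tilt uses
#: the full-helix endpoint pairs; hydrophobic length uses the slightly
#: shorter membrane-spanning windows.
HELIX_PRESETS = {
    "kcsa-m1": HelixSpec(
        span=(24, 51), upper=(44, 51), lower=(24, 42), length_span=(26, 45),
        name="kcsa-m1",
    ),
    "kcsa-m2": HelixSpec(
        span=(86, 122), upper=(86, 103), lower=(105, 121), length_span=(87, 113),
        name="kcsa-m2",
    ),
}


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def align_to_pore_axis(
    frame: Frame,
    pore_residues: Sequence[int] = DEFAULT_PORE_RESIDUES,
    domain_residues: Sequence[int] | None = None,
) -> Frame:
    """Centre the selectivity filter at the origin and align the pore to +z.

    The centroid of the filter Cα atoms (default residues 75-79, all protein
    chains) is moved to the origin; the smallest-moment principal axis of
    the pore-domain Cα cloud is rotated onto +z; the sign is fixed so the
    extracellular (filter) side points to +z.
    """
    chains = frame.protein_chains()
    if not chains:
        raise SelectionError("frame contains no protein Cα atoms")
    filt_mask = frame.mask(resid=tuple(pore_residues), name="CA") & np.isin(
        frame.chains, chains
    )
    if not filt_mask.any():
        raise SelectionError(f"no Cα atoms for pore residues {tuple(pore_residues)}")
    for c in chains:
        if not (filt_mask & (frame.chains == c)).any():
            raise SelectionError(f"pore residues missing from chain {c!r}")

    dom_mask = frame.mask(name="CA") & np.isin(frame.chains, chains)
    if domain_residues is not None:
        dom_mask &= frame.mask(resid=tuple(domain_residues))

    centroid = frame.xyz[filt_mask].mean(axis=0)
    pts = frame.xyz[dom_mask] - centroid
    # inertia tensor of the Cα cloud; its smallest-moment eigenvector is the
    # long (pore) axis of the bundle
    r2 = np.sum(pts**2, axis=1).sum()
    inertia = r2 * np.eye(3) - pts.T @ pts
    evals, evecs = np.linalg.eigh(inertia)
    axis = evecs[:, np.argmin(evals)]
    if axis[2] < 0:
        axis = -axis
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    out = frame.transformed(rot, -centroid)
    # extracellular side (the filter) up: the protein body must lie below it
    if out.xyz[dom_mask][:, 2].mean() > 0:
        out = out.transformed(_axis_angle([1.0, 0.0, 0.0], np.pi), np.zeros(3))
    return out


# ---------------------------------------------------------------------------
# helix observables
# ---------------------------------------------------------------------------


def _spec_chains(frame: Frame, spec: HelixSpec) -> list:
    if spec.chain is not None:
        return [spec.chain]
    chains = frame.protein_chains()
    if not chains:
        raise SelectionError("frame contains no protein Cα atoms")
    return chains


def helix_tilt(frame: Frame, spec: HelixSpec) -> pd.Series:
    """Tilt of the helix endpoint vector from +z, degrees in [0, 90].

    Returns a Series indexed by chain; the subunit mean is ``.mean()``.
    The frame must already be pore-axis aligned.
    """
    out = {}
    for c in _spec_chains(frame, spec):
        v = frame.coord(c, spec.span[1], "CA") - frame.coord(c, spec.span[0], "CA")
        cos_t = abs(v[2]) / np.linalg.norm(v)
        out[c] = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    return pd.Series(out, name="tilt_deg")


def helix_kink(frame: Frame, spec: HelixSpec) -> pd.Series:
    """Kink angle between the lower and upper helix segments, degrees.

    Both segment vectors are taken N→C, so a straight helix reads ≈180° and
    a 40° bend reads 140°.
    """
    out = {}
    for c in _spec_chains(frame, spec):
        low = frame.coord(c, spec.lower[1], "CA") - frame.coord(c, spec.lower[0], "CA")
        up = frame.coord(c, spec.upper[1], "CA") - frame.coord(c, spec.upper[0], "CA")
        cos_a = np.dot(low, up) / (np.linalg.norm(low) * np.linalg.norm(up))
        bend = float(np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0))))
        out[c] = 180.0 - bend
    return pd.Series(out, name="kink_deg")


def hydrophobic_length(frame: Frame, spec: HelixSpec) -> pd.Series:
    """|z-projection| of the helix endpoint Cα vector, Angstrom.

    Uses ``spec.length_span`` when set (the membrane-spanning window),
    otherwise the full tilt span.
    """
    span = spec.length_span if spec.length_span is not None else spec.span
    out = {}
    for c in _spec_chains(frame, spec):
        v = frame.coord(c, span[1], "CA") - frame.coord(c, span[0], "CA")
        out[c] = float(abs(v[2]))
    return pd.Series(out, name="hydrophobic_length_A")


# ---------------------------------------------------------------------------
# radial hydrophobic thickness
# ---------------------------------------------------------------------------


def first_alkyl_carbons(
    frame: Frame,
    lipid_names: Sequence[str] | None = None,
    atom_names: Sequence[str] = DEFAULT_FIRST_ALKYL_NAMES,
) -> np.ndarray:
    """Indices of the first acyl-chain carbons of the named lipid residues."""
    mask = frame.mask(name=tuple(atom_names))
    if lipid_names is not None:
        mask &= frame.mask(resname=tuple(lipid_names))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        pool = frame.mask(resname=tuple(lipid_names)) if lipid_names else slice(None)
        available = sorted(set(frame.names[pool]))[:40]
        raise SelectionError(
            f"no atoms named {tuple(atom_names)} found; available names: {available}"
        )
    return idx


def _assign_leaflets(z: np.ndarray, exclude_band: float = 2.0):
    """Upper/lower leaflet masks by sign of z about an iterated midplane."""
    mid = float(np.mean(z))
    for _ in range(2):
        up, lo = z > mid, z < mid
        if not up.any() or not lo.any():
            break
        mid = 0.5 * (z[up].mean() + z[lo].mean())
    upper = z > mid + exclude_band
    lower = z < mid - exclude_band
    return upper, lower


@dataclass
class RadialThicknessProfile:
    """Leaflet-to-leaflet hydrophobic thickness binned in annuli around +z."""

    r_bins: np.ndarray  # annulus edges, A
    thickness: np.ndarray  # mean interleaflet distance per bin, A (NaN: undefined)
    stderr: np.ndarray  # blocking-transform error per bin, A
    counts: np.ndarray  # (2, n_bins) atoms per leaflet summed over frames
    n_frames: int = 1
    per_frame: np.ndarray | None = field(default=None, repr=False)

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_bins[:-1] + self.r_bins[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_center": self.r_centers,
                "thickness": self.thickness,
                "stderr": self.stderr,
                "count_upper": self.counts[0],
                "count_lower": self.counts[1],
            }
        )

    def plot(self, ax=None):
        """Thickness vs radial distance with error bars (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = np.isfinite(self.thickness)
        ax.errorbar(
            self.r_centers[ok], self.thickness[ok], yerr=self.stderr[ok], fmt="o-"
        )
        ax.set_xlabel("r from pore axis (A)")
        ax.set_ylabel("hydrophobic thickness (A)")
        return ax


def radial_thickness_profile(
    frames: Sequence[Frame],
    bin_width: float = 2.0,
    r_max: float = 70.0,
    lipid_names: Sequence[str] | None = None,
    atom_names: Sequence[str] = DEFAULT_FIRST_ALKYL_NAMES,
    exclude_band: float = 2.0,
) -> RadialThicknessProfile:
    """Radially averaged leaflet separation of the first alkyl carbons.

    Per annular bin, thickness = mean z(upper) − mean z(lower) with the
    leaflet means pooled over every atom of every frame (the time-averaged
    radial density), so sparse bins use all of their observations.  The
    error bar is the blocking-transform standard error of the per-frame
    thickness series (conservative for sparse bins, where single frames
    may miss one leaflet).  Bins empty in either leaflet over the whole
    trajectory are reported as NaN, never as zero.
    """
    frames = list(frames)
    if not frames:
        raise InsufficientDataError("at least one frame required")
    if bin_width <= 0 or r_max <= bin_width:
        raise InvalidParameterError("need 0 < bin_width < r_max")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    nb = edges.size - 1
    per_frame = np.full((len(frames), nb), np.nan)
    counts = np.zeros((2, nb), dtype=int)
    zsum = np.zeros((2, nb))
    for fi, frame in enumerate(frames):
        idx = first_alkyl_carbons(frame, lipid_names, atom_names)
        xyz = frame.xyz[idx]
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        z = xyz[:, 2]
        upper, lower = _assign_leaflets(z, exclude_band)
        which = np.digitize(r, edges) - 1
        inside = (which >= 0) & (which < nb)
        for b in range(nb):
            sel = inside & (which == b)
            zu, zl = z[sel & upper], z[sel & lower]
            counts[0, b] += zu.size
            counts[1, b] += zl.size
            zsum[0, b] += zu.sum()
            zsum[1, b] += zl.sum()
            if zu.size and zl.size:
                per_frame[fi, b] = zu.mean() - zl.mean()
    thickness = np.full(nb, np.nan)
    stderr = np.full(nb, np.nan)
    for b in range(nb):
        if counts[0, b] == 0 or counts[1, b] == 0:
            continue
        thickness[b] = zsum[0, b] / counts[0, b] - zsum[1, b] / counts[1, b]
        vals = per_frame[:, b]
        vals = vals[np.isfinite(vals)]
        if vals.size >= 8:
            stderr[b] = blocking_stderr(vals).stderr
        elif vals.size > 1:
            stderr[b] = vals.std(ddof=1) / np.sqrt(vals.size)
        elif vals.size == 1:
            stderr[b] = 0.0
    return RadialThicknessProfile(
        r_bins=edges,
        thickness=thickness,
        stderr=stderr,
        counts=counts,
        n_frames=len(frames),
        per_frame=per_frame,
    )


def bulk_thickness(
    profile: RadialThicknessProfile, r_min: float = 45.0
) -> tuple[float, float]:
    """Count-weighted mean thickness of bins beyond ``r_min`` (the far field).

    Returns ``(thickness, stderr)``; the error combines the per-bin blocking
    errors under the count weights.
    """
    centers = profile.r_centers
    ok = (centers > r_min) & np.isfinite(profile.thickness)
    if not ok.any():
        raise InsufficientDataError(f"no populated bins beyond r_min={r_min} A")
    w = (profile.counts[0] + profile.counts[1])[ok].astype(float)
    t = profile.thickness[ok]
    se = profile.stderr[ok]
    wsum = w.sum()
    value = float(np.sum(w * t) / wsum)
    err = float(np.sqrt(np.sum((w * se) ** 2)) / wsum) if np.all(np.isfinite(se)) else float("nan")
    return value, err


# ---------------------------------------------------------------------------
# carbonyl flips
# ---------------------------------------------------------------------------


def carbonyl_flip_projection(frame: Frame, chain, residue: int) -> float:
    """Radial projection u·r̂ of the unit backbone C→O vector.

    ``r̂`` is the outward unit vector from the pore (z) axis to the carbonyl
    carbon.  Negative: oxygen points toward the axis (inward); positive:
    flipped away.
    """
    c = frame.coord(chain, residue, "C")
    o = frame.coord(chain, residue, "O")
    u = o - c
    u = u / np.linalg.norm(u)
    rhat = np.array([c[0], c[1], 0.0])
    nr = np.linalg.norm(rhat)
    if nr < 1e-9:
        raise SelectionError(
            f"carbonyl C of residue {residue} chain {chain} sits on the pore axis"
        )
    return float(np.dot(u, rhat / nr))


def carbonyl_flip_state(frame: Frame, chain, residue: int) -> str:
    """Classify one carbonyl as ``"inward"`` or ``"flipped"`` (single frame)."""
    return "inward" if carbonyl_flip_projection(frame, chain, residue) < 0 else "flipped"


@dataclass
class FlipTrace:
    """Per-frame carbonyl orientation labels for one residue/chain."""

    residue: str
    chain: str
    states: np.ndarray  # of "inward" / "flipped"
    frame_dt: float  # ns

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        if self.states.size == 0:
            raise InvalidParameterError("empty flip trace")
        bad = set(self.states) - {"inward", "flipped"}
        if bad:
            raise InvalidParameterError(f"unknown states {bad}")


def classify_flip_trace(
    frames: Sequence[Frame],
    chain,
    residue: int,
    frame_dt: float,
    hysteresis: float = 0.17,
    residue_label: str | None = None,
) -> FlipTrace:
    """Classify a carbonyl's orientation over a trajectory with hysteresis.

    A state change is accepted only when the radial projection exceeds
    ``hysteresis`` in magnitude (default 0.17 ≈ a ±10° band about the
    perpendicular), suppressing frame-to-frame chatter near the boundary.
    """
    proj = np.array([carbonyl_flip_projection(f, chain, residue) for f in frames])
    states = np.empty(proj.size, dtype=object)
    current = "inward" if proj[0] < 0 else "flipped"
    for i, p in enumerate(proj):
        if abs(p) > hysteresis:
            candidate = "inward" if p < 0 else "flipped"
            if candidate != current:
                current = candidate
        states[i] = current
    return FlipTrace(
        residue=residue_label or str(residue),
        chain=str(chain),
        states=states,
        frame_dt=frame_dt,
    )


def flip_dwells(
    trace: FlipTrace, long_threshold: float = 75.0
) -> tuple[pd.DataFrame, float]:
    """Run-length encode a flip trace into dwells.

    Returns a DataFrame (state, duration_ns, censored) — first and last
    dwells are flagged censored since their true extent is unobserved — and
    the fraction of all dwells longer than ``long_threshold`` ns.
    """
    states = trace.states
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    df = pd.DataFrame(
        {
            "state": [states[s] for s in starts],
            "duration_ns": (ends - starts) * trace.frame_dt,
            "censored": [False] * starts.size,
        }
    )
    df.loc[0, "censored"] = True
    df.loc[df.index[-1], "censored"] = True
    fraction_long = float((df["duration_ns"] > long_threshold).mean())
    return df, fraction_long
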