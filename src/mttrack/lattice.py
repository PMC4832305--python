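"""Ground-truth microtubule lattice simulation.

A microtubule is modelled as 13 protofilaments of 8 nm tubulin subunits
arranged on a 3-start B-lattice.  Growth is diffusive: the net number of
subunits exchanged per frame is drawn from a normal distribution whose
mean is set by the average growth speed ``v_g`` and whose variance is
set by an effective tip diffusion coefficient ``D_p``.  A linear
distribution of protofilament lengths (the "taper") of fixed axial
extent is maintained as subunits are added or removed.  Thermal bending
is modelled as a first-order uniformly loaded cantilever clamped at the
seed, with a normally distributed tip deflection redrawn every frame.

The tip position used as ground truth is the mean of the axial
coordinates of the terminal subunit on each protofilament, regardless
of labelling state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeParams",
    "GrowthParams",
    "LatticeState",
    "new_lattice",
    "step_growth",
    "place_subunits",
    "removed_subunit_coords",
    "tip_coords_local",
    "true_end",
    "sigma_pf",
    "beam_shape",
    "apply_thermal_deflection",
    "to_frame",
]


@dataclass(frozen=True)
class LatticeParams:
    """Static structural parameters of the microtubule lattice."""

    n_protofilaments: int = 13
    subunit_length: float = 8.0  # nm per alpha-beta tubulin dimer
    lattice_radius: float = 12.5  # nm; half the 25 nm outer diameter
    helix_start: int = 3  # 3-start B lattice
    labelling_ratio: float = 0.2  # fluorophores per subunit

    def __post_init__(self) -> None:
        if self.n_protofilaments < 1:
            raise ValueError("n_protofilaments must be >= 1")
        if not 0.0 <= self.labelling_ratio <= 1.0:
            raise ValueError("labelling_ratio must be in [0, 1]")
        if self.subunit_length <= 0:
            raise ValueError("subunit_length must be positive")

    @property
    def helix_rise(self) -> float:
        """Axial rise per protofilament around one turn (nm)."""
        return self.helix_start * self.subunit_length / self.n_protofilaments


@dataclass(frozen=True)
class GrowthParams:
    """Dynamic parameters of a growth episode.

    v_g : mean growth speed, nm/s
    D_p : effective diffusion coefficient of the tip about its mean
          trajectory, nm^2/s
    sigma_LD : SD of the thermal lateral tip deflection, nm
    taper_length : axial extent of the protofilament-length ramp, nm
    frame_interval, exposure : s
    """

    v_g: float = 11.0
    D_p: float = 271.0
    sigma_LD: float = 150.0
    taper_length: float = 96.0
    frame_interval: float = 0.2
    exposure: float = 0.2

    def __post_init__(self) -> None:
        if self.D_p < 0 or self.sigma_LD < 0 or self.taper_length < 0:
            raise ValueError("D_p, sigma_LD and taper_length must be >= 0")
        if not 0 < self.exposure <= self.frame_interval:
            raise ValueError("need 0 < exposure <= frame_interval")


@dataclass
class LatticeState:
    """Mutable per-frame lattice state.

    ``labels[p]`` holds one boolean per subunit of protofilament ``p``;
    flags are assigned once at incorporation and never resampled.
    ``last_added``/``last_removed_labelled`` record the subunit turnover
    of the most recent growth step in chronological order, for exposure
    weighting during rendering.
    """

    pf_lengths: np.ndarray  # integer subunit counts, shape (n_pf,)
    labels: list[np.ndarray]
    seed_lengths: np.ndarray  # lattice below this is the immobile seed
    seed_origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    axis_angle: float = 0.0
    tip_deflection: float = 0.0  # nm, current thermal tip deflection
    clamp_length: float = 0.0  # nm of rigid seed for the beam model
    last_added: list[tuple[int, int]] = field(default_factory=list)
    last_removed_labelled: list[tuple[int, int]] = field(default_factory=list)
    hit_seed: bool = False  # shrinkage clamped at the seed this step

    @property
    def n_subunits(self) -> int:
        return int(self.pf_lengths.sum())


def _target_lengths(total: int, lp: LatticeParams, taper_length: float) -> np.ndarray:
    """Integer protofilament lengths whose tips form a linear ramp.

    The tip of protofilament ``p`` sits at ``(L_p - 1)*d + p*rise``;
    targets are chosen so the sorted tip positions span ``taper_length``
    and the counts sum exactly to ``total`` (largest-remainder rounding).
    """
    n = lp.n_protofilaments
    d = lp.subunit_length
    if n == 1:
        return np.array([total])
    ramp = (np.arange(n) / (n - 1) - 0.5) * taper_length
    stagger = np.arange(n) * lp.helix_rise
    # real-valued lengths with the correct sum
    l_real = (ramp - stagger) / d
    l_real += (total - l_real.sum()) / n
    base = np.floor(l_real).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(l_real - base), kind="stable")
    base[order[:short]] += 1
    return np.maximum(base, 1)


def new_lattice(
    lp: LatticeParams,
    gp: GrowthParams,
    seed_length_nm: float,
    initial_length_nm: float | None = None,
    seed_origin: tuple[float, float] = (0.0, 0.0),
    axis_angle: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LatticeState:
    """Create a lattice with a blunt seed and an optional tapered extension."""
    rng = np.random.default_rng(rng)
    n = lp.n_protofilaments
    seed_sub = max(int(round(seed_length_nm / lp.subunit_length)), 2)
    seed_lengths = np.full(n, seed_sub)
    if initial_length_nm is None or initial_length_nm <= seed_length_nm:
        pf_lengths = seed_lengths.copy()
    else:
        total = max(int(round(initial_length_nm / lp.subunit_length)) * n, seed_sub * n)
        pf_lengths = np.maximum(_target_lengths(total, lp, gp.taper_length), seed_lengths)
    labels = [rng.random(int(m)) < lp.labelling_ratio for m in pf_lengths]
    return LatticeState(
        pf_lengths=pf_lengths,
        labels=labels,
        seed_lengths=seed_lengths,
        seed_origin=np.asarray(seed_origin, dtype=float),
        axis_angle=axis_angle,
        clamp_length=seed_sub * lp.subunit_length,
    )


def _subunit_z(pf: int, index: int, lp: LatticeParams) -> float:
    return index * lp.subunit_length + pf * lp.helix_rise


def step_growth(
    state: LatticeState,
    gp: GrowthParams,
    lp: LatticeParams,
    rng: np.random.Generator,
) -> LatticeState:
    """Advance the lattice by one frame interval.

    The net subunit change ``N`` is drawn from a normal law with mean
    ``v_g * dt * n_pf / d`` and variance ``2 * D_p * dt * (n_pf / d)**2``
    (so the tip position performs diffusion with coefficient ``D_p``
    about its mean trajectory), rounded half-to-even.  New subunits fill
    the shortest protofilaments so the taper ramp stays stationary; net
    loss removes from the longest.  Shrinkage below the seed clamps.
    """
    dt = gp.frame_interval
    n = lp.n_protofilaments
    per_nm = n / lp.subunit_length
    mu = gp.v_g * dt * per_nm
    sigma = np.sqrt(2.0 * gp.D_p * dt) * per_nm
    raw = mu if sigma == 0 else rng.normal(mu, sigma)
    n_net = int(np.rint(raw))

    total = state.n_subunits + n_net
    seed_total = int(state.seed_lengths.sum())
    hit_seed = total < seed_total
    if hit_seed:
        total = seed_total
    new_lengths = np.maximum(
        _target_lengths(total, lp, gp.taper_length), state.seed_lengths
    )

    labels = [lab.copy() for lab in state.labels]
    added: list[tuple[int, int, float]] = []
    removed_lab: list[tuple[int, int, float]] = []
    for p in range(n):
        old, new = int(state.pf_lengths[p]), int(new_lengths[p])
        if new > old:
            fresh = rng.random(new - old) < lp.labelling_ratio
            labels[p] = np.concatenate([labels[p], fresh])
            for i in range(old, new):
                added.append((p, i, _subunit_z(p, i, lp)))
        elif new < old:
            for i in range(new, old):
                if labels[p][i]:
                    removed_lab.append((p, i, _subunit_z(p, i, lp)))
            labels[p] = labels[p][:new]
    # chronological order: growth fills from below, shrinkage eats from the top
    added.sort(key=lambda t: (t[2], t[0]))
    removed_lab.sort(key=lambda t: (-t[2], t[0]))

    return replace(
        state,
        pf_lengths=new_lengths,
        labels=labels,
        last_added=[(p, i) for p, i, _ in added],
        last_removed_labelled=[(p, i) for p, i, _ in removed_lab],
        hit_seed=hit_seed,
    )


def _local_coords(pf: np.ndarray, index: np.ndarray, lp: LatticeParams) -> np.ndarray:
    """Axis-frame [x=axial, y=lateral] nm coordinates of subunits."""
    x = index * lp.subunit_length + pf * lp.helix_rise
    y = lp.lattice_radius * np.sin(2.0 * np.pi * pf / lp.n_protofilaments)
    return np.column_stack([x, y])


def place_subunits(state: LatticeState, lp: LatticeParams) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Axis-frame coordinates of every labelled subunit in the lattice.

    Returns the ``(m, 2)`` coordinate array and the matching
    ``(protofilament, index)`` identifiers.  Helical projection: subunit
    ``i`` of protofilament ``p`` sits at axial ``i*d + p*rise`` with
    lateral offset ``r * sin(2*pi*p/n)``.
    """
    pfs, idxs = [], []
    for p in range(lp.n_protofilaments):
        lab = np.flatnonzero(state.labels[p])
        pfs.append(np.full(lab.size, p))
        idxs.append(lab)
    pf = np.concatenate(pfs) if pfs else np.empty(0, dtype=int)
    idx = np.concatenate(idxs) if idxs else np.empty(0, dtype=int)
    if pf.size == 0:
        return np.empty((0, 2)), []
    coords = _local_coords(pf, idx, lp)
    return coords, list(zip(pf.tolist(), idx.tolist()))


def removed_subunit_coords(state: LatticeState, lp: LatticeParams) -> np.ndarray:
    """Axis-frame coordinates of labelled subunits lost in the last step."""
    if not state.last_removed_labelled:
        return np.empty((0, 2))
    pf = np.array([p for p, _ in state.last_removed_labelled])
    idx = np.array([i for _, i in state.last_removed_labelled])
    return _local_coords(pf, idx, lp)


def tip_coords_local(state: LatticeState, lp: LatticeParams) -> np.ndarray:
    """Axis-frame coordinates of the protofilament tips.

    A subunit rendered at axial coordinate ``i*d`` occupies
    ``[i*d - d/2, i*d + d/2]``; the tip of a protofilament — and hence
    the ground-truth end — is the distal edge of its terminal subunit,
    half a subunit beyond the last emitter position.
    """
    coords = _local_coords(
        np.arange(lp.n_protofilaments), state.pf_lengths - 1, lp
    )
    coords[:, 0] += lp.subunit_length / 2.0
    return coords


def true_end(state: LatticeState, lp: LatticeParams) -> np.ndarray:
    """Ground-truth end: mean terminal-subunit coordinate, axis frame."""
    return tip_coords_local(state, lp).mean(axis=0)


def sigma_pf(state: LatticeState, lp: LatticeParams) -> float:
    """SD of the protofilament tip axial positions (nm)."""
    return float(np.std(tip_coords_local(state, lp)[:, 0]))


def beam_shape(u: np.ndarray) -> np.ndarray:
    """Normalized deflection of a uniformly loaded cantilever.

    ``u`` is the fractional position along the free length; the shape is
    ``u**2 * (6 - 4u + u**2) / 3`` with ``w(0) = 0`` and ``w(1) = 1``.
    """
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return u * u * (6.0 - 4.0 * u + u * u) / 3.0


def apply_thermal_deflection(
    coords: np.ndarray,
    gp: GrowthParams,
    clamp_length: float,
    rng: np.random.Generator,
    free_length: float | None = None,
    deflection: float | None = None,
) -> tuple[np.ndarray, float]:
    """Displace axis-frame coordinates by a thermal bending fluctuation.

    A tip deflection ``d ~ Normal(0, sigma_LD^2)`` is drawn (or passed
    in) and every subunit beyond the clamped seed region is displaced
    perpendicular to the axis by ``d * w(s / L_free)`` where ``s`` is
    its axial distance past the clamp.  Axial positions are unchanged.
    Returns the displaced coordinates and the deflection used.
    """
    if clamp_length < 0:
        raise ValueError("clamp_length must be >= 0")
    coords = np.asarray(coords, dtype=float)
    if deflection is None:
        deflection = float(rng.normal(0.0, gp.sigma_LD)) if gp.sigma_LD > 0 else 0.0
    if deflection == 0.0 or coords.size == 0:
        return coords.copy(), deflection
    if free_length is None:
        free_length = float(coords[:, 0].max()) - clamp_length
    out = coords.copy()
    if free_length > 0:
        u = (coords[:, 0] - clamp_length) / free_length
        out[:, 1] += deflection * beam_shape(u)
    return out, deflection


def to_frame(coords: np.ndarray, state: LatticeState) -> np.ndarray:
    """Rotate axis-frame coordinates by the axis angle and translate to the seed origin."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        return coords.reshape(0, 2)
    c, s = np.cos(state.axis_angle), np.sin(state.axis_angle)
    rot = np.column_stack(
        [c * coords[:, 0] - s * coords[:, 1], s * coords[:, 0] + c * coords[:, 1]]
    )
    return rot + state.seed_origin
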