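"""Synthetic inputs with known ground truth for every stage of the pipeline.

The toy system is an idealized two-chain helical backbone ("toy dimer") with
named components — a rigid core, a mobile lid loop and rim helix, and two
metal-binding sites — standing in for a real homodimeric enzyme.  Analyses
downstream depend only on coordinates and labels, not on physical realism,
so an idealized backbone is sufficient and keeps every ground truth
analytic:

* state-mixture trajectories sample named conformational states with known
  rigid offsets (the noiseless per-state component RMSD is returned exactly);
* ion binding/unbinding follows a two-state Markov chain whose stationary
  bound fraction is ``p_on/(p_on+p_off)``;
* kinetics datasets are Michaelis–Menten values with multiplicative noise;
* melt curves are sums of logistic transitions with known midpoints.

All generators are bitwise deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ions import BindingSiteDefinition
from .kinetics import KineticsDataset, MeltCurve, michaelis_menten
from .superpose import rmsd
from .trajectory import Atom, ComponentSelection, Topology, Trajectory, resolve_selection

__all__ = [
    "ToyDimerSpec",
    "StateSpec",
    "StateMixtureSpec",
    "IonBindingSpec",
    "make_toy_dimer",
    "default_selections",
    "default_site",
    "make_state_mixture_trajectory",
    "make_ion_trajectory",
    "make_mm_dataset",
    "make_melt_curve",
]


@dataclass(frozen=True)
class ToyDimerSpec:
    """Geometry of the toy dimer: two helical chains, 4 backbone atoms/residue."""

    n_residues_per_chain: int = 40
    helix_radius: float = 2.3  # Å
    helix_rise: float = 1.5  # Å per residue
    helix_turn_deg: float = 100.0
    chain_offset: tuple[float, float, float] = (18.0, 0.0, 0.0)
    # named component residue ranges (applied per chain)
    core_range: tuple[int, int] = (1, 20)
    lid_range: tuple[int, int] = (25, 32)
    rim_range: tuple[int, int] = (35, 38)
    site_a_residues: tuple[int, ...] = (22, 23)
    site_a_backup_residues: tuple[int, ...] = (24,)
    site_b_residues: tuple[int, ...] = (34,)


def make_toy_dimer(spec: ToyDimerSpec = ToyDimerSpec()) -> tuple[Topology, Trajectory]:
    """Deterministic idealized dimer backbone: chains A and B, atoms N/CA/C/O."""
    n = spec.n_residues_per_chain
    if not (spec.core_range[0] >= 1 and spec.rim_range[1] <= n):
        raise ValueError("component ranges must fall inside the chain")
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    omega = np.deg2rad(spec.helix_turn_deg)
    offsets = {"N": -0.30, "CA": 0.0, "C": 0.30, "O": 0.45}
    radial = {"N": 0.0, "CA": 0.0, "C": 0.0, "O": 0.6}
    idx = 0
    for chain, shift in (("A", np.zeros(3)), ("B", np.asarray(spec.chain_offset))):
        for res in range(1, n + 1):
            for name in ("N", "CA", "C", "O"):
                t = (res - 1) + offsets[name]
                r = spec.helix_radius + radial[name]
                pos = np.array(
                    [r * np.cos(omega * t), r * np.sin(omega * t), spec.helix_rise * t]
                )
                if chain == "B":
                    # flip chain B so the dimer is not a pure translation copy
                    pos = np.array([-pos[0], pos[1], -pos[2]]) + shift
                atoms.append(Atom(idx, name, name[0], "GLY", res, chain))
                coords.append(pos)
                idx += 1
    topo = Topology(atoms)
    traj = Trajectory(topo, np.asarray(coords)[None, :, :], replica_id="reference")
    return topo, traj


def default_selections(spec: ToyDimerSpec = ToyDimerSpec()) -> dict[str, ComponentSelection]:
    """Named selections for the toy dimer mirroring a real analysis config."""
    both = lambda lohi: (("A", *lohi), ("B", *lohi))
    return {
        "core": ComponentSelection("core", both(spec.core_range), "backbone"),
        "lid": ComponentSelection("lid", both(spec.lid_range), "backbone"),
        "rim": ComponentSelection("rim", both(spec.rim_range), "backbone"),
        "lid_rim": ComponentSelection(
            "lid_rim", both(spec.lid_range) + both(spec.rim_range), "backbone"
        ),
    }


def default_site(spec: ToyDimerSpec = ToyDimerSpec(), species: str = "CA") -> BindingSiteDefinition:
    """Site A of the toy dimer: backbone carbonyl oxygens of its residues."""
    prim = tuple(("A", r, ("O",)) for r in spec.site_a_residues)
    backup = tuple(("A", r, ("O",)) for r in spec.site_a_backup_residues)
    return BindingSiteDefinition(
        site_id="site_A", primary_residues=prim, backup_residues=backup,
        ion_species=species,
    )


@dataclass(frozen=True)
class StateSpec:
    """One conformational state: rigid translation per component, and a weight."""

    offsets: tuple[tuple[str, tuple[float, float, float]], ...]  # component -> Δ (Å)
    weight: float


@dataclass(frozen=True)
class StateMixtureSpec:
    states: tuple[StateSpec, ...]
    noise_sigma: float = 0.05  # Å, isotropic per atom
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(s.weight for s in self.states)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1, got {w}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def make_state_mixture_trajectory(
    topology: Topology,
    reference: Trajectory,
    spec: StateMixtureSpec,
    selections: dict[str, ComponentSelection],
    replica_id: str = "r0",
) -> tuple[Trajectory, np.ndarray, list[dict[str, float]]]:
    """Sample frames from a mixture of rigid-offset conformational states.

    Each frame draws a state by weight, displaces every named component by
    that state's rigid offset, and adds isotropic Gaussian noise to all
    atoms.  Returns the trajectory, the true per-frame state labels, and the
    analytic (noiseless) per-state component RMSD — for a pure translation
    Δ of a component whose alignment core is unmoved, that RMSD is exactly
    ``|Δ|``.
    """
    rng = np.random.default_rng(spec.seed)
    base = reference.frames[0]
    weights = np.array([s.weight for s in spec.states])
    labels = rng.choice(len(spec.states), size=spec.n_frames, p=weights)
    sel_idx = {name: resolve_selection(topology, sel) for name, sel in selections.items()}
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for k, state in enumerate(spec.states):
        which = labels == k
        for comp, delta in state.offsets:
            frames[np.ix_(which, sel_idx[comp])] += np.asarray(delta)
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    analytic = []
    for state in spec.states:
        per_comp = {}
        for comp, delta in state.offsets:
            moved = base[sel_idx[comp]] + np.asarray(delta)
            per_comp[comp] = rmsd(moved, base[sel_idx[comp]])
        analytic.append(per_comp)
    traj = Trajectory(topology, frames, replica_id=replica_id)
    return traj, labels, analytic


@dataclass(frozen=True)
class IonBindingSpec:
    """Two-state Markov binding/unbinding with analytic stationary fraction."""

    p_on: float  # per-frame unbound -> bound probability
    p_off: float  # per-frame bound -> unbound probability
    bound_distance: float = 2.4  # Å from the first coordinating atom when bound
    box_half_width: float = 12.0  # Å, unbound diffusion box around the site
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_on < 1.0 and 0.0 < self.p_off < 1.0):
            raise ValueError("transition probabilities must lie strictly in (0, 1)")

    @property
    def stationary_bound_fraction(self) -> float:
        return self.p_on / (self.p_on + self.p_off)


def make_ion_trajectory(
    topology: Topology,
    reference: Trajectory,
    site: BindingSiteDefinition,
    spec: IonBindingSpec,
    replica_id: str = "ion",
) -> tuple[Trajectory, np.ndarray, float]:
    """Static protein plus one ion hopping between bound and unbound states.

    The chain is started at stationarity.  Bound frames place the ion at
    ``bound_distance`` from the first coordinating atom; unbound frames place
    it uniformly in the diffusion box, excluding the shell within the site's
    distance cutoff of any coordinating atom.  Returns the trajectory, the
    true per-frame bound flags, and the stationary bound fraction.
    """
    rng = np.random.default_rng(spec.seed)
    coord_idx = site.coordinating_atom_indices(topology)
    coord_pos = reference.frames[0, coord_idx]
    anchor = coord_pos[0]
    center = coord_pos.mean(axis=0)
    half = spec.box_half_width
    if half <= site.distance_cutoff + 1.0:
        raise ValueError("diffusion box too small to contain an unbound pose")
    # fixed bound pose: displace away from the site centroid (or +z if degenerate)
    direction = anchor - center
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
    bound_pos = anchor + spec.bound_distance * direction

    pi = spec.stationary_bound_fraction
    states = np.empty(spec.n_frames, dtype=bool)
    u = rng.random(spec.n_frames)
    states[0] = u[0] < pi
    for f in range(1, spec.n_frames):
        states[f] = (not states[f - 1] and u[f] < spec.p_on) or (
            states[f - 1] and u[f] >= spec.p_off
        )

    n_unbound = int((~states).sum())
    unbound_positions = np.empty((n_unbound, 3))
    filled = 0
    while filled < n_unbound:
        cand = center + rng.uniform(-half, half, size=(n_unbound - filled, 3))
        d = np.linalg.norm(cand[:, None, :] - coord_pos[None, :, :], axis=2)
        ok = np.all(d > site.distance_cutoff, axis=1)
        good = cand[ok]
        unbound_positions[filled : filled + len(good)] = good
        filled += len(good)

    ion_atom = Atom(
        topology.n_atoms, site.ion_species.upper(), site.ion_species.capitalize(),
        site.ion_species.upper(), 1, "X",
    )
    new_topo = Topology(topology.atoms + [ion_atom])
    frames = np.empty((spec.n_frames, new_topo.n_atoms, 3))
    frames[:, : topology.n_atoms, :] = reference.frames[0]
    frames[states, topology.n_atoms, :] = bound_pos
    frames[~states, topology.n_atoms, :] = unbound_positions
    traj = Trajectory(new_topo, frames, replica_id=replica_id)
    return traj, states, pi


def make_mm_dataset(
    kcat: float,
    Km: float,
    concentrations_uM: np.ndarray | None = None,
    noise_rel: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    buffer: str = "calcium",
) -> KineticsDataset:
    """Michaelis–Menten rates with multiplicative Gaussian noise.

    Default concentrations log-span 1 µM – 2 mM (8 points), the substrate
    range used in phenylalanine decarboxylation assays.
    """
    if concentrations_uM is None:
        concentrations_uM = np.geomspace(1.0, 2000.0, 8)
    rng = np.random.default_rng(seed)
    S = np.tile(np.asarray(concentrations_uM, dtype=float), replicates)
    v = michaelis_menten(S, kcat, Km)
    if noise_rel > 0:
        v = v * (1.0 + rng.normal(0.0, noise_rel, size=v.shape))
    return KineticsDataset(
        concentrations_uM=S, rates_per_s=np.clip(v, 0.0, None), buffer=buffer
    )


def make_melt_curve(
    tms_C: tuple[float, ...] = (52.0,),
    amplitudes: tuple[float, ...] = (1000.0,),
    slopes_C: tuple[float, ...] = (1.5,),
    baseline: tuple[float, float] = (100.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    t_range: tuple[float, float] = (20.0, 85.0),
    n_points: int = 131,
) -> MeltCurve:
    """Sum of logistic unfolding transitions plus a linear baseline.

    Fluorescence rises through each transition (SYPRO-style); the derivative
    has a local extremum at each midpoint, deepest for the transition with
    the largest ``amplitude/slope`` ratio.
    """
    if not (len(tms_C) == len(amplitudes) == len(slopes_C)):
        raise ValueError("tms, amplitudes and slopes must have equal length")
    T = np.linspace(t_range[0], t_range[1], n_points)
    F = baseline[0] + baseline[1] * T
    for tm, amp, slope in zip(tms_C, amplitudes, slopes_C):
        F = F + amp / (1.0 + np.exp(-(T - tm) / slope))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    return MeltCurve(temperatures_C=T, fluorescence=F)
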