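"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators:

* :func:`simulate_timecourse` — limited-proteolysis peak-list time courses
  for a protein free and in complex.  Each cleavage site is cut
  independently with first-order kinetics, P(cut by t) = 1 − exp(−k·t);
  interface protection in the bound state scales the rate by (1 − ρ).
  Fragment populations follow from the per-molecule cut patterns and are
  reported as [M+H]+ peaks with multiplicative log-normal intensity noise.
* :func:`make_toy_complex` — an idealised two-helix complex (poly-alanine,
  backbone + CB) with a defined interface, written in plain PDB.
* :func:`make_mock_poses` — docking-output stand-ins: near-native poses
  (small rigid perturbations of the ligand) with strictly better scores
  than far-from-native ones, with ground-truth labels.

Secondary digestion of released fragments is ignored (sites are cut once,
independently); this suffices for testing propensity *differences*, which
is what the restraint derivation consumes.  All generators are
deterministic per seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import (
    Fragment,
    ProteaseRule,
    ProteinSequence,
    TRYPSIN,
    cleavage_sites,
    enumerate_fragments,
)
from .evaluation import DockPose, interface_residues
from .spectra import DEFAULT_TIME_POINTS, PROTON_MASS, PeakList
from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_timecourse",
    "make_toy_complex",
    "ToyComplex",
    "make_mock_poses",
]

#: Default per-site cleavage rate, min⁻¹ — reaches ~98% digestion of an
#: accessible site by the last (200 min) time point of the default series,
#: with early time points still far from saturation.
DEFAULT_RATE = 0.02


@dataclass
class SimulationConfig:
    """Study conditions for one free/bound proteolysis time course.

    Defaults mirror the wet protocol the pipeline targets: quench series
    0–200 min, triplicates, ~10⁴ molecules contributing intensity, 10%
    intensity CV.  ``protection`` ρ scales protected sites' bound-state
    rate to k·(1 − ρ); ρ = 1 is complete interface protection.
    """

    sequence: ProteinSequence
    protease: ProteaseRule = TRYPSIN
    rate: float | Mapping[int, float] = DEFAULT_RATE  # min⁻¹, per site
    protected_sites: frozenset[int] = frozenset()
    protection: float = 1.0  # ρ
    times: tuple[float, ...] = DEFAULT_TIME_POINTS
    n_molecules: int = 10_000
    intensity_cv: float = 0.10
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.protection <= 1:
            raise ValueError("protection must be in [0, 1]")
        if list(self.times) != sorted(self.times) or self.times[0] != 0:
            raise ValueError("time points must ascend from 0")
        rates = (
            [self.rate] if np.isscalar(self.rate) else list(dict(self.rate).values())
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")


@dataclass
class SimulationResult:
    peaklists: list[PeakList]  # free + bound, per replicate and time
    sites: list[int]  # ground truth: P1 positions of all cleavage sites
    protected_sites: set[int]
    fragments: list[Fragment]  # theoretical fragment set (incl. intact)
    truth: dict[float, Fragment]  # m/z (to 4 dp) -> generating fragment

    def by_condition(self, condition: str) -> list[PeakList]:
        return [pl for pl in self.peaklists if pl.condition == condition]


def _site_rates(cfg: SimulationConfig, sites: list[int]) -> np.ndarray:
    if np.isscalar(cfg.rate):
        return np.full(len(sites), float(cfg.rate))
    rates = dict(cfg.rate)
    missing = [s for s in sites if s not in rates]
    if missing:
        raise ValueError(f"no rate given for sites {missing}")
    return np.array([rates[s] for s in sites], float)


def _pattern_fragments(
    seq: ProteinSequence, sites: list[int]
) -> tuple[list[tuple[int, int]], list[np.ndarray]]:
    """For each of the 2^m cut patterns, the fragment (start, end) spans."""
    frag_index: dict[tuple[int, int], int] = {}
    patterns = []
    for pattern in itertools.product((False, True), repeat=len(sites)):
        cuts = [seq.first_residue - 1] + [
            s for s, on in zip(sites, pattern) if on
        ] + [seq.last_residue]
        ids = []
        for left, right in zip(cuts[:-1], cuts[1:]):
            span = (left + 1, right)
            ids.append(frag_index.setdefault(span, len(frag_index)))
        patterns.append(np.array(ids))
    return list(frag_index), patterns


def simulate_timecourse(cfg: SimulationConfig) -> SimulationResult:
    """Generate free and bound peak-list time courses plus ground truth.

    Per time point the population is distributed over the 2^m cut patterns
    (m = number of sites); with ``intensity_cv`` = 0 the expected fragment
    populations are used directly (fully deterministic), otherwise molecule
    counts are drawn multinomially and intensities carry log-normal noise
    at the given CV.
    """
    seq = cfg.sequence
    site_objs = cleavage_sites(seq, cfg.protease)
    sites = [s.position for s in site_objs]
    if not sites:
        raise ValueError(f"{seq.id}: no {cfg.protease.name} cleavage sites")
    if len(sites) > 16:
        raise ValueError("more than 16 sites: pattern enumeration too large")
    unknown = set(cfg.protected_sites) - set(sites)
    if unknown:
        raise ValueError(f"protected sites {sorted(unknown)} are not cleavage sites")

    rates = _site_rates(cfg, sites)
    spans, patterns = _pattern_fragments(seq, sites)
    all_frags = {
        (f.start, f.end): f for f in enumerate_fragments(seq, site_objs)
    }
    frag_list = [all_frags[span] for span in spans]
    mzs = np.round([f.mass + PROTON_MASS for f in frag_list], 4)

    rng = np.random.default_rng(cfg.seed)
    sigma = float(np.sqrt(np.log(1 + cfg.intensity_cv**2)))
    protected = np.array([s in cfg.protected_sites for s in sites])
    peaklists = []
    for condition in ("free", "bound"):
        k = np.where(protected, rates * (1 - cfg.protection), rates) \
            if condition == "bound" else rates
        for rep in range(1, cfg.replicates + 1):
            for t in cfg.times:
                p_cut = 1.0 - np.exp(-k * t)
                # probability of each full cut pattern (independent sites)
                probs = np.array(
                    [
                        np.prod(np.where(pattern_on, p_cut, 1 - p_cut))
                        for pattern_on in itertools.product(
                            (False, True), repeat=len(sites)
                        )
                    ]
                )
                counts = np.zeros(len(frag_list))
                if cfg.intensity_cv == 0:
                    weights = probs * cfg.n_molecules
                else:
                    weights = rng.multinomial(cfg.n_molecules, probs).astype(float)
                for w, ids in zip(weights, patterns):
                    if w:
                        np.add.at(counts, ids, w)
                intensities = counts.copy()
                nz = intensities > 0
                if cfg.intensity_cv > 0 and nz.any():
                    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=int(nz.sum()))
                    intensities[nz] *= noise
                peaks = np.column_stack([mzs[nz], intensities[nz]])
                peaklists.append(
                    PeakList(seq.id, condition, rep, float(t), peaks)
                )
    return SimulationResult(
        peaklists=peaklists,
        sites=sites,
        protected_sites=set(cfg.protected_sites),
        fragments=list(all_frags.values()),
        truth={float(m): f for m, f in zip(mzs, frag_list)},
    )


# --- toy structures --------------------------------------------------------

_CA_RADIUS = 2.3  # Å, ideal alpha-helix
_RISE = 1.5  # Å per residue
_TWIST = np.deg2rad(100.0)


def _helix_chain(
    chain_id: str,
    n_residues: int,
    origin: np.ndarray,
    axis_dir: int = 1,
    first_residue: int = 1,
) -> Chain:
    """Idealised poly-alanine alpha-helix along z: backbone N, CA, C, O
    plus a CB pseudo-side-chain pointing radially outward."""
    residues = []
    for i in range(n_residues):
        phi = i * _TWIST
        z = origin[2] + axis_dir * i * _RISE
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
        ca = np.array([origin[0] + _CA_RADIUS * radial[0],
                       origin[1] + _CA_RADIUS * radial[1], z])
        n_at = ca - 1.46 * (0.55 * tangent + 0.45 * np.array([0, 0, axis_dir]))
        c_at = ca + 1.52 * (0.55 * tangent + 0.45 * np.array([0, 0, axis_dir]))
        o_at = c_at + 1.23 * radial * -1.0
        cb = ca + 1.53 * radial
        residues.append(
            Residue(
                first_residue + i,
                "ALA",
                [
                    Atom("N", "N", n_at),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c_at),
                    Atom("O", "O", o_at),
                    Atom("CB", "C", cb),
                ],
            )
        )
    return Chain(chain_id, residues)


@dataclass
class ToyComplex:
    receptor: Structure  # chain A alone, unbound frame
    ligand: Structure  # chain B alone, unbound frame
    complex: Structure  # chains A + B, bound frame
    interface: dict[str, set[int]]  # ground truth, 10 Å heavy-atom rule


def make_toy_complex(
    seed: int = 0,
    n_receptor: int = 30,
    n_ligand: int = 20,
    separation: float = 9.0,
) -> ToyComplex:
    """Two parallel idealised helices docked side by side.

    Chain A (receptor, ``n_receptor`` residues) sits at the origin, chain B
    (ligand) at ``separation`` Å along x, shifted along z so the helices
    overlap mid-chain.  The recorded interface is exactly the 10 Å
    heavy-atom rule applied to the bound complex.  A small seed-dependent
    jitter (< 0.05 Å) decorrelates different seeds without moving the
    interface.
    """
    rng = np.random.default_rng(seed)
    a = _helix_chain("A", n_receptor, np.zeros(3))
    z_shift = (n_receptor - n_ligand) / 2 * _RISE
    b = _helix_chain(
        "B", n_ligand, np.array([separation, 0.0, z_shift]), first_residue=1
    )
    for chain in (a, b):
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0, 0.015, 3)
    cplx = Structure("toy_complex", [a, b])
    receptor = Structure("toy_receptor", [_copy_chain(a)])
    ligand = Structure("toy_ligand", [_copy_chain(b)])
    return ToyComplex(receptor, ligand, cplx, interface_residues(cplx, 10.0))


def _copy_chain(chain: Chain) -> Chain:
    return Chain(
        chain.id,
        [
            Residue(
                r.number, r.name,
                [Atom(a.name, a.element, a.coord.copy()) for a in r.atoms],
                r.icode,
            )
            for r in chain.residues
        ],
    )


def _transform_chain(chain: Chain, R: np.ndarray, t: np.ndarray) -> Chain:
    new = _copy_chain(chain)
    for res in new.residues:
        for atom in res.atoms:
            atom.coord = R @ atom.coord + t
    return new


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_mock_poses(
    toy: ToyComplex,
    n_near: int = 10,
    n_far: int = 10,
    noise: float = 1.0,
    seed: int = 0,
) -> tuple[list[DockPose], list[str]]:
    """Docking-output stand-ins with ground-truth near/far labels.

    Near poses perturb the bound ligand by a random rotation (≤ 5·noise
    degrees about its centroid) plus a random translation (≤ noise Å);
    far poses are placed on the opposite face of the receptor with larger
    perturbations.  Scores are strictly ordered: every near pose scores
    lower (better) than every far pose.
    """
    if n_near + n_far < 1:
        raise ValueError("need at least one pose")
    rng = np.random.default_rng(seed)
    rec_chain = toy.complex.chains[0]
    lig_chain = toy.complex.chains[1]
    lig_centroid = lig_chain.heavy_coords().mean(axis=0)
    rec_centroid = rec_chain.heavy_coords().mean(axis=0)

    poses, labels = [], []
    for i in range(n_near):
        R = _random_rotation(rng, 5.0 * noise)
        t = rng.uniform(-noise, noise, 3)
        moved = _transform_chain(
            lig_chain, R, t + lig_centroid - R @ lig_centroid
        )
        poses.append(
            DockPose(
                Structure(f"near_{i}", [_copy_chain(rec_chain), moved]),
                score=-80.0 + 0.5 * i + rng.uniform(0, 0.1),
                id=f"near_{i}",
            )
        )
        labels.append("near")
    # far poses: ligand mirrored through the receptor centroid (opposite face)
    for i in range(n_far):
        R = _random_rotation(rng, 30.0)
        flip = 2 * rec_centroid - lig_centroid  # point reflection target
        t = flip - R @ lig_centroid + rng.uniform(-2 * noise - 0.5, 2 * noise + 0.5, 3)
        poses.append(
            DockPose(
                Structure(f"far_{i}", [_copy_chain(rec_chain), _transform_chain(lig_chain, R, t)]),
                score=-40.0 + 0.5 * i + rng.uniform(0, 0.1),
                id=f"far_{i}",
            )
        )
        labels.append("far")
    return poses, labels
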