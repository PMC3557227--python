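"""Spatial patch detection on active residues (PATCHUP).

False-positive protections (e.g. allosteric loosening remote from the
interface) show up as a second spatial group of active residues.  The atom
point cloud of the active residues' heavy atoms is k-means clustered and
each residue is assigned to the cluster holding the majority of its atoms
(ties go to the cluster whose centroid is nearest the residue's own atom
centroid).  Patches are returned largest first; the filter docking run then
decides which patch is the true interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .structure import Structure

__all__ = ["Patch", "kmeans_patches", "suggest_k"]


@dataclass(frozen=True)
class Patch:
    label: int
    residues: frozenset[int]
    centroid: tuple[float, float, float]
    atom_count: int

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty patch")


def _active_atom_cloud(
    structure: Structure, active: list[int], chain: str | None
) -> tuple[np.ndarray, np.ndarray]:
    chain_obj = structure.chain(chain) if chain else structure.chains[0]
    coords, owner = [], []
    for n in active:
        c = chain_obj.residue(n).heavy_coords()
        if len(c) == 0:
            raise ValueError(f"residue {n} has no heavy atoms with coordinates")
        coords.append(c)
        owner.extend([n] * len(c))
    return np.vstack(coords), np.array(owner)


def kmeans_patches(
    structure: Structure,
    active: Iterable[int],
    k: int,
    seed: int = 0,
    chain: str | None = None,
    n_restarts: int = 20,
) -> list[Patch]:
    """Partition active residues into ``k`` spatial patches.

    k-means (k-means++ seeding, ``n_restarts`` restarts, best inertia kept)
    on the heavy atoms of the active residues, then majority-vote residue
    assignment.  Patches are sorted by size descending (ties by smallest
    residue number) and relabelled 1..k accordingly; empty patches (all of a
    cluster's atoms outvoted) are dropped.
    """
    active = sorted(set(active))
    if not active:
        raise ValueError("empty active set")
    if k < 1 or k > len(active):
        raise ValueError(f"k must be in 1..{len(active)} (number of active residues)")
    cloud, owner = _active_atom_cloud(structure, active, chain)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(cloud)
    labels, centers = km.labels_, km.cluster_centers_

    assigned: dict[int, list[int]] = {c: [] for c in range(k)}
    for n in active:
        mask = owner == n
        counts = np.bincount(labels[mask], minlength=k)
        best = np.flatnonzero(counts == counts.max())
        if len(best) == 1:
            cl = int(best[0])
        else:  # tie: nearest cluster centroid to the residue's atom centroid
            rc = cloud[mask].mean(axis=0)
            d = np.linalg.norm(centers[best] - rc, axis=1)
            cl = int(best[int(np.argmin(d))])
        assigned[cl].append(n)

    patches = []
    for cl, residues in assigned.items():
        if not residues:
            continue
        atoms = np.isin(owner, residues)
        patches.append(
            Patch(
                label=0,
                residues=frozenset(residues),
                centroid=tuple(np.round(cloud[atoms].mean(axis=0), 6)),
                atom_count=int(atoms.sum()),
            )
        )
    patches.sort(key=lambda p: (-len(p.residues), min(p.residues)))
    return [
        Patch(i + 1, p.residues, p.centroid, p.atom_count)
        for i, p in enumerate(patches)
    ]


def suggest_k(
    structure: Structure,
    active: Iterable[int],
    seed: int = 0,
    chain: str | None = None,
    max_k: int = 4,
    silhouette_min: float = 0.6,
) -> int:
    """Smallest k in 2..min(max_k, |active|) with atom-cloud silhouette ≥
    ``silhouette_min``; 1 if none qualifies (a single coherent patch)."""
    active = sorted(set(active))
    if not active:
        raise ValueError("empty active set")
    cloud, _ = _active_atom_cloud(structure, active, chain)
    for k in range(2, min(max_k, len(active), len(cloud) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(cloud)
        if len(set(km.labels_)) < 2:
            continue
        if silhouette_score(cloud, km.labels_) >= silhouette_min:
            return k
    return 1
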