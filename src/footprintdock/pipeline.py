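"""Two-stage docking protocol orchestration.

Stage 1 (*filter*): dock with every candidate patch active and 50% of the
AIRs randomly excluded per structure calculation; the extra sampling lets
the engine express a preference between patches.  Clusters of the returned
poses are ranked by score; each cluster is attributed to the patch nearest
its best pose, and the patch of the best-scored cluster wins (score always
beats size; size only breaks exact ties).

Stage 2 (*final*): dock again with actives restricted to the winning
patch, surface-exposed immediate neighbours promoted to active, and no
random exclusion.

Docking itself is external — the pipeline emits restraint/parameter files
and resumes from returned model ensembles with scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .digestion import ProteaseRule, ProteinSequence, cleavage_sites, digest
from .evaluation import (
    DockPose,
    PoseCluster,
    cluster_poses,
    patch_distance,
    rank_clusters,
)
from .patchup import Patch
from .restraints import (
    MoleculeRestraints,
    RestraintSet,
    RunSpec,
    promote_neighbors,
)
from .spectra import PeakList, PropensityTable, assign_peaks, cleavage_propensity
from .structure import Structure

__all__ = [
    "FilterOutcome",
    "compute_propensity",
    "build_filter_run",
    "build_filter_runs_per_patch",
    "assign_clusters_to_patches",
    "choose_patch",
    "run_filter_analysis",
    "build_final_run",
]


def compute_propensity(
    seq: ProteinSequence,
    rule: ProteaseRule,
    peaklists: Iterable[PeakList],
    condition: str,
    tol: float = 0.5,
    tol_unit: str = "Da",
    ambiguous: str = "exclude",
) -> PropensityTable:
    """Digest → assign → propensity for one protein/condition.

    Convenience wrapper over the digestion and spectra layers: enumerates
    the theoretical fragment set once and assigns every replicate/time
    peak list of the requested condition.
    """
    frags = digest(seq, rule)
    sites = [s.position for s in cleavage_sites(seq, rule)]
    selected = [pl for pl in peaklists if pl.condition == condition]
    if not selected:
        raise ValueError(f"no {condition!r} peak lists for {seq.id}")
    assignments = {
        (pl.replicate, pl.time_point): assign_peaks(pl, frags, tol, tol_unit)
        for pl in selected
    }
    return cleavage_propensity(assignments, sites, seq.id, condition, ambiguous)


def _restrict_actives(
    rs: RestraintSet, molecule: str, residues: set[int]
) -> RestraintSet:
    mols = dict(rs.molecules)
    mol = mols[molecule]
    mols[molecule] = MoleculeRestraints(
        segid=mol.segid,
        active=set(residues),
        passive=mol.passive if mol.passive == "auto" else mol.passive_set() - residues,
        provenance={n: mol.provenance.get(n, "LP/MS") for n in residues},
    )
    return RestraintSet(mols)


def build_filter_run(
    restraints: RestraintSet,
    patches: Sequence[Patch],
    molecule: str | None = None,
    removal_fraction: float = 0.5,
) -> RunSpec:
    """Filter-stage RunSpec: all patches' actives, random removal on.

    ``molecule`` names the partner whose actives the patches partition
    (default: the molecule that has active residues).
    """
    if not patches:
        raise ValueError("at least one patch required")
    molecule = molecule or _lpms_molecule(restraints)
    actives: set[int] = set().union(*(p.residues for p in patches))
    if not actives:
        raise ValueError("patches carry no active residues")
    if len(patches) == 1:
        warnings.warn(
            "single patch: the filter run is skippable (no ambiguity to resolve)",
            stacklevel=2,
        )
    return RunSpec(
        stage="filter",
        restraints=_restrict_actives(restraints, molecule, actives),
        random_removal=True,
        removal_fraction=removal_fraction,
    )


def build_filter_runs_per_patch(
    restraints: RestraintSet,
    patches: Sequence[Patch],
    molecule: str | None = None,
    removal_fraction: float = 0.5,
) -> list[RunSpec]:
    """Alternative filter mode: one docking run per patch."""
    if not patches:
        raise ValueError("at least one patch required")
    molecule = molecule or _lpms_molecule(restraints)
    return [
        RunSpec(
            stage="filter",
            restraints=_restrict_actives(restraints, molecule, set(p.residues)),
            random_removal=True,
            removal_fraction=removal_fraction,
        )
        for p in patches
    ]


def _lpms_molecule(rs: RestraintSet) -> str:
    with_active = [n for n, m in rs.molecules.items() if m.active]
    if len(with_active) != 1:
        raise ValueError(
            "cannot infer the footprinted molecule: pass molecule= explicitly"
        )
    return with_active[0]


@dataclass
class FilterOutcome:
    """Result of analysing the filter run's returned poses."""

    clusters: list[PoseCluster]  # ranked, best first
    patch_distances: list[dict[int, float]]  # per cluster: patch label -> Å
    cluster_patches: list[int | None]  # assigned patch per cluster (None = far)
    chosen_patch: int


def assign_clusters_to_patches(
    clusters: Sequence[PoseCluster],
    patches: Sequence[Patch],
    ligand_chain: str,
    assign_cutoff: float = 5.0,
) -> tuple[list[dict[int, float]], list[int | None]]:
    """Per-cluster patch distances (best-scored member pose) and assignment.

    A cluster belongs to its nearest patch when that minimum heavy-atom
    distance is within ``assign_cutoff``; otherwise it stays unassigned.
    """
    distances, assigned = [], []
    for c in clusters:
        best_pose = min(c.members, key=lambda p: p.score)
        d = {p.label: patch_distance(best_pose, p, ligand_chain) for p in patches}
        distances.append(d)
        nearest = min(d, key=d.get)
        assigned.append(nearest if d[nearest] <= assign_cutoff else None)
    return distances, assigned


def choose_patch(
    ranked_clusters: Sequence[PoseCluster],
    cluster_patches: Sequence[int | None],
) -> int:
    """The patch of the best-scored cluster (clusters already ranked).

    The engine score always takes priority over cluster size; the ranking
    already encodes the size tie-break.  An unassigned best cluster means
    the docking did not land on any detected patch — manual review.
    """
    if not ranked_clusters:
        raise ValueError("no clusters to choose from")
    chosen = cluster_patches[0]
    if chosen is None:
        raise ValueError(
            "best-scored cluster lies on none of the patches "
            f"(distances exceed the assignment cutoff): manual review required"
        )
    return chosen


def run_filter_analysis(
    poses: Sequence[DockPose],
    patches: Sequence[Patch],
    ligand_chain: str,
    cutoff: float = 7.5,
    min_size: int = 4,
    assign_cutoff: float = 5.0,
) -> FilterOutcome:
    """Cluster & rank filter-run poses, attribute clusters to patches,
    and pick the winning patch."""
    ranked = rank_clusters(cluster_poses(poses, cutoff=cutoff, min_size=min_size))
    if not ranked:
        raise ValueError("no cluster of the required minimum size")
    distances, assigned = assign_clusters_to_patches(
        ranked, patches, ligand_chain, assign_cutoff
    )
    return FilterOutcome(
        clusters=ranked,
        patch_distances=distances,
        cluster_patches=assigned,
        chosen_patch=choose_patch(ranked, assigned),
    )


def build_final_run(
    restraints: RestraintSet,
    patch: Patch,
    structure: Structure,
    molecule: str | None = None,
    chain: str | None = None,
    sasa_cutoff: float = 0.5,
    dist_cutoff: float = 6.5,
) -> RunSpec:
    """Final-stage RunSpec: chosen patch only, neighbours promoted, no removal."""
    if not patch.residues:
        raise ValueError("empty patch")
    molecule = molecule or _lpms_molecule(restraints)
    chain_id = chain or structure.chains[0].id
    present = set(structure.chain(chain_id).residue_numbers())
    missing = set(patch.residues) - present
    if missing:
        raise ValueError(
            f"patch residues {sorted(missing)} absent from structure chain {chain_id}"
        )
    expanded, provenance = promote_neighbors(
        structure, patch.residues, sasa_cutoff, dist_cutoff, chain_id
    )
    rs = _restrict_actives(restraints, molecule, expanded)
    rs.molecules[molecule].provenance.update(provenance)
    return RunSpec(stage="final", restraints=rs, random_removal=False,
                   removal_fraction=0.0)
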