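"""CAPRI-style assessment of docked models and pose clustering.

Docked two-chain models are compared to a reference complex by three
standard metrics:

* **iRMSD** — backbone RMSD over the reference-defined interface residues
  (any heavy atom within 10 Å of the partner chain) after least-squares
  superposition on those atoms;
* **lRMSD** — ligand RMSD: superpose on the larger chain's backbone,
  measure RMSD over the other chain's backbone without re-fitting;
* **fnat** — fraction of the reference's residue-wise cross-chain contacts
  (heavy atoms within 5 Å) reproduced by the model.

A model is CAPRI *acceptable* when iRMSD < 4 Å, lRMSD < 10 Å and
fnat > 0.1 (all strict).  Poses are grouped by greedy largest-neighbourhood
(Daura-style) clustering on a pairwise interface-ligand RMSD at a 7.5 Å
cutoff with minimum cluster size 4, and clusters are ranked by the mean of
their four lowest member scores (the docking engine's score, consumed as
input — lower is better), ties broken by size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .patchup import Patch
from .structure import Chain, PDBFormatError, Structure, read_pdb

__all__ = [
    "DockPose",
    "EvaluationResult",
    "PoseCluster",
    "read_pdb",
    "kabsch_superpose",
    "interface_residues",
    "irmsd",
    "lrmsd",
    "fnat",
    "capri_class",
    "cluster_poses",
    "rank_clusters",
    "patch_distance",
    "evaluate_model",
    "evaluation_report",
    "read_scores",
]


@dataclass
class DockPose:
    """A docked model plus its engine score (lower is better)."""

    structure: Structure
    score: float | None = None
    id: str = ""


@dataclass(frozen=True)
class EvaluationResult:
    irmsd: float
    lrmsd: float
    fnat: float

    @property
    def capri_acceptable(self) -> bool:
        return capri_class(self) == "acceptable"


@dataclass
class PoseCluster:
    members: list[DockPose]
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def score(self) -> float:
        """Mean of the four lowest member scores."""
        scores = [p.score for p in self.members]
        if any(s is None for s in scores):
            raise ValueError("cluster member without a score; ranking disabled")
        return float(np.mean(sorted(scores)[:4]))

    @property
    def center(self) -> DockPose:
        return self.members[0]


# --- superposition ---------------------------------------------------------


def kabsch_superpose(
    coords_fit: np.ndarray, coords_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets (Kabsch/SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_fit @ rotation.T + translation`` best matches ``coords_ref``;
    the rotation is proper (det = +1).
    """
    P = np.asarray(coords_fit, float)
    Q = np.asarray(coords_ref, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = len(P)
    if n < 3:
        raise ValueError("at least 3 atom pairs required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def _apply(R: np.ndarray, t: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


# --- interface and metrics -------------------------------------------------


def _two_chains(s: Structure) -> tuple[Chain, Chain]:
    if len(s.chains) < 2:
        raise ValueError(f"structure {s.id} has a single chain")
    return s.chains[0], s.chains[1]


def interface_residues(
    complex_structure: Structure, cutoff: float = 10.0
) -> dict[str, set[int]]:
    """Residues with any heavy atom within ``cutoff`` Å of the partner chain."""
    a, b = _two_chains(complex_structure)
    out = {a.id: set(), b.id: set()}
    tree_a, tree_b = cKDTree(a.heavy_coords()), cKDTree(b.heavy_coords())
    for chain, tree_other in ((a, tree_b), (b, tree_a)):
        for res in chain.residues:
            coords = res.heavy_coords()
            if len(coords) and np.min(tree_other.query(coords)[0]) <= cutoff:
                out[chain.id].add(res.number)
    return out


def _interface_backbone(
    s: Structure, interface: dict[str, set[int]]
) -> np.ndarray:
    parts = []
    for chain_id, residues in sorted(interface.items()):
        if residues:
            parts.append(s.chain(chain_id).backbone_coords(sorted(residues)))
    return np.vstack(parts) if parts else np.empty((0, 3))


def irmsd(model: Structure, reference: Structure, cutoff: float = 10.0) -> float:
    """Interface backbone RMSD after superposing on the reference interface.

    The interface is defined on the *reference* (10 Å heavy-atom rule);
    model and reference must share residue numbering there.
    """
    iface = interface_residues(reference, cutoff)
    ref_bb = _interface_backbone(reference, iface)
    try:
        mod_bb = _interface_backbone(model, iface)
    except KeyError as exc:
        raise ValueError(f"model missing interface residues: {exc}") from exc
    if len(ref_bb) < 3 or len(mod_bb) != len(ref_bb):
        raise ValueError("fewer than 3 shared interface backbone atoms")
    return kabsch_superpose(mod_bb, ref_bb)[2]


def lrmsd(model: Structure, reference: Structure) -> float:
    """Ligand RMSD: fit on the larger chain's backbone, measure the other.

    Equal chain lengths fit on the first chain by file order.
    """
    ra, rb = _two_chains(reference)
    receptor, ligand = (ra, rb) if len(ra) >= len(rb) else (rb, ra)
    try:
        m_rec = model.chain(receptor.id)
        m_lig = model.chain(ligand.id)
    except KeyError as exc:
        raise ValueError(f"model missing chain: {exc}") from exc
    rec_nums = [n for n in receptor.residue_numbers() if n in set(m_rec.residue_numbers())]
    lig_nums = [n for n in ligand.residue_numbers() if n in set(m_lig.residue_numbers())]
    fit_ref = receptor.backbone_coords(rec_nums)
    fit_mod = m_rec.backbone_coords(rec_nums)
    if len(fit_ref) < 3 or len(fit_ref) != len(fit_mod):
        raise ValueError("insufficient shared receptor backbone atoms")
    R, t, _ = kabsch_superpose(fit_mod, fit_ref)
    lig_ref = ligand.backbone_coords(lig_nums)
    lig_mod = _apply(R, t, m_lig.backbone_coords(lig_nums))
    if len(lig_ref) == 0 or len(lig_ref) != len(lig_mod):
        raise ValueError("mismatched ligand backbone atoms")
    return float(np.sqrt(np.mean(np.sum((lig_mod - lig_ref) ** 2, axis=1))))


def _residue_contacts(s: Structure, cutoff: float) -> set[tuple[int, int]]:
    a, b = _two_chains(s)
    contacts = set()
    trees_b = [(res.number, cKDTree(res.heavy_coords())) for res in b.residues
               if len(res.heavy_atoms())]
    for res_a in a.residues:
        ca = res_a.heavy_coords()
        if not len(ca):
            continue
        for nb, tree in trees_b:
            if np.min(tree.query(ca)[0]) <= cutoff:
                contacts.add((res_a.number, nb))
    return contacts


def fnat(model: Structure, reference: Structure, contact_cutoff: float = 5.0) -> float:
    """Fraction of reference cross-chain residue contacts kept by the model."""
    ref_contacts = _residue_contacts(reference, contact_cutoff)
    if not ref_contacts:
        raise ValueError("reference structure has no cross-chain contacts")
    mod_contacts = _residue_contacts(model, contact_cutoff)
    return len(mod_contacts & ref_contacts) / len(ref_contacts)


def capri_class(r: EvaluationResult) -> str:
    """``acceptable`` iff iRMSD < 4 Å, lRMSD < 10 Å and fnat > 0.1 (strict)."""
    if not all(np.isfinite([r.irmsd, r.lrmsd, r.fnat])):
        raise ValueError("non-finite metrics")
    ok = r.irmsd < 4.0 and r.lrmsd < 10.0 and r.fnat > 0.1
    return "acceptable" if ok else "not_acceptable"


def evaluate_model(
    model: Structure, reference: Structure, interface_cutoff: float = 10.0
) -> EvaluationResult:
    return EvaluationResult(
        irmsd=irmsd(model, reference, interface_cutoff),
        lrmsd=lrmsd(model, reference),
        fnat=fnat(model, reference),
    )


# --- pose clustering and ranking -------------------------------------------


def pairwise_pose_rmsd(
    pose_a: Structure, pose_b: Structure, interface_cutoff: float = 10.0
) -> float:
    """Interface-ligand RMSD between two poses of the same two chains.

    Interface residues are the union of both poses' 10 Å interfaces
    (symmetric); the receptor (larger chain) interface backbone is
    superposed and the RMSD measured over the ligand interface backbone.
    Falls back to whole-chain backbones when a pose pair has no interface.
    """
    a1, b1 = _two_chains(pose_a)
    receptor_id, ligand_id = (
        (a1.id, b1.id) if len(a1) >= len(b1) else (b1.id, a1.id)
    )
    iface_a = interface_residues(pose_a, interface_cutoff)
    iface_b = interface_residues(pose_b, interface_cutoff)
    rec_res = sorted(iface_a[receptor_id] | iface_b[receptor_id])
    lig_res = sorted(iface_a[ligand_id] | iface_b[ligand_id])
    if not rec_res or not lig_res:
        rec_res = lig_res = None  # no interface anywhere: whole chains
    fit_a = pose_a.chain(receptor_id).backbone_coords(rec_res)
    fit_b = pose_b.chain(receptor_id).backbone_coords(rec_res)
    R, t, _ = kabsch_superpose(fit_a, fit_b)
    la = _apply(R, t, pose_a.chain(ligand_id).backbone_coords(lig_res))
    lb = pose_b.chain(ligand_id).backbone_coords(lig_res)
    return float(np.sqrt(np.mean(np.sum((la - lb) ** 2, axis=1))))


def pose_rmsd_matrix(
    poses: Sequence[DockPose], interface_cutoff: float = 10.0
) -> np.ndarray:
    n = len(poses)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_pose_rmsd(
                poses[i].structure, poses[j].structure, interface_cutoff
            )
    return D


def cluster_poses(
    poses: Sequence[DockPose],
    cutoff: float = 7.5,
    min_size: int = 4,
    rmsd_matrix: np.ndarray | None = None,
) -> list[PoseCluster]:
    """Greedy largest-neighbourhood (Daura-style) clustering.

    Repeatedly take the pose with the most neighbours within ``cutoff``
    (ties: lowest input index) as a cluster centre together with its
    neighbours, remove them, and iterate.  Clusters smaller than
    ``min_size`` are discarded; every retained member is within ``cutoff``
    of its cluster centre.  May return zero clusters.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    D = pose_rmsd_matrix(poses) if rmsd_matrix is None else np.asarray(rmsd_matrix)
    n = len(poses)
    remaining = list(range(n))
    clusters = []
    while remaining:
        idx = np.array(remaining)
        neigh = (D[np.ix_(idx, idx)] <= cutoff).sum(axis=1)  # includes self
        center_pos = int(np.argmax(neigh))  # first max = lowest index
        center = idx[center_pos]
        members = [int(i) for i in idx if D[center, i] <= cutoff]
        clusters.append((center, members))
        remaining = [i for i in remaining if i not in set(members)]
    out = []
    for center, members in clusters:
        if len(members) < min_size:
            continue
        ordered = [center] + [m for m in members if m != center]
        out.append(PoseCluster([poses[m] for m in ordered]))
    return out


def rank_clusters(clusters: Iterable[PoseCluster]) -> list[PoseCluster]:
    """Order clusters by score ascending (mean of 4 lowest member scores),
    ties broken by larger size; ranks assigned 1..n."""
    ordered = sorted(clusters, key=lambda c: (c.score, -c.size))
    return [
        PoseCluster(c.members, rank=i + 1) for i, c in enumerate(ordered)
    ]


def patch_distance(pose: DockPose, patch: Patch, ligand_chain: str) -> float:
    """Minimum heavy-atom distance from the ligand chain to the patch residues."""
    s = pose.structure
    lig = s.chain(ligand_chain)
    receptor_chains = [c for c in s.chains if c.id != ligand_chain]
    if not receptor_chains:
        raise ValueError(f"no receptor chain besides {ligand_chain!r}")
    if not patch.residues:
        raise ValueError("empty patch")
    rec = receptor_chains[0]
    patch_coords = np.vstack(
        [rec.residue(n).heavy_coords() for n in sorted(patch.residues)]
    )
    lig_coords = lig.heavy_coords()
    return float(np.min(cKDTree(patch_coords).query(lig_coords)[0]))


# --- reports ---------------------------------------------------------------


def read_scores(path) -> dict[str, float]:
    """Two-column (model-id, score) sidecar table; whitespace or tab separated."""
    scores = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'model score'")
        scores[parts[0]] = float(parts[1])
    return scores


def evaluation_report(
    clusters: Sequence[PoseCluster],
    reference: Structure,
    n_best: int = 4,
) -> pd.DataFrame:
    """Per-cluster table: rank, size, score, and iRMSD/lRMSD/fnat of the
    ``n_best`` lowest-score members (mean) against the reference."""
    rows = []
    for c in clusters:
        best = sorted(c.members, key=lambda p: p.score)[:n_best]
        evals = [evaluate_model(p.structure, reference) for p in best]
        rows.append(
            {
                "cluster": c.rank,
                "size": c.size,
                "score": round(c.score, 1),
                "irmsd": round(float(np.mean([e.irmsd for e in evals])), 2),
                "lrmsd": round(float(np.mean([e.lrmsd for e in evals])), 2),
                "fnat": round(float(np.mean([e.fnat for e in evals])), 3),
                "capri": capri_class(
                    EvaluationResult(
                        float(np.mean([e.irmsd for e in evals])),
                        float(np.mean([e.lrmsd for e in evals])),
                        float(np.mean([e.fnat for e in evals])),
                    )
                ),
            }
        )
    return pd.DataFrame(rows)
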