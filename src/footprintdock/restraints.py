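"""From propensity differences to docking restraints.

A residue is *active* (experimentally implicated in the interface) when its
relative cleavage propensity in the complex drops by at least a threshold
fraction (default 20%) relative to the free protein — interface residues
are protected from proteolysis in the bound state.  *Passive* residues are
solvent-exposed surface neighbours of active ones; ambiguous interaction
restraints (AIRs) force every active residue to contact any active/passive
residue of the partner.  This module derives active sets, selects passive
residues by relative solvent accessibility, optionally promotes exposed
neighbours to active for the final docking run, and emits the CNS-style
``.tbl`` restraint file and a flat key=value run-parameter document for the
two-stage (filter → final) protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

from .spectra import PropensityTable
from .structure import Structure

__all__ = [
    "ComparisonConfig",
    "MoleculeRestraints",
    "RestraintSet",
    "RunSpec",
    "MAX_ASA",
    "derive_active",
    "relative_sasa",
    "select_passive",
    "promote_neighbors",
    "random_exclusion_sets",
    "write_air_tbl",
    "format_air_tbl",
    "write_run_param",
    "read_run_param",
    "read_residue_list",
]

#: Maximum accessible surface area per residue type (Å²), extended
#: Gly-X-Gly tripeptide reference (theoretical values of Tien et al. 2013).
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass(frozen=True)
class ComparisonConfig:
    """Free-vs-bound comparison rule.

    ``threshold`` is a *relative* decrease — bound propensity at least
    ``threshold`` × 100% smaller than free.  Sites whose free propensity is
    below ``floor`` carry no signal and are never called active.
    ``aggregation`` is ``"mean"`` (mean propensity over t > 0, default) or
    ``"max"`` (largest single-time relative drop).
    """

    threshold: float = 0.20
    floor: float = 0.01
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        if self.aggregation not in ("mean", "max"):
            raise ValueError("aggregation must be mean|max")


def derive_active(
    free: PropensityTable, bound: PropensityTable, cfg: ComparisonConfig | None = None
) -> list[int]:
    """Residues protected upon complex formation, sorted ascending.

    Site *s* is active iff free(s) ≥ floor and
    (free(s) − bound(s)) / free(s) ≥ threshold, with free/bound aggregated
    over time points t > 0 per the config.
    """
    cfg = cfg or ComparisonConfig()
    if free.protein_id != bound.protein_id:
        raise ValueError(
            f"protein mismatch: {free.protein_id!r} vs {bound.protein_id!r}"
        )
    if not np.array_equal(free.sites, bound.sites):
        raise ValueError("free and bound tables cover different site sets")
    if not np.array_equal(free.times, bound.times):
        raise ValueError("free and bound tables use different time grids")
    if cfg.aggregation == "mean":
        f = free.mean_over_time()
        b = bound.mean_over_time()
        ok = np.isfinite(f) & np.isfinite(b) & (f >= cfg.floor)
        drop = np.zeros_like(f)
        drop[ok] = (f[ok] - b[ok]) / f[ok]
        hit = ok & (drop >= cfg.threshold - 1e-12)
    else:  # max single-time relative drop
        F, B = free.propensity, bound.propensity
        cols = free.times > 0
        F, B = F[:, cols], B[:, cols]
        valid = np.isfinite(F) & np.isfinite(B) & (F >= cfg.floor)
        with np.errstate(invalid="ignore", divide="ignore"):
            drop = np.where(valid, (F - B) / F, -np.inf)
        hit = np.max(drop, axis=1) >= cfg.threshold - 1e-12
    return [int(s) for s in free.sites[hit]]


# --- solvent accessibility -------------------------------------------------


def _to_biopython(structure: Structure):
    sb = StructureBuilder()
    sb.init_structure(structure.id)
    sb.init_model(0)
    for chain in structure.chains:
        sb.init_chain(chain.id)
        sb.init_seg("    ")
        for res in chain.residues:
            sb.init_residue(res.name, " ", res.number, res.icode or " ")
            used: set[str] = set()
            for i, atom in enumerate(res.atoms):
                name = atom.name
                while name in used:  # Biopython keys atoms by name
                    name = f"{atom.name}{i}"
                used.add(name)
                sb.init_atom(
                    name, atom.coord, 0.0, 1.0, " ",
                    name if len(name) == 4 else f" {name:<3s}",
                    i, atom.element,
                )
    return sb.get_structure()


def relative_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chain: str | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue relative solvent accessibility (side chain inclusive).

    Shrake–Rupley numerical SASA (probe 1.4 Å, 960 sphere points per atom)
    divided by the residue type's extended Gly-X-Gly reference area.  Values
    can slightly exceed 1 for unusually extended conformations.  Residues of
    unknown type or with no heavy atoms are excluded from the result.
    """
    if structure.n_atoms() == 0:
        raise ValueError("empty structure")
    bio = _to_biopython(structure)
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(
        bio[0], level="R"
    )
    out: dict[tuple[str, int], float] = {}
    for bc in bio[0]:
        if chain is not None and bc.id != chain:
            continue
        for br in bc:
            ref = MAX_ASA.get(br.get_resname().strip())
            if ref is None or len(br) == 0:
                continue
            out[(bc.id, br.id[1])] = float(br.sasa) / ref
    return out


def _min_distance_to_actives(
    chain_obj, active_coords: np.ndarray
) -> dict[int, float]:
    from scipy.spatial import cKDTree

    tree = cKDTree(active_coords)
    dists = {}
    for res in chain_obj.residues:
        coords = res.heavy_coords()
        if len(coords) == 0:
            continue
        dists[res.number] = float(np.min(tree.query(coords)[0]))
    return dists


def select_passive(
    structure: Structure,
    active: Iterable[int],
    sasa_cutoff: float = 0.5,
    dist_cutoff: float = 6.5,
    chain: str | None = None,
) -> set[int]:
    """Surface neighbours of the active residues.

    A residue is passive when it is not active, has relative SASA at least
    ``sasa_cutoff`` (default 50%), and has a heavy atom within
    ``dist_cutoff`` Å of any active residue's heavy atoms.
    """
    active = set(active)
    chain_id = chain or structure.chains[0].id
    chain_obj = structure.chain(chain_id)
    missing = active - set(chain_obj.residue_numbers())
    if missing:
        raise ValueError(f"active residues {sorted(missing)} not in chain {chain_id}")
    active_coords = np.vstack(
        [chain_obj.residue(n).heavy_coords() for n in sorted(active)]
    )
    rel = relative_sasa(structure, chain=chain_id)
    dmin = _min_distance_to_actives(chain_obj, active_coords)
    return {
        n
        for n in chain_obj.residue_numbers()
        if n not in active
        and rel.get((chain_id, n), 0.0) >= sasa_cutoff
        and dmin.get(n, math.inf) <= dist_cutoff
    }


def promote_neighbors(
    structure: Structure,
    active: Iterable[int],
    sasa_cutoff: float = 0.5,
    dist_cutoff: float = 6.5,
    chain: str | None = None,
) -> tuple[set[int], dict[int, str]]:
    """Final-run rule: surface-exposed immediate neighbours become active.

    Because a protease only samples its own cleavable residues, the
    experimentally identified set under-covers the interface; for the final
    docking run the exposed residues adjacent to it are promoted from
    passive to active.  Returns the expanded set and a provenance map
    (``promoted-neighbor`` for the additions).
    """
    active = set(active)
    promoted = select_passive(structure, active, sasa_cutoff, dist_cutoff, chain)
    provenance = {n: "promoted-neighbor" for n in promoted - active}
    return active | promoted, provenance


# --- restraint containers --------------------------------------------------


@dataclass
class MoleculeRestraints:
    """Active/passive residues of one molecule (chain/segid)."""

    segid: str
    active: set[int] = field(default_factory=set)
    passive: set[int] | str = field(default_factory=set)  # set or "auto"
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.passive, str):
            if self.passive != "auto":
                raise ValueError("passive must be a residue set or 'auto'")
        elif self.active & self.passive:
            raise ValueError(
                f"{self.segid}: active/passive overlap "
                f"{sorted(self.active & self.passive)}"
            )

    def passive_set(self) -> set[int]:
        return set() if self.passive == "auto" else set(self.passive)


@dataclass
class RestraintSet:
    """Active/passive residues for both molecules of a binary complex."""

    molecules: dict[str, MoleculeRestraints]

    def __post_init__(self) -> None:
        if len(self.molecules) != 2:
            raise ValueError("a RestraintSet covers exactly two molecules")

    def partner(self, name: str) -> MoleculeRestraints:
        others = [m for n, m in self.molecules.items() if n != name]
        return others[0]


@dataclass
class RunSpec:
    """One docking run of the two-stage protocol.

    The *filter* stage uses all candidate patches with 50% random AIR
    exclusion per structure calculation (which widens sampling, hence the
    raised structure counts 4000/400/400); the *final* stage uses the
    chosen patch, neighbour promotion, and no random exclusion.
    """

    stage: str  # "filter" | "final"
    restraints: RestraintSet
    random_removal: bool
    removal_fraction: float = 0.5
    n_rigid: int = 4000
    n_anneal: int = 400
    n_water: int = 400
    cluster_cutoff: float = 7.5
    cluster_min_size: int = 4

    def __post_init__(self) -> None:
        if self.stage not in ("filter", "final"):
            raise ValueError("stage must be filter|final")
        if self.stage == "filter" and not self.random_removal:
            raise ValueError("filter stage requires random AIR removal")
        if self.stage == "final" and self.random_removal:
            raise ValueError("final stage forbids random AIR removal")
        if min(self.n_rigid, self.n_anneal, self.n_water) <= 0:
            raise ValueError("structure counts must be positive")
        if not 0 <= self.removal_fraction < 1:
            raise ValueError("removal fraction must be in [0, 1)")


def random_exclusion_sets(
    airs: Sequence, fraction: float, n_sets: int, seed: int
) -> list[list]:
    """Per-structure random AIR subsets, each keeping ⌈(1−fraction)·n⌉ restraints."""
    if not airs:
        raise ValueError("empty AIR list")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    keep = math.ceil((1 - fraction) * len(airs))
    rng = np.random.default_rng(seed)
    return [
        [airs[i] for i in sorted(rng.choice(len(airs), size=keep, replace=False))]
        for _ in range(n_sets)
    ]


# --- file emission ---------------------------------------------------------


def format_air_tbl(rs: RestraintSet) -> str:
    """CNS-style AIR statements: every active residue restrained to the
    union of the partner's active+passive residues, bounds 2.0 2.0 0.0."""
    lines = []
    any_assign = False
    for name in sorted(rs.molecules):
        mol = rs.molecules[name]
        partner = rs.partner(name)
        targets = sorted(partner.active | partner.passive_set())
        if not mol.active:
            continue
        if not targets:
            raise ValueError(
                f"molecule {name}: partner {partner.segid} has no active or "
                "passive residues to target (is it 'auto'?)"
            )
        for resid in sorted(mol.active):
            any_assign = True
            lines.append(f"assign ( resid {resid} and segid {mol.segid})")
            lines.append("       (")
            for j, t in enumerate(targets):
                if j:
                    lines.append("     or")
                lines.append(f"        ( resid {t} and segid {partner.segid})")
            lines.append("       ) 2.0 2.0 0.0")
            lines.append("")
    if not any_assign:
        raise ValueError("no active residues on either molecule")
    return "\n".join(lines) + "\n"


def write_air_tbl(rs: RestraintSet, path) -> None:
    Path(path).write_text(format_air_tbl(rs))


def _fmt_resset(v: set[int] | str) -> str:
    if v == "auto":
        return "auto"
    return ",".join(map(str, sorted(v))) if v else "-"


def _parse_resset(s: str) -> set[int] | str:
    if s == "auto":
        return "auto"
    if s == "-":
        return set()
    return {int(x) for x in s.split(",")}


def write_run_param(
    run: RunSpec, structures: Mapping[str, str | Path], path
) -> None:
    """Write the flat key=value docking parameter document.

    ``structures`` maps molecule name → unbound-structure PDB path; paths
    must exist.  The AIR block is embedded verbatim between ``air_begin``
    and ``air_end`` so one file carries the whole run definition.
    """
    for name, spath in structures.items():
        if not Path(spath).exists():
            raise FileNotFoundError(f"structure file for {name}: {spath}")
    rs = run.restraints
    lines = [
        "# footprintdock docking run parameters",
        f"stage={run.stage}",
        f"random_removal={'true' if run.random_removal else 'false'}",
        f"removal_fraction={run.removal_fraction:g}",
        f"n_rigid={run.n_rigid}",
        f"n_anneal={run.n_anneal}",
        f"n_water={run.n_water}",
        f"cluster_cutoff={run.cluster_cutoff:g}",
        f"cluster_min_size={run.cluster_min_size}",
        f"molecules={','.join(sorted(rs.molecules))}",
    ]
    for name in sorted(rs.molecules):
        mol = rs.molecules[name]
        lines.append(f"structure_{name}={structures[name]}")
        lines.append(f"segid_{name}={mol.segid}")
        lines.append(f"active_{name}={_fmt_resset(mol.active)}")
        lines.append(f"passive_{name}={_fmt_resset(mol.passive)}")
    lines.append("air_begin")
    lines.append(format_air_tbl(rs).rstrip("\n"))
    lines.append("air_end")
    Path(path).write_text("\n".join(lines) + "\n")


def read_run_param(path) -> tuple[RunSpec, dict[str, str]]:
    """Parse a parameter document back into (RunSpec, structure paths)."""
    kv: dict[str, str] = {}
    in_air = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line == "air_begin":
            in_air = True
            continue
        if line == "air_end":
            in_air = False
            continue
        if in_air or not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        k, v = line.split("=", 1)
        kv[k] = v
    molecules = {}
    structures = {}
    for name in kv["molecules"].split(","):
        molecules[name] = MoleculeRestraints(
            segid=kv[f"segid_{name}"],
            active=_parse_resset(kv[f"active_{name}"]),
            passive=_parse_resset(kv[f"passive_{name}"]),
        )
        structures[name] = kv[f"structure_{name}"]
    run = RunSpec(
        stage=kv["stage"],
        restraints=RestraintSet(molecules),
        random_removal=kv["random_removal"] == "true",
        removal_fraction=float(kv["removal_fraction"]),
        n_rigid=int(kv["n_rigid"]),
        n_anneal=int(kv["n_anneal"]),
        n_water=int(kv["n_water"]),
        cluster_cutoff=float(kv["cluster_cutoff"]),
        cluster_min_size=int(kv["cluster_min_size"]),
    )
    return run, structures


def read_residue_list(path) -> set[int]:
    """Read a residue-number list (one per line, ``#`` comments allowed)."""
    out = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            out.add(int(line))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: not a residue number: {line!r}") from None
    return out
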