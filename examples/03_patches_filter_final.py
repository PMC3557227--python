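"""Patch detection and the two-stage (filter -> final) docking protocol.

Active residues split into two spatial patches on the receptor: the true
interface patch and a remote false-positive patch.  A filter docking run
(emulated by mock poses: near-native poses score better) decides the
patch; the final run keeps only that patch, promotes exposed neighbours
to active, and turns random AIR exclusion off.
"""

from pathlib import Path

import footprintdock as fd
from footprintdock.pipeline import run_filter_analysis
from footprintdock.structure import write_pdb
from footprintdock.synthetic import make_mock_poses, make_toy_complex

toy = make_toy_complex(seed=0)
active = [5, 8, 12, 17, 21, 28]  # 5, 8, 12 face the ligand

patches = fd.kmeans_patches(toy.receptor, active, k=fd.suggest_k(toy.receptor, active))
for p in patches:
    print(f"patch {p.label}: residues {sorted(p.residues)} ({p.atom_count} atoms)")

poses, labels = make_mock_poses(toy, n_near=8, n_far=8, noise=1.0, seed=2)
outcome = run_filter_analysis(poses, patches, ligand_chain="B")
for c, d, assigned in zip(outcome.clusters, outcome.patch_distances,
                          outcome.cluster_patches):
    dist = ", ".join(f"patch {k}: {v:.1f} A" for k, v in sorted(d.items()))
    print(f"cluster {c.rank}: {c.size} poses, score {c.score:.1f} ({dist})"
          f" -> patch {assigned}")
print(f"chosen patch: {outcome.chosen_patch}")

chosen = next(p for p in patches if p.label == outcome.chosen_patch)
rs = fd.RestraintSet({
    "rec": fd.MoleculeRestraints("A", active=set(active)),
    "lig": fd.MoleculeRestraints("B", passive=set(range(1, 21))),
})
final = fd.build_final_run(rs, chosen, toy.receptor)
print(f"final actives (patch + promoted neighbours): "
      f"{sorted(final.restraints.molecules['rec'].active)}")
print(f"random AIR removal in final run: {final.random_removal}")

out = Path("scratch_example_out")
out.mkdir(exist_ok=True)
write_pdb(toy.receptor, out / "rec.pdb")
write_pdb(toy.ligand, out / "lig.pdb")
fd.write_air_tbl(final.restraints, out / "final_air.tbl")
fd.write_run_param(final, {"rec": out / "rec.pdb", "lig": out / "lig.pdb"},
                   out / "final_run.param")
print(f"wrote {out}/final_air.tbl and {out}/final_run.param")
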