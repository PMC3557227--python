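"""CAPRI-style evaluation of docked models against a reference complex.

Mock docking output (near-native and wrong-face poses with engine scores)
is clustered at 7.5 A / minimum size 4, clusters are ranked by the mean of
their four lowest scores, and each cluster's best members are measured by
iRMSD, lRMSD and fnat against the reference.
"""

import footprintdock as fd
from footprintdock.evaluation import evaluation_report
from footprintdock.synthetic import make_mock_poses, make_toy_complex

toy = make_toy_complex(seed=0)
poses, labels = make_mock_poses(toy, n_near=8, n_far=8, noise=1.0, seed=4)

clusters = fd.rank_clusters(fd.cluster_poses(poses, cutoff=7.5, min_size=4))
report = evaluation_report(clusters, toy.complex)
print(report.to_string(index=False))
# The near-native cluster ranks first (best score), is CAPRI-acceptable
# (iRMSD < 4 A, lRMSD < 10 A, fnat > 0.1); the wrong-face cluster is not.

best = min(clusters[0].members, key=lambda p: p.score)
r = fd.evaluate_model(best.structure, toy.complex)
print(f"best pose {best.id}: iRMSD {r.irmsd:.2f} A, lRMSD {r.lrmsd:.2f} A, "
      f"fnat {r.fnat:.3f}, CAPRI {'acceptable' if r.capri_acceptable else 'not acceptable'}")
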