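"""Generate a small synthetic cohort and assess all its links.

Places nodes in two hemisphere-shaped half-ellipsoids, builds signals
whose pairwise correlations decay with distance according to the
three-regime ground truth, runs the link assessment, and prints the
per-subject link ratio R.
"""

import numpy as np

from obscor import (MethodParams, SyntheticConfig, assess_links,
                    generate_cohort, links_to_frame, subject_summary)

cfg = SyntheticConfig.reduced_desk(seed=3, n_nodes=16, n_subjects=2)
params = MethodParams.reduced(seed=3)
nodes, series, gt = generate_cohort(cfg)

print(f"{len(nodes)} nodes, min pair distance "
      f"{nodes.min_pair_distance():.1f} mm")
for ts in series:
    records = assess_links(ts, ts.nodes, params)
    frame = links_to_frame(records, ts.subject_id)
    s = subject_summary(frame, ts.subject_id)
    print(f"subject {s.subject_id}: R = {s.R:.2f} "
          f"({s.n_links}/{s.n_pairs} pairs linked), "
          f"mean W = {s.mean_W:.1f} s")
print("-> R is the fraction of node pairs with a detectable link;")
print(f"   the generator left {gt.unlinked_fraction:.0%} of pairs with no "
      "shared signal, and weak long-range links escape detection.")
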