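"""Simulate the desk-scale synthetic cohort and write it to results/data.

Two groups of 20 subjects, 30 ROIs in 4 networks, 240 time points; group A
carries extra co-fluctuation on 12 planted inter-network edges while expected
static correlations are identical across groups.  Prints the realized
modulation amplitude (after positive-semidefiniteness shrinkage) and a quick
check that static correlations on planted edges match between groups.
"""

import argparse
from pathlib import Path

import numpy as np

from efcpipe import SimParams, generate_cohort, make_toy_affiliation, write_cohort
from efcpipe.graph import static_fc
from efcpipe.edges import edge_id


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    params = SimParams(seed=args.seed)
    cohort, truth = generate_cohort(params)
    aff = make_toy_affiliation(params.R, params.M, overlap_fraction=0.2)
    manifest = write_cohort(cohort, truth, args.out, aff)

    idx = [edge_id(i, j, params.R) for i, j in truth.planted_edges]
    r = np.stack([static_fc(mat)[idx] for mat in cohort.data])
    r_a = r[cohort.labels == 1].mean()
    r_b = r[cohort.labels == -1].mean()
    print(f"cohort written: {manifest}")
    print(f"requested delta {params.delta}, effective {truth.effective_delta:.3f} "
          "(shrunk to keep every instantaneous covariance PSD)")
    print(f"mean static r on planted edges: group A {r_a:.3f}, group B {r_b:.3f} "
          f"(|difference| {abs(r_a - r_b):.3f} — statics matched)")


if __name__ == "__main__":
    main()
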