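"""Static-FC baselines: group t-tests with FDR and static classifiers.

Shows the planted cohort's defining property: mass-univariate tests on
full-scan correlations find (essentially) nothing, and classifiers fed
static features (raw correlations, or their clustering coefficients) hover
at chance, in contrast to the dynamic eFC classifier of 03_classify_efc.py.
Writes the per-edge test table and a comparison table of the three feature
kinds.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from efcpipe import CVConfig, read_cohort
from efcpipe.edges import edge_pairs, num_edges
from efcpipe.graph import static_fc
from efcpipe.stats import classify_static, groupwise_ttest_fdr


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--manifest", type=Path, default=Path("results/data/manifest.csv"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/baselines"))
    args = ap.parse_args()

    cohort = read_cohort(args.manifest)
    args.out.mkdir(parents=True, exist_ok=True)

    X = np.stack([static_fc(mat) for mat in cohort.data])
    res = groupwise_ttest_fdr(X, cohort.labels)
    R = cohort.n_rois
    iu, ju = edge_pairs(R)
    pd.DataFrame(
        {
            "edge_id": np.arange(num_edges(R)) + 1,
            "roi_i": iu + 1,
            "roi_j": ju + 1,
            "t": res.t,
            "p": res.p,
            "q": res.q,
            "significant": res.significant,
        }
    ).to_csv(args.out / "static_ttests.tsv", sep="\t", index=False)
    print(f"static FC group comparison: {res.n_significant} of {num_edges(R)} "
          f"edges BH-significant at q < {res.alpha}")

    rows = []
    cfg = CVConfig(seed=args.seed)
    for kind in ("sFC", "sFC-WLCC"):
        report, _ = classify_static(cohort, cfg, kind=kind)
        rows.append({"features": kind, **report.mean})
        print(report.summary())
    pd.DataFrame(rows).to_csv(args.out / "static_classifiers.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
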