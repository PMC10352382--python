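"""Nuclear twin and family design model ladder.

Fits the saturated reference model and the six baseline NTFD models
(phenotypic assortment and social homogamy, each with one of the
non-identified components fixed to zero), prunes non-significant paths, and
selects by AIC.

Usage: python analysis/05_ntfd_ladder.py [--data results/families_preprocessed.csv]
       [--out-dir results] [--starts 2]
"""

import argparse
from pathlib import Path

import pandas as pd

from twinfam.fit import FamilyData, run_ladder
from twinfam.report import render_ladder


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/families_preprocessed.csv")
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--starts", type=int, default=2)
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data = FamilyData.from_table(pd.read_csv(args.data))
    report = run_ladder(data, n_starts=args.starts)
    render_ladder(report, out)
    print(report.comparisons.to_string(index=False))
    best = report.best
    print(f"\nbest model: {report.best_name} (AIC {best.AIC:.2f})")
    print("components (%):",
          {k: round(100 * v, 1) for k, v in (best.components or {}).items()})


if __name__ == "__main__":
    main()
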