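"""How much training data does the abundance model need?

Refits the GLM on random training subsets of 10-450 quadrats (5 repeats per
size), scoring each by LOOCV within the subset, and locates the smallest
size whose error stays within 0.005 of the full-data LOOCV error.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from kelpscape.pipeline import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--dir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    config = RunConfig(seed=args.seed, preset="paperlike", out_dir=str(args.dir))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_pipeline(config, stages=("simulate", "qc", "learning_curve"))

    table = pd.read_csv(args.dir / "learning_curve.csv")
    summary = json.loads((args.dir / "learning_curve_summary.json").read_text())
    mean = table[table["converged"]].groupby("n_train")["error"].mean()
    print(mean.round(4).to_string())
    print(f"full-data LOOCV error: {summary['full_error']:.4f}")
    asym = summary["asymptote_n"]
    print(
        "no improvement in accuracy beyond "
        + (f"~{asym} training quadrats" if asym is not None else "the tested grid")
    )


if __name__ == "__main__":
    main()
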