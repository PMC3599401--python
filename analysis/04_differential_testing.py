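"""Moderated-t testing of tumor-vs-normal, CIMP and BRAF contrasts with
BH selection at FDR <= 0.01."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

import pandas as pd

from dmh.pipeline import step_test


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args.seed, args.dir)
    step_test(cfg, args.dir)
    for contrast in ("tumor", "cimp", "braf"):
        res = pd.read_csv(args.dir / "test" / f"results_{contrast}.tsv", sep="\t")
        sel = res[res["selected"]]
        hyper = 100 * (sel["effect"] > 0).mean() if len(sel) else float("nan")
        print(f"{contrast}: {len(sel)} regions at FDR<=0.01, "
              f"{hyper:.1f}% with higher tumor/normal ratio in the group")


if __name__ == "__main__":
    main()
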