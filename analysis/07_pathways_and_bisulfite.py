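"""Binomial gene-set enrichment of BRAF-specific promoter genes (after
pre-mark and copy-number filtering) and bisulfite validation by
one-sided Mann-Whitney."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

import pandas as pd

from dmh.pipeline import step_downstream


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args.seed, args.dir)
    step_downstream(cfg, args.dir)
    enr = pd.read_csv(args.dir / "downstream" / "enrichment.tsv", sep="\t")
    print("top gene sets by binomial P:")
    print(enr.head(5).to_string(index=False,
                                formatters={"P": "{:.3g}".format,
                                            "expected": "{:.2f}".format}))
    bs = pd.read_csv(args.dir / "downstream" / "bisulfite_tests.tsv", sep="\t")
    for row in bs.itertuples():
        print(f"{row.gene}: mutant > wildtype one-sided Mann-Whitney "
              f"U={row.U:.0f}, P={row.P:.3g}")


if __name__ == "__main__":
    main()
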