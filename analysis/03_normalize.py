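"""Preprocess the dye-swap scans: within-array LOESS, between-array
aquantile, dye-swap combination, median log2 ratio per fragment."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

import pandas as pd

from dmh.pipeline import step_normalize


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args.seed, args.dir)
    step_normalize(cfg, args.dir)
    matrix = pd.read_csv(args.dir / "normalize" / "matrix.tsv", sep="\t",
                         index_col="fragment_id")
    print(f"normalized matrix: {matrix.shape[0]} fragments x "
          f"{matrix.shape[1]} samples")
    print(f"per-sample log2 ratio SD (median across samples): "
          f"{matrix.std().median():.3f}")


if __name__ == "__main__":
    main()
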