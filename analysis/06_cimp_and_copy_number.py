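"""CIMP calls from the marker panel and the copy-number exclusion filter
on BRAF-specific regions (cut at wildtype median - SD)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

import pandas as pd

from dmh.pipeline import step_classify


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args.seed, args.dir)
    step_classify(cfg, args.dir)
    calls = pd.read_csv(args.dir / "classify" / "cimp_calls.tsv", sep="\t")
    print("CIMP calls:", calls["call"].value_counts().to_dict())
    report = pd.read_csv(args.dir / "classify" / "cn_filter.tsv", sep="\t")
    thr = report["threshold"].iloc[0]
    print(f"copy-number filter: median {report['median'].iloc[0]:.3f}, "
          f"SD {report['sd'].iloc[0]:.3f}, threshold {thr:.3f}")
    print(f"excluded {int(report['excluded'].sum())} of {len(report)} "
          f"BRAF-specific regions as likely copy-number losses")


if __name__ == "__main__":
    main()
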