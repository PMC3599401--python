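"""Digest the genome with MseI in silico, map probes to fragments and
select informative fragments (150-3,000 bp, >=1 complete probe, >=1
HpaII/BstUI site)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

import pandas as pd

from dmh.pipeline import step_digest


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args.seed, args.dir)
    step_digest(cfg, args.dir)
    frags = pd.read_csv(args.dir / "digest" / "fragments.tsv", sep="\t")
    inf = pd.read_csv(args.dir / "digest" / "informative.tsv", sep="\t")
    pm = pd.read_csv(args.dir / "digest" / "probe_map.tsv", sep="\t")
    mapped = pm["fragment_id"].notna().mean()
    print(f"{len(frags)} MseI fragments; {len(inf)} informative "
          f"({100 * len(inf) / len(frags):.1f}%)")
    print(f"{mapped * 100:.1f}% of probes map completely inside a fragment")
    print(f"probes per informative fragment: median "
          f"{inf['n_probes'].median():.0f}, max {inf['n_probes'].max()}")


if __name__ == "__main__":
    main()
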