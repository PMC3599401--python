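"""Generate the synthetic DMH study: genome, array, cohort, scans,
chromatin tracks, marker panel and bisulfite tables, with ground truth."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_args, pipeline_config

from dmh.pipeline import step_simulate


def main() -> None:
    args = parse_args(__doc__)
    cfg = pipeline_config(args.seed, args.dir)
    sim_dir = step_simulate(cfg, args.dir)
    import json
    manifest = json.loads((sim_dir / "manifest.json").read_text())
    print(f"synthetic study written to {sim_dir} ({len(manifest['files'])} files)")
    print(f"cohort: {cfg.simulation.n_wildtype} BRAF-wildtype + "
          f"{cfg.simulation.n_mutant} mutant tumors, "
          f"{cfg.simulation.n_cimp_pos} CIMP-positive")


if __name__ == "__main__":
    main()
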