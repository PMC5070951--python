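"""Correlate CFS network strength with working-memory capacity.

Builds each subject's network strength over the positive-tail
Mean-condition edges, detrends and normalizes strength and capacity
(removing subject level and common load trend), and correlates them
across pooled (subject, load) observations per low frequency and ratio
group, with Benjamini-Hochberg correction.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from demo_config import demo_config, parse_args

from crossfreq.pipeline import stage_behavior


def main() -> None:
    args = parse_args(__doc__)
    cfg = demo_config(seed=args.seed, out_dir=args.out_dir)
    path = stage_behavior(cfg)
    if path is None:
        print("no behavior table in the study; nothing to correlate")
        return
    df = pd.read_csv(path, sep="\t")
    print("strength-capacity correlations (pooled subject x load points):")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
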