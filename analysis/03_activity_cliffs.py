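#!/usr/bin/env python
"""SALI activity/selectivity cliffs, similarity network and clustering.

Ranks all compound pairs by SALI in both activity (pIC50) and selectivity
(log10 SI) modes, exports the similarity network as GraphML with per-node
local SALI contributions, and average-linkage clusters the set.
"""

from pathlib import Path

import pandas as pd

from maosel.dataset import records_from_frame
from maosel.pipeline import RunConfig, stage_cliffs

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig(outdir=str(OUTDIR), seed=1)
    records = records_from_frame(pd.read_csv(OUTDIR / "dataset_normalized.csv"))
    stage_cliffs(cfg, records, OUTDIR)
    for mode in ("activity", "selectivity"):
        top = pd.read_csv(OUTDIR / f"cliffs_{mode}.csv").head(3)
        print(f"top {mode} cliffs:")
        print(top[["i", "j", "activity_delta", "sim", "sali"]].to_string(index=False))
    clusters = pd.read_csv(OUTDIR / "clusters.csv")
    print(f"{clusters['cluster'].nunique()} clusters over {len(clusters)} compounds")


if __name__ == "__main__":
    main()
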