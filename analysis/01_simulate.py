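#!/usr/bin/env python
"""Generate the synthetic study inputs with recorded ground truth.

Writes a phylogeographic bundle (alignment, tree, tip areas) and an
environmental bundle (layer stack, truth suitability, presences,
background) under results/data/.
"""

import sys
from pathlib import Path

from phylogeo.simulate import save_bundle, sim_env_occurrences, sim_phylogeography

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")


def main() -> None:
    bundle = sim_phylogeography(
        seed=SEED, n_tips=24, n_regions=4, seq_len=600,
        sub_rate=0.002, indel_rate=0.3, dispersal_rate=0.15,
    )
    env = sim_env_occurrences(seed=SEED + 1)
    save_bundle(bundle, OUT)
    save_bundle(env, OUT)
    n_regions = len({next(iter(v)) for v in bundle.true_tip_areas.values()})
    print(f"wrote bundle to {OUT}: {len(bundle.alignment)} sequences "
          f"({bundle.alignment.length} bp) across {n_regions} regions; "
          f"{env.env.shape} grid with {len(env.env.names)} layers, "
          f"{len(env.presences)} presences, {len(env.background)} background cells")


if __name__ == "__main__":
    main()
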