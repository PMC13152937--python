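#!/usr/bin/env python
"""Weight-perturbation sensitivity of the prioritization.

Draws criterion-weight vectors from a Dirichlet distribution centered on
the AHP baseline (alpha = concentration x weights), re-ranks per draw, and
reports how often the top tier keeps its identity and how strongly the
full rankings correlate with the baseline (Kendall tau).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stampc.mcda import MCDAConfig, weight_sensitivity


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/sensitivity"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--draws", type=int, default=500)
    ap.add_argument("--concentration", type=float, default=100.0)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    sources = pd.read_csv(args.data_dir / "sources.csv", index_col=0)
    res = weight_sensitivity(
        sources,
        MCDAConfig(),
        n_draws=args.draws,
        concentration=args.concentration,
        seed=args.seed,
    )
    payload = {
        "n_draws": res.n_draws,
        "concentration": res.concentration,
        "seed": res.seed,
        "top_k": res.top_k,
        "top_k_stability": res.top_k_stability,
        "mean_rank_correlation": res.mean_rank_correlation,
    }
    (args.out_dir / "sensitivity.json").write_text(json.dumps(payload, indent=2) + "\n")
    res.rank_quantiles.to_csv(args.out_dir / "rank_quantiles.csv")
    print(
        f"{res.n_draws} Dirichlet draws (concentration {res.concentration:g}): "
        f"top-{res.top_k} identity stable in {100 * res.top_k_stability:.1f}% "
        f"of draws; mean Kendall tau {res.mean_rank_correlation:.3f}"
    )


if __name__ == "__main__":
    main()
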