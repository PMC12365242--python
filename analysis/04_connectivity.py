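"""Connectivity under layer accumulation.

The accumulation report [C; C+E+H; +N; +S; +W]: vertices, edges,
components, giant-component share, exact diameter and sampled mean
shortest path, plus sampled closeness on the full network.  Writes
results/connectivity_table.csv and results/closeness_sample.csv.
"""

import importlib.util
import sys
from pathlib import Path

from popnet.connectivity import closeness_sampled, layer_accumulation_table

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("deg", ROOT / "analysis" / "03_degree_structure.py")
deg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(deg)
SEED = 2017


def main() -> None:
    _, net = deg.load_network()
    table = layer_accumulation_table(net, seed=SEED, n_sources=300)
    table.to_csv(ROOT / "results" / "connectivity_table.csv", index=False)
    print(table.to_string(index=False))

    close = closeness_sampled(net, seed=SEED, sample_size=300)
    close.rename_axis("person_id").reset_index().to_csv(
        ROOT / "results" / "closeness_sample.csv", index=False
    )
    print(f"\nmean sampled closeness (full network): {close.mean():.4f}")
    print("the family layers alone leave the population fragmented; the"
          "\nfirst affiliation layer (neighbors) assembles the giant component")


if __name__ == "__main__":
    sys.exit(main())
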