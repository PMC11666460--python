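#!/usr/bin/env python
"""Chemotag cell typing and the ensemble composition of inhibitory neurons.

On the example animal's CNO session: rank cells by prominent-peak count in
minutes 10-40, flag the top 10% as putative inhibitory neurons, propagate
the flags to offline 2 through the match table, and test each ensemble for
inhibitory enrichment. Writes results/chemotag_composition.csv.
"""

from pathlib import Path

import pandas as pd

from coreact import io as io_mod
from coreact.chemotag import ensemble_composition, propagate_labels, rank_chemotag
from coreact.core import assign_ensembles

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    exp = io_mod.read_experiment(ROOT / "example_mouse" / "manifest.json")
    ranking = rank_chemotag(exp.sessions["chemotag"].matrix)
    n_flagged = sum(ranking.flags.values())
    print(f"chemotag session: {len(ranking.cell_ids)} cells, "
          f"{n_flagged} flagged putative inhibitory (top 10%)")
    offline_cells = exp.sessions["offline2"].matrix.cell_ids.tolist()
    propagated = propagate_labels(
        ranking, exp.match_table("chemotag", "offline2"),
        "chemotag", "offline2", offline_cells,
    )
    assignment = assign_ensembles(
        "offline2", offline_cells,
        exp.match_table("offline2", "neutral_encoding"),
        exp.match_table("offline2", "aversive_encoding"),
    )
    comp = ensemble_composition(assignment, propagated.flags)
    rows = []
    for name, c in comp.items():
        rows.append({"ensemble": name, **c})
        print(
            f"  {name:<10} {c['n_flagged']}/{c['n_cells']} inhibitory "
            f"({100 * c['fraction']:.0f}% vs {100 * c['global_fraction']:.0f}%"
            f" globally), enrichment p = {c['p_enrichment']:.3f}"
        )
    pd.DataFrame(rows).to_csv(ROOT / "chemotag_composition.csv", index=False)
    print(f"wrote {ROOT / 'chemotag_composition.csv'}")


if __name__ == "__main__":
    main()
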