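#!/usr/bin/env python
"""Genotype-network fragmentation and its mechanistic cause on the two-route fixture.

Builds swap-adjacency networks for every occupied size of the pentose-like
universe, verifies the parent-clique propagation rule against direct
component computation, and contrasts per-component superessentiality
indices: the reactions of each alternative route are essential in every
genotype of their own component and dispensable wherever they appear in the
other.  Writes the fragmentation report and the superessentiality table
under results/fragmentation/.
"""

from pathlib import Path

import pandas as pd

from genonet import (
    brute_force_enumerate,
    build_network,
    fragmentation_report,
    load_model,
    propagate_connectivity,
    superessentiality_index,
)

MODELS = Path("results/models")
OUT = Path("results/fragmentation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    universe, env_map = load_model(MODELS / "pentose_like.json")
    envs = list(env_map.values())
    oracle = brute_force_enumerate(universe, envs)

    networks = {
        n: build_network(v, universe)
        for n, v in oracle.viable_by_size.items()
        if v
    }
    report = fragmentation_report(None, networks)
    report.to_csv(OUT / "fragmentation.csv", index=False)
    print("per-size component structure:")
    print(report.to_string(index=False))

    # parent-clique propagation reproduces direct component computation
    for n in sorted(networks):
        if n + 1 not in networks:
            continue
        propagated = propagate_connectivity(
            networks[n].components, oracle.minimal_by_size[n + 1], universe, envs
        )
        assert set(propagated) == set(networks[n + 1].components), n + 1
    print("\nparent-clique propagation matches direct BFS at every size")

    n_frag = int(report.loc[report["fragmented"], "n"].min())
    blocks = networks[n_frag].components
    a_side = sorted(
        next(b for b in blocks if all(g.has(universe.reaction_index("A1_1")) for g in b))
    )
    b_side = sorted(
        next(b for b in blocks if all(g.has(universe.reaction_index("B1_1")) for g in b))
    )
    rows = []
    for rid in ("A1_1", "A1_2", "B1_1", "B1_2", "B1_3"):
        for label, sample in (("route_A_component", a_side), ("route_B_component", b_side)):
            try:
                idx = superessentiality_index(universe, rid, sample, envs)
            except ValueError:
                idx = float("nan")  # reaction absent from every sampled genotype
            rows.append({"reaction": rid, "component": label, "superessentiality": idx})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "superessentiality.csv", index=False)
    print(f"\nsuperessentiality contrast at the fragmented size n={n_frag}:")
    print(table.pivot(index="reaction", columns="component", values="superessentiality"))
    print(
        "\neach route is fully essential inside its own component and "
        "dispensable in the other: alternative essential pathways of length "
        ">= 2 are what keeps the components apart"
    )


if __name__ == "__main__":
    main()
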