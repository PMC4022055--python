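#!/usr/bin/env python
"""Generate the library of synthetic reaction universes used by the analyses.

Writes one model JSON per fixture under results/models/ and prints each
universe's dimensions.  Every downstream script reads these files, so the
whole analysis chain is reproducible from this step alone.
"""

from pathlib import Path

from genonet import fixture_library, generate_universe, get_engine

OUT = Path("results/models")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, case in sorted(fixture_library().items()):
        path = OUT / f"{name}.json"
        universe, envs = generate_universe(case.spec, path=path)
        engine = get_engine(universe)
        refs = {env.name: engine.reference_rate(env) for env in envs}
        print(
            f"{name}: N={universe.N} internal reactions, m={universe.m} "
            f"metabolites, reference biomass rate(s) {refs} -> {path}"
        )
    print(f"\nwrote {len(fixture_library())} models to {OUT}/")


if __name__ == "__main__":
    main()
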