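"""Tabular outputs and run manifests.

CSV number formatting is fixed (plain integers for counts, 17 significant
digits for rates) so outputs diff cleanly across runs; every output
directory carries a manifest with the model hash, configuration and seeds
needed to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .network import GenotypeNetwork, export_components_csv, export_edges_csv
from .universe import Environment, ReactionUniverse, model_to_dict
from .walks import WalkTrace


def model_hash(universe: ReactionUniverse, environments: Sequence[Environment] = ()) -> str:
    doc = json.dumps(model_to_dict(universe, environments), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: format(x, ".17g"))
    return out


def write_manifest(
    outdir: str | Path,
    *,
    universe: ReactionUniverse,
    environments: Sequence[Environment],
    config: Mapping,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model_hash": model_hash(universe, environments),
        "N": universe.N,
        "m": universe.m,
        "environments": [e.name for e in environments],
        "config": dict(config),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def report_tables(
    census: pd.DataFrame | None,
    networks: Mapping[int, GenotypeNetwork] | None,
    walks: Sequence[WalkTrace] | None,
    outdir: str | Path,
    *,
    universe: ReactionUniverse,
    environments: Sequence[Environment],
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write the census / component / walk bundle with a provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    written["manifest"] = write_manifest(
        outdir, universe=universe, environments=environments, config=config or {}
    )
    if census is not None:
        path = outdir / "census.csv"
        _format_frame(census).to_csv(path, index=False)
        written["census"] = path
    if networks:
        for n, net in sorted(networks.items()):
            epath = outdir / f"edges_n{n}.csv"
            cpath = outdir / f"components_n{n}.csv"
            export_edges_csv(net, epath)
            export_components_csv(net, cpath)
            written[f"edges_n{n}"] = epath
            written[f"components_n{n}"] = cpath
    traces = list(walks) if walks is not None else []
    path = outdir / "walks.json"
    path.write_text(
        json.dumps([t.to_dict() for t in traces], indent=1, sort_keys=True) + "\n"
    )
    written["walks"] = path
    return written
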