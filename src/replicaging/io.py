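"""Tab-separated readers/writers and the run manifest.

All tables are UTF-8 TSV with one header row; missing values are written
as "NA".  Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .synthdata import AbundanceTable, GroundTruth
from .unmix import UnmixedSeries

NA = "NA"


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA, index_label=index_label or df.index.name or "id")
    return path


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], index_col=index_col)
    # numeric column headers (time points) come back as strings
    try:
        df.columns = df.columns.astype(float)
    except (TypeError, ValueError):
        pass
    return df


def write_abundance_table(table: AbundanceTable, prefix) -> tuple[Path, Path]:
    """Write values and the sample-metadata companion sheet."""
    prefix = Path(prefix)
    p_vals = write_table(table.values, prefix.with_suffix(".tsv"), index_label="gene")
    meta = table.samples
    p_meta = Path(str(prefix) + "_samples.tsv")
    p_meta.parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(p_meta, sep="\t", na_rep=NA, index=False)
    return p_vals, p_meta


def read_abundance_table(values_path, samples_path) -> AbundanceTable:
    values = pd.read_csv(values_path, sep="\t", na_values=[NA], index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", na_values=[NA])
    return AbundanceTable(values=values, samples=samples)


def write_unmixed_series(series: UnmixedSeries, prefix) -> tuple[Path, Path]:
    """Write values plus the per-entry status sidecar (gene, time_h, status)."""
    prefix = Path(prefix)
    p_vals = write_table(series.values, prefix.with_suffix(".tsv"), index_label="gene")
    flags = series.status.stack().rename("status").reset_index()
    flags.columns = ["gene", "time_h", "status"]
    p_flags = Path(str(prefix) + "_flags.tsv")
    flags.to_csv(p_flags, sep="\t", index=False)
    return p_vals, p_flags


def read_unmixed_series(values_path, flags_path, cell_type: str) -> UnmixedSeries:
    values = read_table(values_path)
    flags = pd.read_csv(flags_path, sep="\t")
    status = flags.pivot(index="gene", columns="time_h", values="status")
    status = status.loc[values.index]
    status.columns = values.columns
    return UnmixedSeries(cell_type=cell_type, values=values, status=status)


def write_ground_truth(truth: GroundTruth, outdir) -> Path:
    """Write pure trajectories as TSVs plus a JSON manifest (for oracles)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for level in ("protein", "transcript"):
        for ct, tab in getattr(truth, level).items():
            write_table(tab, outdir / f"truth_{level}_{ct}.tsv", index_label="gene")
    write_table(truth.archetype.to_frame(), outdir / "truth_archetypes.tsv", index_label="gene")
    write_table(truth.bead_loss.to_frame(), outdir / "truth_bead_loss.tsv", index_label="gene")
    manifest = {
        "seed": truth.seed,
        "times": [float(t) for t in truth.times],
        "complexes": truth.complexes,
        "complex_kind": truth.complex_kind,
    }
    p = outdir / "truth_manifest.json"
    p.write_text(json.dumps(manifest, indent=1))
    return p


def write_network(net, prefix) -> tuple[Path, Path]:
    """Write the directed network as edge-list TSV and GraphML."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"source": u, "target": v, "pcor": d.get("pcor", np.nan), "direction": "->"}
        for u, v, d in net.directed.edges(data=True)
    ]
    rows += [
        {
            "source": u,
            "target": v,
            "pcor": net.undirected.edges[u, v].get("pcor", np.nan),
            "direction": "none",
        }
        for u, v in net.directed.graph.get("undirected_ties", [])
    ]
    p_edges = Path(str(prefix) + "_edges.tsv")
    pd.DataFrame(rows, columns=["source", "target", "pcor", "direction"]).to_csv(
        p_edges, sep="\t", index=False
    )
    p_gml = Path(str(prefix) + ".graphml")
    D = net.directed.copy()
    D.graph.clear()  # GraphML cannot hold list-valued graph attributes
    nx.write_graphml(D, p_gml)
    return p_edges, p_gml


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, config: dict, stages: list[str], outputs: list[Path]) -> Path:
    manifest = {
        "config": config,
        "stages": stages,
        "outputs": {str(p): file_digest(p) for p in sorted(map(str, outputs))},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    p = Path(outdir) / "run_manifest.json"
    p.write_text(json.dumps(manifest, indent=1, default=str))
    return p
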