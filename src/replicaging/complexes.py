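"""Protein-complex stoichiometry loss.

A complex whose members change in lockstep keeps its internal
stoichiometry; one whose members drift apart loses it.  The statistic is
the interquartile range (IQR) of the members' log2 fold changes at a time
point: 0 for perfectly coordinated change, growing as members diverge.
IQR is translation-invariant, so a complex that is uniformly up- or
down-regulated scores 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    catalog: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            catalog[parts[0]] = parts[2:]
    return catalog


def write_gmt(catalog: dict[str, list[str]], path, description: str = "NA") -> None:
    with open(path, "w") as fh:
        for name, members in catalog.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def stoichiometry_loss(member_fold_changes, quantile_method: str = "linear") -> float:
    """IQR (Q3 - Q1) of a complex's member log2 fold changes.

    Quantiles use linear interpolation between order statistics by default
    (configurable, since box-plot conventions differ).  Requires at least
    two finite values.
    """
    x = np.asarray(member_fold_changes, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("stoichiometry loss needs >= 2 finite member fold changes")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=quantile_method)
    return float(q3 - q1)


def complex_trajectories(
    fc: pd.DataFrame,
    catalog: dict[str, list[str]],
    min_members: int = 2,
    quantile_method: str = "linear",
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Per-complex stoichiometry-loss (IQR) time series.

    Complexes with fewer than ``min_members`` quantified members are
    skipped and reported rather than scored.  Returns (complexes x times
    IQR table, mean IQR across complexes per time, skipped complex names).
    """
    rows, skipped = {}, []
    for name, members in catalog.items():
        present = [m for m in members if m in fc.index]
        if len(present) < min_members:
            skipped.append(name)
            continue
        sub = fc.loc[present].to_numpy(dtype=float)
        q1, q3 = np.nanquantile(sub, [0.25, 0.75], axis=0, method=quantile_method)
        rows[name] = q3 - q1
    if not rows:
        raise ValueError(f"no complex has >= {min_members} members in the data; missing: {skipped}")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=fc.columns)
    table.index.name = "complex"
    return table, table.mean(axis=0).rename("mean_iqr"), skipped


def compare_populations(
    fc_a: pd.DataFrame,
    fc_b: pd.DataFrame,
    catalog: dict[str, list[str]],
    *,
    restrict_to_shared_genes: bool = True,
    min_members: int = 2,
) -> pd.DataFrame:
    """Paired stoichiometry-loss comparison on shared complexes.

    Used both for mother vs daughter populations and for proteome vs
    transcriptome; in the latter case the comparison is restricted to the
    genes quantified on both levels so complex membership is identical on
    the two sides.  Returns a table with the two mean-IQR trajectories and
    their difference (a - b).
    """
    if restrict_to_shared_genes:
        shared = fc_a.index.intersection(fc_b.index)
        fc_a, fc_b = fc_a.loc[shared], fc_b.loc[shared]
    tab_a, mean_a, _ = complex_trajectories(fc_a, catalog, min_members=min_members)
    tab_b, mean_b, _ = complex_trajectories(fc_b, catalog, min_members=min_members)
    common = tab_a.index.intersection(tab_b.index)
    mean_a = tab_a.loc[common].mean(axis=0)
    mean_b = tab_b.loc[common].mean(axis=0)
    return pd.DataFrame({"mean_iqr_a": mean_a, "mean_iqr_b": mean_b, "difference": mean_a - mean_b})
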