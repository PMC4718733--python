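"""Proteome-transcriptome coupling dynamics over the lifespan.

Four complementary views of how protein levels detach from their
transcripts with age: rank-correlation of each time point against the
young reference (divergence from the youthful state), correlation between
the proteome and transcriptome per time point (cross-level coupling), a
sign-based co-expression quadrant map of paired terminal fold changes, and
the relative protein overabundance (protein log2 FC minus transcript log2
FC).  A two-fold-change census tracks when genes first cross the change
threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

_METHODS = {
    "spearman": lambda a, b: stats.spearmanr(a, b).statistic,
    "pearson_raw": lambda a, b: stats.pearsonr(a, b).statistic,
    "pearson_log2": lambda a, b: stats.pearsonr(np.log2(a), np.log2(b)).statistic,
    "kendall": lambda a, b: stats.kendalltau(a, b).statistic,
}


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method not in _METHODS:
        raise ValueError(f"unknown correlation method: {method!r}")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    if method == "pearson_log2" and (np.any(a <= 0) or np.any(b <= 0)):
        return float("nan")
    return float(_METHODS[method](a, b))


def divergence_from_young(
    values: pd.DataFrame, reference_time_h: float, method: str = "spearman"
) -> pd.Series:
    """Correlation of each time point's abundance vector with the reference.

    A declining curve quantifies divergence of the aging population away
    from its young state.
    """
    times = np.asarray(values.columns, dtype=float)
    ref_idx = np.flatnonzero(np.isclose(times, reference_time_h))
    if len(ref_idx) == 0:
        raise ValueError(f"reference time {reference_time_h} not in table")
    clean = values.dropna()
    if len(clean) < 3:
        raise ValueError("need at least 3 shared genes")
    ref = clean.iloc[:, ref_idx[0]].to_numpy(dtype=float)
    out = pd.Series(
        [_corr(clean[c].to_numpy(dtype=float), ref, method) for c in clean.columns],
        index=values.columns,
        name=f"{method}_vs_reference",
    )
    return out


def crosslevel_correlation(
    proteome: pd.DataFrame,
    transcriptome: pd.DataFrame,
    methods: tuple[str, ...] = ("spearman", "pearson_raw", "pearson_log2", "kendall"),
) -> pd.DataFrame:
    """Proteome-transcriptome correlation per time point, over shared genes.

    One column per method; constant vectors yield NaN for that method at
    that time point.
    """
    shared = proteome.index.intersection(transcriptome.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between proteome and transcriptome")
    times = [c for c in proteome.columns if c in set(transcriptome.columns)]
    rows = {}
    for t in times:
        a = proteome.loc[shared, t].to_numpy(dtype=float)
        b = transcriptome.loc[shared, t].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        rows[t] = {m: _corr(a[ok], b[ok], m) for m in methods}
    return pd.DataFrame.from_dict(rows, orient="index")[list(methods)]


def quadrant_map(
    protein_fc: pd.Series, transcript_fc: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign genes to co-expression quadrants by fold-change signs.

    Q1: both log2 FCs positive (coupled, up).  Q3: both negative (coupled,
    down).  Q2: protein up, transcript down (protein overabundant,
    uncoupled).  Q4: protein down, transcript up.  Genes with an exactly
    zero FC land on an "axis" and are excluded from the quadrant fractions
    (their count is still reported).

    Returns (assignment table with columns protein_fc/transcript_fc/quadrant,
    per-quadrant fractions over Q1-Q4 plus the axis count).
    """
    shared = protein_fc.index.intersection(transcript_fc.index)
    p = protein_fc[shared].astype(float)
    t = transcript_fc[shared].astype(float)
    if not (np.isfinite(p).all() and np.isfinite(t).all()):
        raise ValueError("fold changes must be finite")
    quad = pd.Series("axis", index=shared, dtype=object)
    quad[(p > 0) & (t > 0)] = "Q1"
    quad[(p > 0) & (t < 0)] = "Q2"
    quad[(p < 0) & (t < 0)] = "Q3"
    quad[(p < 0) & (t > 0)] = "Q4"
    table = pd.DataFrame({"protein_fc": p, "transcript_fc": t, "quadrant": quad})
    non_axis = (quad != "axis").sum()
    fractions = pd.Series(
        {q: float((quad == q).sum() / non_axis) if non_axis else float("nan") for q in QUADRANTS}
    )
    fractions["axis_count"] = float((quad == "axis").sum())
    return table, fractions


def overabundance_series(
    protein_fc: pd.DataFrame, transcript_fc: pd.DataFrame
) -> dict[str, pd.DataFrame | pd.Series]:
    """Relative protein overabundance per gene and time.

    overabundance(g, t) = protein log2 FC(g, t) - transcript log2 FC(g, t).
    Quadrant sums group genes by their final-time quadrant assignment; the
    sum over quadrants equals the total at every time (axis genes are kept
    in their own group so nothing is lost).
    """
    shared = protein_fc.index.intersection(transcript_fc.index)
    times = [c for c in protein_fc.columns if c in set(transcript_fc.columns)]
    over = protein_fc.loc[shared, times] - transcript_fc.loc[shared, times]
    final = times[-1]
    assignment, _ = quadrant_map(protein_fc.loc[shared, final], transcript_fc.loc[shared, final])
    by_quadrant = over.groupby(assignment["quadrant"]).sum()
    return {
        "per_gene": over,
        "quadrant_sums": by_quadrant,
        "total": over.sum(axis=0),
        "final_quadrant": assignment["quadrant"],
    }


def foldchange_census(fc: pd.DataFrame, threshold: float = 2.0) -> dict:
    """Census of genes crossing the fold-change threshold per time point.

    A gene counts "up" at time t when its log2 FC vs the young reference is
    >= +log2(threshold) and "down" when <= -log2(threshold); it is "new" at
    the first time it crosses in that direction and "previously changed"
    afterwards.  The summary fraction is the share of final-time changers
    that had already crossed in the same direction at an earlier time
    (NaN when nothing changes at the final time).
    """
    log_thr = np.log2(threshold)
    up = fc >= log_thr
    down = fc <= -log_thr
    prior_up = up.shift(1, axis=1, fill_value=False).cumsum(axis=1) > 0
    prior_down = down.shift(1, axis=1, fill_value=False).cumsum(axis=1) > 0
    counts = pd.DataFrame(
        {
            "new_up": (up & ~prior_up).sum(axis=0),
            "new_down": (down & ~prior_down).sum(axis=0),
            "previously_up": (up & prior_up).sum(axis=0),
            "previously_down": (down & prior_down).sum(axis=0),
        }
    )
    counts["total"] = counts.sum(axis=1)
    final = fc.columns[-1]
    final_changers = int(up[final].sum() + down[final].sum())
    presaged = int((up[final] & prior_up[final]).sum() + (down[final] & prior_down[final]).sum())
    fraction = presaged / final_changers if final_changers else float("nan")
    return {
        "counts": counts,
        "final_changers": final_changers,
        "presaged": presaged,
        "fraction_presaged": fraction,
    }
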