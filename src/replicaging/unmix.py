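"""Mathematical un-mixing of mixed-cell abundance measurements.

Given, for each harvest time, the measured abundances of every gene in a
set of mixed-cell samples and the measured cell-type composition of each
sample, the pure per-cell-type abundances solve the square linear system

    W @ a_pure = a_mix

per gene, where the rows of W are the composition fractions of the mixed
samples.  Early time points without mortality use a 2x2 (mother, daughter)
system; later ones a 3x3 including dead cells.  Entries whose exact solve
is negative (physically impossible) are flagged unsolvable rather than
constrained; traces with at least ``min_solved`` solved time points keep
the gene and have unsolvable gaps linearly interpolated in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import CELL_TYPES, GroundTruth

#: W condition numbers above this make a time point unsolvable outright.
CONDITION_LIMIT = 1e8

STATUS_SOLVED = "solved"
STATUS_UNSOLVABLE = "unsolvable"
STATUS_INTERPOLATED = "interpolated"


class DimensionError(ValueError):
    """Raised when mix abundances and composition matrix do not align."""


@dataclass
class UnmixedSeries:
    """Pure-cell-type abundance trajectories for one cell type.

    ``values`` is genes x time points (NaN where no solution is available);
    ``status`` carries one of {"solved", "unsolvable", "interpolated"} per
    entry.
    """

    cell_type: str
    values: pd.DataFrame
    status: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    def solved_counts(self) -> pd.Series:
        return (self.status == STATUS_SOLVED).sum(axis=1)


def composition_matrix(composition_long: pd.DataFrame, time_h: float) -> pd.DataFrame:
    """Extract the mixes x cell-types matrix W for one time point.

    ``composition_long`` has columns time_h, mix, frac_mother,
    frac_daughter, frac_dead (the TSV schema).
    """
    sel = composition_long[np.isclose(composition_long["time_h"], time_h)]
    W = sel.set_index("mix")[["frac_mother", "frac_daughter", "frac_dead"]]
    W.columns = list(CELL_TYPES)
    return W


def unmix_timepoint(
    mix_abundances: pd.DataFrame, W: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Solve W @ a = a_mix per gene for one time point.

    Parameters
    ----------
    mix_abundances:
        Genes x mixes measured abundances; columns must match W's rows.
    W:
        Mixes x cell-types composition matrix (square).

    Returns
    -------
    (values, solvable):
        ``values`` is genes x cell types (the exact solve, including any
        negative components); ``solvable`` is a boolean mask, False where a
        component came out negative or W is ill-conditioned.
    """
    if W.shape[0] != W.shape[1]:
        raise DimensionError(f"W must be square, got {W.shape}")
    if list(mix_abundances.columns) != list(W.index):
        if set(mix_abundances.columns) != set(W.index):
            raise DimensionError("mix abundance columns do not match composition rows")
        mix_abundances = mix_abundances[list(W.index)]
    arr = mix_abundances.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise DimensionError("mix abundances must be finite and non-negative")

    Wm = W.to_numpy(dtype=float)
    if np.linalg.cond(Wm) > CONDITION_LIMIT:
        values = pd.DataFrame(np.nan, index=mix_abundances.index, columns=W.columns)
        solvable = pd.DataFrame(False, index=mix_abundances.index, columns=W.columns)
        return values, solvable

    sol = np.linalg.solve(Wm, arr.T).T
    values = pd.DataFrame(sol, index=mix_abundances.index, columns=W.columns)
    solvable = values >= 0
    return values, solvable


def unmix_series(
    table, composition_long: pd.DataFrame, cell_types: tuple[str, ...] = CELL_TYPES
) -> dict[str, UnmixedSeries]:
    """Un-mix an AbundanceTable across all its harvest times.

    At times where the dead fraction is ~0 in every mix, the redundant dead
    column would make the 3x3 system singular; such time points are solved
    as a 2x2 (mother, daughter) system using the first two mixes, and the
    dead trace is marked unsolvable there.
    """
    times = sorted(table.samples["time_h"].unique())
    genes = table.values.index
    values = {ct: pd.DataFrame(np.nan, index=genes, columns=times) for ct in cell_types}
    status = {ct: pd.DataFrame(STATUS_UNSOLVABLE, index=genes, columns=times) for ct in cell_types}
    for t in times:
        W = composition_matrix(composition_long, t)
        mix = table.for_time(t)
        use_types = list(cell_types)
        if "dead" in W.columns and W["dead"].abs().max() < 1e-9:
            use_types = [ct for ct in use_types if ct != "dead"]
            W = W.loc[W.index[: len(use_types)], use_types]
            W = W.div(W.sum(axis=1), axis=0)  # renormalize the 2x2 rows
            mix = mix[list(W.index)]
        vals, ok = unmix_timepoint(mix, W)
        for ct in use_types:
            values[ct][t] = vals[ct]
            status[ct].loc[ok[ct], t] = STATUS_SOLVED
    return {
        ct: UnmixedSeries(cell_type=ct, values=values[ct], status=status[ct]) for ct in cell_types
    }


def finalize_series(raw: UnmixedSeries, min_solved: int = 5) -> UnmixedSeries:
    """Apply the trace-quality rule and interpolate remaining gaps.

    Genes with fewer than ``min_solved`` solved time points are dropped.
    For retained genes, unsolvable entries are linearly interpolated in
    time from the neighboring solved values; gaps at the boundary take the
    nearest solved value (no extrapolation, which could go negative).
    """
    solved = raw.status == STATUS_SOLVED
    keep = solved.sum(axis=1) >= min_solved
    values = raw.values.loc[keep].copy()
    status = raw.status.loc[keep].copy()
    solved = solved.loc[keep]

    values[~solved] = np.nan
    times = raw.times
    filled = values.T
    filled.index = times
    filled = filled.interpolate(method="index", limit_direction="both").T
    filled.columns = raw.values.columns

    status = status.where(solved, STATUS_INTERPOLATED)
    out = UnmixedSeries(cell_type=raw.cell_type, values=filled, status=status)
    assert not (out.values < 0).any().any(), "negative abundance survived finalization"
    return out


def normalize_total(series: UnmixedSeries, total: float = 1e6) -> UnmixedSeries:
    """Scale each time-point column so its abundances sum to ``total``."""
    sums = series.values.sum(axis=0)
    if (sums <= 0).any():
        bad = [c for c, s in sums.items() if s <= 0]
        raise ZeroDivisionError(f"cannot normalize all-zero column(s): {bad}")
    scaled = series.values * (total / sums)
    return UnmixedSeries(cell_type=series.cell_type, values=scaled, status=series.status.copy())


def validate_unmixing(
    recovered: dict[str, pd.DataFrame] | dict[str, UnmixedSeries], truth: GroundTruth, level: str = "protein"
) -> dict:
    """Recovery accuracy of un-mixed profiles against ground truth.

    Returns per-gene mean relative error, the average relative error over
    all genes/cell types/times, and the per-cell-type Pearson correlation
    on the log2 scale.  Entries with zero true abundance are excluded and
    counted.
    """
    per_gene = {}
    corr = {}
    errs = []
    excluded = 0
    for ct, rec in recovered.items():
        rec_vals = rec.values if isinstance(rec, UnmixedSeries) else rec
        true_vals = getattr(truth, level)[ct]
        true_vals = true_vals.loc[rec_vals.index, rec_vals.columns]
        t = true_vals.to_numpy(dtype=float)
        r = rec_vals.to_numpy(dtype=float)
        mask = t > 0
        excluded += int((~mask).sum())
        rel = np.full_like(t, np.nan)
        rel[mask] = np.abs(r[mask] - t[mask]) / t[mask]
        per_gene[ct] = pd.Series(np.nanmean(rel, axis=1), index=rec_vals.index)
        errs.append(rel[np.isfinite(rel)])
        pos = mask & (r > 0)
        corr[ct] = float(np.corrcoef(np.log2(r[pos]), np.log2(t[pos]))[0, 1])
    all_errs = np.concatenate(errs)
    return {
        "per_gene_relative_error": per_gene,
        "average_relative_error": float(all_errs.mean()),
        "log2_correlation": corr,
        "n_excluded_zero_truth": excluded,
    }
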