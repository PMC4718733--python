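"""Bead-effect correction, reference standardization, replicate fusion and
reproducibility filtering.

Magnetic beads attached to mother cells cause reproducible, protein-specific
signal losses in bead-containing samples; a per-protein multiplicative
factor estimated from paired with/without-beads measurements removes the
artifact before un-mixing.  Downstream, trajectories are expressed as log2
fold changes against a young reference time point, the two replicate
campaigns are fused with locally weighted polynomial regression (LOWESS)
and resampled at the experimental harvest times, and only genes whose
replicate profiles agree (coefficient of variation below a cutoff) are
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class PipelineConfig:
    """Tunable parameters of the processing pipeline.

    loess_span:
        Fraction of points used in each local regression (default 0.75,
        the conventional span).
    cv_cutoff:
        Replicate coefficient-of-variation threshold; genes with CV below
        it (strictly) are retained.
    reference_time_h:
        The young reference time point (first harvest, 7.8 h by default);
        only data from this time onward enters downstream analyses.
    normalization_total:
        Column total after abundance normalization.
    fold_change_threshold:
        Linear fold-change threshold for the change census (2 = twofold).
    """

    loess_span: float = 0.75
    cv_cutoff: float = 0.3
    reference_time_h: float = 7.8
    normalization_total: float = 1e6
    fold_change_threshold: float = 2.0
    fit_log_space: bool = False
    drop_negative_fits: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must lie in (0, 1]")
        if self.cv_cutoff <= 0:
            raise ValueError("cv_cutoff must be positive")


# ---------------------------------------------------------------------------
# Bead correction
# ---------------------------------------------------------------------------


def bead_correction_factors(
    with_beads: pd.DataFrame, without_beads: pd.DataFrame
) -> tuple[pd.Series, pd.Index]:
    """Per-protein correction factor from paired with/without-beads samples.

    factor = mean(without-beads replicates) / mean(with-beads replicates).
    Proteins with a zero with-beads mean get no factor and are reported in
    the second return value.
    """
    if not with_beads.index.equals(without_beads.index):
        raise ValueError("with- and without-beads tables must share the same protein set")
    mean_with = with_beads.mean(axis=1)
    mean_without = without_beads.mean(axis=1)
    bad = mean_with[mean_with == 0].index
    factors = mean_without / mean_with.replace(0, np.nan)
    factors.name = "factor"
    return factors, bad


def apply_bead_correction(
    table: pd.DataFrame, factors: pd.Series, bead_samples: list[str] | None = None
) -> pd.DataFrame:
    """Multiply bead-containing sample columns by the per-protein factors.

    ``bead_samples`` defaults to every column.  Re-applying to an already
    corrected table is refused (the factor is not idempotent).
    """
    if table.attrs.get("bead_corrected"):
        raise ValueError("table is already bead-corrected; refusing to apply twice")
    out = table.copy()
    cols = list(table.columns) if bead_samples is None else list(bead_samples)
    fac = factors.reindex(table.index)
    for c in cols:
        out[c] = out[c] * fac
    out.attrs["bead_corrected"] = True
    return out


# ---------------------------------------------------------------------------
# Young-reference standardization
# ---------------------------------------------------------------------------


def standardize_reference(
    values: pd.DataFrame,
    reference_time_h: float,
    unprocessed: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Express trajectories as log2 fold changes against the young reference.

    Returns (fold-change table restricted to t >= reference, per-gene
    processing offset).  The offset, log2(reference / unprocessed), records
    how much the column-loading procedure itself shifted each gene; it is
    carried as metadata rather than applied, so recovery from the loading
    procedure is not mislabeled as aging.  Genes with a zero reference
    abundance are flagged (NaN fold changes).
    """
    times = np.asarray(values.columns, dtype=float)
    ref_idx = np.flatnonzero(np.isclose(times, reference_time_h))
    if len(ref_idx) == 0:
        raise ValueError(f"reference time {reference_time_h} not present in series")
    ref = values.iloc[:, ref_idx[0]]
    keep = times >= reference_time_h - 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(values.loc[:, values.columns[keep]].div(ref.replace(0, np.nan), axis=0))
    if unprocessed is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            offset = np.log2(ref.replace(0, np.nan) / unprocessed.replace(0, np.nan))
    else:
        offset = pd.Series(0.0, index=values.index)
    offset.name = "processing_offset_log2"
    fc.attrs["processing_offset_log2"] = offset
    return fc, offset


# ---------------------------------------------------------------------------
# Replicate fusion by local polynomial regression
# ---------------------------------------------------------------------------


def fit_profiles(
    replicate_series: list[pd.DataFrame],
    config: PipelineConfig | None = None,
    *,
    eval_times: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Index]:
    """Fuse replicate trajectories into one smooth curve per gene.

    All replicate points are pooled and fit with LOWESS (span from the
    config); the fit is evaluated at ``eval_times`` (default: the union of
    the replicates' time points).  Genes with fewer than 4 pooled finite
    points are dropped and reported.  Negative fitted values (possible for
    a local linear fit near zero) cause the gene to be dropped by default
    (``config.drop_negative_fits``); otherwise they are clamped to a small
    positive floor (1e-6 x the column median).

    Deterministic, and invariant to the order of the replicates.
    """
    config = config or PipelineConfig()
    genes = replicate_series[0].index
    for rep in replicate_series[1:]:
        genes = genes.intersection(rep.index)
    genes = genes.sort_values()
    if eval_times is None:
        eval_times = np.unique(
            np.concatenate([np.asarray(r.columns, dtype=float) for r in replicate_series])
        )
    eval_times = np.asarray(eval_times, dtype=float)

    x_all = np.concatenate([np.asarray(r.columns, dtype=float) for r in replicate_series])
    order = np.argsort(x_all, kind="stable")

    rows, unfittable = {}, []
    for g in genes:
        y_all = np.concatenate([r.loc[g].to_numpy(dtype=float) for r in replicate_series])
        x, y = x_all[order], y_all[order]
        ok = np.isfinite(y)
        if ok.sum() < 4:
            unfittable.append(g)
            continue
        yy = np.log2(np.maximum(y[ok], 1e-12)) if config.fit_log_space else y[ok]
        fit = lowess(yy, x[ok], frac=config.loess_span, xvals=eval_times)
        rows[g] = 2.0**fit if config.fit_log_space else fit

    fused = pd.DataFrame.from_dict(rows, orient="index", columns=eval_times)
    fused.index.name = genes.name
    if (fused < 0).any().any():
        neg_genes = fused.index[(fused < 0).any(axis=1)]
        if config.drop_negative_fits:
            fused = fused.drop(index=neg_genes)
            unfittable.extend(neg_genes)
        else:
            floor = 1e-6 * fused.median(axis=0)
            fused = fused.clip(lower=floor, axis=1)
    return fused, pd.Index(unfittable, name="unfittable")


# ---------------------------------------------------------------------------
# Reproducibility (CV) filter
# ---------------------------------------------------------------------------


def replicate_cv(replicate_series: list[pd.DataFrame]) -> pd.Series:
    """Per-gene replicate coefficient of variation over shared time points.

    At each shared time point the CV across replicates is the sample SD
    (n-1 denominator; for two replicates |a-b|/sqrt(2)) divided by the
    mean; the gene's CV is the mean of these over time.  Time points with a
    zero mean are excluded from that gene's average.
    """
    times = np.asarray(replicate_series[0].columns, dtype=float)
    shared = times
    for rep in replicate_series[1:]:
        shared = np.intersect1d(shared, np.asarray(rep.columns, dtype=float))
    genes = replicate_series[0].index
    for rep in replicate_series[1:]:
        genes = genes.intersection(rep.index)
    stack = np.stack(
        [r.loc[genes, shared].to_numpy(dtype=float) for r in replicate_series]
    )  # (n_reps, genes, times)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return pd.Series(np.nanmean(np.abs(cv), axis=1), index=genes, name="cv")


def cv_filter(
    replicate_series: list[pd.DataFrame], config: PipelineConfig | None = None
) -> tuple[pd.Index, pd.Series, float]:
    """Retain genes whose replicate CV is strictly below the cutoff.

    Returns (retained gene index, per-gene CV, retained fraction).
    """
    config = config or PipelineConfig()
    cv = replicate_cv(replicate_series)
    retained = cv.index[cv < config.cv_cutoff]
    return retained, cv, float(len(retained) / len(cv)) if len(cv) else float("nan")
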