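"""Synthetic replicative-aging cohorts and mixed-cell omics measurements.

This module generates everything the downstream pipeline needs, with known
ground truth: a dividing/dying cohort of bead-labeled mother cells, smooth
per-gene protein and transcript trajectories for the pure mother, daughter
and dead populations, and noisy mixed-cell measurements composed from those
pure profiles according to per-time-point composition matrices.

The emulated experiment: a starting cohort of mother cells is retained on a
magnetic column while daughters wash out; at each harvest time three mixed
samples with different mother/daughter/dead fractions are collected and
profiled (mass-spectrometry proteome, FPKM-like transcriptome) over 72 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("mother", "daughter", "dead")

#: Gene archetypes for the protein/transcript relationship at the end of the
#: lifespan.  "Coupled" genes change in the same direction on both levels;
#: "uncoupled_protein_up" is the Q2-type gene (protein up, transcript down),
#: "uncoupled_protein_down" the Q4-type (protein down, transcript up).
ARCHETYPES = (
    "coupled_up",
    "coupled_down",
    "uncoupled_protein_up",
    "uncoupled_protein_down",
    "flat",
)

#: Harvest times named after the experimental campaign the generator emulates.
NAMED_HARVEST_TIMES = (7.8, 10.7, 22.0, 26.8, 45.4, 53.0, 72.0)


class ParameterError(ValueError):
    """Raised when a simulation parameter violates its contract."""


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class DeathModel:
    """Logistic hazard on replicative age.

    Each cell draws a replicative-lifespan limit from a logistic distribution
    with location ``midpoint`` (divisions) and scale ``scale``; the cell dies
    once its division count reaches the limit and its count freezes there.
    Defaults put population viability at 72 h (at the default division rate
    of 0.5 h^-1) near the ~40-50% observed for column-aged cohorts.
    """

    midpoint: float = 34.0
    scale: float = 5.0


@dataclass
class CohortTrajectory:
    """Division-count and survival state of a founder cohort at query times."""

    times: np.ndarray  # (n_times,)
    division_counts: np.ndarray  # (n_times, n_cells) int
    alive: np.ndarray  # (n_times, n_cells) bool
    rates: np.ndarray  # (n_cells,) per-cell division rates, events/h

    def counts_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.division_counts[i]

    def viability(self) -> pd.Series:
        """Fraction of founders alive at each query time."""
        return pd.Series(self.alive.mean(axis=1), index=self.times, name="viability")

    def sd_of_counts(self) -> pd.Series:
        return pd.Series(self.division_counts.std(axis=1, ddof=1), index=self.times)


def simulate_cohort(
    n_cells: int,
    mean_rate: float,
    duration: float,
    seed: int,
    *,
    times: np.ndarray | None = None,
    rate_cv: float = 0.2,
    rate_model: str = "heterogeneous",
    death: DeathModel | None = None,
) -> CohortTrajectory:
    """Simulate a cohort of founder (mother) cells dividing over time.

    Each cell divides via a homogeneous Poisson process.  With
    ``rate_model="heterogeneous"`` (default) the per-cell rate is drawn from a
    gamma distribution with mean ``mean_rate`` and coefficient of variation
    ``rate_cv``, which reproduces the widening of the replicative-age
    distribution at later harvests; ``rate_model="shared"`` gives every cell
    the same rate (pure Poisson-process spread only).

    Parameters
    ----------
    n_cells:
        Founder cohort size (>= 1).
    mean_rate:
        Mean division rate in events per hour (> 0).
    duration:
        Total simulated time in hours (> 0).
    seed:
        Seed for the generator; results are reproducible bit-for-bit.
    times:
        Query times; defaults to an hourly grid over ``[0, duration]``.
    death:
        Optional :class:`DeathModel`; ``None`` disables mortality.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if mean_rate <= 0:
        raise ParameterError("mean_rate must be positive")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if rate_model not in ("heterogeneous", "shared"):
        raise ParameterError(f"unknown rate_model: {rate_model!r}")

    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(0.0, duration, max(int(round(duration)) + 1, 2))
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ParameterError("query times must be strictly increasing")

    if rate_model == "heterogeneous" and rate_cv > 0:
        shape = 1.0 / rate_cv**2
        rates = rng.gamma(shape, mean_rate / shape, size=n_cells)
    else:
        rates = np.full(n_cells, mean_rate)

    if death is not None:
        limits = rng.logistic(death.midpoint, death.scale, size=n_cells)
        limits = np.maximum(limits, 1.0)
    else:
        limits = np.full(n_cells, np.inf)

    counts = np.zeros((len(times), n_cells), dtype=np.int64)
    alive = np.ones((len(times), n_cells), dtype=bool)
    current = np.zeros(n_cells, dtype=np.int64)
    living = np.ones(n_cells, dtype=bool)
    prev_t = 0.0
    for i, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            inc = rng.poisson(rates * dt)
            current = current + np.where(living, inc, 0)
            died = living & (current >= limits)
            # a dying cell freezes at its lifespan limit
            current[died] = np.ceil(limits[died]).astype(np.int64)
            living = living & ~died
        counts[i] = current
        alive[i] = living
        prev_t = t
    return CohortTrajectory(times=times, division_counts=counts, alive=alive, rates=rates)


def harvest_schedule(t_start: float, t_end: float, n_points: int, mode: str = "exponential") -> np.ndarray:
    """Harvest times from ``t_start`` to ``t_end`` inclusive.

    ``exponential`` returns a geometric progression (denser early, sparser
    late, matching the widening age distribution), ``linear`` an arithmetic
    one.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    if not (t_end > t_start > 0):
        raise ParameterError("need t_end > t_start > 0")
    if mode == "exponential":
        return np.geomspace(t_start, t_end, n_points)
    if mode == "linear":
        return np.linspace(t_start, t_end, n_points)
    raise ParameterError(f"unknown mode: {mode!r}")


DEFAULT_HARVEST_TIMES = harvest_schedule(7.8, 72.0, 12, "exponential")


# ---------------------------------------------------------------------------
# Ground-truth molecular trajectories
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Known pure-population trajectories and planted structure.

    ``protein`` and ``transcript`` map each cell type to a genes x times
    abundance table (strictly positive).  ``archetype`` labels each gene by
    the signs of its terminal log2 fold changes.  ``bead_loss`` holds the
    multiplicative per-protein loss factor applied to bead-containing
    samples.  ``complexes`` maps complex names to member gene lists;
    ``complex_kind`` marks each as "coordinated" (identical member slopes)
    or "drifting" (heterogeneous slopes).
    """

    times: np.ndarray
    genes: pd.Index
    protein: dict[str, pd.DataFrame]
    transcript: dict[str, pd.DataFrame]
    archetype: pd.Series
    bead_loss: pd.Series
    protein_slopes: pd.Series
    transcript_slopes: pd.Series
    complexes: dict[str, list[str]] = field(default_factory=dict)
    complex_kind: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def log2_fc(self, level: str, cell_type: str) -> pd.DataFrame:
        """Planted log2 fold changes vs the first time point."""
        tab = getattr(self, level)[cell_type]
        return np.log2(tab.div(tab.iloc[:, 0], axis=0))


def _archetype_from_signs(p: float, t: float) -> str:
    if p > 0 and t > 0:
        return "coupled_up"
    if p < 0 and t < 0:
        return "coupled_down"
    if p > 0 and t < 0:
        return "uncoupled_protein_up"
    if p < 0 and t > 0:
        return "uncoupled_protein_down"
    return "flat"


def generate_molecular_truth(
    n_genes: int,
    archetype_fractions,
    n_complexes: int = 0,
    complex_size_range: tuple[int, int] = (4, 8),
    seed: int = 0,
    *,
    times: np.ndarray | None = None,
    slope_range: tuple[float, float] = (0.5, 2.5),
    daughter_attenuation: float = 0.5,
    coordinated_fraction: float = 0.5,
    bead_loss_range: tuple[float, float] = (0.5, 1.0),
    baseline_log_correlation: float = 0.78,
) -> GroundTruth:
    """Plant per-gene protein/transcript trajectories for the three cell types.

    Mother trajectories are linear in log2 space: ``log2 FC(t) = s * u(t)``
    with ``u`` the time normalized to [0, 1] and ``s`` the terminal log2
    fold change, its sign fixed by the gene's archetype and its magnitude
    drawn uniformly from ``slope_range``.  Daughter trajectories are
    attenuated copies of the mother trends (partial rejuvenation); dead
    cells carry a fixed, time-independent signature distinct from both.

    ``archetype_fractions`` may be a mapping ``{archetype: fraction}`` or a
    sequence ordered as :data:`ARCHETYPES`; fractions must sum to 1.
    Complexes override their members' protein slopes: "coordinated"
    complexes share a single slope, "drifting" complexes get a heterogeneous
    fan of slopes so their internal stoichiometry degrades linearly in time.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if isinstance(archetype_fractions, dict):
        fracs = np.array([archetype_fractions.get(a, 0.0) for a in ARCHETYPES], dtype=float)
    else:
        fracs = np.asarray(archetype_fractions, dtype=float)
        if fracs.shape != (len(ARCHETYPES),):
            raise ParameterError(f"archetype_fractions must have length {len(ARCHETYPES)}")
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ParameterError("archetype fractions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    if times is None:
        times = DEFAULT_HARVEST_TIMES
    times = np.asarray(times, dtype=float)
    u = (times - times[0]) / (times[-1] - times[0])
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")

    # deterministic archetype counts: largest-remainder apportionment
    counts = np.floor(fracs * n_genes).astype(int)
    rem = n_genes - counts.sum()
    order = np.argsort(-(fracs * n_genes - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.array(ARCHETYPES, dtype=object), counts)
    rng.shuffle(labels)
    archetype = pd.Series(labels, index=genes, name="archetype")

    mag_p = rng.uniform(*slope_range, size=n_genes)
    mag_t = rng.uniform(*slope_range, size=n_genes)
    sign_p = pd.Series(0.0, index=genes)
    sign_t = pd.Series(0.0, index=genes)
    sign_p[archetype.isin(["coupled_up", "uncoupled_protein_up"])] = 1.0
    sign_p[archetype.isin(["coupled_down", "uncoupled_protein_down"])] = -1.0
    sign_t[archetype.isin(["coupled_up", "uncoupled_protein_down"])] = 1.0
    sign_t[archetype.isin(["coupled_down", "uncoupled_protein_up"])] = -1.0
    p_slope = pd.Series(sign_p.to_numpy() * mag_p, index=genes)
    t_slope = pd.Series(sign_t.to_numpy() * mag_t, index=genes)

    # complexes: disjoint member sets with overridden protein slopes
    complexes: dict[str, list[str]] = {}
    complex_kind: dict[str, str] = {}
    lo, hi = complex_size_range
    if n_complexes > 0:
        pool = list(genes)
        rng.shuffle(pool)
        cursor = 0
        for ci in range(n_complexes):
            size = int(rng.integers(lo, hi + 1))
            members = pool[cursor : cursor + size]
            cursor += size
            if len(members) < 2:
                break
            name = f"cpx{ci:03d}"
            kind = "coordinated" if ci < round(coordinated_fraction * n_complexes) else "drifting"
            complexes[name] = members
            complex_kind[name] = kind
            if kind == "coordinated":
                s = rng.uniform(*slope_range)
                p_slope[members] = s
            else:
                p_slope[members] = np.linspace(0.2, 1.8, len(members))
            t_slope[members] = 0.5 * np.abs(p_slope[members])
        # relabel overridden genes so archetypes stay consistent with signs
        touched = [g for mem in complexes.values() for g in mem]
        for g in touched:
            archetype[g] = _archetype_from_signs(p_slope[g], t_slope[g])

    # protein and transcript baselines share the gene-abundance hierarchy:
    # rank correlation ~0.75 at the young reference, as observed for
    # single-study proteome/transcriptome comparisons
    rho = baseline_log_correlation
    z = rng.normal(size=n_genes)
    w = rng.normal(size=n_genes)
    base_p = 10 ** (3.0 + 0.6 * z)
    base_t = 10 ** (2.0 + 0.6 * (rho * z + np.sqrt(1 - rho**2) * w))
    dead_sig = rng.normal(0.0, 1.0, size=n_genes)

    def _tables(base, slope):
        fc_m = np.outer(slope, u)  # log2 FC, mother
        mother = pd.DataFrame(base[:, None] * 2.0**fc_m, index=genes, columns=times)
        daughter = pd.DataFrame(
            base[:, None] * 2.0 ** (daughter_attenuation * fc_m), index=genes, columns=times
        )
        dead = pd.DataFrame(
            np.tile((base * 2.0**dead_sig)[:, None], (1, len(times))), index=genes, columns=times
        )
        return {"mother": mother, "daughter": daughter, "dead": dead}

    protein = _tables(base_p, p_slope.to_numpy())
    transcript = _tables(base_t, t_slope.to_numpy())
    bead_loss = pd.Series(rng.uniform(*bead_loss_range, size=n_genes), index=genes, name="bead_loss")

    return GroundTruth(
        times=times,
        genes=genes,
        protein=protein,
        transcript=transcript,
        archetype=archetype,
        bead_loss=bead_loss,
        protein_slopes=p_slope,
        transcript_slopes=t_slope,
        complexes=complexes,
        complex_kind=complex_kind,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mixed-sample composition
# ---------------------------------------------------------------------------


@dataclass
class MixDesign:
    """Target mixed-sample compositions and measurement-noise settings.

    ``compositions`` maps each harvest time to a mixes x cell-types
    DataFrame whose rows lie on the simplex.  ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal measurement
    noise; ``composition_concentration`` controls the Dirichlet perturbation
    of the measured (vs true) compositions (``None`` = compositions measured
    exactly).  ``has_beads`` flags which mixes contain magnetic beads and
    therefore suffer the per-protein bead losses.
    """

    compositions: dict[float, pd.DataFrame]
    noise_cv: float = 0.10
    composition_concentration: float | None = None
    seed: int = 0
    has_beads: dict[str, bool] = field(default_factory=lambda: {"mix1": True, "mix2": True, "mix3": False})

    def __post_init__(self):
        for t, W in self.compositions.items():
            arr = W.to_numpy(dtype=float)
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ParameterError(f"composition entries at t={t} outside [0, 1]")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
                raise ParameterError(f"composition rows at t={t} must sum to 1")


def default_mix_design(
    times: np.ndarray | None = None,
    noise_cv: float = 0.10,
    composition_concentration: float | None = None,
    seed: int = 0,
    *,
    max_dead_fraction: float = 0.30,
) -> MixDesign:
    """Compositions emulating the harvested mixed-cell samples.

    Mix 2 (mother-enriched wash retentate) runs 80-99% mothers, mix 3 (the
    column effluent) is dominated by daughters, and mix 1 (the wash) is
    intermediate.  The dead fraction rises with time toward
    ``max_dead_fraction``, split between the bead-carrying mixes.
    """
    if times is None:
        times = DEFAULT_HARVEST_TIMES
    times = np.asarray(times, dtype=float)
    u = (times - times[0]) / (times[-1] - times[0])
    comps: dict[float, pd.DataFrame] = {}
    for ui, t in zip(u, times):
        dead = max_dead_fraction * ui
        m2_mother = 0.99 - 0.15 * ui  # 0.99 young -> 0.84 old, within 80-99%
        rows = np.array(
            [
                [0.45 - 0.1 * ui, 1.0 - (0.45 - 0.1 * ui) - 0.8 * dead, 0.8 * dead],
                [m2_mother, 1.0 - m2_mother - 0.5 * dead, 0.5 * dead],
                [0.08, 0.92 - 0.3 * dead, 0.3 * dead],
            ]
        )
        comps[float(t)] = pd.DataFrame(
            rows, index=["mix1", "mix2", "mix3"], columns=list(CELL_TYPES)
        )
    return MixDesign(
        compositions=comps,
        noise_cv=noise_cv,
        composition_concentration=composition_concentration,
        seed=seed,
    )


#: Mixing proportions for the three-population validation experiment, in
#: which pure cultures from three distinct growth phases are combined in
#: known ratios with each phase dominant in one mixed sample.  Enriched
#: mixes keep the system well conditioned, which is what allows accurate
#: recovery of all three populations.
VALIDATION_WEIGHTS = np.array(
    [
        [0.70, 0.20, 0.10],
        [0.15, 0.70, 0.15],
        [0.10, 0.20, 0.70],
    ]
)


def validation_pure_profiles(n_genes: int = 1000, seed: int = 42) -> pd.DataFrame:
    """Three pure population profiles for the un-mixing validation.

    Gene baselines are lognormal over genes; each population carries its own
    moderate lognormal signature on top (distinct growth phases of the same
    organism share most of their expression program).  Columns are the three
    populations.
    """
    rng = np.random.default_rng(seed)
    base = 10 ** rng.normal(3.0, 0.6, size=n_genes)
    sig = 2.0 ** rng.normal(0.0, 0.5, size=(n_genes, 3))
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")
    return pd.DataFrame(base[:, None] * sig, index=genes, columns=["pop1", "pop2", "pop3"])


@dataclass
class AbundanceTable:
    """Genes x samples abundance matrix with per-sample metadata.

    ``samples`` columns: sample_id, time_h, replicate, mix, has_beads,
    molecule_kind.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def for_time(self, time_h: float) -> pd.DataFrame:
        """Genes x mixes sub-table for one harvest time."""
        sel = self.samples[np.isclose(self.samples["time_h"], time_h)]
        sub = self.values[sel["sample_id"]]
        sub.columns = sel["mix"].to_numpy()
        return sub


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape))


def compose_mixed_samples(
    truth: GroundTruth,
    design: MixDesign,
    *,
    replicate: str = "R1",
    apply_bead_loss: bool = True,
) -> tuple[AbundanceTable, AbundanceTable, pd.DataFrame]:
    """Form noisy mixed-cell measurements from pure ground-truth profiles.

    Each measured mix abundance is the composition-weighted sum of the pure
    cell-type abundances, multiplied by unit-mean lognormal noise with the
    design's CV; protein channels of bead-containing mixes are additionally
    multiplied by the per-protein bead-loss factors.  Measured compositions
    are Dirichlet perturbations of the truth (re-normalized to the simplex),
    or exact when the design's concentration is ``None``.

    Returns (protein table, transcript table, measured compositions) with
    the compositions in long form: time_h, mix, frac_mother, frac_daughter,
    frac_dead.
    """
    rng = np.random.default_rng(design.seed)
    times = sorted(design.compositions)
    missing = [t for t in times if not np.any(np.isclose(truth.times, t))]
    if missing:
        raise ParameterError(f"truth does not cover harvest times: {missing}")

    prot_cols, trans_cols, meta_rows, comp_rows = {}, {}, [], []
    for t in times:
        W = design.compositions[t]
        pure_p = np.column_stack([truth.protein[ct][t].to_numpy() for ct in W.columns])
        pure_t = np.column_stack([truth.transcript[ct][t].to_numpy() for ct in W.columns])
        for mix in W.index:
            w = W.loc[mix].to_numpy()
            sid = f"{replicate}_t{t:05.1f}_{mix}"
            beads = design.has_beads.get(mix, False)
            p = pure_p @ w
            if apply_bead_loss and beads:
                p = p * truth.bead_loss.to_numpy()
            p = p * _lognormal_noise(rng, design.noise_cv, p.shape)
            q = (pure_t @ w) * _lognormal_noise(rng, design.noise_cv, pure_t.shape[0])
            prot_cols[sid] = p
            trans_cols[sid] = q
            meta_rows.append(
                dict(sample_id=sid, time_h=t, replicate=replicate, mix=mix, has_beads=beads)
            )
            if design.composition_concentration is None:
                w_meas = w
            else:
                alpha = np.maximum(design.composition_concentration * w, 1e-6)
                w_meas = rng.dirichlet(alpha)
            comp_rows.append(
                dict(
                    time_h=t,
                    mix=mix,
                    frac_mother=w_meas[0],
                    frac_daughter=w_meas[1],
                    frac_dead=w_meas[2],
                )
            )

    meta = pd.DataFrame(meta_rows)
    prot = AbundanceTable(
        values=pd.DataFrame(prot_cols, index=truth.genes),
        samples=meta.assign(molecule_kind="protein"),
    )
    trans = AbundanceTable(
        values=pd.DataFrame(trans_cols, index=truth.genes),
        samples=meta.assign(molecule_kind="transcript"),
    )
    return prot, trans, pd.DataFrame(comp_rows)


def weighted_viability(viability_per_mix, cell_counts_per_mix) -> float:
    """Population viability as the cell-count-weighted mean over mixes.

    Mirrors the lifespan-curve construction where per-mix viabilities are
    weighted by the number of cells present in each harvested sample.
    """
    v = np.asarray(viability_per_mix, dtype=float)
    c = np.asarray(cell_counts_per_mix, dtype=float)
    if v.shape != c.shape:
        raise ParameterError("viability and count lists must have equal length")
    if np.any((v < 0) | (v > 1)):
        raise ParameterError("viabilities must lie in [0, 1]")
    if np.any(c < 0):
        raise ParameterError("cell counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ZeroDivisionError("all-zero cell counts: weighted viability undefined")
    return float((v * c).sum() / total)


# ---------------------------------------------------------------------------
# Driver/responder profiles for network inference
# ---------------------------------------------------------------------------


def generate_driver_responder(
    n_drivers: int = 50,
    n_responders: int = 150,
    times: np.ndarray | None = None,
    *,
    n_parents: int = 2,
    lag: float = 0.21,
    lengthscale: float = 0.25,
    noise_fraction: float = 0.15,
    n_replicates: int = 2,
    measurement_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Profiles with planted causal structure for the directional network.

    Drivers are independent smooth curves drawn from a Gaussian process
    with squared-exponential temporal covariance (``lengthscale`` as a
    fraction of the time range).  Each responder is a sparse linear map of
    ``n_parents`` drivers evaluated with a transmission delay of ``lag``
    (fraction of the time range), plus independent Gaussian noise carrying
    ``noise_fraction`` of its variance.  The delay is what makes the
    planted causality detectable by the orientation statistic: a
    responder is well explained by profiles that share its (delayed)
    inputs, while no profile in the system carries a driver's un-delayed
    trajectory, so drivers retain high standardized partial variance.
    The experiment's replicate structure is emulated by concatenating
    ``n_replicates`` measurement series (shared biology, independent
    measurement noise of SD ``measurement_sd``), matching how the
    replicate datasets jointly feed the network stage.

    Returns (profiles genes x samples, role labels in {"driver",
    "responder"}, parent map responder -> list of driver names).
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = DEFAULT_HARVEST_TIMES
    times = np.asarray(times, dtype=float)
    span = times[-1] - times[0]
    u = (times - times[0]) / span
    n_t = len(times)

    # joint kernel over current and lagged grids, so d(t) and d(t - lag)
    # are evaluations of one consistent process
    uu = np.concatenate([u, u - lag])
    d2 = (uu[:, None] - uu[None, :]) ** 2
    K = np.exp(-0.5 * d2 / lengthscale**2) + 1e-8 * np.eye(2 * n_t)
    L = np.linalg.cholesky(K)
    g = rng.normal(size=(n_drivers, 2 * n_t)) @ L.T
    drivers, drivers_lag = g[:, :n_t], g[:, n_t:]
    drivers = drivers / drivers.std(axis=1, ddof=1, keepdims=True)
    drivers_lag = drivers_lag / drivers_lag.std(axis=1, ddof=1, keepdims=True)

    parents = np.stack(
        [rng.choice(n_drivers, size=n_parents, replace=False) for _ in range(n_responders)]
    )
    weights = np.abs(rng.normal(1.0, 0.15, size=(n_responders, n_parents)))
    signal = np.einsum("rp,rpt->rt", weights, drivers_lag[parents])
    signal = signal / signal.std(axis=1, ddof=1, keepdims=True)
    responders = (
        np.sqrt(1 - noise_fraction) * signal
        + np.sqrt(noise_fraction) * rng.normal(size=(n_responders, n_t))
    )

    underlying = np.vstack([drivers, responders])
    series = [
        underlying
        + (rng.normal(0.0, measurement_sd, size=underlying.shape) if measurement_sd > 0 else 0.0)
        for _ in range(n_replicates)
    ]
    X = np.hstack(series)
    cols = [f"R{r + 1}_t{t:05.1f}" for r in range(n_replicates) for t in times]

    names = [f"drv{i:04d}" for i in range(n_drivers)] + [f"rsp{i:04d}" for i in range(n_responders)]
    profiles = pd.DataFrame(X, index=pd.Index(names, name="gene"), columns=cols)
    labels = pd.Series(
        ["driver"] * n_drivers + ["responder"] * n_responders, index=profiles.index, name="role"
    )
    parent_map = {names[n_drivers + j]: [names[p] for p in ps] for j, ps in enumerate(parents)}
    return profiles, labels, parent_map
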