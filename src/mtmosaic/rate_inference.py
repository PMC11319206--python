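"""MSE-rejection inference of mtDNA turnover and mutation rates.

Turnover rate: for each fertilized-egg variant (caVAF > 0.005), forward
drift simulations are run at the donor's copy number ``n`` from the caVAF,
over a grid of candidate total turnover counts ``g``.  Each candidate is
resampled at the donor's clone count to mimic sequencing, summarized into
25 statistics (20 clone-VAF bin counts from 0.5-5% to 95-100%, mean, SD,
and wild-type/heteroplasmic/homoplasmic proportions at the 5%/90% cuts),
and scored by mean squared error against the observed statistics.  The
turnover rate is g / age averaged over the lowest-MSE draws.

Mutation rate: with ``g`` fixed from the tissue turnover rate x age,
log10(r) is drawn uniformly on (-9, -3); each draw runs a mutation
accumulation simulation, is resampled at the clone count and summarized
into 22 statistics (20 bins of the per-cell maximum clone-VAF plus counts
of cells with two and with three homoplasmic mutations, clone-VAF > 90%).

MSE is computed on standardized statistics by default (counts as
proportions, each statistic divided by its standard deviation across all
candidate draws); a raw mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drift_sim
from .drift_sim import (
    RCRS_LENGTH,
    as_rng,
    mitotic_turnover_counts,
    homeostatic_turnover_counts,
    simulate_mutation_counts_independent,
)

DETECTION_FLOOR = 0.005
WT_CUT = 0.05
HOM_CUT = 0.90
#: 20 clone-VAF bins, right-inclusive: [0.5%, 5%], (5%, 10%], ..., (95%, 100%]
BIN_UPPER = np.arange(1, 21) * 0.05
LOG10_R_RANGE = (-9.0, -3.0)


def _bin_counts(vafs: np.ndarray) -> np.ndarray:
    """Counts per clone-VAF bin; values below the detection floor are not
    binned (they enter the wild-type proportion only)."""
    v = vafs[vafs >= DETECTION_FLOOR]
    idx = np.clip(np.searchsorted(BIN_UPPER, v, side="left"), 0, 19)
    return np.bincount(idx, minlength=20).astype(float)


def hetfe_summary_stats(clone_vafs) -> np.ndarray:
    """The 25 summary statistics of a clone-VAF sample.

    VAFs below the 0.5% detection floor contribute to the wild-type
    proportion only, never to a bin.
    """
    vafs = np.sort(np.asarray(clone_vafs, dtype=float))  # permutation-exact
    if vafs.size == 0:
        raise ValueError("summary statistics need at least one clone")
    bins = _bin_counts(vafs)
    wt = float(np.mean(vafs < WT_CUT))
    het = float(np.mean((vafs >= WT_CUT) & (vafs <= HOM_CUT)))
    hom = float(np.mean(vafs > HOM_CUT))
    return np.concatenate([bins,
                           [vafs.mean(), vafs.std(ddof=0), wt, het, hom]])


def pz_summary_stats(per_clone_vafs) -> np.ndarray:
    """The 22 summary statistics of per-clone postzygotic VAF ledgers.

    ``per_clone_vafs`` is a sequence of per-clone VAF arrays.  The per-cell
    maximum clone-VAF is binned like the fertilized-egg statistics; the two
    trailing statistics count cells carrying exactly two and exactly three
    homoplasmic (clone-VAF > 90%) mutations.
    """
    max_vafs = []
    n_hom = []
    for vafs in per_clone_vafs:
        vafs = np.asarray(vafs, dtype=float)
        max_vafs.append(vafs.max() if vafs.size else 0.0)
        n_hom.append(int((vafs > HOM_CUT).sum()))
    max_vafs = np.asarray(max_vafs)
    n_hom = np.asarray(n_hom)
    bins = _bin_counts(max_vafs)
    return np.concatenate([bins,
                           [float((n_hom == 2).sum()),
                            float((n_hom == 3).sum())]])


def _mse_matrix(sim_stats: np.ndarray, observed: np.ndarray,
                normalize: str, n_count_stats: int,
                sample_size: int) -> np.ndarray:
    """Row-wise MSE of simulated statistics against the observed vector."""
    sim = sim_stats.astype(float).copy()
    obs = observed.astype(float).copy()
    if normalize == "standardize":
        sim[:, :n_count_stats] /= sample_size
        obs = obs.copy()
        obs[:n_count_stats] /= sample_size
        sd = sim.std(axis=0, ddof=0)
        weight = np.where(sd > 0, 1.0 / sd, 0.0)
        diff = (sim - obs) * weight
    elif normalize == "raw":
        diff = sim - obs
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return np.mean(diff ** 2, axis=1)


@dataclass
class InferenceResult:
    """Candidate draws with their MSEs plus the retained-draw estimate."""

    draws: pd.DataFrame
    estimate: float
    estimate_range: tuple[float, float]
    keep: int
    detail: dict = field(default_factory=dict)


def infer_turnover_rate(
    observed_vafs,
    n: int,
    age: float,
    model: str = "mitotic",
    grid=None,
    n_cells: int = 3_000,
    resamples: int = 100,
    keep: int = 50,
    rng=None,
    normalize: str = "standardize",
) -> InferenceResult:
    """Infer total turnover count (and per-year rate) for one variant.

    A single cell population is simulated forward and snapshotted at every
    candidate ``g`` of the grid (the process is Markovian, so snapshots of
    one trajectory are distributed as independent runs of each candidate);
    each snapshot is resampled ``resamples`` times at the observed clone
    count.  The estimate is the mean g (and g/age) over the ``keep``
    lowest-MSE draws.
    """
    rng = as_rng(rng)
    observed_vafs = np.asarray(observed_vafs, dtype=float)
    n_clones = observed_vafs.size
    if n_clones == 0:
        raise ValueError("no observed clones")
    p0 = float(observed_vafs.mean())  # caVAF proxy for the egg frequency
    if grid is None:
        grid = np.arange(0, 5_001, 50)
    grid = np.asarray(sorted(set(int(g) for g in grid)))
    observed_stats = hetfe_summary_stats(observed_vafs)

    k = np.full(n_cells, int(round(p0 * n)), dtype=np.int64)
    snapshots = {}
    current = 0
    for g in grid:
        for _ in range(g - current):
            if model == "mitotic":
                k = mitotic_turnover_counts(k, n, rng)
            else:
                k = homeostatic_turnover_counts(k, n, rng)
        current = g
        snapshots[g] = k / n

    rows = []
    stats_rows = []
    for g in grid:
        freqs = snapshots[g]
        for rep in range(resamples):
            sample = rng.choice(freqs, size=n_clones, replace=False)
            stats_rows.append(hetfe_summary_stats(sample))
            rows.append((g, rep))
    sim_stats = np.vstack(stats_rows)
    mse = _mse_matrix(sim_stats, observed_stats, normalize,
                      n_count_stats=20, sample_size=n_clones)
    draws = pd.DataFrame(rows, columns=["g", "resample"])
    draws["mse"] = mse
    draws = draws.sort_values("mse", kind="stable").reset_index(drop=True)

    kept = draws.head(keep)
    g_hat = float(kept["g"].mean())
    g_range = (float(kept["g"].min()), float(kept["g"].max()))
    if age > 0:
        rate = g_hat / age
        rate_range = (g_range[0] / age, g_range[1] / age)
    else:
        rate, rate_range = float("nan"), (float("nan"), float("nan"))
    return InferenceResult(
        draws=draws, estimate=rate, estimate_range=rate_range, keep=keep,
        detail={"g_hat": g_hat, "g_range": g_range, "p0": p0, "n": n,
                "age": age, "model": model, "n_clones": n_clones},
    )


def infer_mutation_rate(
    observed_pz_vafs,
    n: int,
    g: int,
    model: str = "mitotic",
    draws: int = 1_000,
    n_cells: int = 500,
    resamples: int = 10,
    keep: int = 50,
    rng=None,
    normalize: str = "standardize",
    event_budget: float = 3e5,
) -> InferenceResult:
    """Infer the per-bp-per-replication mutation rate for one donor.

    ``observed_pz_vafs`` is the per-clone list of postzygotic VAF arrays.
    Each draw samples log10(r) uniformly on (-9, -3), runs a mutation
    accumulation simulation over ``g`` turnovers at copy number ``n`` and
    is resampled ``resamples`` times at the observed clone count.  The
    estimate is 10**mean(log10 r) over the ``keep`` lowest-MSE draws.

    Draws with a very high expected mutation load are simulated with fewer
    cells (an explicit event budget) — their statistics sit far from any
    low-rate observation, so ranking precision is not limiting there.
    """
    if model != "mitotic":
        raise NotImplementedError(
            "the fast independent-lineage engine backs mitotic inference; "
            "run the genotype engine directly for homeostatic studies"
        )
    rng = as_rng(rng)
    per_clone = [np.asarray(v, dtype=float) for v in observed_pz_vafs]
    n_clones = len(per_clone)
    if n_clones == 0:
        raise ValueError("no observed clones")
    if g <= 0:
        raise ValueError("g must be positive (donor age or rate was 0)")
    observed_stats = pz_summary_stats(per_clone)

    lo, hi = LOG10_R_RANGE
    log_r = rng.uniform(lo, hi, size=draws)
    rows = []
    stats_rows = []
    for d, lr in enumerate(log_r):
        lam = (10.0 ** lr) * RCRS_LENGTH
        births_per_cell = lam * n * g
        cells = n_cells
        if births_per_cell > 0:
            cells = int(min(n_cells,
                            max(event_budget / max(births_per_cell, 1), 2)))
        result = simulate_mutation_counts_independent(
            n, g, lam, cells, rng=rng
        )
        freqs = result["frequencies"]
        floor = [f[f >= DETECTION_FLOOR] for f in freqs]
        for rep in range(resamples):
            idx = rng.choice(cells, size=n_clones,
                             replace=n_clones > cells)
            stats_rows.append(pz_summary_stats([floor[i] for i in idx]))
            rows.append((d, lr, rep, cells))
    sim_stats = np.vstack(stats_rows)
    mse = _mse_matrix(sim_stats, observed_stats, normalize,
                      n_count_stats=22, sample_size=n_clones)
    table = pd.DataFrame(rows, columns=["draw", "log10_r", "resample",
                                        "n_cells"])
    table["mse"] = mse
    table = table.sort_values("mse", kind="stable").reset_index(drop=True)

    kept = table.head(keep)
    log_r_hat = float(kept["log10_r"].mean())
    r_hat = 10.0 ** log_r_hat
    r_range = (10.0 ** float(kept["log10_r"].min()),
               10.0 ** float(kept["log10_r"].max()))
    return InferenceResult(
        draws=table, estimate=r_hat, estimate_range=r_range, keep=keep,
        detail={"log10_r_hat": log_r_hat, "n": n, "g": g, "model": model,
                "n_clones": n_clones},
    )


def aggregate_estimates(estimates) -> dict:
    """Mean and normal-approximation 95% CI across variant- or donor-level
    point estimates (one tissue)."""
    values = np.asarray([e for e in estimates if np.isfinite(e)], dtype=float)
    if values.size == 0:
        return {"mean": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "n": 0}
    mean = float(values.mean())
    if values.size > 1:
        se = float(values.std(ddof=1) / np.sqrt(values.size))
    else:
        se = 0.0
    return {"mean": mean, "ci_low": mean - 1.96 * se,
            "ci_high": mean + 1.96 * se, "n": int(values.size)}


def expected_mutations_per_division(r: float, L: int = RCRS_LENGTH,
                                    n: int = 750) -> float:
    """Expected de novo mutations per daughter cell per division, r*L*n/2.

    A division replicates n molecules (each drawing Poisson(r*L) mutations)
    and each daughter keeps half of the doubled pool.
    """
    if r < 0 or L <= 0 or n <= 0:
        raise ValueError("r must be >= 0 and L, n positive")
    return r * L * n / 2.0
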