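"""Forward drift simulation: urn dynamics, oracles, mutation engines."""

import numpy as np
import pytest
from scipy import stats

from mtmosaic.drift_sim import (
    SimulationConfig,
    _dirichlet_multinomial_rows,
    _homeostatic_events_rows,
    _mvh_rows,
    homeostatic_turnover_counts,
    homoplasmic_fraction_trajectory,
    lineage_fixation_profile,
    mitotic_turnover_counts,
    oracle_homeostatic_event,
    oracle_homeostatic_turnover,
    oracle_mitotic_turnover,
    simulate_drift,
    simulate_mutation_accumulation,
    simulate_mutation_counts_independent,
    turnovers_to_fixation,
)


# ---------------------------------------------------------------------------
# two-type dynamics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model", ["mitotic", "homeostatic"])
def test_absorbing_states(model, rng):
    n = 40
    step = (mitotic_turnover_counts if model == "mitotic"
            else homeostatic_turnover_counts)
    zeros = np.zeros(100, dtype=np.int64)
    full = np.full(100, n, dtype=np.int64)
    for _ in range(5):
        zeros = step(zeros, n, rng)
        full = step(full, n, rng)
    assert (zeros == 0).all() and (full == n).all()


@pytest.mark.parametrize("model", ["mitotic", "homeostatic"])
def test_martingale_mean_frequency(model, rng):
    """E[variant frequency] is conserved by both turnover models."""
    n, cells, g = 50, 4000, 100
    k = np.full(cells, 15, dtype=np.int64)
    step = (mitotic_turnover_counts if model == "mitotic"
            else homeostatic_turnover_counts)
    for _ in range(g):
        k = step(k, n, rng)
    freq = k / n
    se = freq.std(ddof=1) / np.sqrt(cells)
    assert abs(freq.mean() - 0.3) < 3 * se


def test_homeostatic_single_event_transition(rng):
    """One replacement event moves k by +-1 each with probability
    k(n-k)/(n(n-1)) — matched against enumeration of the two draws."""
    n, k0, reps = 12, 4, 60_000
    k = homeostatic_turnover_counts(
        np.full(reps, k0, dtype=np.int64), n, rng, n_events=1
    )
    q = k0 * (n - k0) / (n * (n - 1))
    up, down = np.mean(k == k0 + 1), np.mean(k == k0 - 1)
    se = np.sqrt(q * (1 - q) / reps)
    assert abs(up - q) < 4 * se and abs(down - q) < 4 * se
    # molecule-level oracle agrees
    labels = np.array([1] * k0 + [0] * (n - k0))
    oracle_up = np.mean([
        oracle_homeostatic_event(labels, rng).sum() == k0 + 1
        for _ in range(20_000)
    ])
    assert abs(oracle_up - q) < 4 * np.sqrt(q * (1 - q) / 20_000)


def test_mitotic_one_step_matches_oracle(rng):
    """Beta-binomial doubling + hypergeometric halving reproduces the
    molecule-by-molecule urn distribution (chi-squared)."""
    n, k0, reps = 10, 5, 30_000
    labels = np.array([1] * k0 + [0] * (n - k0))
    oracle_counts = np.zeros(n + 1)
    for _ in range(reps):
        oracle_counts[oracle_mitotic_turnover(labels, rng).sum()] += 1
    short = mitotic_turnover_counts(np.full(reps, k0, dtype=np.int64), n, rng)
    short_counts = np.bincount(short, minlength=n + 1)
    mask = oracle_counts >= 20
    _, p = stats.chisquare(
        short_counts[mask],
        oracle_counts[mask] / oracle_counts[mask].sum() * short_counts[mask].sum(),
    )
    assert p > 0.01


def test_homeostatic_turnover_matches_oracle(rng):
    """Full homeostatic turnover (n events) against the molecule oracle."""
    n, k0, reps = 8, 4, 20_000
    labels = np.array([1] * k0 + [0] * (n - k0))
    oracle_counts = np.zeros(n + 1)
    for _ in range(reps):
        oracle_counts[oracle_homeostatic_turnover(labels, rng).sum()] += 1
    short = homeostatic_turnover_counts(
        np.full(reps, k0, dtype=np.int64), n, rng
    )
    short_counts = np.bincount(short, minlength=n + 1)
    mask = oracle_counts >= 20
    _, p = stats.chisquare(
        short_counts[mask],
        oracle_counts[mask] / oracle_counts[mask].sum() * short_counts[mask].sum(),
    )
    assert p > 0.01


def test_fixation_probability_equals_p0(rng):
    n, p0, cells = 30, 0.3, 4000
    k = np.full(cells, int(p0 * n), dtype=np.int64)
    for _ in range(600):
        k = mitotic_turnover_counts(k, n, rng)
    assert ((k == 0) | (k == n)).all()  # effectively absorbed at n=30
    fixed = np.mean(k == n)
    se = np.sqrt(p0 * (1 - p0) / cells)
    assert abs(fixed - p0) < 3 * se


def test_heterozygosity_decays_faster_homeostatically(rng):
    """E[p(1-p)] decays geometrically; the homeostatic model needs about
    half as many turnovers for the same decay."""
    n, cells, g = 100, 6000, 60
    km = np.full(cells, 30, dtype=np.int64)
    kh = km.copy()
    for _ in range(g):
        km = mitotic_turnover_counts(km, n, rng)
        kh = homeostatic_turnover_counts(kh, n, rng)
    het_m = np.mean(km / n * (1 - km / n))
    het_h = np.mean(kh / n * (1 - kh / n))
    assert het_h < het_m
    # ratio of decay rates ~ 2
    rate_m = -np.log(het_m / 0.21) / g
    rate_h = -np.log(het_h / 0.21) / g
    assert rate_h / rate_m == pytest.approx(2.0, abs=0.5)


def test_simulate_drift_deterministic_and_initialized():
    cfg = SimulationConfig(n=50, p0=0.2, g_max=20, n_cells=200, seed=11)
    a = simulate_drift(cfg)
    b = simulate_drift(cfg)
    assert a.equals(b)
    start = a[a["turnover"] == 0]
    assert (start["frequency"] == 0.2).all()


def test_turnovers_to_fixation_monotone_in_p0(rng):
    table = turnovers_to_fixation(
        50, [0.1, 0.9], n_cells=600, g_max=2000, rng=rng
    )
    t_low = table.loc[table["p0"] == 0.1, "mean_turnovers_to_fixation"].iloc[0]
    t_high = table.loc[table["p0"] == 0.9, "mean_turnovers_to_fixation"].iloc[0]
    assert t_high < t_low
    assert table["fixing_fraction"].between(0, 1).all()


def test_mitotic_fixation_time_matches_oracle(rng):
    """Mean turnovers to fixation at n=20, p0=0.5 against the brute-force
    molecule simulator."""
    n, cells = 20, 4000
    k = np.full(cells, n // 2, dtype=np.int64)
    fix_time = np.full(cells, -1)
    for g in range(1, 400):
        active = fix_time < 0
        k[active] = mitotic_turnover_counts(k[active], n, rng)
        fix_time[active & (k == n)] = g
    a = fix_time[fix_time > 0]

    times = []
    for _ in range(300):
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        for g in range(1, 400):
            labels = oracle_mitotic_turnover(labels, rng)
            s = labels.sum()
            if s == n:
                times.append(g)
                break
            if s == 0:
                break
    b = np.asarray(times)
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    assert abs(a.mean() - b.mean()) < 3 * se


# ---------------------------------------------------------------------------
# multi-category engine
# ---------------------------------------------------------------------------

def test_copy_number_conserved_by_matrix_steps(rng):
    n, cells = 30, 50
    counts = rng.multinomial(n, np.full(6, 1 / 6), size=cells)
    for _ in range(5):
        added = _dirichlet_multinomial_rows(counts, n, rng)
        assert (added.sum(axis=1) == n).all()
        counts = _mvh_rows(counts + added, n, rng)
        assert (counts.sum(axis=1) == n).all()
    counts = _homeostatic_events_rows(counts, n, rng)
    assert (counts.sum(axis=1) == n).all()


def test_lineage_profile_starts_uniform_and_fixes(rng):
    prof = lineage_fixation_profile(20, 300, 60, rng=rng,
                                    checkpoints=[1, 60])
    first = prof.iloc[0]
    assert first["fraction_fixed"] == 0.0
    assert first["mean_top_frequency"] < 0.5
    last = prof.iloc[-1]
    assert last["fraction_fixed"] > 0.5  # n=20 fixes quickly


# ---------------------------------------------------------------------------
# mutation accumulation
# ---------------------------------------------------------------------------

def test_no_mutations_without_rate(rng):
    cfg = SimulationConfig(n=40, p0=0.0, g_max=10, n_cells=30, r=0.0)
    ledger, _ = simulate_mutation_accumulation(cfg, rng=rng)
    assert all(not c for c in ledger.cell_mutation_counts)


def test_expected_mutation_influx(rng):
    """New mutations per mitotic turnover per cell are Poisson(r*L*n)."""
    from mtmosaic.drift_sim import _GenotypeEngine
    n, cells, lam = 100, 400, 0.05  # lam = r*L per replication
    engine = _GenotypeEngine(n, cells, rng)
    engine.mitotic_turnover(lam)
    created = engine.next_mutation
    expected = lam * n * cells
    assert abs(created - expected) < 4 * np.sqrt(expected)


def test_mutation_frequencies_valid_and_pruned(rng):
    cfg = SimulationConfig(n=60, p0=0.0, g_max=40, n_cells=50, r=2e-6)
    ledger, profile = simulate_mutation_accumulation(
        cfg, rng=rng, checkpoints=[20, 40]
    )
    for cell in range(cfg.n_cells):
        freqs = ledger.frequencies(cell)
        assert ((freqs > 0) & (freqs <= 1)).all()
    assert list(profile["turnover"]) == [20, 40]


def test_independent_engine_agrees_with_genotype_engine(rng):
    """The fast per-mutation engine reproduces the genotype engine's
    summary statistics at small scale (its marginals are exact; linkage is
    the only approximation)."""
    n, g, lam, cells = 100, 60, 8e-3, 400
    cfg = SimulationConfig(n=n, p0=0.0, g_max=g, n_cells=cells,
                           r=lam / 16_569)
    ledger, _ = simulate_mutation_accumulation(cfg, rng=rng)
    top_geno = np.array([ledger.top_frequency(c) for c in range(cells)])
    fast = simulate_mutation_counts_independent(n, g, lam, cells, rng=rng)
    top_fast = fast["max_frequency"]
    se = np.sqrt(top_geno.var(ddof=1) / cells + top_fast.var(ddof=1) / cells)
    assert abs(top_geno.mean() - top_fast.mean()) < 4 * se
    # burden agrees too
    n_geno = np.array([len(ledger.frequencies(c)) for c in range(cells)])
    n_fast = np.array([len(f) for f in fast["frequencies"]])
    se_n = np.sqrt(n_geno.var(ddof=1) / cells + n_fast.var(ddof=1) / cells)
    assert abs(n_geno.mean() - n_fast.mean()) < 4 * se_n


def test_seeded_runs_are_bit_identical():
    cfg = SimulationConfig(n=50, p0=0.0, g_max=30, n_cells=40, r=1e-5,
                           seed=5)
    ledger_a, prof_a = simulate_mutation_accumulation(cfg)
    ledger_b, prof_b = simulate_mutation_accumulation(cfg)
    assert prof_a.equals(prof_b)
    assert ledger_a.cell_mutation_counts == ledger_b.cell_mutation_counts
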