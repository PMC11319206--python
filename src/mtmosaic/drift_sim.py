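"""Forward simulation of intracellular mtDNA drift.

Two turnover models act on the pool of ``n`` mtDNA molecules in a cell:

* **mitotic turnover** — the pool doubles by sequential random replication
  (a Pólya urn: each of the n added copies replicates a molecule chosen
  uniformly from the *current* pool, newly made copies included) and is then
  halved by random segregation at division.  The added copies therefore
  follow a Dirichlet-multinomial law and the halving a multivariate
  hypergeometric law; this exact sampling shortcut is validated against a
  molecule-by-molecule oracle (see ``oracle_*``).
* **homeostatic turnover** — n Moran-style replacement events: one molecule
  chosen uniformly is degraded, then one chosen uniformly from the n-1
  survivors is replicated.  Copy number is constant throughout.

Both models are neutral and keep the copy number at ``n`` after every
completed turnover; the variant frequency is a martingale, so the fixation
probability equals the initial frequency.

Mutation acquisition attaches Poisson(r x L) new mutations to every newly
replicated molecule (infinite-sites labelling).  A mutation arising at the
j-th replication of a doubling phase is itself further replicated within
the same phase; its copy number at the end of the doubling is
1 + BetaBinomial(n - j; 1, n + j - 1), which the genotype engine samples
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RCRS_LENGTH = 16_569


def as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a drift simulation.

    ``r`` is the mutation rate per base pair per replication event; the
    Poisson rate of new mutations per newly made molecule is r * L.
    """

    n: int = 750
    p0: float = 0.1
    g_max: int = 1_440
    n_cells: int = 10_000
    model: str = "mitotic"
    r: float = 0.0
    L: int = RCRS_LENGTH
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if self.model not in ("mitotic", "homeostatic"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def poisson_rate(self) -> float:
        return self.r * self.L


# ---------------------------------------------------------------------------
# two-type (wild-type / variant) fast paths, vectorized across cells
# ---------------------------------------------------------------------------

def mitotic_turnover_counts(k, n: int, rng) -> np.ndarray:
    """One mitotic turnover of variant counts ``k`` (vector of cells).

    Doubling adds BetaBinomial(n; k, n-k) variant copies (the two-type
    marginal of the Pólya urn); halving retains a hypergeometric sample of
    n of the 2n molecules.  States 0 and n are absorbing.
    """
    rng = as_rng(rng)
    k = np.asarray(k, dtype=np.int64)
    out = k.copy()
    seg = (k > 0) & (k < n)
    if seg.any():
        ks = k[seg]
        p = rng.beta(ks, n - ks)
        doubled = ks + rng.binomial(n, p)
        out[seg] = rng.hypergeometric(doubled, 2 * n - doubled, n)
    return out


def homeostatic_turnover_counts(k, n: int, rng, n_events: int | None = None
                                ) -> np.ndarray:
    """One homeostatic turnover (n replacement events) of variant counts.

    Each event moves k by +-1, each with probability k(n-k)/(n(n-1)) (the
    Moran transition for degrade-then-replicate-from-survivors).
    """
    rng = as_rng(rng)
    k = np.asarray(k, dtype=np.int64).copy()
    events = n if n_events is None else n_events
    # per-state transition probability, precomputed for lookup
    states = np.arange(n + 1, dtype=np.float64)
    q_table = states * (n - states) / (n * (n - 1))
    for _ in range(events):
        q = q_table[k]
        u = rng.random(k.shape)
        k += (u < q).astype(np.int64)
        k -= ((u >= q) & (u < 2 * q)).astype(np.int64)
    return k


def _turnover_step(k, n, model, rng):
    if model == "mitotic":
        return mitotic_turnover_counts(k, n, rng)
    return homeostatic_turnover_counts(k, n, rng)


def simulate_drift(cfg: SimulationConfig, rng=None, record_every: int = 1,
                   max_recorded: int = 20_000) -> pd.DataFrame:
    """Simulate ``n_cells`` independent cells from frequency ``p0``.

    Returns a long-format frame (turnover, cell, frequency) thinned to at
    most ``max_recorded`` turnover snapshots.
    """
    rng = as_rng(cfg.seed if rng is None else rng)
    if cfg.g_max // max(record_every, 1) > max_recorded:
        record_every = int(np.ceil(cfg.g_max / max_recorded))
    k0 = int(round(cfg.p0 * cfg.n))
    k = np.full(cfg.n_cells, k0, dtype=np.int64)
    frames = [(0, k.copy())]
    for g in range(1, cfg.g_max + 1):
        k = _turnover_step(k, cfg.n, cfg.model, rng)
        if g % record_every == 0 or g == cfg.g_max:
            frames.append((g, k.copy()))
    rows = []
    for g, counts in frames:
        rows.append(pd.DataFrame({
            "turnover": g,
            "cell": np.arange(cfg.n_cells),
            "frequency": counts / cfg.n,
        }))
    return pd.concat(rows, ignore_index=True)


def homoplasmic_fraction_trajectory(
    n: int, p0: float, n_turnovers: int, n_cells: int, model: str, rng,
) -> np.ndarray:
    """Fraction of cells at frequency exactly 1.0 after each turnover
    (index 0 = after the first turnover)."""
    rng = as_rng(rng)
    k = np.full(n_cells, int(round(p0 * n)), dtype=np.int64)
    out = np.empty(n_turnovers)
    for g in range(n_turnovers):
        k = _turnover_step(k, n, model, rng)
        out[g] = np.mean(k == n)
    return out


def turnovers_to_fixation(
    n: int,
    p0_grid,
    n_cells: int = 10_000,
    g_max: int = 10_000,
    model: str = "mitotic",
    rng=None,
) -> pd.DataFrame:
    """Mean turnover count to homoplasmy (frequency exactly 1.0) per p0.

    Reports the mean over cells that fixed by ``g_max`` together with the
    fixing fraction, and a mean with non-fixing cells capped at ``g_max``.
    """
    rng = as_rng(rng)
    rows = []
    for p0 in p0_grid:
        if not 0.0 < p0 < 1.0:
            raise ValueError("p0 grid values must lie in (0, 1)")
        k = np.full(n_cells, int(round(p0 * n)), dtype=np.int64)
        fix_time = np.full(n_cells, -1, dtype=np.int64)
        for g in range(1, g_max + 1):
            active = fix_time < 0
            if not active.any():
                break
            k[active] = _turnover_step(k[active], n, model, rng)
            newly = active & (k == n)
            fix_time[newly] = g
        fixed = fix_time > 0
        capped = np.where(fixed, fix_time, g_max)
        rows.append({
            "p0": p0,
            "mean_turnovers_to_fixation":
                float(fix_time[fixed].mean()) if fixed.any() else np.nan,
            "fixing_fraction": float(fixed.mean()),
            "capped_mean": float(capped.mean()),
            "n_cells": n_cells,
            "g_max": g_max,
            "model": model,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# molecule-by-molecule oracle (small n only)
# ---------------------------------------------------------------------------

def oracle_mitotic_turnover(labels: np.ndarray, rng) -> np.ndarray:
    """One mitotic turnover simulated molecule by molecule.

    ``labels`` is the array of per-molecule labels (any ints).  Replication
    picks uniformly from the current, growing pool; halving keeps a uniform
    subset of half the doubled pool.
    """
    rng = as_rng(rng)
    pool = list(labels)
    n = len(pool)
    for _ in range(n):
        pool.append(pool[rng.integers(len(pool))])
    keep = rng.choice(2 * n, size=n, replace=False)
    return np.asarray([pool[i] for i in keep])


def oracle_homeostatic_turnover(labels: np.ndarray, rng) -> np.ndarray:
    """One homeostatic turnover (n degrade-then-replicate events) on
    explicit molecule labels."""
    rng = as_rng(rng)
    pool = list(labels)
    n = len(pool)
    for _ in range(n):
        del pool[rng.integers(len(pool))]
        pool.append(pool[rng.integers(len(pool))])
    return np.asarray(pool)


def oracle_homeostatic_event(labels: np.ndarray, rng) -> np.ndarray:
    """A single degrade-then-replicate event (for enumeration checks)."""
    rng = as_rng(rng)
    pool = list(labels)
    del pool[rng.integers(len(pool))]
    pool.append(pool[rng.integers(len(pool))])
    return np.asarray(pool)


# ---------------------------------------------------------------------------
# multi-category urn engine (lineage and genotype tracking)
# ---------------------------------------------------------------------------

def _mvh_rows(pool: np.ndarray, nsample: int, rng) -> np.ndarray:
    """Row-wise multivariate hypergeometric sampling via iterated
    univariate hypergeometric conditionals."""
    rng = as_rng(rng)
    m, G = pool.shape
    remaining_total = pool.sum(axis=1)
    remaining_draw = np.full(m, nsample, dtype=np.int64)
    out = np.zeros_like(pool)
    for j in range(G):
        good = pool[:, j]
        bad = remaining_total - good
        active = (remaining_draw > 0) & (good + bad > 0)
        draw = np.zeros(m, dtype=np.int64)
        if active.any():
            draw[active] = rng.hypergeometric(
                good[active], bad[active], remaining_draw[active]
            )
        out[:, j] = draw
        remaining_total -= good
        remaining_draw -= draw
    return out


def _dirichlet_multinomial_rows(counts: np.ndarray, nsample: int, rng
                                ) -> np.ndarray:
    """Row-wise Dirichlet-multinomial draw with integer concentration equal
    to the current counts (the Pólya-urn law of the doubling phase)."""
    rng = as_rng(rng)
    w = rng.standard_gamma(counts.astype(np.float64))
    tot = w.sum(axis=1, keepdims=True)
    # a row of all zeros cannot occur: every cell keeps n molecules
    p = w / tot
    p[:, -1] = 1.0 - p[:, :-1].sum(axis=1)
    np.clip(p, 0.0, 1.0, out=p)
    return rng.multinomial(nsample, p)


def _compact_rows(counts: np.ndarray, companions: list[np.ndarray]
                  ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shift nonzero entries left in every row and drop all-zero columns;
    companion matrices are permuted identically."""
    order = np.argsort(counts == 0, axis=1, kind="stable")
    counts = np.take_along_axis(counts, order, axis=1)
    companions = [np.take_along_axis(c, order, axis=1) for c in companions]
    width = int((counts > 0).sum(axis=1).max())
    width = max(width, 1)
    return counts[:, :width], [c[:, :width] for c in companions]


def _homeostatic_events_rows(counts: np.ndarray, n_events: int, rng
                             ) -> np.ndarray:
    """Explicit replacement events on category-count rows (small n only)."""
    rng = as_rng(rng)
    m = counts.shape[0]
    rows = np.arange(m)
    counts = counts.copy()
    for _ in range(n_events):
        tot = counts.sum(axis=1)
        cum = np.cumsum(counts, axis=1)
        u = rng.random(m) * tot
        victim = (cum <= u[:, None]).sum(axis=1)
        counts[rows, victim] -= 1
        cum = np.cumsum(counts, axis=1)
        u = rng.random(m) * (tot - 1)
        source = (cum <= u[:, None]).sum(axis=1)
        counts[rows, source] += 1
    return counts


def lineage_fixation_profile(
    n: int,
    n_cells: int,
    n_turnovers: int,
    rng=None,
    model: str = "mitotic",
    checkpoints=None,
) -> pd.DataFrame:
    """Track ``n`` initially distinct founder lineages per cell.

    Returns, per checkpoint turnover, the distribution over cells of the
    most prevalent founder-lineage frequency, as the fraction of cells whose
    top lineage is fully fixed (frequency 1.0) plus deciles of the top
    frequency.
    """
    rng = as_rng(rng)
    if checkpoints is None:
        checkpoints = [n_turnovers]
    checkpoints = sorted(set(int(c) for c in checkpoints))
    counts = np.ones((n_cells, n), dtype=np.int64)
    top = np.ones(n_cells, dtype=np.int64)  # current top-lineage count
    fixed = np.zeros(n_cells, dtype=bool)
    rows = []
    for g in range(1, max(checkpoints) + 1):
        live = ~fixed
        if live.any():
            sub = counts[live]
            if model == "mitotic":
                added = _dirichlet_multinomial_rows(sub, n, rng)
                sub = _mvh_rows(sub + added, n, rng)
            else:
                sub = _homeostatic_events_rows(sub, n, rng)
            counts[live] = sub
            top[live] = sub.max(axis=1)
            fixed = top == n
            counts, _ = _compact_rows(counts, [])
        if g in checkpoints:
            freq = top / n
            deciles = np.quantile(freq, np.linspace(0.1, 0.9, 9))
            rows.append({
                "model": model, "n": n, "turnover": g,
                "fraction_fixed": float(np.mean(freq == 1.0)),
                "mean_top_frequency": float(freq.mean()),
                **{f"q{int(q * 100)}": float(v)
                   for q, v in zip(np.linspace(0.1, 0.9, 9), deciles)},
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutation accumulation, genotype-faithful engine
# ---------------------------------------------------------------------------

@dataclass
class MutationLedger:
    """Final state of a mutation-accumulation run.

    ``cell_mutation_counts[i]`` maps mutation id -> copy count in cell i
    (extinct mutations pruned); frequencies are counts / n.
    """

    n: int
    n_cells: int
    n_turnovers: int
    cell_mutation_counts: list[dict[int, int]] = field(default_factory=list)

    def frequencies(self, cell: int) -> np.ndarray:
        counts = self.cell_mutation_counts[cell]
        if not counts:
            return np.zeros(0)
        return np.asarray(sorted(counts.values(), reverse=True)) / self.n

    def top_frequency(self, cell: int) -> float:
        counts = self.cell_mutation_counts[cell]
        return max(counts.values()) / self.n if counts else 0.0

    def n_homoplasmic(self, cell: int, cutoff: float = 0.9) -> int:
        counts = self.cell_mutation_counts[cell]
        return sum(1 for v in counts.values() if v / self.n > cutoff)


class _GenotypeEngine:
    """Padded (cells x genotype-slot) state with global genotype ancestry."""

    def __init__(self, n: int, n_cells: int, rng):
        self.n = n
        self.n_cells = n_cells
        self.rng = as_rng(rng)
        self.counts = np.full((n_cells, 1), n, dtype=np.int64)
        self.gids = np.zeros((n_cells, 1), dtype=np.int64)
        # genotype 0 is the unmutated founder
        self.parent: list[int] = [-1]
        self.mutation: list[int] = [-1]
        self.next_mutation = 0
        self._mutset_cache: dict[int, frozenset[int]] = {0: frozenset()}

    def mutations_of(self, gid: int) -> frozenset[int]:
        cached = self._mutset_cache.get(gid)
        if cached is not None:
            return cached
        chain = []
        g = gid
        while g not in self._mutset_cache:
            chain.append(g)
            g = self.parent[g]
        current = self._mutset_cache[g]
        for g in reversed(chain):
            current = current | {self.mutation[g]}
            self._mutset_cache[g] = current
        return current

    def _new_genotype(self, parent_gid: int) -> int:
        self.parent.append(parent_gid)
        self.mutation.append(self.next_mutation)
        self.next_mutation += 1
        return len(self.parent) - 1

    def _ensure_free_slot(self, cell: int) -> int:
        row = self.counts[cell]
        free = np.flatnonzero(row == 0)
        if free.size:
            return int(free[0])
        width = self.counts.shape[1]
        self.counts = np.pad(self.counts, ((0, 0), (0, 4)))
        self.gids = np.pad(self.gids, ((0, 0), (0, 4)))
        return width

    def mitotic_turnover(self, lam: float) -> None:
        n, rng = self.n, self.rng
        added = _dirichlet_multinomial_rows(self.counts, n, rng)
        if lam > 0:
            n_events = rng.poisson(lam * n, self.n_cells)
            for cell in np.flatnonzero(n_events):
                for _ in range(int(n_events[cell])):
                    added = self._inject_mitotic_mutation(cell, added)
        pool = self.counts + added
        self.counts = _mvh_rows(pool, n, rng)
        self._prune()

    def _inject_mitotic_mutation(self, cell: int, added: np.ndarray
                                 ) -> np.ndarray:
        """Attach one new mutation to a newly made copy of this doubling.

        The mutated copy is the j-th replication (j uniform on 1..n); its
        descendant count at the end of the doubling is
        1 + BetaBinomial(n - j; 1, n + j - 1).  The parent genotype is
        chosen proportionally to the added-copy composition.
        """
        n, rng = self.n, self.rng
        row_added = added[cell]
        total_added = row_added.sum()
        if total_added <= 0:
            return added
        u = rng.random() * total_added
        slot = int(np.searchsorted(np.cumsum(row_added), u, side="right"))
        j = int(rng.integers(1, n + 1))
        extra = 0
        if n - j > 0:
            p = rng.beta(1.0, n + j - 1)
            extra = int(rng.binomial(n - j, p))
        descendants = min(1 + extra, int(row_added[slot]))
        if descendants <= 0:
            return added
        gid = self._new_genotype(int(self.gids[cell, slot]))
        free_slots = np.flatnonzero(
            (self.counts[cell] == 0) & (added[cell] == 0)
        )
        if free_slots.size:
            free = int(free_slots[0])
        else:
            free = self.counts.shape[1]
            self.counts = np.pad(self.counts, ((0, 0), (0, 4)))
            self.gids = np.pad(self.gids, ((0, 0), (0, 4)))
            added = np.pad(added, ((0, 0), (0, 4)))
        added[cell, slot] -= descendants
        self.gids[cell, free] = gid
        self.counts[cell, free] = 0
        added[cell, free] += descendants
        return added

    def homeostatic_turnover(self, lam: float) -> None:
        """n explicit replacement events per cell; each replication draws
        Poisson(lam) mutations on the new copy."""
        n, rng = self.n, self.rng
        rows = np.arange(self.n_cells)
        for _ in range(n):
            counts = self.counts
            tot = counts.sum(axis=1)
            cum = np.cumsum(counts, axis=1)
            u = rng.random(self.n_cells) * tot
            victim = (cum <= u[:, None]).sum(axis=1)
            counts[rows, victim] -= 1
            cum = np.cumsum(counts, axis=1)
            u = rng.random(self.n_cells) * (tot - 1)
            source = (cum <= u[:, None]).sum(axis=1)
            if lam > 0:
                n_muts = rng.poisson(lam, self.n_cells)
                mutated = np.flatnonzero(n_muts)
            else:
                mutated = np.empty(0, dtype=int)
            plain = np.setdiff1d(rows, mutated, assume_unique=True)
            counts[plain, source[plain]] += 1
            for cell in mutated:
                gid = int(self.gids[cell, source[cell]])
                for _ in range(int(n_muts[cell])):
                    gid = self._new_genotype(gid)
                free = self._ensure_free_slot(cell)
                self.gids[cell, free] = gid
                self.counts[cell, free] = 1
        self._prune()

    def _prune(self) -> None:
        self.counts, companions = _compact_rows(self.counts, [self.gids])
        self.gids = companions[0]

    def ledger(self) -> MutationLedger:
        out = MutationLedger(self.n, self.n_cells, -1)
        for cell in range(self.n_cells):
            per: dict[int, int] = {}
            row = self.counts[cell]
            for slot in np.flatnonzero(row):
                for mut in self.mutations_of(int(self.gids[cell, slot])):
                    per[mut] = per.get(mut, 0) + int(row[slot])
            out.cell_mutation_counts.append(per)
        return out


def simulate_mutation_accumulation(
    cfg: SimulationConfig,
    rng=None,
    checkpoints=None,
) -> tuple[MutationLedger, pd.DataFrame]:
    """Genotype-faithful mutation accumulation under either turnover model.

    Every cell starts from a single unmutated genotype; mutations arise at
    Poisson(r x L) per replication event and are propagated with full
    linkage through the turnover steps.  Returns the final per-cell
    mutation ledger and a per-checkpoint table of the top mutation
    frequency distribution.
    """
    if cfg.r < 0:
        raise ValueError("r must be >= 0")
    rng = as_rng(cfg.seed if rng is None else rng)
    engine = _GenotypeEngine(cfg.n, cfg.n_cells, rng)
    lam = cfg.poisson_rate
    checkpoints = sorted(set(int(c) for c in (checkpoints or [cfg.g_max])))
    rows = []
    for g in range(1, cfg.g_max + 1):
        if cfg.model == "mitotic":
            engine.mitotic_turnover(lam)
        else:
            engine.homeostatic_turnover(lam)
        if g in checkpoints:
            ledger = engine.ledger()
            freqs = np.asarray([
                ledger.top_frequency(c) for c in range(cfg.n_cells)
            ])
            rows.append({
                "model": cfg.model, "n": cfg.n, "r": cfg.r, "turnover": g,
                "mean_top_mutation_frequency": float(freqs.mean()),
                "fraction_above_090": float(np.mean(freqs > 0.9)),
                "fraction_fixed": float(np.mean(freqs == 1.0)),
            })
    return engine.ledger(), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutation accumulation, independent-lineage fast engine
# ---------------------------------------------------------------------------

def simulate_mutation_counts_independent(
    n: int,
    n_turnovers: int,
    lam: float,
    n_cells: int,
    rng=None,
    homoplasmy_cutoff: float = 0.9,
) -> dict:
    """Fast mitotic mutation accumulation treating mutations independently.

    Each mutation's copy number follows the exact two-type marginal chain
    (birth count 1 + BetaBinomial within its birth doubling, then
    beta-binomial doubling and hypergeometric halving); linkage between
    mutations sharing a molecule is ignored, which leaves each mutation's
    marginal law exact while approximating within-cell joint statistics.
    Returns per-cell max frequency, per-cell homoplasmic-mutation counts
    and the ragged per-cell frequency arrays.
    """
    rng = as_rng(rng)
    cell_idx = np.empty(0, dtype=np.int64)
    count = np.empty(0, dtype=np.int64)
    fixed = np.zeros(n_cells, dtype=np.int64)
    for _ in range(n_turnovers):
        if count.size:
            count = mitotic_turnover_counts(count, n, rng)
        if lam > 0:
            births = rng.poisson(lam * n, n_cells)
            total = int(births.sum())
            if total:
                cells = np.repeat(np.arange(n_cells), births)
                j = rng.integers(1, n + 1, size=total)
                extra = np.zeros(total, dtype=np.int64)
                room = n - j
                has_room = room > 0
                if has_room.any():
                    p = rng.beta(1.0, n + j[has_room] - 1)
                    extra[has_room] = rng.binomial(room[has_room], p)
                d = 1 + extra
                surv = rng.hypergeometric(d, 2 * n - d, n)
                keep = surv > 0
                cell_idx = np.concatenate([cell_idx, cells[keep]])
                count = np.concatenate([count, surv[keep]])
        newly_fixed = count == n
        if newly_fixed.any():
            np.add.at(fixed, cell_idx[newly_fixed], 1)
        alive = (count > 0) & ~newly_fixed
        cell_idx, count = cell_idx[alive], count[alive]

    max_freq = np.zeros(n_cells)
    if count.size:
        np.maximum.at(max_freq, cell_idx, count / n)
    max_freq[fixed > 0] = 1.0
    hom = fixed.astype(np.int64).copy()
    if count.size:
        np.add.at(hom, cell_idx, count > homoplasmy_cutoff * n)
    per_cell = [np.empty(0)] * n_cells
    if count.size or fixed.any():
        order = np.argsort(cell_idx, kind="stable")
        sorted_cells = cell_idx[order]
        sorted_counts = count[order]
        bounds = np.searchsorted(sorted_cells, np.arange(n_cells + 1))
        for c in range(n_cells):
            seg = sorted_counts[bounds[c]:bounds[c + 1]] / n
            if fixed[c]:
                seg = np.concatenate([np.ones(fixed[c]), seg])
            per_cell[c] = np.sort(seg)[::-1]
    return {
        "max_frequency": max_freq,
        "n_homoplasmic": hom,
        "frequencies": per_cell,
        "n_fixed": fixed,
    }


# ---------------------------------------------------------------------------
# purification / Fig.-7-style contour tables
# ---------------------------------------------------------------------------

def purification_profile(
    n_grid=(500, 750, 1_000, 1_500, 2_000),
    n_turnovers: int = 1_000,
    n_cells: int = 1_000,
    r: float = 0.0,
    L: int = RCRS_LENGTH,
    model: str = "mitotic",
    rng=None,
    checkpoint_every: int = 100,
) -> pd.DataFrame:
    """Long-format contour tables over a copy-number grid.

    Without mutations (r = 0), tracks the most prevalent founder lineage
    (all n molecules initially distinct); with r > 0, tracks the top
    postzygotic mutation frequency via the genotype engine.
    """
    rng = as_rng(rng)
    checkpoints = list(range(checkpoint_every, n_turnovers + 1, checkpoint_every))
    if not checkpoints or checkpoints[-1] != n_turnovers:
        checkpoints.append(n_turnovers)
    frames = []
    for n in n_grid:
        if r > 0:
            cfg = SimulationConfig(n=n, p0=0.0, g_max=n_turnovers,
                                   n_cells=n_cells, model=model, r=r, L=L)
            _, profile = simulate_mutation_accumulation(
                cfg, rng=rng, checkpoints=checkpoints
            )
        else:
            profile = lineage_fixation_profile(
                n, n_cells, n_turnovers, rng=rng, model=model,
                checkpoints=checkpoints,
            )
        frames.append(profile)
    return pd.concat(frames, ignore_index=True)
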