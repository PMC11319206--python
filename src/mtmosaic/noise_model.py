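"""Locus-specific background-noise panel and call reconciliation.

Sequencing noise on the mitochondrial genome is strongly locus-dependent
(repeats, NUMT misalignment).  A panel of normal clones yields, for every
(position, alternate allele), the distribution of measured VAFs across all
panel clones (zeros included).  Two per-site cutoffs are derived:

* a one-sided 95% upper confidence bound, mean + 1.645 * sd, on the normal
  approximation of the panel VAFs; and
* a "relative gap" threshold: panel VAFs inside [0.05%, 15%] are sorted and
  the largest adjacent gap with (VAF' - VAF)/VAF >= 0.33 is taken as the
  boundary between noise and signal, with the cutoff placed at
  min(mean(VAF, VAF'), VAF * 1.33).

Reconciliation removes called variants at or below the effective cutoff
(false positives) and rescues uncalled clone VAFs above it (false
negatives).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CohortData

logger = logging.getLogger(__name__)

Z_ONE_SIDED_95 = 1.6448536269514722  # scipy.stats.norm.ppf(0.95)

GAP_VAF_LOW = 0.0005
GAP_VAF_HIGH = 0.15
MIN_RELATIVE_GAP = 0.33
DEFAULT_MIN_PANEL_CLONES = 20


def gap_threshold(
    panel_vafs,
    low: float = GAP_VAF_LOW,
    high: float = GAP_VAF_HIGH,
    min_relative_gap: float = MIN_RELATIVE_GAP,
) -> float | None:
    """Relative-gap cutoff for one site's panel VAF vector, or None.

    Only VAFs inside [low, high] participate.  Among adjacent sorted pairs
    with relative gap (VAF' - VAF)/VAF >= ``min_relative_gap``, the pair with
    the largest absolute gap is selected and the cutoff is
    min(mean(VAF, VAF'), VAF * (1 + min_relative_gap)).
    """
    vafs = np.sort(np.asarray(panel_vafs, dtype=float))
    if np.any((vafs < 0) | (vafs > 1)):
        raise ValueError("VAFs outside [0, 1]")
    window = vafs[(vafs >= low) & (vafs <= high)]
    if window.size < 2:
        return None
    lower, upper = window[:-1], window[1:]
    gaps = upper - lower
    rel = gaps / lower
    qualifying = rel >= min_relative_gap
    if not qualifying.any():
        return None
    best = np.flatnonzero(qualifying)[np.argmax(gaps[qualifying])]
    v, v_prime = lower[best], upper[best]
    return float(min((v + v_prime) / 2.0, v * (1.0 + min_relative_gap)))


@dataclass
class NoisePanel:
    """Per-(position, alt) background statistics across a clone panel.

    ``sites`` is indexed by (position, alt) with columns mean, sd, ci_bound
    and gap_threshold (NaN when no qualifying gap exists); ``panel_vafs``
    is the clone x site VAF matrix the statistics were computed from.
    """

    sites: pd.DataFrame
    panel_vafs: pd.DataFrame
    n_clones: int

    def has_site(self, position: int, alt: str) -> bool:
        return (position, alt) in self.sites.index

    def effective_threshold(self, position: int, alt: str,
                            precedence: str = "gap") -> tuple[float, str]:
        """Cutoff for a site: the gap threshold when present, else the CI
        bound (or the other way around under precedence='ci')."""
        row = self.sites.loc[(position, alt)]
        gap = row["gap_threshold"]
        ci = row["ci_bound"]
        if precedence not in ("gap", "ci"):
            raise ValueError(f"unknown precedence {precedence!r}")
        if precedence == "gap" and not math.isnan(gap):
            return float(gap), "gap"
        return float(ci), "ci"

    def to_frame(self) -> pd.DataFrame:
        return self.sites.reset_index()


def build_noise_panel(
    cohort: CohortData,
    min_clones: int = DEFAULT_MIN_PANEL_CLONES,
) -> NoisePanel:
    """Build the background-noise panel from all clones of a cohort.

    The panel includes every clone (the clone under evaluation is not left
    out); VAF vectors include zeros for clones without an observation at a
    site.
    """
    n = len(cohort.clones)
    if n < min_clones:
        raise ValueError(
            f"noise panel requires at least {min_clones} clones, got {n}"
        )
    matrix = cohort.vaf_matrix()
    if matrix.shape[1] == 0:
        sites = pd.DataFrame(
            columns=["mean", "sd", "ci_bound", "gap_threshold"],
            index=pd.MultiIndex.from_tuples([], names=["position", "alt"]),
        )
        return NoisePanel(sites=sites, panel_vafs=matrix, n_clones=n)

    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if n > 1 else np.zeros(values.shape[1])
    ci = mean + Z_ONE_SIDED_95 * sd
    gaps = [gap_threshold(values[:, j]) for j in range(values.shape[1])]
    sites = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci_bound": ci,
            "gap_threshold": [math.nan if g is None else g for g in gaps],
        },
        index=pd.MultiIndex.from_tuples(matrix.columns, names=["position", "alt"]),
    )
    return NoisePanel(sites=sites, panel_vafs=matrix, n_clones=n)


#: practical detection floor of the assay (~0.3% heteroplasmy)
DETECTION_FLOOR = 0.003


def reconcile_calls(
    calls: pd.DataFrame,
    panel: NoisePanel,
    cohort: CohortData,
    precedence: str = "gap",
    min_vaf: float = DETECTION_FLOOR,
) -> pd.DataFrame:
    """Reconcile an upstream call set against the noise panel.

    ``calls`` needs columns clone_id, position, alt.  Returns one row per
    (clone, site) decision with columns clone_id, position, alt, vaf,
    threshold, rule and status in {kept, removed, rescued}.  The reconciled
    mutant set is the rows with status != 'removed'.  A clone's VAF must
    strictly exceed the effective cutoff — the per-site noise threshold or
    the assay's practical detection floor ``min_vaf``, whichever is larger —
    to count as a mutant.
    """
    called = {(r.clone_id, r.position, r.alt)
              for r in calls[["clone_id", "position", "alt"]].itertuples(index=False)}

    measured = {
        (r.clone_id, r.position, r.alt): r.vaf
        for r in cohort.variants[["clone_id", "position", "alt", "vaf"]]
        .itertuples(index=False)
    }

    rows = []
    # sites under panel control: decide every clone
    sites_in_play = sorted(
        {(p, a) for (_, p, a) in called} | set(panel.sites.index),
        key=lambda s: (s[0], s[1]),
    )
    for position, alt in sites_in_play:
        if not panel.has_site(position, alt):
            for clone in cohort.clone_ids:
                if (clone, position, alt) in called:
                    logger.warning(
                        "site %s:%s absent from noise panel; call kept",
                        position, alt,
                    )
                    rows.append((clone, position, alt,
                                 measured.get((clone, position, alt), 0.0),
                                 math.nan, "none", "kept"))
            continue
        threshold, rule = panel.effective_threshold(position, alt, precedence)
        cutoff = max(threshold, min_vaf)
        for clone in cohort.clone_ids:
            vaf = measured.get((clone, position, alt), 0.0)
            was_called = (clone, position, alt) in called
            exceeds = vaf > cutoff
            if was_called and exceeds:
                status = "kept"
            elif was_called and not exceeds:
                status = "removed"
            elif exceeds:
                status = "rescued"
            else:
                continue
            rows.append((clone, position, alt, vaf, threshold, rule, status))

    return pd.DataFrame(
        rows,
        columns=["clone_id", "position", "alt", "vaf",
                 "threshold", "rule", "status"],
    )


def reconciled_call_set(reconciled: pd.DataFrame) -> pd.DataFrame:
    """Mutant calls surviving reconciliation (kept + rescued)."""
    return (reconciled[reconciled["status"] != "removed"]
            .drop(columns=["status"]).reset_index(drop=True))
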