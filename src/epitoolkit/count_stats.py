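"""Exact and Monte Carlo contingency-table tests for gene-count comparisons.

The family-level comparison between two species builds, for each gene family
f, the 2x2 table

    [[n_f^A, N^A - n_f^A],
     [n_f^B, N^B - n_f^B]]

(family vs the sum of all other epigenetic genes) and applies a two-sided
Fisher exact test: the p-value is the sum of hypergeometric point
probabilities, over all tables with the observed margins, that do not exceed
the observed table's probability (relative tie tolerance 1e-7). The full
family-by-species table is tested with a Monte Carlo Fisher test that samples
fixed-margin tables by Patefield's algorithm. Bonferroni correction handles
the multiplicity over families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "fisher_exact_2x2",
    "fisher_mc",
    "bonferroni",
    "compare_family_counts",
]

_TIE_RTOL = 1e-7


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("contingency table entries must be non-negative")
        if not (self.counts.sum(axis=1) > 0).any() or not (self.counts.sum(axis=0) > 0).any():
            raise ValueError("table needs at least one positive row and column margin")


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        arr = table.counts
    else:
        arr = np.asarray(table, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the point
    probabilities that are <= the observed one (within relative tolerance
    1e-7, so floating-point ties count as ties).
    """
    t = _as_array(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    amin = max(0, r1 + c1 - n)
    amax = min(r1, c1)
    support = np.arange(amin, amax + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - amin]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def _log_prob_fixed_margins(t: np.ndarray) -> float:
    """log P(table | margins) under the fixed-margin (multiple hypergeometric) null."""
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1) - gammaln(t + 1).sum()
    )


def fisher_mc(table, reps: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Monte Carlo Fisher exact test for an r x c table.

    Samples ``reps`` tables with the observed margins (Patefield's algorithm)
    and estimates p = (1 + #{P(sim) <= P(obs)}) / (reps + 1), so the estimate
    is never exactly zero. Returns ``(p_hat, binomial_se)``.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    t = _as_array(table)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: every row and column margin must be positive")
    logp_obs = _log_prob_fixed_margins(t)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row, col)
    sims = sampler.rvs(reps, method="patefield", random_state=rng)
    # vectorized log-probability of each simulated table
    logp_sim = (
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(t.sum() + 1)
        - gammaln(sims + 1).sum(axis=(1, 2))
    )
    hits = int((logp_sim <= logp_obs + abs(logp_obs) * _TIE_RTOL + 1e-12).sum())
    p_hat = (1 + hits) / (reps + 1)
    se = float(np.sqrt(p_hat * (1 - p_hat) / reps))
    return p_hat, se


def bonferroni(pvals) -> list[float]:
    """Bonferroni adjustment: p -> min(1, m*p) with m = len(pvals)."""
    pvals = list(pvals)
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    m = len(pvals)
    return [min(1.0, m * p) for p in pvals]


def compare_family_counts(
    counts: pd.DataFrame,
    species_a: str | None = None,
    species_b: str | None = None,
    reps: int = 20000,
    seed: int = 0,
) -> dict:
    """Per-family 2x2 Fisher tests plus a global family-by-species MC test.

    ``counts`` must have columns ``family`` and two species count columns
    (named explicitly or taken as the last two columns). Subfamily rows are
    summed within family. Returns a dict with a tidy per-family DataFrame
    (p, p_bonferroni) and the global Monte Carlo p and its SE.
    """
    if species_a is None or species_b is None:
        species_a, species_b = counts.columns[-2], counts.columns[-1]
    fam = counts.groupby("family", sort=False)[[species_a, species_b]].sum()
    if len(fam) < 2:
        raise ValueError("need at least two families")
    total_a = int(fam[species_a].sum())
    total_b = int(fam[species_b].sum())
    rows = []
    for family, r in fam.iterrows():
        na, nb = int(r[species_a]), int(r[species_b])
        p = fisher_exact_2x2([[na, total_a - na], [nb, total_b - nb]])
        rows.append({"family": family, species_a: na, species_b: nb, "p": p})
    report = pd.DataFrame(rows)
    report["p_bonferroni"] = bonferroni(report["p"].tolist())
    global_p, global_se = fisher_mc(fam.to_numpy(), reps=reps, seed=seed)
    return {
        "per_family": report,
        "global_mc_p": global_p,
        "global_mc_se": global_se,
        "totals": {species_a: total_a, species_b: total_b},
    }
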