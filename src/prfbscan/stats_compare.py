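"""Group comparisons and small statistical utilities.

All group comparisons in the analysis are Welch two-sample t-tests (unequal
variances, Welch-Satterthwaite degrees of freedom); genome subsets are drawn
with a seeded, named PRNG so they are portable; per-taxon aggregation turns
frameshift calls into percent-with-motif tables; and the frameshifting
efficiency of a reporter is the frameshifted band intensity over the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "welch_t_test",
    "random_subset",
    "aggregate_by_taxon",
    "frameshift_efficiency",
    "SUBSET_PRNG",
]

# Named, versioned PRNG for subsetting, recorded in run manifests so seeds
# are portable across machines and releases.
SUBSET_PRNG = "numpy.random.PCG64"


@dataclass
class TestResult:
    t_stat: float
    df: float
    p_two_sided: float
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    notes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "t_stat": self.t_stat,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "mean_x": self.mean_x,
            "mean_y": self.mean_y,
            "notes": list(self.notes),
        }


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch two-sample t-test.

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y), degrees of freedom by
    Welch-Satterthwaite, p two-sided from the t distribution.  Degenerate
    inputs: both samples constant with equal means -> t = 0, p = 1; both
    constant with unequal means -> p = 0 with a degeneracy note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 2 or n_y < 2:
        raise ValueError("each sample needs n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return TestResult(0.0, float(n_x + n_y - 2), 1.0, n_x, n_y, mx, my,
                              ("both samples constant; equal means",))
        t = np.inf if mx > my else -np.inf
        return TestResult(float(t), float(n_x + n_y - 2), 0.0, n_x, n_y, mx, my,
                          ("both samples constant; unequal means",))
    se2 = vx / n_x + vy / n_y
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / n_x) ** 2 / (n_x - 1) + (vy / n_y) ** 2 / (n_y - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), n_x, n_y, float(mx), float(my))


def random_subset(items: Sequence, n: int, seed: int) -> list:
    """Draw ``n`` distinct items deterministically.

    Items are first ordered by their string form, so the draw depends only
    on the item identities and the seed, not on input permutation.
    """
    items = list(items)
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > len(items):
        raise ValueError(f"cannot draw {n} items from {len(items)}")
    if n == 0:
        return []
    ordered = sorted(items, key=str)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(idx)]


def aggregate_by_taxon(rows, rank: str = "phylum") -> pd.DataFrame:
    """Percent of scannable genomes with the frameshift motif, per taxon.

    ``rows`` are :class:`~prfbscan.genome_stats.GenomeStatsRow`.  Genomes
    with status ``gene_absent`` or ``unscannable`` are excluded from the
    percentage denominator and reported in their own columns; taxa without
    an assignment at ``rank`` bucket under ``unclassified``.
    """
    buckets: dict = {}
    for r in rows:
        taxon = r.taxonomy.get(rank, "unclassified") or "unclassified"
        b = buckets.setdefault(
            taxon,
            {"n_genomes": 0, "n_frameshift": 0, "n_no_frameshift": 0,
             "n_gene_absent": 0, "n_unscannable": 0},
        )
        b["n_genomes"] += 1
        key = f"n_{r.prfb_status}"
        if key in b:
            b[key] += 1
    records = []
    for taxon in sorted(buckets):
        b = buckets[taxon]
        n_scannable = b["n_frameshift"] + b["n_no_frameshift"]
        pct = 100.0 * b["n_frameshift"] / n_scannable if n_scannable else float("nan")
        records.append({"taxon": taxon, **b, "n_scannable": n_scannable,
                        "percent_frameshift": pct})
    return pd.DataFrame(
        records,
        columns=["taxon", "n_genomes", "n_scannable", "n_frameshift",
                 "n_no_frameshift", "n_gene_absent", "n_unscannable",
                 "percent_frameshift"],
    )


def frameshift_efficiency(i_fs: float, i_term: float) -> float:
    """Frameshifting efficiency from reporter band intensities.

    efficiency = I_frameshifted / (I_frameshifted + I_terminated).
    """
    if i_fs < 0 or i_term < 0:
        raise ValueError("band intensities must be non-negative")
    denom = i_fs + i_term
    if denom == 0:
        raise ValueError("zero total band intensity")
    return i_fs / denom
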