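"""Differential-abundance screening by the two-tailed Mann-Whitney U test.

Each taxon's abundances are compared between the healthy-implant (HI) and
peri-implantitis (PI) groups with a rank-based two-sample test; taxa with
p < alpha (default 0.05, no multiple-testing correction) are flagged as
candidate biomarkers. The U statistic reported is the one for the first
sample (x), i.e. the number of (x, y) pairs with x > y counting ties as
one half.

Two p-value routes are used: exact enumeration of the null U distribution
for small untied samples (combined n <= 12), and the tie-corrected,
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.stats import rankdata, norm

from .errors import ValidationError
from .io import AbundanceTable, CohortLabels

HIGHER_IN_PI = "higher_in_PI"
LOWER_IN_PI = "lower_in_PI"

_EXACT_MAX_N = 12


@dataclass
class ScreeningResult:
    """Per-taxon screening outcome."""

    taxon_id: str
    u_statistic: float
    p_value: float
    direction: str  # higher_in_PI / lower_in_PI by group-mean comparison
    significant: bool
    mean_tied: bool = False  # direction fell back to the higher_in_PI convention
    q_value: float | None = None  # BH-adjusted p, when correction requested


@lru_cache(maxsize=64)
def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """cdf[u] = P(U1 <= u) under the null, by enumeration of rank subsets."""
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    offset = n1 * (n1 + 1) // 2
    for ranks in combinations(range(1, n1 + n2 + 1), n1):
        counts[sum(ranks) - offset] += 1
    return np.cumsum(counts) / counts.sum()


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Parameters
    ----------
    x, y
        The two abundance vectors (PI group conventionally passed first by
        :func:`screen_taxa`, but the test is symmetric up to ``U -> n1*n2 - U``).
    method
        ``"exact"`` (enumeration; only valid without ties), ``"asymptotic"``
        (tie-corrected normal approximation with continuity correction), or
        ``"auto"``: exact when ``len(x) + len(y) <= 12`` and there are no
        tied values, asymptotic otherwise.

    Returns
    -------
    (U, p) : U statistic for ``x`` and the two-tailed p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("abundance vectors must be finite")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if method == "auto":
        method = "exact" if (n1 + n2 <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise ValidationError("exact method is not defined with tied values")
        cdf = _exact_u_cdf(n1, n2)
        u_small = min(u1, n1 * n2 - u1)
        p = min(1.0, 2.0 * cdf[int(round(u_small))])
        return float(u1), float(p)
    if method != "asymptotic":
        raise ValidationError(f"unknown method {method!r}")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # every value identical
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)  # 0.5 = continuity correction
    p = min(1.0, 2.0 * norm.sf(z))
    return float(u1), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def screen_taxa(
    table: AbundanceTable,
    labels: CohortLabels,
    alpha: float = 0.05,
    direction_stat: str = "mean",
    correction: str | None = None,
) -> list[ScreeningResult]:
    """Screen every taxon for a PI-vs-HI abundance difference.

    ``significant`` is ``p < alpha`` on the raw p-value by default; with
    ``correction="bh"`` the Benjamini-Hochberg adjusted p is used instead.
    Direction is set by comparing group means (or medians with
    ``direction_stat="median"``); exact ties fall back to ``higher_in_PI``
    and are flagged.
    """
    if direction_stat not in ("mean", "median"):
        raise ValidationError("direction_stat must be 'mean' or 'median'")
    if correction not in (None, "bh"):
        raise ValidationError("correction must be None or 'bh'")
    aligned = labels.align_with(table)
    pi_mask = (aligned == "PI").to_numpy()
    hi_mask = (aligned == "HI").to_numpy()
    if pi_mask.sum() < 2 or hi_mask.sum() < 2:
        raise ValidationError("each group needs at least 2 samples for screening")

    values = table.data.to_numpy()
    stat = np.mean if direction_stat == "mean" else np.median
    results = []
    for j, taxon in enumerate(table.taxon_ids):
        x = values[pi_mask, j]
        y = values[hi_mask, j]
        u, p = mann_whitney_u(x, y)
        center_pi, center_hi = stat(x), stat(y)
        tied = bool(center_pi == center_hi)
        direction = HIGHER_IN_PI if center_pi >= center_hi else LOWER_IN_PI
        results.append(
            ScreeningResult(
                taxon_id=taxon,
                u_statistic=u,
                p_value=p,
                direction=direction,
                significant=bool(p < alpha),
                mean_tied=tied,
            )
        )
    if correction == "bh":
        q = benjamini_hochberg([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.significant = bool(qv < alpha)
    return results


def results_frame(results: list[ScreeningResult]):
    """Screening results as a tidy DataFrame (one row per taxon)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "taxon_id": [r.taxon_id for r in results],
            "u_statistic": [r.u_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )
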