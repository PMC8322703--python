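"""Robust Rank Aggregation (RRA) of ordered item lists.

Each input list ranks items within a universe of size N; an item at 1-based
position i receives the normalized rank r = i/N.  Under the null that an
item's positions are uniform, its sorted rank vector r_(1) <= ... <= r_(m)
is a draw of uniform order statistics, so

    beta_k = P(U_(k) <= r_k) = sum_{j=k..m} C(m, j) r_k^j (1 - r_k)^(m-j)

is a valid p-value for each k.  The rho score is the minimum beta_k over k,
and a Bonferroni factor m (one test per order statistic) turns it back into
a conservative p-value: score = min(1, m * rho).  Small scores mean the
item sits consistently near the top of the lists.

Items absent from a list are treated as ranked worst (r = 1), which is
conservative for partially overlapping universes such as different
microarray platforms.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = np.nan


def normalized_ranks(lists: Sequence[Sequence[str]],
                     universes: Sequence[int]) -> pd.DataFrame:
    """Build the items x lists matrix of normalized ranks.

    ``universes[j]`` is the number of rankable items behind list ``j``
    (e.g. all genes measured on that platform); it must be at least the
    list length.  Entries for items absent from a list are NaN.
    """
    if len(lists) != len(universes):
        raise ValueError("one universe size per list required")
    union: list[str] = []
    seen: set[str] = set()
    for lst in lists:
        for item in lst:
            if item not in seen:
                seen.add(item)
                union.append(item)
    mat = pd.DataFrame(MISSING, index=sorted(union),
                       columns=range(len(lists)), dtype=float)
    for j, (lst, n_univ) in enumerate(zip(lists, universes)):
        if len(set(lst)) != len(lst):
            dupes = [x for x in lst if lst.count(x) > 1]
            raise ValueError(f"duplicate items in list {j}: {sorted(set(dupes))}")
        if n_univ < len(lst):
            raise ValueError(f"universe {n_univ} smaller than list {j} "
                             f"({len(lst)} items)")
        for i, item in enumerate(lst, start=1):
            mat.at[item, j] = i / n_univ
    return mat


def beta_scores(r: Sequence[float], m: int) -> np.ndarray:
    """Order-statistic tail probabilities beta_k for a sorted rank vector.

    ``r`` must be ascending with entries in (0, 1] and length ``m`` (missing
    entries already substituted with 1.0).  beta_k is the binomial upper
    tail P(Bin(m, r_k) >= k).
    """
    r = np.asarray(r, dtype=float)
    if r.size != m:
        raise ValueError(f"rank vector length {r.size} != m = {m}")
    if np.any(np.diff(r) < 0):
        raise ValueError("rank vector must be sorted ascending")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("ranks must lie in (0, 1]")
    k = np.arange(1, m + 1)
    return stats.binom.sf(k - 1, m, r)


def rho_score(r: Sequence[float], m: int) -> tuple[float, float]:
    """(rho, Bonferroni-corrected score) for one item's rank vector."""
    beta = beta_scores(np.sort(np.asarray(r, dtype=float)), m)
    rho = float(beta.min())
    return rho, min(1.0, m * rho)


def aggregate(lists: Sequence[Sequence[str]],
              universes: Sequence[int],
              lfc_table: pd.DataFrame | Mapping[str, Mapping[str, float]] | None = None,
              ) -> pd.DataFrame:
    """Aggregate ranked lists into a per-item RRA table.

    Returns a DataFrame indexed by item with columns ``rho``, ``score`` and
    ``mean_lfc`` (NaN when no fold-change table is supplied), sorted by
    score ascending with ties broken by item id.  ``lfc_table`` holds one
    log2 fold change column per input list; the mean is taken over the
    lists in which the item is measured (non-NaN).
    """
    if len(lists) == 0:
        raise ValueError("need at least one list")
    mat = normalized_ranks(lists, universes)
    if mat.empty:
        raise ValueError("union of input lists is empty")
    m = len(lists)
    filled = mat.fillna(1.0).to_numpy()
    filled.sort(axis=1)
    k = np.arange(1, m + 1)
    beta = stats.binom.sf(k - 1, m, filled)  # broadcasts row-wise
    rho = beta.min(axis=1)
    score = np.minimum(1.0, m * rho)
    out = pd.DataFrame({"rho": rho, "score": score},
                       index=mat.index.rename("item"))
    if lfc_table is not None:
        lfc = pd.DataFrame(lfc_table)
        out["mean_lfc"] = lfc.reindex(out.index).mean(axis=1)
    else:
        out["mean_lfc"] = np.nan
    out = out.reset_index().sort_values(["score", "item"]).set_index("item")
    return out


def select_robust(rra_up: pd.DataFrame, rra_down: pd.DataFrame,
                  score_cut: float = 0.05,
                  lfc_cut: float = 0.5) -> pd.DataFrame:
    """Combine up/down aggregations into a robust DE table with direction.

    Keeps items with score < ``score_cut`` and |mean_lfc| > ``lfc_cut``.
    An item passing in both directions indicates inconsistent inputs and
    raises.
    """

    def passing(rra: pd.DataFrame, sign: int) -> pd.DataFrame:
        ok = (rra["score"] < score_cut) & (sign * rra["mean_lfc"] > lfc_cut)
        return rra[ok]

    up = passing(rra_up, +1).assign(direction="up")
    down = passing(rra_down, -1).assign(direction="down")
    both = set(up.index) & set(down.index)
    if both:
        raise ValueError(f"items significant in both directions: {sorted(both)}")
    out = pd.concat([up, down])
    return out.reset_index().sort_values(["score", "item"]).set_index("item")
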