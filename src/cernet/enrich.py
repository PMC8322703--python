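"""Over-representation analysis (ORA) against gene-set collections.

The enrichment p-value for a set with K members in a universe of N genes,
given a query of n genes overlapping the set in k, is the hypergeometric
upper tail P(X >= k) — equivalent to a one-sided Fisher exact test on the
2x2 table.  Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, members = parts[0], parts[1], {g for g in parts[2:] if g}
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = (desc, members)
    return sets


def ora(query: set[str], gene_sets: dict[str, tuple[str, set[str]]],
        universe: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped with a warning; gene sets
    are clipped to the universe.  Returns a DataFrame (set, description,
    k, K, n, N, p, q, significant) sorted by p ascending.
    """
    stray = query - universe
    if stray:
        logger.warning("dropping %d query genes outside the universe", len(stray))
    query = query & universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")
    n, N = len(query), len(universe)
    rows = []
    for name, (desc, members) in gene_sets.items():
        members = members & universe
        if not members:
            continue
        k, K = len(query & members), len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "description": desc, "k": k, "K": K,
                     "n": n, "N": N, "p": min(p, 1.0)})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p"] < alpha
    return out.sort_values(["p", "set"]).reset_index(drop=True)
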