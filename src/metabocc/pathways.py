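"""Over-representation pathway analysis (hypergeometric test).

Given the set of annotated metabolites and a pathway collection over a
metabolite universe, each pathway is tested for excess overlap with the
query via the exact upper-tail hypergeometric probability
P(X >= k | N, K, n); p-values are BH-adjusted across pathways and a
pathway is flagged at q <= delta.  "Impact" is reported as the covered
fraction k/K of the pathway — an explicitly simple stand-in for
topology-weighted impact measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chemdb import PathwayDB, canonical_hmdb
from .univariate import bh_adjust


class OraError(ValueError):
    pass


def ora_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    N metabolites in the universe, K in the pathway, n in the query,
    k in both.
    """
    if N <= 0:
        raise OraError("empty universe")
    if not (0 <= k <= min(K, n)):
        raise OraError(f"impossible overlap k={k} for K={K}, n={n}")
    # sf(k-1) = P(X >= k); exact summation inside scipy's hypergeom
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query_metabolites,
    pathway_db: PathwayDB,
    delta: float = 0.15,
    universe=None,
) -> pd.DataFrame:
    """Hypergeometric ORA of a metabolite hit list over all pathways.

    The universe defaults to the pathway collection's own; query
    metabolites outside it are dropped with a warning.  Returns one row
    per pathway with >= 1 member in the universe, sorted by p, with BH
    q-values and a ``flagged`` column at q <= delta.
    """
    universe = frozenset(
        canonical_hmdb(m) for m in (universe if universe is not None else pathway_db.universe)
    )
    query = {canonical_hmdb(m) for m in query_metabolites}
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query metabolites outside the universe; dropped")
        query &= universe
    if not query:
        raise OraError("no annotated metabolites in the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in pathway_db.pathways.items():
        members = members & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        p = ora_test(k, K, n, N)
        rows.append((name, k, K, n, N, p, k / K))
    out = pd.DataFrame(
        rows, columns=["pathway", "hits", "size", "query_size", "universe_size", "p_value", "impact"]
    ).set_index("pathway")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["neg_log_p"] = -np.log10(out["p_value"])
    out["flagged"] = out["q_value"] <= delta
    return out.sort_values("p_value", kind="stable")
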