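"""Community breeding synchrony: pairwise correlation of annual mean dates.

For every species pair the Pearson correlation of annual mean clutch
initiation dates is computed over the shared years in which both species had
multiple nests monitored; two-sided p-values come from the t-transform of r
with n-2 degrees of freedom, and the family of dyad tests is controlled at
FDR 0.05 with the Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["pairwise_correlations", "bh_adjust"]


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, significant)`` where adjusted values are monotone
    (each >= its raw p) and ``significant = adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    ok = ~np.isnan(p)
    if ok.any() and (p[ok].min() < 0 or p[ok].max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    if ok.any():
        _, adj_ok, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = adj_ok
    sig = np.where(ok, adj <= q, False)
    return adj, sig


def pairwise_correlations(annual: pd.DataFrame, q: float = 0.05,
                          min_shared_years: int = 3) -> pd.DataFrame:
    """Dyad-level synchrony matrix (long form, one row per unordered pair).

    ``annual`` is the stacked per-species annual summary (columns ``species``,
    ``year``, ``mean``, ``multiple_nests``); only years with multiple nests
    qualify, and dyads sharing fewer than ``min_shared_years`` such years are
    reported with missing statistics.
    """
    usable = annual[annual["multiple_nests"]]
    series = {sp: g.set_index("year")["mean"]
              for sp, g in usable.groupby("species")}
    rows = []
    for a, b in combinations(sorted(series), 2):
        shared = series[a].index.intersection(series[b].index)
        if len(shared) < min_shared_years:
            rows.append({"species_a": a, "species_b": b,
                         "n_years": len(shared), "r": np.nan, "p_raw": np.nan})
            continue
        r, p = sps.pearsonr(series[a].loc[shared], series[b].loc[shared])
        rows.append({"species_a": a, "species_b": b, "n_years": len(shared),
                     "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        adj, sig = bh_adjust(out["p_raw"].to_numpy(), q=q)
        out["p_adj"], out["significant"] = adj, sig
    else:
        out["p_adj"], out["significant"] = [], []
    return out
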