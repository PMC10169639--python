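"""Genomic-context enrichment of a CpG set against the array universe.

For each region category, island-context level and the repeat flag, the
CpG set is tested against the universe with a two-sided Fisher exact test
on the (in set) x (in category) 2x2 table; p-values are BH-adjusted
across the tested categories.  Multi-category CpGs count once per
category (marginal per-category tests, not a partition chi-square) —
the convention behind array-context barplots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ISLAND_STATUSES, REGION_CATEGORIES, CpGAnnotation
from .diffmeth import bh_adjust


def context_enrichment(
    cpg_set: set,
    universe: set,
    annot: CpGAnnotation,
) -> pd.DataFrame:
    """Per-category over/under-representation of ``cpg_set`` in ``universe``.

    Returns a frame with one row per category: kind (region / island /
    repeat), counts and fractions in set and universe, the sample odds
    ratio (inf/nan sentinels for empty margins), two-sided Fisher p and
    BH-adjusted p.  Empty sets yield p = 1 everywhere.
    """
    cpg_set = set(cpg_set)
    universe = set(universe)
    if not cpg_set <= universe:
        extra = sorted(cpg_set - universe)[:5]
        raise ValueError(f"cpg_set is not a subset of the universe, e.g. {extra}")
    uni_ids = sorted(universe)
    sub = annot.for_cpgs(uni_ids)
    in_set = np.array([c in cpg_set for c in uni_ids])
    n_set = int(in_set.sum())
    n_uni = len(uni_ids)

    masks: list[tuple[str, str, np.ndarray]] = []
    for cat in sorted(REGION_CATEGORIES):
        masks.append(("region", cat, sub.has_category(cat).to_numpy()))
    status = sub.table["island_status"].to_numpy()
    for st in ISLAND_STATUSES:
        masks.append(("island", st, status == st))
    masks.append(("repeat", "repeat", sub.table["repeat_overlap"].to_numpy()))

    rows = []
    for kind, label, mask in masks:
        a = int((in_set & mask).sum())       # in set, in category
        b = n_set - a                        # in set, not category
        c = int(mask.sum()) - a              # category, not set
        d = n_uni - a - b - c
        if n_set == 0:
            orat, p = float("nan"), 1.0
        else:
            orat, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "kind": kind,
                "category": label,
                "count_in_set": a,
                "count_in_universe": a + c,
                "fraction_set": a / n_set if n_set else 0.0,
                "fraction_universe": (a + c) / n_uni if n_uni else 0.0,
                "odds_ratio": float(orat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
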