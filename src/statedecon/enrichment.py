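"""Fisher-exact enrichment of gene lists against named gene-set collections."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def restricted(self, universe: set[str]) -> dict[str, set[str]]:
        return {name: members & universe for name, members in self.sets.items()}


def fisher_enrichment(
    query: list[str], collection: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``query`` in each set of the collection.

    Sets are intersected with the universe before testing; the 2x2 table per
    set is (query∩set, query\\set, set\\query, neither).  P-values are
    Benjamini-Hochberg adjusted across sets; ``significant`` marks adjusted
    p < 0.05.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("query gene list is empty")
    uni = set(universe)
    stray = query_set - uni
    if stray:
        raise ValueError(f"query gene {sorted(stray)[0]!r} not in universe")

    rows = []
    for name, members in sorted(collection.restricted(uni).items()):
        a = len(query_set & members)
        b = len(query_set - members)
        c = len(members - query_set)
        d = len(uni) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(members), odds, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "odds_ratio", "p"])
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < 0.05
    return out.sort_values(["p", "set"]).reset_index(drop=True)
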