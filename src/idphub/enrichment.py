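"""Hypergeometric over-representation analysis with multiple-testing control.

Given a foreground protein set (e.g. the IDPs, or the disordered TFs), a
background universe and a term → protein map (GO terms, KEGG pathways or
the stress-pathway vocabulary), each term is tested for over-representation
of the foreground with an upper-tail hypergeometric test; p-values are
adjusted with Benjamini–Hochberg (default) or Bonferroni.  Only
over-representation is tested; depletion is out of scope.
"""

from __future__ import annotations

from collections.abc import Collection, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "benjamini_hochberg",
    "enrich",
    "read_term_map",
    "write_enrichment_table",
]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` proteins from a universe of ``N`` containing ``K``
    term members, the probability of seeing at least the observed ``k``
    members in the draw.  Evaluated through the survival function, which
    scipy computes stably (log-space internals) even in far tails.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_CORRECTIONS = {"fdr_bh", "bonferroni"}


@dataclass
class EnrichmentResult:
    """Term-level enrichment table plus the terms skipped for lack of background hits."""

    table: pd.DataFrame
    skipped_terms: list[str] = field(default_factory=list)


def enrich(
    foreground: Collection[str],
    background: Collection[str],
    term_map: Mapping[str, Collection[str]],
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    significance_on: str = "adjusted",
) -> EnrichmentResult:
    """Test every term for over-representation of ``foreground``.

    ``significance_on`` selects whether the ``alpha`` filter applies to the
    adjusted value (default) or the raw p-value.  Terms with no background
    member are skipped and listed in the result.  The returned table is
    sorted by raw p-value.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; choose from {sorted(_CORRECTIONS)}")
    if significance_on not in {"adjusted", "raw"}:
        raise ValueError("significance_on must be 'adjusted' or 'raw'")
    fg = set(foreground)
    bg = set(background)
    offenders = sorted(fg - bg)
    if offenders:
        raise ValueError(f"foreground ids outside background: {offenders}")
    if not term_map:
        raise ValueError("term_map is empty")

    N, n = len(bg), len(fg)
    rows = []
    skipped: list[str] = []
    for term, members in term_map.items():
        members_bg = set(members) & bg
        K = len(members_bg)
        if K == 0:
            skipped.append(term)
            continue
        k = len(members_bg & fg)
        rows.append((term, k, n, K, N, hypergeom_pvalue(k, K, n, N)))

    table = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_raw"])
    if len(table):
        if correction == "fdr_bh":
            table["q_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
        else:
            table["q_adj"] = np.minimum(table["p_raw"].to_numpy() * len(table), 1.0)
        crit = table["q_adj"] if significance_on == "adjusted" else table["p_raw"]
        table["significant"] = crit < alpha
        table = table.sort_values("p_raw", kind="stable").reset_index(drop=True)
    else:
        table["q_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(table=table, skipped_terms=skipped)


def read_term_map(path) -> dict[str, set[str]]:
    """Read a term-map TSV (term_id, term_label, protein_id) into {term: ids}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"term_id", "protein_id"} - set(df.columns)
    if missing:
        raise ValueError(f"term map {path}: missing columns {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for term, grp in df.groupby("term_id", sort=False):
        out[str(term)] = set(grp["protein_id"])
    return out


def write_enrichment_table(result: EnrichmentResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("# over-representation (upper-tail hypergeometric); sorted by p_raw\n")
        if result.skipped_terms:
            fh.write(f"# skipped terms with no background hits: {','.join(result.skipped_terms)}\n")
        result.table.to_csv(fh, sep="\t", index=False)
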