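"""Over-representation analysis of a ranked gene list against GMT gene sets.

Given the top-k symbols from a selection method and a collection of named
gene sets, each set is tested with the one-sided hypergeometric upper tail
(equivalently one-sided Fisher): for a universe of N symbols containing K
set members, the probability that a random list of n symbols overlaps the
set in at least the observed k members.  Sets with p below the significance
threshold (default 0.05) are reported sorted by p; no multiple-testing
adjustment is applied by default, with Benjamini–Hochberg available as an
option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .data_model import DataError, GeneSetCollection


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int  # k: list ∩ set
    set_size: int  # K within the universe
    list_size: int  # n within the universe
    universe_size: int  # N
    p_value: float
    overlapping_symbols: tuple[str, ...]


def map_probes(features: list[str], probe_map: dict[str, str]) -> list[str]:
    """Map probe IDs to gene symbols; drop unmapped probes, collapse duplicates.

    Order follows the input list (first occurrence wins for duplicated
    symbols, so a ranked probe list stays ranked after mapping).
    """
    symbols: list[str] = []
    seen: set[str] = set()
    unmapped = 0
    for probe in features:
        sym = probe_map.get(probe)
        if sym is None or not sym or sym == "-":
            unmapped += 1
            continue
        if sym not in seen:
            seen.add(sym)
            symbols.append(sym)
    if unmapped:
        warnings.warn(f"{unmapped} probe(s) had no symbol mapping and were dropped")
    if not symbols:
        raise DataError("no probes could be mapped to symbols")
    return symbols


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    gene_list: list[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    universe: set[str] | None = None,
    bh: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    The universe defaults to the collection's own universe; list symbols
    outside the universe are dropped with a warning.  Rows with p < alpha
    are returned sorted ascending by p (ties by set name, so output is
    reproducible byte for byte).  With ``bh=True`` the cutoff is applied to
    Benjamini–Hochberg adjusted p-values instead.
    """
    uni = frozenset(universe) if universe is not None else sets.universe
    if not uni:
        raise DataError("empty universe")
    listed = [g for g in dict.fromkeys(gene_list)]
    if not listed:
        raise DataError("empty gene list")
    inside = [g for g in listed if g in uni]
    if len(inside) < len(listed):
        warnings.warn(
            f"{len(listed) - len(inside)} list symbol(s) outside the universe dropped"
        )
    if not inside:
        raise DataError("no list symbols in the universe")
    N = len(uni)
    n = len(inside)
    list_set = set(inside)

    rows: list[EnrichmentRow] = []
    for name, genes in sets.sets:
        genes_u = genes & uni
        if not genes_u:
            continue
        overlap = sorted(genes_u & list_set)
        p = hypergeom_pvalue(len(overlap), N, len(genes_u), n)
        rows.append(
            EnrichmentRow(
                set_name=name,
                overlap=len(overlap),
                set_size=len(genes_u),
                list_size=n,
                universe_size=N,
                p_value=p,
                overlapping_symbols=tuple(overlap),
            )
        )
    if bh and rows:
        ps = sorted((r.p_value, r.set_name) for r in rows)
        m = len(rows)
        # BH step-up: adjusted p = min over j>=i of p_(j)*m/j
        adj: dict[str, float] = {}
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, ps[i][0] * m / (i + 1))
            adj[ps[i][1]] = running
        rows = [r for r in rows if adj[r.set_name] < alpha]
    else:
        rows = [r for r in rows if r.p_value < alpha]
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in rows],
            "overlap": [r.overlap for r in rows],
            "set_size": [r.set_size for r in rows],
            "list_size": [r.list_size for r in rows],
            "universe_size": [r.universe_size for r in rows],
            "p_value": [r.p_value for r in rows],
            "genes": [",".join(r.overlapping_symbols) for r in rows],
        }
    )
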