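"""Target-gene mapping and gene-set over-representation analysis.

Candidate miRNAs are mapped to target genes through a user-supplied
interaction table (any two-column miRNA -> gene map; no database content
is bundled), and each gene set of a GMT collection is tested for
over-representation of the target list with a hypergeometric upper-tail
test on the 2x2 table (optionally the conservative EASE variant that
subtracts one from the overlap).  Reported per set: overlap count,
percent of the list, fold enrichment relative to the background rate,
raw p and Bonferroni-adjusted p.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def read_target_map(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns ``mirna_id`` and ``gene_symbol``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("mirna_id", "gene_symbol") if c not in df.columns]
    if missing:
        raise ValueError(f"target map missing columns: {missing}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def map_targets(
    mirna_ids: Sequence[str], target_map: pd.DataFrame
) -> list[str]:
    """Sorted union of target genes of the given miRNAs.

    miRNAs absent from the map contribute nothing (with a warning).
    """
    if len(target_map) == 0:
        raise ValueError("target map is empty")
    known = set(target_map["mirna_id"])
    absent = [m for m in mirna_ids if m not in known]
    if absent:
        warnings.warn(
            f"miRNAs absent from target map: {absent}", RuntimeWarning
        )
    mask = target_map["mirna_id"].isin(set(mirna_ids))
    return sorted(set(target_map.loc[mask, "gene_symbol"]))


def enrich(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    ``background`` defaults to the union of all genes in the collection;
    gene sets (and the list) are intersected with it.  For a set with K
    background members and a list of n genes with overlap k out of N
    background genes, p = P(X >= k) hypergeometric (EASE: P(X >= k) with
    k reduced by one; a non-positive reduced overlap gives p = 1), fold
    enrichment = (k/n)/(K/N), Bonferroni = min(1, p * number of sets
    tested).  Rows are sorted by p.
    """
    gene_sets = {name: set(genes) for name, genes in gene_sets.items()}
    if background is None:
        background = set().union(*gene_sets.values()) if gene_sets else set()
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    gene_list = set(gene_list) & background
    n = len(gene_list)
    N = len(background)
    m = len(gene_sets)

    rows = []
    for name, genes in gene_sets.items():
        genes = genes & background
        K = len(genes)
        k = len(gene_list & genes)
        if n == 0 or K == 0:
            p = 1.0
        elif ease:
            p = 1.0 if k - 1 <= 0 else float(hypergeom.sf(k - 2, N, K, n))
        else:
            p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        rows.append(
            {
                "term": name,
                "count": k,
                "percent": 100.0 * k / n if n else 0.0,
                "p_value": min(p, 1.0),
                "fold_enrichment": fold,
                "bonferroni": min(1.0, p * m),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["p_value", "term"], kind="stable"
    ).set_index("term")
    return out
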