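"""Over-representation analysis of circRNA source genes.

One-tailed hypergeometric test of a selected gene list against GO/KEGG-style
term annotations, with Benjamini–Hochberg adjustment within each category.
The universe defaults to the caller's detected source-gene set (standard
practice for a derived list); genes annotated to a term but absent from the
universe are dropped before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class InputError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """gene → term mapping plus term descriptions.

    ``gene_terms``: DataFrame with columns gene_id, term_id.
    ``terms``: DataFrame with columns term_id, name, category.
    """

    gene_terms: pd.DataFrame
    terms: pd.DataFrame

    @classmethod
    def from_tsv(cls, gene_term_path: str | Path,
                 term_desc_path: str | Path | None = None) -> "AnnotationMap":
        gt = pd.read_csv(gene_term_path, sep="\t", header=0,
                         names=["gene_id", "term_id"], usecols=[0, 1])
        if term_desc_path is not None:
            terms = pd.read_csv(term_desc_path, sep="\t", header=0,
                                names=["term_id", "name", "category"],
                                usecols=[0, 1, 2])
        else:
            ids = gt["term_id"].drop_duplicates()
            terms = pd.DataFrame(
                {"term_id": ids, "name": ids, "category": "unspecified"}
            )
        return cls(gene_terms=gt, terms=terms)

    def term_sets(self) -> dict[str, set[str]]:
        return {
            term: set(sub["gene_id"])
            for term, sub in self.gene_terms.groupby("term_id")
        }

    def term_info(self) -> dict[str, tuple[str, str]]:
        return {
            row.term_id: (row.name_, row.category)
            for row in self.terms.rename(columns={"name": "name_"}).itertuples()
        }


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    category: str
    k: int  # selected genes carrying the term
    n: int  # selected genes
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float  # hypergeometric upper tail P[X >= k]
    q: float  # BH-adjusted within category


def enrich(
    selected_genes,
    universe_genes,
    annotation: AnnotationMap,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation per term, sorted by p.

    p = P[X ≥ k] for X ~ Hypergeom(N, K, n); BH adjustment is applied
    across the tested terms of each category separately.
    """
    selected = set(selected_genes)
    universe = set(universe_genes)
    if not universe:
        raise InputError("empty universe")
    stray = selected - universe
    if stray:
        raise InputError(f"selected genes absent from universe: {sorted(stray)}")
    N, n = len(universe), len(selected)
    info = annotation.term_info()

    results = []
    for term, genes in sorted(annotation.term_sets().items()):
        members = genes & universe
        K = len(members)
        if K == 0:
            continue  # no annotated universe gene: nothing to test
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        name, category = info.get(term, (term, "unspecified"))
        results.append(
            EnrichmentResult(term_id=term, name=name, category=category,
                             k=k, n=n, K=K, N=N, p=min(1.0, p), q=1.0)
        )

    # BH within category
    by_cat: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_cat.setdefault(r.category, []).append(r)
    for cat_results in by_cat.values():
        pvals = [r.p for r in cat_results]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(cat_results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "name": [r.name for r in results],
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
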