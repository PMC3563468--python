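"""Module validation: expression coherence and function-term enrichment.

Coherence of a module is the mean of all pairwise Pearson correlation
coefficients among its member gene profiles.  Functional consistency is
tested per term by the upper-tail hypergeometric probability of observing at
least the module's hit count, with Benjamini–Hochberg adjustment across the
tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, GnetError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """gene -> set of function-term ids, with an explicit background.

    A probe mapping to several genes is represented by one TSV row per
    mapped gene, so all corresponding genes are counted.
    """

    gene_to_terms: dict = field(default_factory=dict)
    term_names: dict = field(default_factory=dict)
    background_gene_ids: set = field(default_factory=set)

    def __post_init__(self):
        missing = set(self.gene_to_terms) - self.background_gene_ids
        if missing:
            raise GnetError(
                f"{len(missing)} annotated gene(s) missing from background")

    @property
    def n_background(self) -> int:
        return len(self.background_gene_ids)

    def term_genes(self, term: str) -> set:
        return {g for g, ts in self.gene_to_terms.items() if term in ts}

    @classmethod
    def from_tsv(cls, path, background=None) -> "AnnotationTable":
        """Read TSV with columns gene_id, term_id[, term_name].

        If ``background`` is None the background is the set of genes
        appearing in the table.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("gene_id", "term_id"):
            if col not in df.columns:
                raise GnetError(f"annotation table missing column {col}")
        g2t: dict = {}
        names: dict = {}
        for row in df.itertuples(index=False):
            g2t.setdefault(row.gene_id, set()).add(row.term_id)
            if hasattr(row, "term_name") and isinstance(row.term_name, str):
                names[row.term_id] = row.term_name
        bg = set(background) if background is not None else set(g2t)
        return cls(g2t, names, bg)

    def to_tsv(self, path) -> None:
        rows = [(g, t, self.term_names.get(t, ""))
                for g in sorted(self.gene_to_terms)
                for t in sorted(self.gene_to_terms[g])]
        pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

def mean_pairwise_correlation(matrix: ExpressionMatrix, gene_ids) -> float:
    """Mean Pearson r over all unordered member pairs.

    Pairs involving a zero-variance profile (correlation undefined)
    contribute 0 and are logged.
    """
    ids = list(gene_ids)
    if len(ids) < 2:
        raise GnetError("coherence requires at least 2 genes")
    rows = np.vstack([matrix.row(g) for g in ids])
    sd = rows.std(axis=1)
    ok = sd > 0
    if (~ok).any():
        logger.warning("%d zero-variance gene(s) contribute correlation 0",
                       int((~ok).sum()))
    n_pairs = len(ids) * (len(ids) - 1) // 2
    if ok.sum() < 2:
        return 0.0
    c = np.corrcoef(rows[ok])
    iu = np.triu_indices(int(ok.sum()), k=1)
    return float(np.sum(c[iu]) / n_pairs)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric test of one term in one module."""

    term_id: str
    term_name: str
    module_hits: int          # a
    module_size: int          # n
    background_hits: int      # K
    background_size: int      # N
    p_value: float
    adjusted_p: float = float("nan")


def hypergeom_enrichment(module_genes, annotations: AnnotationTable,
                         min_hits: int = 3) -> list[EnrichmentResult]:
    """Enrichment of every term with >= ``min_hits`` hits in the module.

    p = P(X >= a) for X ~ Hypergeom(N, K, n) with N the background size,
    K the term's background count, n the module size, a the module hit
    count.  Results carry BH-adjusted p-values and are sorted ascending
    by raw p (ties by term id).
    """
    genes = set(module_genes)
    outside = genes - annotations.background_gene_ids
    if outside:
        raise GnetError(f"module gene(s) outside background: {sorted(outside)[:5]}")
    N = annotations.n_background
    n = len(genes)
    term_hits: dict[str, int] = {}
    term_K: dict[str, int] = {}
    for g, terms in annotations.gene_to_terms.items():
        in_module = g in genes
        for t in terms:
            term_K[t] = term_K.get(t, 0) + 1
            if in_module:
                term_hits[t] = term_hits.get(t, 0) + 1
    results = []
    for t, K in term_K.items():
        a = term_hits.get(t, 0)
        if a < min_hits:
            continue
        p = float(hypergeom.sf(a - 1, N, K, n))
        results.append(EnrichmentResult(t, annotations.term_names.get(t, ""),
                                        a, n, K, N, min(p, 1.0)))
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def summarize_modules(fit_result, annotations: AnnotationTable | None = None,
                      min_hits: int = 3) -> pd.DataFrame:
    """Per-module report: coherence, sizes, tree TFs, top enriched term."""
    matrix = fit_result.model.matrix
    rows = []
    for m in fit_result.modules:
        rec = {"module_id": m.module_id,
               "n_genes": m.n_genes,
               "n_tfs": len(m.tree.tf_ids) if m.tree else 0,
               "tfs": ",".join(sorted(m.tree.tf_ids)) if m.tree else "",
               "coherence": m.coherence,
               "log_likelihood": m.log_likelihood,
               "top_term": "", "top_term_name": "",
               "top_term_p": np.nan, "top_term_adj_p": np.nan}
        if annotations is not None and annotations.gene_to_terms:
            inside = [g for g in m.gene_ids
                      if g in annotations.background_gene_ids]
            enr = hypergeom_enrichment(inside, annotations, min_hits) \
                if inside else []
            if enr:
                top = enr[0]
                rec.update(top_term=top.term_id, top_term_name=top.term_name,
                           top_term_p=top.p_value,
                           top_term_adj_p=top.adjusted_p)
        rows.append(rec)
    return pd.DataFrame(rows)


def coherence_histogram(fit_result, bins=None) -> pd.DataFrame:
    """Histogram of module coherences (bin edges and counts), TSV-ready."""
    edges = np.asarray(bins) if bins is not None else np.linspace(-1, 1, 21)
    coh = [m.coherence for m in fit_result.modules
           if np.isfinite(m.coherence)]
    counts, edges = np.histogram(coh, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "n_modules": counts})
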