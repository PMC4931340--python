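"""Gene-set enrichment, membrane classes and conservation summaries.

Enrichment of a term in a gene set is quantified as the ratio of its
frequency in the set to its frequency in the genome, with a one-sided
(over-representation) hypergeometric p-value and Benjamini–Hochberg
adjustment across terms.  Membrane classes partition proteins by their
signal-peptide and transmembrane predictions.  The summary builders
tally conservation categories, expression-divergence patterns, domain
families and the limited-conservation gene table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io_formats import DICTYOSTELIDS, UNICELLULAR_AMOEBOZOA
from .expression import PATTERNS


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    set_count: int  # k: genes in set annotated with term
    set_size: int  # n
    genome_count: int  # K
    genome_size: int  # N
    factor: float
    pvalue: float
    adjusted_pvalue: float = math.nan


def enrichment_factor(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): frequency in set over frequency in genome.

    Undefined (NaN) when the term never occurs in the genome.
    """
    if n <= 0 or N <= 0:
        raise ValueError("set and genome sizes must be positive")
    if K == 0:
        return math.nan
    return (k / n) / (K / N)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("invalid urn parameters")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k < 0:
        raise ValueError("k must be >= 0")
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


def propagate_terms(gene_terms: dict[str, set], ontology_edges=None) -> dict[str, set]:
    """Propagate annotations to ancestor terms (child -> parents edges)."""
    if not ontology_edges:
        return {g: set(t) for g, t in gene_terms.items()}
    parents: dict[str, set] = {}
    for child, parent in ontology_edges:
        parents.setdefault(child, set()).add(parent)

    def ancestors(term, seen):
        for p in parents.get(term, ()):  # cycles tolerated via seen-set
            if p not in seen:
                seen.add(p)
                ancestors(p, seen)
        return seen

    out = {}
    for g, terms in gene_terms.items():
        full = set(terms)
        for t in terms:
            full |= ancestors(t, set())
        out[g] = full
    return out


def go_enrichment(set_genes, genome_records, ontology_edges=None,
                  propagate: bool = True) -> list[EnrichmentRow]:
    """Over-representation of GO terms in a gene set vs the genome."""
    gene_terms = {r.id: set(r.go_terms) for r in genome_records}
    if propagate:
        gene_terms = propagate_terms(gene_terms, ontology_edges)
    set_ids = [g for g in set_genes if g in gene_terms]
    N, n = len(gene_terms), len(set_ids)
    terms = sorted({t for ts in gene_terms.values() for t in ts})
    rows = []
    for term in terms:
        K = sum(1 for ts in gene_terms.values() if term in ts)
        k = sum(1 for g in set_ids if term in gene_terms[g])
        rows.append(EnrichmentRow(
            term, k, n, K, N,
            factor=enrichment_factor(k, n, K, N),
            pvalue=hypergeom_pvalue(k, n, K, N)))
    adjusted = adjust_pvalues([r.pvalue for r in rows])
    return [EnrichmentRow(r.term, r.set_count, r.set_size, r.genome_count,
                          r.genome_size, r.factor, r.pvalue, adj)
            for r, adj in zip(rows, adjusted)]


MEMBRANE_CLASSES = ("soluble", "tm_only", "sigp_only", "both")


def membrane_classify(records) -> tuple[dict[str, str], dict]:
    """Class per protein from its SigP/TM flags, plus set percentages.

    The summary reports the percentage of proteins with SigP or TM
    (secreted or exposed) and with both; empty input is flagged
    undefined.
    """
    classes = {}
    for r in records:
        if r.sigp and r.tm:
            cls = "both"
        elif r.sigp:
            cls = "sigp_only"
        elif r.tm:
            cls = "tm_only"
        else:
            cls = "soluble"
        classes[r.id] = cls
    n = len(classes)
    if n == 0:
        summary = {"n": 0, "pct_sigp_or_tm": math.nan, "pct_both": math.nan,
                   "undefined": True}
    else:
        n_any = sum(1 for c in classes.values() if c != "soluble")
        n_both = sum(1 for c in classes.values() if c == "both")
        summary = {"n": n, "pct_sigp_or_tm": 100.0 * n_any / n,
                   "pct_both": 100.0 * n_both / n, "undefined": False}
    return classes, summary


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def conservation_percentages(profiles) -> dict:
    """Percent of genes conserved over 1-5 dictyostelid genomes.

    For each x in 1..5 reports the percentage of focal genes with
    orthologs in exactly x dictyostelid genomes (the focal genome
    counts as one), and the analogous series for homologs with
    conserved domain architecture and with conserved expression.
    Also tallies presence per unicellular amoebozoan genome.
    """
    n = len(profiles)
    orth = {x: 0 for x in range(1, 6)}
    dom = {x: 0 for x in range(1, 6)}
    expr = {x: 0 for x in range(1, 6)}
    uni = {sp: 0 for sp in UNICELLULAR_AMOEBOZOA}
    present_calls = ("ortholog", "paralog", "homolog_unresolved")
    for prof in profiles:
        focal_sp = "DD"
        n_orth = n_dom = n_expr = 1  # the focal genome itself
        for sp in DICTYOSTELIDS:
            if sp == focal_sp:
                continue
            call = prof.calls.get(sp)
            callname = call.call if hasattr(call, "call") else (call or "absent")
            present = callname in present_calls
            if callname == "ortholog":
                n_orth += 1
            if present and prof.domain_conserved.get(sp, False):
                n_dom += 1
            if present and not prof.expression_divergent.get(sp, False):
                n_expr += 1
        orth[min(n_orth, 5)] += 1
        dom[min(n_dom, 5)] += 1
        expr[min(n_expr, 5)] += 1
        for sp in UNICELLULAR_AMOEBOZOA:
            call = prof.calls.get(sp)
            callname = call.call if hasattr(call, "call") else (call or "absent")
            if callname in present_calls:
                uni[sp] += 1
    pct = lambda c: {k: (100.0 * v / n if n else math.nan) for k, v in c.items()}
    return {
        "n_genes": n,
        "ortholog_pct": pct(orth),
        "domain_conserved_pct": pct(dom),
        "expression_conserved_pct": pct(expr),
        "unicellular_presence_pct": pct(uni),
    }


def divergence_distribution(results) -> dict[str, int]:
    """Counts of expression-divergence patterns across genes."""
    counts = {p: 0 for p in PATTERNS}
    for r in results:
        counts[r.pattern] += 1
    return counts


def family_counts(records, domain_pairs) -> dict:
    """Count proteins carrying either or both domains of each pair.

    Per species and domain pair, proteins with both domains are counted
    once under 'both' and excluded from the single-domain counts.
    """
    out: dict = {}
    for first, second in domain_pairs:
        per_species: dict = {}
        for r in records:
            has1 = first in r.architecture
            has2 = second in r.architecture
            if not (has1 or has2):
                continue
            slot = per_species.setdefault(
                r.species, {"first_only": 0, "second_only": 0, "both": 0})
            if has1 and has2:
                slot["both"] += 1
            elif has1:
                slot["first_only"] += 1
            else:
                slot["second_only"] += 1
        out[(first, second)] = per_species
    return out


def limited_conservation_table(profiles, records) -> dict:
    """Genes confined to DD, group 4 or branch II, with S/T annotation.

    Returns the rows (gene, S/T label, Only category) and a summary:
    row count, count with a signal peptide or transmembrane domain and
    the percentage (rounded to the nearest integer, half away from
    zero) — the secreted-or-exposed fraction of the limited-
    conservation set.
    """
    by_id = {r.id: r for r in records}
    rows = []
    for prof in sorted(profiles, key=lambda p: p.focal):
        cat = prof.category
        only = cat.only if cat is not None else None
        if only not in ("DD", "4", "II"):
            continue
        rec = by_id.get(prof.focal)
        if rec is None:
            st = "-"
        elif rec.sigp and rec.tm:
            st = "S+T"
        elif rec.sigp:
            st = "S"
        elif rec.tm:
            st = "T"
        else:
            st = "-"
        rows.append({"gene": prof.focal, "s_t": st, "only": only})
    n = len(rows)
    n_st = sum(1 for r in rows if r["s_t"] != "-")
    return {
        "rows": rows,
        "n_rows": n,
        "n_sigp_or_tm": n_st,
        "pct_sigp_or_tm": _round_half_away(100.0 * n_st / n) if n else math.nan,
    }
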