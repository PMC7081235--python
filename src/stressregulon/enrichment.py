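"""Gene-set enrichment: hypergeometric and permutation tests, TF-family
summaries, temporal wave grouping, and network-module co-occurrence.

Two tail conventions appear in this field and both are provided:

* ``hypergeom_tail`` — the inclusive upper tail P(X >= x), the textbook
  over-representation p-value, used for annotation/TFBS enrichment.
* The *exceedance* tail P(X > x) (the upper tail of R's ``phyper`` without
  the off-by-one shift), used by :func:`module_enrichment` for the batch
  module co-occurrence test with a Bonferroni correction over all gene-set x
  module combinations tested together.

The permutation test draws uniform query-sized subsets of the background and
uses the add-one estimator ``(1 + #{perm >= obs}) / (1 + n_perm)`` so the
empirical p-value is never zero; ties count as exceeding (conservative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import hypergeom, spearmanr

from .core_io import AnnotationMap, GeneSet, ValidationError
from .diffexp import bh_adjust


def _check_hypergeom_args(x: int, K: int, n: int, N: int) -> None:
    for name, v in (("x", x), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name}={v} must be a non-negative integer")
    if K > N or n > N:
        raise ValidationError(f"K={K} and n={n} must not exceed N={N}")
    if x > min(K, n):
        raise ValidationError(f"x={x} exceeds min(K={K}, n={n})")


def hypergeom_tail(x: int, K: int, n: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N population, K successes, n draws)."""
    _check_hypergeom_args(x, K, n, N)
    if x == 0:
        return 1.0
    # sf(x-1) = P(X > x-1) = P(X >= x); scipy evaluates the sum in a
    # numerically safe way (log-gamma based pmf terms)
    return float(hypergeom.sf(x - 1, N, K, n))


def hypergeom_exceedance(x: int, K: int, n: int, N: int) -> float:
    """P(X > x): the strict upper tail."""
    _check_hypergeom_args(x, K, n, N)
    return float(hypergeom.sf(x, N, K, n))


def _overlap_table(query: GeneSet, background: GeneSet,
                   annotation: AnnotationMap) -> pd.DataFrame:
    extra = query.genes - background.genes
    if extra:
        raise ValidationError(
            f"query genes outside background: {sorted(extra)[:10]}")
    restricted = annotation.restricted_to(background.genes)
    rows = []
    for term in restricted.terms:
        targets = restricted.targets[term]
        rows.append({
            "term": term,
            "family": (restricted.family or {}).get(term),
            "K": len(targets),
            "n": len(query.genes),
            "x": len(targets & query.genes),
            "N": len(background.genes),
        })
    return pd.DataFrame(rows, columns=["term", "family", "K", "n", "x", "N"])


def enrich_annotation(query: GeneSet, background: GeneSet,
                      annotation: AnnotationMap, alpha: float = 0.01,
                      correction: str = "bh") -> pd.DataFrame:
    """Hypergeometric over-representation of every term in the query set.

    Term target sets are intersected with the background before testing.
    ``correction`` is one of {"bh", "bonferroni", "none"}; significance is
    assessed on the corrected p (raw p when correction is "none").
    """
    table = _overlap_table(query, background, annotation)
    if table.empty:
        return table.assign(p_raw=[], p_adj=[], significant=[])
    p_raw = np.array([hypergeom_tail(r.x, r.K, r.n, r.N)
                      for r in table.itertuples()])
    if correction == "bh":
        p_adj = bh_adjust(p_raw)
    elif correction == "bonferroni":
        p_adj = np.minimum(p_raw * len(p_raw), 1.0)
    elif correction == "none":
        p_adj = p_raw.copy()
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return table.assign(p_raw=p_raw, p_adj=p_adj, significant=p_adj < alpha)


def permutation_enrich(query: GeneSet, background: GeneSet,
                       annotation: AnnotationMap, n_perm: int = 10_000,
                       alpha: float = 0.05, seed: int = 0,
                       chunk: int = 2_000) -> pd.DataFrame:
    """Permutation-null enrichment for small backgrounds.

    Overlap of each term with ``n_perm`` uniformly drawn query-sized subsets
    of the background; ``p_emp = (1 + #{perm overlap >= observed}) /
    (1 + n_perm)``.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if len(query.genes) > len(background.genes):
        raise ValidationError("query larger than background")
    table = _overlap_table(query, background, annotation)
    if table.empty:
        return table.assign(p_raw=[], p_adj=[], significant=[])
    bg = sorted(background.genes)
    pos = {g: i for i, g in enumerate(bg)}
    n_bg, n_query = len(bg), len(query.genes)
    restricted = annotation.restricted_to(background.genes)
    member = np.zeros((len(table), n_bg), dtype=np.float32)
    for row_i, term in enumerate(table["term"]):
        for g in restricted.targets[term]:
            member[row_i, pos[g]] = 1.0

    observed = table["x"].to_numpy()
    exceed = np.zeros(len(table), dtype=np.int64)
    rng = np.random.default_rng(seed)
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        # m uniform subsets of size n_query: first n_query of random orderings
        order = np.argsort(rng.random((m, n_bg)), axis=1)[:, :n_query]
        indicator = np.zeros((n_bg, m), dtype=np.float32)
        indicator[order.T, np.arange(m)[None, :].repeat(n_query, axis=0)] = 1.0
        overlaps = member @ indicator  # terms x m
        exceed += (overlaps >= observed[:, None]).sum(axis=1)
    p_emp = (1.0 + exceed) / (1.0 + n_perm)
    return table.assign(p_raw=p_emp, p_adj=p_emp, significant=p_emp < alpha)


def summarize_families(results: pd.DataFrame,
                       family: dict[str, str] | None = None,
                       allow_unassigned: bool = False) -> pd.DataFrame:
    """Per-family counts of significant terms among tested terms.

    ``results`` is an enrichment table with ``term`` and ``significant``
    columns and (optionally) a ``family`` column; an explicit ``family`` map
    overrides it.  Terms without a family label raise unless
    ``allow_unassigned``, in which case they are pooled under "unassigned".
    """
    if results.empty:
        return pd.DataFrame(columns=["family", "n_significant",
                                     "family_size", "proportion"])
    fam = results["term"].map(family) if family is not None else (
        results["family"] if "family" in results.columns
        else pd.Series(index=results.index, dtype=object))
    if fam.isna().any():
        if not allow_unassigned:
            missing = results.loc[fam.isna(), "term"].tolist()
            raise ValidationError(f"terms without family label: {missing[:10]}")
        fam = fam.fillna("unassigned")
    out = (results.assign(family=fam)
           .groupby("family", sort=True)
           .agg(n_significant=("significant", "sum"),
                family_size=("term", "size"))
           .reset_index())
    out["n_significant"] = out["n_significant"].astype(int)
    out["proportion"] = out["n_significant"] / out["family_size"]
    return out


_WAVE_CONTEXTS = {"up": ("early_up", "late_up"),
                  "down": ("early_down", "late_down")}


def wave_groups(summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Temporal grouping of TF families across the four regulon contexts.

    Within the UP contexts, a family with significant members only in
    EARLY UP is "early-only", in both "early-and-late", only in LATE UP
    "late-only"; analogous labels are computed independently for the DOWN
    contexts.  Families significant nowhere are omitted.
    """
    sig: dict[str, dict[str, int]] = {}
    for context, table in summaries.items():
        for row in table.itertuples():
            sig.setdefault(row.family, {})[context] = int(row.n_significant)
    rows = []
    for family in sorted(sig):
        labels = {}
        for direction, (early_ctx, late_ctx) in _WAVE_CONTEXTS.items():
            early = sig[family].get(early_ctx, 0) > 0
            late = sig[family].get(late_ctx, 0) > 0
            if early and late:
                labels[direction] = "early-and-late"
            elif early:
                labels[direction] = "early-only"
            elif late:
                labels[direction] = "late-only"
            else:
                labels[direction] = None
        if labels["up"] is None and labels["down"] is None:
            continue
        rows.append({"family": family, "up_group": labels["up"],
                     "down_group": labels["down"]})
    return pd.DataFrame(rows, columns=["family", "up_group", "down_group"])


def module_enrichment(query: GeneSet, modules: AnnotationMap,
                      population: GeneSet, m_tests: int,
                      tail: str = "inclusive") -> pd.DataFrame:
    """Bonferroni-corrected module co-occurrence test for one query set.

    Per module: ``p_adj = min(1, m_tests * tail_p(x, K, n, N))`` with N the
    population size, K the module's genes within the population, n the query
    size and x the observed overlap.  ``m_tests`` should be the total number
    of tests in the batch (number of query sets x number of modules).  The
    default inclusive tail P(X >= x) is the standard over-representation
    p-value and never degenerates; ``tail="exceedance"`` selects P(X > x),
    the convention of R's ``phyper(x, ..., lower.tail = FALSE)`` used by the
    batch co-occurrence workflow this pipeline reproduces (note it is 0 when
    the overlap saturates, so it is only meaningful with a Bonferroni batch).
    """
    if m_tests < 1:
        raise ValidationError("m_tests must be >= 1")
    tail_fn = {"exceedance": hypergeom_exceedance,
               "inclusive": hypergeom_tail}.get(tail)
    if tail_fn is None:
        raise ValidationError(f"unknown tail {tail!r}")
    table = _overlap_table(query, population, modules)
    if table.empty:
        return table.assign(p_raw=[], p_adj=[], significant=[])
    p_raw = np.array([tail_fn(r.x, r.K, r.n, r.N) for r in table.itertuples()])
    p_adj = np.minimum(p_raw * m_tests, 1.0)
    return (table.rename(columns={"term": "module"})
            .assign(p_raw=p_raw, p_adj=p_adj, significant=p_adj < 0.05))


def focus_modules(enrichments: pd.DataFrame, module_sizes: dict[str, int],
                  p_cut: float = 1e-5, min_size: int = 50) -> pd.DataFrame:
    """Modules passing both the p-value and the module-size cut-off, sorted by p."""
    if enrichments.empty:
        return enrichments
    sizes = enrichments["module"].map(module_sizes)
    keep = (enrichments["p_adj"] <= p_cut) & (sizes >= min_size)
    return (enrichments.loc[keep]
            .assign(module_size=sizes[keep])
            .sort_values("p_adj", kind="stable")
            .reset_index(drop=True))


def detect_modules_simple(matrix, corr_cut: float = 0.8) -> AnnotationMap:
    """Plumbing stand-in module detector: thresholded |Spearman| components.

    Builds a graph connecting gene pairs with absolute Spearman correlation
    >= ``corr_cut`` over samples and returns connected components of size
    >= 2 as modules (singletons unassigned).  Constant genes are excluded
    with a warning.  Deterministic; module ids follow the lexicographically
    smallest member.
    """
    import warnings

    values = matrix.values
    genes = list(matrix.genes)
    if values.shape[1] < 3:
        raise ValidationError("need >= 3 samples to correlate")
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant gene(s) from "
                      "module detection", stacklevel=2)
    values = values[keep]
    genes = [g for g, k in zip(genes, keep) if k]
    if len(genes) < 2:
        return AnnotationMap(targets={})
    rho = spearmanr(values, axis=1).statistic
    rho = np.atleast_2d(rho)
    adj = (np.abs(rho) >= corr_cut)
    np.fill_diagonal(adj, False)
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(adj), directed=False)
    order = np.argsort(np.asarray(genes, dtype=object))
    targets: dict[str, frozenset[str]] = {}
    seen: dict[int, str] = {}
    for i in order:
        comp = labels[i]
        members = [genes[j] for j in np.flatnonzero(labels == comp)]
        if len(members) < 2 or comp in seen:
            continue
        seen[comp] = f"M{len(seen) + 1}"
        targets[seen[comp]] = frozenset(members)
    return AnnotationMap(targets=targets)
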