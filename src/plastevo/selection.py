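"""Gene-, site- and branch-level selection analysis with a consensus rule.

Gene-wide Kn/Ks uses the Nei–Gojobori (1986) counting method: fractional
synonymous/nonsynonymous site counts per codon (mutations to stop codons
discarded), pathway averaging with equal weights over stop-free orderings
for codons differing at more than one position, Jukes–Cantor correction of
the proportions, averaged over all unordered sequence pairs.

Two independent site-level detectors are then combined:

* **method A (counting test)** — ancestral codons by 61-state Fitch
  parsimony; per-branch changes classified syn/nonsyn with pathway
  averaging; a one-sided binomial tail compares the nonsynonymous count
  against the neutral expectation given the site's syn/nonsyn opportunity.
* **method B (empirical-Bayes grid)** — a 20x20 grid of synonymous and
  nonsynonymous rates (alpha, beta) on [0, 5]; per-site likelihoods by
  Felsenstein pruning under an MG94-style codon model with fixed branch
  lengths; grid weights fitted by EM; the per-site posterior mass on
  beta > alpha is the evidence for positive selection.

A site counts as selected only when flagged by **both** methods.  Branch
screening reports branches whose aggregated Kn/Ks exceeds 1 with at least
3 reconstructed substitutions (a screen, not a likelihood-ratio test).
Ontology enrichment compares selected/non-selected site ratios between the
seven functional gene groups by two-sided Fisher exact tests with
Holm–Bonferroni step-down adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import fisher_exact

from . import codons
from .codon_align import GeneAlignment
from .phylo import CompiledTree, fitch_sets

logger = logging.getLogger("plastevo")

METHOD_A_P = 0.05          # counting-test one-sided threshold
METHOD_B_POSTERIOR = 0.9   # EB posterior threshold
BRANCH_MIN_SUBS = 3        # branch screen: minimum substitutions
MAX_GAP_FRACTION = 0.5     # sites with gaps in > 50% of taxa are excluded
EB_GRID_POINTS = 20
EB_GRID_MAX = 5.0

_UNIVERSE = frozenset(codons.SENSE_CODONS)


# ---------------------------------------------------------------------------
# NG86 site counts and gene-wide Kn/Ks
# ---------------------------------------------------------------------------

_NG_CACHE: dict[str, tuple[float, float] | None] = {}


def ng_site_counts(codon: str) -> tuple[float, float] | None:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes thirds over its three single-base mutants;
    mutants that are stop codons are discarded from the per-position count,
    so S + N <= 3 with equality iff no neighbor is a stop.  Returns None for
    stop or ambiguous codons.
    """
    try:
        return _NG_CACHE[codon]
    except KeyError:
        pass
    if not codons.is_sense(codon):
        _NG_CACHE[codon] = None
        return None
    s = n = 0.0
    aa = codons.translate_codon(codon)
    for k in range(3):
        for nt in codons.NUCLEOTIDES:
            if nt == codon[k]:
                continue
            mut = codon[:k] + nt + codon[k + 1:]
            if codons.is_stop(mut):
                continue
            if codons.translate_codon(mut) == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    _NG_CACHE[codon] = (s, n)
    return (s, n)


@dataclass
class GeneSelectionSummary:
    gene: str
    kn: float | None
    ks: float | None
    kn_ks: float | None
    n_codon_columns: int
    n_pairs: int = 0
    n_pairs_excluded: int = 0   # saturated or Ks=0 pairs


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction of a difference proportion."""
    if p < 0:
        return None
    if p >= 0.75:
        return None  # saturated
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _pair_kn_ks(c1: list[str], c2: list[str]) -> tuple[float, float] | None:
    """NG86 Kn and Ks for one sequence pair given parallel codon lists."""
    s_sites = n_sites = sd = nd = 0.0
    for a, b in zip(c1, c2):
        sn_a = ng_site_counts(a)
        sn_b = ng_site_counts(b)
        if sn_a is None or sn_b is None:
            continue
        path = codons.pathway_counts_cached(a, b)
        if path is None:
            continue
        s_sites += 0.5 * (sn_a[0] + sn_b[0])
        n_sites += 0.5 * (sn_a[1] + sn_b[1])
        sd += path[0]
        nd += path[1]
    if s_sites == 0 or n_sites == 0:
        return None
    ks = _jc_correct(sd / s_sites)
    kn = _jc_correct(nd / n_sites)
    if ks is None or kn is None:
        return None
    return kn, ks


def gene_kn_ks(aln: GeneAlignment | dict[str, str], gene: str = "") -> GeneSelectionSummary:
    """Gene-wide NG86 Kn/Ks averaged over all unordered intact-row pairs.

    Pairs with Ks = 0 (and saturated pairs) are excluded from the average
    with a logged count; the ratio is null when no pair remains.
    """
    rows = aln if isinstance(aln, dict) else {r.id: r.residues for r in aln.records}
    gene = gene or (aln.gene if isinstance(aln, GeneAlignment) else "")
    taxa = [t for t in rows if set(rows[t]) != {"-"}]
    width = len(next(iter(rows.values()))) if rows else 0
    if width % 3 != 0:
        raise ValueError(f"{gene}: alignment width {width} not a codon multiple")
    n_cols = width // 3
    if len(taxa) < 2:
        return GeneSelectionSummary(gene, None, None, None, n_cols)
    codon_rows = {t: [rows[t][3 * i:3 * i + 3] for i in range(n_cols)] for t in taxa}
    kns, kss = [], []
    excluded = 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            res = _pair_kn_ks(codon_rows[taxa[i]], codon_rows[taxa[j]])
            if res is None or res[1] == 0:
                excluded += 1
                continue
            kns.append(res[0])
            kss.append(res[1])
    if not kns:
        if excluded:
            logger.info("%s: all %d pairs excluded (Ks=0 or saturated)", gene, excluded)
        return GeneSelectionSummary(gene, 0.0, 0.0, None, n_cols,
                                    n_pairs=0, n_pairs_excluded=excluded)
    kn = float(np.mean(kns))
    ks = float(np.mean(kss))
    return GeneSelectionSummary(gene, kn, ks, kn / ks if ks > 0 else None,
                                n_cols, n_pairs=len(kns), n_pairs_excluded=excluded)


# ---------------------------------------------------------------------------
# codon columns and ancestral reconstruction
# ---------------------------------------------------------------------------

@dataclass
class CodonColumn:
    site: int                       # 1-based codon position in the alignment
    leaf_codons: dict[str, str]     # taxon -> sense codon (missing taxa absent)


def codon_columns(aln: GeneAlignment | dict[str, str],
                  max_gap_fraction: float = MAX_GAP_FRACTION) -> list[CodonColumn]:
    """Analyzable codon columns: sense codons per taxon, gap-heavy and
    ambiguous-only columns dropped (logged)."""
    rows = aln if isinstance(aln, dict) else {r.id: r.residues for r in aln.records}
    width = len(next(iter(rows.values())))
    if width % 3 != 0:
        raise ValueError(f"alignment width {width} not a codon multiple")
    taxa = list(rows)
    out = []
    n_skipped = 0
    for i in range(width // 3):
        col: dict[str, str] = {}
        for t in taxa:
            c = rows[t][3 * i:3 * i + 3]
            if codons.is_sense(c):
                col[t] = c
        if len(col) < len(taxa) * (1.0 - max_gap_fraction) or len(col) < 2:
            n_skipped += 1
            continue
        out.append(CodonColumn(site=i + 1, leaf_codons=col))
    if n_skipped:
        logger.debug("%d codon columns skipped (gaps/ambiguity)", n_skipped)
    return out


def _nonsyn_cost(a: str, b: str) -> float:
    path = codons.pathway_counts_cached(a, b)
    if path is None:
        return 10.0 + len(codons.codon_diffs(a, b))
    return path[1]


def reconstruct_codon_column(ctree: CompiledTree, col: CodonColumn
                             ) -> tuple[list[str], list[tuple[int, str, str]]]:
    """Fitch ancestral codons for one column plus the implied branch changes.

    Ambiguous/missing leaves carry the full 61-codon universe and therefore
    never force a change.  Ties are resolved toward the minimal
    nonsynonymous change from the parent, then lexicographically; the root
    takes the lexicographically smallest member of its Fitch set.
    Returns (per-node codon, [(node, parent_codon, node_codon), ...]).
    """
    leaf_sets: list[frozenset] = []
    for i in range(ctree.n_leaves):
        c = col.leaf_codons.get(ctree.taxa[i])
        leaf_sets.append(frozenset((c,)) if c is not None else _UNIVERSE)
    node_sets, _ = fitch_sets(ctree, leaf_sets, _UNIVERSE)
    assign: list[str] = [""] * ctree.n_nodes
    changes: list[tuple[int, str, str]] = []
    for i in reversed(ctree.postorder):      # preorder
        options = node_sets[i]
        if ctree.parent[i] < 0:
            assign[i] = min(options)
            continue
        parent_codon = assign[ctree.parent[i]]
        if parent_codon in options:
            assign[i] = parent_codon
        else:
            assign[i] = min(options, key=lambda c: (_nonsyn_cost(parent_codon, c), c))
            changes.append((i, parent_codon, assign[i]))
    return assign, changes


# ---------------------------------------------------------------------------
# method A: counting test
# ---------------------------------------------------------------------------

@dataclass
class SiteSelectionResult:
    gene: str
    site: int
    s: float = 0.0
    n: float = 0.0
    f: float = 0.0                      # expected nonsynonymous fraction
    p_pos: float = 1.0
    p_neg: float = 1.0
    alpha: float | None = None          # EB posterior mean syn rate
    beta: float | None = None           # EB posterior mean nonsyn rate
    posterior_prob_pos: float | None = None
    posterior_prob_neg: float | None = None
    method_a: bool = False
    method_b: bool = False
    consensus: bool = False


def _binom_upper_tail(n_obs: float, total: float, f: float) -> float:
    """P(X >= n_obs) for X ~ Binomial(total, f), continuous extension."""
    if n_obs <= 0:
        return 1.0
    if total - n_obs < -1e-9:
        return 0.0
    return float(betainc(n_obs, total - n_obs + 1.0, f))


def _binom_lower_tail(n_obs: float, total: float, f: float) -> float:
    """P(X <= n_obs), continuous extension (== upper tail of the syn count)."""
    if n_obs >= total:
        return 1.0
    return float(betainc(total - n_obs, n_obs + 1.0, 1.0 - f))


def site_test_counting(aln: GeneAlignment, ctree: CompiledTree,
                       p_threshold: float = METHOD_A_P,
                       columns: list[CodonColumn] | None = None,
                       ) -> list[SiteSelectionResult]:
    """Per-site syn/nonsyn change counts and one-sided binomial tests.

    ``p_pos`` is the upper tail of the nonsynonymous count given s+n
    reconstructed changes and the site's neutral nonsynonymous opportunity
    fraction f; a site is flagged when p_pos <= threshold and s+n >= 1.
    """
    gene = aln.gene
    if columns is None:
        columns = codon_columns(aln)
    results = []
    for col in columns:
        s_tot = n_tot = 0.0
        sn = [ng_site_counts(c) for c in col.leaf_codons.values()]
        sn = [x for x in sn if x is not None]
        s_sites = float(np.mean([x[0] for x in sn]))
        n_sites = float(np.mean([x[1] for x in sn]))
        f = n_sites / (n_sites + s_sites) if (n_sites + s_sites) > 0 else 0.75
        _, changes = reconstruct_codon_column(ctree, col)
        for _node, pa, ch in changes:
            path = codons.pathway_counts_cached(pa, ch)
            if path is None:
                continue
            s_tot += path[0]
            n_tot += path[1]
        total = s_tot + n_tot
        p_pos = _binom_upper_tail(n_tot, total, f) if total > 0 else 1.0
        p_neg = _binom_lower_tail(n_tot, total, f) if total > 0 else 1.0
        results.append(SiteSelectionResult(
            gene=gene, site=col.site, s=s_tot, n=n_tot, f=f,
            p_pos=p_pos, p_neg=p_neg,
            method_a=(p_pos <= p_threshold and total >= 1.0),
        ))
    return results


# ---------------------------------------------------------------------------
# method B: empirical-Bayes rate grid
# ---------------------------------------------------------------------------

def estimate_kappa(ctree: CompiledTree, columns: list[CodonColumn]) -> float:
    """Gene-level ts/tv rate ratio from reconstructed single-base changes.

    kappa = 2 * (transitions / transversions): each position offers one
    transition and two transversion neighbors, so the count ratio is
    halved relative to the rate ratio.  Clipped to [0.5, 20]; default 2
    when there are no transversions to anchor the ratio.
    """
    ts = tv = 0
    for col in columns:
        _, changes = reconstruct_codon_column(ctree, col)
        for _node, pa, ch in changes:
            for k in codons.codon_diffs(pa, ch):
                if codons.is_transition(pa[k], ch[k]):
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 2.0
    return float(np.clip(2.0 * ts / tv, 0.5, 20.0))


def _mg94_components(kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized synonymous and nonsynonymous generator components so that
    Q(alpha, beta) = alpha * Qs + beta * Qn has, at alpha=beta=1, three
    expected substitutions per codon per unit branch length (uniform codon
    frequencies)."""
    q_neutral = codons.mg94_rate_matrix(kappa=kappa, omega=1.0)
    qs = np.zeros_like(q_neutral)
    qn = np.zeros_like(q_neutral)
    for i, ci in enumerate(codons.SENSE_CODONS):
        for j, cj in enumerate(codons.SENSE_CODONS):
            if i == j or len(codons.codon_diffs(ci, cj)) != 1:
                continue
            if codons.CODON_TO_AA[ci] == codons.CODON_TO_AA[cj]:
                qs[i, j] = q_neutral[i, j]
            else:
                qn[i, j] = q_neutral[i, j]
    np.fill_diagonal(qs, -qs.sum(axis=1))
    np.fill_diagonal(qn, -qn.sum(axis=1))
    return qs, qn


def _site_likelihoods(ctree: CompiledTree, columns: list[CodonColumn],
                      q: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood under generator ``q`` with the tree's lengths."""
    n_sites = len(columns)
    k = codons.N_SENSE
    # symmetric generator (uniform frequencies) -> eigh
    evals, evecs = np.linalg.eigh(q)
    leaf_part = np.ones((ctree.n_leaves, n_sites, k))
    for s, col in enumerate(columns):
        for li in range(ctree.n_leaves):
            c = col.leaf_codons.get(ctree.taxa[li])
            if c is not None:
                leaf_part[li, s] = 0.0
                leaf_part[li, s, codons.CODON_INDEX[c]] = 1.0
    partial: list[np.ndarray | None] = [None] * ctree.n_nodes
    log_scale = np.zeros(n_sites)
    for i in ctree.postorder:
        if not ctree.children[i]:
            partial[i] = leaf_part[i]
            continue
        acc = np.ones((n_sites, k))
        for ch in ctree.children[i]:
            p = (evecs * np.exp(evals * ctree.lengths[ch])) @ evecs.T
            np.clip(p, 0.0, None, out=p)
            acc = acc * (partial[ch] @ p.T)
        mx = acc.max(axis=1)
        mx[mx == 0] = 1e-300
        acc = acc / mx[:, None]
        log_scale += np.log(mx)
        partial[i] = acc
    root = partial[ctree.root]
    return np.log(root.mean(axis=1) + 1e-300) + log_scale  # uniform prior


@dataclass
class EbGridFit:
    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    weights: np.ndarray              # (n_grid,) fitted prior
    posterior: np.ndarray            # (n_sites, n_grid)
    loglik_trace: list[float] = field(default_factory=list)


def site_test_ebgrid(aln: GeneAlignment, ctree: CompiledTree,
                     posterior_threshold: float = METHOD_B_POSTERIOR,
                     columns: list[CodonColumn] | None = None,
                     kappa: float | None = None,
                     n_grid: int = EB_GRID_POINTS, grid_max: float = EB_GRID_MAX,
                     ) -> tuple[list[SiteSelectionResult], EbGridFit]:
    """Empirical-Bayes site selection on an (alpha, beta) rate grid.

    Branch lengths must be present on ``ctree`` (expected substitutions per
    neutral nucleotide site, e.g. from the JC69 fit on the concatenate).
    Grid weights are fitted by EM on the per-site marginal likelihoods; the
    EM objective is checked to be non-decreasing at every iteration.
    """
    if ctree.n_leaves < 2:
        raise ValueError("degenerate alignment: need >= 2 taxa")
    if columns is None:
        columns = codon_columns(aln)
    if not columns:
        return [], EbGridFit(np.array([]), np.array([]), np.array([]),
                             np.zeros((0, 0)))
    if kappa is None:
        kappa = estimate_kappa(ctree, columns)
    qs, qn = _mg94_components(kappa)
    axis = np.linspace(0.0, grid_max, n_grid)
    pairs = [(a, b) for a in axis for b in axis]
    loglik = np.empty((len(columns), len(pairs)))
    for gi, (a, b) in enumerate(pairs):
        loglik[:, gi] = _site_likelihoods(ctree, columns, a * qs + b * qn)

    # EM on grid weights
    n_grid_pts = len(pairs)
    w = np.full(n_grid_pts, 1.0 / n_grid_pts)
    trace: list[float] = []
    shift = loglik.max(axis=1, keepdims=True)
    lik = np.exp(loglik - shift)
    for _ in range(500):
        mix = lik @ w
        obj = float(np.sum(np.log(mix + 1e-300) + shift[:, 0]))
        if trace and obj < trace[-1] - 1e-9:
            raise AssertionError("EM objective decreased")
        if trace and obj - trace[-1] < 1e-6:
            trace.append(obj)
            break
        trace.append(obj)
        post = lik * w[None, :] / (mix[:, None] + 1e-300)
        w = post.mean(axis=0)
        w = w / w.sum()
    post = lik * w[None, :]
    post = post / post.sum(axis=1, keepdims=True)

    alphas = np.array([a for a, _ in pairs])
    betas = np.array([b for _, b in pairs])
    pos_mask = betas > alphas
    neg_mask = betas < alphas
    results = []
    for s, col in enumerate(columns):
        prob_pos = float(post[s, pos_mask].sum())
        prob_neg = float(post[s, neg_mask].sum())
        results.append(SiteSelectionResult(
            gene=aln.gene, site=col.site,
            alpha=float(post[s] @ alphas), beta=float(post[s] @ betas),
            posterior_prob_pos=prob_pos, posterior_prob_neg=prob_neg,
            method_b=prob_pos >= posterior_threshold,
        ))
    fit = EbGridFit(alpha_grid=alphas, beta_grid=betas, weights=w,
                    posterior=post, loglik_trace=trace)
    return results, fit


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_sites(method_a: list[SiteSelectionResult],
                    method_b: list[SiteSelectionResult],
                    ) -> list[SiteSelectionResult]:
    """Merge the two per-site result lists; consensus = flagged by both."""
    if [(r.gene, r.site) for r in method_a] != [(r.gene, r.site) for r in method_b]:
        raise ValueError("method A and method B site indexing differs")
    merged = []
    for ra, rb in zip(method_a, method_b):
        merged.append(SiteSelectionResult(
            gene=ra.gene, site=ra.site, s=ra.s, n=ra.n, f=ra.f,
            p_pos=ra.p_pos, p_neg=ra.p_neg,
            alpha=rb.alpha, beta=rb.beta,
            posterior_prob_pos=rb.posterior_prob_pos,
            posterior_prob_neg=rb.posterior_prob_neg,
            method_a=ra.method_a, method_b=rb.method_b,
            consensus=ra.method_a and rb.method_b,
        ))
    return merged


def gene_summary_table(per_gene_sites: dict[str, list[SiteSelectionResult]],
                       kn_ks: dict[str, GeneSelectionSummary] | None = None,
                       ) -> pd.DataFrame:
    """Per-gene site-selection summary (one row per gene)."""
    recs = []
    for gene, sites in per_gene_sites.items():
        confirmed = sorted(r.site for r in sites if r.consensus)
        row = {
            "gene": gene,
            "n_sites": len(sites),
            "methodA_sites": sum(r.method_a for r in sites),
            "methodB_pos": sum(r.method_b for r in sites),
            "methodB_neg": sum((r.posterior_prob_neg or 0.0) >= METHOD_B_POSTERIOR
                               for r in sites),
            "confirmed_positions": ",".join(map(str, confirmed)),
            "n_confirmed": len(confirmed),
        }
        if kn_ks and gene in kn_ks:
            row["kn"] = kn_ks[gene].kn
            row["ks"] = kn_ks[gene].ks
            row["kn_ks"] = kn_ks[gene].kn_ks
        recs.append(row)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# branch-level screening
# ---------------------------------------------------------------------------

def branch_kn_ks(aln: GeneAlignment, ctree: CompiledTree,
                 columns: list[CodonColumn] | None = None,
                 min_subs: int = BRANCH_MIN_SUBS) -> pd.DataFrame:
    """Per-branch Kn/Ks screen from reconstructed substitutions.

    Counts are normalized by the gene's total synonymous/nonsynonymous site
    opportunities; a branch is reported as selected when its ratio exceeds 1
    with at least ``min_subs`` substitutions.  Branches with Ks = 0 get an
    infinite ratio and still face the substitution filter.
    """
    from .phylo import branch_names

    if columns is None:
        columns = codon_columns(aln)
    names = branch_names(ctree)
    syn = np.zeros(ctree.n_nodes)
    nonsyn = np.zeros(ctree.n_nodes)
    s_sites = n_sites = 0.0
    for col in columns:
        sn = [ng_site_counts(c) for c in col.leaf_codons.values()]
        sn = [x for x in sn if x is not None]
        s_sites += float(np.mean([x[0] for x in sn]))
        n_sites += float(np.mean([x[1] for x in sn]))
        _, changes = reconstruct_codon_column(ctree, col)
        for node, pa, ch in changes:
            path = codons.pathway_counts_cached(pa, ch)
            if path is None:
                continue
            syn[node] += path[0]
            nonsyn[node] += path[1]
    recs = []
    for i in range(ctree.n_nodes):
        if ctree.parent[i] < 0:
            continue
        total = syn[i] + nonsyn[i]
        if total == 0:
            continue
        ks = syn[i] / s_sites if s_sites > 0 else np.nan
        kn = nonsyn[i] / n_sites if n_sites > 0 else np.nan
        ratio = np.inf if ks == 0 else kn / ks
        recs.append({
            "gene": aln.gene, "branch": names[i],
            "syn": round(float(syn[i]), 4), "nonsyn": round(float(nonsyn[i]), 4),
            "kn": kn, "ks": ks, "kn_ks": ratio,
            "n_subs": round(float(total), 4),
            "selected": bool(ratio > 1.0 and total >= min_subs),
        })
    return pd.DataFrame(recs, columns=["gene", "branch", "syn", "nonsyn", "kn",
                                       "ks", "kn_ks", "n_subs", "selected"])


# ---------------------------------------------------------------------------
# ontology enrichment
# ---------------------------------------------------------------------------

def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm–Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def ontology_enrichment(site_results: dict[str, list[SiteSelectionResult]],
                        ontology_map: dict[str, str]) -> pd.DataFrame:
    """Selected-site enrichment between ontology groups.

    Per ontology the consensus-selected and non-selected site totals are
    pooled over its genes; all pairwise 2x2 Fisher exact tests (two-sided)
    are Holm-adjusted as one family, and each-vs-rest tests are emitted as a
    separate Holm family.  Ontologies with zero analyzable sites are
    excluded with a log message.
    """
    missing = [g for g in site_results if g not in ontology_map]
    if missing:
        raise ValueError(f"ontology map does not cover genes: {sorted(missing)}")
    counts: dict[str, tuple[int, int]] = {}
    for gene, sites in site_results.items():
        ont = ontology_map[gene]
        sel = sum(r.consensus for r in sites)
        tot = len(sites)
        c = counts.get(ont, (0, 0))
        counts[ont] = (c[0] + sel, c[1] + tot)
    for ont in list(counts):
        if counts[ont][1] == 0:
            logger.warning("ontology %s has zero analyzable sites; excluded", ont)
            del counts[ont]
    onts = sorted(counts)
    recs = []
    pair_ps = []
    for i in range(len(onts)):
        for j in range(i + 1, len(onts)):
            a, b = onts[i], onts[j]
            sa, ta = counts[a]
            sb, tb = counts[b]
            table = [[sa, ta - sa], [sb, tb - sb]]
            odds, p = fisher_exact(table, alternative="two-sided")
            recs.append({"group_a": a, "group_b": b,
                         "selected_a": sa, "nonselected_a": ta - sa,
                         "selected_b": sb, "nonselected_b": tb - sb,
                         "odds_ratio": float(odds), "fisher_p": float(p),
                         "family": "pairwise"})
            pair_ps.append(float(p))
    rest_ps = []
    total_sel = sum(s for s, _ in counts.values())
    total_all = sum(t for _, t in counts.values())
    for a in onts:
        sa, ta = counts[a]
        table = [[sa, ta - sa], [total_sel - sa, (total_all - ta) - (total_sel - sa)]]
        odds, p = fisher_exact(table, alternative="two-sided")
        recs.append({"group_a": a, "group_b": "rest",
                     "selected_a": sa, "nonselected_a": ta - sa,
                     "selected_b": total_sel - sa,
                     "nonselected_b": (total_all - ta) - (total_sel - sa),
                     "odds_ratio": float(odds), "fisher_p": float(p),
                     "family": "vs_rest"})
        rest_ps.append(float(p))
    adj = holm_adjust(pair_ps) + holm_adjust(rest_ps)
    df = pd.DataFrame(recs)
    if not df.empty:
        df["holm_p"] = adj
    return df
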