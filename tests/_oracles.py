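"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — quadratic scans, explicit
enumeration, textbook formulas — and shares no code with the package, so
agreement between the two is evidence of correctness, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_h2h(genes, max_distance, max_overlap):
    """All (minus, plus) gene pairs satisfying the divergent-pair predicate."""
    out = set()
    for m, p in itertools.product(genes, genes):
        if m.strand != "-" or p.strand != "+" or m.chrom != p.chrom:
            continue
        d = p.tss - m.tss
        if d > max_distance:
            continue
        if max_overlap is not None and -d > max_overlap:
            continue
        lo, hi = min(m.tss, p.tss), max(m.tss, p.tss)
        if any(g.chrom == m.chrom and lo < g.tss < hi for g in genes):
            continue
        out.add(tuple(sorted((m.gene_id, p.gene_id))))
    return out


def brute_force_adjacent(genes, focal):
    """Nearest same-strand neighbour of each focal gene, per side."""
    out = set()
    by_id = {g.gene_id: g for g in genes}
    for gid in focal:
        g = by_id[gid]
        same_chrom = sorted(
            (x for x in genes if x.chrom == g.chrom), key=lambda x: (x.tss, x.gene_id)
        )
        i = same_chrom.index(g)
        left = [x for x in same_chrom[:i] if x.strand == g.strand]
        right = [x for x in same_chrom[i + 1:] if x.strand == g.strand]
        if left:
            out.add(tuple(sorted((gid, left[-1].gene_id))))
        if right:
            out.add(tuple(sorted((gid, right[0].gene_id))))
    return out


def brute_force_rank(dataset_values, gene_ids, a, b, method="pearson"):
    """Rank of b in a's neighbour list by naive sort (ties: ascending id)."""
    from scipy import stats as ss

    corr = {}
    xa = dataset_values[gene_ids.index(a)]
    for g, row in zip(gene_ids, dataset_values):
        if g == a:
            continue
        if method == "spearman":
            corr[g] = ss.spearmanr(xa, row).statistic
        else:
            corr[g] = np.corrcoef(xa, row)[0, 1]
    ordered = sorted(corr, key=lambda g: (-corr[g], g))
    return ordered.index(b) + 1


def pearson_by_hand(x, y):
    """Covariance over product of standard deviations, summed explicitly."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def cochran_armitage_textbook(r, n, s):
    """Trend chi-squared from the standard CA formula, coded independently."""
    r, n, s = (list(map(float, v)) for v in (r, n, s))
    N = sum(n)
    pbar = sum(r) / N
    sbar = sum(ni * si for ni, si in zip(n, s)) / N
    num = sum(si * (ri - ni * pbar) for si, ri, ni in zip(s, r, n)) ** 2
    den = pbar * (1 - pbar) * sum(ni * (si - sbar) ** 2 for ni, si in zip(n, s))
    return num / den if den else 0.0


def chi2_2x2_by_hand(table):
    """Pearson chi-squared, sum over cells of (O-E)^2/E."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def brute_force_ancestors(parents, term):
    """Transitive is_a closure by repeated expansion."""
    anc = set()
    frontier = set(parents[term])
    while frontier:
        anc |= frontier
        frontier = {p for t in frontier for p in parents[t]} - anc
    return anc


def brute_force_min_subsumer(parents, ic, t1, t2):
    """Max-IC common (inclusive) ancestor; ties broken by term id."""
    c1 = brute_force_ancestors(parents, t1) | {t1}
    c2 = brute_force_ancestors(parents, t2) | {t2}
    common = [t for t in c1 & c2 if t in ic]
    best = sorted(common, key=lambda t: (-ic[t], t))[0]
    return best, ic[best]


def wilcoxon_exact_enumeration(a, b):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # assumes no ties
    obs = sum(ranks[v] for v in a)
    n = len(a)
    stats = [
        sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n)
    ]
    mean = (len(a) * (len(pooled) + 1)) / 2
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean))
    return extreme / len(stats)


def fisher_z_power(rho, n, alpha=0.05):
    """Analytic power of the two-sided correlation test via Fisher's z."""
    from scipy import stats as ss

    z_crit = ss.norm.ppf(1 - alpha / 2)
    mu = np.arctanh(rho) * math.sqrt(n - 3)
    return float(ss.norm.sf(z_crit - mu) + ss.norm.cdf(-z_crit - mu))
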