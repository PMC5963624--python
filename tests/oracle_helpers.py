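"""Brute-force reference implementations used only by the test suite.

Each function recomputes a pipeline quantity by direct enumeration
over records, independently of the library's vectorized code paths.
"""

from collections import defaultdict

import numpy as np
from scipy.stats import hypergeom


def key_of(r):
    return (r.chrom, r.pos, r.ref, r.alt)


def sample_key_sets(records, manifest):
    out = {sid: set() for sid in manifest.sample_ids}
    for r in records:
        out[r.sample_id].add(key_of(r))
    return out


def brute_burden(records, manifest):
    totals = {}
    for g in manifest.groups:
        members = set(manifest.samples_in(g))
        sub = [r for r in records if r.sample_id in members]
        totals[g] = (
            len(sub),
            sum(1 for r in sub if r.is_coding),
            sum(1 for r in sub if r.is_deleterious),
        )
    return totals


def brute_gene_matrix(records, manifest):
    per_sample = defaultdict(set)
    per_group = defaultdict(set)
    for r in records:
        if r.gene == ".":
            continue
        per_sample[(r.gene, r.sample_id)].add(key_of(r))
        per_group[(r.gene, manifest.group_of(r.sample_id))].add(key_of(r))
    return (
        {k: len(v) for k, v in per_sample.items()},
        {k: len(v) for k, v in per_group.items()},
    )


def brute_mutated_sets(records, manifest):
    sets = {g: set() for g in manifest.groups}
    for r in records:
        if r.gene != ".":
            sets[manifest.group_of(r.sample_id)].add(r.gene)
    return sets


def brute_hyper(records, manifest, threshold):
    _, per_group = brute_gene_matrix(records, manifest)
    flags = {g: set() for g in manifest.groups}
    for (gene, group), n in per_group.items():
        if n > threshold:
            flags[group].add(gene)
    return flags


def brute_shared_keys(records, manifest, group):
    per_sample = sample_key_sets(records, manifest)
    members = manifest.samples_in(group)
    shared = per_sample[members[0]].copy()
    for s in members[1:]:
        shared &= per_sample[s]
    return shared


def brute_exclusive_shared(records, manifest, g1, g2):
    per_sample = sample_key_sets(records, manifest)
    out = []
    for a, b in ((g1, g2), (g2, g1)):
        shared = brute_shared_keys(records, manifest, a)
        present_b = set()
        for s in manifest.samples_in(b):
            present_b |= per_sample[s]
        out.append(shared - present_b)
    return tuple(out)


def brute_universal(records, manifest):
    per_sample = sample_key_sets(records, manifest)
    keys = None
    for s in manifest.sample_ids:
        keys = per_sample[s] if keys is None else keys & per_sample[s]
    return keys or set()


def brute_recurrent(records, manifest, g1, g2, min_variants):
    _, per_group = brute_gene_matrix(records, manifest)
    per_gene_sample = defaultdict(set)
    genes = set()
    for r in records:
        if r.gene != ".":
            per_gene_sample[r.gene].add(r.sample_id)
            genes.add(r.gene)
    out = {}
    for a, b in ((g1, g2), (g2, g1)):
        hits = []
        for gene in genes:
            n = per_group.get((gene, a), 0)
            in_all = all(s in per_gene_sample[gene] for s in manifest.samples_in(a))
            in_none = all(
                s not in per_gene_sample[gene] for s in manifest.samples_in(b)
            )
            if n > min_variants and in_all and in_none:
                hits.append((gene, n))
        out[a] = sorted(hits, key=lambda t: (-t[1], t[0]))
    return out


def brute_bh(p_values):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def brute_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by enumerating the hypergeometric support and
    summing tables no more probable than the observed one."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, n, row1, col1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def brute_chi2_stat(a, b, c, d):
    """Pearson chi-square statistic from first principles."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - expected) ** 2 / expected).sum())
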