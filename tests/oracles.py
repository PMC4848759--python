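"""Independent straight-line re-implementations used as test oracles.

Everything here is deliberately naive — plain loops, exhaustive subset
enumeration via itertools — and shares no code with the package, so agreement
is evidence rather than tautology.
"""

import itertools


def oracle_classify(values, cutoff=0.5, fold=5.0, group_min=2, group_max=7):
    """Literal category rules with brute-force group search over all subsets.

    Returns (category, detail) where detail is the enriched tissue index, the
    smallest satisfying group size, or None.
    """
    values = list(values)
    n = len(values)
    if all(v < cutoff for v in values):
        return "not_detected", None
    for t in range(n):
        others = [values[j] for j in range(n) if j != t]
        if values[t] >= cutoff and values[t] >= fold * max(others):
            return "tissue_enriched", t
    for k in range(group_min, min(group_max, n - 1) + 1):
        for combo in itertools.combinations(range(n), k):
            if any(values[i] < cutoff for i in combo):
                continue
            rest = [values[j] for j in range(n) if j not in combo]
            if sum(values[i] for i in combo) / k >= fold * max(rest):
                return "group_enriched", k
    mean_all = sum(values) / n
    if any(v >= cutoff and v >= fold * mean_all for v in values):
        return "enhanced", None
    if all(v >= cutoff for v in values):
        return "expressed_in_all", None
    return "mixed", None


def oracle_group_satisfiable(values, k, cutoff=0.5, fold=5.0):
    """Exhaustively: does ANY size-k subset satisfy the group rule?"""
    n = len(values)
    for combo in itertools.combinations(range(n), k):
        if any(values[i] < cutoff for i in combo):
            continue
        rest = [values[j] for j in range(n) if j not in combo]
        if rest and sum(values[i] for i in combo) / k >= fold * max(rest):
            return True
    return False


def oracle_crosstab(a_categories, b_categories, shared):
    """Double-loop tally of (category_a, category_b) pairs over shared genes."""
    tab = {}
    for g in shared:
        key = (a_categories[g], b_categories[g])
        tab[key] = tab.get(key, 0) + 1
    return tab


def oracle_tissue_agreement(a_records, b_records, pairs, elevated_categories):
    """Per-gene re-evaluation of the enriched-call agreement rule.

    ``a_records``/``b_records``: gene_id -> (category, elevated tissue tuple).
    ``pairs``: list of (tissue_a, tissue_b).  Returns {tissue: [both, only_a,
    only_b]} keyed by A-side tissue label (or "unmapped").
    """
    out = {}

    def bump(t, idx):
        out.setdefault(t, [0, 0, 0])[idx] += 1

    shared = set(a_records) & set(b_records)
    for g in sorted(shared):
        cat_a, ts_a = a_records[g]
        cat_b, ts_b = b_records[g]
        if cat_a == "tissue_enriched":
            for t in ts_a:
                partners = {b for a, b in pairs if a == t}
                if not partners:
                    bump("unmapped", 1)
                elif cat_b in elevated_categories and partners & set(ts_b):
                    bump(t, 0)
                else:
                    bump(t, 1)
        if cat_b == "tissue_enriched":
            for u in ts_b:
                groups = {a for a, b in pairs if b == u}
                if not groups:
                    bump("unmapped", 2)
                    continue
                hit = cat_a in elevated_categories and bool(groups & set(ts_a))
                for t in sorted(groups):
                    bump(t, 0 if hit else 2)
    return out
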