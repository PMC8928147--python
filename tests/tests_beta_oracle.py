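"""Naive per-edge UniFrac oracle, independent of the package's
incidence-matrix implementation: classify every tree edge by explicit
tip-set membership and accumulate lengths."""


def brute_force_unifrac_pair(tree, counts, ids, i, j):
    """Return (unweighted, weighted-raw) UniFrac between samples i and j."""
    totals = counts.sum(axis=1)
    u_num = u_den = w_num = 0.0
    for node in tree.traverse(include_self=True):
        length = node.length or 0.0
        tips = {t.name for t in node.tips(include_self=True)}
        idx = [k for k, f in enumerate(ids) if f in tips]
        a = counts[i, idx].sum()
        b = counts[j, idx].sum()
        w_num += length * abs(a / totals[i] - b / totals[j])
        in_a, in_b = a > 0, b > 0
        if in_a != in_b:
            u_num += length
        if in_a or in_b:
            u_den += length
    unweighted = u_num / u_den if u_den else 0.0
    return unweighted, w_num
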