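"""Independent brute-force reference implementations used to check the
package against first principles.  Nothing here may import the modules
it validates beyond plain data containers."""

import numpy as np


def reachable_targets_bruteforce(receptor, edges, k_max):
    """Genes reachable via <= k_max signaling edges then exactly one
    regulatory edge, by boolean adjacency-matrix powers."""
    nodes = sorted({n for e in edges for n in e[:2]} | {receptor})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    sig = np.zeros((n, n), dtype=bool)
    reg = np.zeros((n, n), dtype=bool)
    for src, dst, kind in edges:
        (sig if kind == "signaling" else reg)[idx[src], idx[dst]] = True
    reach = np.zeros(n, dtype=bool)
    reach[idx[receptor]] = True
    frontier = reach.copy()
    for _ in range(k_max):
        frontier = (frontier @ sig) & ~reach
        if not frontier.any():
            break
        reach |= frontier
    targets = reach @ reg
    return {nodes[i] for i in np.nonzero(targets)[0]}


def loop_strength_bruteforce(pair, sender, receiver, all_pairs, edges, s0_lookup,
                             k_max, timepoints):
    """Max reverse-pair S0 over qualifying loop partners, enumerating
    every candidate pair and timepoint."""
    t_fwd = reachable_targets_bruteforce(pair[1], edges, k_max)
    best = 0.0
    partners = []
    for rev in all_pairs:
        if rev[0] not in t_fwd:
            continue
        if pair[0] not in reachable_targets_bruteforce(rev[1], edges, k_max):
            continue
        partners.append(rev)
        for tp in timepoints:
            best = max(best, s0_lookup(rev, receiver, sender, tp))
    return best, partners


def ds_lr_bruteforce(score_table, high, low):
    """score_table: dict (subclass, timepoint) -> S_LR.  Missing
    subclass entries count as 0."""
    def side(subs):
        vals = []
        for sub in subs:
            per_tp = [v for (s, _), v in score_table.items() if s == sub]
            vals.append(max(per_tp) if per_tp else 0.0)
        return sum(vals) / len(vals)
    return side(high) - side(low)


def ks_statistic_bruteforce(x, y):
    """Two-sample KS statistic by sweeping both ECDFs over all values."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    d = 0.0
    for v in np.concatenate([x, y]):
        fx = np.searchsorted(x, v, side="right") / len(x)
        fy = np.searchsorted(y, v, side="right") / len(y)
        d = max(d, abs(fx - fy))
    return d


def qc_keep_bruteforce(numi, ngene, mito_rate, ratio, th):
    """Literal per-cell QC rule: removed on strict violations."""
    if numi < th.numi_min or numi > th.numi_max:
        return False
    if ngene < th.ngene_min or ngene > th.ngene_max:
        return False
    if mito_rate > th.mito_rate_max:
        return False
    if ratio < th.log10_genes_per_umi_min:
        return False
    return True
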