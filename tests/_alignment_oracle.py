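"""Brute-force oracle for signature/cluster alignment.

Independent of the package's dynamic-programming search: enumerates every
subset of signature positions (largest first) and checks, by greedy
earliest-match subsequence embedding, whether that token subsequence fits
into the cluster within the insertion budget.  For a fixed start position,
greedy earliest matching minimizes the embedding end, hence the number of
skipped cluster genes inside the span, so feasibility is decided exactly.
"""

from itertools import combinations


def _embeds(tokens, cluster, max_insertions) -> bool:
    k = len(tokens)
    for s in range(len(cluster)):
        if cluster[s] != tokens[0]:
            continue
        pos, ok = s, True
        for t in tokens[1:]:
            pos += 1
            while pos < len(cluster) and cluster[pos] != t:
                pos += 1
            if pos >= len(cluster):
                ok = False
                break
        if ok and (pos - s + 1) - k <= max_insertions:
            return True
    return False


def oracle_best_match(sig_tokens, cluster_tokens, max_insertions) -> int:
    """Max number of signature tokens matchable, over both orientations."""
    best = 0
    for orient in (list(cluster_tokens), list(reversed(cluster_tokens))):
        for k in range(len(sig_tokens), best, -1):
            hit = False
            for subset in combinations(range(len(sig_tokens)), k):
                toks = [sig_tokens[i] for i in subset]
                if _embeds(toks, orient, max_insertions):
                    hit = True
                    break
            if hit:
                best = k
                break
    return best
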