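"""Independent brute-force reference implementations used as test oracles.

Pure-Python (lists + math), deliberately sharing no code with the package:
full sorts, no vectorization, no heaps.
"""

import math


def oracle_cosine(u, v):
    du = math.sqrt(sum(x * x for x in u))
    dv = math.sqrt(sum(x * x for x in v))
    return sum(a * b for a, b in zip(u, v)) / (du * dv)


def _unit(v):
    n = math.sqrt(sum(x * x for x in v))
    return [x / n for x in v]


def _mean(vecs):
    return [sum(col) / len(vecs) for col in zip(*vecs)]


def oracle_neighbors(vocab, query, m, exclude=()):
    """Full sort over the vocabulary; ties by ascending word."""
    banned = set(exclude) | {query}
    qv = vocab[query]
    scored = [
        (w, oracle_cosine(v, qv)) for w, v in vocab.items() if w not in banned
    ]
    scored.sort(key=lambda wc: (-wc[1], wc[0]))
    return scored[:m]


def oracle_relatedness(vocab, x, y, k1, k2, m, rule="separate"):
    """Step-by-step predication: neighbourhood of y, top-k selection,
    spherical averaging, cosine of the adjusted vectors."""
    vocab = {w: _unit(v) for w, v in vocab.items()}
    xv, yv = vocab[x], vocab[y]
    ranked = oracle_neighbors(vocab, y, m, exclude={x})
    named = [(w, vocab[w]) for w, _ in ranked]
    if rule == "separate":
        s1 = sorted(named, key=lambda wv: (-oracle_cosine(wv[1], xv), wv[0]))[:k1]
        s2 = sorted(named, key=lambda wv: (-oracle_cosine(wv[1], yv), wv[0]))[:k2]
        x_adj = _mean([xv] + [v for _, v in s1])
        y_adj = _mean([yv] + [v for _, v in s2])
    elif rule == "common":
        s = sorted(
            named,
            key=lambda wv: (
                -(oracle_cosine(wv[1], xv) + oracle_cosine(wv[1], yv)),
                wv[0],
            ),
        )[:k1]
        x_adj = _mean([xv] + [v for _, v in s])
        y_adj = _mean([yv] + [v for _, v in s])
    else:
        raise ValueError(rule)
    return oracle_cosine(x_adj, y_adj)


def oracle_greedy_match(literals, metaphors):
    """Replay of the sequential matching definition: repeatedly scan every
    remaining (literal, metaphor) pair, take the one with smallest summed
    absolute z-difference (ties: literal id, then metaphor id), remove both.

    Items are (id, [z1, z2, z3, z4]) tuples.
    """
    remaining_l = dict(literals)
    remaining_m = dict(metaphors)
    pairs = []
    while remaining_l:
        best = None
        for lid in sorted(remaining_l):
            for mid in sorted(remaining_m):
                d = sum(
                    abs(a - b)
                    for a, b in zip(remaining_l[lid], remaining_m[mid])
                )
                key = (d, lid, mid)
                if best is None or key < best:
                    best = key
        d, lid, mid = best
        pairs.append((lid, mid, d))
        del remaining_l[lid]
        del remaining_m[mid]
    return pairs


def oracle_zscores(values):
    """Sample-SD z-scores by the textbook formula."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    if sd == 0:
        return [0.0] * n
    return [(v - mean) / sd for v in values]


def oracle_pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in xs) * sum((b - my) ** 2 for b in ys)
    )
    return num / den
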