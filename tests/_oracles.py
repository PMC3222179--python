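"""Independent brute-force oracles used to audit the package's numerics.

Everything here is deliberately naive (pure-python math.exp loops, direct
textbook formulas) and shares no code with the implementation under test.
"""
import math


def naive_probs(theta, delta, taus):
    """RSM category probabilities by direct evaluation of the closed form."""
    numerators = []
    for k in range(len(taus) + 1):
        numerators.append(math.exp(k * (theta - delta) - sum(taus[:k])))
    z = sum(numerators)
    return [v / z for v in numerators]


def naive_expected(theta, delta, taus):
    return sum(k * p for k, p in enumerate(naive_probs(theta, delta, taus)))


def naive_variance(theta, delta, taus):
    p = naive_probs(theta, delta, taus)
    e = sum(k * pk for k, pk in enumerate(p))
    return sum((k - e) ** 2 * pk for k, pk in enumerate(p))


def naive_loglik(theta, scored_items, taus):
    """scored_items: list of (delta, score)."""
    return sum(
        math.log(naive_probs(theta, delta, taus)[score])
        for delta, score in scored_items
    )


def naive_paired_t(x, y):
    """Textbook paired t statistic."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n)


def naive_chi2(table):
    """Pearson chi-square, Σ(O−E)²/E, no correction."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    chi2 = 0.0
    for i, r in enumerate(table):
        for j, o in enumerate(r):
            e = rows[i] * cols[j] / total
            chi2 += (o - e) ** 2 / e
    return chi2
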