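"""Independent brute-force oracles used by the test suite.

These are deliberately naive (plain Python loops) and share no code
with the package's optimized implementations.
"""


def brute_force_sampen_counts(y, m, r_abs):
    """O(L^2 * m) pair enumerator for sample-entropy match counts.

    Counts ordered pairs (i, j), i != j, of templates drawn from
    positions 0..L-m-1 whose Chebyshev distance is <= r_abs, at lengths
    m (count B) and m+1 (count A).
    """
    y = list(map(float, y))
    n = len(y) - m
    a_count = 0
    b_count = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if max(abs(y[i + k] - y[j + k]) for k in range(m)) <= r_abs:
                b_count += 1
                if abs(y[i + m] - y[j + m]) <= r_abs:
                    a_count += 1
    return a_count, b_count


def mann_whitney_auc_oracle(values, labels):
    """Exhaustive pairwise AUC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pooled_ttest_oracle(a, b):
    """Textbook pooled-variance two-sample t-test, two-sided p-value."""
    import math

    from scipy.stats import t as tdist

    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    t_stat = (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))
    return 2 * tdist.sf(abs(t_stat), n1 + n2 - 2)
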