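"""Independent brute-force reference implementations.

Pure-Python, loop-based, no shared code with the package internals:
these recompute every statistic from its definition so the vectorized
implementations can be checked against them.
"""

import math


def common_labels(sets):
    labels = set(sets[0].shifts)
    for s in sets[1:]:
        labels &= set(s.shifts)
    return sorted(labels)


def brute_mae(a, b):
    labels = common_labels([a, b])
    return sum(abs(a.shifts[l] - b.shifts[l]) for l in labels) / len(labels)


def brute_rmsd(a, b):
    labels = common_labels([a, b])
    return math.sqrt(
        sum((a.shifts[l] - b.shifts[l]) ** 2 for l in labels) / len(labels)
    )


def brute_rmsd_summary(sets):
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            vals.append(brute_rmsd(sets[i], sets[j]))
    return {
        "average": sum(vals) / len(vals),
        "min": min(vals),
        "max": max(vals),
    }


def brute_mae_dddelta(calc_sets, exp_sets, perm):
    """Mean |Δδ_calc − Δδ_exp| over all unordered set pairs and atoms."""
    labels = common_labels(list(calc_sets) + list(exp_sets))
    exp = [exp_sets[j] for j in perm]
    total, count = 0.0, 0
    n = len(calc_sets)
    for i in range(n):
        for j in range(i + 1, n):
            for lab in labels:
                d_calc = calc_sets[i].shifts[lab] - calc_sets[j].shifts[lab]
                d_exp = exp[i].shifts[lab] - exp[j].shifts[lab]
                total += abs(d_calc - d_exp)
                count += 1
    return total / count


def brute_avg_mae(calc_sets, exp_sets, perm):
    maes = [
        brute_mae(c, exp_sets[j]) for c, j in zip(calc_sets, perm)
    ]
    return sum(maes) / len(maes)


def brute_best_alignment(calc_sets, exp_sets):
    """Exhaustive argmin over all permutations, recursion-generated."""

    def perms(items):
        if len(items) <= 1:
            yield tuple(items)
            return
        for k, head in enumerate(items):
            for tail in perms(items[:k] + items[k + 1 :]):
                yield (head,) + tail

    best, best_score = None, float("inf")
    for perm in perms(list(range(len(calc_sets)))):
        score = brute_mae_dddelta(calc_sets, exp_sets, perm)
        if score < best_score:
            best, best_score = perm, score
    return best, best_score


def brute_boltzmann(energies, rt):
    factors = [math.exp(-e / rt) for e in energies]
    total = sum(factors)
    return [f / total for f in factors]
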