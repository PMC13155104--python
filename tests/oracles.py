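"""Independent, deliberately naive reimplementations used as test oracles.

Everything here is loop-based scalar arithmetic straight from the model
definitions, sharing no code with the vectorized pipeline it checks.
"""

import math


def naive_eaf_chain(
    reads_by_asv: dict[str, list[float]],
    sq: list[float],
    densities: list[float],
    reads_by_asv_unlabeled: dict[str, list[float]],
    sq_unlabeled: list[float],
    densities_unlabeled: list[float],
    asv: str,
) -> float:
    """EAF for one ASV from one labeled and one unlabeled replicate."""

    def weighted_density(reads_by, sqs, dens, target):
        num = den = 0.0
        for k in range(len(sqs)):
            total = sum(reads_by[a][k] for a in reads_by)
            if total == 0:
                continue
            copies = reads_by[target][k] / total * sqs[k]
            num += dens[k] * copies
            den += copies
        return num / den

    w_lab = weighted_density(reads_by_asv, sq, densities, asv)
    w_light = weighted_density(
        reads_by_asv_unlabeled, sq_unlabeled, densities_unlabeled, asv
    )
    gc = (w_light - 1.646057) / 0.083506
    m_light = 0.496 * gc + 307.691
    m_heavy = -0.4987282 * gc + 9.974564 + m_light
    m_lab = (w_lab / w_light) * m_light
    return (m_lab - m_light) / (m_heavy - m_light) * (1.0 - 0.01111233)


def naive_shannon(counts: list[float]) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def naive_permanova_f(dmat, labels) -> float:
    """Pseudo-F from the definition, nested loops over pairs."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += dmat[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += dmat[idx[a]][idx[b]] ** 2
        ss_within += s / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))
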