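"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np

from nestipm import io as nio


def cjs_enumeration_loglik(histories, sJ, sA, pB, pCapB):
    """CJS likelihood by exhaustive enumeration over mortality times.

    For each individual, sums the probability of its detection history over
    every possible last-alive occasion. Independent of the recursive
    chi-based implementation; exact for small occasion counts.
    """
    sJ = np.asarray(sJ, float)
    sA = np.asarray(sA, float)
    pB = np.atleast_2d(np.asarray(pB, float))
    pCapB = np.asarray(pCapB, float)
    T = pCapB.size
    p_y = pB[0] * pCapB
    p_a = pB[1] * pCapB
    total = 0.0
    for i in range(len(histories)):
        f = int(histories.first_year[i])
        det = histories.detections[i]
        juv = histories.ring_age[i] == "nestling"
        last = int(np.nonzero(det)[0][-1])
        prob = 0.0
        # m = last occasion at which the individual is alive
        for m in range(last, T):
            pr = 1.0
            for t in range(f, m):          # survive each interval t -> t+1
                pr *= sJ[t] if (juv and t == f) else sA[t]
            if m < T - 1:                  # dies in interval m -> m+1
                pr *= 1.0 - (sJ[m] if (juv and m == f) else sA[m])
            for t in range(f + 1, m + 1):  # detection outcomes while alive
                p = p_y[t] if (juv and t == f + 1) else p_a[t]
                pr *= p if det[t] else 1.0 - p
            prob += pr
        total += np.log(prob)
    return total


def random_histories(rng, T, n):
    """Random capture histories over T occasions (mixed ring ages)."""
    rows_age = []
    first = []
    det = np.zeros((n, T), dtype=np.int8)
    for i in range(n):
        f = int(rng.integers(0, T - 1))
        age = "nestling" if rng.random() < 0.5 else "adult"
        det[i, f] = 1
        for t in range(f + 1, T):
            if rng.random() < 0.35:
                det[i, t] = 1
        first.append(f)
        rows_age.append(age)
    return nio.CaptureHistories(
        individuals=np.array([f"i{i}" for i in range(n)]),
        ring_age=np.array(rows_age),
        first_year=np.array(first),
        detections=det,
        years=np.arange(2000, 2000 + T),
    )


def random_cjs_params(rng, T):
    return dict(
        sJ=rng.uniform(0.05, 0.6, T),
        sA=rng.uniform(0.2, 0.9, T),
        pB=rng.uniform(0.3, 1.0, (2, T)),
        pCapB=rng.uniform(0.4, 1.0, T),
    )
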