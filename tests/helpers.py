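"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the vectorized implementation paths in the package:
group-pair counting enumerates index pairs one by one, metrics are recomputed
from per-sample (label, prediction) lists, and the mRMR score is evaluated by
exhaustive search over candidate subsets.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GROUPS = ("GAVLMI", "FYW", "KRH", "DE", "STCPNQ")
GROUP_OF = {aa: gi for gi, g in enumerate(GROUPS) for aa in g}


def cksaagp_oracle(sequence: str, k_values=(0, 1, 2, 3, 4, 5)) -> np.ndarray:
    """Count group pairs (i, i+k+1) one pair at a time and normalize."""
    L = len(sequence)
    out = np.zeros(25 * len(k_values))
    for bi, k in enumerate(k_values):
        denom = L - (k + 1)
        if denom <= 0:
            continue
        counts = Counter()
        for i in range(L):
            j = i + k + 1
            if j < L:
                counts[(GROUP_OF[sequence[i]], GROUP_OF[sequence[j]])] += 1
        for (g1, g2), c in counts.items():
            out[bi * 25 + g1 * 5 + g2] = c / denom
    return out


def metrics_from_pairs(pairs: list[tuple[int, int]]) -> dict[str, float]:
    """Accuracy / specificity / F1 / MCC recomputed from (label, prediction)
    pairs using the textbook formulas, independent of the package."""
    tp = sum(1 for t, p in pairs if t == 1 and p == 1)
    tn = sum(1 for t, p in pairs if t == 0 and p == 0)
    fp = sum(1 for t, p in pairs if t == 0 and p == 1)
    fn = sum(1 for t, p in pairs if t == 1 and p == 0)
    n = len(pairs)
    acc = (tp + tn) / n
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"accuracy": acc, "specificity": spec, "f1": f1, "mcc": mcc,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


def discrete_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) computed cell by cell."""
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.sum((x == xv) & (y == yv)) / n
            if pxy > 0:
                px = np.sum(x == xv) / n
                py = np.sum(y == yv) / n
                mi += pxy * math.log(pxy / (px * py))
    return mi


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))
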