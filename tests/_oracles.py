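"""Independent reference implementations used only for cross-checking.

These deliberately avoid the code paths of the package: the envelope
oracle enumerates isotopologue combinations exhaustively (stars-and-bars
with exact multinomial weights) instead of convolving truncated
polynomials, and the digestion oracle enumerates subsets of cleavage
sites instead of scanning cut-point pairs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from glycoquant.isotopes import atomic_isotopes


def envelope_oracle(formula, n: int = 7) -> np.ndarray:
    """Aggregated isotope distribution by exhaustive enumeration."""
    total = {0: 1.0}
    for element, count in formula.items():
        offs, abund = atomic_isotopes(element)
        k = len(offs)
        dist: dict[int, float] = {}
        for combo in itertools.combinations(range(count + k - 1), k - 1):
            counts, prev = [], -1
            for c in combo:
                counts.append(c - prev - 1)
                prev = c
            counts.append(count + k - 2 - prev)
            p = math.factorial(count)
            off = 0
            for ci, pi, oi in zip(counts, abund, offs):
                p *= pi ** ci / math.factorial(ci)
                off += ci * int(oi)
            dist[off] = dist.get(off, 0.0) + p
        new: dict[int, float] = {}
        for o1, p1 in total.items():
            for o2, p2 in dist.items():
                if o1 + o2 < n:
                    new[o1 + o2] = new.get(o1 + o2, 0.0) + p1 * p2
        total = new
    out = np.zeros(n)
    for off, p in total.items():
        out[off] = p
    return out / out.sum()


def digest_oracle(protein: str, specificity, max_missed: int
                  ) -> set[tuple[int, int, str, int]]:
    """All (start, end, sequence, missed) peptides by enumerating every
    subset of cleavage sites."""
    cuts = [i for i in range(1, len(protein))
            if protein[i - 1] in specificity and protein[i] != "P"]
    peptides = set()
    for r in range(len(cuts) + 1):
        for chosen in itertools.combinations(cuts, r):
            bounds = [0, *chosen, len(protein)]
            for a, b in zip(bounds, bounds[1:]):
                internal = sum(1 for c in cuts if a < c < b)
                if internal <= max_missed:
                    peptides.add((a + 1, b, protein[a:b], internal))
    return peptides
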