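"""RNA secondary structure by base-pair maximization (Nussinov DP).

The curation engine needs a self-contained, exactly testable notion of
"hairpin-like structure", so folding maximizes the number (or a weighted
score) of nested base pairs over {AU, GC, GU} with a minimum hairpin
loop of 3 unpaired nucleotides, rather than minimizing free energy.
The traceback is deterministic: at each subproblem the 5'-most base is
paired with the largest admissible partner that preserves optimality,
which recovers the outermost stem first and so reads out clean
stem-loops whenever one attains the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

MIN_LOOP = 3  # j - i >= 4 for every pair

#: unit weights: plain pair counting
UNIT_WEIGHTS = {"GC": 1.0, "AU": 1.0, "GU": 1.0}
#: stacked-strength weights used as an energy proxy by the accessibility
#: predictor (GC strongest, GU wobble weakest)
ENERGY_WEIGHTS = {"GC": 3.0, "AU": 2.0, "GU": 1.0}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class FoldInputError(ValueError):
    pass


def _weight_matrix(weights: dict[str, float]) -> np.ndarray:
    w = np.full((5, 5), -np.inf)
    gc, au, gu = weights["GC"], weights["AU"], weights["GU"]
    w[2, 1] = w[1, 2] = gc
    w[0, 3] = w[3, 0] = au
    w[2, 3] = w[3, 2] = gu
    return w


def nussinov(
    seq: str,
    weights: dict[str, float] | None = None,
    blocked: Iterable[int] = (),
) -> tuple[float, set[tuple[int, int]]]:
    """Maximum-weight nested pairing of *seq*.

    Parameters
    ----------
    seq : DNA or RNA string (T and U equivalent).
    weights : pair-class weights keyed by "GC", "AU", "GU".
    blocked : positions forbidden from pairing (used to model a target
        site forced single-stranded).

    Returns the optimal score and the deterministic-traceback pair set.
    """
    n = len(seq)
    if n == 0:
        return 0.0, set()
    code = np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.intp)
    W = _weight_matrix(UNIT_WEIGHTS if weights is None else weights)[
        code[:, None], code[None, :]
    ]
    for b in blocked:
        W[b, :] = -np.inf
        W[:, b] = -np.inf
    # min loop: forbid pairs closer than MIN_LOOP+1
    ii, jj = np.indices((n, n))
    W[jj - ii < MIN_LOOP + 1] = -np.inf

    # dp[i, j] = best score for the inclusive segment seq[i..j]
    dp = np.zeros((n, n))
    for span in range(1, n):
        i = np.arange(0, n - span)
        j = i + span
        # pair (i, j): empty interior when span < 2 is impossible anyway
        interior = dp[i + 1, j - 1] if span >= 2 else np.zeros(len(i))
        pair_term = interior + W[i, j]
        # bifurcation dp[i][k] + dp[k+1][j], k = i..j-1 (covers i/j unpaired)
        t = np.arange(span)
        left = dp[i[:, None], i[:, None] + t[None, :]]
        right = dp[i[:, None] + t[None, :] + 1, j[:, None]]
        best = (left + right).max(axis=1)
        dp[i, j] = np.maximum(best, pair_term)

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i:
            continue
        target = dp[i, j]
        paired = False
        for j2 in range(j, i + MIN_LOOP, -1):
            if W[i, j2] == -np.inf:
                continue
            interior = dp[i + 1, j2 - 1] if j2 - i >= 2 else 0.0
            tail = dp[j2 + 1, j] if j2 < j else 0.0
            if interior + W[i, j2] + tail == target:
                pairs.add((i, j2))
                stack.append((i + 1, j2 - 1))
                stack.append((j2 + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return float(dp[0, n - 1]), pairs


def pairs_to_dotbracket(n: int, pairs: set[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def count_terminal_loops(pairs: set[tuple[int, int]]) -> int:
    """Number of hairpin (terminal) loops: pairs enclosing no paired base."""
    paired_pos = sorted(p for ij in pairs for p in ij)
    import bisect

    n_loops = 0
    for i, j in pairs:
        lo = bisect.bisect_right(paired_pos, i)
        hi = bisect.bisect_left(paired_pos, j)
        if lo == hi:  # nothing paired strictly inside (i, j)
            n_loops += 1
    return n_loops


@dataclass(slots=True)
class HairpinStructure:
    """Predicted structure of a candidate precursor.

    ``seq`` is kept in RNA alphabet; ``pairs`` are nested (i, j) index
    pairs with j − i ≥ 4; ``paired_fraction`` is 2·|pairs|/len(seq).
    """

    seq: str
    pairs: set[tuple[int, int]]
    dotbracket: str
    n_terminal_loops: int
    paired_fraction: float

    def partner_map(self) -> dict[int, int]:
        pm: dict[int, int] = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm


def fold_hairpin(seq: str) -> HairpinStructure:
    """Fold a candidate precursor by base-pair maximization.

    Accepts DNA or RNA, 8–200 nt.  Deterministic for a given input.
    """
    if not (8 <= len(seq) <= 200):
        raise FoldInputError(f"sequence length {len(seq)} outside [8, 200]")
    _, pairs = nussinov(seq)
    rna = seq.upper().replace("T", "U")
    return HairpinStructure(
        seq=rna,
        pairs=pairs,
        dotbracket=pairs_to_dotbracket(len(seq), pairs),
        n_terminal_loops=count_terminal_loops(pairs),
        paired_fraction=2.0 * len(pairs) / len(seq),
    )
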