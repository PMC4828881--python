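"""UTR secondary-structure disruption ranking.

For a UTR variant, the structure-change score is
``distance = 1 - Pearson correlation`` between the base-pairing
probability profiles of the wild-type and mutant sequences. The variant
is then ranked against every other possible single-nucleotide
substitution of the UTR (3L of them for a UTR of length L), most
disruptive first, and ``p_value = rank / total``: a small p-value means
few substitutions anywhere in the UTR disturb the ensemble structure as
much. Variants with p < 0.1 are prioritized.

The folding engine is pluggable: the production engine uses the
ViennaRNA partition function when its python bindings are importable;
the built-in engine is a deterministic Boltzmann-weighted
Nussinov/McCaskill pair-probability calculator (exact inside-outside
sums over non-crossing structures with per-pair weights), adequate for
exercising the ranking statistic without thermodynamic tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StructureRank", "ToyPartitionEngine", "ViennaPartitionEngine",
           "get_engine", "structure_disruption_rank", "rank_to_pvalue",
           "all_substitutions"]

PRIORITIZE_P = 0.1
MIN_HAIRPIN = 3
#: Boltzmann-like weights per closing pair (canonical + wobble)
PAIR_WEIGHTS = {
    ("G", "C"): 8.0, ("C", "G"): 8.0,
    ("A", "U"): 3.0, ("U", "A"): 3.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}


@dataclass(frozen=True)
class StructureRank:
    variant: tuple[int, str, str]
    distance: float
    rank: int
    total: int

    @property
    def p_value(self) -> float:
        return self.rank / self.total

    @property
    def prioritized(self) -> bool:
        return self.p_value < PRIORITIZE_P


def rank_to_pvalue(rank: int, total: int) -> float:
    """The rank statistic as a p-value, rank / total."""
    if not (1 <= rank <= total):
        raise ValueError("rank must lie in [1, total]")
    return rank / total


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _pair_weight(a: str, b: str) -> float:
    return PAIR_WEIGHTS.get((a, b), 0.0)


class ToyPartitionEngine:
    """Exact pair probabilities under a pair-weight Boltzmann ensemble.

    Every non-crossing secondary structure with hairpin loops of at least
    MIN_HAIRPIN unpaired bases gets weight = product of its pair weights;
    pair probabilities are computed by inside-outside sums. O(n^4) — meant
    for short test sequences, not genome-scale work.
    """

    name = "toy"

    def pair_probabilities(self, sequence: str) -> np.ndarray:
        s = _rna(sequence)
        n = len(s)
        # inside: Z[i][j] = partition function of s[i..j], 1 if empty
        Z = np.ones((n + 2, n + 2))
        pairable = [
            (i, j)
            for i in range(n)
            for j in range(i + MIN_HAIRPIN + 1, n)
            if _pair_weight(s[i], s[j]) > 0
        ]
        for span in range(1, n + 1):
            for i in range(0, n - span + 1):
                j = i + span - 1
                total = Z[i + 1][j + 1 - 1]  # j unpaired -> Z[i..j-1]
                for k in range(i, j - MIN_HAIRPIN):
                    w = _pair_weight(s[k], s[j])
                    if w > 0:
                        total += Z[i + 1][k - 1 + 1] * w * Z[k + 2][j - 1 + 1]
                Z[i + 1][j + 1] = total

        def Zin(i: int, j: int) -> float:
            """Z over s[i..j] inclusive; 1 when empty."""
            if i > j:
                return 1.0
            return Z[i + 1][j + 1]

        Ztot = Zin(0, n - 1)
        P = np.zeros((n, n))
        # decreasing span so enclosing pairs are resolved first
        for (p, q) in sorted(pairable, key=lambda pq: pq[0] - pq[1]):
            w = _pair_weight(s[p], s[q])
            zb = w * Zin(p + 1, q - 1)
            prob = Zin(0, p - 1) * zb * Zin(q + 1, n - 1) / Ztot
            for (i, j) in pairable:
                if i < p and q < j and P[i, j] > 0:
                    prob += (P[i, j] * Zin(i + 1, p - 1) * zb
                             * Zin(q + 1, j - 1) / Zin(i + 1, j - 1))
            P[p, q] = prob
        return P + P.T

    def unpaired_profile(self, sequence: str) -> np.ndarray:
        P = self.pair_probabilities(sequence)
        return 1.0 - P.sum(axis=1)

    def mfe_structure(self, sequence: str) -> str:
        """Dot-bracket of the maximum-weight structure (log-weight Nussinov)."""
        s = _rna(sequence)
        n = len(s)
        best = np.zeros((n + 1, n + 1))
        for span in range(MIN_HAIRPIN + 2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span - 1
                cand = best[i][j - 1]
                for k in range(i, j - MIN_HAIRPIN):
                    w = _pair_weight(s[k], s[j])
                    if w > 0:
                        left = best[i][k - 1] if k > i else 0.0
                        inner = best[k + 1][j - 1]
                        cand = max(cand, left + math.log(w) + inner)
                best[i][j] = cand
        pairs = []

        def traceback(i: int, j: int) -> None:
            if j - i < MIN_HAIRPIN + 1:
                return
            if best[i][j] == best[i][j - 1]:
                traceback(i, j - 1)
                return
            for k in range(i, j - MIN_HAIRPIN):
                w = _pair_weight(s[k], s[j])
                if w > 0:
                    left = best[i][k - 1] if k > i else 0.0
                    if math.isclose(best[i][j],
                                    left + math.log(w) + best[k + 1][j - 1]):
                        pairs.append((k, j))
                        if k > i:
                            traceback(i, k - 1)
                        traceback(k + 1, j - 1)
                        return
            traceback(i, j - 1)

        traceback(0, n - 1)
        dots = ["."] * n
        for a, b in pairs:
            dots[a], dots[b] = "(", ")"
        return "".join(dots)


class ViennaPartitionEngine:
    """Partition-function pair probabilities from the ViennaRNA bindings."""

    name = "vienna"

    def __init__(self):
        import RNA  # noqa: F401 — fails fast when bindings are absent
        self._RNA = RNA

    def pair_probabilities(self, sequence: str) -> np.ndarray:
        s = _rna(sequence)
        n = len(s)
        fc = self._RNA.fold_compound(s)
        fc.pf()
        bpp = np.array(fc.bpp())[1:, 1:]  # 1-indexed in ViennaRNA
        P = np.zeros((n, n))
        P[: bpp.shape[0], : bpp.shape[1]] = bpp
        return P + P.T

    def unpaired_profile(self, sequence: str) -> np.ndarray:
        return 1.0 - self.pair_probabilities(sequence).sum(axis=1)

    def mfe_structure(self, sequence: str) -> str:
        structure, _ = self._RNA.fold(_rna(sequence))
        return structure


def get_engine(name: str = "auto"):
    if name == "toy":
        return ToyPartitionEngine()
    if name == "vienna":
        return ViennaPartitionEngine()
    if name == "auto":
        try:
            return ViennaPartitionEngine()
        except ImportError:
            return ToyPartitionEngine()
    raise ValueError(f"unknown folding engine {name!r}")


def all_substitutions(sequence: str) -> list[tuple[int, str, str]]:
    """All 3L single-nucleotide substitutions of the sequence (U read as T)."""
    seq = sequence.upper().replace("U", "T")
    subs = []
    for i, ref in enumerate(seq):
        for alt in "ACGT":
            if alt != ref:
                subs.append((i, ref, alt))
    return subs


def _profile(engine, sequence: str, mode: str) -> np.ndarray:
    if mode == "unpaired":
        return engine.unpaired_profile(sequence)
    if mode == "matrix":
        P = engine.pair_probabilities(sequence)
        return P[np.triu_indices_from(P, k=1)]
    raise ValueError(f"unknown correlation mode {mode!r}")


def _distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation, with degenerate profiles handled."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0 if np.allclose(a, b) else 1.0
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def structure_disruption_rank(utr_sequence: str,
                              variant: tuple[int, str, str],
                              folding_engine=None,
                              mode: str = "unpaired") -> StructureRank:
    """Rank one substitution's structure disruption among all 3L of them.

    Ties on equal distance break deterministically by genomic position,
    then alt allele lexicographically. A variant identical to the
    reference has distance 0 and rank = total by convention.
    """
    engine = folding_engine or get_engine("auto")
    seq = utr_sequence.upper().replace("U", "T")
    if len(seq) < 20:
        raise ValueError("UTR must be at least 20 nt for structure ranking")
    pos, ref, alt = variant
    ref = ref.upper().replace("U", "T")
    alt = alt.upper().replace("U", "T")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("structure ranking supports substitutions only")
    if seq[pos] != ref:
        raise ValueError(f"reference mismatch at {pos}: expected {ref!r}, "
                         f"found {seq[pos]!r}")
    subs = all_substitutions(seq)
    total = len(subs)
    if alt == ref:
        return StructureRank(variant=(pos, ref, alt), distance=0.0,
                             rank=total, total=total)
    wt = _profile(engine, seq, mode)
    scored = []
    for (i, r, a) in subs:
        mut = seq[:i] + a + seq[i + 1:]
        d = _distance(wt, _profile(engine, mut, mode))
        scored.append((-d, i, a))
    scored.sort()
    query = next(k for k, (_, i, a) in enumerate(scored)
                 if i == pos and a == alt)
    return StructureRank(variant=(pos, ref, alt),
                         distance=-scored[query][0],
                         rank=query + 1, total=total)
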