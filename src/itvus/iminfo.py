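"""Individual-information weight matrices and site scoring.

Everything in this package is built on individual information (Ri): the
log-odds surprisal, in bits, of a specific sequence under a binding-site
model relative to an equiprobable background. A model is summarised by an
information weight matrix (IWM) with one bit value per (position, base);
the Ri of a candidate site is the sum of the cells its bases select.
Rsequence is the mean information content of the model (the average Ri of
its training sites) and bounds what a "strong" site means for that factor.
For a variant, the change ``delta_ri = Ri(alt) - Ri(ref)`` bounds the fold
change in binding affinity by ``2**delta_ri``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

__all__ = [
    "BASES",
    "FrequencyMatrix",
    "InformationWeightMatrix",
    "SiteScore",
    "SiteChange",
    "FoldChange",
    "reverse_complement",
    "sampling_correction",
    "build_iwm_from_sites",
    "build_iwm_from_pwm",
    "score_site",
    "scan_sequence",
    "delta_ri",
    "fold_change",
    "read_matrix",
    "write_matrix",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sampling_correction(n_sites: int) -> float:
    """Small-sample information correction e(n) in bits per position.

    Standard first-order approximation for a 4-letter alphabet,
    e(n) ~= 3 / (2 ln2 n).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive for sampling correction")
    return 3.0 / (2.0 * math.log(2.0) * n_sites)


@dataclass
class FrequencyMatrix:
    """Per-position base frequencies f(b, l) for a binding-site model.

    ``freq`` has shape (length, 4) in A,C,G,T order, every row summing to 1
    with strictly positive cells after pseudocount renormalization.
    ``n_sites`` is the number of training sites (0 = unknown, e.g. a
    published PWM).
    """

    freq: np.ndarray
    n_sites: int = 0
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError("frequency matrix must have shape (length, 4)")
        if self.freq.shape[0] < 1:
            raise ValueError("frequency matrix needs at least one position")
        sums = self.freq.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("frequency matrix column sums to 0")
        # pseudocount probability mass, then renormalize
        self.freq = self.freq / sums[:, None]
        if np.any(self.freq <= 0):
            self.freq = self.freq + self.pseudocount
            self.freq = self.freq / self.freq.sum(axis=1)[:, None]

    @property
    def length(self) -> int:
        return self.freq.shape[0]


@dataclass
class InformationWeightMatrix:
    """Information weight matrix: riw(b, l) in bits, plus model summaries.

    ``offset`` is the index of the position aligned to the biological
    anchor (for splice-site models, the intron/exon boundary); scoring a
    site "at position p" places column ``offset`` on reference coordinate p.
    """

    riw: np.ndarray
    r_sequence: float
    r_sequence_sd: float = 0.0
    sampling_correction: float = 0.0
    polarity: str = "motif"
    offset: int = 0
    model_id: str = ""
    n_sites: int = 0
    sd_undefined_from_pwm: bool = False

    def __post_init__(self) -> None:
        self.riw = np.asarray(self.riw, dtype=float)
        if self.riw.ndim != 2 or self.riw.shape[1] != 4:
            raise ValueError("riw must have shape (length, 4)")
        if self.polarity not in ("acceptor", "donor", "motif"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def length(self) -> int:
        return self.riw.shape[0]

    @property
    def max_ri(self) -> float:
        """Ri of the consensus sequence: sum of per-column maxima."""
        return float(self.riw.max(axis=1).sum())

    @property
    def min_ri(self) -> float:
        return float(self.riw.min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.riw.argmax(axis=1))


@dataclass(frozen=True)
class SiteScore:
    """Ri of one candidate site: the model anchor sits at ``position``."""

    position: int
    strand: str
    ri: float
    model_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.ri):
            raise ValueError("site Ri must be finite")


@dataclass(frozen=True)
class SiteChange:
    """Ref vs alt Ri for one variant at one site anchor."""

    ref_score: SiteScore
    alt_score: SiteScore
    delta_ri: float
    best_alt_score: SiteScore | None = None  # indel re-anchoring, secondary

    @property
    def ri_initial(self) -> float:
        return self.ref_score.ri

    @property
    def ri_final(self) -> float:
        return self.alt_score.ri


@dataclass(frozen=True)
class FoldChange:
    fold: float
    direction: str  # "increase" | "reduction" | "none"

    def __str__(self) -> str:
        return f"{format_fold(self.fold)}-fold {self.direction}"


def _site_array(sites: list[str]) -> np.ndarray:
    if not sites:
        raise ValueError("need at least one aligned site")
    length = len(sites[0])
    for s in sites:
        if len(s) != length:
            raise ValueError("aligned sites must all have the same length")
    arr = np.full((len(sites), length), -1, dtype=int)
    for i, s in enumerate(sites):
        for j, c in enumerate(s.upper()):
            if c in BASE_INDEX:
                arr[i, j] = BASE_INDEX[c]
            elif c != "N":
                raise ValueError(f"unexpected character {c!r} in site {s!r}")
    return arr


def build_iwm_from_sites(
    aligned_sites: list[str],
    apply_correction: bool = True,
    pseudocount: float = 1.0,
    polarity: str = "motif",
    offset: int = 0,
    model_id: str = "",
) -> InformationWeightMatrix:
    """Build an IWM from equal-length aligned binding sites.

    riw(b, l) = 2 + log2 f(b, l) - e(n), with f from Laplace-smoothed
    counts (``pseudocount`` counts added to every cell; N bases contribute
    nothing at their position). Rsequence is the mean Ri of the training
    sites and Rsequence_sd their standard deviation; with zero pseudocount
    Rsequence coincides with the column-entropy sum sum_l(2 - H(l) - e(n)).
    """
    arr = _site_array(aligned_sites)
    n, length = arr.shape
    counts = np.zeros((length, 4), dtype=float)
    for b in range(4):
        counts[:, b] = (arr == b).sum(axis=0)
    if pseudocount == 0 and np.any(counts == 0):
        raise ValueError("zero counts present; a positive pseudocount is required")
    counts += pseudocount
    freq = counts / counts.sum(axis=1)[:, None]
    e_n = sampling_correction(n) if apply_correction else 0.0
    riw = 2.0 + np.log2(freq) - e_n

    # Ri of every training site; N positions contribute nothing.
    site_ri = np.zeros(n)
    for i in range(n):
        idx = arr[i]
        ok = idx >= 0
        site_ri[i] = riw[np.nonzero(ok)[0], idx[ok]].sum()
    r_sequence = float(site_ri.mean())
    r_sequence_sd = float(site_ri.std(ddof=0))
    return InformationWeightMatrix(
        riw=riw,
        r_sequence=r_sequence,
        r_sequence_sd=r_sequence_sd,
        sampling_correction=e_n,
        polarity=polarity,
        offset=offset,
        model_id=model_id,
        n_sites=n,
    )


def build_iwm_from_pwm(
    pwm: FrequencyMatrix,
    polarity: str = "motif",
    offset: int = 0,
    model_id: str = "",
) -> InformationWeightMatrix:
    """Convert a base-frequency PWM to an IWM.

    riw(b, l) = 2 + log2 f(b, l); no sampling correction (n unknown).
    Rsequence is the column-entropy sum sum_l(2 - H(l)); the training-site
    S.D. is undefined for a PWM and reported as 0 with a marker flag.
    """
    freq = pwm.freq
    riw = 2.0 + np.log2(freq)
    entropy = -(freq * np.log2(freq)).sum(axis=1)
    r_sequence = float((2.0 - entropy).sum())
    return InformationWeightMatrix(
        riw=riw,
        r_sequence=r_sequence,
        r_sequence_sd=0.0,
        sampling_correction=0.0,
        polarity=polarity,
        offset=offset,
        model_id=model_id,
        n_sites=pwm.n_sites,
        sd_undefined_from_pwm=True,
    )


def _score_window(window: str, matrix: InformationWeightMatrix) -> float:
    total = 0.0
    warned = False
    for l, c in enumerate(window):
        idx = BASE_INDEX.get(c)
        if idx is None:
            if not warned:
                warnings.warn(
                    f"non-ACGT base {c!r} in scored window; "
                    "contributing the minimum cell value",
                    stacklevel=3,
                )
                warned = True
            total += float(matrix.riw[l].min())
        else:
            total += float(matrix.riw[l, idx])
    return total


def score_site(
    sequence: str,
    matrix: InformationWeightMatrix,
    position: int,
    strand: str = "+",
) -> SiteScore:
    """Score the site whose model anchor sits at ``position``.

    On the minus strand the reverse complement is read 5'->3', i.e. the
    result equals scoring the reverse-complemented sequence on the plus
    strand at the mirrored coordinate.
    """
    sequence = sequence.upper()
    if strand == "-":
        mirrored = score_site(
            reverse_complement(sequence), matrix, len(sequence) - 1 - position, "+"
        )
        return SiteScore(position=position, strand="-", ri=mirrored.ri,
                         model_id=matrix.model_id)
    if strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    start = position - matrix.offset
    end = start + matrix.length
    if start < 0 or end > len(sequence):
        raise ValueError(
            f"window [{start}, {end}) out of bounds for sequence of "
            f"length {len(sequence)}"
        )
    ri = _score_window(sequence[start:end], matrix)
    return SiteScore(position=position, strand="+", ri=ri, model_id=matrix.model_id)


def scan_sequence(
    sequence: str,
    matrix: InformationWeightMatrix,
    start: int | None = None,
    end: int | None = None,
    strand: str = "+",
    min_ri: float | None = None,
) -> list[SiteScore]:
    """Score every anchor position in [start, end) that fits the footprint."""
    sequence = sequence.upper()
    n = len(sequence)
    lo = matrix.offset if start is None else max(start, matrix.offset)
    hi = (n - matrix.length + matrix.offset + 1) if end is None else min(
        end, n - matrix.length + matrix.offset + 1
    )
    out = []
    for pos in range(lo, hi):
        s = score_site(sequence, matrix, pos, strand)
        if min_ri is None or s.ri > min_ri:
            out.append(s)
    return out


def apply_variant(sequence: str, position: int, ref: str, alt: str) -> str:
    """Return the sequence with ref->alt applied at 0-based ``position``."""
    found = sequence[position : position + len(ref)].upper()
    if found != ref.upper():
        raise ValueError(
            f"reference allele mismatch at position {position}: "
            f"expected {ref!r}, found {found!r}"
        )
    return sequence[:position] + alt + sequence[position + len(ref) :]


def delta_ri(
    sequence: str,
    variant: tuple[int, str, str],
    matrix: InformationWeightMatrix,
    site_anchor: int,
    strand: str = "+",
) -> SiteChange:
    """Ri change at one site anchor for a ref->alt edit.

    SNVs re-score the same window; indels re-score the edited sequence at
    the same boundary coordinate and additionally report the best-scoring
    anchor within +-(indel length) as a secondary result.
    """
    pos, ref, alt = variant
    sequence = sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    edited = apply_variant(sequence, pos, ref, alt)
    ref_score = score_site(sequence, matrix, site_anchor, strand)
    shift = len(alt) - len(ref)
    # same boundary coordinate, shifted if the edit is upstream of the anchor
    alt_anchor = site_anchor if site_anchor <= pos else site_anchor + shift
    alt_score = score_site(edited, matrix, alt_anchor, strand)
    best = None
    if shift != 0:
        candidates = []
        for d in range(-abs(shift), abs(shift) + 1):
            try:
                candidates.append(score_site(edited, matrix, alt_anchor + d, strand))
            except ValueError:
                continue
        if candidates:
            best = max(candidates, key=lambda s: s.ri)
    return SiteChange(
        ref_score=ref_score,
        alt_score=alt_score,
        delta_ri=alt_score.ri - ref_score.ri,
        best_alt_score=best,
    )


def fold_change(delta: float) -> FoldChange:
    """Minimum binding-affinity fold change implied by a bit change.

    A change of delta_ri bits bounds the affinity change by 2**|delta_ri|,
    a reduction when delta_ri < 0.
    """
    if not math.isfinite(delta):
        raise ValueError("delta_ri must be finite")
    if delta == 0:
        return FoldChange(fold=1.0, direction="none")
    direction = "increase" if delta > 0 else "reduction"
    return FoldChange(fold=2.0 ** abs(delta), direction=direction)


def format_bits(x: float) -> str:
    """Report convention: bits to 1 decimal place."""
    return f"{x:.1f}"


def format_fold(x: float) -> str:
    """Report convention: folds to 2 significant figures >= 10, 1 decimal < 10."""
    if x >= 10:
        rounded = float(f"{x:.2g}")
        return f"{rounded:g}"
    return f"{x:.1f}"


# ---------------------------------------------------------------------------
# matrix file format
# ---------------------------------------------------------------------------

def write_matrix(path, matrix: InformationWeightMatrix | FrequencyMatrix,
                 model_id: str | None = None) -> None:
    """Write a matrix in the tab-delimited exchange format.

    IWMs carry a ``#IWM`` header with polarity/offset/rsequence/sd; PWMs a
    ``#PWM`` header. One row per position, four values in A,C,G,T order.
    """
    with open(path, "w") as fh:
        if isinstance(matrix, InformationWeightMatrix):
            mid = model_id or matrix.model_id or "model"
            fh.write(
                f"#IWM {mid} polarity={matrix.polarity} offset={matrix.offset} "
                f"rsequence={matrix.r_sequence:.6f} sd={matrix.r_sequence_sd:.6f}\n"
            )
            values = matrix.riw
        else:
            mid = model_id or "model"
            fh.write(f"#PWM {mid}\n")
            values = matrix.freq
        for row in values:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix(path) -> InformationWeightMatrix | FrequencyMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        rows = [
            [float(x) for x in line.split("\t")]
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
    values = np.array(rows, dtype=float)
    parts = header.split()
    kind = parts[0].lstrip("#")
    model_id = parts[1] if len(parts) > 1 else ""
    kv = dict(p.split("=", 1) for p in parts[2:] if "=" in p)
    if kind == "PWM":
        return FrequencyMatrix(freq=values)
    if kind != "IWM":
        raise ValueError(f"unknown matrix header {header!r}")
    return InformationWeightMatrix(
        riw=values,
        r_sequence=float(kv.get("rsequence", 0.0)),
        r_sequence_sd=float(kv.get("sd", 0.0)),
        polarity=kv.get("polarity", "motif"),
        offset=int(kv.get("offset", 0)),
        model_id=model_id,
    )
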