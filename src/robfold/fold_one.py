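"""Primary-structure layer: positional frequencies, consensus, identity curve.

Conservation around the anchor is quantified three ways: a positional
frequency matrix over the 20 amino acids plus padding, a threshold consensus
string (variable positions shown as 'X'), and the sequence-identity curve

    SI = 100 * (1 - D / L)

where D is the Hamming distance between two equal-length windows and L the
window length.  Residues are additionally mapped to Chou-Fasman structural
equivalence classes (helix-former H, sheet-former E, turn-former T) so that
positions divergent in sequence but convergent in folding propensity are
still recognized as conserved.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from robfold.anchoring import ExpansionWindow

log = logging.getLogger(__name__)

#: Alphabet of the frequency matrix: 20 amino acids plus the padding symbol.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Chou-Fasman conformational propensities (P_alpha, P_beta, P_turn) x 100.
CHOU_FASMAN_PROPENSITIES: dict[str, tuple[int, int, int]] = {
    "A": (142, 83, 66),
    "R": (98, 93, 95),
    "N": (67, 89, 156),
    "D": (101, 54, 146),
    "C": (70, 119, 119),
    "Q": (111, 110, 98),
    "E": (151, 37, 74),
    "G": (57, 75, 156),
    "H": (100, 87, 95),
    "I": (108, 160, 47),
    "K": (114, 74, 101),
    "L": (121, 130, 59),
    "M": (145, 105, 60),
    "F": (113, 138, 60),
    "P": (57, 55, 152),
    "S": (77, 75, 143),
    "T": (83, 119, 96),
    "W": (108, 137, 96),
    "Y": (69, 147, 114),
    "V": (106, 170, 50),
}

# Each residue's class is the argmax of its propensities; ties broken by the
# fixed priority helix > sheet > turn (only Cys ties, at P_beta = P_turn).
CHOU_FASMAN_CLASS: dict[str, str] = {
    aa: "HET"[int(np.argmax(p))] for aa, p in CHOU_FASMAN_PROPENSITIES.items()
}


@dataclass
class FrequencyMatrix:
    """Positional symbol counts for a set of equal-length windows.

    ``counts`` is (window_length, 21) over :data:`ALPHABET`; every row sums
    to ``n_windows``.
    """

    counts: np.ndarray
    n_windows: int

    @property
    def window_length(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_windows

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (rows = window positions, columns = symbols)."""
        return pd.DataFrame(self.counts, columns=list(ALPHABET))


@dataclass
class ConsensusString:
    symbols: str
    threshold: float

    def __str__(self) -> str:
        return self.symbols


def frequency_matrix(windows: list[ExpansionWindow]) -> FrequencyMatrix:
    """Tally symbols per position across same-length windows (padding 'X'
    counted in its own column)."""
    if not windows:
        raise ValueError("need at least one window")
    wlen = windows[0].window_length
    if any(w.window_length != wlen for w in windows):
        raise ValueError("windows have mixed lengths")
    counts = np.zeros((wlen, len(ALPHABET)), dtype=int)
    for w in windows:
        for pos, sym in enumerate(w.padded_seq):
            counts[pos, _AA_INDEX[sym]] += 1
    return FrequencyMatrix(counts=counts, n_windows=len(windows))


def consensus_sequence(matrix: FrequencyMatrix, threshold: float = 1.0) -> ConsensusString:
    """Threshold consensus: a position holds residue ``a`` iff its relative
    frequency is at least ``threshold`` (padding never wins); otherwise 'X'.

    When several residues reach the threshold the most frequent wins; exact
    ties are broken alphabetically (logged).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    freqs = matrix.frequencies
    out = []
    for pos in range(matrix.window_length):
        best = "X"
        best_freq = 0.0
        for i, aa in enumerate(ALPHABET[:-1]):  # exclude padding column
            f = freqs[pos, i]
            if f >= threshold and f > best_freq:
                best, best_freq = aa, f
            elif f >= threshold and f == best_freq and best != "X" and aa < best:
                best = aa
        if best != "X" and np.count_nonzero(freqs[pos, :-1] == best_freq) > 1:
            log.info("consensus tie at position %d broken alphabetically -> %s", pos, best)
        out.append(best)
    return ConsensusString(symbols="".join(out), threshold=threshold)


def chou_fasman_classes(seq: str) -> str:
    """Translate residues to structural equivalence classes over {H, E, T};
    the padding symbol 'X' maps to 'x'."""
    out = []
    for aa in seq:
        if aa == "X":
            out.append("x")
        else:
            try:
                out.append(CHOU_FASMAN_CLASS[aa])
            except KeyError:
                raise ValueError(f"unknown amino acid {aa!r}") from None
    return "".join(out)


@dataclass(frozen=True)
class IdentityResult:
    si_percent: float
    hamming: int
    length: int


def sequence_identity(a: str, b: str, ignore_padding: bool = False) -> IdentityResult:
    """Sequence identity SI = 100 * (1 - D/L) between equal-length strings.

    By default the padding symbol 'X' is an ordinary 21st symbol (X = X counts
    as identical).  With ``ignore_padding=True`` positions padded in either
    string are excluded from both D and L.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty strings")
    if ignore_padding:
        pairs = [(x, y) for x, y in zip(a, b) if x != "X" and y != "X"]
        if not pairs:
            raise ValueError("no unpadded positions in common")
        L = len(pairs)
        D = sum(x != y for x, y in pairs)
    else:
        L = len(a)
        D = sum(x != y for x, y in zip(a, b))
    return IdentityResult(si_percent=100.0 * (1.0 - D / L), hamming=D, length=L)


def _mean_pairwise_si(seqs: list[str]) -> float:
    # vectorized over all unordered pairs: windows as a byte matrix
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(len(seqs), -1)
    L = arr.shape[1]
    total = 0.0
    n_pairs = 0
    for i, j in itertools.combinations(range(len(seqs)), 2):
        D = int(np.count_nonzero(arr[i] != arr[j]))
        total += 100.0 * (1.0 - D / L)
        n_pairs += 1
    return total / n_pairs


def conservation_curve(groups: dict[int, list[ExpansionWindow]]) -> pd.DataFrame:
    """Mean SI over all unordered same-length window pairs, per length.

    Returns a DataFrame with columns ``window_length``, ``n_pairs`` and
    ``mean_si``, ordered by ascending length.  Lengths with fewer than two
    windows are omitted with a warning.
    """
    rows = []
    for wlen in sorted(groups):
        windows = groups[wlen]
        if len(windows) < 2:
            log.warning("window length %d has <2 windows; omitted from curve", wlen)
            continue
        n = len(windows)
        rows.append(
            {
                "window_length": wlen,
                "n_pairs": n * (n - 1) // 2,
                "mean_si": _mean_pairwise_si([w.padded_seq for w in windows]),
            }
        )
    return pd.DataFrame(rows, columns=["window_length", "n_pairs", "mean_si"])
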