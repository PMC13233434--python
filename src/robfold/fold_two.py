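"""Secondary-structure layer: anchor-aligned 3-state consensus and topology.

Per-window secondary structure (from DSSP ingestion or the synthetic
generator) is stacked into an alignment keyed by anchor-relative offset.
Column-wise modal labels with padding-aware denominators yield consensus
strings at partial (>=50%) or complete (100%) recurrence; run-length encoding
of a consensus then supports element-level topology searches such as the
thioredoxin-like beta-alpha-beta-alpha-beta pattern around the CXXC motif or
the triple-helix arrangement flanking EEVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from robfold.anchoring import ExpansionWindow

log = logging.getLogger(__name__)


@dataclass
class SSAlignment:
    """n_windows x window_length table over {H, E, C, x}.

    Offsets run from ``-r`` through ``m - 1 + r`` relative to the anchor
    start; columns 0..m-1 of the motif occupy rows' central positions.
    """

    labels: np.ndarray  # dtype '<U1'
    radius: int
    motif_length: int
    window_ids: list[str]

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.radius, self.motif_length + self.radius)


@dataclass
class SSConsensus:
    labels: str
    support: np.ndarray
    threshold: float
    radius: int = 0

    def __str__(self) -> str:
        return self.labels


@dataclass(frozen=True)
class TopologyMatch:
    """A matched element pattern: ordered (label, start_offset, end_offset)
    runs, offsets anchor-relative and closed."""

    element_pattern: tuple[str, ...]
    matched_runs: tuple[tuple[str, int, int], ...]


def align_secondary(windows: list[ExpansionWindow]) -> SSAlignment:
    """Stack per-window 3-state strings into an anchor-aligned matrix."""
    if not windows:
        raise ValueError("no windows to align")
    wlen = windows[0].window_length
    if any(w.window_length != wlen for w in windows):
        raise ValueError("windows have mixed lengths")
    for w in windows:
        if w.ss3 is None:
            raise ValueError(f"window {w.window_id} has no secondary structure assigned")
    labels = np.array([list(w.ss3) for w in windows], dtype="<U1")
    return SSAlignment(
        labels=labels,
        radius=windows[0].radius,
        motif_length=windows[0].site.length,
        window_ids=[w.window_id for w in windows],
    )


def ss_consensus(
    alignment: SSAlignment,
    threshold: float = 0.5,
    min_coverage: int = 2,
) -> SSConsensus:
    """Column-wise modal consensus with padding-aware denominators.

    Per column, among rows that are not 'x', the modal label is emitted when
    it is the unique mode and its fraction is at least ``threshold``; exact
    ties (no strict majority) and columns covered by fewer than
    ``min_coverage`` rows yield 'x'.
    """
    if alignment.labels.size == 0:
        raise ValueError("empty alignment")
    if threshold not in (0.5, 1.0):
        log.warning("non-standard consensus threshold %.2f (expected 0.5 or 1.0)", threshold)
    n, wlen = alignment.labels.shape
    out = []
    support = np.zeros(wlen)
    for col in range(wlen):
        column = alignment.labels[:, col]
        valid = column[column != "x"]
        if len(valid) < min_coverage:
            out.append("x")
            continue
        labels, counts = np.unique(valid, return_counts=True)
        order = np.argsort(-counts)
        top = counts[order[0]]
        frac = top / len(valid)
        support[col] = frac
        tie = len(counts) > 1 and counts[order[1]] == top
        if not tie and frac >= threshold:
            out.append(str(labels[order[0]]))
        else:
            out.append("x")
    return SSConsensus(labels="".join(out), support=support, threshold=threshold, radius=alignment.radius)


def _runs(labels: str) -> list[tuple[str, int, int]]:
    """Run-length encode as (label, start, end) with closed indices."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - 1))
            start = i
    return runs


def find_topology_pattern(
    consensus: SSConsensus,
    element_pattern: list[str],
    min_run: int = 2,
) -> list[TopologyMatch]:
    """Find ordered element patterns (e.g. [E,H,E,H,E]) in a consensus.

    Coil and undefined runs may separate matched elements and are ignored, as
    are H/E runs shorter than ``min_run`` residues (single-residue calls are
    treated as assignment noise).  Every contiguous subsequence of the
    remaining element runs matching the pattern is reported, with offsets
    relative to the anchor start.
    """
    if any(e not in ("H", "E") for e in element_pattern):
        raise ValueError("element pattern must be drawn from {H, E}")
    elements = [
        (label, start, end)
        for label, start, end in _runs(consensus.labels)
        if label in ("H", "E") and end - start + 1 >= min_run
    ]
    pat = tuple(element_pattern)
    k = len(pat)
    matches = []
    for i in range(len(elements) - k + 1):
        window = elements[i : i + k]
        if tuple(lab for lab, _, _ in window) == pat:
            offset = consensus.radius
            matches.append(
                TopologyMatch(
                    element_pattern=pat,
                    matched_runs=tuple((lab, s - offset, e - offset) for lab, s, e in window),
                )
            )
    return matches
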