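"""Null-model control and site-level benchmarking.

Two independent checks of the pipeline's output:

* A composition-preserving null model: the anchor motif's letters are
  permuted (destroying its biological ordering while keeping its exact
  amino-acid composition) and placed at random positions constrained to the
  same terminal-distance envelope as the biological anchors.  Running the
  conservation-curve computation at these non-biological anchors yields a
  null distribution of decay curves against which the biological curve is
  compared.

* An interval benchmark against reference motif annotations (e.g. a PROSITE
  scan): predicted and reference sites in author-residue space are matched
  one-to-one when their intersection-over-union is at least a threshold
  (default 0.5), yielding TP/FP/FN, precision, recall, F1 and mean IoU, plus
  micro-averages pooled across motifs.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from robfold.anchoring import AnchorSite, ExpansionWindow, expand_window
from robfold.fold_one import conservation_curve
from robfold.structure_io import ProteinRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullTrial:
    """One non-biological-anchor trial: a permuted motif placed at
    margin-constrained random positions of each record."""

    trial_id: int
    seed: int
    permuted_motif: str
    positions: dict[str, int]  # protein_id -> 0-based anchor start
    curve: pd.DataFrame | None = None


def _canonical_motif(bio_sites: Sequence[AnchorSite]) -> str:
    """The motif instance whose letters are permuted: the most frequent
    matched string across biological sites, ties broken lexicographically."""
    counts = Counter(s.matched for s in bio_sites)
    top = max(counts.values())
    return min(m for m, c in counts.items() if c == top)


def _permute_motif(motif: str, rng: np.random.Generator) -> str:
    """Random reordering of the motif letters, rejecting the identity
    permutation whenever a distinct one exists."""
    letters = list(motif)
    if len(set(letters)) == 1:
        return motif
    for _ in range(1000):
        perm = rng.permutation(len(letters))
        out = "".join(letters[i] for i in perm)
        if out != motif:
            return out
    return out  # unreachable for non-uniform motifs


def terminal_margins(records: Sequence[ProteinRecord], bio_sites: Sequence[AnchorSite]) -> tuple[int, int]:
    """Safety margins: the minimum N- and C-terminal distances observed over
    all biological anchors of the family."""
    lengths = {r.id: len(r) for r in records}
    n_margin = min(s.seq_start for s in bio_sites)
    c_margin = min(lengths[s.protein_id] - s.seq_end for s in bio_sites)
    return n_margin, c_margin


def sample_null_anchors(
    records: Sequence[ProteinRecord],
    bio_sites: Sequence[AnchorSite],
    n: int = 50,
    seed: int = 0,
) -> list[NullTrial]:
    """Draw ``n`` composition-preserving null trials.

    Per trial the canonical biological motif is permuted and, for every
    record, an anchor start is drawn uniformly from positions whose N- and
    C-terminal distances are each at least the family-wide minima of the
    biological anchors.  Records with no admissible position are skipped for
    that trial with a warning.  Fully reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not bio_sites:
        raise ValueError("no biological anchor sites supplied")
    motif = _canonical_motif(bio_sites)
    m = len(motif)
    n_margin, c_margin = terminal_margins(records, bio_sites)
    root = np.random.SeedSequence(seed)
    trials = []
    for trial_id, child in enumerate(root.spawn(n), start=1):
        rng = np.random.Generator(np.random.PCG64(child))
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        permuted = _permute_motif(motif, rng)
        positions: dict[str, int] = {}
        for rec in records:
            lo = n_margin
            hi = len(rec) - c_margin - m  # inclusive upper bound for start
            if hi < lo:
                log.warning("trial %d: no admissible null position in %s; skipped", trial_id, rec.id)
                continue
            positions[rec.id] = int(rng.integers(lo, hi + 1))
        trials.append(NullTrial(trial_id=trial_id, seed=trial_seed, permuted_motif=permuted, positions=positions))
    return trials


def _windows_at_positions(
    records: Sequence[ProteinRecord],
    positions: Mapping[str, int],
    m: int,
    radii: Sequence[int],
) -> dict[int, list[ExpansionWindow]]:
    by_id = {r.id: r for r in records}
    groups: dict[int, list[ExpansionWindow]] = {}
    for r in sorted(set(radii)):
        wlen = m + 2 * r
        windows = []
        for rec_id, start in positions.items():
            rec = by_id[rec_id]
            site = AnchorSite(
                protein_id=rec_id,
                seq_start=start,
                seq_end=start + m,
                res_start=rec.seq_to_author(start),
                res_end=rec.seq_to_author(start + m - 1),
                matched=rec.sequence[start : start + m],
            )
            windows.append(expand_window(rec, site, r))
        groups[wlen] = windows
    return groups


@dataclass
class NullDecayResult:
    """Biological curve, per-trial null curves and the per-length envelope."""

    biological: pd.DataFrame
    trials: list[NullTrial]
    envelope: pd.DataFrame = field(default_factory=pd.DataFrame)
    # envelope columns: window_length, null_mean, null_min, null_max, n_trials


def null_decay_experiment(
    records: Sequence[ProteinRecord],
    bio_sites: Sequence[AnchorSite],
    n: int = 50,
    seed: int = 0,
    radii: Sequence[int] = tuple(range(10, 201, 10)),
) -> NullDecayResult:
    """Run the conservation-curve computation at biological and null anchors.

    The biological curve is computed from ``bio_sites``; each null curve is
    computed identically from that trial's sampled positions.  The envelope
    summarizes per length the mean, min and max of the null curves.
    """
    m = len(_canonical_motif(bio_sites))
    # multiple anchors per protein are all kept for the biological curve
    bio_groups: dict[int, list[ExpansionWindow]] = {}
    by_id = {r.id: r for r in records}
    for r in sorted(set(radii)):
        wlen = m + 2 * r
        bio_groups[wlen] = [expand_window(by_id[s.protein_id], s, r) for s in bio_sites]
    biological = conservation_curve(bio_groups)

    trials = sample_null_anchors(records, bio_sites, n=n, seed=seed)
    frames = []
    for trial in trials:
        groups = _windows_at_positions(records, trial.positions, m, radii)
        trial.curve = conservation_curve(groups)
        frames.append(trial.curve.assign(trial_id=trial.trial_id))
    stacked = pd.concat(frames, ignore_index=True)
    envelope = (
        stacked.groupby("window_length")["mean_si"]
        .agg(null_mean="mean", null_min="min", null_max="max", n_trials="count")
        .reset_index()
    )
    return NullDecayResult(biological=biological, trials=trials, envelope=envelope)


# ---------------------------------------------------------------------------
# IoU site benchmark
# ---------------------------------------------------------------------------

Interval = tuple[str, int, int]  # (protein_id, start, end) closed, author space


def interval_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Intersection-over-union of two closed residue intervals."""
    for s, e in (a, b):
        if e < s:
            raise ValueError(f"malformed interval [{s}, {e}]")
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


@dataclass
class BenchmarkResult:
    motif: str
    n_pred: int
    n_ref: int
    tp: int
    fp: int
    fn: int
    mean_iou: float  # over matched (TP) pairs; NaN when no TPs

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            # zero predictions and zero misses: perfect-agreement tables
            # stay well-defined (logged)
            log.info("%s: no predictions; precision reported as 1.0", self.motif)
            return 1.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            log.info("%s: no reference sites; recall reported as 1.0", self.motif)
            return 1.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def to_row(self) -> dict:
        return {
            "motif": self.motif,
            "n_pred": self.n_pred,
            "n_ref": self.n_ref,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "F1": self.f1,
            "mean_IoU": self.mean_iou,
        }


def match_sites_iou(
    predicted: Sequence[Interval],
    reference: Sequence[Interval],
    iou_min: float = 0.5,
    motif: str = "",
) -> BenchmarkResult:
    """Optimal one-to-one matching of predicted vs reference sites by IoU.

    Candidate pairs within the same protein with IoU >= ``iou_min`` enter a
    linear assignment that maximizes the number of matched pairs first and
    total IoU second (a purely greedy descending-IoU pass can strand
    matchable sites); unmatched predictions count as false positives and
    unmatched references as false negatives.
    """
    iou_matrix = np.zeros((len(predicted), len(reference)))
    for i, (pid_p, sp, ep) in enumerate(predicted):
        for j, (pid_r, sr, er) in enumerate(reference):
            if pid_p != pid_r:
                continue
            iou = interval_iou((sp, ep), (sr, er))
            if iou >= iou_min:
                iou_matrix[i, j] = iou
    matched_ious: list[float] = []
    if iou_matrix.size and iou_matrix.any():
        # weight >> max total IoU makes cardinality dominate the assignment
        weights = np.where(iou_matrix > 0, 1e6 + iou_matrix, 0.0)
        rows, cols = linear_sum_assignment(weights, maximize=True)
        matched_ious = [iou_matrix[i, j] for i, j in zip(rows, cols) if iou_matrix[i, j] > 0]
    tp = len(matched_ious)
    return BenchmarkResult(
        motif=motif,
        n_pred=len(predicted),
        n_ref=len(reference),
        tp=tp,
        fp=len(predicted) - tp,
        fn=len(reference) - tp,
        mean_iou=float(np.mean(matched_ious)) if matched_ious else float("nan"),
    )


def micro_average(results: Sequence[BenchmarkResult]) -> BenchmarkResult:
    """Pool TP/FP/FN across motifs and recompute the derived metrics."""
    if not results:
        raise ValueError("no per-motif results to pool")
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    ious = [r.mean_iou * r.tp for r in results if r.tp > 0]
    return BenchmarkResult(
        motif="micro-avg",
        n_pred=sum(r.n_pred for r in results),
        n_ref=sum(r.n_ref for r in results),
        tp=tp,
        fp=fp,
        fn=fn,
        mean_iou=float(sum(ious) / tp) if tp else float("nan"),
    )


def benchmark_table(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    rows = [r.to_row() for r in results]
    rows.append(micro_average(results).to_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PROSITE pattern compiler
# ---------------------------------------------------------------------------

def compile_prosite(pattern: str) -> str:
    """Compile PROSITE pattern syntax to a Python regex.

    Supports the standard constructs: ``-`` separators, ``x`` (any residue),
    ``[ND]`` (alternatives), ``{P}`` (exclusion), ``(n)`` / ``(n,m)``
    repetition, ``<``/``>`` anchors and a trailing period.  Example:
    ``C-x(2)-C`` compiles to ``C.{2}C``.
    """
    pat = pattern.strip().rstrip(".")
    out = []
    if pat.startswith("<"):
        out.append("^")
        pat = pat[1:]
    anchor_end = pat.endswith(">")
    if anchor_end:
        pat = pat[:-1]
    for token in pat.split("-"):
        if not token:
            continue
        m = re.fullmatch(r"([A-Za-z]|\[[A-Z]+\]|\{[A-Z]+\})(?:\((\d+)(?:,(\d+))?\))?", token)
        if m is None:
            raise ValueError(f"unsupported PROSITE token {token!r} in {pattern!r}")
        atom, lo, hi = m.groups()
        if atom in ("x", "X"):
            rx = "."
        elif atom.startswith("["):
            rx = atom
        elif atom.startswith("{"):
            rx = "[^" + atom[1:-1] + "]"
        else:
            rx = atom.upper()
        if hi is not None:
            rx += f"{{{lo},{hi}}}"
        elif lo is not None:
            rx += f"{{{lo}}}"
        out.append(rx)
    if anchor_end:
        out.append("$")
    return "".join(out)


def scan_prosite(
    records: Sequence[ProteinRecord],
    pattern: str,
    motif_name: str = "",
) -> list[Interval]:
    """Scan records with a PROSITE pattern, reporting author-residue
    intervals (closed) for every overlapping occurrence."""
    rx = compile_prosite(pattern)
    sites: list[Interval] = []
    for rec in records:
        for m in re.finditer(f"(?=({rx}))", rec.sequence):
            start, end = m.start(1), m.end(1)
            sites.append((rec.id, rec.seq_to_author(start), rec.seq_to_author(end - 1)))
    return sites
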