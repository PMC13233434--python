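"""Geometric layer: pairwise C-alpha superposition RMSD and the conservation
radius.

For every pair of coordinate-complete windows of the same length, the optimal
least-squares rigid-body superposition (Kabsch, rotation + translation, no
reflection) is computed and the RMSD over paired C-alpha atoms recorded.
Per-length means and the fraction of pairs below a cutoff (default 15 A)
summarize geometric persistence; the conservation radius is the largest
window length whose mean RMSD stays below the cutoff before the first
crossing, separating the rigid scaffold core from flexible flanks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from robfold.anchoring import ExpansionWindow

log = logging.getLogger(__name__)

DEFAULT_RMSD_CUTOFF = 15.0  # Angstrom


def superimpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal rigid-body superposition of two C-alpha sets.

    Kabsch algorithm: centre both sets, take the SVD of the covariance and
    correct the rotation's determinant so reflections are never applied.
    Requires equal lengths of at least 3 points with no missing coordinates.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (N, 3); got {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superimpose")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("coordinate sets contain missing (non-finite) entries")

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # residual-based RMSD (rather than the trace identity) stays exact near 0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    resid = ac @ R.T - bc
    return float(np.sqrt((resid**2).sum() / a.shape[0]))


@dataclass
class RMSDSummary:
    """Per-length and global pairwise RMSD statistics."""

    per_length: pd.DataFrame  # window_length, n_pairs, mean_rmsd, fraction_below_cutoff
    cutoff: float
    global_median: float
    global_sd: float
    histogram: pd.DataFrame  # bin_left, count

    @property
    def fraction_below_cutoff_overall(self) -> float:
        n = self.per_length["n_pairs"].to_numpy()
        f = self.per_length["fraction_below_cutoff"].to_numpy()
        return float((n * f).sum() / n.sum())


def pairwise_rmsd(
    groups: dict[int, list[ExpansionWindow]],
    cutoff: float = DEFAULT_RMSD_CUTOFF,
    bin_width: float = 1.0,
) -> tuple[pd.DataFrame, RMSDSummary]:
    """Score all unordered pairs of coordinate-complete windows per length.

    Windows pair across proteins and across multiple anchors of the same
    protein, so a family with k anchor sites yields C(k, 2) pairs at every
    length where all windows remain complete.  Returns the long-format record
    table (window_length, id_a, id_b, rmsd) and an :class:`RMSDSummary`.
    """
    records = []
    per_length_rows = []
    for wlen in sorted(groups):
        complete = [w for w in groups[wlen] if w.coord_complete]
        if len(complete) < 2:
            log.warning("window length %d: <2 coordinate-complete windows; omitted", wlen)
            continue
        vals = []
        for wa, wb in itertools.combinations(complete, 2):
            r = superimpose_rmsd(wa.coords, wb.coords)
            records.append({"window_length": wlen, "id_a": wa.window_id, "id_b": wb.window_id, "rmsd": r})
            vals.append(r)
        vals = np.array(vals)
        per_length_rows.append(
            {
                "window_length": wlen,
                "n_pairs": len(vals),
                "mean_rmsd": float(vals.mean()),
                "fraction_below_cutoff": float((vals < cutoff).mean()),
            }
        )
    rec_df = pd.DataFrame(records, columns=["window_length", "id_a", "id_b", "rmsd"])
    per_length = pd.DataFrame(
        per_length_rows, columns=["window_length", "n_pairs", "mean_rmsd", "fraction_below_cutoff"]
    )
    all_vals = rec_df["rmsd"].to_numpy()
    if len(all_vals):
        edges = np.arange(0.0, all_vals.max() + bin_width, bin_width)
        counts, edges = np.histogram(all_vals, bins=edges if len(edges) > 1 else 1)
        hist = pd.DataFrame({"bin_left": edges[:-1], "count": counts})
        summary = RMSDSummary(
            per_length=per_length,
            cutoff=cutoff,
            global_median=float(np.median(all_vals)),
            global_sd=float(all_vals.std(ddof=1)) if len(all_vals) > 1 else 0.0,
            histogram=hist,
        )
    else:
        summary = RMSDSummary(
            per_length=per_length,
            cutoff=cutoff,
            global_median=float("nan"),
            global_sd=float("nan"),
            histogram=pd.DataFrame(columns=["bin_left", "count"]),
        )
    return rec_df, summary


@dataclass(frozen=True)
class ConservationRadius:
    cutoff: float
    radius_window_length: int | None  # None when no analysed length stays below cutoff


def conservation_radius(summary: RMSDSummary, cutoff: float | None = None) -> ConservationRadius:
    """Largest analysed window length whose mean RMSD stays below the cutoff.

    Lengths are scanned in ascending order and the scan stops at the first
    crossing, so an isolated dip back below the cutoff at longer lengths does
    not extend the radius.  Undefined (None) when even the shortest analysed
    length is at or above the cutoff.
    """
    if cutoff is None:
        cutoff = summary.cutoff
    if summary.per_length.empty:
        raise ValueError("summary contains no analysed lengths")
    per = summary.per_length.sort_values("window_length")
    radius = None
    for _, row in per.iterrows():
        if row["mean_rmsd"] < cutoff:
            radius = int(row["window_length"])
        else:
            break
    return ConservationRadius(cutoff=cutoff, radius_window_length=radius)
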