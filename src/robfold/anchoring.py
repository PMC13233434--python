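"""Anchor-motif detection and symmetric window expansion.

An anchor motif is a short, functionally critical pattern (CXXC, EEVD, ...)
written either in motif shorthand, where ``X`` means "any residue", or
directly as a regular expression.  Each match becomes the fixed origin for
bidirectional expansions in discrete radius increments; positions beyond the
chain termini are filled with the neutral padding symbol ``X`` so windows of
the same nominal length stay comparable across proteins of different sizes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from robfold.structure_io import ProteinRecord

log = logging.getLogger(__name__)

#: Default expansion radii: discrete increments of ten residues per side,
#: up to 200 (typical domain sizes and motif-centred functional regions).
DEFAULT_RADII: tuple[int, ...] = tuple(range(10, 201, 10))

PAD = "X"


@dataclass(frozen=True)
class MotifPattern:
    """A named, fixed-length anchor motif.

    ``regex`` must match only fixed-length strings (no ``*``/``+``/``?`` or
    variable alternations); the motif length is validated at construction.
    """

    name: str
    regex: str
    _compiled: re.Pattern = field(init=False, repr=False, compare=False)
    length: int = field(init=False, compare=False)

    def __post_init__(self) -> None:
        try:
            compiled = re.compile(self.regex)
        except re.error as exc:
            raise ValueError(f"invalid motif regex {self.regex!r}: {exc}") from exc
        object.__setattr__(self, "_compiled", compiled)
        m = _fixed_pattern_length(self.regex)
        object.__setattr__(self, "length", m)

    @classmethod
    def from_motif(cls, name: str, motif: str | None = None) -> "MotifPattern":
        """Build from motif shorthand: ``CXXC`` compiles to ``C..C``.

        ``X`` denotes any of the 20 amino acids (not the padding symbol).
        """
        motif = motif if motif is not None else name
        regex = "".join("." if c == "X" else re.escape(c) for c in motif.upper())
        return cls(name=name, regex=regex)

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled


def _fixed_pattern_length(regex: str) -> int:
    """Length of the strings a fixed-length regex matches.

    Probes the pattern structure: counts literal characters, ``.`` and
    character classes at the top level.  Rejects quantifiers other than
    fixed repetitions ``{n}``.
    """
    n = 0
    i = 0
    while i < len(regex):
        c = regex[i]
        if c == "\\":
            i += 2
            n += 1
        elif c == "[":
            j = regex.index("]", i + 1)
            i = j + 1
            n += 1
        elif c in "*+?|()":
            raise ValueError(f"motif regex must be fixed-length, got {regex!r}")
        elif c == "{":
            j = regex.index("}", i + 1)
            reps = regex[i + 1 : j]
            if not reps.isdigit():
                raise ValueError(f"motif regex must be fixed-length, got {regex!r}")
            n += int(reps) - 1  # the repeated atom was already counted once
            i = j + 1
        else:
            i += 1
            n += 1
    if n == 0:
        raise ValueError("empty motif pattern")
    return n


@dataclass(frozen=True)
class AnchorSite:
    """A motif match carried in both coordinate spaces.

    ``seq_start``/``seq_end`` are 0-based half-open sequence indices;
    ``res_start``/``res_end`` are the author residue numbers of the first and
    last matched residues (closed interval).
    """

    protein_id: str
    seq_start: int
    seq_end: int
    res_start: int
    res_end: int
    matched: str

    @property
    def length(self) -> int:
        return self.seq_end - self.seq_start


@dataclass
class ExpansionWindow:
    """A padded, anchor-centred window of length ``m + 2r``.

    ``padded_seq[r : r+m]`` is always the matched motif; ``pad_mask`` flags
    positions outside the chain.  ``ss3`` carries the window's 3-state
    secondary structure ('x' where padded or unassigned) and ``coords`` the
    C-alpha coordinates (NaN rows where padded or missing), so downstream
    layers never need to re-index the source record.
    """

    site: AnchorSite
    radius: int
    padded_seq: str
    pad_mask: np.ndarray
    ss3: str | None = None
    coords: np.ndarray | None = None

    @property
    def window_length(self) -> int:
        return len(self.padded_seq)

    @property
    def protein_id(self) -> str:
        return self.site.protein_id

    @property
    def window_id(self) -> str:
        """Stable identifier: protein plus anchor position in author space."""
        return f"{self.site.protein_id}@{self.site.res_start}"

    @property
    def coord_complete(self) -> bool:
        """True iff the window has no padding and a C-alpha at every position."""
        if self.pad_mask.any():
            return False
        if self.coords is None:
            return False
        return bool(np.isfinite(self.coords).all())


def find_anchors(
    record: ProteinRecord,
    pattern: MotifPattern,
    overlapping: bool = True,
) -> list[AnchorSite]:
    """All left-to-right matches of the motif, in both coordinate spaces.

    With ``overlapping=True`` (default) a lookahead scan reports every match
    position, so adjacent or overlapping occurrences — e.g. the two active
    sites of a multi-domain disulfide isomerase — are all captured.
    """
    if not record.sequence:
        raise ValueError(f"record {record.id} has an empty sequence")
    sites: list[AnchorSite] = []
    m = pattern.length
    if overlapping:
        scanner = re.finditer(f"(?=({pattern.regex}))", record.sequence)
        spans = [(mo.start(1), mo.end(1), mo.group(1)) for mo in scanner]
    else:
        spans = [(mo.start(), mo.end(), mo.group()) for mo in pattern.compiled.finditer(record.sequence)]
    for start, end, matched in spans:
        sites.append(
            AnchorSite(
                protein_id=record.id,
                seq_start=start,
                seq_end=end,
                res_start=record.seq_to_author(start),
                res_end=record.seq_to_author(end - 1),
                matched=matched,
            )
        )
    return sites


def expand_window(record: ProteinRecord, site: AnchorSite, radius: int) -> ExpansionWindow:
    """Symmetric expansion of ``radius`` residues on each side of the anchor.

    Covers sequence indices ``[seq_start - r, seq_end + r)``; out-of-bounds
    positions are padded with 'X' and flagged in ``pad_mask``.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    L = len(record)
    lo = site.seq_start - radius
    hi = site.seq_end + radius
    wlen = hi - lo

    chars = []
    ss = []
    coords = np.full((wlen, 3), np.nan)
    mask = np.zeros(wlen, dtype=bool)
    for k, i in enumerate(range(lo, hi)):
        if i < 0 or i >= L:
            chars.append(PAD)
            ss.append("x")
            mask[k] = True
        else:
            chars.append(record.sequence[i])
            ss.append(record.ss3[i] if record.ss3 is not None else "x")
            if record.ca_coords is not None:
                coords[k] = record.ca_coords[i]
    return ExpansionWindow(
        site=site,
        radius=radius,
        padded_seq="".join(chars),
        pad_mask=mask,
        ss3="".join(ss) if record.ss3 is not None else None,
        coords=coords if record.ca_coords is not None else None,
    )


def build_expansion_sets(
    records: Sequence[ProteinRecord],
    pattern: MotifPattern,
    radii: Iterable[int] = DEFAULT_RADII,
    overlapping: bool = True,
    include_motif: bool = False,
) -> dict[int, list[ExpansionWindow]]:
    """One window per anchor site per radius, grouped by window length.

    Ordering inside each length group is deterministic: record order, then
    anchor position.  ``include_motif=True`` additionally emits the bare
    radius-0 windows (the motif itself).
    """
    radii = sorted(set(radii) | ({0} if include_motif else set()))
    anchors = [(rec, site) for rec in records for site in find_anchors(rec, pattern, overlapping)]
    if not anchors:
        log.warning("no anchors for motif %s in any of %d records", pattern.name, len(records))
        return {}
    groups: dict[int, list[ExpansionWindow]] = {}
    for r in radii:
        wlen = pattern.length + 2 * r
        groups[wlen] = [expand_window(rec, site, r) for rec, site in anchors]
    return groups


def filter_representative(
    groups: Mapping[int, list[ExpansionWindow]],
    group_map: Mapping[str, str],
    require_coords: bool = True,
) -> dict[int, list[ExpansionWindow]]:
    """Keep only length categories represented in every taxonomic subgroup.

    For structural analyses (``require_coords=True``) a subgroup counts as
    represented at a length only if it contributes at least one
    coordinate-complete window there; categories failing this for any
    subgroup are dropped.  Sequence-level analyses keep all categories, since
    padding already guarantees representation.
    """
    all_groups = set(group_map.values())
    missing = {w.protein_id for ws in groups.values() for w in ws} - set(group_map)
    if missing:
        raise KeyError(f"protein ids missing from group map: {sorted(missing)}")
    if not require_coords:
        return dict(groups)
    kept: dict[int, list[ExpansionWindow]] = {}
    for wlen in sorted(groups):
        windows = groups[wlen]
        covered = {group_map[w.protein_id] for w in windows if w.coord_complete}
        if covered >= all_groups:
            kept[wlen] = windows
        else:
            log.info(
                "dropping window length %d: subgroups %s lack a complete window",
                wlen,
                sorted(all_groups - covered),
            )
    return kept
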