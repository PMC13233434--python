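"""Self-contained synthetic protein-family fixtures with planted ground truth.

The generator emulates the situation the pipeline is built for: a family of
homologs sharing a short anchor motif (one or more copies per protein) whose
neighbourhood is strongly conserved, embedded in increasingly variable
flanks.  Homologs are derived from a common ancestor by per-position
substitution at a rate that depends on the distance to the nearest anchor;
C-alpha coordinates follow idealized helix/strand/coil templates drawn from a
planted secondary-structure layout, with isotropic noise growing away from
the anchor.  Author residue numbering may start above 1 to emulate crystal
structures with non-contiguous numbering.

Everything is deterministic under the spec seed, and spurious motif
occurrences outside the planted sites are eliminated by rejection sampling so
ground-truth site counts are exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from robfold.anchoring import AnchorSite
from robfold.structure_io import ProteinRecord, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Idealized C-alpha geometry per secondary-structure state:
#: (rise per residue along the segment axis in Angstrom, radial offset, twist per residue in degrees)
_GEOMETRY = {"H": (1.5, 2.3, 100.0), "E": (3.3, 0.8, 180.0), "C": (3.0, 0.5, 65.0)}


@dataclass
class FamilySpec:
    """Parameters of one synthetic family.

    The defaults mirror a disulfide-isomerase-like study family: 11 homologs
    of 400 residues, two CGHC anchors per protein (searched as ``C..C``), a
    strand-helix alternation planted around each anchor, full conservation
    within 20 residues of an anchor and a 0.5 substitution rate in the
    flanks, with coordinate noise growing linearly away from the anchor.
    """

    n_proteins: int = 11
    length: int = 400
    motif: str = "CGHC"
    # regex used for detection and spurious-occurrence rejection; must match the
    # planted motif (default: the CXXC wildcard form of the default motif)
    search_pattern: str | None = "C..C"
    anchors_per_protein: int = 2
    layout: tuple[tuple[str, int], ...] = (
        ("E", 6), ("C", 3), ("H", 10), ("C", 3), ("E", 6), ("C", 3), ("H", 10), ("C", 3), ("E", 6),
    )
    core_radius: int = 20
    core_rate: float = 0.0
    flank_rate: float = 0.5
    profile: Callable[[int], float] | None = None  # overrides the step profile
    coord_noise: float = 1.0  # Angstrom scale; sigma = coord_noise * (0.25 + |offset| / 50)
    numbering_offset: int = 1
    n_groups: int = 2
    seed: int = 0
    id_prefix: str = "SYN"

    def substitution_rate(self, offset: int) -> float:
        """Per-position substitution probability at ``offset`` residues from
        the nearest anchor (step profile unless a custom one is supplied)."""
        if self.profile is not None:
            return float(self.profile(offset))
        return self.core_rate if abs(offset) <= self.core_radius else self.flank_rate

    def noise_sigma(self, offset: int) -> float:
        """Coordinate noise (Angstrom) at ``offset`` from the nearest anchor:
        a small baseline plus a linear rise with distance."""
        return self.coord_noise * (0.25 + abs(offset) / 50.0)

    @property
    def pattern_regex(self) -> str:
        return self.search_pattern if self.search_pattern is not None else re.escape(self.motif)


@dataclass
class GroundTruth:
    """What the generator planted: anchor sites, the conserved-core letters,
    the secondary-structure layout and the full per-residue assignment."""

    sites: list[AnchorSite]
    ancestor: str
    ss3: str
    anchor_starts: list[int]  # 0-based, shared by all homologs
    topology: tuple[str, ...]  # element pattern of the planted layout, e.g. (E,H,E,H,E)
    core_positions: dict[int, str] = field(default_factory=dict)  # seq index -> conserved letter


def _plant_positions(spec: FamilySpec) -> list[int]:
    """Evenly spaced anchor starts, clear of the termini."""
    m = len(spec.motif)
    k = spec.anchors_per_protein
    starts = []
    for i in range(k):
        centre = int(round(spec.length * (i + 1) / (k + 1)))
        starts.append(max(0, min(spec.length - m, centre - m // 2)))
    if len(set(starts)) != k:
        raise ValueError("protein too short for the requested anchors")
    return starts


def _offset_to_nearest(idx: int, starts: Sequence[int], m: int) -> int:
    """Signed distance from a sequence index to the nearest anchor span
    (0 inside a motif)."""
    best = None
    for s in starts:
        if s <= idx < s + m:
            return 0
        d = idx - (s + m - 1) if idx >= s + m else idx - s
        if best is None or abs(d) < abs(best):
            best = d
    return best


def _draw_ancestor(spec: FamilySpec, rng: np.random.Generator) -> str:
    """Random ancestor with the motif planted at the chosen positions and no
    spurious pattern occurrence anywhere else (rejection sampling).

    Every anchor receives the *same* conserved-core template (motif plus
    ``core_radius`` residues per side), mirroring families whose repeated
    anchor-bearing domains are themselves homologous — e.g. the two
    thioredoxin-like active-site domains of a disulfide isomerase — so that
    windows cut at different anchors stay comparable inside the core.
    """
    m = len(spec.motif)
    starts = _plant_positions(spec)
    pattern = re.compile(f"(?=({spec.pattern_regex}))")
    for _ in range(200):
        seq = list(rng.choice(list(AA20), size=spec.length))
        core = list(rng.choice(list(AA20), size=2 * spec.core_radius + m))
        core[spec.core_radius : spec.core_radius + m] = list(spec.motif)
        for s in starts:
            lo = s - spec.core_radius
            for k, aa in enumerate(core):
                if 0 <= lo + k < spec.length:
                    seq[lo + k] = aa
        text = "".join(seq)
        if [mo.start(1) for mo in pattern.finditer(text)] == sorted(starts):
            return text
    raise RuntimeError("could not draw a spurious-free ancestor; pattern too permissive")


def _mutate(spec: FamilySpec, ancestor: str, starts: Sequence[int], rng: np.random.Generator) -> str:
    """One homolog: per-position substitution by the distance-to-anchor
    profile, motif spans held fixed, spurious matches rejected."""
    m = len(spec.motif)
    pattern = re.compile(f"(?=({spec.pattern_regex}))")
    motif_idx = {i for s in starts for i in range(s, s + m)}
    for _ in range(200):
        seq = list(ancestor)
        for i in range(len(seq)):
            if i in motif_idx:
                continue
            rate = spec.substitution_rate(_offset_to_nearest(i, starts, m))
            if rate > 0 and rng.random() < rate:
                choices = AA20.replace(seq[i], "")
                seq[i] = choices[rng.integers(len(choices))]
        text = "".join(seq)
        if [mo.start(1) for mo in pattern.finditer(text)] == sorted(starts):
            return text
    raise RuntimeError("rejection sampling failed to remove spurious motif occurrences")


def _planted_ss(spec: FamilySpec, starts: Sequence[int]) -> str:
    """Whole-chain 3-state assignment: coil everywhere except the layout,
    centred on each anchor motif."""
    ss = ["C"] * spec.length
    layout_len = sum(n for _, n in spec.layout)
    m = len(spec.motif)
    for s in starts:
        centre = s + m // 2
        pos = centre - layout_len // 2
        for state, n in spec.layout:
            for i in range(pos, pos + n):
                if 0 <= i < spec.length:
                    ss[i] = state
            pos += n
    return "".join(ss)


def _ideal_coords(ss: str) -> np.ndarray:
    """Continuous idealized backbone: segment-wise helix/strand/coil walk.

    Helices use a 1.5 A rise and 100 deg twist per residue at 2.3 A radius;
    strands a 3.3 A rise with alternating lateral offset; coil an extended
    walk.  The chain advances along a common axis so window geometry differs
    by secondary structure but remains a single connected curve.
    """
    coords = np.zeros((len(ss), 3))
    z = 0.0
    angle = 0.0
    for i, state in enumerate(ss):
        rise, radius, twist = _GEOMETRY[state]
        angle += np.deg2rad(twist)
        coords[i] = (radius * np.cos(angle), radius * np.sin(angle), z)
        z += rise
    return coords


def generate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate the family and its ground truth, deterministic under
    ``spec.seed``."""
    m = len(spec.motif)
    if m > spec.length:
        raise ValueError("motif longer than protein length")
    rng = np.random.default_rng(spec.seed)
    starts = _plant_positions(spec)
    ancestor = _draw_ancestor(spec, rng)
    ss = _planted_ss(spec, starts)
    base_coords = _ideal_coords(ss)
    sigma = np.array([spec.noise_sigma(_offset_to_nearest(i, starts, m)) for i in range(spec.length)])

    groups = [f"group{chr(65 + i % spec.n_groups)}" for i in range(spec.n_proteins)]
    records = []
    sites: list[AnchorSite] = []
    resnums = list(range(spec.numbering_offset, spec.numbering_offset + spec.length))
    for p in range(spec.n_proteins):
        seq = _mutate(spec, ancestor, starts, rng)
        noise = rng.normal(0.0, 1.0, size=(spec.length, 3)) * sigma[:, None]
        rec = ProteinRecord(
            id=f"{spec.id_prefix}{p:02d}",
            sequence=seq,
            residue_numbers=list(resnums),
            ca_coords=base_coords + noise,
            ss3=ss,
            group=groups[p],
            source="fasta_only",
        )
        records.append(rec)
        for s in starts:
            sites.append(
                AnchorSite(
                    protein_id=rec.id,
                    seq_start=s,
                    seq_end=s + m,
                    res_start=resnums[s],
                    res_end=resnums[s + m - 1],
                    matched=seq[s : s + m],
                )
            )

    core = {
        i: ancestor[i]
        for i in range(spec.length)
        if spec.substitution_rate(_offset_to_nearest(i, starts, m)) == 0.0
    }
    truth = GroundTruth(
        sites=sites,
        ancestor=ancestor,
        ss3=ss,
        anchor_starts=starts,
        topology=tuple(state for state, _ in spec.layout if state in ("H", "E")),
        core_positions=core,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_ca_pdb(record: ProteinRecord, path: str | Path) -> None:
    """Minimal valid PDB: one CA ATOM record per residue, chain A."""
    lines = []
    serial = 1
    for i, (aa, num) in enumerate(zip(record.sequence, record.residue_numbers)):
        x, y, z = record.ca_coords[i]
        if not np.isfinite([x, y, z]).all():
            continue
        res3 = _ONE_TO_THREE[aa]
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:3s} A{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dssp_like(record: ProteinRecord, path: str | Path) -> None:
    """Classic-DSSP-shaped text: fixed-column residue number, chain, amino
    acid and summary code (coil written as blank)."""
    lines = [
        "==== Secondary Structure Definition (synthetic, DSSP-like layout) ====",
        "  #  RESIDUE AA STRUCTURE",
    ]
    for i, (aa, num) in enumerate(zip(record.sequence, record.residue_numbers)):
        code = record.ss3[i] if record.ss3 else "C"
        code = " " if code == "C" else code
        lines.append(f"{i + 1:5d}{num:5d} A {aa}  {code}")
    Path(path).write_text("\n".join(lines) + "\n")


def emit_fixture_files(
    records: Sequence[ProteinRecord],
    ground_truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write PDB + DSSP-like + FASTA + group map + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for rec in records:
        pdb = out / f"{rec.id}.pdb"
        write_ca_pdb(rec, pdb)
        paths[f"pdb:{rec.id}"] = pdb
        dssp = out / f"{rec.id}.dssp"
        write_dssp_like(rec, dssp)
        paths[f"dssp:{rec.id}"] = dssp
    fasta = out / "family.fasta"
    write_fasta(records, fasta)
    paths["fasta"] = fasta
    gmap = out / "groups.tsv"
    gmap.write_text("".join(f"{r.id}\t{r.group}\n" for r in records))
    paths["groups"] = gmap
    truth = out / "ground_truth.json"
    truth.write_text(
        json.dumps(
            {
                "anchor_starts": ground_truth.anchor_starts,
                "ancestor": ground_truth.ancestor,
                "ss3": ground_truth.ss3,
                "topology": list(ground_truth.topology),
                "sites": [
                    {
                        "protein_id": s.protein_id,
                        "seq_start": s.seq_start,
                        "seq_end": s.seq_end,
                        "res_start": s.res_start,
                        "res_end": s.res_end,
                        "matched": s.matched,
                    }
                    for s in ground_truth.sites
                ],
                "core_positions": {str(k): v for k, v in ground_truth.core_positions.items()},
            },
            indent=1,
        )
    )
    paths["ground_truth"] = truth
    return paths
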