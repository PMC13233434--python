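# robfold

Motif-anchored structural conservation analysis for protein families.

Protein families often concentrate their functional identity in a short,
nearly invariant motif — the `CXXC` redox active site of protein disulfide
isomerases, the `EEVD` C-terminal tail of HSP70 chaperones — embedded in a
scaffold that is conserved near the motif and increasingly variable away
from it. `robfold` is a deterministic, rule-based toolkit for mapping that
conservation gradient. It is aimed at structural bioinformaticians and
protein engineers who want an interpretable answer to: *how far around this
motif does the family keep the same sequence, the same topology, the same
geometry?*

Given a set of structures (PDB/mmCIF, e.g. AlphaFold models or crystal
structures), an anchor motif as a regular expression, and optionally DSSP
files and a taxon map, the pipeline:

1. **anchors** — finds every motif occurrence (overlapping scan), reported
   in author (PDB) residue numbering, and cuts symmetric windows of length
   *m* + 2*r* for radii *r* = 10, 20, …, 200, padding with `X` beyond chain
   termini;
2. **primary layer** — builds positional frequency matrices, threshold
   consensus strings, Chou–Fasman structural-equivalence classes, and the
   identity curve SI = 100 × (1 − D/L) (D = Hamming distance, L = window
   length) averaged over all same-length window pairs;
3. **secondary layer** — aligns 3-state secondary structure relative to the
   anchor, takes ≥50% / 100% recurrence consensus, and searches element
   topologies such as the thioredoxin-like β–α–β–α–β core;
4. **geometric layer** — computes pairwise Cα Kabsch-superposition RMSD per
   window length and the *conservation radius*: the largest window length
   whose mean RMSD stays below a cutoff (default 15 Å);
5. **validation** — a composition-preserving permutation null model
   (non-biological anchors at margin-matched random positions) and an
   IoU ≥ 0.5 site-level benchmark against reference annotations, with a
   PROSITE-pattern compiler for offline reference scans.

A synthetic-family generator (`robfold.synthetic`) produces fully
self-contained fixtures — planted anchors, tunable conservation decay,
idealized helix/strand geometry, crystal-style numbering offsets — so the
whole pipeline is testable without downloading anything.

## Worked example

Generate a disulfide-isomerase-like synthetic family (11 proteins, two
planted `CGHC` anchors each, conserved 20-residue core, variable flanks) and
run the pipeline:

```bash
robfold simulate --seed 5 --out demo/family
robfold run --structures demo/family --dssp demo/family \
    --groups demo/family/groups.tsv --motif CXXC=C..C \
    --step 10 --max-radius 100 --out demo/report
```

`demo/report/conservation_curve.tsv` starts:

```
window_length	n_pairs	mean_si
4	231	100.0
24	231	100.0
44	231	100.0
64	231	72.84902597402598
84	231	59.04452690166977
```

22 anchor sites give C(22,2) = 231 window pairs per length. Identity holds
at 100% through window 44 — exactly the planted core (motif + 20 residues
per side) — then decays as the variable flanks enter the window. The
unanimous consensus at window 44 recovers the planted core letters around
the anchor (variable positions would appear as `X`):

```
>consensus_L44_t1
YCMWLINEQANCAFRKKPCYCGHCHPTWLDYVRIDSFHVPGMPD
```

`demo/report/rmsd_summary.tsv` shows near-perfect superposition at the
motif itself (0.40 Å mean over 231 pairs at window 4) growing smoothly with
window length, and `manifest.json` records 22 anchor sites, a global median
pairwise RMSD of 1.94 Å and a conservation radius of 204 residues — at this
noise level every analysed window keeps its mean RMSD under 15 Å, so the
radius is the longest window analysed.

The null model and the benchmark run as:

```bash
robfold null --structures demo/family --motif CXXC=C..C --n 50 --seed 3 \
    --step 10 --max-radius 100 --out demo/null
robfold benchmark --pred sites.tsv --ref prosite.tsv --iou-min 0.5
```

The null run reports, per window length, the biological identity curve
against the min/mean/max envelope of 50 permuted-anchor trials; on the demo
family the biological curve stays above the null mean at every length
(null curves sit near the ~5% random-alignment baseline, the biological
curve at 100% inside the core).

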