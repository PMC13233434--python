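# Methods

`robfold` identifies conserved structural scaffolds in a protein family by
anchoring every analysis on a short, functionally critical motif and asking,
layer by layer, how far outward from that anchor conservation persists. This
note records the model, the parameters that matter, the numerical choices,
and what the synthetic validation families do and do not show.

## The anchored-expansion model

A family is a set of homologous protein records, each carrying a one-letter
sequence, author (PDB) residue numbers, optional per-residue C-alpha
coordinates and an optional 3-state secondary-structure string. The anchor
motif is a fixed-length pattern over the amino-acid alphabet — `CXXC`
(regex `C..C`) for the redox active site of protein disulfide isomerases,
`EEVD` for the HSP70 chaperone tail — matched by an overlapping
(lookahead) scan so that adjacent occurrences, such as the two active-site
domains of a multi-domain isomerase, are all captured. Every match is kept
in both coordinate spaces: the 0-based sequence index used internally, and
the author residue number used in every report. The two differ whenever a
deposited structure numbers its chain from something other than 1 (a chain
beginning at residue 22 after a leading hetero-group is the canonical trap),
and conflating them misplaces every reported site by the numbering offset.

Around each anchor of length *m*, symmetric windows of length *m* + 2*r* are
cut for radii *r* = 10, 20, …, 200 residues (configurable step and maximum;
the bare *r* = 0 motif window is available on request). Positions beyond a
chain terminus are filled with the neutral padding symbol `X` and flagged,
so windows of one nominal length stay comparable across proteins of
different sizes. Windows carry their own sequence, secondary-structure slice
and coordinate slice; a window is *coordinate-complete* when it has no
padding and a C-alpha at every position. Length categories can additionally
be filtered for taxonomic representativeness: for structural analyses a
category is dropped unless every subgroup contributes at least one
coordinate-complete window, while sequence-level analyses keep all
categories because padding already guarantees representation.

## Layer one — primary sequence

For each window length, a positional frequency matrix over the 21-symbol
alphabet (20 amino acids + padding) tallies symbol occurrences. A consensus
string shows, per position, the residue whose relative frequency reaches a
threshold (default 1.0, i.e. unanimity), and `X` otherwise; when several
residues reach a sub-unanimity threshold the most frequent wins, with exact
ties broken alphabetically and logged.

Conservation between two equal-length windows is the sequence identity

SI = 100 × (1 − D/L),

with D the Hamming distance and L the window length. Padding is treated as
an ordinary 21st symbol (X = X counts as a match); the alternative —
excluding padded positions from both D and L — is available via
`ignore_padding=True`, and output metadata states which convention was used.
The conservation curve is the mean SI over all C(n, 2) unordered
same-length window pairs, as a function of window length. Pairs are formed
across proteins *and* across multiple anchors of the same protein: with 25
anchor sites in a family, every length has 300 pairs as long as all windows
stay coordinate-complete.

Residues are also mapped to Chou–Fasman structural equivalence classes —
helix-former (H), sheet-former (E), turn-former (T) — by taking the argmax
of each residue's canonical conformational propensities (P_alpha, P_beta,
P_turn). The full class map, precomputed from the propensity table shipped
in `fold_one.CHOU_FASMAN_PROPENSITIES`, is:

| class | residues |
|---|---|
| helix-former (H) | A, R, Q, E, H, K, M |
| sheet-former (E) | C, I, L, F, T, W, Y, V |
| turn-former (T) | N, D, G, P, S |

Cysteine's sheet and turn propensities tie at 1.19; the tie is broken by the
fixed priority helix > sheet > turn, assigning it to the sheet class, in line
with its usual classification. Because classes merge residues, translating
two windows to class strings can only lower their Hamming distance — a
divergent position whose residues share folding propensity becomes a match,
which is exactly the "hidden conservation" the class layer is for.

## Layer two — secondary-structure topology

Per-residue 3-state assignments come from DSSP-format files (the standard
8-state codes are reduced H/G/I→H, E/B→E, everything else→C; residues absent
from a DSSP file default to coil). Window slices are stacked into an
anchor-aligned matrix and a consensus is taken per column among non-padded
rows: the modal label is emitted when it is the unique mode and its fraction
reaches the threshold (0.5 for partial, 1.0 for complete recurrence).
Exact ties yield `x` — "at least half" is ambiguous under a 50/50 split, and
requiring a strict majority is the conservative reading — as do columns
covered by fewer than `min_coverage` (default 2) non-padded rows. The
padding-aware denominator is itself a choice: padded rows are absent
evidence, not disagreement, so they are excluded from the count rather than
counted against the modal label. By construction the unanimous consensus is
a subset of the majority consensus.

Topology search run-length encodes a consensus string, discards coil and
undefined runs and any helix/strand run shorter than `min_run` residues
(default 2 — single-residue calls are assignment noise), and reports every
contiguous subsequence of the remaining element runs matching a query
pattern such as E-H-E-H-E (the thioredoxin-like β–α–β–α–β core) or H-H-H
(the triple-helix arrangement around the chaperone tail), with
anchor-relative offsets.

## Layer three — geometry and the conservation radius

For every pair of coordinate-complete windows of a length, the C-alpha sets
are superimposed by the Kabsch algorithm — centre both sets, SVD of the
covariance, determinant-corrected rotation so reflections are never applied
— and the RMSD is computed from the aligned residuals rather than the
trace identity, which loses precision catastrophically near zero. Per
length, the mean RMSD and the fraction of pairs below a cutoff (default
15 Å, configurable via `--rmsd-cutoff`) are reported, plus a global median,
standard deviation and 1 Å-binned histogram.

The *conservation radius* is the largest analysed window length whose mean
RMSD stays below the cutoff, scanning lengths in ascending order and
stopping at the first crossing — an isolated dip back under the cutoff at a
longer length does not extend the radius, since the quantity is meant to
delimit the contiguous rigid core. When even the shortest analysed length
is at or above the cutoff the radius is undefined and reported as such.

## The null model

To show that sustained conservation is a property of the anchor's biological
ordering and not of amino-acid composition or chain position, the null model
permutes the anchor's letters (rejecting the identity permutation whenever a
distinct one exists) and re-anchors each protein at a uniformly random
position constrained to the same terminal-distance envelope as the
biological anchors: a candidate start must lie at least as far from the N-
and C-termini as the closest biological anchor does, taking the minimum over
all biological anchors of the family. When biological motif instances
differ (CXXC instances vary in their middle residues), the most frequent
matched string is the one permuted, ties broken lexicographically. The
permuted motif labels the trial; windows are cut at the sampled positions of
the real sequences, which is the only construction under which the full
conservation-curve computation runs unchanged at non-biological anchors.
Each of the *n* trials (default 50) yields a decay curve computed exactly
like the biological one, and the envelope (per-length min/mean/max) is
reported alongside it. All trial randomness flows from one seed through a
spawned generator per trial, so the experiment is reproducible
byte-for-byte.

Note one structural feature of the comparison: biological windows compare
*homologous* positions, while null windows compare unrelated positions drawn
independently per protein, so null identity sits near the random-alignment
baseline (~5%) even when flanks are moderately conserved, and the biological
curve additionally carries a forced 100·m/L contribution from the matched
anchor itself. Assessments of "no separation" must discount that term.

## Site benchmark

Predicted anchor sites are compared against a reference annotation table
(e.g. a PROSITE scan) at the site level. Two closed author-residue
intervals on the same protein are candidates when their
intersection-over-union is at least `iou_min` (default 0.5); the matcher
then solves the one-to-one assignment maximizing the number of matched
pairs first and total IoU second (a purely greedy descending-IoU pass can
strand matchable sites in overlapping clusters, which an exhaustive check
confirms). Matched pairs are true positives; unmatched predictions and
references are false positives and negatives. Precision, recall, F1 and
mean IoU over matches are reported per motif and micro-averaged by pooling
counts. With zero predictions and zero references, precision (resp.
recall) is reported as 1.0 with a logged note so perfect-agreement tables
stay well-defined. A compiler for PROSITE pattern syntax (`C-x(2)-C` →
`C.{2}C`, with `[..]`, `{..}`, `(n[,m])`, `<`/`>` supported) lets a
reference be produced by a local offline scan.

## Synthetic families

The generator builds a family from a common ancestor: a random sequence with
the motif planted at fixed, evenly spaced positions (default two per
protein) and a *shared* conserved-core template — motif plus `core_radius`
(default 20) residues per side — pasted around every anchor, mirroring
families whose repeated anchor-bearing domains are themselves homologous,
like the two thioredoxin-like active-site domains of a disulfide isomerase.
Homologs substitute each non-motif position independently at a rate given by
a step profile: `core_rate` (default 0) within the core radius, `flank_rate`
(default 0.5) outside; a custom per-offset profile can be supplied.
Rejection sampling removes any homolog in which the search pattern matches
anywhere other than the planted sites, so ground-truth site counts are
exact.

Coordinates follow an idealized, continuous backbone walk driven by a
planted secondary-structure layout (default E-H-E-H-E centred on each
anchor, coil elsewhere): helices rise 1.5 Å per residue with a 100° twist at
2.3 Å radius, strands rise 3.3 Å, coil 3.0 Å. Isotropic Gaussian noise with
σ = `coord_noise` × (0.25 + |offset|/50) Å — a small baseline plus a linear
rise with distance from the nearest anchor — makes geometric divergence grow
away from the core, which is what gives the conservation radius something to
detect. Author numbering can start above 1 (`numbering_offset=22` emulates
crystal-style numbering with a leading gap). Fixtures are emitted as
C-alpha-only PDB files, DSSP-shaped text, FASTA, a group-map TSV and a
ground-truth JSON; the defaults (11 proteins of 400 residues, or 7 of 450
with a single `EEVD` anchor and an H-H-H layout for the chaperone-like
family) are sized so that the whole pipeline, the 50-trial null experiment
and the multi-seed consensus-recovery checks together run in seconds.

What these fixtures do *not* emulate: real evolutionary correlation
structure (substitutions are independent across positions and proteins),
physically realistic geometry (no side chains, no excluded volume, no
lever-arm rigid-body motions between domains — noise is isotropic and
independent per residue), indels (homologs are length-aligned by
construction, so no alignment step is tested), and real secondary-structure
assignment noise. Passing tests therefore demonstrate the correctness of
the machinery — coordinate bookkeeping, combinatorics, consensus logic,
superposition, null-model construction — not the biological claims about any
real family, which require the real structure sets.

## Known limitations

* Only sequence-regex anchors are supported; structural-fingerprint anchors
  are out of scope.
* The first polymer chain is analysed unless a chain id is configured;
  multi-model files use the first model only.
* Insertion codes are not modelled; author numbering is treated as strictly
  increasing integers, which holds for the predicted-model and
  crystal-structure inputs the tool targets but not for every PDB entry.
* Windows with partial coordinate coverage participate in the sequence and
  secondary-structure layers but are excluded from RMSD pairing, so
  geometric summaries at long windows can rest on fewer pairs than
  sequence summaries at the same length.
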