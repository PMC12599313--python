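# Methods

This note records the models, conventions and numerical choices behind
`petmine`, in the spirit of a methods supplement: what each stage assumes,
which defaults matter, and what the synthetic benchmarks do and do not
demonstrate.

## Sequences and ingestion

Proteins live on the 20-letter amino-acid alphabet plus `X`.  Ingestion is
permissive in the ways metagenomic ORF sets require: ambiguous codes
(B, Z, J) and the rare translated residues (U, O) map to `X` with a logged
warning; a single trailing `*` (translated stop) is stripped; an internal
`*` is an error, since it usually flags a frameshifted gene call.  All
residue positions in reports are 1-based inclusive.  Sample-of-origin is
carried as a `sample=<id>` token in FASTA descriptions and resolved
against a tab-separated site-metadata table (temperature range in °C,
sediment depth in cm).

## Pairwise alignment and percent identity

Global Needleman–Wunsch with affine gaps (Gotoh's three-state dynamic
program), exact — no banding or k-mer prefilters, which at desk scale buys
reproducibility cheaply.  A gap of length L costs
`gap_open + L·gap_extend`; defaults are BLOSUM62 with open 10 / extend 1,
the BLAST-compatible convention, so identities are comparable to common
practice.  `X` scores 0 against everything and never counts as an
identity.  Traceback ties break deterministically: diagonal, then
gap-in-b, then gap-in-a.

Two identity conventions exist because the pipeline's two consumers
disagree: clustering uses `identities / min(ungapped lengths)` (the CD-HIT
convention, mode `shorter`), novelty reporting uses
`identities / alignment columns` (mode `alignment`).  `shorter` ≥
`alignment` always.  Both are config-exposed.

## Greedy identity clustering

CD-HIT semantics: sequences sorted longest-first (stable), each joining
the first existing cluster whose *representative* it matches at or above
the threshold, else founding a new cluster.  Representatives are therefore
the longest member, and every representative is below threshold to all
earlier representatives.  Identity is computed by the exact aligner rather
than a word filter.  Sequences under 10 residues are rejected — identity
is not meaningful there.  The pipeline uses 30% for the seed set and 40%
for candidate diversification.

## Seed alignment and match columns

The seed cluster is aligned progressively: pairwise identity distances
(`1 − alignment-mode identity`) feed an average-linkage (UPGMA) guide tree
(scipy's agglomeration; node height = merge distance / 2), and profiles
are merged post-order.  Profile columns are scored by the expected
sum-of-pairs substitution score (`f_Aᵀ · S · f_B` over a 22-channel
frequency vector: 20 residues, X, gap), with gap characters scoring
`−gap_extend` against residues; new inter-profile gaps pay the affine
penalties.  There is no iterative refinement — for a family sharing ≥30%
identity the progressive answer is adequate, and determinism is worth
more here than a point of alignment accuracy.

A column is a *match column* when its gap fraction is below 0.5 (the
standard profile-construction rule, config-exposed).

## Profile HMM

The architecture is Plan7-lite: M match states with the usual insert and
delete companions and seven transition types.  Emissions and transitions
are estimated from the masked MSA with Laplace-style pseudocounts
(weight 1 by default): match emission `(count + w)/(n + 20·w)`; transition
bundles the same way from the observed state paths.  The two adjacencies
the architecture forbids (I→D, D→I) are dropped from the counts;
pseudocounts keep all permitted transitions positive.  Insert emissions
are tied to the background, making inserts score-neutral — the standard
simplification.  The background composition defaults to average
Swiss-Prot residue frequencies.

Scoring is fully local forward (sum over all alignments), reported as a
log-odds in bits.  The local wrapper is chosen so the score is a *proper*
log-likelihood ratio: entry is uniform over the L·M (position, match
state) pairs, and exit from match state k happens with probability
`1/(M−k+1)`, which makes the exit state uniform over the remaining states
and conserves total path probability.  Two consequences matter.  First,
the `1/L` entry prior length-normalizes the null: without it, longer
random sequences score higher simply by offering more alignment starts.
Second, mass conservation makes null tails comparable across profiles of
different lengths; with unnormalized free exits, the measured null tail
rate drifted systematically with M.  Flanking residues are emitted by the
background and cancel in the ratio.  There is no multi-domain (J-state)
loop: the pipeline needs ranking and thresholding, not domain
decomposition, so each target gets one envelope, and envelopes span the
full sequence (posterior-decoded envelopes are not implemented).

The recursion runs in scaled probability space (per-row rescaling at
1e120 with a log accumulator) inside a numba kernel; for small models it
agrees with exhaustive path enumeration to ~1e-9 relative probability,
and that agreement is a standing test.

## E-value calibration

E-values are `E(S) = N · min(1, e^{−λ(S−τ)})` with `(λ, τ)` fitted to
scores of background decoys matching the database's residue composition
and length distribution.  The fit is a maximum-likelihood exponential on
the exceedances over an upper quantile of the decoy scores, with the
survival anchored at that quantile.

The crucial choice is *where* the tail is fitted.  The null score
distribution decays faster near its bulk than further out, so a slope
estimated from shallow exceedances (e.g. everything above the median) and
extrapolated three or more orders of magnitude mis-states extreme
E-values severalfold.  The default therefore uses a large decoy budget —
50 000 decoys, seconds of kernel time — and fits the top 1% of scores, so
that the fitted stretch (survival 1e-2 down to ~2e-5) brackets the
E ≈ 1 regime of databases up to a few 10⁴ sequences instead of reaching
beyond the data.  With small decoy budgets the threshold is lowered
automatically to keep at least 20 exceedances.  The shallow median-up
variant remains available (`fit_exponential_tail(..., tail_mass=0.5)`) as
a diagnostic of the local bulk rate.  Calibration sanity — roughly one
hit per decoy-only database at `E ≤ 1` and essentially none at `1e-5` —
is asserted by the acceptance tests and recomputed by
`scripts/acceptance.py`; calibration decoys are drawn from a
purpose-salted random stream so that a user reusing one seed for both
simulation and search cannot collide the decoy stream with the generator
stream.

The hit cutoff defaults to `E ≤ 1e-5` on the full-sequence score.

## Candidate selection

Hits from all profiles and samples are merged; candidates with identical
residue strings collapse to one record keeping the minimum E-value and
all source samples (near-duplicates are left to the 40% clustering).
Within each candidate cluster the minimum-E member is the representative
(ties: longer sequence, then lexicographic id).  Annotation attaches the
maximum identity to the seed enzymes (`novelty_identity`, with the
nearest reference) and the hottest linked site temperature.

Final selection codifies the three published criteria deterministically:
a hard novelty ceiling (default 0.65 — anything closer to a known enzyme
is not "novel"), ranking by structural TM-score (candidates without
structures rank last), ties broken by ascending E-value then id, top_n
(default 22) flagged.  Temperature is deliberately carried as annotation
rather than a filter: sites, not sequences, carry the thermal signal, and
a hard thermal cutoff would silently discard candidates from unmeasured
sites.

## Structure triage

Geometry is CA-only — predicted models' side chains are their least
reliable part.  Superposition is least-squares Kabsch (SVD with
proper-rotation correction, via scipy after in-package centering).
TM-score uses the standard normalization by the *reference* length with
`d0 = 1.24·(L_ref − 15)^⅓ − 1.8` floored at 0.5 Å, maximized over
superpositions seeded from fragments of the correspondence and refined on
the close pairs.  `structural_align` starts from the sequence-alignment
correspondence and alternates superposition with a dynamic program on the
TM-style weights `1/(1+(d/d0)²)` (gap penalty 0.6) until the
correspondence is stable (≤20 iterations); it is deterministic and
rigid-motion invariant.

Aromatic contacts count F/Y/W/H pairs with CA distance ≤ 7 Å and sequence
separation ≥ 2.  This is a coarse surrogate for ring-geometry interaction
analyses (no centroids, no angles); counts are comparable within this
toolkit only and are not asserted against published per-protein values.

## Physicochemical annotation

Net charge follows Henderson–Hasselbalch per ionizable group — basics
{N-terminus, K, R, H}, acidics {C-terminus, D, E, C, Y} — and is strictly
decreasing in pH; the isoelectric point is located by bisection on
[0.5, 13.5] to 1e-3 pH by default.  The default pKa set is Bjellqvist
(ExPASy-compatible), with a single N-terminal pKa (7.5) rather than
residue-specific values; EMBOSS values are selectable.  Cysteines are
treated as free thiols (no disulfide correction).  pI is computed on the
sequence as supplied — callers decide full-length versus signal-trimmed
mature versus tagged constructs, which can shift pI by a few tenths.
GRAVY is the Kyte–Doolittle mean over non-X residues.  Signal-peptide
consensus takes a strict-majority position when one exists, otherwise the
median (lower middle on even counts — the conservative, shorter trim);
the predictors themselves are out of scope.

## Synthetic worlds

The generator emulates the *shape* of a metagenomic mining problem:
i.i.d. background proteins with Swiss-Prot-like composition and
log-normal lengths (median ~230 residues, log-sd 0.35); a seed family of
one 240-residue ancestor plus 11 mutants at 65–90% identity; homologs of
the ancestor planted at controlled identity (default 10 each at
0.35/0.45/0.55); and three site-metadata templates spanning the thermal
range of hydrothermally influenced sediments (20–38 °C, 74.1–115 °C, and
an 89 °C point estimate), so thermal annotation is exercised
realistically.  Planted identity is controlled post hoc: BLOSUM-weighted
substitutions plus geometric-length indels, tuned by bisection against
the measured global-alignment identity until within ±0.05 of target —
exactness beats elegance for fixtures — and the realized identity is
recorded in the truth manifest.  Everything is deterministic per seed,
with child streams derived so outputs are byte-reproducible.

What the worlds do *not* emulate: real domain architecture or secondary
structure, phylogenetic correlation among background proteins, ORF-calling
artifacts, compositional bias of any particular biome, or real PETase
sequences.  Passing the recovery benchmarks therefore shows the machinery
is correct and calibrated under controlled homology, not that any
particular database would yield candidates; helix-trace structure
fixtures exercise the triage geometry, not fold recognition.

## Validation problem sizes

The standing benchmarks use a 5000-background world with 30 planted
homologs for recovery (recall of homologs ≥35% realized identity at
`E ≤ 1e-5`, zero background admitted), 50 composition-matched decoy-only
databases of 5000 sequences for calibration sanity, and exhaustive
oracles at small scale (all alignments for length ≤ 6; all HMM paths for
M ≤ 3, length ≤ 4; dense rotation grids for superposition) — sizes chosen
to make the checks sharp while keeping a full run in minutes on one core.

## Known limitations

Exact O(nm) alignment makes clustering quadratic in cohort size — fine
for hundreds of candidates, wrong tool for millions.  The profile HMM has
no multi-domain model, no posterior envelopes and no glocal mode.
E-values are calibrated per profile and database composition; transferring
a calibration across databases of different composition is unsupported.
Calibrated E-values are accurate to within about a factor of two near the
reporting threshold — ample for a `1e-5` cutoff, but not for fine
significance claims.  Structure triage assumes reasonable CA traces;
badly broken models will superpose, just meaninglessly.
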