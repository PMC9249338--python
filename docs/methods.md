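# Methods

This note describes the models and procedures implemented in `ribovar`, the
parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical conventions adopted where the design was open.

## Transcript model and variant consequences

All positions are 1-based inclusive transcript coordinates, the frame of
reference of HGVS `c.` notation; `c.1` is the A of the initiator ATG. No
genomic coordinates appear anywhere: the analysis operates on a processed
transcript (cDNA plus exon intervals plus CDS bounds), which is the level at
which coding-variant consequence and NMD prediction are defined. RNA-style
input (`U`) is mapped to `T` on load, and lowercase is normalized, because
variant databases mix mRNA and cDNA vocabulary freely.

The supported variant grammar covers substitutions, deletions, insertions,
duplications and deletion–insertions with exonic coordinates. Intronic
positions (`c.N+M` / `c.N-M`) are rejected with a *distinct* error class:
splice-site variants cannot be applied to a spliced transcript, so the
pipeline routes them straight to the not-applicable NMD category rather than
guessing a protein product. Duplications are treated as insertions of the
duplicated span immediately after it.

Consequence prediction re-translates the mutant transcript from the original
CDS start with the standard genetic code, continuing past the natural stop
position into the 3' UTR when a frameshift removes the stop. Classification
is a total function over the grammar:

- net length change not divisible by 3 → **frameshift**;
- substitution creating a stop before the natural one → **nonsense** (as is
  a net-zero delins that creates one);
- substitution changing / preserving the protein → **missense** /
  **synonymous**;
- in-frame deletion / insertion → the corresponding in-frame class;
- disruption of the initiator ATG → **start loss** (this takes precedence
  over frameshift: with no initiation there is no reading frame to shift);
- disruption of the natural stop codon → **stop loss**, with a `no_stop`
  flag when translation runs off the transcript end.

The start-loss and stop-loss conventions are this package's explicit choices
for edge cases on which variant-effect literature is not prescriptive; both
are excluded from junction-rule evaluation downstream.

## NMD classification

The exon-junction rule: a PTC more than `threshold_nt` nucleotides upstream
of the *last* exon–exon junction predicts degradation (NMD+); a PTC in the
last exon or within the threshold predicts escape (NMD−). Three conventions
fix the remaining freedom:

- **Threshold.** The rule is quoted in the literature as "50–55 nt" without
  a canonical single value. The default is 50 nt; `nmd_band_report` reruns
  at 50 and 55 and flags calls that flip inside the band, so the
  indeterminacy is surfaced rather than hidden.
- **Distance.** Measured from the last base of the PTC codon to the
  junction, in mutant coordinates: junctions at or downstream of the edit
  site shift by the variant's net length change.
- **Tie.** A PTC at exactly the threshold escapes (the rule is "more than"
  in the sources that state it precisely).

Consequences with no PTC (missense, synonymous, in-frame indels reaching the
natural stop) are counted as escaping; start-loss, stop-loss/no-stop and
splice-site inputs are not evaluable and form the third category.
Single-exon transcripts have no junction; every PTC escapes, and the call is
flagged. Raising the threshold can only move calls from NMD+ to NMD−; this
monotonicity is enforced by property tests over randomized transcripts.

## Structure analysis

**Contacts.** A contact is an interchain heavy-atom pair at Euclidean
distance ≤ 4.0 Å. Hydrogens are excluded throughout because the cryo-EM
depositions this analysis targets do not contain them. Residue-level counts
are numbers of qualifying atom pairs — the reading under which a single
arginine can accumulate dozens of contacts with two nucleotides. Author
chain ids and residue numbers are authoritative, since residues are cited in
the field as authored. The search uses a k-d tree but is defined
extensionally; tests compare it to a dense all-pairs scan on clouds up to
2000 atoms at 3/4/5 Å.

**Superposition and chain substitution.** Rigid-body fits use the Kabsch
algorithm (SVD with the proper-rotation correction; collinear references are
rejected). Chain substitution — replacing a poorly resolved chain with the
equivalent chain from a reference structure — pairs atoms by (residue
number, atom name) over a fit subset (Cα for protein, P for nucleic acids by
default), drops mismatched residues from the fit and reports them, then
transforms and swaps the whole donor chain. An independent quaternion
(Horn) solver serves as the test oracle.

**Hydrogen bonds.** Candidate donors/acceptors are N, O and S heavy atoms;
a bond is an interchain donor–acceptor pair at ≤ 3.5 Å, additionally
requiring a D–H–A angle ≥ 120° when the donor residue carries explicit
hydrogens (a hydrogen within 1.3 Å of the donor counts as bonded). This is
a declared geometric approximation of the relaxed criteria interactive
structure viewers use; it is deterministic and tool-independent.

**Solvent accessibility.** Shrake–Rupley point sampling on a deterministic
golden-angle (Fibonacci) sphere lattice with Bondi van der Waals radii and a
1.4 Å probe. The default lattice has 256 points: the classic 92-point set
leaves up to ~3% discretization error on heavily overlapped atom pairs,
while 256 points keep the worst case near 1% of a 10,000-point reference at
modest cost. Unknown elements fall back to 1.7 Å with a warning. A lone
atom's area equals the closed form 4π(r + probe)² up to lattice resolution.

**Site classification.** A mutated residue is labelled assembly-critical
when it is in contact in at least half the assembly states, exposed/low
contact when it has no contacts (and measurable exposure where SASA was
computed), intermediate otherwise, and unresolved when absent from the
models. Assembly-factor chains are identified by a user-supplied chain-role
map — never guessed from entity names — and each residue carries a flag for
whether it ever contacts a factor-labelled chain.

## Pseudogene rescue scoring

Each pseudogene is translated in all six frames (internal stops rendered
`*`, no truncation). Every frame product is aligned globally to the
reference protein and the highest-scoring frame wins (ties go to the frame
earliest in the order +1, +2, +3, −1, −2, −3). Frame choice by maximum
alignment score — rather than by longest ORF or an annotated frame — is this
package's convention and is reported alongside the statistics.

Alignment is Needleman–Wunsch with affine gaps in the EMBOSS NEEDLE
parameterisation, since NEEDLE's documented defaults are the only defensible
choice where no parameters are stated: BLOSUM62, gap open 10.0 charged at
the first gap column, extend 0.5 per additional column, end gaps free. The
BLOSUM62 table ships with the `*` column (+1 self, −4 otherwise), so
internal pseudogene stops degrade similarity instead of failing. Traceback
ties break diagonal, then up, then left, making output deterministic.
Statistics use the EMBOSS definitions: identity = identical columns /
alignment length; similarity = positively scoring columns / length; gaps =
columns with a gap in either row / length. The dynamic program is verified
against exhaustive path enumeration (all pairs of length ≤ 3 over a
four-letter alphabet, plus seeded random pairs up to length 6 — the scale at
which enumeration stays tractable) and against an independent
library aligner configured identically.

## Synthetic fixtures

The generator emulates the study conditions of the RPS19/eS19 analysis with
one integer seed driving fixed per-generator substreams, so outputs are
byte-reproducible and adding a generator never perturbs existing fixtures.

- **Transcript**: 6 exons, a CDS coding 145 amino acids (ATG + non-stop
  codons + TAA), UTRs ≥ 30 nt. The last junction is placed inside the CDS at
  least 150 nt after the start and 60 nt before the stop — not fully
  uniformly — so that both NMD-triggering and NMD-escaping premature stops
  are constructible on every generated transcript; inner junctions are
  uniform.
- **Variant cohort**: 64 variants by default — 30 escaping (missense,
  synonymous, in-frame, late nonsense/frameshift), 19 degraded
  (nonsense/frameshift with early PTCs), 15 not-applicable (splice-site,
  start-loss, stop-loss) — the integer split closest to the 47% / 29% / ~24%
  profile the cohort emulates. Variants are rejection-sampled until the
  package's own classifiers reproduce the requested class and category, so
  the planted truth is exact by construction.
- **Structures**: three pseudo assembly states of a toy protein
  chain / RNA chain pair whose backbones are kept > 5 Å apart, with planted
  contact clusters (including a hotspot residue reaching exactly 45 atom
  pairs to two RNA residues at 2.9–4 Å in one state, and a loop triplet of
  which only the middle residue ever touches a neighbor), isolated N···O
  hydrogen-bond pairs, and a factor-labelled chain placed > 10 Å from
  everything. Ground-truth counts are recomputed from the final coordinates
  by an all-pairs scan at generation time, so they are exact regardless of
  jitter. Coordinates are rounded to 3 decimals (PDB fixed-format precision)
  so the PDB and mmCIF renderings carry identical atom sets.
- **Pseudogenes**: the reference protein degraded to a ladder of target
  identities (the near-intact member at 90.4%, without indels; the rest with
  short indels), back-translated with a fixed codon per residue, optionally
  frame-shifted by a prefix or stored reverse-complemented to exercise frame
  selection. For indel-free, lightly degraded members the recovered identity
  is guaranteed within one alignment column of the target; heavily degraded
  members can legitimately align better in another frame or recover a
  different identity, and their ground truth only asserts what the generator
  guarantees (e.g., gap columns exist).

What the fixtures do **not** emulate: realistic ribosome geometry, codon
usage, splice-site sequence context, or the mutational spectrum of any real
cohort. Passing the closed-loop tests therefore demonstrates that the
pipeline recovers planted truth under controlled conditions — correctness of
the machinery — not that its predictions match any particular experimental
dataset.

## Problem sizes and determinism

The test suite runs the alignment oracle exhaustively at short lengths and
by seeded sampling at length 4–6, the contact oracle on twenty clouds of
200–2000 atoms, the closed loop on bundles for seeds 1–5, and the junction
rule on 1000 randomized transcript/PTC cases; the whole suite completes in
well under a minute per module on one CPU. Everything downstream of a seed
is deterministic: rerunning any generator, pipeline stage or the acceptance
script with the same inputs reproduces outputs byte for byte.

## Known limitations

- Variant coordinates are restricted to the CDS; UTR variants and
  multi-variant haplotypes are out of scope.
- The H-bond criterion is purely geometric; no energy model, and no
  inference of missing hydrogens.
- The NMD model implements only the junction rule — no start-proximal
  escape, long-exon effects, or uORFs.
- Pseudogene scoring is pairwise protein-level alignment; it does not
  assess promoter integrity, expression, or DNA-level conservation.
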