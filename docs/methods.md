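# Methods

## The character being scanned for

A conserved signature indel (CSI) is a fixed-length insertion or deletion in
a protein that sits inside an otherwise well-conserved region and is shared
by (essentially) all members of one monophyletic group and by no one else.
Because an in-frame indel is a discrete, rare genetic event, the most
parsimonious explanation of such sharing is a single event in the group's
common ancestor, which makes the CSI a molecular synapomorphy: unlike a
phylogenetic branch, it is a concrete, checkable character. The outgroup
state polarises the event — if outgroups carry residues where the group is
gapped, the group's ancestor suffered a deletion; in the mirrored case, an
insertion.

`csiscan` operationalises the visual scan that identifies such markers in
protein multiple sequence alignments, as a deterministic pipeline with
explicit, configurable thresholds.

## Detection model

Given a gapped alignment and a hierarchical clade partition (taxon → label
at each of several levels, with designated outgroups and a list of candidate
clades), detection proceeds:

1. **Column conservation.** A column is conserved when the majority residue
   among non-gap, non-`X` rows reaches `conservation_threshold` (default
   0.8) and the column's gap fraction is at most `max_column_gap_fraction`
   (default 0.1). `X` never counts toward a majority and mismatches
   everything. "Conserved" has no standard quantitative definition in this
   literature; 0.8/0.1 match the near-identity flanks characteristic of
   published signature figures and are exposed as parameters.
2. **Candidate enumeration.** An indel candidate is a maximal run of columns
   sharing one constant, nonempty, proper gap-taxon set. Every taxon is
   either gapped across the whole interval or in none of it; ragged gap
   patterns necessarily split into several shorter candidates.
3. **Fixed-length boundary guard.** A candidate is discarded if any of its
   gap taxa is also gapped in a column immediately adjacent to the interval.
   This is the operational form of the fixed-length rule for length-variable
   indel clusters: when members of a clade carry indels of different lengths
   at one locus, an aligner renders them flush-left and the shared core
   would otherwise masquerade as a fixed-length signature. The cost is that
   a genuine CSI whose immediate neighbour column contains a second,
   independent indel in the same taxa is also discarded; such stacked events
   are rare and are better revisited manually than silently called.
4. **Flank filter.** Both windows of `flank_window` (default 45) columns
   adjacent to the candidate (excluding the indel itself, clipped at the
   alignment edges) must contain at least `min_conserved_flank` (default 5)
   conserved columns. The published rule of thumb is 4–5 conserved residues
   within 40–50 neighbouring positions; we take the upper bound of the first
   range and the midpoint of the second, per side (the "both sides" phrasing
   implies per-side windows).
5. **Specificity.** For each side of the candidate (gap taxa / residue taxa)
   and each candidate clade C with aligned members A, the side passes when
   `|side ∩ A| ≥ |A| − max_exceptions`, `|side \ A \ outgroups| ≤
   max_foreign`, and `|side| ≥ min_carriers`. The smallest passing clade
   wins; a size tie between distinct clades is ambiguous and rejected with a
   log entry. Defaults: `max_exceptions = 1` (a single lineage may have
   secondarily lost the signature and is reported by name, never silently
   absorbed), `max_foreign = 0` (shared presence outside the clade suggests
   homoplasy), `min_carriers = 3` (signatures confined to one or two
   isolated taxa are not reliable markers; a study clade with only two
   sequenced members needs a lowered per-run value, as the CLI exposes).
6. **Polarity.** If at least `outgroup_unanimity` (default 0.9) of the
   outgroup taxa present hold residues at the indel columns while the
   carriers are gapped, the call is a deletion; mirrored, an insertion;
   anything else — mixed outgroups, or no outgroup in the alignment — is
   `undetermined` rather than a majority vote, because disagreement among
   outgroups is itself a homoplasy warning.
7. **Reporting coordinates.** Internally columns are 0-based half-open;
   everything user-facing is 1-based inclusive. The "displayed region" of a
   call is the indel plus the nearest `min_conserved_flank` conserved
   columns per side, mapped to ungapped residue positions of a reference
   taxon (the first alignment row holding residues across the indel). The
   raw indel interval is reported alongside, since the displayed-region
   convention is a presentation choice. A query region (reference residues
   covering the indel ± 60 aa by default, within the conventional 50–100 aa
   range) is exported so group specificity can be re-checked against an
   external sequence database; the pipeline itself performs no network
   searches.

## Signature figures

`render_signature` reproduces the classic dash-notation excerpt: the
reference row verbatim on top, `-` for identity with the top line, the
residue letter for a difference, and a blank cell for a gap, with taxa
grouped carriers-first, then remaining in-group clades, then outgroups. When
the reference cannot be a carrier (deletions), a one-row reference block
precedes the carrier block. The encoding is bijective given the reference
row, and `reconstruct_slice` inverts it exactly; a strict-ASCII mode uses
`.` for identity so plain-text output cannot confuse identity dashes with
gaps.

## Supermatrix tree stage

The tree stage is a deliberately desk-scale stand-in for a maximum-
likelihood analysis (which, with genome-scale supermatrices and WAG/JTT
models, is out of scope here):

* per-protein alignments are concatenated with all-gap filling for missing
  taxa and a recorded partition map;
* poorly conserved regions are removed by three explicit rules replacing a
  Gblocks run — delete runs of more than 8 consecutive nonconserved columns
  (majority fraction over all rows ≤ 0.5, or any gap), trim surviving blocks
  to highly conserved (≥ 0.85) end columns, and drop blocks shorter than 10
  columns — with every kept interval reported for audit;
* columns under 95% site coverage are then removed (the trimming/coverage
  order follows the order in which the steps are usually described);
* pairwise distances are Poisson-corrected mismatch fractions over
  pairwise-ungapped columns, d = −ln(1 − p);
* the tree is standard neighbor joining on the Q-criterion with negative
  branch lengths clamped to zero and deterministic tie-breaking, so the same
  input and seed give byte-identical newick;
* bootstrap support resamples columns of the final filtered matrix (the
  supermatrix is treated as a single character sample, not per-partition)
  and reports the percentage of replicates containing each internal
  bipartition of the full-data tree;
* rooting places the root at the midpoint of the outgroup's terminal edge.

NJ on Poisson distances is statistically consistent on additive matrices and
recovers them exactly (verified over random 5–8 leaf trees), which is the
honest scope of this stand-in; no claim is made that it reproduces a
published ML topology.

## Synthetic data: what it emulates, and what it does not

The generator evolves protein families down a 35-taxon species tree shaped
like the study system: four rodent suborders (Sciuromorpha basal, then
Hystricomorpha, then Castorimorpha sister to Myomorpha), nested Myomorpha
families with Muroidea = Muridae + Cricetidae + Spalacidae, Lagomorpha,
a tree shrew sister to that whole in-group, and four primate/dermopteran
outgroup taxa. The tree shrew is deliberately not in the outgroup set: the
composite candidate clade "Glires and Scandentia" must not intersect the
outgroups, and polarity is inferred from the remaining four taxa.

Defaults: 50 families of 600 residues; substitution probability 0.02 per
site per branch, applied uniformly over the 20 amino acids (no
exchangeability matrix — identity-based conservation is all the detector
consumes, so a JTT-like model would add realism the scan cannot see); 50% of
sites are immutable, mimicking the strongly conserved context that real
signature-bearing regions have and guaranteeing that planted events satisfy
the flank rule. Planted events (0–2 per family, lengths 1–5 aa, insertion or
deletion with equal probability) are applied on the target clade's ancestral
branch; loss taxa revert it on their terminal branch; ragged decoys give
clade members different lengths at one locus; homoplastic decoys plant the
identical-coordinate indel independently on one non-clade terminal, chosen
so that neither side of the resulting pattern satisfies any candidate clade
(otherwise the decoy would be a genuine composite signature, not a
distractor — the generator checks this explicitly, and likewise only plants
loss taxa whose removal cannot make the carrier set mimic a different
candidate clade). Event loci are kept at least 120 columns apart.

The simulator emits the true alignment directly — there is no realignment
step — so these tests isolate the detector's behaviour from aligner
artifacts. Real pipelines inherit additional failure modes the synthetic
scenario does not model: alignment errors around indels, rate heterogeneity,
compositional bias, paralog contamination, and missing homologs. Perfect
precision/recall here therefore validates the scan's logic, not its
end-to-end performance on raw genome data.

## The packaged catalog

The catalog ships the 41 published rodent/Glires CSIs as transcribed records
(protein, accession, size, kind, printed location range, specificity clade,
source table). Two printed inconsistencies are preserved with flags rather
than corrected: the Rodentia signature is stored with size 28 as the table
prints although the body text says 29 aa, and one Sciuromorpha location is
printed in abbreviated form ("1326-28"), which the parsed view expands to
1326–1328. Composite specificities are single labels and are never
double-counted; the set of labels is exactly the candidate-clade label set
of the shipped partition config.

## Numerical and degenerate-input choices

* Ties everywhere are broken deterministically (lexicographic residue for
  column majorities, first-pair order in NJ's Q search), so all outputs are
  reproducible bit-for-bit under a fixed seed.
* An alignment column that is all-gap is invalid input; subsetting taxa
  drops columns left all-gap, with a logged warning.
* A taxon pair sharing no ungapped column, or with mismatch fraction 1
  (undefined Poisson distance), is a hard error naming the pair.
* Trimming everything yields a valid empty supermatrix with a warning, not
  an exception; both trimming and coverage filtering are idempotent.
* Scoring conventions: with zero calls, precision is reported as 1.0 with an
  explicit zero-denominator flag (likewise recall with empty truth), so
  perfect-empty and failed runs are distinguishable.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data
generated at call time: 50–60 families of 600 residues over 35 taxa for
detection metrics, ≥ 50 random instances per brute-force oracle comparison
(alignments up to 8 × 120, supermatrices up to 6 × 200), 100 random 5–8 leaf
additive matrices for NJ recovery, and 100 bootstrap replicates on small
matrices. These sizes exercise every code path at full fidelity while
keeping a complete run in seconds.

## Known limitations

* Identity-based conservation only; similarity-matrix flank scoring is out
  of scope.
* The boundary guard rejects genuinely stacked adjacent events (see above).
* The exception semantics are set-based: with `max_exceptions ≥ 1`, a large
  clade lacking one member can in principle be confused with a smaller
  nested clade plus exception; the classifier resolves this toward the
  smallest consistent clade and rejects exact ties as ambiguous rather than
  guessing.
* Nucleotide alignments, paralog disambiguation, and external database
  validation are the caller's responsibility.
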