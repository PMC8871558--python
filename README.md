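# csiscan

Conserved signature indel (CSI) discovery in protein multiple sequence
alignments, built around the rodent/Glires study system.

A CSI is a fixed-length insertion or deletion that sits inside a conserved
region of a protein and is shared by essentially all members of one
monophyletic group — a rare, discrete genetic event whose most parsimonious
explanation is a single change in the group's common ancestor. Such indels
are molecular synapomorphies: concrete characters that demarcate clades
independently of phylogenetic tree topology, and whose insertion/deletion
polarity follows from outgroup states. `csiscan` is for molecular
evolutionists and comparative genomicists who want that visual scanning
procedure as a reproducible, parameterised computation.

The package provides:

* **Detection** (`csiscan.detection`) — enumerate fixed-length indel
  candidates (maximal column runs with a constant gap-taxon set), filter by
  flank conservation (≥ 5 conserved columns within 45 on each side, by
  default), classify clade specificity against a hierarchical taxonomy with
  bounded exceptions (default 1) and zero tolerated foreign carriers, and
  polarise each call by near-unanimous outgroup states.
* **Signature figures** (`csiscan.render`) — the classic dash-notation
  excerpt (top-line reference, `-` for identity, blank for gaps, grouped
  taxon blocks), losslessly invertible.
* **A supermatrix tree stage** (`csiscan.phylogeny`) — concatenation with a
  partition map, rule-based conserved-block trimming, a 95% site-coverage
  filter, Poisson-corrected distances, neighbor joining with seeded
  column-resampling bootstrap, and outgroup rooting; newick in/out.
* **A synthetic-data generator** (`csiscan.simulate`) — Glires-like
  35-taxon families with planted clade-ancestral indels, substitution
  noise, lineage-specific losses, ragged-length decoys and homoplastic
  distractors, with a ground-truth table and scoring.
* **The study catalog** (`csiscan.catalog`) — the 41 published
  rodent/Glires CSIs as queryable records with per-clade tallies.

## Worked example

Simulate three families over the default Glires-like scenario, scan them,
and render the first detected signature:

```python
from csiscan.simulate import SimulationParams, generate_scenario
from csiscan.detection import detect_csis
from csiscan.render import render_signature

alns, truth, partition, tree = generate_scenario(3, SimulationParams(), seed=7)
for aln in alns:
    for call in detect_csis(aln, partition):
        print(aln.id, call.clade_label, call.length, call.polarity,
              call.reference_taxon, call.reference_range)
```

prints

```
fam0000 Lagomorpha 2 deletion Homo_sapiens (442, 453)
```

meaning: in family `fam0000` a 2-aa deletion specific to Lagomorpha was
found, displayed (indel plus five conserved flank columns per side) at
residues 442–453 of the Homo sapiens sequence. Rendering it:

```python
fig = render_signature(call, aln, partition, display_flank=12)
print(fig.to_text())
```

```
fam0000: 2 aa deletion specific for Lagomorpha
                                          ^^
[reference]
Homo_sapiens                  TDMYGRMICVYGRCPPLANHGVLQNQ

[Lagomorpha]
Oryctolagus_cuniculus         ------------  ------L-----
Lepus_europaeus               ------------  ------L-----
Ochotona_princeps             ------------  ------L-----

[Rodentia]
Ictidomys_tridecemlineatus    ---------T-F--------L-----
...
[outgroup]
Pan_troglodytes               --------------------L-----
```

Dashes denote identity with the top line, letters denote substitutions, and
the blank cells under the caret are the deletion shared by the three
lagomorphs and nobody else.

The same operations are available from the shell:

```sh
csiscan simulate --families 50 --seed 7 --out sim/
csiscan detect --alignment sim/fam0000.fasta --clades sim/clades.yaml --out report.tsv
csiscan tree --alignments sim/ --outgroup Homo_sapiens --bootstrap 100 --seed 17 --out tree.nwk
csiscan catalog --tally
```

`csiscan catalog --tally` prints the packaged per-clade counts
(Hystricomorpha 7, Sciuromorpha 9, … Total 41).

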