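# ribovar

Variant-to-structure analysis for ribosomal protein genes, built around the
case of *RPS19* and its protein product eS19, the most frequently mutated
gene in Diamond Blackfan anemia (DBA). Given a transcript model, a list of
coding variants in HGVS `c.` notation, one or more (pre-)ribosome structures,
and candidate pseudogene sequences, the package answers four questions a
ribosomopathy study asks:

1. **What protein does each variant produce?** Each variant is applied to
   the cDNA and the mutant coding sequence is re-translated, yielding a
   consequence class (missense, nonsense, frameshift, in-frame indel,
   start/stop loss), the mutant protein length, and the position of any
   premature termination codon (PTC).
2. **Is the mutant transcript degraded?** The 50–55 nt exon-junction rule:
   a transcript is predicted to undergo nonsense-mediated decay (NMD+) when
   its PTC lies more than the threshold upstream of the last exon–exon
   junction, and to escape (NMD−) when the PTC falls in the last exon or
   within the threshold. Junction positions are tracked in mutant
   coordinates, so indels upstream of a junction shift it correctly.
3. **Which residues matter for assembly?** Interchain atom pairs at ≤ 4 Å
   (hydrogens excluded) are profiled per residue across ribosome assembly
   states, together with geometric hydrogen bonds (N/O/S donor–acceptor
   pairs at ≤ 3.5 Å, D–H–A ≥ 120° when explicit hydrogens exist) and
   Shrake–Rupley solvent accessibility. Poorly resolved chains can be
   replaced by an equivalent chain from a reference structure after a
   least-squares (Kabsch) superposition. A chain-role map flags any contact
   with assembly-factor chains.
4. **Could a pseudogene substitute for the lost protein?** Each pseudogene
   is translated in all six frames; the best-scoring frame is aligned
   globally to the wild-type protein (Needleman–Wunsch, BLOSUM62, affine
   gaps 10/0.5, end gaps free) and EMBOSS-style identity / similarity /
   gaps percentages are reported.

A deterministic fixture generator (`ribovar.synthetic_data`) produces a full
input bundle with known ground truth — transcript, 64-variant cohort,
three-state toy structures with planted contact counts, and a pseudogene
identity ladder — so the entire pipeline is testable without downloading any
database entry.

## Worked example

```bash
# generate a synthetic input bundle (seed-reproducible, ships its own config)
ribovar fixtures --outdir demo --seed 2

# run every stage on it
ribovar run -c demo/config.yaml --outdir demo_out
```

or, from Python:

```python
from ribovar.genemodel import read_fasta
from ribovar.mutate import parse_hgvs_c, predict_consequence
from ribovar.pseudogene import pseudogene_rescue_report
from ribovar.synthetic_data import write_fixture_bundle

bundle = write_fixture_bundle("demo", seed=1)
model = bundle.transcript

cons = predict_consequence(model, parse_hgvs_c("c.25_42del"))
print(cons.klass.value, cons.mutant_length)      # INFRAME_DEL 139

ref = read_fasta("demo/reference_protein.fa", "PROTEIN")[0]
best = max(
    (pseudogene_rescue_report(pg, ref) for pg in read_fasta("demo/pseudogenes.fa")),
    key=lambda r: r.alignment.identity_pct,
)
print(best.pseudogene_id, round(best.alignment.identity_pct, 1))  # PSEUDO3 90.3
```

The first call classifies an 18-nt deletion as in-frame and predicts a
product six residues shorter than the 145-aa wild type; the second finds the
near-intact member of the pseudogene family, whose best reading frame aligns
to the wild-type protein at 90.3% identity with no gap columns — the kind of
candidate that could compensate for a heavily truncated gene product.

Running all stages on the bundle prints the cohort summary to
`demo_out/summary.json`: 46.9% of the 64 variants escape NMD, 29.7% are
predicted degraded, and the remainder (splice-site, start-loss and stop-loss
variants) are not evaluable under the junction rule; the contact profile
shows a hotspot residue reaching 45 interchain atom pairs with two RNA
residues in one assembly state and no contact with the factor-labelled chain
in any state.

## Layout

- `src/ribovar/genemodel.py` — sequences, transcript models, translation
- `src/ribovar/mutate.py` — HGVS `c.` parsing and consequence prediction
- `src/ribovar/nmd.py` — exon-junction NMD classification
- `src/ribovar/structcontact.py` — structure I/O, contacts, superposition, H-bonds, SASA
- `src/ribovar/pseudogene.py` — six-frame translation and global alignment
- `src/ribovar/synthetic_data.py` — deterministic fixture generator
- `src/ribovar/pipeline.py`, `cli.py` — orchestration and command line

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
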