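# phiskit

Structure-based discovery and classification of **PHIS transposons** — the
superfamily of cut-and-paste DNA transposons comprising the *PIF/Harbinger*,
*ISL2EU*, *Spy*, *Pangu*, *NuwaI* and *NuwaII* groups. The six groups share a
DDE-motif transposase but differ in the sequence signature they leave at the
insertion site, which is what identifies them:

| group         | target site duplication (TSD)      | accessory ORF      |
|---------------|------------------------------------|--------------------|
| PIF/Harbinger | 3 bp `5'-TWA-3'`                   | Myb/SANT protein   |
| ISL2EU        | 2 bp `AT`, cut `A\|AT\|T`          | YqaJ exonuclease   |
| Spy           | none; inserts within `AAATTT`      | — (single ORF)     |
| Pangu         | 3 bp `5'-ANT-3'`                   | no known domain    |
| NuwaI         | 3 bp `5'-CWG-3'`                   | Myb/SANT protein   |
| NuwaII        | 3 bp `TNA`, cut `C\|TNA\|G`        | Myb/SANT protein   |

The package is aimed at people who annotate repeats in genome assemblies: it
takes a genome FASTA plus transposase protein queries and produces classified
element families with their terminal inverted repeats (TIRs), TSD models,
ORF/domain annotations and copy censuses.

## What it does

1. **Translated homology search** (`phiskit.homology_search`) — a
   seed-and-extend scan of all six reading frames with BLOSUM62 scoring and
   Karlin–Altschul statistics (`E = K·m·n·e^{-λS}`); hits with `E < 1e-4`
   become candidate transposase loci.
2. **Family building** (`phiskit.family_builder`) — each locus recruits its
   genomic copies (`E < 1e-5`, aligned length > 50 bp, identity > 80%,
   all strict), copies are extended 2 kb each side, aligned with MAFFT, and
   the element boundaries are defined from column consistency refined by
   TSD-junction and terminal-inverted-repeat evidence; a majority-rule
   consensus represents the family.
3. **Structure annotation** (`phiskit.structure_annotator`) — end-anchored
   TIR detection, full-length copy calls, TSD inference from per-copy flank
   duplications, Spy-motif testing, paralogous empty-site reconstruction and
   search, and sequence-logo matrices (information content in bits).
4. **ORF/domain annotation** (`phiskit.orf_domain_annotator`) — Met-to-stop
   ORFs on six frames and PSSM detection of the diagnostic domains (DDE with
   its catalytic D..D..E triad, HTH, Myb/SANT, THAP, YqaJ).
5. **Classification & census** (`phiskit.classifier_census`) — TSD-composition
   rules assign the group; families with the full intact ORF layout are
   flagged potentially active; copy counts are re-estimated per family.
6. **Synthetic genomes** (`phiskit.synthetic_data`) — a simulator that plants
   multi-copy families under each group's cut mechanics with per-copy
   divergence, truncation and strand, emitting complete ground truth. All
   tests run against it; no downloads are needed.

## Worked example

```python
from phiskit.synthetic_data import SimulationConfig, simulate, reference_transposases
from phiskit.pipeline import PipelineConfig, run_pipeline

sim = simulate(SimulationConfig(seed=42))         # 1 Mb, one family per group
result = run_pipeline(sim.genome, reference_transposases(), PipelineConfig())
for row in result.report_rows:
    print(row["family"], row["group"], row["tsd_consensus"],
          row["outer5"], row["outer3"], row["n_copies"], row["potential_active"])
```

prints (sequence-derived fields vary with the seed):

```
fam1 ISL2EU AT A T 20 True
fam2 Spy    20 True
fam3 NuwaII TVA C G 20 True
fam4 Pangu AWT   20 True
fam5 NuwaI CWG   20 True
fam6 PIF/Harbinger TWA   20 True
```

Reading the rows: the ISL2EU family shows the 2 bp `AT` duplication with the
conserved outer `A…T` (the `A|AT|T` cut); Spy has no duplication (its flanks
join across `AAATTT`); `TVA` and `AWT` are seed-42 samples of the `TNA` and
`ANT` patterns; each family recovered all 20 planted copies and both ORFs
intact, hence potentially active.

The same pipeline is available from the shell:

```bash
phis simulate --out sim/                      # synthetic genome + truth
phis run --genome sim/genome.fa --out run/    # full discovery run
phis search --genome sim/genome.fa --out hits.tsv
```

`run/` contains `hits.tsv`, per-family consensus FASTA and copy GFF3,
`report.tsv` (family, group, TSD, TIR, counts) and a `manifest.json` with
parameters and output checksums; re-running with the same inputs is
bit-identical.

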