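# allofoot

Structural analysis of human alloantibody recognition of HLA class I.

Anti-HLA alloantibodies arise after transfusion, pregnancy or
transplantation and are a major driver of antibody-mediated graft
rejection. Clinical practice infers their fine specificity from
single-antigen-bead (SAB) binding patterns and sequence-based *eplet*
prediction; a crystal structure of an alloantibody Fab bound to its HLA
target lets those inferences be grounded in an actual epitope footprint.
`allofoot` is a toolkit for that analysis chain, written for structural
immunologists and transplant-immunology researchers:

* **Epitope footprint** — Shrake–Rupley solvent-accessible surface area
  (SASA), the one-sided buried surface area (BSA) of the HLA side,
  decomposed exactly per Fab chain; residue contacts; geometric hydrogen
  bonds; the discontinuous epitope segments along the α chain; backbone
  displacement versus an unbound reference.
* **Allele reactivity** — classification of epitope-position substitutions
  (hydrogen-bond loss, charge reversal, charged→hydrophobic, side-chain
  truncation), reactive/nonreactive prediction per allele, and concordance
  with SAB mean-fluorescence intensities (MFI, reactive at MFI ≥ 500).
* **Receptor co-engagement** — Kabsch superposition of TCR/KIR/CD8–HLA
  complexes onto the Fab–HLA complex via the shared α chain, and van der
  Waals clash counting between the Fab and each superposed receptor.
* **Binding kinetics** — closed-form simulation and nonlinear fitting of
  1:1 Langmuir single-cycle sensorgrams (k_a, k_d, K_D = k_d/k_a) and
  saturation (ELISA-style) isotherms.
* **Cytotoxicity statistics** — CDC/ADCC cytotoxicity% =
  (experimental − baseline)/(maximum − baseline) × 100, with an exact
  (full-enumeration) two-tailed Mann–Whitney test, tie-corrected
  Kruskal–Wallis, and Dunn's post-hoc comparisons for the small replicate
  groups (N = 3–4) typical of these assays.
* **Synthetic data** — generators for every input class (toy complexes
  with planted contacts/H-bonds/BSA, allele panels with planted variants
  and MFI bands, noisy sensorgrams, cytotoxicity replicate tables), each
  carrying its exact ground truth, so the whole pipeline is testable
  offline.

## The model in brief

The buried footprint is ΔSASA of the HLA side: `BSA = SASA(HLA alone) −
SASA(HLA in complex)`, computed on a deterministic golden-spiral lattice
with Chothia-type radii (C 1.70, N 1.55, O 1.52, S 1.80 Å) and a 1.4 Å
probe. Each newly occluded surface point is attributed to the occluding
Fab chain, so the per-chain decomposition sums to the total exactly.
Hydrogen bonds use heavy-atom criteria (donor–acceptor ≤ 3.5 Å,
antecedent angle ≥ 90°) appropriate for structures without modeled
hydrogens. Epitope positions within 3 of each other merge into one
segment. Single-cycle kinetics follow the piecewise closed form
`R(t) = R_eq + (R_0 − R_eq)·exp(−(k_a·C + k_d)·t)` with
`R_eq = R_max·C/(C + K_D)` per injection phase.

## Worked example

```
$ allofoot synth complex --out toy.pdb
wrote toy.pdb; alpha epitope [14, 16, 17, 18, 19, 39, 90], 5 hydrogen bonds

$ allofoot footprint toy.pdb --roles A=hla_alpha,B=b2m,H=fab_heavy,L=fab_light
total footprint: 387.1 A^2
  hla_alpha vs fab_heavy: 277.0 A^2
  hla_alpha vs fab_light: 72.2 A^2
  b2m vs fab_heavy: 37.9 A^2
  b2m vs fab_light: 0.0 A^2
alpha-chain epitope segments: [[14, 16, 17, 18, 19], [39], [90]]
hydrogen bonds: 5
```

The synthetic complex plants the lateral binding topology: the α chain is
touched in three discontinuous runs ({14,16–19}, {39}, {90}), the light
chain donates one hydrogen bond to Asp90 (the eplet position), the heavy
chain makes four hydrogen bonds to Arg17 and buries a small patch on
β2-microglobulin, which never touches the light chain (0.0 Å²). The
decomposition columns sum to the total footprint by construction.

```
$ allofoot synth panel --fasta panel.fasta --mfi panel.csv --seed 0
wrote 20 alleles (8 nonreactive) to panel.fasta, panel.csv

$ allofoot reactivity --fasta panel.fasta --mfi panel.csv \
    --reference "SYN*11:01" --epitope-positions 14,17,19,39,90 \
    --hbonded-positions 90,17
alleles: 19  TP=11 FP=0 TN=8 FN=0 accuracy=1.000
```

All eight alleles planted with an abrogating epitope substitution
(Asp90→Ala, Arg14→Trp or Arg17→Ser) are predicted nonreactive and sit
below the MFI threshold; the prediction is fully concordant with the
bead-assay classes.

For the real crystallographic analysis, fetch the depositions and run

```
python scripts/fetch_structures.py
allofoot footprint data/structures/6id4.cif --roles <chain roles>   # or:
python - <<'PY'
from allofoot.deposited import analyze_deposited_fab_hla
st, report = analyze_deposited_fab_hla("data/structures/6id4.cif")
print(report.total_footprint, report.segments)
PY
```

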