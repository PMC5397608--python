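# solubis

Structure-corrected aggregation-propensity scoring and solubility engineering
of antibodies.

## The problem

Most antibodies carry short (≥ 5-residue) aggregation-prone regions (APRs) —
hydrophobic, β-sheet-prone stretches that can nucleate aggregation.  Raw
sequence-based aggregation predictors over-count them, because an APR that is
buried in a thermodynamically stable part of the fold is protected and never
sees solvent.  What matters for developability is the handful of *critical*
APRs: those whose local structural environment is not stabilising enough to
keep them out of trouble, typically APRs in or near the CDR loops.

This package scores that distinction and designs variants that remove it.
It is aimed at protein engineers triaging antibody candidates or designing
aggregation-suppressing mutations before expression.

## The score

For each APR the pipeline computes

* `tango_sum` — the summed per-residue intrinsic aggregation propensity
  (0–100 per residue) over the APR;
* `ΔG_contrib` — the summed contribution of the APR's residues to the free
  energy of folding, in kcal/mol (negative = stabilising), either from a
  structural surrogate or from a real per-residue free-energy table
  (e.g. FoldX SequenceDetail output);
* a stability weight `w = clip((ΔG_contrib + 5) / 10, 0, 1)`, so that APRs at
  ΔG ≤ −5 kcal/mol are thermodynamically protected (w = 0) and APRs at
  ΔG ≥ +5 keep their full propensity (w = 1).

The **Solubis score** of an antibody is `Σ_APR tango_sum × w`.  APRs whose
corrected score `tango_sum × w` passes a threshold (default 50) are flagged
*critical*.  Variant design then runs two scans: a **MASS scan** (every
critical-APR residue × the five gatekeepers D, E, K, R, P, scored for
Δaggregation and ΔΔG) and a **supercharge scan** (net-charge-increasing
substitutions outside the heavy-chain CDRs).

## Worked example

Generate a toy Fv with a hydrophobic APR planted in CDR-L1 and score it
against its (solvent-exposed) structure:

```sh
solubis fixtures --seed 1 --apr-in-cdr --burial exposed --out-dir demo
solubis score demo/toy.fasta --pdb demo/toy.pdb --out-dir demo/score
```

```
INFO solubis score 122.8 over 1 APRs (1 critical)
```

`demo/score/stretch_points.csv`:

```
antibody,chain,region,start,end,sequence,tango_sum,dg_contrib,weight,corrected_score,critical
antibody,L,CDR1,26,31,VYIIVF,435.353,-2.17873,0.282127,122.825,1
```

The APR `VYIIVF` at light-chain positions 26–31 has a raw propensity sum of
435 but sits in a weakly stabilising environment (ΔG_contrib = −2.2 kcal/mol,
weight 0.28), so it stays critical with a corrected score of 123.  Had the
same sequence been buried (`--burial buried`), ΔG_contrib would fall below
−5 kcal/mol and the corrected score would be exactly 0.

Designing suppressing mutations:

```sh
solubis design demo/toy.fasta --pdb demo/toy.pdb --out-dir demo/design
```

```
INFO variant antibody_IL29P: solubis 0 (wild-type 122.8)
```

The top-ranked gatekeeper substitution (Ile→Pro at L29, ΔΔG +0.29 kcal/mol)
abolishes the APR and drives the variant's Solubis score to 0.

Real per-residue aggregation scores and free energies from external tools can
replace both surrogates (`--energy-table`, TSV dialects documented in
`solubis.io`); they flow through all downstream stages unchanged.

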