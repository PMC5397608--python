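# Methods

This note documents the models behind `solubis`, their assumptions, the
defaults that matter, and what the synthetic fixtures do and do not show.

## Pipeline overview

1. Annotate each antibody chain (Chothia-style CDR/FR labels).
2. Compute a per-residue intrinsic aggregation-propensity profile (0–100).
3. Call APRs: maximal runs of ≥ `min_len` residues scoring ≥ `threshold`
   (defaults 5 and 5, the conventional per-residue floor of summed TANGO-style
   output).
4. Sum each APR's per-residue folding free-energy contributions
   (`ΔG_contrib`, kcal/mol) from a structure-derived surrogate or an external
   per-residue table.
5. Weight: `w = clip((ΔG_contrib + 5)/10, 0, 1)`; corrected score
   `tango_sum × w`; Solubis score = Σ corrected scores; APRs with corrected
   score ≥ `critical_threshold` (default 50) are critical.
6. Variant design: gatekeeper MASS scans over critical APRs and
   net-charge-increasing scans outside heavy-chain CDRs.
7. Evaluation: Tm−Tagg class labels (cutoff 5 °C, strict inequality,
   per-antibody overrides), pair-counting ROC/AUC, MCC, Pearson.

## Aggregation-propensity surrogate

The propensity model is a windowed sequence potential, not a reimplementation
of TANGO (whose full parameterisation is proprietary to its authors).  For a
5-residue window `w`:

    E_w = Σ_j (h_j + b_j) − λ·|q_w| − γ·n_P(w)

with `h` min-max-normalised Kyte–Doolittle hydropathy, `b` normalised
Chou–Fasman β-sheet preference, `q_w` the window formal charge (K/R +1,
D/E −1, His neutral), `n_P` the window proline count.  Residue *i* takes its
best covering window and is scored `100·σ((E_{w*} − E0)/s)` with a logistic σ.

Defaults (fixed, versioned constants — never fitted at run time):
`E0 = 8.5`, `s = 0.4`, `λ = 3.0`, `γ = 3.5`, window 5.  They were calibrated
once against three qualitative contracts: (a) STVIIE-like hydrophobic
hexapeptides in a polar context are called as APRs; (b) poly-charged and
proline-rich controls are not; (c) gatekeeper-flanked hydrophobic segments
planted in the synthetic fixtures are recovered at exactly the planted
boundaries.  The steep slope makes the logistic nearly a threshold on window
energy, which keeps APR boundaries sharp; the one known smear is that a polar
residue immediately adjacent to a strong hydrophobic stretch (with no
gatekeeper between them) can inherit a supra-threshold window.  Gatekeeper
flanks — which is where gatekeepers sit in real sequences — remove that
ambiguity, and the fixtures plant them deliberately.

`X` scores exactly 0 and invalidates every window containing it, so unknown
residues break APRs.  External per-residue scores (real TANGO output) can be
injected via `profile_from_scores` or the generic TSV reader and flow through
APR calling, scoring and design unchanged.

The surrogate deliberately omits the competing-conformation partition
function of the real predictor (helix/turn populations, pH and ionic-strength
dependence).  It shares the interface, the 0–100 per-residue scale, the
≥5-at-≥5 APR convention and the gatekeeper response, which is what the
downstream scoring contract needs.

## Local-stability surrogate

Per-residue folding free energy (kcal/mol, negative = stabilising):

    ΔG_i = −(α·(1−RSA_i)·H_i + β·HB_i) + κ·C_i

* `RSA` — relative solvent accessibility: Shrake–Rupley accessible area
  (probe 1.4 Å, 960 sphere points, computed over *all* chains) divided by the
  residue type's Gly-X-Gly maximum (Tien et al. theoretical values), clipped
  to [0, 1].
* `H` — normalised Kyte–Doolittle hydrophobicity: burial of hydrophobic
  surface is stabilising.
* `HB` — hydrogen bonds: N/O atom pairs < 3.5 Å between residues ≥ 2 apart in
  sequence (or on different chains), with a coarse angular criterion (the
  partner must lie beyond 90° of the covalent bond at each atom).
* `C` — steric strain: non-bonded heavy-atom contacts < 2.5 Å.

Defaults `α = 0.8`, `β = 0.5`, `κ = 1.0` kcal/mol; all cutoffs configurable
via `StabilityParams`.  The magnitudes were chosen so that a buried,
hydrogen-bonded hydrophobic APR of typical length accumulates ΔG_contrib well
below −5 kcal/mol (weight 0) while a solvent-exposed one stays in the
−5..0 band — i.e. the surrogate is built to place APRs correctly relative to
the ±5 kcal/mol clipping window that the scoring applies, which in turn
absorbs its inaccuracy in absolute terms.  It is a ranking potential; per-
residue tables computed by a real force field are the preferred input and
take precedence over coordinates whenever supplied.

ΔΔG of a substitution keeps the wild type's burial and backbone hydrogen
bonds, swaps the hydrophobicity term, and drops side-chain hydrogen bonds on
polar→apolar substitutions.  No repacking or relaxation is attempted —
adequate for ranking mutation scans, not for quantitative stability
prediction.

## Annotation

CDRs are located by conserved anchors rather than a full numbering-scheme
alignment: the first framework cysteine (Cys23 light / Cys22 heavy), the
tryptophan after CDR1, the second cysteine before CDR3, and the FG-x-G /
WG-x-G J-segment motifs, with CDR lengths bounded by canonical limits.
CDR-L2 starts 16 residues after the CDR-L1 end and is 7 long; CDR-H2 starts
15 after the CDR-H1 end and is 6 long.  Numbering counts from the anchored
first cysteine.  This is robust for standard variable domains and exactly
right for the fixtures; non-standard domains should use the external
numbering sidecar (TSV: `chain position insertion aa region`), which is taken
verbatim.  Kabat/IMGT schemes and canonical-class typing are out of scope.

Net charge counts K/R as +1 and D/E as −1; histidine is neutral by default
(`CHARGE` is the single place to change that), termini ignored.  "Outside
the CDRs" means labels FR1–FR4 plus CONST.

## Variant design choices

* Gatekeeper set {D, E, K, R, P}; MASS scans skip the substitution when the
  wild type already is that gatekeeper, giving exactly `5·L − #gatekeepers`
  candidates for an APR of length L.
* MASS shortlist: ΔΔG ≤ +0.5 kcal/mol by default (the intent is "maximal
  aggregation suppression at minimal stability cost"; the cutoff is reported
  in output metadata), ranked by Δtango, ties by ΔΔG, then position, then
  mutant letter — a total order, so output is deterministic.
* Supercharge alphabet: X→K and X→R at any non-K/R framework position, plus
  the acid→amide pairs D→N/Q and E→N/Q (each +1 to +2 unit charges).  This is
  the minimal chemically conservative realisation of "increase the net charge
  outside the CDRs"; the rule is configurable in `supercharge_scan`.
* `compose_variant` re-runs the whole pipeline on the mutated sequence; the
  structure (if any) is carried over with wild-type coordinates, consistent
  with the fixed-backbone assumption of the scan heuristics.

## Evaluation conventions

* Class label 1 iff Tm − Tagg > 5 °C, strict at the boundary; antibodies
  without a measurable gap are handled by explicit per-antibody overrides.
* AUC by the Mann–Whitney pair-counting identity (ties ½) rather than
  trapezoids, making the tie convention explicit; prediction is positive at
  score ≥ threshold.
* MCC returns 0 when a confusion-table marginal is empty.
* The bundled published table encodes "less than 1 degree" gaps as 0.5 °C;
  the score/gap correlation is insensitive to that choice within rounding
  (0.0, 0.5 or 0.9 °C all give r = 0.88–0.89).

## What the fixtures show — and what they do not

The toy Fv plants one gatekeeper-flanked hydrophobic APR (drawn from
I/V/L/F/Y with at most one Tyr per 5-window, so every window clears the
calling energy) in a polar S/T/G/N/Q background with scattered K/E.  The toy
structures are extended chains on a deterministic lattice; side chains are
not modelled, burial is produced by a pseudo-atom cage plus planted
hydrogen-bond partners (two per APR residue).  The buried/exposed pair
differs only in coordinates, so score differences isolate the
stability-weighting mechanism — the package's central claim that a buried
APR is thermodynamically protected.

Passing tests on these fixtures therefore demonstrate the *pipeline's
contracts* (boundary-exact APR calling, monotone gatekeeper response, exact
arithmetic, burial-driven protection, deterministic outputs), not predictive
accuracy on real antibodies: fixture structures are not immunoglobulin folds,
the surrogates are not TANGO/FoldX, and the published-table statistics are
computed from printed values, not re-derived from structures.

## Numerical and degenerate-input conventions

Positions are 1-based, intervals closed.  Sequences shorter than the window
give an all-zero profile with a warning; residues with < 3 atoms get RSA 1
with a warning; residues without coordinates get ΔG 0 with a warning (but are
an error for ΔΔG).  Floats in reports are written to 6 significant digits;
JSON keys and CSV columns have a fixed order, so equal inputs produce
byte-identical files.  Report sizes: the default test suite and the
acceptance script use ~110-residue chains, ≤ 1000-profile oracle sweeps and
500 random ROC instances, which keeps a full run around a minute on one core.

## Known limitations

* Anchor-based annotation fails on domains missing the conserved motifs
  (error names the missing anchor; the sidecar is the escape hatch).
* The ΔΔG heuristic cannot see repacking, so it underestimates the cost of
  burying a charge in a tight core; the MASS ΔΔG filter inherits that.
* The FoldX SequenceDetail reader is best-effort (layouts vary by version);
  the energy-column index is configurable and the generic 4-column TSV is the
  canonical interchange format.
* Structure repair/minimisation is out of scope: HETATM/waters are dropped,
  altlocs resolved by occupancy, hydrogens ignored.
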