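# Methods

This note documents the models, numerical choices and limitations behind
xlscout, in the spirit of the methods documentation of mature scientific
Python packages.

## Cross-linker model

A cleavable linker is described by its intact (residue) mass and the two
cleavage-fragment stump masses. For symmetric linkers the stumps are
complementary, `light + heavy = intact`; the constructor enforces this to
1e-4 Da. Built-in presets (masses from elemental compositions,
monoisotopic):

| linker | light (Da) | heavy (Da) | intact (Da) | reactivity |
|--------|-----------:|-----------:|------------:|------------|
| DSSO   | 54.01057   | 103.99320  | 158.00377   | K |
| DSBU   | 85.05276   | 111.03203  | 196.08479   | K |

Arbitrary linkers, including diagnostic-ion lists and protein-N-terminal
reactivity, can be supplied through the INI config. Constants: proton
1.007276 Da, water 18.0105647 Da, C13–C12 1.0033548 Da; residue masses from
the standard monoisotopic table (cross-checked in the test suite against an
independent mass calculator).

## Digestion and the candidate index

Tryptic digestion cleaves after K/R but not before P (the simple rule, no
W·KP/M·RP exceptions), up to 2 missed cleavages, peptide length 5–30 by
default. Fixed carbamidomethyl-C and variable oxidation-M (≤2 sites) are the
default modifications. Decoys are full protein reversals with a `REV_`
accession prefix; a peptide found in both target and decoy space is counted
as target (conservative for FDR). A residue is a valid link site if it is
reactive and not the C-terminal residue of the peptide — a cross-linked K
cannot be cleaved by trypsin, which is also why linkable peptides come from
missed-cleavage products — except at the protein C-terminus. The candidate
index holds only peptides with ≥1 valid site, sorted by neutral mass, and
answers ppm/Da range queries by binary search.

## Doublet detection

For each fragment charge `z` from 1 to `precursor_charge − 1` every peak
pair whose gap matches `(heavy − light)/z` within the doublet tolerance
(default 10 ppm, evaluated at the heavier peak) is a full doublet; the
peptide neutral mass follows from the light peak. Spectra with more than
2000 peaks are trimmed to the 2000 most intense before the O(peaks²)
pairing, and partial-evidence single ions are taken from the 200 most
intense unassigned peaks — both bounds keep the pairing cost fixed per
spectrum, so total pairing work scales with (doublet pairs × spectra) and is
independent of database size (instrumented counters assert this in the
tests).

Pair hypotheses must satisfy `|m₁ + m₂ + intact − mass_P| ≤ T_D` with
`T_D` = 5 ppm of the precursor mass by default. In indication mode the
partner mass is computed by subtraction (the relation then holds by
construction) and partner masses below 300 Da are discarded as implausible;
observed light/heavy single ions of the inferred partner are annotated (all
four light/heavy combinations are checked) but are not required for
emission. Diagnostic ions are advisory flags; a strict mode can require
them, but they never replace the doublet requirement. Alternative
(monoisotopic-corrected) precursors are generated at offsets 0, −1, …, −k of
1.0033548 Da, either assumed or verified against a supplied MS1 scan.

A consequence of planting both stump variants of site-containing fragments
is that *fragments* also form genuine light/heavy doublets. These produce
spurious peptide-mass hypotheses that the precursor-sum relation discards;
they cost time but not correctness, which is why detector output is a set of
hypotheses rather than a classification by doublet count alone.

## Scoring

For `n` theoretical fragments (b/y at charges 1–2; fragments containing the
link site counted once per stump variant, so both variants contribute to `n`
and matching either contributes to `k`) the chance-match probability per
fragment is

```
p = clamp(n_peaks · 2 · tol_Da / (mz_max − mz_min), 1e-6, 0.5)
```

with the ppm tolerance converted to Da at the centre of the observed m/z
range. The peptide score is `−log₁₀ P(X ≥ k | n, p)` weighted by the
explained intensity fraction and floored at 0. The tail is computed by
log-space summation of exact binomial terms (`lgamma`-based), with the
`k = n` case taken as `n·log₁₀(p)` directly so that the closed form is exact
in floating point; the test suite checks the tail against an independent
`scipy.stats.binom.sf` oracle to 1e-9. The pair score of a CSM is the
minimum of the two peptide scores; ties between candidate pairs are broken
by summed explained intensity, then TT over TD over DD, then lexicographic
sequence order, making results deterministic. Pairing a peptide with itself
is allowed only when it occurs at least twice in the database or homodimer
search is enabled. One best CSM is reported per spectrum.

Candidate lookup uses a 20 ppm peptide-mass tolerance by default — wider
than the 10 ppm fragment tolerance because a doublet-inferred peptide mass
carries the fragment-level error amplified by the fragment charge, plus the
precursor error in indication mode. Intact-partner fragment ions (fragment
+ intact linker + whole partner peptide) are not generated by default:
stepped-HCD spectra are dominated by cleaved species and omitting them keeps
`n` small.

## Validation

FDR is estimated by a single descending-score scan with
`FDR = #decoys/#targets` (the plain target-decoy assumption; a `(D+1)/T`
pseudocount variant is available as a config switch). Equal-score tie
groups pass or fail as a whole, judged at the bottom of the group. The
high/medium tiers (default 1%/5%) are nested by construction. Cross-links
are keyed by the unordered pair of absolute residue positions, so a peptide
that is a substring of a longer peptide maps to the same cross-link; shared
peptides contribute every protein location, and a CSM joins every
residue-pair group it supports. Intra/inter separation validates the two
classes independently and reconcatenates, so labels in one class are
invariant to the other. Decoy items are labeled but never exported as
identifications.

## Synthetic data generator

The generator emulates stepped-collision-energy acquisition of DSSO-linked
tryptic peptides: random proteins (K frequency boosted to 10% so peptides
carry linkable sites), two distinct linkable peptides per spectrum, the
precursor computed exactly from the mass relation, both stump doublets
planted with probability 0.95 per peptide, 70% of the theoretical b/y
ladder planted, 50 uniform noise peaks, log-normal intensities (μ=10, σ=1,
arbitrary units), 5 ppm Gaussian jitter on fragment m/z and 2 ppm on the
precursor (MS1 mass accuracy is better than MS2 on Orbitrap-class
instruments). Entrapment databases are residue-shuffled copies of the
targets, re-shuffled until tryptic-peptide-disjoint from them. Defaults are
20 proteins of 300 residues and 500 spectra; one seed fixes every output
byte-for-byte.

What the generator does **not** emulate: isotope envelopes, co-isolated
chimeric precursors, retention-time structure, intensity correlations along
fragment ladders, dead-end/loop-link side products, and ion mobility.
Passing tests therefore demonstrate the correctness of the inference
machinery under the stated error models, not instrument-grade performance on
real acquisitions.

## Benchmark problem sizes

The bundled benchmarks use desk-scale problems chosen to exercise every code
path: 500-spectrum end-to-end recovery runs, 200-spectrum comparisons
against an exhaustive all-pairs search oracle on a ~50-target-peptide
database, 20 seeded 100-spectrum entrapment repetitions with a 4× entrapment
database, and pairing-counter scaling runs against ~1k and ~10k-peptide
indexes.

## Known limitations

- Dead-end (mono-link) and loop-link species are out of scope; spectra
  without doublets are simply classified non-cross-link.
- Only b/y ions are modelled; c/z ions (ETD) are not.
- No MS2 deisotoping: fragment charges are enumerated, not read from isotope
  spacing.
- The `--threads` option is accepted for interface compatibility, but
  spectra are currently processed sequentially; since each spectrum is
  independent and output ordering is canonical, results are identical for
  any requested thread count.
- Scores are not recalibrated (no machine-learned rescoring, no posterior
  error probabilities).
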