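# xlscout

An MS2-only search engine for **MS-cleavable cross-linking mass spectrometry
(XL-MS)**, written for structural and interaction proteomics workflows that
use linkers such as DSSO or DSBU.

Cleavable cross-linkers fragment in the collision cell into a lighter and a
heavier *stump*, each remaining attached to one of the two linked peptides.
In a stepped-collision-energy MS2 spectrum each peptide therefore shows up as
a peak *doublet* separated by `(heavy − light) / z`. xlscout exploits this:

1. **Detector** — finds stump-ion doublets at every plausible fragment charge
   and converts them into peptide-mass hypotheses. A spectrum is classified
   as a cross-link spectrum when two hypotheses explain the precursor:
   `|m₁ + m₂ + mass(XL) − mass_P| ≤ T_D`, where `mass_P` is the uncharged
   precursor mass and `mass(XL)` the intact linker mass. *Evidence mode*
   requires ions from both peptides (two full doublets, or one doublet plus a
   lone stump ion of the partner); *indication mode* infers the partner mass
   from the precursor by subtraction; *combined mode* is their union.
2. **Search** — each hypothesized peptide mass is looked up in a mass-sorted
   index of linkable tryptic peptides (targets + reversed decoys). Every
   candidate is scored with a probability-based score
   `S = −log₁₀ P(X ≥ k | n, p) · f`, the binomial tail probability that `k`
   of `n` theoretical b/y fragments (site-containing fragments carry both
   stump variants) match by chance, weighted by the explained intensity
   fraction `f`. The two candidate lists are combined under the
   precursor-mass constraint and the pair score of a cross-link spectrum
   match (CSM) is `A = min(S₁, S₂)`; the best pair per spectrum is kept.
3. **Validator** — CSMs that resolve to the same pair of linked protein
   residues merge into one *cross-link* (score = max over member CSMs). A
   hit is a decoy when **either** peptide comes from the reversed database.
   FDR = #decoys / #targets is estimated independently at the CSM and
   cross-link levels with two confidence tiers (default 1% *high*, 5%
   *medium*), optionally with intra-/inter-protein links validated
   separately.

A synthetic-spectrum generator (doublets, b/y ladders, noise, ppm mass
errors, entrapment databases) makes the whole chain testable without any
instrument data.

## Worked example

```bash
xlscout simulate --seed 7 --n-proteins 6 --n-spectra 50 --out demo
xlscout search --spectra demo/spectra.mgf --fasta demo/targets.fasta \
    --linker DSSO --mode combined --out demo/results
xlscout export-xiview --csms demo/results/csms.tsv --min-confidence high \
    --out demo/links.csv
```

The search step prints its tallies, e.g.:

```
version: 0.1.0
spectra_read: 50
spectra_with_doublets: 48
csms: 48
csms_target: 47
crosslinks: 48
crosslinks_high: 47
crosslinks_medium_or_better: 47
```

48 of the 50 simulated spectra contained recognisable stump doublets and
each yielded one CSM; one CSM matched the reversed-decoy database, and the
47 target residue pairs all pass the 1% estimated cross-link-level FDR
(`xlscout export-xiview` then writes those 47 links). `demo/results/csms.tsv` lists one row per spectrum
(both peptide sequences, link positions, per-peptide scores, the pair score,
precursor error in ppm, target/decoy class); `crosslinks.tsv` lists one row
per unique linked residue pair with its confidence tier; `links.csv` is a
xiView-style table (`Protein1, Protein2, …, AbsPos1, AbsPos2, Score`) ready
for structural mapping.

The same pipeline is available as a library:

```python
from xlscout import RunConfig, run_search
summary = run_search("demo/spectra.mgf", "demo/targets.fasta",
                     RunConfig(), "demo/results")
```

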