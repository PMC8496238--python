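# tagback

Design engine for two-step knock-out / add-back CRISPR genome editing.

Many genomic features worth editing — transcription-factor binding sites,
short cis-regulatory motifs, anything small and A/T-rich — have no usable
RNA-guided nuclease (RGN) target of their own: no PAM overlaps them, so
one-step HDR editing would force unwanted substitutions outside the
feature. The two-step strategy sidesteps this. **Step one** cuts at a
nearby high-quality guide target and replaces an expanded window around
the feature with a short engineered *landing pad* — an RGN site that
exists nowhere else in the genome. **Step two** cuts the landing pad and
restores the deleted window with the feature either wild-type
(complementation) or edited. `tagback` designs everything both steps
need: ranked guide targets, the landing pad, both donor DNAs, and an
annealing-optimized validation-primer set with in-silico PCR predictions
for the wild-type (+), knock-out (Δ) and add-back (AB) genome states.

The core pieces, in the field's usual notation:

- **Target motifs** are written in the IUPAC-quantifier dialect, e.g.
  `N{17}|N{3}>NGG` for SpCas9 (20 nt spacer, blunt cut 3 nt from the
  3' NGG PAM) or `TTTV<N{20}` for a 5'-PAM nuclease.
- **Guide QC**: polyT ≤ 4.5, 25 ≤ GC ≤ 75, no non-identical genomic site
  within 1 mismatch (searched up to 5), on-target ≥ 45 (pluggable scorer;
  the bundled surrogate is rule-based, not a trained model), and aggregate
  off-target specificity ≥ 90, with per-hit scores
  `100·Π(1−W[p])·[4(19−d)/19+1]⁻¹·n⁻²` aggregated as
  `100·100/(100+Σ)`.
- **Feature expansion**: bounds grow alternately left/right (50 bp steps,
  cap 4096 bp) until a QC-passing target fits inside; otherwise the
  feature is reported not editable.
- **Donors**: homology arms (default 50 nt) flanking the expanded window;
  step one carries the landing pad, step two the restored window, so a
  wild-type add-back donor is a literal substring of the + genome.
  Combinatorial add-backs over k sub-sites produce all 2^k bitmasked
  donors.
- **Primers**: sliding-window candidates weighted by Gaussian closeness to
  Tm/GC/length optima (nearest-neighbor Tm), paired with ΔTm and
  cross-dimer penalties, and assembled into the role set
  (sF/sR, oF/oR, iF/iR, AmpF/AmpR) by seeded simulated annealing.

## Worked example

A 12 kb synthetic locus carries a 9 bp Wor1-binding-site feature with a
clean Cas9 site planted 172 bp upstream (the bundled fixture
`tagback.fixtures.wor1_locus`):

```python
from tagback.fixtures import wor1_locus
from tagback import DesignConfig, run_design

sg, feature = wor1_locus()           # feature: chr1:6000-6009
res = run_design(sg.genome, feature, DesignConfig(rng_seed=5))

print("expanded bounds:", res.feature.expanded_start, res.feature.expanded_end)
print("chosen guide:", res.chosen_target.spacer, res.chosen_target.pam)
print("landing pad:", res.insert)
print("restored == wild-type:",
      res.states["addback"].genome.contigs == sg.genome.contigs)
print("verdict:", res.cpcr_table.attrs["sf_sr_verdict"])
```

prints

```
expanded bounds: 5950 6009
chosen guide: AATGTGCTACCGTGGAGTCT GGG
landing pad: AGTAGTATAGGGCAGCGAAGAGG
restored == wild-type: True
verdict: not_discriminating
```

The feature itself has no PAM, so the bounds expanded from 9 bp to 59 bp
to take in a passing guide (GC 50 %, no polyT run, no genomic near-match,
specificity 100). The landing pad is a fresh 23 nt Cas9 site with ≥ 6
mismatches to every PAM-adjacent window of the genome; applying both HDR
steps in silico restores the wild-type sequence byte-for-byte. The sF/sR
verdict says the locus-spanning pair cannot by itself separate the three
genotypes here — the deleted window is small, so + (997 bp), Δ (961 bp)
and a wild-type add-back (997 bp) leave + and AB identical, and the
junction pairs (sF/oR, oF/sR) carry the discrimination instead; a
length-changing edit or a larger window yields `distinct_lengths` or
`delta_only`.

The same pipeline is scriptable from the shell:

```
tagback synth --length 20000 --seed 7 --outdir locus/
tagback design --genome locus/synthetic.fasta --feature chr1:10000-10009 \
        --seed 5 --outdir design/
tagback sweep --genome locus/synthetic.fasta --n-loci 200 --out sweep.tsv
```

`design` writes the four result artifacts (ranked targets, donors,
primer set, cPCR table) plus predicted Δ/AB genomes and an edit log, and
exits nonzero with a documented code when the feature is not editable,
no unique insert exists, or a mandatory primer role is empty.

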