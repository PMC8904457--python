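# loopscan

Systematic deletion scanning of surface-exposed loops in trypsin-like
serine proteases: library enumeration, conformer-ensemble statistics,
and functional-assay fitting, with a fully synthetic data generator so
the whole pipeline runs and is tested offline.

## The problem

Trypsin-like proteases share a conserved double β-barrel fold; their
functional diversity is carried largely by surface-exposed loops whose
lengths vary in evolution. Sliding a deletion window of 1..k residues
through a loop probes how loop length and deletion position shape
activity, cofactor response and active-site integrity — a far larger
deletion space than the 2–3 residue truncations of classical
mutagenesis. The packaged example is the 170 loop of coagulation factor
VIIa (chymotrypsin numbering 170–170I; full-length residues 308–321),
the allosteric hub of tissue-factor activation: a window of 1–6 residues
through scan positions 313–321 (sequence `QSRKVGDSP`) gives the
canonical 39-variant library.

For each variant the analysis asks two kinds of question:

* **structural** — over an ensemble of N rebuilt loop conformations with
  per-pose scores (REU), compute the RMSF around the ensemble mean
  structure, the score-vs-RMSD funnel relative to the lowest-scoring
  pose, hydrogen-bond distance statistics (mean/SD against the
  2.5–3.8 Å stability window, histograms over 2.5–4.0 Å), polar-contact
  frequencies (strict < 3.5 Å), and the tilt angle of the
  cofactor-binding helix;
* **functional** — fit the assay panel: Michaelis–Menten
  (v = V·S/(K_M+S)), competitive inhibition at fixed substrate
  (v = V·S/(K_M(1+I/K_i)+S)), hyperbolic binding
  (v = v₀+(v∞−v₀)·T/(K_d+T)) and initial rates from linear progress
  curves, then report every variant as WT-normalised percentages
  (100·k_cat/K_M relative to the reference, etc.).

Deletion variants keep wild-type residue numbering with gaps, and
contacts defined at a wild-type position are re-addressed in a variant
by *slot resolution*: the residue now occupying the same ordinal
position from the N-terminal loop anchor.

## Worked example

```python
import loopscan as ls

library = ls.enumerate_deletions(ls.fviia_loop_definition())
v = library[36]                      # canonical 1-based variant index
print(v.window.start, v.window.end, v.deleted_sequence,
      v.resulting_loop_length)       # -> 313 318 QSRKVG 8

nm = ls.fviia_numbering_map()
print(nm.to_chymotrypsin(313))       # -> 170A
```

Variant 36 deletes the six residues 313–318 (chymotrypsin 170A–170F),
leaving an 8-residue loop. Fitting a synthetic substrate titration with
known ground truth (K_M = 1.1 mM, k_cat = 8 s⁻¹, 2 % noise, duplicate
averaged):

```python
from loopscan import MichaelisMenten
from loopscan.kinetics import average_replicates
from loopscan.synthetic import SyntheticKineticsSpec, gen_kinetics

data = gen_kinetics(SyntheticKineticsSpec(km_mm=1.1, kcat_s=8.0, seed=42))
print(MichaelisMenten(average_replicates(data["michaelis_menten"])).fit().summary())
```

```
Michaelis-Menten fit
============================================
n points:      8    R^2: 0.9996    RSS: 55.5
--------------------------------------------
parameter           estimate       std err
V_max                397.335          2.84
K_M                  1.08217        0.0282
k_cat                 7.9467        0.0569
kcat_over_km         7.34333
```

K_M is recovered at 1.08 mM (truth 1.1 mM) with its asymptotic standard
error; `k_cat` is V_max divided by the enzyme concentration.

The full pipeline — enumerate, generate a 250-pose ensemble per variant,
compute geometry statistics, simulate and fit the assay panel, assemble
the WT-normalised heatmap table — runs as

```
loopscan run --seed 17 --out run_dir/
```

and writes `variants.tsv`/`.fasta`, `geometry.json`,
`rmsf_vs_loop_length.tsv`, `hbond_mean_sd.tsv`,
`contact_frequencies.tsv`, `activity.tsv` (+ heatmap PNG) and a
`manifest.json` with the seed, package version and SHA-256 checksums of
every output. Identical config and seed reproduce identical checksums.
Other subcommands: `enumerate`, `simulate ensemble|kinetics`,
`validate-ensemble`, `analyze`, `fit-kinetics`.

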