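# pmhc

Analysis toolkit for peptide–MHC structural ensembles and the biophysical
experiments that characterize them: NOE distance-restraint evaluation and
docking-decoy post-processing, methyl chemical-shift-perturbation and
kinetics analysis, back-exchange-corrected HDX-MS uptake with residue
resolution, trajectory-ensemble statistics (RMSF, dihedral order
parameters, two-stage clustering, water-occupancy maps), and HLA-repertoire
analytics. A seeded synthetic-data module generates ground-truth inputs for
every stage so the whole pipeline is testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `pmhc.structio` | Coordinate model, multi-model PDB/mmCIF reading, PDB writing, selections, SVD superposition, RMSD/RMSF, φ/ψ/χ1 torsions, Ramachandran classification, interface contacts, simplified clash score |
| `pmhc.restraints` | AtomPair/BOUNDED restraint parsing with pseudo-atom expansion, r⁻⁶ ambiguous distances, violation filtering, energy-vs-RMSD landscapes, greedy quality-threshold decoy clustering |
| `pmhc.nmr` | Methyl CSPs (`sqrt((ΔδH² + ΔδC²/4)/2)`), outlier/broadening flags, single-phase decay fits (t½), Boltzmann melt fits (Tm), percent-empty, competitive-anisotropy IC50 fits |
| `pmhc.hdx` | Percent uptake with selectable back-exchange correction variants, uptake curves, residue-resolved maps from overlapping fragments, Welch + Brown–Forsythe ANOVA |
| `pmhc.dynamics` | Equally-spaced frame subsampling, replicate-averaged RMSF, circular-resultant S², single-linkage backbone → side-chain clustering, water-occupancy grids (OpenDX output) |
| `pmhc.repertoire` | BLOSUM62 pseudo-groove similarity, strong/weak binder classification, KL sequence logos, allele-frequency joins |
| `pmhc.synth` | Seeded generators with recorded ground truth for decoy sets, switching trajectories, HDX tables, peak lists, decay/melt/competition series, and water patterns |

## CLI

All functionality is exposed through the `pmhc` command:

```bash
# generate a seeded synthetic decoy set, then post-process it
pmhc sim decoys --seed 1 --n 100 --fraction 0.37 --out run/
pmhc decoys filter --cst run/contacts.cst --scores run/scores.sc run/decoys.pdb
pmhc decoys landscape --scores run/scores.sc run/decoys.pdb
pmhc decoys cluster --scores run/scores.sc --radius 2.3 --top 500 \
    --max-clusters 5 --max-size 10 run/decoys.pdb

# structure-level operations
pmhc struct rmsd --fit "A:backbone" --report "C:all-heavy" ref.pdb mob.pdb
pmhc struct rama --chain C model.pdb
pmhc struct contacts --cutoff 3.5 model.pdb
pmhc struct clash model.pdb

# solution observables
pmhc nmr csp peaks.csv
pmhc nmr kinetics decay.csv
pmhc dsf tm melt.csv
pmhc dsf percent-empty sample.csv empty_reference.csv
pmhc fa ic50 competition.csv

# HDX-MS
pmhc hdx curves --out curves.tsv fragments.csv
pmhc hdx resolve --time 600 --length 300 --out map.tsv fragments.csv
pmhc hdx compare values.csv

# trajectory statistics (multi-model PDB exports)
pmhc md rmsf rep1.pdb rep2.pdb rep3.pdb
pmhc md s2 --chain C frames.pdb
pmhc md cluster --bb-cutoff 0.5 --sc-cutoff 1.0 frames.pdb
pmhc md watermap --near "A:150-155" --within 5 --spacing 1.0 \
    --out map.dx frames.pdb

# HLA repertoire
pmhc hla similarity --ref HLA-A*01:01 pseudo.dat
pmhc hla classify predictions.csv
pmhc hla logo --background uniform peptides.txt
pmhc hla rank-by-frequency predictions.csv frequencies.csv
```

Selections use a compact `CHAIN[:RANGE][:CLASS]` syntax, e.g.
`"A:backbone"`, `"C:all-heavy"`, `"A:150-155"`, `"C:55-64:sidechain"`.

## Notes on conventions

- Ambiguous NOE distances use r⁻⁶ summation by default; a closest-pair
  mode (`--group-min`) is available.
- The HDX back-exchange correction defaults to the `span` denominator
  (m100 − m0); the literal `d-scaled` form (m100 − D·m0) is selectable and
  the variant in force is recorded in every output.
- Decoy and trajectory clustering measure RMSD in a common receptor frame
  by default so rigid peptide motion is not erased by the fit; pairwise
  self-fitting is available behind a flag.
- Ramachandran region masks are coarse polygonal approximations of the
  standard empirical contours, shipped as static data and documented in
  `pmhc/structio/rama.py`; labels are approximate by design.
- All fits are deterministic least squares from analytic initial guesses;
  all generators are pure functions of their seed and parameters.
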