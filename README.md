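# torsionqa

Torsion-space quality assessment of predicted protein structures, plus the
surrounding machinery used to evaluate template-based models:

- **Structure handling** (`torsionqa.structure`) — PDB/mmCIF parsing into a
  light in-memory model (Biopython-backed), altloc resolution by highest
  occupancy, residue pairing by author numbering or per-chain sequence
  alignment, fixed-column PDB and minimal mmCIF writers.
- **Torsion engine** (`torsionqa.torsions`) — phi/psi/omega and chi1/chi2
  dihedrals, minimal angular deltas (with optional 2-fold chi2 symmetry for
  Asp/Phe/Tyr), cis/trans/twisted peptide-bond classification.
- **Conformation scores** (`torsionqa.scores`) — the unit chord score
  gamma = (1 − cos Δ)/2; per-residue backbone score (mean of gamma over
  phi/psi/omega); burial-weighted sidechain score with chi2 contribution
  damped by exp(−(Δchi1/tau)²); per-model aggregates; template-vs-model
  per-residue comparison tables with CA residuals after superposition.
- **Ranking** (`torsionqa.ranking`) — two-pass adjusted z-scores
  (outlier pruning below −2, negative clipping) and the combined schemes
  `S_CASP12`, `S_CASP12-ASE`, `S_torsion`, `S_geom`; per-group rankings over
  targets with model-1 or best-of-5 selection.
- **MR preparation** (`torsionqa.mrprep`) — B-factor inflation by
  (8π²/3)·error², B-column reinterpretation modes, the GDT_TS < 30 /
  median-error > 3 Å rejection filter (rejected models get LLG 0), and the
  LLG-gain ≥ 60 success classifier. LLG values are always external inputs.
- **Template triage** (`torsionqa.triage`) — the log-scale composite
  stereochemistry (MolProbity) score from clashscore / rotamer / Ramachandran
  percentages, resolution-band trust tiers with score escalation, and
  lexicographic template recommendation.
- **Synthetic data** (`torsionqa.synth`) — ideal-geometry peptide builder
  with exactly prescribed torsions (NeRF), torsion-space perturbations with
  an exact ground-truth ledger, and random metric tables with a planted
  group ordering.

## CLI

```sh
# score a model (and optionally a template) against the target
torsionqa score --target target.pdb --model model.pdb --out scores.csv \
    --template template.pdb --plot comparison.png

# per-residue torsion dump
torsionqa torsions --structure model.pdb --out torsions.csv

# rank groups from a per-model metric table
torsionqa rank --table metrics.csv --scheme S_torsion --out ranking.csv

# prepare a model for molecular replacement
torsionqa mrprep --model model.pdb --b-mode error --out prepped.pdb \
    --gdt-ts 72 --llg-gain 140 --report filter.csv

# triage candidate templates
torsionqa triage --templates templates.csv --identity-floor 90 --out advice.csv

# synthetic inputs
torsionqa simulate peptide --spec spec.json --out peptide.pdb
torsionqa simulate metrics --groups 8 --targets 20 --seed 1 --out metrics.csv
```

Metric tables are CSV/TSV with columns `group, target, model_index` plus any
of `GDT_HA, GDT_TS, lDDT, CADaa, SG, ASE, clashscore, mean_backbone,
mean_sidechain` (externally computed scores are consumed, never derived from
coordinates here).

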