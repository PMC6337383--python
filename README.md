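# sbpharm

Analysis toolkit for structure-based inhibitor-discovery campaigns built
around pharmacophore models. It implements the computational stages that sit
*between* the black-box engines (homology modeling, docking, MD simulation are
consumed as file inputs):

- **Common-scaffold pose clustering** — scaffold RMSD matrices over docked
  pose ensembles, complete-linkage clustering at a fixed height (2.0 Å
  default), partition into common scaffold clusters (CSCs, poses of ≥ 4
  distinct ligands) vs residual clusters, medoid representative selection.
- **Interaction fingerprints** — per-residue involvement percentages
  (contact / H-bond / hydrophobic / halogen channels) over pose ensembles
  (SIFt) and trajectories (DIFt), residue-pair H-bond occupancy, and a
  per-residue electrostatic + Lennard-Jones energy decomposition.
- **Dynamic pharmacophores** — per-frame structure-based feature perception
  with exclusion-volume spheres, feature-signature occupancy profiles with
  major/minor classification, rigid-motion-invariant RDF descriptor codes,
  average-linkage model clustering and representative-model (RPM) selection.
- **Screening** — pharmacophore matching of multi-conformer libraries with
  the n / n−1 omitted-feature rule, Kabsch alignment, exclusion-volume
  checks, fit scoring, and common-hits-approach ranking over model ensembles.
- **Metrics** — min-max consensus scoring over ChemPLP/GoldScore/fit columns,
  ROC AUC and robust initial enhancement (RIE), ligand efficiency (LE),
  lipophilic ligand efficiency (LLE), fit quality (FQ), Spearman rank
  correlation and bit-vector Tanimoto similarity.
- **Synthetic data** — seeded generators for pose ensembles with planted
  cluster structure, toy binding pockets with planted interactions,
  trajectories with per-feature toggle probabilities, and active/decoy score
  populations, so every stage is testable offline.

## CLI

All commands live under one entry point:

```sh
sbpharm cluster-poses --poses poses.sdf --scaffold scaffold.json --height 2.0 --min-distinct 4 --out clusters.csv
sbpharm sift --poses poses.sdf --protein pocket.pdb --out sift.csv
sbpharm dift --traj traj.pdb --out dift.csv
sbpharm energies --pose p.sdf --protein pocket.pdb --params ff.yaml --center 0,0,0 --radius 12 --out energies.csv
sbpharm dynophore --traj traj.pdb --out-models models/ --out-profile occupancy.csv
sbpharm cluster-models --models models/ --similarity 0.5 --top 10 --out rpm/
sbpharm screen --library lib.sdf --model rpm/rpm0.json --max-omit 1 --out hits.csv
sbpharm cha --library lib.sdf --models rpm/ --out cha.csv
sbpharm consensus --scores scores.csv --out ranked.csv
sbpharm validate --actives a.csv --decoys d.csv --alpha 20
sbpharm efficiency --table ligands.csv
sbpharm simulate poses|trajectory|screening|pocket --seed 1 --out dir/
sbpharm pipeline --config campaign.yaml
```

`sbpharm pipeline` runs the whole campaign (pose clustering → SIFt →
dynamic pharmacophores → model clustering → screening → consensus →
enrichment validation) on synthetic inputs from one YAML config, writes all
stage artifacts plus a `report.json` summary, and logs every threshold used
to `run_log.jsonl`. Re-running the same config + seed reproduces identical
outputs.

Formats: SDF (V2000) for molecules/poses/libraries, PDB for structures
(multi-model PDB = trajectory, 2 ps default frame spacing), a documented JSON
schema for pharmacophore models, CSV for scores and profiles.

## Layout

```
src/sbpharm/
  chem_core.py        domain types + SDF/PDB/JSON/CSV readers and writers
  scaffold_cluster.py scaffold RMSD, complete linkage, CSC partition, medoids
  interactions.py     contact/H-bond/halogen detectors, SIFt/DIFt, energies
  dynophore.py        per-frame perception, occupancy, RDF codes, RPMs
  screen.py           Kabsch, conformer matching, library and CHA screening
  metrics.py          consensus, AUC/RIE, LE/LLE/FQ, Spearman, Tanimoto
  synthetic_data.py   seeded generators with machine-readable truth tables
  cli_pipeline.py     click CLI and the end-to-end pipeline driver
tests/                unit + property tests; test_acceptance.py covers the
                      acceptance criteria at their stated tolerances
```
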