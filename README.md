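# pairscape

Quantifying the propensity of DNA base pairs to open into the minor groove,
as a tested analysis pipeline: base-pair reference-frame geometry (simple
Opening/Shear and competing collective variables), adaptive-biasing-force
style mean-force accumulation with multi-walker merging, Gaussian-process
integration of mean forces into free-energy surfaces, reduction to 1D
opening profiles with propagated uncertainty, and the canonical-vs-mismatch
discrimination-gap statistic. Microsecond MD is replaced by built-in
synthetic samplers and coordinate builders, so the entire chain runs on a
laptop.

## Modules

| module | what it does |
| --- | --- |
| `pairscape.nucleic_geometry` | base reference frames (anti/syn), six pair + six step parameters via an exactly invertible hinge decomposition, chi classification, hydrogen bonds |
| `pairscape.collective_variables` | Opening/Shear, N1–N3 and ring distances, pseudo-dihedrals, bending angle, RMSD-to-target; YAML-configurable selections |
| `pairscape.free_energy` | CV grids, Welford/Chan mean-force accumulation, walker merging, statistical inefficiency (IACT + blocking), derivative-observation GP integration with analytic-gradient hyperparameter fitting |
| `pairscape.landscape` | minima detection with barrier pruning, 0.5RT thermodynamic states, Boltzmann reduction to opening profiles, propensities at Δ-Opening, discrimination gaps, Hookean bending stiffness, structure overlays |
| `pairscape.study_design` | the eight-class system catalog, palindromic symmetry reduction (48 → 26 systems), counterion arithmetic |
| `pairscape.synthetic_data` | analytic model surfaces (canonical/mismatch archetypes), seeded overdamped Langevin sampler with ABF-like bias, ideal B-DNA duplex builder, central-pair perturbation |
| `pairscape.io` / `pipeline` / `cli` | PDB and provenance-headed TSV formats, the end-to-end pipeline, the `pairscape` command |

## Command line

```sh
pairscape catalog                       # sequence-class catalog, symmetry-reduced counts
pairscape build --sequence GGTTAAATTAACC --out duplex.pdb
pairscape cv --pdb duplex.pdb --cv-config cvs.yaml --out cv.tsv
pairscape simulate --surface mismatch_like --seed 1 --out sim/
pairscape accumulate sim/walker*.tsv --config grid.yaml --out mf.tsv
pairscape integrate --meanforce mf.tsv --out fes.tsv
pairscape states --fes fes.tsv --out states.json
pairscape reduce --fes fes.tsv --out profile.tsv
pairscape gap --canonical can.tsv --mismatch mis.tsv --at -60
pairscape gap --table-class I           # gap arithmetic on the published table
pairscape stiffness --profile bend.tsv --range 130 170
pairscape overlay --fes fes.tsv struct1.pdb struct2.pdb --out overlay.json
pairscape demo --seed 1 --out demo_out  # small end-to-end run
```

Every numeric artifact is a `#`-headed TSV carrying the tool version, a
config hash and the seeds that produced it.

## Notes

- The synthetic free-energy archetypes are qualitative stand-ins (single
  deep canonical basin; five mismatch basins separated by a 5.4 kcal/mol
  Shear barrier); they are not fitted to any simulation data, and absolute
  published propensities are out of scope.
- Angles are reported in (−180°, 180°]; Opening < 0 means motion toward the
  minor groove.
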