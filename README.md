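# pbtraj

Trajectory post-processing for protein conformational ensembles, built
around the **Protein Blocks (PB) structural alphabet**: 16 local backbone
prototypes (labels *a*–*p*, each an 8-vector of φ/ψ dihedrals over five
consecutive residues; *m* ≈ α-helix core, *d* ≈ central β-strand). The
package was written to analyse the dynamics of the calreticulin (CALR)
C-domain and its essential-thrombocythemia variant classes — monomers and
dimers, with calcium or sodium counter-ions — but every stage is generic.

For each residue *i* and frame, the dihedral window is assigned to the
prototype minimising the RMSDA (root-mean-square deviation over angles,
shortest-arc wrapping). Accumulating assignments over frames gives
per-position frequencies *f_x(i)* and the statistics

* **N_eq(i) = exp(−Σ_x f_x ln f_x)** — the equivalent number of PBs sampled
  at a position (1 = rigid single state, 16 = uniform/random);
* **ΔN_eq(i) = |N_eq¹ − N_eq²|** and
  **ΔPB(i) = Σ_x |f_x^{S1} − f_x^{S2}|** ∈ [0, 2] — per-position contrasts
  between two systems.

Around this core the package provides Cα RMSD/RMSF with least-squares
(Kabsch) superposition, per-residue ion-binding occupancy (fraction of
frames with an ion within 3 Å of a residue's heavy atoms), binding-onset
detection, inter-chain anchor distances with a separation verdict for
dimers, CALR C-domain variant sequence features (length, KDEL, net charge,
CREAC cysteines, counter-ion requirements), and a synthetic-ensemble
generator with exact ground truth (NeRF backbone construction from
dihedrals, scripted PB mixtures, scripted ion binding, scripted dimer
separation) used to validate the whole pipeline.

## Worked example

Generate a synthetic ensemble with three probe positions of known PB
mixtures (pure helix at 358, 50:50 helix/strand at 364, uniform over all 16
blocks at 370), then profile it:

```sh
pbtraj simulate --kind probe --n-frames 2000 --seed 1 --out sim
pbtraj profile --traj sim/trajectory.pdb --equil-cut-ps 5000 --out profile
```

The `neq.tsv` report (positions in author numbering) recovers the
generating mixtures:

```
author_number      neq            flag
          358  1.00000           rigid
          364  1.99998           rigid
          370 15.89010 disordered-like
```

N_eq = 1 at the pure-helix probe, ≈ 2 (= exp H of a 50:50 mixture) at the
two-state probe, and ≈ 16 at the uniform probe. `pb_map.tsv` holds the full
position × PB frequency map, and `pbtraj compare` produces the ΔN_eq/ΔPB
tables between two systems. `pbtraj dynamics` adds RMSD/RMSF, ion occupancy
and (for two-chain systems) anchor distances with a stable/separated
verdict; `pbtraj seqfeat` prints the variant feature table (e.g. the
wild-type C-domain: 66 residues, KDEL present, net charge −26, requiring 13
Ca²⁺ counter-ions).

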