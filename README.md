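# poremode

Elastic-network normal-mode screening of pore-gating motions in membrane
transporters, plus the trajectory statistics used to characterize pore
conformation and hydration.

## The problem

Many membrane transporters — the homodimeric vacuolar iron transporters
(VIT family) are the motivating case — occlude their permeation pathway
with a stack of bulky apolar residue pairs, a *hydrophobic seal*. Whether
and how the seal opens is hard to see in plain molecular dynamics, because
pore opening is a slow, collective motion. Coarse-grained normal-mode
analysis makes it cheap to ask: *which of the protein's intrinsic soft
motions widen the seal?*

`poremode` implements that question as a reusable protocol, together with
the ensemble statistics (RMSF, cross-correlation maps, radial distribution
functions, residue-pair distance series, geometric hydrogen bonds, and
Gaussian-mixture decomposition of distance distributions) used to analyze
conformational ensembles of such pores, and a synthetic-data module that
generates structures and trajectories with closed-form ground truth so the
whole stack is testable without microsecond simulations.

## The model

The Cα trace is turned into an anisotropic elastic network: beads joined by
harmonic springs (spring constant γ) for every pair within a cutoff
R<sub>c</sub> (default 15 Å). The quadratic energy gives the 3n × 3n
Hessian with off-diagonal blocks

&nbsp;&nbsp;H<sub>ij</sub> = −(k<sub>ij</sub>/d<sub>ij</sub>²) (**r**<sub>j</sub>−**r**<sub>i</sub>)(**r**<sub>j</sub>−**r**<sub>i</sub>)ᵀ,

whose eigenpairs (λ<sub>k</sub>, **v**<sub>k</sub>) are the normal modes;
each mode is a harmonic oscillator with mean-square amplitude ∝ 1/λ<sub>k</sub>,
so the softest non-trivial modes carry the collective motions. The
screening protocol then displaces the structure along each of the first
100 modes, in both senses, to an RMSD of 2 Å, and selects the modes for
which every gating pair widens by at least 0.5 Å in one sense. Per-mode
correlation profiles c<sub>ij</sub> = **v**<sub>i</sub>·**v**<sub>j</sub>/(|**v**<sub>i</sub>||**v**<sub>j</sub>|)
and 15×-magnified oscillating trajectories visualize each selected motion.

Ensemble statistics follow the field's standard definitions: RMSF after
two-pass least-squares (Kabsch) superposition; DCCM
C<sub>ij</sub> = ⟨Δ**r**<sub>i</sub>·Δ**r**<sub>j</sub>⟩/√(⟨Δr<sub>i</sub>²⟩⟨Δr<sub>j</sub>²⟩);
g(r) as target density around a reference relative to an ideal gas at bulk
density; 1-D Gaussian mixtures fit by EM with the component count chosen
by BIC (component mean, SD and weight per mode of a multimodal distance
distribution).

## Worked example

Generate the synthetic two-protomer helix bundle and screen its modes:

```
$ poremode synth dimer --out-prefix demo --seed 0
wrote demo.pdb and demo.pairs.tsv

$ cat demo.pairs.tsv          # gating pairs: chainA resid chainB resid
A	9	B	9
A	12	B	12
A	16	B	16

$ poremode screen demo.pdb demo.pairs.tsv --out-prefix demo_screen --cutoff 13
selected modes: [4, 9, 12, 24, 32, 75]

$ head -4 demo_screen.tsv
mode	sense	pair	role	d0	d	delta
1	1	A9-B9	gating	9.711655	9.725535	0.013880
1	1	A12-B12	gating	5.272093	5.274037	0.001945
1	1	A16-B16	gating	8.092950	8.092480	-0.000471
```

The report lists, for every mode and displacement sense, the original and
displaced distance of each gating pair (Å) and the change `delta`; a mode
is *selected* when all pairs widen by ≥ 0.5 Å in one sense (here six of
100 modes under a uniform 13 Å-cutoff network). Mode 1's deltas above are
tiny — the softest mode of this uniform network barely touches the gate.
The same protocol runs on any PDB structure and pairs file; the library
surface (`build_network`, `compute_modes`, `screen_modes`, …) exposes each
stage, and `poremode pipeline --config run.yaml` drives it end to end with
a reproducible manifest.

Trajectory statistics work the same way from multi-model PDB input:
`poremode rmsf`, `dccm`, `rdf`, `dist`, `iondist`, `hbond`, `mix`.

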