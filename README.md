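# axonarray

Quantitative analyses for **outer-arm dynein (OAD) arrays on microtubule
doublets (MTDs)**: disassembly simulation of OAD arrays under nucleotide
treatment, density-guided light-chain identification, inter-protofilament
lattice geometry, filament-signal weakening of micrographs, and
microtubule-gliding velocity statistics.  Every analysis can be exercised on
seeded synthetic data with known ground truth — no downloads are needed.

The package is aimed at structural biologists and biophysicists working on
axonemal dynein / microtubule systems who want these bespoke computations as
a tested, reusable library.

## What it computes

**Fall-off simulation and α estimation** (`axonarray.falloff`).
ATPγS titrations strip reconstituted OAD arrays off MTDs.  Two limiting
mechanisms act on the multiset of contiguous-array OAD counts {N_i}:

* *end release* — only array-end OADs detach; array *i* is chosen with
  probability L_i / Σ_j L_j where **L_i = 1 + α(N_i − 1)**, α ∈ [0, 1].
  At α = 0 all arrays are equally likely; at α = 1 the probability is
  proportional to array length.
* *random break* — every bound OAD detaches with equal probability; an
  interior detachment splits its array in two.

Each event removes one OAD, so *coverage* (bound OADs / apo reference
total, the 100 % mark) decreases deterministically and simulations are run
to the experimentally observed coverage of each condition.  α is estimated
on a grid by minimising the mean Wasserstein-1 discrepancy between observed
and simulated array-length distributions, summed over conditions.

**Light-chain identification** (`axonarray.lcid`).  Side-chain densities are
read as size classes — large {W, Y, R, F, H}, middle {L, Q, N, I, M, K},
small {P, V, S, T, C, E, D, A}, glycine, plus an `X` wildcard — giving a
density pattern that is matched against candidate sequences with
regular-expression semantics.  Every ungapped placement is scored by the
*penalty*: the count of positions whose residue class contradicts the
density.  A candidate is *identified* only if it is a significant MS hit,
matches the density, and no other homolog scores as well.

**Lattice geometry** (`axonarray.geometry`).  Tubulin dimers are rigid-body
fitted (Kabsch; proper rotations only) and the inter-PF angle of an
adjacent protofilament pair is the rotation angle of the relative rotation
of the two fits, summarised over three axial regions (two near the edges,
one in the middle) as mean ± s.d.  The same machinery measures domain
rotations between structural states after superposition (e.g. an 18° stalk
reorientation) and signed axial offsets (e.g. the 8-nm, one-dimer-repeat
lead of one microtubule-binding domain over another).

**Micrograph preparation** (`axonarray.micrograph`).  The MTD signal is
weakened by subtracting, inside a rectangle mask slightly wider than the
filament, the mask-weighted average intensity along the filament axis (one
value per transverse offset), scaled by the local mask weight.  Pixels
outside the mask are returned bit-identical; localized particles survive.

**Gliding statistics** (`axonarray.gliding`).  Tracked filament positions
are smoothed over three frames (0.22 s at 13.5 Hz); tracks under 1 s,
immobile filaments and flagged collisions are excluded; the time-weighted
(total path / total time) and displacement-weighted (Σ d_i v_i / Σ d_i)
mean velocities are reported with s.d. over track velocities,
**s.e.m. = s.d./√N**, and a 0.4 μm s⁻¹ histogram.

**Synthetic data** (`axonarray.synthetic`) generates all inputs with ground
truth: titration array tables at the study's sample sizes
(n = 319/180/214/222/159 arrays at 0/10/30/100/1000 μM ATPγS), proteomes
with planted pattern targets and mismatch-controlled decoys, cylindrical
lattices with planted angles, filament phantoms, and gliding tracks.
`axonarray.io` reads and writes the standard formats (TSV, FASTA,
PDB/mmCIF, float TIFF).

## Worked example

```bash
python examples/falloff_alpha.py
```

```
arrays per condition:
           count      mean
condition
0            319  8.225705
10           180  7.733333
30           214  7.144860
100          165  6.357576
1000          71  5.535211

alpha_hat = 0.1  (planted 0.1)

end-release best discrepancy 2.12 vs random-break 18.61
```

The generator planted an end-release process with α = 0.1 at the study's
per-condition sample sizes; the grid estimator recovers α = 0.1, and the
random-break model fits the same data an order of magnitude worse — the
arrays shorten sequentially from their ends rather than breaking randomly.
The other examples (`light_chain_id.py`, `interpf_angles.py`,
`weaken_filament.py`, `gliding_velocities.py`) walk through the remaining
capabilities the same way.

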