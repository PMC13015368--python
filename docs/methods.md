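# Methods

`rnarefine` resolves steric clashes and rebuilds missing heavy atoms in
RNA 3D structures by *conditional regeneration*: the defective atoms are
destroyed by Gaussian noising and re-generated by a denoising diffusion
probabilistic model (DDPM) whose denoiser is an E(3)-equivariant graph
neural network (EGNN), conditioned on the surrounding intact structure.
This note records the model, the procedures around it, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## Structure model and atom catalog

A structure is an ordered list of chains of residues; each residue holds
named heavy atoms with coordinates in Å. Only the four standard
ribonucleotides are supported; entries containing modified nucleotides
are rejected outright rather than coerced, and non-RNA components
(protein, water, ions, ligands) are silently removed during cleaning.
The canonical heavy-atom catalog contains 85 entries — the 12
sugar-phosphate atoms common to all bases (OP3 excluded) plus 10/11/8/8
base atoms for A/G/C/U — and provides the (base, atom-name) one-hot used
in graph encoding. Five atoms per nucleotide form the coarse-grained
"five-point" representation: C4' and C1' of the ribose, and N9/C6/C2
(purines) or N1/N3/C5 (pyrimidines) fixing base orientation.

Missing-atom detection is a set difference against the catalog, with one
policy exception: 5'-terminal residues are not flagged for P/OP1/OP2,
because deposited structures routinely lack the terminal phosphate and
flagging it would trigger pointless reconstruction.

## Secondary structure and motifs

Pairing information enters either as dot-bracket annotation or from a
built-in geometric annotator that accepts a candidate A-U/G-C pair when
the N1(purine)-N3(pyrimidine) distance falls in 2.6-3.4 Å, resolving
conflicts greedily by increasing distance. The annotator knows only the
canonical Watson-Crick family; that is also the only family used
downstream (masking, edge typing, motif extraction).

Motif decomposition walks the pseudoknot-free secondary-structure tree:
stems are maximal stacks of consecutive pairs; a stem's innermost pair
closes a hairpin loop (no nested stems), an internal loop or bulge (one
nested stem, unpaired residues on both or one side), or a junction (two
or more nested stems). Motif records include the closing pairs of the
adjacent stems so extracted coordinates are self-contained units.
Pseudoknots raise an error rather than being silently dropped. Chain
breaks are not given special sentinels in motif extraction; "adjacent"
in graph building and masking always means consecutive within one chain.

## Graph encoding

Nodes are heavy atoms (or the five coarse-grained points), ordered
canonically by chain, residue and catalog order, so encoding is
independent of file record order. Node features concatenate a residue
one-hot (4), the 85-way atom one-hot, and a sinusoidal positional
encoding of the global residue index (PE[2k] = sin(i/10000^(2k/d)),
PE[2k+1] = cos(·), d = 16 by default).

Two edge-typing schemes exist:

* **contact_4type** (default for all-atom): intra-residue, sequential
  (all atom pairs of chain-adjacent residues), Watson-Crick (base atoms
  of annotated pairs), and spatial (all atom pairs of residue pairs with
  C4'-C4' < 8 Å). Precedence intra > sequential > WC > spatial makes the
  types a partition.
* **relation_5type** (default for five-point): C4'-C4' adjacent,
  C4'-C4' non-adjacent, C4'/other intra-residue, other/other
  intra-residue, and inter-residue non-C4' pairs with C4' distance
  < 14 Å. The 14 Å cutoff is also applied to non-adjacent C4'-C4' edges;
  this bounds graph size and is switchable
  (`EncodingConfig.relation_cutoff_on_c4`).

## Denoiser

The denoiser stacks L equivariant blocks. Each block runs
`gcls_per_block` graph convolutional layers

    m_ij = phi_e(h_i, h_j, ||x_i - x_j||^2, a_ij)
    h_i <- h_i + phi_h(h_i, sum_j m_ij)

followed by one coordinate update along radial directions

    x_i <- x_i + C_i * sum_j (x_i - x_j)/(||x_i - x_j|| + 1) * w_ij,
    w_ij = coords_range * tanh(phi_x(m_ij)),

with C_i = 1/sqrt(deg(i)) by default — full degree normalisation caps
selective movements far below the distances a denoiser must cover at
realistic degrees (~100 edges per atom), while an unnormalised sum
destabilises training; the square-root compromise measurably wins on
both the high-noise and mid-noise regimes. During conditional passes the
internal coordinate stream moves only the atoms being regenerated, so
every block measures distances against clean anchors.
Feature updates see geometry only through squared
distances (invariant); coordinate updates move along radial directions
(equivariant); the readout is the total displacement of the coordinate
stream, so the prediction transforms as f(Rx+v) = R f(x) for any
rotation/reflection R and translation v. The radial normalisation and
tanh clamp are the standard EGNN stabilisations: they bound each block's
displacement and keep the reverse chain from diverging when the network
extrapolates; both preserve equivariance. Time conditioning appends a
sinusoidal embedding of the timestep to every node's input features,
together with a binary linker-indicator channel telling the network
which atoms it is regenerating.

All tensor math runs on a small reverse-mode autodiff core written on
numpy (`_autodiff.py`), whose gradients are verified against finite
differences in the test suite; the optimizer is Adam.

## Diffusion process

The forward process is the variance-preserving kernel

    x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps,  eps ~ N(0, I),

over T = 100 steps with a polynomial schedule
abar_t = clip((1 - (t/T)^2)^2); betas are derived as
1 - abar_t/abar_{t-1} and abar is recomputed as cumprod(1 - beta), so
the two tables agree to machine precision. The reverse process is the
standard ancestral DDPM step with zero injected noise at t = 1.

**Anchor-relative frames.** Diffusion acts on each linker atom's
coordinate *relative to the C4' atom of its own residue*, divided by a
3 Å length scale. C4' is part of the conditioning fragment under every
mask mode, so anchors are fixed throughout; the unit Gaussian prior
therefore places each atom in a ~3 Å cloud around its own backbone
anchor rather than in one global blob. Rigid motions transform anchors
and atoms together, so equivariance is untouched. This choice replaces
centring on the global fragment centroid, which at this model scale
forces the network to solve a global atom-to-site assignment problem
and produces unusable samples.

**Parameterization.** The network is trained to output the clean
anchor-relative coordinates (as a displacement from the noisy input,
the "x0 parameterization"); the noise estimate consumed by the reverse
step is derived from it via eps = (y_t - sqrt(abar) y0)/sqrt(1 - abar).
x0- and eps-parameterizations are equivalent up to a t-dependent
reweighting of the noise-matching objective; regressing directly onto
the target geometry is dramatically more sample-efficient for the
near-deterministic conditional task solved here, and the eps form
remains available (`TrainingConfig.parameterization = "eps"`).

**Sampling.** Conditional samples pin all fragment atoms to their input
coordinates at every timestep; linker atoms start from the prior and
take T reverse steps. At each step the implied clean-coordinate
estimate is clamped to a 9 Å ball around the anchor (3 diffusion
units) before being converted back to a noise estimate — the molecular
analogue of the pixel-range clamp in image DDPMs — which prevents
prediction errors from compounding through the 1/sqrt(alpha_t)
expansion of the chain. Each sample consumes an independent child
stream of the caller's generator, so runs are reproducible from one
seed.

## Training masks

Training simulates defect regions with a hybrid two-phase mask over
residues:

* **Phase 1 (sequence/secondary structure):** 1-5% of nucleotides are
  seeded uniformly; each seed's chain neighbours join independently
  with probability 0.4 each, and its WC partner with probability 0.3.
  Expansion is applied once, not recursively.
* **Phase 2 (tertiary structure):** residue pairs are ranked by
  C4'-C4' distance; pairs are excluded when |i-j| <= 3, when the two
  residues are WC partners, when either lies within 2 sequence positions
  of the other's partner, or when either already belongs to phase 1.
  A severity level is drawn from the bucketed law P(0) = 0.60,
  U(0, 0.2] w.p. 0.30, U(0.2, 0.5] w.p. 0.09, U(0.5, 1] w.p. 0.01, and
  K = max(1, round(N * severity * 0.8)) sets the *nucleotide budget*:
  nearest admissible pairs are added until the combined mask covers K
  residues (at least one pair always enters). K counts nucleotides, not
  pairs — this is the only reading under which masks range from a
  single pair up to ~80% of the sequence and ~90% of masks on paired
  100-mers fall within 1-16% of sequence length, the regime matching
  observed clash ratios. The K-pairs variant is retained as
  `phase2_select(..., budget="pairs")`.

The final linker residue set is the union of the phases. Atom-level
partitioning preserves the anchors: in all-atom mode the five-point
atoms of masked residues stay in the fragment; in five-point mode only
C4' stays. Rounding everywhere is half-up; ties in distance ranking
break by residue index, so masks are reproducible.

At inference the masks are deterministic: residues owning clashing
atoms (from a clash report), or detected missing atoms (placeholders
initialised at the residue's C4' plus 1 Å Gaussian jitter — any finite
initialisation is erased by the noising start).

## Clash detection and refinement pipeline

A clash is a non-bonded heavy-atom pair with

    r_i + r_j - d > 0.6 Å    (C 1.70, N 1.55, O 1.52, P 1.80),

excluding pairs within three covalent bonds (canonical intra-residue
bond graph from ideal component geometry, plus the O3'(i)-P(i+1) link)
and the donor-acceptor atom pairs of annotated WC pairs. The detector
uses a k-d tree capped at the maximal clash radius and is verified
against an exhaustive O(N^2) scan; clashscore is pairs per 1000 atoms,
and the reduction rate is (N_initial - N_final)/N_initial. The detector
is heavy-atom only; an optional adapter shells out to MolProbity's
REDUCE/PROBE when those binaries exist, whose hydrogen-aware counts are
not comparable 1:1 with the internal ones.

Clash resolution is best-of-N (default 10): detect, mask, sample N
candidates, re-detect each, take the argmin by clash-pair count (ties:
smaller worst overlap, then lower candidate index), and apply the
protection rule — if the best candidate is worse than the input, return
the input. Output clash count can therefore never exceed the input
count. Hierarchical refinement handles anchor-induced traps: a
five-point model first proposes 5 rearrangements of the non-C4' anchor
atoms of clashing residues (C4' stays pinned), the all-atom model
rebuilds the remaining atoms 5 times for each, and the best of 25 is
selected under the same rule.

RMSD evaluation deliberately does **not** superpose: generation is
frame-anchored by the pinned fragment, and superposition would hide
placement error.

## Synthetic test bed

Training and evaluation run on synthetic fixtures: duplexes and
hairpins assembled from ideal nucleotide geometry (chemical component
dictionary templates) along a helical transform (32.7°/step twist,
4.8 Å rise, pairs displaced 5.3 Å off-axis, glycosidic torsions and
phosphate orientation normalised per base). The constants were chosen
once so that every generated structure clears the 0.6 Å clash criterion
with margin, planted pairs are recovered exactly by the geometric
annotator with no false positives on single strands, and structures
round-trip through PDB. A 2.8 Å rise — the true A-form value — cannot
be made clash-free with rigid ideal-geometry templates, so the
synthetic helix is deliberately more open than real A-RNA.

Defects are injected by construction: `inject_clash` rigidly displaces
a residue's non-five-point atoms toward its nearest neighbour until the
detector fires (five-point atoms stay put so inference masks remain
valid), and `delete_atoms` removes named non-five-point atoms.

What passing on this test bed shows: that the full pipeline — masking,
conditional diffusion, candidate selection, protection — is internally
consistent and that the denoiser can learn and regenerate local
geometry it has seen. What it does not show: performance on
experimental structures, whose geometry is far more heterogeneous than
two idealized motif families, whose clashes have many causes beyond a
rigid displacement, and whose scale (hundreds of nucleotides, tens of
thousands of training motifs) is orders of magnitude beyond the desk
scale used here.

## Problem sizes and defaults

Defaults follow the production configuration where one is stated
(T = 100, hidden width 64, maximum 200 nucleotides, 10 candidates,
5 x 5 hierarchical); unstated choices are fixed here as L = 4 blocks,
2 GCLs per block, Adam at 1e-3 (cosine decay optional), one structure
per step. The packaged experiments train a reduced denoiser (L = 2,
hidden 32, 1 GCL/block) on ~200 fixtures of 6-10 residues for a few
thousand steps, and evaluate reconstruction and clash resolution on
held-out fixtures with reduced candidate counts; these sizes are the
package's own desk-scale experimental design, chosen to keep a full
train-evaluate cycle in the minutes range on one CPU core.

## Known limitations

* The denoiser is numpy-based and single-threaded; it is a reference
  implementation, not a performance one.
* Geometric WC annotation tests a single distance criterion; sheared or
  non-canonical pairs are invisible to it.
* The anchor-relative prior presumes C4' positions are trustworthy — the
  same assumption the refinement procedure itself makes — so a defective
  backbone trace cannot be repaired.
* Clash counts from the internal heavy-atom detector are systematically
  lower than hydrogen-aware MolProbity counts.
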