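# Methods

## Model

The fuzzy-oil-drop picture treats a folded water-soluble protein as an
idealized micelle: the polar environment drives hydrophobic residues
toward the centre of the molecular body, so the expected hydrophobicity
density is a 3D Gaussian spread over the body. The package compares
that expectation (T) with the hydrophobicity actually collected by each
residue from its neighbourhood (O), using the uniform distribution (R)
as the alternative reference, and summarizes the comparison with

    RD = D_KL(O‖T) / (D_KL(O‖T) + D_KL(O‖R)).

RD < 0.5 means O is closer to the micelle-like ideal than to
featureless uniformity. The modified model adds a complement field:
M(K) ∝ T + K·(T_max − T), normalized; K is selected by minimizing
D_KL(O‖M(K)) and measures how much a non-aqueous factor must distort
the aqueous field to account for O.

Assumptions worth keeping in mind: the fields are per-residue (one
effective atom each — no all-atom resolution); the body is modelled as
a single anisotropic Gaussian (multi-lobed bodies are represented only
through their pooled principal axes); intrinsic hydrophobicity is
sequence-local (no charge, no context dependence); and O depends only
on pairwise distances below the cutoff.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| Levitt cutoff `c` | 9.0 | Å | neighbourhood radius of the observed field |
| self term in O | included | — | the j = i term contributes 2·H_i at weight 1 |
| sigma rule | max-extent/3 | Å | σ_k = (max |projection on axis k| + margin)/3 |
| frame margin | 0.0 | Å | optional padding added to each extent before /3 |
| K grid | 0–2 step 0.1 | — | matches the one-decimal convention for reporting K; auto-extends once to 3 if the minimum sits on the boundary |
| divergence base | log2 | bits | RD and K are invariant to the base; bits are reported |
| scale | `aggregate` | — | intrinsic hydrophobicity, min–max normalized to [0,1] |

The intrinsic scale is the genuinely open choice: the literature this
model comes from does not standardize one. The default `aggregate`
scale is the mean of three classical hydropathy scales
(Kyte–Doolittle, inverted Hopp–Woods, Fauchère–Pliška), each min–max
normalized before averaging and the mean re-normalized to [0,1].
Averaging was chosen a priori to damp single-scale idiosyncrasies;
`kyte_doolittle`, `fauchere_pliska`, `hopp_woods_inverted` and user TSV
scales are drop-in replacements. RD and K computed for real structures
carry a tolerance attributable to this choice (and, secondarily, to the
self-term and sigma conventions, which are exposed as flags for the same
reason).

## Structural-unit semantics

A *complete* analysis fits the Gaussian on the full selection. A
fragment *as part of* its parent keeps the parent's frame and raw T/O
values, restricts them to the fragment and renormalizes (R becomes
1/n_fragment) — its RD measures the fragment's contribution to the
parent's order. An *individual* fragment refits the frame and
recomputes both fields within the fragment — its RD asks whether the
fragment is micelle-like in its own right. Residue *elimination*
(e.g. the catalytic set) keeps the complete unit's field, drops the
listed positions, and renormalizes; eliminations and selections are in
author numbering with insertion codes, because that is how catalytic
residues and domain ranges are conventionally quoted. The greedy
`scan_eliminate` procedure removes one residue at a time — always the
largest current |O_i − T_i| — until RD falls below a target (default
0.5) or a step cap (default 20) is reached; the cap exists because the
underlying idea ("remove the most discordant residues") comes with no
natural stopping rule.

## Numerical choices

- Principal axes come from the eigendecomposition of the covariance of
  effective-atom positions; descending variance, signs fixed so each
  axis's largest-magnitude component is positive and the matrix is a
  proper rotation. Near-spherical clouds make the axis *labels*
  arbitrary, but RD and K are rigid-motion invariant (verified to
  ≤ 1e-9), so only reported axis labels are affected.
- Collinear and planar clouds are rejected (no meaningful 3D body).
- Profiles validate normalization to 1e-9; KL terms with P_i = 0
  contribute zero; Q is strictly positive whenever Q is T, R, or M with
  K below the complement-dominance point, so the divergence is always
  defined in practice.
- The K scan evaluates the exact grid values (rounded to the grid
  precision to avoid floating-point drift) and breaks exact ties toward
  smaller K — the least environmental modification consistent with the
  data.
- Alternate locations resolve to the highest-occupancy conformer;
  first model only for multi-model files; MSE/SEC/PYL map onto their
  standard parents; all other HETATM groups (waters, ions, cofactors)
  are excluded, since the fields are defined over amino acids only.

## Synthetic generator

The generator emulates the hydrophobicity *geometry* of four folding
environments, not folding physics: residues are placed at protein-like
packing density (~120 Å³/residue) in an anisotropic ellipsoid (axis
ratios 1.3 : 1.0 : 0.8; also shell, helical-rod and two-domain
geometries), and residue identities are chosen so that intrinsic
hydrophobicity under the active scale tracks a target profile —
Gaussian radial decay for `micelle` (the same three-sigma shape the
theoretical field assumes), its complement for `inverse_micelle`, a
coordinate ramp for `polarized`, uniform noise for `random`. A
`strength` knob blends target with noise; mean RD rises monotonically
as strength falls. Structures are written as single-CA-per-residue PDB
files that pass through the ordinary parser.

What the generator does **not** emulate: chain connectivity and
secondary structure, side-chain packing, the 20-letter composition of
real sequences, crystallographic artefacts (missing residues, altlocs),
and the intermediate, partially ordered distributions real proteins
show. Passing regime tests therefore demonstrates that the statistics
separate clean organizations as designed — not that any particular real
protein will land on a particular side of RD = 0.5. For real
structures, curated selections for a published eight-enzyme reference
set ship in `oildrop.reference`, and the reproduction test runs
whenever the corresponding PDB entries are placed under `data/pdb/`;
entries for which the primary literature does not name catalytic
residues carry an empty catalytic list there.

Profiles with a planted environment parameter are built by drawing a
random frame, taking its T, and setting O := M(T, K*); optional
multiplicative noise (relative magnitude `noise`, renormalized) makes
recovery stochastic. K-recovery is exact at grid resolution in the
noise-free case and holds in the mode across seeds at 1% noise.

## Problem sizes

The test suite and the acceptance script use 60-residue synthetic
bodies (≈11 Å radius, comfortably larger than residue spacing), 20
seeds per regime, 50 noise-free and 250 noisy recovery profiles, 100
brute-force oracle instances of ≤15 residues, and 20 random rigid
motions — sizes at which every quantity is stable to well within the
asserted tolerances while the whole run stays in the seconds range.

## Known limitations

- Absolute RD/K values for real structures depend on the intrinsic
  scale and the sigma/self-term conventions; comparisons *across*
  structures under one configuration are the robust use.
- A single Gaussian body underfits strongly multi-lobed complexes;
  analyse chains or domains as individual units in that case.
- The K grid's 0.1 step is a reporting convention, not an uncertainty:
  differences of one grid step are not meaningful.
- Two-residue fragments make RD formally computable but statistically
  vacuous; interpret fragments of fewer than ~10 residues with care.
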