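# Methods

## The score

`hintmd` scores the internal (intramolecular) interaction network of a
protein conformation with a hydropathic, LogP-derived pair sum:

    B = Σ_i Σ_{j>i} b_ij,        b_ij = S_i a_i S_j a_j T_ij R(d_ij)

* `a_i` — hydrophobic atom constant, dimensionless. Positive for apolar
  atoms, negative for polar ones; derived from atomic fragment
  contributions to the 1-octanol/water partition coefficient. Because
  LogP is a transfer free energy, the sum carries both enthalpic and
  entropic (desolvation) information.
* `S_i` — solvent-accessible surface area of atom *i* in Å², recomputed
  per conformation. Buried atoms contribute nothing.
* `R(d)` — distance response, default `exp(-d)` with `d` in Å.
* `T_ij` — sign term encoding favorability (below).

Atom pairs at bond-graph distance one (1-2, bonded) or two (1-3, angle)
are excluded from the sum. Pairs are enumerated inside a 9 Å cutoff by
default (a k-d tree prunes the search); with the exponential response,
truncation at 9 Å changes the total by well under 0.1 % on compact
systems. Setting `cutoff=None` disables truncation, and the test suite
verifies bit-level agreement of the pruned path against a naive O(N²)
reference sum.

### Interaction classes and signs

Every scored pair is typed into one of six classes from the two atoms'
polarity classes (hydrophobic / acid / base / polar-neutral) and, for
polar pairs, geometry:

| pair                                  | class             | sign |
|---------------------------------------|-------------------|------|
| hydrophobic–hydrophobic               | hydrophobic       | +    |
| donor/acceptor-compatible, d ≤ 3.65 Å | hydrogen_bond     | +    |
| donor/acceptor-compatible, d > 3.65 Å | acid_base         | +    |
| acid–acid                             | acid_acid         | −    |
| base–base                             | base_base         | −    |
| hydrophobic–any polar                 | hydrophobic_polar | −    |

Donor/acceptor compatibility follows from the polarity class: acids
accept, bases donate, polar-neutral atoms (hydroxyls, neutral imidazole
nitrogens) do both. The hydrogen-bond switch distance (3.65 Å, heavy
atom to heavy atom, no angle term) is configurable. When a retained
hydrogen is one of the partners, the switch still measures between the
parent heavy atoms; the hydrogen scores as its own atom otherwise.

`T_ij` is applied to the magnitude `|S_i a_i S_j a_j|`. The bare product
of constants cannot carry the semantics: two polar atoms both have
negative constants, so their product is positive whether the pair is a
salt bridge or a like-charge clash. Favorability is therefore decided by
the class (column "sign" above) and the product supplies only the
magnitude.

Per frame, the class sums are reported in four buckets — hydrogen bond,
electrostatic (the acid_base class), hydrophobic, and unfavorable
(acid_acid + base_base + hydrophobic_polar) — and the total equals their
sum exactly. Because "electrostatic" can also be read as including
salt-bridge hydrogen bonds, the portion of the hydrogen-bond bucket
between formally charged partners is reported separately
(`FrameScore.hbond_salt_bridge_sum`) so either partition can be formed.

## Parameterization

Parameters live in a TSV dictionary keyed by (residue, atom) with
columns `residue atom constant class radius`. The bundled table covers
the 20 standard amino acids, their hydrogens, and common terminal
variants (OXT, H1–H3); `scripts/build_default_dictionary.py` regenerates
it from rules:

* carbons: aliphatic +0.45 (methyls +0.65, CA +0.15), aromatic +0.30;
  carbonyl/carboxylate/amide/guanidinium carbons are polar-neutral
  −0.25;
* oxygens: carboxylates (Asp/Glu side chains, OXT) acid −1.00; backbone
  carbonyl acid −0.75; amide carbonyl acid −0.60; hydroxyls
  polar-neutral −0.55;
* nitrogens: backbone amide base −0.60; Lys NZ base −1.20; Arg
  guanidinium base −1.00; His imidazole polar-neutral −0.60 (neutral
  default; a switch reclassifies to base −1.00 for the doubly protonated
  form); Trp NE1 base −0.40; Asn/Gln amide base −0.55;
* sulfurs polar-neutral (−0.30 Cys, −0.25 Met); polar hydrogens (on
  N/O/S) base −0.20; other hydrogens +0.10;
* radii are standard van der Waals values (C 1.70, N 1.55, O 1.52,
  S 1.80, H 1.20 Å) and are the single source of radii for SASA.

The magnitudes are deliberately of order one, in the spirit of
Ghose–Crippen atomic LogP contributions; they are not the proprietary
constants of any published implementation, so absolute score magnitudes
are not comparable across programs — the meaningful outputs are
per-class decompositions, time-series behavior, and differences between
ensembles scored with the same table. The table is fully replaceable via
`load_parameter_dictionary`; loading validates sign/class consistency
(hydrophobic ⇒ positive constant, polar ⇒ negative) row by row.

Protonation is fixed at neutral pH: Asp/Glu deprotonated, Lys/Arg
protonated, His neutral, Cys/Ser/Thr/Tyr neutral. Unknown residues fall
back to per-element parameters with a warning.

### Hydrogen policy

The default `semi_essential` policy keeps only hydrogens that carry
hydropathic information: those on N/O/S (polar), on sp2 carbons
(unsaturated), and on carbons directly bonded to N/O/S (alpha to a
heteroatom). Other hydrogens are kept in the atom list (indices stay
aligned with trajectory coordinates) but are flagged non-retained and
excluded from SASA and scoring. `all` and `none` policies are available.
sp2 carbons are identified by name for the standard residues, with a
three-neighbor fallback for non-template atoms.

## SASA

Shrake–Rupley with a deterministic Fibonacci sphere lattice (960 points
by default, no random rotation — identical input gives bit-identical
areas), probe radius 1.4 Å (water), atom radii from the dictionary.
Doubling the point count moves per-atom areas by < 1 % on the fixtures;
an isolated atom reproduces 4π(r+probe)² to ≪ 0.5 % and two-atom systems
match the closed-form two-sphere result to ~0.03 %. Areas are exactly
translation invariant; rotations re-sample the fixed lattice and move
individual areas by up to ~1 % at 960 points, which bounds the
rigid-motion noise of the score. SASA is recomputed every frame by
default; `sasa_mode="static"` reuses frame 0 (documented approximation —
burial changes along a trajectory are then ignored).

## Trajectory analytics

* **Score series** — one `FrameScore` per (strided) frame, in order;
  summaries report mean and sample (n−1) standard deviation per
  contribution, treating frames as a sample of the ensemble.
* **Extreme frames** — the "lowest-energy" conformations are the frames
  with the *highest* total score; ties break toward the earlier frame.
* **RMSD** — least-squares (Kabsch, SVD with determinant correction)
  superposition of each frame onto a reference over a selection
  (backbone by default), then RMSD over that selection.
* **RMSF** — frames are superposed onto an iterated mean structure (two
  passes: fit to frame 0, average, re-fit to the average) over a
  configurable selection, then per-atom fluctuations
  sqrt(⟨|x−⟨x⟩|²⟩) are averaged within each residue (backbone atoms by
  default). `superpose_selection=None` skips fitting for pre-aligned
  input. For hinge-type analyses, superposing onto the rigid segment is
  the convention used by the tests: fitting on everything would
  redistribute an engineered displacement between segments.
* **Residue-pair maps** — atom-pair scores aggregate to residue pairs
  per interaction class, averaged over a frame subset. The map is
  symmetric and self-pair-free; intra-residue contributions are
  accumulated separately so the map plus that remainder reproduces the
  mean frame total exactly. Ensemble differences are cellwise A−B with
  an outer join (missing cells are zero), ranked by summed |Δ|.

## Synthetic fixtures

All tests run on generated systems; nothing is downloaded.

* Residue geometries come from idealized component-dictionary templates;
  acidic protons (Asp HD2, Glu HE2) and free-molecule termini are
  stripped to match the neutral-pH table.
* `make_contact_pair` poses two residues with a chosen heavy-atom
  contact at an exact distance (each residue oriented with its body
  away from the contact), exercising every interaction class and the
  3.65 Å switch.
* `make_hinge_trajectory` oscillates the second half of a peptide by
  ±A along one axis about its mean (even frame count, so the mean is the
  base structure and every mobile atom's RMS displacement is exactly A),
  plus optional per-coordinate Gaussian jitter σ; ground truth RMSF is
  A·(mobile), √3·σ (rigid), √(A²+3σ²) (mobile with jitter), recorded in
  a manifest together with the seed (numpy PCG64). Frames are 20 ps
  apart, a typical trajectory output spacing.
* Peptide fixtures space residues 8 Å apart along the chain axis: the
  covalent graph (template bonds plus the inter-residue C–N link) is
  correct while the backbone geometry is deliberately not physical —
  irrelevant for the pinned quantities (exclusion sets, contact
  distances, fluctuation amplitudes), and it keeps residues from
  clashing.
* `brute_force_frame` is the independent reference scorer: plain double
  loop, breadth-first-search exclusions (networkx), direct evaluation of
  the pair term. The engine must match it to 1e-9 relative; golden
  HintTable files regenerate byte-identically.

What the fixtures do **not** emulate: real secondary structure, packing,
correlated motions, solvent, or realistic SASA profiles. Passing tests
demonstrate the correctness of the arithmetic, classification, exclusion
and aggregation machinery — not that the default constants reproduce any
experimental stability ranking.

## Numerical choices

* Canonical pair ordering (i < j, ascending) fixes floating-point
  summation order; repeated runs are byte-identical, and all tabular
  outputs use fixed formats.
* Bond inference: template connectivity by atom name (including the
  peptide link), a covalent-radius distance rule
  d < 1.25·(r_i + r_j) for atoms templates leave unbonded, and the same
  rule between sulfur pairs to catch disulfides. Periodic images are not
  unwrapped — supply whole-molecule trajectories.
* Altlocs resolve to the highest-occupancy variant; waters and common
  ions are stripped by default.
* Degenerate inputs fail loudly: coincident atoms, empty selections,
  single-frame RMSF, atom-count mismatches, non-positive radii or
  distances all raise typed errors.

## Problem sizes

The shipped tests and the reproduction script run on systems of 10–120
atoms and trajectories of 4–1000 frames; a full per-frame scoring pass
on such systems takes milliseconds, so the whole suite completes in well
under a minute. The engine itself scales to protein-sized systems
(k-d-tree enumeration is O(N) at fixed cutoff density; per-frame SASA is
the dominant cost).

## Known limitations

* Absolute score magnitudes depend on the parameter table and are not
  transferable across tables.
* No angle term in hydrogen-bond detection (heavy-atom distance only,
  by design).
* The distance response beyond the exponential default (linear ramp,
  inverse square) is provided for sensitivity checks, not calibrated.
* Formal charges and long-range Coulomb electrostatics are out of scope;
  "electrostatic" here is the acid-base interaction class.
* Ligand parameterization falls back to per-element constants unless a
  user dictionary block provides better ones.
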