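# hintmd

Intramolecular hydropathic-interaction scoring of protein structures and
molecular-dynamics trajectories.

## What it is for

Energy analysis of conformational ensembles: given a structure or an MD
trajectory, `hintmd` quantifies the protein's internal interaction
network with a LogP-based pair score, tracks it over time, decomposes it
by interaction type (hydrogen bond, electrostatic, hydrophobic,
unfavorable), extracts the lowest-energy frames, profiles flexibility
(RMSD/RMSF), and localizes differences between two ensembles down to
residue pairs. The typical user is a structural bioinformatician or
molecular modeller asking *why* two conformational states of the same
protein differ in stability — e.g. how a flexible loop is anchored to a
neighboring helix in one ensemble but not in the other.

## The score

For one conformation,

```
B = Σ_i Σ_{j>i} b_ij,     b_ij = S_i a_i S_j a_j T_ij R(d_ij)
```

where `a_i` is a hydrophobic atom constant derived from atomic LogP_o/w
fragment contributions (positive apolar, negative polar), `S_i` the
atom's solvent-accessible surface area (Å², Shrake–Rupley, recomputed
per frame), `R(d) = exp(−d)` the distance response, and `T_ij` a sign
term making hydrogen bonds, acid–base contacts and hydrophobic contacts
favorable (positive) and acid–acid, base–base and hydrophobic–polar
(desolvation) contacts unfavorable (negative). Pairs that are bonded
(1-2) or share a bond partner (1-3) are excluded. Donor/acceptor-
compatible polar pairs are hydrogen bonds at heavy-atom distance
≤ 3.65 Å and acid–base interactions above it. Atoms are parameterized at
neutral pH from a replaceable TSV dictionary, with the semi-essential
hydrogen treatment (polar, unsaturated, and alpha-to-heteroatom
hydrogens kept). See `docs/methods.md` for the full model description.

## Worked example

Score a salt-bridge contact (an aspartate and a lysine posed with their
carboxylate/ammonium heavy atoms 2.9 Å apart — a built-in fixture):

```python
from hintmd import ScoreConfig, compute_sasa, score_frame
from hintmd.fixtures import make_contact_pair

system, frame = make_contact_pair("ASP", "LYS", 2.9)
sasa = compute_sasa(system, frame)
frame_score, pairs = score_frame(system, frame, sasa, ScoreConfig())
print(f"total B      = {frame_score.total:8.2f}")
print(f"hydrogen bond= {frame_score.hbond_sum:8.2f}")
print(f"electrostatic= {frame_score.electrostatic_sum:8.2f}")
print(f"hydrophobic  = {frame_score.hydrophobic_sum:8.2f}")
print(f"unfavorable  = {frame_score.unfavorable_sum:8.2f}")
print(f"pairs scored = {frame_score.n_pairs_scored}")
```

prints

```
total B      =    57.06
hydrogen bond=   113.06
electrostatic=    25.12
hydrophobic  =     4.90
unfavorable  =   -86.01
pairs scored = 189
```

The total is positive: the favorable hydrogen-bond network (including
the engineered Asp OD1 – Lys NZ contact, classified `hydrogen_bond` at
2.90 Å) outweighs the unfavorable desolvation contacts. The four
contributions always sum to the total exactly. Each scored pair carries
its distance, class, and score; `write_hint_table` dumps them as TSV
with the parameters (`a_i`, `S_i`) used.

The same workflow from the shell — generate a synthetic hinge trajectory
(a 6-residue peptide whose second half oscillates by 3 Å), score it, and
profile its flexibility:

```
$ hintmd fixtures --out fx --seed 1 --n-frames 10
$ hintmd traj --topology fx/hinge_topology.pdb --traj fx/hinge_traj.pdb --out out
total    -67.4708    +/-  0.431513
hbond    343.718     +/-  1.45231
electrostatic  2.30033   +/-  0.111736
hydrophobic    2.39363   +/-  0.00886778
unfavorable   -415.883   +/-  0.917931

$ hintmd rmsf --topology fx/hinge_topology.pdb --traj fx/hinge_traj.pdb \
      --superpose none --region mobile=4-6 --region rigid=1-3 --out out
mobile  4-6  min=3  max=3  mean=3
rigid   1-3  min=0  max=0  mean=0
```

The per-frame series lands in `out/frame_scores.tsv`, the per-residue
profile in `out/rmsf.tsv`; the region report recovers the construction
amplitude (3 Å) exactly on the mobile residues. `hintmd compare` scores
two ensembles and reports the residue pairs whose interaction pattern
differs most; `hintmd traj --extract-top k` writes the k best-scoring
(lowest-energy) frames as PDB.

Note on magnitudes: the bundled atom constants are a documented
rule-based table, so absolute scores are only comparable between runs
using the same dictionary. The informative outputs are the per-class
decomposition, the time behavior, and ensemble differences.

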