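# Methods

## Scope and model

`crossbeta` analyses snapshots of N identical short peptide chains (7–11
residues in the intended use) and reduces each frame to graph-valued and
scalar order parameters of amyloid self-assembly. It does not simulate
anything: trajectories come either from a simulation engine (as multi-model
PDB) or from the package's own synthetic builders.

The analysis chain per frame is:

1. amide-hydrogen completion (if the input lacks polar H),
2. geometric backbone hydrogen-bond detection,
3. four-state secondary structure from the bond pattern,
4. contact graph → oligomers; strand-pairing graph → β-sheets → β-barrels,
5. scalar observables (sizes, propensities, orientation ratios, traces).

Ensemble statistics pool frames (and, if several runs are concatenated,
runs with equal frame weight) over an analysis window; the free-energy
landscape uses every frame because it is meant to cover the whole assembly
pathway, not just the equilibrated tail.

## Hydrogen bonds and secondary structure

A bond requires backbone N–O distance ≤ 3.5 Å *and* N–H···O angle ≥ 120°,
the angle taken at H. Donor and acceptor must be different residues, and
same-chain neighbours (|Δindex| < 2) are excluded; prolines never donate.
When a cubic box edge is attached to a frame, the N–O displacement uses the
minimum-image convention (chains are assumed whole).

Secondary structure uses the Kabsch–Sander patterns evaluated on this
geometric bond set rather than on an energy function, so the strand
assignment and the sheet-pairing criterion share one bond definition and can
never disagree about which bonds exist. Bridges follow the standard
parallel/antiparallel patterns; a residue becomes E only when its bridge
belongs to a ladder of at least two consecutive bridges (an isolated bridge
is left as coil — the same "two bonds, two consecutive residues" floor the
sheet-pairing rule uses). Helices are runs of ≥ 2 consecutive i→i+4 turn
bonds (residues i+1..i+4); isolated 3/4/5-turns mark T over their span.
Conflicts resolve E > H > T > C. The full 8-state alphabet (G, I, B, S) is
deliberately collapsed to the four states the aggregation observables need.

## Aggregate topology

The contact graph places an edge between two peptides when any heavy-atom
pair across them is within 5.5 Å (minimum image when a box is present).
Oligomers are its connected components; monomers are size-1 oligomers.

The pairing graph places an edge between two chains when each contributes at
least two consecutive E residues and those strand segments are linked by at
least two backbone hydrogen bonds. One peptide is one node: these short
chains form single strands, and a chain with two E segments is still one
strand node, paired through whichever of its segments carries the most bonds
(that segment also defines the orientation vector). Each edge stores the
total inter-chain bond count — the weight used by the antiparallel/parallel
ratio — and the orientation sign of the paired segment directions.

β-sheets are pairing-graph components with ≥ 2 strands. A sheet is a
β-barrel when (a) every strand has degree ≥ 2, (b) the pairing subgraph is
2-edge-connected, and (c) it has ≥ 4 strands. Degree alone is not enough: a
path with one doubled region satisfies it without being closed, so
bridge-freedom is required — "closed" means every strand lies on a cycle.
The 4-strand floor excludes degenerate triangles while admitting every
barrel size of interest (observed barrels are typically 6–8 strands).
β-sheet oligomers group the sheets of one contact component; their size
counts sheet-member peptides, so a coil chain merely touching a sheet
inflates the oligomer but not the β-sheet oligomer.

## Size statistics and landscape

For object sizes n_i the mass-weighted mean is (Σ n_i²)/(Σ n_i), and the
mass-weighted distribution is P(s) = s·c(s)/Σ s'·c(s') with c(s) the pooled
occurrence count — the probability that a randomly chosen peptide belongs to
an object of size s. Occurrences are pooled over frames (frame-pooled
occurrence weighting); barrel-size distributions use the same weighting for
consistency. The per-peptide barrel probability is (Σ_frames peptides inside
barrels)/(N × frames).

The landscape bins one observation per oligomer per frame at
(n_oligomer, mean E residues per chain). Oligomer sizes are exact integers;
β-content uses left-closed bins of width 1.0 residue, matching the natural
granularity of the axis (both configurable). PMF = −k_B·T·ln P with
k_B = 0.0019872 kcal/(mol·K), shifted so the sampled minimum is 0; unsampled
bins are reported as missing, never as infinities. Per-oligomer occurrence
weighting is the default (the literal reading of "probability of an
oligomer"); per-peptide weighting is available as an option.

## Analysis window and defaults

Ensemble averages default to the final 50 % of frames
(`equilibrium_fraction = 0.5`), the usual choice when a few hundred ns of
this system class equilibrate in the first half of a run. All thresholds
live in `AnalysisConfig` and nowhere else: contact 5.5 Å, H-bond 3.5 Å/120°,
≥ 2 bonds and ≥ 2 consecutive E per pairing, barrel minimum 4 strands,
landscape at 300 K with 1-residue β bins. Glycine, which has no side-chain
heavy atom, contributes its CA to side-chain contact maps so its rows are
defined rather than empty.

## Synthetic structures

The generator provides labeled inputs at three levels of realism:

* **Dihedral-built chains** — ideal bond lengths/angles (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, C=O 1.229 Å; ω = 180°) extended residue by
  residue from (φ, ψ). (−120°, 120°) gives an extended strand with a
  measured end-to-end rise of 3.32 Å/residue, (−57°, −47°) a helix whose
  interior the classifier labels H. Coil mode draws per-residue dihedrals
  from a uniform mixture over four Ramachandran basins (extended 0.45,
  polyproline-II 0.25, right-helical 0.25, left-helical 0.05) and rejects
  chains with any non-bonded heavy-atom pair under 2.5 Å.
* **Template sheets** — strands with a 2-residue periodic repeat (rise
  3.5 Å, CA pleat ±0.6 Å, donor/acceptor zigzag ±0.35 Å) stacked at 4.85 Å.
  Alternating residues face alternating neighbours, as in real sheets; the
  registry and per-chain parity are chosen in closed form so that every
  intended ladder bond lands within 3.3 Å, and each donor H is aimed
  directly at its acceptor (angle 180°) — a deliberate safety margin inside
  the 3.5 Å/120° rule, verified by a dedicated test. Double layers stack two
  sheets 8 Å apart with CB pseudo-side-chains facing, close enough for
  heavy-atom contact (one β-sheet oligomer) but far beyond hydrogen-bonding
  range (two sheets). Side chains are reduced to CB (CA for glycine):
  contact analyses need heavy-atom presence, not rotamer realism.
* **Barrels** — the same template wrapped onto a cylinder of radius
  r = d/(2·sin(π/n)), d = 4.85 Å, n = 4..12 strands; the zigzag amplitude is
  solved per n so the donor–acceptor chord is 2.9 Å. Parallel barrels close
  at any n; antiparallel (alternating-direction) barrels require even n —
  an odd alternating ring cannot close, and the builder refuses rather than
  silently emitting a mixed seam.

Scenes compose several assemblies on a grid with enough clearance that no
cross-unit contact is possible, and scripted trajectories hold scenes for
stated durations with instantaneous transitions. The script is therefore an
exact oracle for the time-series traces.

What the generator does *not* emulate: thermal backbone disorder beyond
i.i.d. Gaussian coordinate noise, bent (L-/U-turn) sheets, side-chain
packing, solvent, or any energetics. Passing the synthetic suites therefore
demonstrates that the detectors implement their definitions exactly on clean
and mildly noisy geometry (E labels are stable to σ = 0.15 Å coordinate
noise, the documented floor); it does not by itself validate behaviour on
borderline simulation geometries, where the thresholds themselves carry the
scientific meaning.

## Bookkeeping arithmetic

Closed forms with CODATA-2018 constants: concentration
c = n/(N_A·V_box); DMD time units at 50 fs/unit (the nominal calibration;
configurable since the published value is approximate); ionic strength from
a Debye length via I = ε_r·ε₀·k_B·T/(2·N_A·e²·λ_D²) — 10 Å at 300 K and
ε_r = 78.5 gives 93 mM, consistent with the usual "~100 mM physiological"
statement. One campaign-table caveat: a 2-peptide system in a 6.1 nm box
computes to ≈ 15 mM, not the ~26 mM that every other row of the standard
campaign reproduces (26.4 mM at 20 peptides/10.8 nm, 26.9 mM at
8 peptides/7.9 nm); reported tables with that pairing likely carry a
rounding or transcription error, and the arithmetic here is left honest
rather than adjusted.

## Numerical and degenerate-input choices

Both H-bond cutoffs are inclusive (≤ 3.5 Å, ≥ 120°). Orientation ties
(dot product exactly 0) resolve to antiparallel. The alignment ratio over a
window with no pairing edges is undefined and reported as an absent value,
not zero; the mass-weighted mean of an empty size list is an error, while
a frame without sheets reports a 0.0 trace. Empty landscape input is an
error. File I/O preserves chain and residue order exactly; coordinates
round-trip at PDB precision (10⁻³ Å). The plain-text dialect carries no
residue identities, so chains read from it are typed UNK and treated as
standard non-proline residues.
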