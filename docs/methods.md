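# Methods

## The model

`geofold` simulates the formation of compact, protein-like structures from
a one-dimensional chain using geometric constraints only.  The chain is a
sequence of `N` spheres of unit diameter and unit bond length (optionally
heterogeneous: diameters uniform on `[1-a, 1+a]`, consecutive beads
touching).  Folding proceeds by repeatedly selecting a uniformly random
pair of not-yet-linked, non-adjacent beads and attempting to bring the two
into contact.  Three rules are absolute:

1. **links are permanent** — once two beads touch and link, they are held
   at their contact distance `r_i + r_j` for the rest of the run;
2. **volume exclusion** — no two beads may interpenetrate, including every
   bead that moves along during an attempt;
3. an attempt **succeeds** when the pair reaches contact (within a
   relative tolerance) and **fails** when its distance stops improving.

The run terminates when every unlinked pair is marked failed; a success
re-opens the verdicts of pairs whose local geometry changed.  The result
is a compact aggregate and its contact network: nodes are beads, edges are
backbone bonds plus every link formed.  Aggregates are compared with
protein residue networks (PRNs), whose nodes are residues (Cα positions)
and whose edges connect residues within a cutoff `d_c` (default 6.5 Å).

The helper displacements used to realize attempts are *not* a physical
force field; they are a convenient way to move beads "in a consistent way"
while satisfying the constraints continuously.  Any dynamics that
maintains the invariants (bond conservation within `tol_bond`, exclusion
within `tol_overlap` at every accepted step) is a valid realization; the
contract, not the integrator, is the model.

## The constrained dynamics (what the integrator actually does)

Each attempt on a pair `(i, j)` iterates position-based steps:

* **hinge motion.** The bond graph is split by a two-source BFS into the
  side of `i` and the side of `j`.  Each side rotates rigidly (Rodrigues,
  exact to float precision) about the centroid of its beads that carry
  bonds across the cut, with the torque the pull at `i` (resp. `j`)
  exerts there.  The common rotation scale is limited so that no
  constraint crossing the cut leaves its tolerance band.  This is the
  motion an articulated pair of lobes performs when folding shut, and it
  transports arbitrarily large sub-structures in O(1) steps per unit
  distance without stressing any internal bond.
* **bead moves.** `i` and `j` take a step toward each other (clipped
  at 40 % of the gap to avoid overshooting contact) plus a random
  transverse kick.  The move first *slides*: components pressing into
  constraints already at their boundary are projected out, so a bead in a
  cage can still move tangentially.  The remainder is *limited* so no
  constraint of the moved bead leaves its band.  Bonds are asymmetric —
  they may stretch up to `tol_bond` but compress only within
  `tol_overlap` — exactly mirroring the invariants.
* **inertia.** Beads keep a damped fraction (0.9) of their previous
  displacement, clipped the same way against predicted neighbor
  positions.  Co-moving groups coast freely; a bead rattling against a
  rigid cage loses its motion immediately.  This damped coasting is what
  lets dragged chain arms follow a pull instead of creeping diffusively,
  and it doubles as the agitation that anneals the aggregate.
* **local relaxation.** A queue-based Gauss–Seidel projection restores
  every violated constraint, starting from the beads that moved and
  following the constraint graph outward (over-relaxation 1.2 on bond
  corrections).  When the queue drains, the whole configuration satisfies
  the invariants again — constraints far from any moved bead were
  satisfied before the step by induction.
* **failure detection.** The dynamics is damped descent: a geometrically
  blocked pair shows (near-)zero progress from the start.  An attempt
  fails when the best pair distance improves at less than
  `min_progress_frac × step_size` per step over a rolling window, or
  when neither bead achieves any net movement for several consecutive
  steps (a fully caged pair fails within ~4 steps).  "Geometrically
  incapable of connecting" is undecidable in general; this stall rule is
  the operational surrogate, and failed pairs are retried whenever a later
  success changes the geometry around them.

Neighbor bookkeeping uses a Verlet candidate list (skin margin 1.6
diameters) rebuilt whenever accumulated motion could invalidate it; after
each rebuild a full relaxation sweep runs so no pair that entered the list
mid-flight can carry an unseen overlap.  After every success the whole
aggregate is settled to convergence, so the state between attempts is
violation-free and failed attempts (which roll back all positions) cost a
handful of microseconds each.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `a` | 0 | radius heterogeneity, diameters uniform on `[1-a, 1+a]` |
| `tol_contact` | 1e-2 | relative gap at which a pair counts as joined |
| `tol_overlap` | 1e-3 | relative interpenetration never exceeded |
| `tol_bond` | 1e-2 | relative band existing links are held within |
| `step_size` / `step_cap` | 0.05 | per-step displacement of the pulled pair |
| `kick_frac` | 0.35 | transverse random kick, fraction of the step |
| `init_jitter` | 0.05 | seeded transverse perturbation of the straight start |
| `stall_window`, `min_progress_frac` | 12, 0.002 | failure (stall) rule |
| `blocked_limit` | 4 | consecutive no-movement steps before failing |
| `inertia_damp`, `v_cap`, `v_floor` | 0.9, 0.15, 2e-3 | coasting memory and caps |
| `drag_budget`, `rigid_drag`, `push_depth` | in-band | per-step constraint-violation budgets of moved beads |

The transverse kicks and the initial jitter break an exact symmetry: a
perfectly collinear inextensible chain cannot shorten under a purely
longitudinal pull, so the straight initial state is an unstable equilibrium
that the noise-free dynamics could never leave.

Tolerances are far below the contact scale, so they do not alter which
contact topologies are reachable; they sit above first-order integrator
noise.  The stall thresholds were chosen so that the analytically known
small aggregates always complete (N = 3 closes to the triangle, N = 4 to
the tetrahedron of contacts) while a fully caged pair fails in a few
steps.

## What the simulated ensembles show — and what they do not

The generator emulates the study conditions: homogeneous unit spheres
(heterogeneity as an option), chain lengths from 3 to a few hundred,
independent seeded realizations.  Passing tests show that *this geometric
process* reproduces compact aggregates whose contact statistics, diameter
scaling and Laplacian spectra behave like those of real protein residue
networks.  They do not show anything about chemistry: there are no amino
acid identities, no solvent, no temperature, and links never break.  Real
proteins also leave larger internal gaps (weaker interactions, thermal
fluctuation), so their PRN diameters sit above the model's at equal chain
length.

Two quantitative caveats, both documented rather than hidden:

* the mean degree of our final aggregates saturates near `k ≈ 6.0–6.2`,
  somewhat below the published model value (≈ 6.8).  The gap traces to the
  joining dynamics: our attempts never push blocking beads out of the way
  beyond the exclusion tolerance, so hyperstatic contacts that require
  squeezing are not formed.  Diameter scaling and the spectral shape are
  much less sensitive to this than the raw contact count.
* exponent fits on reduced ensembles carry larger uncertainties than the
  published 48 × 30 runs up to N = 398.  The shipped analysis uses
  12 log-spaced chain lengths in [3, 128] with 4 realizations each for
  the scaling fits, and four aggregates at N = 200…218 for the
  saturation observables (one run at N = 300 costs ~8 CPU-minutes, so
  these sizes keep a full reanalysis near ten minutes on one core).  On
  this range the fitted diameter exponent comes out near 0.42 — still
  strictly between the space-filling (1/3) and self-avoiding (3/5)
  limits, but above the published 0.345, consistent with the slightly
  less compact aggregates noted above.  The D-versus-R_g slope
  (≈ 0.82 Å⁻¹ vs 0.777 Å⁻¹) is insensitive to this.

## Numerical choices

* Eigenvalues come from `numpy.linalg.eigvalsh` on the dense combinatorial
  Laplacian `L = diag(k) − A`; "second largest" is literally the
  eigenvalue at descending rank 2, which is the quantity whose growth
  saturates for compact aggregates.  The smallest nonzero (Fiedler) value
  governs the slowest relaxation mode and is reported separately — the
  two must not be conflated.
* Histogram peaks use bin width 0.5, ties toward smaller eigenvalue;
  degenerate eigenvalues all enter the pooled histogram.
* Power laws are ordinary least squares of `log y` on `log N`, with the
  slope standard error from the residuals.  Diameters are averaged across
  realizations per chain length *before* the fit, and the fitted variable
  is `D + 1` (the shifted form handles `N = 2`, `D = 1` gracefully and is
  the form under which the scaling is algebraic).  The D-versus-R_g line
  also uses `D + 1`; using `D` instead changes the slope by well under
  its standard error on our ensembles.
* PRN construction uses a k-d tree with the boundary convention
  `d = d_c` ⇒ connected; an exhaustive double loop serves as the test
  oracle.  Multi-chain PDB files are concatenated in file order (with a
  warning); only the first model and the highest-occupancy alternate
  location of each atom are used.
* Model lengths convert to Å through a single `unit_scale`; comparisons
  with PRNs use the mean PRN link length 5.066 Å per model diameter.

## Known limitations

* The joining dynamics is one conforming realization of the model's
  contract, not a reconstruction of any particular published integrator;
  quantities that depend on fine kinetics (attempt orderings, trace
  lengths) are implementation-specific.  Final-structure observables are
  the meaningful outputs.
* Failure verdicts are heuristic: a pair declared incapable might be
  closable by a more exhaustive search.  Verdicts are re-examined whenever
  nearby geometry changes, but a remote rearrangement that opens a
  corridor without touching either endpoint's neighborhood would be
  missed.
* Blocks of the contact network are treated by the dynamics as rigid only
  implicitly (through the constraints); no symbolic rigidity analysis is
  performed.
* Laplacian spectra are computed densely; beyond a few thousand nodes a
  sparse eigensolver would be preferable.
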