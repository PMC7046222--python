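"""Stochastic folding of a bead chain under geometric constraints.

The process starts from a straight chain of ``N`` touching spheres and
repeatedly picks a random pair of not-yet-linked, non-adjacent beads,
attempting to bring them into contact.  An attempt moves the selected pair
toward each other under over-damped, position-based dynamics in which

* every previously formed link is held at its contact distance (links are
  permanent — connected units stay connected),
* no two beads may overlap (volume exclusion, which applies to every
  co-moving bead, not just the selected pair).

An attempt succeeds when the pair reaches contact within ``tol_contact``;
it fails when the pair distance stops improving (the operational surrogate
for "geometrically incapable of connecting", which is undecidable in
general).  Failed pairs are not excluded forever: any success changes the
geometry, so all failure marks are cleared whenever a new link forms.  The
run terminates when every unlinked pair is marked failed.

The helper displacements are not meant to model physical forces; they only
realize the joining attempts while satisfying the constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .chain import BeadChain, ContactNetwork, make_straight_chain, violates_exclusion

__all__ = [
    "FoldingParams",
    "FoldingTrace",
    "attempt_link",
    "run_folding",
    "run_ensemble",
    "log_spaced_lengths",
    "trace_to_csv",
]


@dataclass(frozen=True)
class FoldingParams:
    """All simulator knobs.

    Parameters
    ----------
    a
        Radius heterogeneity in [0, 0.5]: bead diameters are uniform on
        [1 - a, 1 + a] (mean diameter 1).
    seed
        Base RNG seed; the full run (pair selection, symmetry-breaking
        kicks) is a deterministic function of ``(N, params)``.
    tol_contact
        Relative: a pair counts as joined when d <= (r_i + r_j)(1 + tol).
    tol_overlap
        Relative: exclusion is violated when d < (r_i + r_j)(1 - tol).
    tol_bond
        Relative: existing links are held at contact distance within
        (r_i + r_j) * tol_bond.
    step_size, step_gain, step_cap
        Per-step displacement of each selected bead:
        ``clip(step_gain * gap, step_size, step_cap)``.  The gain term
        shortens long-range pulls; the cap keeps single steps below a bead
        radius so constraints stay resolvable.
    kick_frac
        Transverse random kick amplitude as a fraction of the step; breaks
        the symmetry of collinear configurations (a perfectly straight
        inextensible chain cannot shorten under a purely longitudinal pull).
    init_jitter
        Amplitude of the seeded transverse perturbation applied to the
        straight initial chain before folding, same rationale.
    max_steps_per_attempt
        Hard step budget per attempt; 0 means the default 1000 * N.
    stall_window, min_progress_frac
        An attempt fails when the best pair distance improves by less than
        ``stall_window * min_progress_frac * step_size`` over the last
        ``stall_window`` steps.  The dynamics is deterministic descent, so
        a blocked pair shows (near-)zero progress immediately.
    """

    a: float = 0.0
    seed: int = 0
    tol_contact: float = 1e-2
    tol_overlap: float = 1e-3
    tol_bond: float = 1e-2
    step_size: float = 0.05
    step_gain: float = 0.1
    step_cap: float = 0.05
    kick_frac: float = 0.35
    init_jitter: float = 0.05
    max_steps_per_attempt: int = 0
    stall_window: int = 12
    min_progress_frac: float = 0.002
    push_depth: float = 6e-4
    drag_budget: float = 4.5e-3
    rigid_drag: float = 4.5e-3
    rigid_degree: int = 4
    inertia_damp: float = 0.9
    v_cap: float = 0.15
    v_floor: float = 2e-3
    blocked_limit: int = 4
    max_relax_ops: int = 0  # 0 -> default 60 * N
    verlet_margin: float = 1.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 0.5:
            raise ValueError(f"a must lie in [0, 0.5], got {self.a}")
        for name in ("tol_contact", "tol_overlap", "tol_bond", "step_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.stall_window < 2:
            raise ValueError("stall_window must be >= 2")

    def resolve_max_steps(self, n_beads: int) -> int:
        return self.max_steps_per_attempt or 1000 * n_beads

    def resolve_max_relax_ops(self, n_beads: int) -> int:
        return self.max_relax_ops or 60 * n_beads

    def relax_tolerances(self, radii: np.ndarray) -> tuple:
        """Absolute relaxation tolerances (bond, overlap): half the allowed
        slack of the tightest pair, so post-relaxation states satisfy the
        relative step invariants with margin."""
        min_contact = 2.0 * float(radii.min())
        return (
            0.5 * self.tol_bond * min_contact,
            0.5 * self.tol_overlap * min_contact,
        )


@dataclass
class FoldingTrace:
    """Ordered record of a folding run.

    ``attempts`` is the sequence of ``((i, j), outcome)`` with outcome in
    {"success", "fail"}; ``l`` counts successes; ``snapshots`` holds
    ``(l, BeadChain)`` copies at requested success counts.
    """

    attempts: list = field(default_factory=list)
    l: int = 0
    snapshots: list = field(default_factory=list)
    max_bond_violation: float = 0.0
    max_overlap_violation: float = 0.0


def trace_to_csv(trace: FoldingTrace, path) -> None:
    """Export attempts as CSV: attempt_index,i,j,outcome,l."""
    with open(path, "w") as fh:
        fh.write("attempt_index,i,j,outcome,l\n")
        l = 0
        for idx, ((i, j), outcome) in enumerate(trace.attempts):
            if outcome == "success":
                l += 1
            fh.write(f"{idx},{i},{j},{outcome},{l}\n")


class _SimState:
    """Preallocated working arrays shared by all attempts of one run."""

    def __init__(self, chain: BeadChain, net: ContactNetwork, params: FoldingParams):
        n = chain.n_beads
        self.n = n
        self.params = params
        self.pos = np.ascontiguousarray(chain.positions, dtype=np.float64)
        self.radii = np.ascontiguousarray(chain.radii, dtype=np.float64)
        self.adj = np.zeros((n, n), dtype=np.uint8)
        self.bonds = np.zeros((max(16, 8 * n), 2), dtype=np.int64)
        self.n_bonds = 0
        self.meta = np.zeros(3, dtype=np.int64)  # [n_cand, csr_valid, -]
        for i, j in sorted(net.edges):
            self._register_bond(i, j)
        cand_cap = max(1024, 72 * n)
        self.cand = np.zeros((cand_cap, 2), dtype=np.int64)
        self.pos_ref = np.zeros_like(self.pos)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        nbr_cap = 2 * (self.bonds.shape[0] + cand_cap)
        self.nbr = np.zeros(nbr_cap, dtype=np.int64)
        self.ntype = np.zeros(nbr_cap, dtype=np.int8)
        self.queue = np.zeros(2 * n + 4, dtype=np.int64)
        self.inq = np.zeros(n, dtype=np.uint8)
        self.step_buf = np.zeros_like(self.pos)
        self.snapshot = np.zeros_like(self.pos)
        self.prev = np.zeros_like(self.pos)
        self.mid = np.zeros_like(self.pos)
        self.vel = np.zeros_like(self.pos)
        self.side = np.zeros(n, dtype=np.int8)
        self.dirty = np.zeros(n, dtype=np.uint8)
        self.sdist = np.zeros(n, dtype=np.int64)
        cross_cap = max(1024, 48 * n)
        self.cross = np.zeros((cross_cap, 2), dtype=np.int64)
        self.cross_type = np.zeros(cross_cap, dtype=np.int8)
        self.seeds = np.zeros(2 * n + 4 + 2 * cross_cap, dtype=np.int64)
        self.bond_degree = np.zeros(n, dtype=np.int64)
        for e in range(self.n_bonds):
            self.bond_degree[self.bonds[e, 0]] += 1
            self.bond_degree[self.bonds[e, 1]] += 1
        self.move_budget = np.zeros(n, dtype=np.float64)
        self.tol_bond_half, self.tol_over_half = params.relax_tolerances(self.radii)
        self.max_steps = params.resolve_max_steps(n)
        self.max_relax_ops = params.resolve_max_relax_ops(n)
        self.viol = np.zeros(2, dtype=np.float64)
        self.diag = np.zeros(8, dtype=np.int64)
        self._refresh_budgets()

    def _refresh_budgets(self) -> None:
        # beads held by few links can drag their bonds along (floppy chain
        # segments); beads anchored by many links are kept inside the bond
        # tolerance band so a pull cannot inject energy into a rigid cluster
        drag = self.params.drag_budget or 0.9 * self.tol_bond_half
        rigid = self.params.rigid_drag or 0.9 * self.tol_bond_half
        floppy = self.bond_degree < self.params.rigid_degree
        self.move_budget[:] = np.where(floppy, drag, rigid)

    def _register_bond(self, i: int, j: int) -> None:
        if self.n_bonds >= self.bonds.shape[0]:
            self.bonds = np.vstack([self.bonds, np.zeros_like(self.bonds)])
        self.bonds[self.n_bonds, 0] = min(i, j)
        self.bonds[self.n_bonds, 1] = max(i, j)
        self.n_bonds += 1
        self.adj[i, j] = self.adj[j, i] = 1
        self.meta[1] = 0  # constraint graph changed -> CSR stale
        if hasattr(self, "bond_degree"):
            self.bond_degree[i] += 1
            self.bond_degree[j] += 1
            self._refresh_budgets()

    def _grow_candidate_arrays(self) -> None:
        self.cand = np.zeros((2 * self.cand.shape[0], 2), dtype=np.int64)
        nbr_cap = 2 * (self.bonds.shape[0] + self.cand.shape[0])
        self.nbr = np.zeros(nbr_cap, dtype=np.int64)
        self.ntype = np.zeros(nbr_cap, dtype=np.int8)
        self.cross = np.zeros((2 * self.cross.shape[0], 2), dtype=np.int64)
        self.cross_type = np.zeros(self.cross.shape[0], dtype=np.int8)
        self.seeds = np.zeros(
            2 * self.n + 4 + 2 * self.cross.shape[0], dtype=np.int64
        )
        self.meta[1] = 0

    def _refresh_neighbors(self) -> None:
        while True:
            m = K._rebuild_candidates(
                self.pos, self.radii, self.adj, self.params.verlet_margin, self.cand
            )
            if m < 0:
                self._grow_candidate_arrays()
                continue
            self.meta[0] = m
            self.pos_ref[:, :] = self.pos
            if (
                K._build_csr(
                    self.n, self.bonds, self.n_bonds, self.cand, m,
                    self.indptr, self.nbr, self.ntype,
                )
                < 0
            ):
                self._grow_candidate_arrays()
                continue
            self.meta[1] = 1
            break

    def settle(self) -> None:
        """Relax every constraint to convergence (after the initial jitter
        and after every new link, whose projection may squeeze a captured
        pair the last bit of the way to contact)."""
        for _ in range(200):
            self._refresh_neighbors()
            r = K._relax_all(
                self.pos, self.radii, self.indptr, self.nbr, self.ntype,
                self.queue, self.inq, self.tol_bond_half, self.tol_over_half,
                10_000 * self.n,
            )
            if r == 0:
                return
        raise RuntimeError("constraint relaxation failed to converge")

    def attempt(self, i: int, j: int, kick_seed: int, validate: bool):
        """Run one joining attempt; returns (success: bool, steps: int)."""
        p = self.params
        self.snapshot[:, :] = self.pos
        while True:
            status, steps = K._attempt(
                self.pos, self.radii, self.adj, self.bonds, self.n_bonds,
                self.cand, self.meta, self.pos_ref,
                self.indptr, self.nbr, self.ntype, self.queue, self.inq,
                self.step_buf, self.prev, self.mid, self.vel, self.seeds, self.move_budget,
                self.side, self.sdist, self.cross, self.cross_type,
                i, j,
                p.step_size, p.step_gain, p.step_cap, p.kick_frac, p.push_depth,
                p.inertia_damp, p.v_cap, p.v_floor,
                p.tol_contact, self.tol_bond_half, self.tol_over_half,
                p.verlet_margin,
                self.max_steps, p.stall_window,
                p.min_progress_frac * p.step_size, p.blocked_limit,
                self.max_relax_ops,
                kick_seed, 1 if validate else 0, self.viol, self.diag,
            )
            if status == -2:
                self._grow_candidate_arrays()
                self.pos[:, :] = self.snapshot
                continue
            break
        if status == K.SUCCESS:
            # beads whose neighborhood geometry changed during this attempt:
            # only their pairs need their failure verdicts re-examined
            K._dirty_beads(self.pos, self.snapshot, self.radii, self.indptr,
                           self.nbr, 0.01, self.dirty)
            self.dirty[i] = 1
            self.dirty[j] = 1
            self._register_bond(i, j)
            # settle the whole aggregate: the inter-attempt state must be
            # violation-free, otherwise every subsequent attempt re-corrects
            # (and then rolls back) the same residuals
            self.settle()
            return True, steps
        self.pos[:, :] = self.snapshot  # failure is side-effect free
        return False, steps

    def chain(self, unit_scale: float = 1.0) -> BeadChain:
        return BeadChain(self.pos.copy(), self.radii.copy(), unit_scale)


def attempt_link(
    chain: BeadChain,
    net: ContactNetwork,
    pair: tuple,
    params: FoldingParams = FoldingParams(),
    validate: bool = False,
) -> tuple:
    """Attempt to join one pair of beads.

    Returns ``(outcome, updated_chain)`` with outcome in
    {"success", "fail"}; on success the edge is added to ``net`` in place.
    The input chain is not modified.

    Raises
    ------
    ValueError
        If the pair is already linked or is a backbone-adjacent pair.
    """
    i, j = int(pair[0]), int(pair[1])
    if i == j:
        raise ValueError("cannot link a bead to itself")
    if net.has_edge(i, j):
        raise ValueError(f"pair ({i}, {j}) is already linked")
    if abs(i - j) == 1:
        raise ValueError(f"pair ({i}, {j}) is backbone-adjacent (already connected)")
    state = _SimState(chain.copy(), net, params)
    ok, _ = state.attempt(i, j, kick_seed=int(params.seed) * 2654435761 % (2**62) + 1,
                          validate=validate)
    if ok:
        net.add_edge(i, j)
        return "success", state.chain(chain.unit_scale)
    return "fail", chain.copy()


def _all_candidate_pairs(n: int) -> np.ndarray:
    """All unordered non-backbone pairs (i, j), i < j, j > i + 1."""
    ii, jj = np.triu_indices(n, k=2)
    return np.column_stack([ii, jj]).astype(np.int64)


def run_folding(
    N: int,
    params: FoldingParams = FoldingParams(),
    snapshot_at: tuple = (),
    record_attempts: bool = True,
    validate: bool = False,
) -> tuple:
    """Fold a chain of N beads to completion.

    Returns ``(final_chain, final_network, trace)``.  The final network is
    connected, contains all backbone edges, and no unlinked pair has
    succeeded since the last topology change.

    With ``validate=True`` the run additionally measures the worst bond
    and exclusion violation after every accepted dynamics step (stored on
    the trace); this is O(N^2) per step and meant for small N.
    """
    if N < 2:
        raise ValueError(f"chain length must be >= 2, got {N}")
    chain0 = make_straight_chain(N, params.a, params.seed)
    net = ContactNetwork.backbone(N)
    trace = FoldingTrace()
    rng = np.random.default_rng([int(params.seed) % 2**31, 0xBEAD])

    state = _SimState(chain0, net, params)
    if params.init_jitter > 0 and N > 2:
        # transverse symmetry-breaking: a perfectly collinear chain is a
        # (measure-zero) unstable configuration the descent cannot leave
        state.pos[:, 1] += params.init_jitter * rng.standard_normal(N)
        state.pos[:, 2] += params.init_jitter * rng.standard_normal(N)
    state.settle()

    if 0 in snapshot_at:
        trace.snapshots.append((0, state.chain()))

    pairs = _all_candidate_pairs(N)
    n_pairs = pairs.shape[0]
    # 0 = untried or retriable, 1 = linked, 2 = marked failed
    status = np.zeros(n_pairs, dtype=np.uint8)

    def fresh_order():
        active = np.flatnonzero(status == 0)
        rng.shuffle(active)
        return active

    order = fresh_order()
    cursor = 0
    while cursor < len(order):
        p = order[cursor]
        cursor += 1
        if status[p] != 0:  # linked meanwhile is impossible; defensive
            continue
        i, j = int(pairs[p, 0]), int(pairs[p, 1])
        kick_seed = int(rng.integers(1, 2**62))
        ok, _steps = state.attempt(i, j, kick_seed, validate)
        if ok:
            status[p] = 1
            net.add_edge(i, j)
            trace.l += 1
            if record_attempts:
                trace.attempts.append(((i, j), "success"))
            if trace.l in snapshot_at:
                trace.snapshots.append((trace.l, state.chain()))
            # failure verdicts are stale only where the geometry changed:
            # re-open marked pairs touching the rearranged neighborhood
            dirty = state.dirty.astype(bool)
            stale = (status == 2) & (dirty[pairs[:, 0]] | dirty[pairs[:, 1]])
            status[stale] = 0
            order = fresh_order()
            cursor = 0
        else:
            status[p] = 2
            if record_attempts:
                trace.attempts.append(((i, j), "fail"))

    trace.max_bond_violation = float(state.viol[0])
    trace.max_overlap_violation = float(state.viol[1])
    final = state.chain()
    _check_final(final, net, params)
    return final, net, trace


def _check_final(chain: BeadChain, net: ContactNetwork, params: FoldingParams) -> None:
    violated, pairs = violates_exclusion(chain, params.tol_overlap)
    if violated:
        raise RuntimeError(f"exclusion violated in final state: {pairs[:5]}")
    for i, j in net.edges:
        d = float(np.linalg.norm(chain.positions[i] - chain.positions[j]))
        d0 = float(chain.radii[i] + chain.radii[j])
        if abs(d - d0) > params.tol_bond * d0:
            raise RuntimeError(f"bond ({i},{j}) off contact: d={d:.4f}, d0={d0:.4f}")


def log_spaced_lengths(n_min: int, n_max: int, count: int) -> list:
    """Unique integer chain lengths, logarithmically spaced."""
    vals = np.unique(np.rint(np.geomspace(n_min, n_max, count)).astype(int))
    return [int(v) for v in vals if v >= 2]


def run_ensemble(
    N_values,
    reps: int,
    params: FoldingParams = FoldingParams(),
    progress: bool = False,
) -> pd.DataFrame:
    """Fold ``reps`` independent realizations for every chain length.

    Per-run seeds are derived deterministically from ``params.seed``.
    Returns a DataFrame with one row per run and columns
    ``N, seed, edges, mean_degree, diameter, Rg, lambda_second_largest``.
    """
    from .metrics import (
        average_degree,
        graph_diameter,
        laplacian_spectrum,
        radius_of_gyration,
    )

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    run_idx = 0
    for N in N_values:
        for rep in range(reps):
            ss = np.random.SeedSequence(entropy=int(params.seed), spawn_key=(run_idx,))
            run_seed = int(ss.generate_state(1)[0] % 2**31)
            run_params = replace(params, seed=run_seed)
            chain, net, _tr = run_folding(N, run_params, record_attempts=False)
            spec = laplacian_spectrum(net)
            rows.append(
                {
                    "N": int(N),
                    "seed": run_seed,
                    "edges": net.n_edges,
                    "mean_degree": average_degree(net),
                    "diameter": graph_diameter(net),
                    "Rg": radius_of_gyration(chain),
                    "lambda_second_largest": spec.second_largest,
                }
            )
            run_idx += 1
            if progress:
                print(f"  folded N={N} rep={rep + 1}/{reps}", flush=True)
    return pd.DataFrame(rows)
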