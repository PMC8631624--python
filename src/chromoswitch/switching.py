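"""The landscape-switching protocol.

Representative starting structures are picked by hierarchical clustering of
an equilibrium ensemble on the pairwise-distance RMS metric (d_rms).  Each
switching run then equilibrates under the pre-switch landscape, swaps the
restraint matrix instantaneously (coordinates and velocities untouched --
the energy excitation that models an abrupt cell-state change), and relaxes
under the post-switch landscape while snapshots are logged on a
logarithmic grid that resolves the early, fast stages of the transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .dynamics import DynamicsParams, Trajectory, log_snapshot_times, run_langevin
from .maxent import Landscape
from .polymer import Conformation

# desk-scale defaults; the full-scale protocol uses 5000 / 10000 tau
DEFAULT_T_PRE = 50.0
DEFAULT_T_POST = 200.0
SNAPSHOTS_PER_PHASE = 60
SNAPSHOT_T_MIN = 0.05  # first post-switch snapshot (tau); resolves 0.1-10 tau


def pairwise_drms(a: Conformation, b: Conformation) -> float:
    """RMS difference of the two internal distance matrices over all pairs
    i < j; invariant to rigid motions and reflection."""
    if a.n_beads != b.n_beads:
        raise ValueError("conformations must have the same size")
    da = pdist(a.positions)
    db = pdist(b.positions)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def drms_matrix(ensemble) -> np.ndarray:
    """Condensed d_rms matrix over an ensemble (scipy pdist layout)."""
    d = np.stack([pdist(c.positions) for c in ensemble])
    return pdist(d) / np.sqrt(d.shape[1])


@dataclass
class ClusterSet:
    """Hierarchical clusters of an ensemble plus representative members."""

    labels: np.ndarray                 # per-conformation cluster id (1-based)
    populations: np.ndarray            # fraction per cluster id
    representatives: list              # chosen Conformations
    representative_clusters: list      # cluster id of each representative
    linkage: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.populations.size


def cluster_ensemble(ensemble, cutoff: float = 3.0, pop_threshold: float = 0.003,
                     picks_per_cluster: int = 2) -> ClusterSet:
    """Average-linkage clustering on d_rms, tree cut at ``cutoff`` (sigma).

    Representatives are the ``picks_per_cluster`` members nearest each
    qualifying cluster's medoid; a cluster qualifies if its population is at
    least ``pop_threshold``.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ValueError("need at least two conformations to cluster")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    condensed = drms_matrix(ensemble)
    link = average(condensed)
    labels = fcluster(link, t=cutoff, criterion="distance")
    n = len(ensemble)
    ids = np.arange(1, labels.max() + 1)
    populations = np.array([(labels == k).sum() / n for k in ids])

    from scipy.spatial.distance import squareform
    full = squareform(condensed)
    reps, rep_clusters = [], []
    for k in ids:
        if populations[k - 1] < pop_threshold:
            continue
        members = np.flatnonzero(labels == k)
        sub = full[np.ix_(members, members)]
        medoid_order = np.argsort(sub.mean(axis=1), kind="stable")
        for m in medoid_order[:picks_per_cluster]:
            reps.append(ensemble[members[m]])
            rep_clusters.append(int(k))
    if not reps:
        raise ValueError(
            "no cluster passes the population threshold; lower pop_threshold")
    return ClusterSet(labels, populations, reps, rep_clusters, link)


@dataclass
class SwitchRun:
    """One landscape-switching trajectory (pre phase + post phase)."""

    direction: str                # e.g. "normal->cancer"
    pre_trajectory: Trajectory
    post_trajectory: Trajectory
    initial_index: int
    seed: int

    @property
    def switch_frame(self) -> np.ndarray:
        """Coordinates at the switch instant (last pre = first post frame)."""
        return self.post_trajectory.frames[0]


def _phase_times(duration: float, n_snapshots: int, include_zero: bool) -> np.ndarray:
    t_min = min(SNAPSHOT_T_MIN, duration / 10.0)
    return log_snapshot_times(t_min, duration, n_snapshots, include_zero=include_zero)


def run_switch(initials, pre: Landscape, post: Landscape,
               t_pre: float = DEFAULT_T_PRE, t_post: float = DEFAULT_T_POST,
               dyn: DynamicsParams | None = None, master_seed: int = 0,
               direction: str | None = None, n_runs: int | None = None,
               n_snapshots: int = SNAPSHOTS_PER_PHASE) -> list:
    """Run the switching protocol once per initial structure.

    Per run: equilibrate under ``pre`` for ``t_pre`` tau, swap the restraint
    matrix, relax under ``post`` for ``t_post`` tau.  Velocities carry over
    across the switch; coordinates are bitwise unchanged at the boundary.
    Seeds derive from ``master_seed`` via ``numpy.random.SeedSequence``
    spawning, one child per run.  If ``n_runs`` exceeds the number of
    initials they are reused cyclically (with fresh seeds).
    """
    if t_pre <= 0 or t_post <= 0:
        raise ValueError("phase durations must be positive")
    if pre.n_beads != post.n_beads:
        raise ValueError("pre and post landscapes must share the bead count")
    if dyn is None:
        dyn = DynamicsParams()
    initials = list(initials)
    if not initials:
        raise ValueError("need at least one initial structure")
    if n_runs is None:
        n_runs = len(initials)
    if direction is None:
        direction = f"{pre.target_id or 'pre'}->{post.target_id or 'post'}"

    children = np.random.SeedSequence(master_seed).spawn(n_runs)
    runs = []
    for r in range(n_runs):
        seed_pair = [int(s % (2 ** 31)) for s in children[r].generate_state(2)]
        start = initials[r % len(initials)]
        pre_traj, v = run_langevin(
            start, pre.alpha, pre.params,
            DynamicsParams(dyn.dt, dyn.gamma, dyn.T, seed_pair[0]),
            t_pre, snapshot_times=_phase_times(t_pre, n_snapshots, False),
            provenance={"landscape": pre.target_id, "phase": "pre"},
            return_velocities=True)
        switch_conf = pre_traj.conformation(pre_traj.n_frames - 1)
        post_traj = run_langevin(
            switch_conf, post.alpha, post.params,
            DynamicsParams(dyn.dt, dyn.gamma, dyn.T, seed_pair[1]),
            t_post, snapshot_times=_phase_times(t_post, n_snapshots, True),
            velocities=v,
            provenance={"landscape": post.target_id, "phase": "post"})
        runs.append(SwitchRun(direction, pre_traj, post_traj, r % len(initials),
                              seed_pair[1]))
    return runs
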