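"""End-to-end study driver: generate -> fit -> switch -> analyze.

``run_study`` executes the whole desk-scale experiment in memory and
``analyze_study`` computes the transition statistics; ``run_pipeline``
wraps both, persists every artifact and writes a manifest of seeds and
content hashes so a run is reproducible from its config alone.

All randomness flows from one master seed: each named stage draws its own
``numpy.random.SeedSequence`` child keyed by (master_seed, crc32(stage)).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .contact_analysis import (cluster_stages, contact_prob_curve,
                               delta_p_frames, delta_p_reference,
                               dendrogram_split_time, fit_pl_slope,
                               insulation_score, obs_over_exp,
                               tad_boundary_overlap)
from .dynamics import DynamicsParams
from .maps import ContactMap
from .maxent import (Landscape, MaxEntSchedule, contact_matrix,
                     estimate_contact_map, fit_landscape, sample_ensemble)
from .pathway import default_pca_bands, hysteresis_by_band
from .polymer import Conformation, PolymerParams
from .structure import (Q_BAND_LOCAL, mean_pairwise_distances, q_native,
                        radial_profile, radial_profile_diff,
                        shape_descriptors)
from .switching import SwitchRun, cluster_ensemble, run_switch
from .synthetic import TripletConfig, make_gene_density, make_state_triplet


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyConfig:
    """Desk-scale study settings (full-scale values live in the comments)."""

    n_bins: int = 120
    resolution_bp: int = 100_000
    master_seed: int = 7
    triplet: TripletConfig = field(default_factory=TripletConfig)
    dyn: DynamicsParams = field(default_factory=DynamicsParams)
    # 15 sweeps: the 120-bead fits plateau near Pearson 0.9 around sweep 10
    maxent: MaxEntSchedule = field(
        default_factory=lambda: MaxEntSchedule(sweeps=15))
    t_pre: float = 50.0        # full scale: 5000 tau
    t_post: float = 200.0      # full scale: 10000 tau
    n_runs: int = 10           # switching runs per direction
    ensemble_samples: int = 60  # equilibrium samples per state
    cluster_cutoff: float = 3.0
    cluster_pop_threshold: float = 0.003
    picks_per_cluster: int = 2
    n_stages: int = 8
    insulation_window: int = 5
    pl_band_bp: tuple = (500_000, 7_000_000)

    def replace(self, **kw) -> "StudyConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class StudyResult:
    config: StudyConfig
    triplet: object
    gene_track: object
    landscapes: dict            # state -> Landscape
    ensembles: dict             # state -> list[Conformation]
    reference_maps: dict        # state -> ContactMap (simulated ensemble map)
    forward_runs: list
    reverse_runs: list


def _fit_state(name: str, target: ContactMap, config: StudyConfig) -> Landscape:
    return fit_landscape(target, schedule=config.maxent,
                         seed=stage_seed(config.master_seed, f"fit:{name}"),
                         dyn=config.dyn, target_id=name)


def run_study(config: StudyConfig | None = None, verbose: bool = False) -> StudyResult:
    """Generate the synthetic states, fit all landscapes, and run the
    switching protocol in both directions."""
    config = config or StudyConfig()
    triplet = make_state_triplet(config.n_bins,
                                 stage_seed(config.master_seed, "triplet"),
                                 config.triplet)
    gene_track = make_gene_density(triplet.profile_normal,
                                   seed=stage_seed(config.master_seed, "genes"))

    landscapes, ensembles, reference_maps = {}, {}, {}
    for name, target in (("normal", triplet.normal), ("cancer", triplet.cancer),
                         ("es", triplet.es)):
        if verbose:
            print(f"fitting landscape: {name}")
        scape = _fit_state(name, target, config)
        landscapes[name] = scape
        ensembles[name] = sample_ensemble(
            scape, config.ensemble_samples,
            seed=stage_seed(config.master_seed, f"ensemble:{name}"),
            dyn=config.dyn, burn_in=10.0, spacing=2.0)
        reference_maps[name] = estimate_contact_map(
            ensembles[name], scape.params, target.segment)

    runs = {}
    for direction, pre, post in (("forward", "normal", "cancer"),
                                 ("reverse", "cancer", "normal")):
        if verbose:
            print(f"switching: {pre} -> {post}")
        clusters = cluster_ensemble(ensembles[pre], config.cluster_cutoff,
                                    config.cluster_pop_threshold,
                                    config.picks_per_cluster)
        runs[direction] = run_switch(
            clusters.representatives, landscapes[pre], landscapes[post],
            config.t_pre, config.t_post, config.dyn,
            master_seed=stage_seed(config.master_seed, f"switch:{direction}"),
            direction=f"{pre}->{post}", n_runs=config.n_runs)

    return StudyResult(config, triplet, gene_track, landscapes, ensembles,
                       reference_maps, runs["forward"], runs["reverse"])


# ---------------------------------------------------------------------------
# per-frame observables over a set of switching runs
# ---------------------------------------------------------------------------

def frame_contact_maps(runs, params: PolymerParams, segment,
                       phase: str = "post") -> list:
    """Run-averaged contact map at each snapshot of the chosen phase."""
    trajs = [getattr(r, f"{phase}_trajectory") for r in runs]
    n_frames = trajs[0].n_frames
    maps = []
    for k in range(n_frames):
        acc = None
        for t in trajs:
            cm = contact_matrix(Conformation(t.frames[k]), params)
            acc = cm if acc is None else acc + cm
        acc /= len(trajs)
        acc = np.clip(0.5 * (acc + acc.T), 0.0, 1.0)
        maps.append(ContactMap(acc, segment))
    return maps


def rg_time_series(runs, phase: str = "post") -> tuple:
    """(times, per-run Rg array of shape (n_runs, n_frames))."""
    trajs = [getattr(r, f"{phase}_trajectory") for r in runs]
    times = trajs[0].times
    rg = np.array([[shape_descriptors(Conformation(f)).Rg for f in t.frames]
                   for t in trajs])
    return times, rg


def radial_profile_series(runs, Rc: float, subset=None, phase: str = "post") -> list:
    """Radial profile per snapshot, pooling all runs at that snapshot."""
    trajs = [getattr(r, f"{phase}_trajectory") for r in runs]
    out = []
    for k in range(trajs[0].n_frames):
        frame_ensemble = [Conformation(t.frames[k]) for t in trajs]
        out.append(radial_profile(frame_ensemble, Rc, subset=subset))
    return out


# ---------------------------------------------------------------------------
# full analysis bundle
# ---------------------------------------------------------------------------

def analyze_study(study: StudyResult, verbose: bool = False) -> dict:
    """All transition statistics of a completed study."""
    config = study.config
    segment = study.triplet.normal.segment
    params = study.landscapes["normal"].params
    res = {"config": config}

    maps = {}
    for direction, runs in (("forward", study.forward_runs),
                            ("reverse", study.reverse_runs)):
        maps[direction] = frame_contact_maps(runs, params, segment)
    res["frame_maps"] = maps
    times_post = study.forward_runs[0].post_trajectory.times
    res["times_post"] = times_post

    # stage reduction and local vs non-local separation times (forward)
    res["stages"] = {}
    res["split_times"] = {}
    res["delta_frames"] = {}
    for direction in ("forward", "reverse"):
        dl = delta_p_frames(maps[direction], "local")
        dn = delta_p_frames(maps[direction], "nonlocal")
        res["delta_frames"][direction] = {"local": dl, "nonlocal": dn}
        res["stages"][direction] = cluster_stages(dl, dn, config.n_stages)
        res["split_times"][direction] = {
            "local": dendrogram_split_time(dl, times_post),
            "nonlocal": dendrogram_split_time(dn, times_post),
        }

    # similarity to the three reference states over time
    res["delta_p_ref"] = {}
    for direction in ("forward", "reverse"):
        res["delta_p_ref"][direction] = {
            state: delta_p_reference(maps[direction], study.reference_maps[state])
            for state in ("normal", "cancer", "es")}

    # expansion: Rg paths and endpoint means
    res["rg"] = {}
    for direction, runs in (("forward", study.forward_runs),
                            ("reverse", study.reverse_runs)):
        _, rg_post = rg_time_series(runs, "post")
        _, rg_pre = rg_time_series(runs, "pre")
        res["rg"][direction] = {
            "times": times_post, "post_mean": rg_post.mean(axis=0),
            "post_runs": rg_post, "pre_mean": float(rg_pre[:, -10:].mean()),
        }
    res["rg_state"] = {
        state: float(np.mean([shape_descriptors(c).Rg
                              for c in study.ensembles[state]]))
        for state in ("normal", "cancer", "es")}

    # radial-density similarity to the reference states
    Rc = params.Rc
    ref_profiles = {state: radial_profile(study.ensembles[state], Rc)
                    for state in ("normal", "cancer", "es")}
    res["radial_reference"] = ref_profiles
    res["delta_rho"] = {}
    for direction, runs in (("forward", study.forward_runs),
                            ("reverse", study.reverse_runs)):
        series = radial_profile_series(runs, Rc)
        res["delta_rho"][direction] = {
            state: np.array([radial_profile_diff(p, ref_profiles[state])
                             for p in series])
            for state in ("normal", "cancer", "es")}

    # native-contact similarity Q to both end states (local band)
    res_bp = segment.resolution_bp
    q_refs = {state: mean_pairwise_distances(study.ensembles[state])
              for state in ("normal", "cancer")}
    res["q_local"] = {}
    for direction, runs in (("forward", study.forward_runs),
                            ("reverse", study.reverse_runs)):
        trajs = [r.post_trajectory for r in runs]
        res["q_local"][direction] = {
            state: np.array([
                np.mean([q_native(Conformation(t.frames[k]), q_refs[state],
                                  band=Q_BAND_LOCAL, resolution_bp=res_bp)
                         for t in trajs])
                for k in range(trajs[0].n_frames)])
            for state in ("normal", "cancer")}

    # contact-evolution PCA and hysteresis per band
    oe_fwd = [obs_over_exp(m) for m in maps["forward"]]
    oe_rev = [obs_over_exp(m) for m in maps["reverse"]]
    endpoints = {state: obs_over_exp(study.reference_maps[state])
                 for state in ("normal", "cancer", "es")}
    bands = default_pca_bands(config.n_bins, config.resolution_bp)
    res["pca_bands"] = bands
    res["hysteresis"] = hysteresis_by_band(oe_fwd, oe_rev, bands, endpoints)

    # P(l) slope through time (forward) and for the states
    res["pl_slope"] = {}
    for name, cmap in (("normal", study.triplet.normal),
                       ("cancer", study.triplet.cancer),
                       ("es", study.triplet.es)):
        l_bp, p = contact_prob_curve(cmap)
        res["pl_slope"][name] = fit_pl_slope(l_bp, p, config.pl_band_bp)

    return res


# ---------------------------------------------------------------------------
# persisted pipeline
# ---------------------------------------------------------------------------

def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: StudyConfig | None = None, outdir="pipeline_out",
                 verbose: bool = False) -> dict:
    """Run the full study, write every artifact under ``outdir`` and return
    the analysis bundle.  Identical config and master seed reproduce
    identical outputs (the manifest records content hashes)."""
    config = config or StudyConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = run_study(config, verbose=verbose)
    analysis = analyze_study(study, verbose=verbose)

    manifest = {"master_seed": config.master_seed,
                "n_bins": config.n_bins, "hashes": {}}
    for name in ("normal", "cancer", "es"):
        cio.write_contact_map(getattr(study.triplet, name), out / f"{name}.tsv")
        cio.save_landscape(study.landscapes[name], out / f"{name}.landscape.npz")
        manifest["hashes"][f"map:{name}"] = _sha(getattr(study.triplet, name).probs)
        manifest["hashes"][f"alpha:{name}"] = _sha(study.landscapes[name].alpha)
    cio.write_gene_track(study.gene_track, study.triplet.normal.segment,
                         out / "genes.bed")

    for direction, runs in (("forward", study.forward_runs),
                            ("reverse", study.reverse_runs)):
        rundir = out / direction
        rundir.mkdir(exist_ok=True)
        for i, r in enumerate(runs):
            cio.save_trajectory(r.post_trajectory, rundir / f"run{i:03d}.npz")
        manifest["hashes"][f"runs:{direction}"] = _sha(
            np.concatenate([r.post_trajectory.frames.ravel() for r in runs]))

    # analysis exports
    times = analysis["times_post"]
    for direction in ("forward", "reverse"):
        stages = analysis["stages"][direction]
        cols = [times, stages.frame_to_stage,
                analysis["rg"][direction]["post_mean"]]
        names = ["time_tau", "stage", "rg_mean"]
        for state in ("normal", "cancer", "es"):
            cols.append(analysis["delta_p_ref"][direction][state])
            names.append(f"delta_p_{state}")
            cols.append(analysis["delta_rho"][direction][state])
            names.append(f"delta_rho_{state}")
        table = np.column_stack(cols)
        np.savetxt(out / f"{direction}_timecourse.tsv", table,
                   delimiter="\t", header="\t".join(names), comments="")

    hysteresis = {
        f"{h.band[0]}-{h.band[1]}bins": h.omega for h in analysis["hysteresis"]}
    (out / "hysteresis.json").write_text(json.dumps(hysteresis, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    analysis["manifest"] = manifest
    analysis["study"] = study
    return analysis
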