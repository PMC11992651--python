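"""End-to-end analysis pipeline over synthetic or file-based inputs.

Stage order: simulate → loops → cluster → repstruct → dockselect →
contacts → energystats → report.  Every stage reads its inputs from,
and writes its outputs to, the run's output directory; files are the
only inter-stage contract, so re-running any single stage from the
persisted intermediates reproduces the end-to-end result.

The study-design planner reproduces the sampling bookkeeping implied by
the configuration: pre-docking systems × replicates × simulation
length, docking-run count, post-docking sampling, and the per-frame
energy-record count over the analysis window.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conformational_clustering as cc
from . import energetics_stats as es
from . import geometry_metrics as gm
from . import interface_analysis as ia
from . import structure_io as sio
from . import synthetic_data as sd

__all__ = [
    "PipelineConfig",
    "validate_config",
    "study_plan",
    "run_pipeline",
    "STAGES",
]

logger = logging.getLogger("cdrflex.pipeline")

STAGES = (
    "simulate",
    "loops",
    "cluster",
    "repstruct",
    "dockselect",
    "contacts",
    "energystats",
    "report",
)

VARIANTS = ("WT", "R47H")
ISOFORMS = ("E2", "E3", "E4")
CONFORMATIONS = ("A", "B", "C")


@dataclass
class PipelineConfig:
    """Validated pipeline parameters.

    Defaults are the study conditions: analysis window 450-500 ns
    sampled every 0.5 ns (101 frames per complex), 4.0 Å contact
    cutoff, 2 receptor variants × 3 replicates pre-docking, and
    3 cluster representatives × 3 partner isoforms = 18 docked
    complexes.
    """

    out_dir: Path = Path("cdrflex_run")
    seed: int = 0
    # analysis window (ns)
    t_start: float = 450.0
    t_end: float = 500.0
    dt: float = 0.5
    contact_cutoff: float = 4.0
    # pre-docking simulation block
    n_replicates: int = 3
    pre_frames: int = 400
    pre_dt: float = 0.5
    pre_sim_length_us: float = 1.0   # nominal production length per replicate
    post_sim_length_us: float = 0.5  # nominal length per docked complex
    # two-state loop dynamics per variant: flexible WT, rigid R47H
    loop_params: dict = field(default_factory=lambda: {
        "WT": {"mu_closed": 10.0, "mu_open": 16.0, "sigma": 0.8,
               "switch_prob": 0.01},
        "R47H": {"mu_closed": 10.0, "mu_open": 16.0, "sigma": 0.5,
                 "switch_prob": 0.002},
    })
    # docking stage
    n_dock_candidates: int = 5
    dock_exclusions: dict = field(default_factory=dict)
    # energy stage: per-cluster mean shifts (kcal/mol)
    energy_base: dict = field(default_factory=lambda: {
        "E2": -28.0, "E3": -30.0, "E4": -38.0})
    energy_variant_shift: dict = field(default_factory=lambda: {
        "WT": 0.0, "R47H": 8.0})
    energy_cluster_shift: dict = field(default_factory=lambda: {
        "A": 4.0, "B": 0.0, "C": -2.0})
    energy_sd: float = 5.0
    # rank-concordance input: per-isoform 1/K_D on an arbitrary scale
    inverse_affinities: dict = field(default_factory=lambda: {
        "E2": 1.0, "E3": 1.3, "E4": 3.0})
    # secondary-structure stage (motif composition per isoform)
    ss_frames: int = 20
    ss_jitter_deg: float = 5.0
    ss_composition: dict = field(default_factory=lambda: {
        "E2": {"rh_helix": 18, "beta": 2},
        "E3": {"rh_helix": 16, "beta": 4},
        "E4": {"rh_helix": 12, "beta": 8},
    })
    # literature interface residues for overlap reporting (optional)
    literature_residues: list = field(default_factory=list)
    # alternative to synthetic simulation: paths to multi-model PDBs
    trajectory_paths: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.loop_params)

    @property
    def n_pre_systems(self) -> int:
        # receptor variants plus one system per partner isoform
        return self.n_variants + len(ISOFORMS)

    @property
    def n_dock_runs(self) -> int:
        return self.n_variants * len(CONFORMATIONS) * len(ISOFORMS)


def validate_config(data: dict | str) -> tuple[PipelineConfig | None, list[str]]:
    """Build a PipelineConfig from a TOML string or mapping.

    Collects every validation error instead of failing fast; returns
    ``(config, [])`` on success or ``(None, errors)``.  Unset fields are
    filled with defaults and logged.
    """
    import tomllib

    if isinstance(data, str):
        try:
            data = tomllib.loads(data)
        except tomllib.TOMLDecodeError as exc:
            return None, [f"TOML parse error: {exc}"]

    errors: list[str] = []
    cfg = PipelineConfig()
    known = set(cfg.__dataclass_fields__)
    for key, value in data.items():
        if key not in known:
            errors.append(f"unknown config key {key!r}")
            continue
        if key == "out_dir":
            value = Path(value)
        setattr(cfg, key, value)
    for key in known - set(data):
        logger.info("config: %s defaulted to %r", key, getattr(cfg, key))

    if cfg.contact_cutoff <= 0:
        errors.append("contact_cutoff must be positive")
    if cfg.dt <= 0:
        errors.append("dt must be positive")
    elif cfg.t_end <= cfg.t_start:
        errors.append("t_end must exceed t_start")
    else:
        try:
            es.window_frame_times(cfg.t_start, cfg.t_end, cfg.dt)
        except ValueError as exc:
            errors.append(f"analysis window: {exc}")
    if cfg.n_replicates < 1:
        errors.append("n_replicates must be at least 1")
    if cfg.pre_frames < 2:
        errors.append("pre_frames must be at least 2")
    if cfg.trajectory_paths and "simulate_block" in data:
        errors.append("give either trajectory_paths or synthetic simulation, not both")
    if cfg.trajectory_paths:
        if not isinstance(cfg.trajectory_paths, dict) or not cfg.trajectory_paths:
            errors.append("trajectory_paths must map variant -> list of paths")
    for variant, params in cfg.loop_params.items():
        try:
            sd.LoopDynamicsParams(n_frames=max(2, cfg.pre_frames), **params)
        except (TypeError, ValueError) as exc:
            errors.append(f"loop_params[{variant}]: {exc}")
    if cfg.n_dock_candidates < 1:
        errors.append("n_dock_candidates must be at least 1")
    if cfg.energy_sd <= 0:
        errors.append("energy_sd must be positive")
    if errors:
        return None, errors
    return cfg, []


def study_plan(config: PipelineConfig) -> dict:
    """Sampling-design bookkeeping implied by the configuration.

    With the defaults: 5 pre-docking systems × 3 replicates × 1 µs
    = 15 µs; 18 docking runs (6 receptor structures × 3 isoforms);
    18 complexes × 0.5 µs = 9 µs post-docking; 101 energy frames per
    complex over the 450-500 ns window at 0.5 ns → 1818 records total,
    909 per receptor variant.
    """
    window = es.window_frame_times(config.t_start, config.t_end, config.dt)
    frames_per_complex = len(window)
    n_dock = config.n_dock_runs
    per_variant_complexes = len(CONFORMATIONS) * len(ISOFORMS)
    return {
        "n_pre_systems": config.n_pre_systems,
        "n_replicates": config.n_replicates,
        "pre_sampling_us": config.n_pre_systems * config.n_replicates
        * config.pre_sim_length_us,
        "n_dock_runs": n_dock,
        "n_complexes": n_dock,
        "post_sampling_us": n_dock * config.post_sim_length_us,
        "energy_frames_per_complex": frames_per_complex,
        "n_energy_records": n_dock * frames_per_complex,
        "n_energy_records_per_variant": per_variant_complexes * frames_per_complex,
    }


# ---------------------------------------------------------------------------
# stage helpers

def _rng(config: PipelineConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


def _traj_path(out: Path, variant: str, rep: int) -> Path:
    return out / f"traj_{variant}_rep{rep}.pdb"


LOOP2_ANCHORS = ((("A", sd.CORE_SIZE + 1), ("A", sd.CORE_SIZE + sd.LOOP_SIZE)))
LOOP1_ANCHORS = (("A", sd.ANCHOR_CORE_RESIDUE), ("A", sd.ANCHOR_LOOP_RESIDUE))


def stage_simulate(config: PipelineConfig) -> None:
    """Generate (or verify presence of) pre-docking loop trajectories."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.trajectory_paths:
        # real inputs: copy through so downstream stages have one location
        for variant, paths in config.trajectory_paths.items():
            for rep, src in enumerate(paths):
                text = Path(src).read_text()
                sio.read_multimodel_pdb(text, frame_dt=config.pre_dt)  # validate
                _traj_path(out, variant, rep).write_text(text)
        return
    for vi, (variant, lp) in enumerate(sorted(config.loop_params.items())):
        for rep in range(config.n_replicates):
            params = sd.LoopDynamicsParams(
                n_frames=config.pre_frames,
                dt=config.pre_dt,
                seed=int(_rng(config, 0, vi, rep).integers(2**31)),
                **lp,
            )
            traj, labels = sd.generate_two_state_loop_trajectory(params)
            with open(_traj_path(out, variant, rep), "w") as fh:
                sio.write_multimodel_pdb(traj, fh)
            pd.DataFrame({"time_ns": traj.times, "state": labels}).to_csv(
                out / f"states_{variant}_rep{rep}.csv", index=False
            )
    logger.info("simulate: wrote %d trajectories",
                config.n_variants * config.n_replicates)


def _load_trajectories(config: PipelineConfig) -> dict[tuple[str, int], sio.Trajectory]:
    out = Path(config.out_dir)
    trajs: dict[tuple[str, int], sio.Trajectory] = {}
    variants = sorted(config.trajectory_paths or config.loop_params)
    for variant in variants:
        n_rep = (len(config.trajectory_paths[variant])
                 if config.trajectory_paths else config.n_replicates)
        for rep in range(n_rep):
            path = _traj_path(out, variant, rep)
            if not path.exists():
                raise FileNotFoundError(
                    f"stage 'loops' needs {path}; run 'simulate' first"
                )
            with open(path) as fh:
                trajs[(variant, rep)] = sio.read_multimodel_pdb(fh, frame_dt=config.pre_dt)
    return trajs


def stage_loops(config: PipelineConfig) -> None:
    """Loop 1 / Loop 2 distance series and the inter-loop regression."""
    out = Path(config.out_dir)
    rows = []
    fits = []
    for (variant, rep), traj in _load_trajectories(config).items():
        loop1 = gm.pair_distance_series(traj, *LOOP1_ANCHORS)
        loop2 = gm.pair_distance_series(traj, *LOOP2_ANCHORS)
        series = gm.LoopMetricSeries(traj.times, loop1, loop2,
                                     variant=variant, replicate=str(rep))
        rows.append(series.to_frame())
        slope, intercept, r2 = gm.fit_linear(loop1, loop2)
        fits.append({"variant": variant, "replicate": rep,
                     "slope": slope, "intercept": intercept, "r_squared": r2})
    pd.concat(rows, ignore_index=True).to_csv(out / "loop_metrics.csv", index=False)
    with open(out / "loop_regressions.json", "w") as fh:
        json.dump(fits, fh, indent=2)
    logger.info("loops: %d series", len(rows))


def stage_cluster(config: PipelineConfig) -> None:
    """Pooled per-variant loop statistics and A/B/C assignments."""
    out = Path(config.out_dir)
    metrics = pd.read_csv(out / "loop_metrics.csv")
    stats_out = {}
    frames = []
    for variant, grp in metrics.groupby("variant"):
        stats = cc.loop_stats([g["loop1_A"].to_numpy()
                               for _, g in grp.groupby("replicate")],
                              variant=variant)
        stats_out[variant] = {"mean": stats.mean, "sd": stats.sd,
                              "n_frames": stats.n_frames}
        for rep, g in grp.groupby("replicate"):
            assignment = cc.assign_clusters(g["loop1_A"].to_numpy(), stats)
            sub = g[["time_ns", "loop1_A"]].copy()
            sub["variant"] = variant
            sub["replicate"] = rep
            sub["cluster"] = assignment.labels
            frames.append(sub)
    assigned = pd.concat(frames, ignore_index=True)
    assigned.to_csv(out / "cluster_assignments.csv", index=False)
    occupancy = {
        variant: {
            lab: int((grp["cluster"] == lab).sum()) for lab in cc.CLUSTER_LABELS
        }
        for variant, grp in assigned.groupby("variant")
    }
    with open(out / "loop_stats.json", "w") as fh:
        json.dump({"stats": stats_out, "occupancy": occupancy}, fh, indent=2)
    logger.info("cluster: occupancy %s", occupancy)


MAX_MEDOID_MEMBERS = 40  # pairwise-RMSD medoid cost is quadratic; subsample beyond this


def stage_repstruct(config: PipelineConfig) -> None:
    """Medoid representative per (variant, cluster), exported as PDB."""
    out = Path(config.out_dir)
    assigned = pd.read_csv(out / "cluster_assignments.csv")
    trajs = _load_trajectories(config)
    reps: dict[str, dict] = {}
    for variant in sorted(assigned["variant"].unique()):
        reps[variant] = {}
        # medoid is taken within each variant's first replicate so a frame
        # index maps to one trajectory
        rep0 = assigned[(assigned["variant"] == variant)
                        & (assigned["replicate"] == 0)].reset_index(drop=True)
        traj = trajs[(variant, 0)]
        selection = list(traj.topology.residues)
        for label in cc.CLUSTER_LABELS:
            members = rep0.index[rep0["cluster"] == label].to_list()
            if not members:
                reps[variant][label] = None
                continue
            if len(members) > MAX_MEDOID_MEMBERS:
                stride = int(np.ceil(len(members) / MAX_MEDOID_MEMBERS))
                members = members[::stride]
            frame = cc.select_representative(traj, members, selection)
            reps[variant][label] = int(frame)
            with open(out / f"repr_{variant}_{label}.pdb", "w") as fh:
                sio.write_pdb(traj.frame_structure(frame), fh)
    with open(out / "representatives.json", "w") as fh:
        json.dump(reps, fh, indent=2)
    logger.info("repstruct: %s", reps)


def _complex_list(config: PipelineConfig) -> list[tuple[str, str, str]]:
    variants = sorted(config.loop_params)
    return [(v, c, iso) for v in variants for c in CONFORMATIONS for iso in ISOFORMS]


def stage_dockselect(config: PipelineConfig) -> None:
    """Generate candidate poses per docking run, score, rank and select."""
    out = Path(config.out_dir)
    scheme = sio.default_region_scheme()
    n_cdr = 26
    report = []
    for run_idx, (variant, conf, iso) in enumerate(_complex_list(config)):
        rng = _rng(config, 1, run_idx)
        scores = []
        poses = {}
        for cand in range(config.n_dock_candidates):
            k = int(rng.integers(0, n_cdr + 1))
            pose = sd.generate_complex_pose(
                n_query_residues=n_cdr, k_in_contact=k,
                cutoff=config.contact_cutoff,
                seed=int(rng.integers(2**31)),
            )
            model_id = f"{variant}-{conf}_{iso}_m{cand}"
            score = ia.cdr_hinge_fraction(
                pose, scheme, cutoff=config.contact_cutoff, model_id=model_id
            )
            scores.append(score)
            poses[model_id] = pose
        ordered, selected = ia.rank_dock_models(
            scores, exclusions=config.dock_exclusions
        )
        receptor, partner = poses[selected.model_id]
        with open(out / f"pose_{variant}-{conf}_{iso}.pdb", "w") as fh:
            fh.write(sio.write_pdb(receptor))
            fh.write(sio.write_pdb(partner))
        report.append({
            "complex": f"{variant}-{conf}/{iso}",
            "selected": selected.model_id,
            "fraction": selected.fraction,
            "ranking": [
                {"model": m.model_id, "fraction": m.fraction,
                 "excluded": m.excluded, "reason": m.exclusion_reason}
                for m in ordered
            ],
        })
    with open(out / "dock_selection.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("dockselect: %d runs", len(report))


def stage_contacts(config: PipelineConfig) -> None:
    """Contact maps (and optional literature overlap) for selected poses."""
    out = Path(config.out_dir)
    scheme = sio.default_region_scheme()
    overlaps = {}
    for variant, conf, iso in _complex_list(config):
        tag = f"{variant}-{conf}_{iso}"
        text = (out / f"pose_{tag}.pdb").read_text()
        # the pose file holds two single-model structures back to back
        part_a, part_b = text.split("END\n")[:2]
        receptor = sio.read_pdb(part_a + "END\n")
        partner = sio.read_pdb(part_b + "END\n")
        cdr = [r for name in ia.CDR_REGION_NAMES
               for r in sio.select_region(receptor, scheme, name).residues]
        hinge = list(sio.select_region(partner, scheme, ia.HINGE_FILTER_REGION).residues)
        cmap = ia.residue_min_distance_map(receptor, cdr, partner, hinge)
        long = cmap.to_frame()
        long["in_contact"] = long["min_dist_A"] <= config.contact_cutoff
        long.to_csv(out / f"contacts_{tag}.csv", index=False)
        if config.literature_residues:
            observed = {int(ra[1:]) for ra, flag
                        in zip(long["res_a"], long["in_contact"]) if flag}
            if observed or config.literature_residues:
                try:
                    count, jaccard = ia.residue_set_overlap(
                        observed, set(config.literature_residues)
                    )
                    overlaps[tag] = {"intersection": count, "jaccard": jaccard}
                except ValueError:
                    overlaps[tag] = {"intersection": 0, "jaccard": None}
    if overlaps:
        with open(out / "literature_overlap.json", "w") as fh:
            json.dump(overlaps, fh, indent=2)
    logger.info("contacts: wrote maps for %d complexes", len(_complex_list(config)))


def stage_energystats(config: PipelineConfig) -> None:
    """Synthesize windowed energy tables, classify, and run the statistics."""
    out = Path(config.out_dir)
    with open(out / "loop_stats.json") as fh:
        stats_doc = json.load(fh)
    window = es.window_frame_times(config.t_start, config.t_end, config.dt)
    n_frames = len(window)

    tables = []
    for run_idx, (variant, conf, iso) in enumerate(_complex_list(config)):
        rng = _rng(config, 2, run_idx)
        vstat = stats_doc["stats"][variant]
        occ_info = stats_doc["occupancy"][variant]
        total = sum(occ_info.values())
        fractions = np.array([occ_info[lab] / total for lab in cc.CLUSTER_LABELS])
        counts = rng.multinomial(n_frames, fractions)
        means = {
            lab: config.energy_base[iso]
            + config.energy_variant_shift[variant]
            + config.energy_cluster_shift[lab]
            for lab in cc.CLUSTER_LABELS
        }
        params = sd.EnergyTableParams(
            cluster_means=means,
            cluster_sds={lab: config.energy_sd for lab in cc.CLUSTER_LABELS},
            occupancies=dict(zip(cc.CLUSTER_LABELS, (int(c) for c in counts))),
            seed=int(rng.integers(2**31)),
        )
        table = sd.generate_energy_table(
            params,
            loop_stats=(vstat["mean"], vstat["sd"]),
            t_start=config.t_start,
            dt=config.dt,
            complex_id=f"{variant}-{conf}/{iso}",
            trem2_variant=variant,
            trem2_conformation=conf,
            apoe_isoform=iso,
        )
        stats = cc.LoopStats(vstat["mean"], vstat["sd"],
                             vstat["n_frames"], variant)
        classified = es.classify_energy_frames(
            table[["time_ns", "complex_id", "trem2_variant",
                   "trem2_conformation", "apoe_isoform", "energy_kcal_mol"]],
            table[["time_ns", "loop1_A"]],
            stats,
        )
        tables.append(classified)
    records = pd.concat(tables, ignore_index=True)
    records.to_csv(out / "energy_records.csv", index=False)

    summaries = es.summarize_groups(records)
    pd.DataFrame(
        [{"group": "/".join(map(str, s.key)), "n": s.n, "mean": s.mean,
          "sd": s.sd, "sem": s.sem, "min": s.minimum, "max": s.maximum}
         for s in summaries]
    ).to_csv(out / "group_summaries.csv", index=False)

    stats_report: dict = {"anova": {}, "tukey": {}}
    for variant, grp in records.groupby("trem2_variant"):
        anova = es.two_way_anova(grp, "cluster", "apoe_isoform")
        stats_report["anova"][variant] = {
            effect: {"F": None if np.isnan(row["F"]) else float(row["F"]),
                     "p": None if np.isnan(row["p"]) else float(row["p"]),
                     "df": float(row["df"])}
            for effect, row in anova.iterrows()
        }
        tukey = es.tukey_kramer(grp, grouping=["apoe_isoform", "cluster"])
        stats_report["tukey"][variant] = tukey.to_dict(orient="records")

    ensemble = {}
    mp = {}
    for cid, grp in records.groupby("complex_id"):
        cluster_summaries = es.summarize_groups(grp, keys=["cluster"])
        ensemble[cid] = es.weighted_cluster_mean(cluster_summaries)
        top = es.mp_cluster(cluster_summaries)
        mp[cid] = {"cluster": top.key[0], "mean": top.mean, "n": top.n}
    stats_report["ensemble_energies"] = ensemble
    stats_report["mp_clusters"] = mp

    # rank concordance per variant: MP-cluster energies averaged per isoform
    concordance = {}
    for variant in sorted(config.loop_params):
        per_iso = {}
        for iso in ISOFORMS:
            vals = [mp[cid]["mean"] for cid in mp
                    if cid.startswith(f"{variant}-") and cid.endswith(f"/{iso}")]
            per_iso[iso] = float(np.mean(vals))
        try:
            concordance[variant] = es.rank_concordance(
                per_iso, config.inverse_affinities
            )
        except ValueError:
            concordance[variant] = None
    stats_report["rank_concordance"] = concordance

    with open(out / "energy_stats.json", "w") as fh:
        json.dump(stats_report, fh, indent=2)
    logger.info("energystats: %d records", len(records))


def stage_ss(config: PipelineConfig) -> None:
    """Secondary-structure counting on synthetic motif-angle sets."""
    out = Path(config.out_dir)
    results = {}
    for iso_idx, iso in enumerate(ISOFORMS):
        comp = config.ss_composition.get(iso)
        if not comp:
            continue
        frames = []
        for f in range(config.ss_frames):
            angles, _ = sd.generate_phi_psi_set(
                comp, jitter_deg=config.ss_jitter_deg,
                seed=int(_rng(config, 3, iso_idx, f).integers(2**31)),
            )
            n = len(angles)
            frames.append(pd.DataFrame({
                "frame": f,
                "time_ns": f * config.dt,
                "residue_number": np.arange(1, n + 1),
                "phi": angles[:, 0],
                "psi": angles[:, 1],
            }))
        table = pd.concat(frames, ignore_index=True)
        counts = gm.count_ss_residues(table, region_name=f"{iso}_hinge")
        results[iso] = {m: float(v) for m, v in counts.window_means.items()}
    with open(out / "ss_counts.json", "w") as fh:
        json.dump(results, fh, indent=2)


def stage_report(config: PipelineConfig) -> dict:
    """Aggregate stage outputs into the machine-readable run report."""
    out = Path(config.out_dir)
    report: dict = {
        "config": {
            "seed": config.seed,
            "window_ns": [config.t_start, config.t_end, config.dt],
            "contact_cutoff_A": config.contact_cutoff,
            "n_replicates": config.n_replicates,
            "pre_frames": config.pre_frames,
        },
        "plan": study_plan(config),
        "stages": {},
    }
    loaders = {
        "loop_stats": "loop_stats.json",
        "representatives": "representatives.json",
        "dock_selection": "dock_selection.json",
        "energy_stats": "energy_stats.json",
        "ss_counts": "ss_counts.json",
    }
    for key, fname in loaders.items():
        path = out / fname
        if path.exists():
            with open(path) as fh:
                report["stages"][key] = json.load(fh)
        else:
            report["stages"][key] = "skipped"
    if (out / "energy_records.csv").exists():
        records = pd.read_csv(out / "energy_records.csv")
        report["n_energy_records"] = int(len(records))
        report["n_energy_records_per_variant"] = {
            v: int(n) for v, n in records["trem2_variant"].value_counts().items()
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "loops": stage_loops,
    "cluster": stage_cluster,
    "repstruct": stage_repstruct,
    "dockselect": stage_dockselect,
    "contacts": stage_contacts,
    "energystats": stage_energystats,
    "ss": stage_ss,
    "report": stage_report,
}


def run_stage(config: PipelineConfig, stage: str):
    """Run one named stage against the persisted intermediates."""
    if stage not in _STAGE_FUNCS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGE_FUNCS)}")
    try:
        return _STAGE_FUNCS[stage](config)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the final run report."""
    for stage in ("simulate", "loops", "cluster", "repstruct",
                  "dockselect", "contacts", "energystats", "ss"):
        logger.info("running stage %s", stage)
        run_stage(config, stage)
    return stage_report(config)
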