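"""End-to-end orchestration: simulate/ingest -> QC -> connectome ->
harmonize -> age effects -> trajectories -> graph, with a validated
config, deterministic seeding and a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome, effects as effects_mod, graph as graph_mod, harmonize, qc, synthetic, trajectory

log = logging.getLogger("fconntraj")


class ConfigError(ValueError):
    pass


@dataclass
class StageToggles:
    qc: bool = True
    harmonize: bool = True
    age_effects: bool = True
    trajectories: bool = True
    graph: bool = True
    fetal_only: bool = True
    infant_only: bool = True


@dataclass
class Thresholds:
    fdr_q: float = 0.05
    dice_min: float = qc.DICE_MIN
    infant_dvars: float = qc.INFANT_DVARS
    top_proportion: float = 0.15
    min_frames: int = qc.MIN_FRAMES

    def validate(self):
        if not 0 < self.fdr_q <= 1:
            raise ConfigError("thresholds.fdr_q must lie in (0, 1]")
        if not 0 <= self.dice_min <= 1:
            raise ConfigError("thresholds.dice_min must lie in [0, 1]")
        if not 0 < self.top_proportion <= 1:
            raise ConfigError("thresholds.top_proportion must lie in (0, 1]")
        if self.min_frames < 0:
            raise ConfigError("thresholds.min_frames must be nonnegative")
        if self.infant_dvars <= 0:
            raise ConfigError("thresholds.infant_dvars must be positive")


@dataclass
class SimulationSettings:
    n_subjects: int = 140
    n_parcels: int = 40
    n_networks: int = 4
    subject_sd: float = 0.1
    residual_sd: float = 0.1
    batch_effects: bool = True
    spike_fraction: float = 0.1  # fraction of sessions given motion spikes
    n_frames: int = 160


@dataclass
class Paths:
    cohort: str | None = None
    edges: str | None = None
    atlas: str | None = None
    out_dir: str = "fconntraj_out"


@dataclass
class PipelineConfig:
    paths: Paths = field(default_factory=Paths)
    stages: StageToggles = field(default_factory=StageToggles)
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    seed: int = 0

    def validate(self):
        self.thresholds.validate()
        for name in ("cohort", "edges", "atlas"):
            p = getattr(self.paths, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"paths.{name} does not exist: {p}")


_SECTIONS = {
    "paths": Paths,
    "stages": StageToggles,
    "thresholds": Thresholds,
    "simulation": SimulationSettings,
}


def validate_config(raw) -> PipelineConfig:
    """Parse + validate a config mapping or YAML text; defaults filled.

    Unknown keys are rejected with their key paths.
    """
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw) or {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key == "seed":
            if not isinstance(val, int):
                raise ConfigError("seed must be an integer")
            cfg.seed = val
        elif key in _SECTIONS:
            section = getattr(cfg, key)
            if not isinstance(val, dict):
                raise ConfigError(f"{key} must be a mapping")
            for k, v in val.items():
                if not hasattr(section, k):
                    raise ConfigError(f"unknown config key: {key}.{k}")
                default = getattr(section, k)
                if default is not None and v is not None and not isinstance(
                    v, (type(default), int) if isinstance(default, float) else type(default)
                ):
                    raise ConfigError(f"wrong type for {key}.{k}: expected {type(default).__name__}")
                setattr(section, k, v)
        else:
            raise ConfigError(f"unknown config key: {key}")
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["outputs"][path.name] = {"rows": int(len(df)), "sha256": _sha256(path)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write all report tables.

    Returns the run manifest (also written to out_dir/manifest.json).
    Identical config + seed produces byte-identical outputs.
    """
    config.validate()
    out = Path(config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    rng = np.random.default_rng(config.seed)
    sim = config.simulation
    thr = config.thresholds

    # ---- simulate or ingest -------------------------------------------------
    if config.paths.cohort and config.paths.edges:
        log.info("[ingest] reading cohort and edge tables")
        cohort = pd.read_csv(config.paths.cohort)
        edges = pd.read_csv(config.paths.edges, sep="\t").to_numpy(dtype=float)
        truths = None
        manifest["stages"].append("ingest")
    else:
        log.info("[simulate] generating synthetic cohort and edge data")
        spec = synthetic.CohortSpec(
            n_subjects=sim.n_subjects,
            n_parcels=sim.n_parcels,
            n_networks=sim.n_networks,
            seed=int(rng.integers(2**31)),
        )
        cohort = synthetic.make_cohort(spec)
        E = connectome.n_edges(sim.n_parcels)
        truths = synthetic.make_edge_truths(E, seed=int(rng.integers(2**31)))
        if sim.batch_effects:
            batch_rng = np.random.default_rng(int(rng.integers(2**31)))
            add = {b: float(batch_rng.normal(0, 0.1)) for b in spec.batch_labels}
            mult = {b: float(batch_rng.uniform(0.8, 1.25)) for b in spec.batch_labels}
            add = {b: v for b, v in add.items() if b in set(cohort["sequence_id"])}
            mult = {b: v for b, v in mult.items() if b in set(cohort["sequence_id"])}
        else:
            add, mult = {}, {}
        noise = synthetic.NoiseModel(
            subject_sd=sim.subject_sd,
            residual_sd=sim.residual_sd,
            batch_additive=add,
            batch_multiplicative=mult,
        )
        ds = synthetic.simulate_connectomes(cohort, truths, noise, seed=int(rng.integers(2**31)))
        edges = ds.edges
        _write(cohort, out / "cohort.csv", manifest)
        (out / "ground_truth.json").write_text(ds.to_json_sidecar())
        manifest["stages"].append("simulate")
    atlas = (
        connectome.Atlas.from_csv(config.paths.atlas)
        if config.paths.atlas
        else connectome.Atlas.synthetic(sim.n_parcels, sim.n_networks)
    )

    # ---- qc -----------------------------------------------------------------
    if config.stages.qc:
        log.info("[qc] censoring and scan exclusion")
        qc_rows = []
        keep_sessions = np.ones(len(cohort), dtype=bool)
        qc_seed = int(rng.integers(2**31))
        for s in range(len(cohort)):
            srng = np.random.default_rng((qc_seed + s) % 2**31)
            spikes = (
                srng.choice(sim.n_frames, size=srng.integers(1, 6), replace=False)
                if srng.random() < sim.spike_fraction
                else []
            )
            scan = synthetic.simulate_timeseries(
                sim.n_frames, sim.n_parcels, spikes, seed=int(srng.integers(2**31))
            )
            fd = qc.framewise_displacement(scan.motion)
            dv = qc.dvars(scan.timeseries)
            if cohort.iloc[s]["cohort"] == "fetal":
                dc = np.array([qc.dice(m, scan.reference_mask) for m in scan.masks])
                cres = qc.censor_fetal(dc, fd, dv, qc.CensorPolicy(dice_min=thr.dice_min))
            else:
                cres = qc.censor_infant(dv, threshold=thr.infant_dvars)
            decision = qc.exclude_scan(cres, scan.motion, min_frames=thr.min_frames)
            keep_sessions[s] = not decision.excluded
            qc_rows.append(
                {
                    "subject_id": cohort.iloc[s]["subject_id"],
                    "session_id": cohort.iloc[s]["session_id"],
                    "n_retained": cres.n_retained,
                    "excluded": decision.excluded,
                    "reasons": "|".join(sorted(decision.reasons)),
                    "mean_fd": float(fd.mean()),
                }
            )
        _write(pd.DataFrame(qc_rows), out / "qc_summary.csv", manifest)
        cohort = cohort[keep_sessions].reset_index(drop=True)
        edges = edges[keep_sessions]
        manifest["stages"].append("qc")

    # ---- connectome (group mean) -------------------------------------------
    log.info("[connectome] group-mean edge statistics")
    _write(connectome.group_mean_ttest(edges), out / "group_mean_ttest.csv", manifest)
    manifest["stages"].append("connectome")

    # ---- harmonize ----------------------------------------------------------
    if config.stages.harmonize and cohort["sequence_id"].nunique() > 1:
        log.info("[harmonize] longitudinal ComBat")
        model = harmonize.fit_longcombat(edges, cohort)
        harmonized = harmonize.apply_longcombat(model, edges, cohort)
        _write(
            harmonize.harmonization_report(edges, harmonized, cohort),
            out / "harmonization_report.csv",
            manifest,
        )
        (out / "harmonization_model.json").write_text(model.to_json())
        edges = harmonized
        manifest["stages"].append("harmonize")

    # ---- age effects --------------------------------------------------------
    eff = None
    if config.stages.age_effects:
        log.info("[effects] edge-wise age regression + FDR")
        eff = effects_mod.edgewise_age_model(edges, cohort, alpha=thr.fdr_q)
        ii, jj = connectome.edge_index(atlas.n_parcels)
        eff_out = eff.assign(i=ii, j=jj)
        _write(eff_out, out / "edge_effects.csv", manifest)
        pair_tab = effects_mod.network_pair_series(edges, eff, atlas)
        _write(pair_tab, out / "network_pair_series.csv", manifest)
        manifest["stages"].append("age_effects")

    # ---- trajectories -------------------------------------------------------
    if config.stages.trajectories and eff is not None:
        log.info("[trajectory] spline mixed-model growth curves")
        ages = cohort["age_weeks"].to_numpy(dtype=float)
        subs = cohort["subject_id"].to_numpy()
        rows = []
        for sign in ("positive", "negative"):
            if (eff["sign"] == sign).any():
                series = effects_mod.average_significant(edges, eff, sign)
                fit = trajectory.fit_gamm(series, ages, subs)
                tab = trajectory.fit_summary_table(fit).assign(series=sign)
                rows.append(tab)
        if rows:
            _write(pd.concat(rows, ignore_index=True), out / "global_trajectories.csv", manifest)
        pair_tab = effects_mod.network_pair_series(edges, eff, atlas)
        pair_rows = []
        for pair, sub_tab in pair_tab.groupby("pair"):
            vals = sub_tab.sort_values("session")["value"].to_numpy()
            if np.isnan(vals).all():
                continue
            fit = trajectory.fit_gamm(vals, ages, subs)
            pair_rows.append(trajectory.fit_summary_table(fit).assign(pair=pair))
        if pair_rows:
            _write(pd.concat(pair_rows, ignore_index=True), out / "pair_trajectories.csv", manifest)
        manifest["stages"].append("trajectories")

    # ---- graph --------------------------------------------------------------
    if config.stages.graph:
        log.info("[graph] efficiency measures and their age effects")
        ge, le = graph_mod.session_efficiencies(edges, atlas.n_parcels, thr.top_proportion)
        eff_rows = []
        for name, vals in (("ge", ge), ("le", le)):
            tab = pd.DataFrame(vals, columns=[f"node_{k}" for k in range(atlas.n_parcels)])
            tab.insert(0, "session", np.arange(len(cohort)))
            _write(tab, out / f"{name}_values.csv", manifest)
            node_eff = effects_mod.edgewise_age_model(vals, cohort, alpha=thr.fdr_q)
            node_eff = node_eff.rename(columns={"edge_id": "node"}).assign(measure=name)
            eff_rows.append(node_eff)
        _write(pd.concat(eff_rows, ignore_index=True), out / "efficiency_age_effects.csv", manifest)
        manifest["stages"].append("graph")

    # ---- within-period follow-ups ------------------------------------------
    for subset, flag in (("fetal", config.stages.fetal_only), ("infant", config.stages.infant_only)):
        if not flag:
            continue
        n_sub = (cohort["cohort"] == subset).sum()
        if n_sub < 10 or cohort.loc[cohort["cohort"] == subset, "subject_id"].nunique() < 2:
            log.warning("[%s-only] too few sessions (%d); skipped", subset, n_sub)
            continue
        log.info("[%s-only] within-period age effects", subset)
        sub_eff = effects_mod.edgewise_age_model(edges, cohort, alpha=thr.fdr_q, subset=subset)
        _write(sub_eff, out / f"edge_effects_{subset}.csv", manifest)
        manifest["stages"].append(f"{subset}_only")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest


def summarize_run(out_dir) -> dict[str, pd.DataFrame]:
    """Load the report tables of a completed run, keyed by report name.

    Raises FileNotFoundError naming the missing upstream output.
    """
    out = Path(out_dir)
    wanted = {
        "edge_effects": "edge_effects.csv",
        "network_pairs": "network_pair_series.csv",
        "efficiency": "efficiency_age_effects.csv",
    }
    reports = {}
    # keep_default_na=False so the literal sign label "null" survives the
    # round trip; genuinely missing values are written as empty strings
    read = lambda p: pd.read_csv(p, keep_default_na=False, na_values=[""])
    for key, fname in wanted.items():
        p = out / fname
        if not p.exists():
            raise FileNotFoundError(f"missing upstream output for report {key!r}: {p}")
        reports[key] = read(p)
    optional = {
        "global_trajectories": "global_trajectories.csv",
        "pair_trajectories": "pair_trajectories.csv",
        "edge_effects_fetal": "edge_effects_fetal.csv",
        "edge_effects_infant": "edge_effects_infant.csv",
    }
    for key, fname in optional.items():
        p = out / fname
        if p.exists():
            reports[key] = read(p)
    return reports


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(stream=sys.stderr, level=level, format="%(name)s %(levelname)s: %(message)s")
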