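"""Config-driven orchestration: calibrate references, score systems, kinetics.

The workflow mirrors a calcium-activation study: an *active* reference
ensemble (e.g. wild type with calcium) and an *inactive* reference (e.g. a
truncated or sodium-substituted system) calibrate the RCV scale per
component; every other system is then scored against that calibration, its
components clustered per subunit, ion residence evaluated at declared sites,
and contact/SASA summaries written.  A companion kinetics stage turns
substrate-rate tables into Michaelis–Menten fits with Ca/Na fold ratios, and
a melt stage extracts Tm values from thermal-shift curves.

Analyses pool both monomers from all replica trajectories; alignment uses
each monomer's core for per-monomer quantities.  All outputs carry a run log
with the package version, the seed and a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_report, gromos_cluster, pairwise_rmsd_matrix
from .contacts import contact_map, differential_contact_map, sasa_series
from .ions import BindingSiteDefinition, assign_residence, residence_probability
from .kinetics import (
    KineticsDataset,
    MeltCurve,
    fit_michaelis_menten,
    fold_activation,
    fold_catalytic_efficiency,
    melt_tm,
)
from .rcv import classify_mutant, load_calibration, rcv_profile, save_calibration
from .superpose import apply_transform, kabsch_fit, rmsd_series, summarize_pooled
from .trajectory import (
    ComponentSelection,
    Trajectory,
    read_structure,
    read_trajectory,
    resolve_selection,
)

logger = logging.getLogger("rcvkit")

__all__ = [
    "AnalysisConfig",
    "load_config",
    "run_calibrate",
    "run_score",
    "run_kinetics",
    "run_melt",
    "simulate_study",
]


@dataclass
class AnalysisConfig:
    reference_path: Path
    systems: dict[str, list[dict]]  # label -> [{path, format, replica}]
    components: dict[str, ComponentSelection]
    align_component: str
    rcv_components: list[str]
    cluster_cutoffs: dict[str, float]
    sites: dict[str, BindingSiteDefinition]
    active_system: str
    inactive_system: str
    contact_cutoff: float
    sasa_component: str | None
    kinetics: dict[str, dict[str, Path]]  # system -> {calcium: csv, sodium: csv}
    melt_curves: dict[str, Path]
    output_dir: Path
    seed: int
    raw: dict

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_selection(name: str, node: dict) -> ComponentSelection:
    ranges = tuple((str(c), int(a), int(b)) for c, a, b in node["ranges"])
    af = node.get("atom_filter", "backbone")
    if isinstance(af, list):
        af = tuple(af)
    return ComponentSelection(name, ranges, af)


def _parse_site(site_id: str, node: dict) -> BindingSiteDefinition:
    def residues(key):
        return tuple((str(c), int(r), tuple(atoms)) for c, r, atoms in node.get(key, []))

    return BindingSiteDefinition(
        site_id=site_id,
        primary_residues=residues("primary"),
        backup_residues=residues("backup"),
        ion_species=node.get("ion_species", "CA"),
        distance_cutoff=float(node.get("distance_cutoff", 3.5)),
        min_contacts=int(node.get("min_contacts", 1)),
    )


def load_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    components = {name: _parse_selection(name, node) for name, node in raw.get("components", {}).items()}
    systems = {
        label: [
            {
                "path": base / t["path"],
                "format": t.get("format", "pdb"),
                "replica": t.get("replica", f"r{i}"),
            }
            for i, t in enumerate(node.get("trajectories", []))
        ]
        for label, node in raw.get("systems", {}).items()
    }
    refs = raw.get("rcv_references", {})
    active = refs.get("active", "")
    inactive = refs.get("inactive", "")
    if active and active == inactive:
        raise ValueError("active and inactive reference labels must differ")
    kin = {
        sys_label: {buf: base / p for buf, p in node.items()}
        for sys_label, node in raw.get("kinetics", {}).items()
    }
    return AnalysisConfig(
        reference_path=base / raw["reference"],
        systems=systems,
        components=components,
        align_component=raw.get("align_component", "core"),
        rcv_components=list(raw.get("rcv_components", [])),
        cluster_cutoffs={k: float(v) for k, v in raw.get("cluster_cutoffs", {}).items()},
        sites={sid: _parse_site(sid, node) for sid, node in raw.get("sites", {}).items()},
        active_system=active,
        inactive_system=inactive,
        contact_cutoff=float(raw.get("contact_cutoff", 4.5)),
        sasa_component=raw.get("sasa_component"),
        kinetics=kin,
        melt_curves={k: base / p for k, p in raw.get("melt", {}).items()},
        output_dir=base / raw.get("output_dir", "results"),
        seed=int(raw.get("seed", 0)),
        raw=raw,
    )


def _split_by_chain(sel: ComponentSelection) -> dict[str, ComponentSelection]:
    chains: dict[str, list] = {}
    for chain, a, b in sel.ranges:
        chains.setdefault(chain, []).append((chain, a, b))
    return {
        chain: ComponentSelection(sel.name, tuple(rs), sel.atom_filter)
        for chain, rs in chains.items()
    }


def _load_system(config: AnalysisConfig, label: str, topology) -> list[Trajectory]:
    trajs = []
    for entry in config.systems[label]:
        trajs.append(
            read_trajectory([entry["path"]], topology, fmt=entry["format"], replica_id=entry["replica"])
        )
    if not trajs:
        raise ValueError(f"system {label!r} has no trajectories")
    return trajs


def _component_series(config, trajs, reference, component_name):
    """Per-(replica, monomer) RMSD series for one component.

    Each monomer is aligned on its own chain's slice of the alignment core
    and measured on its own chain's slice of the component.
    """
    align_by_chain = _split_by_chain(config.components[config.align_component])
    comp_by_chain = _split_by_chain(config.components[component_name])
    series = []
    for traj in trajs:
        for chain, comp_sel in comp_by_chain.items():
            align_sel = align_by_chain.get(chain) or config.components[config.align_component]
            series.append(
                rmsd_series(traj, reference, align_sel, comp_sel, source=(traj.replica_id, chain))
            )
    return series


def run_calibrate(config: AnalysisConfig, calibration_path: str | Path | None = None) -> Path:
    """Compute per-component active/inactive reference medians; write calibration JSON."""
    for label in (config.active_system, config.inactive_system):
        if label not in config.systems:
            raise ValueError(f"reference system {label!r} missing from config")
    _topo, reference = read_structure(config.reference_path)
    active_refs, inactive_refs = {}, {}
    for label, target in ((config.active_system, active_refs), (config.inactive_system, inactive_refs)):
        trajs = _load_system(config, label, reference.topology)
        for comp in config.rcv_components:
            summary = summarize_pooled(_component_series(config, trajs, reference, comp))
            target[comp] = summary.median
            logger.info("calibrate %s/%s: median %.3f Å over %d frames", label, comp, summary.median, summary.n_samples)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = Path(calibration_path) if calibration_path else config.output_dir / "calibration.json"
    save_calibration(
        out, active_refs, inactive_refs, config.cluster_cutoffs,
        meta={"active_system": config.active_system, "inactive_system": config.inactive_system,
              "config_hash": config.config_hash, "version": __version__},
    )
    return out


def _aligned_frames(config, trajs, reference, chain):
    """Concatenate all replicas' frames, each aligned on this monomer's core."""
    align_by_chain = _split_by_chain(config.components[config.align_component])
    align_sel = align_by_chain.get(chain) or config.components[config.align_component]
    ai = resolve_selection(trajs[0].topology, align_sel)
    ar = resolve_selection(reference.topology, align_sel)
    ref_align = reference.frames[0, ar]
    out = []
    for traj in trajs:
        aligned = np.empty_like(traj.frames)
        for f in range(traj.n_frames):
            R, t, _ = kabsch_fit(traj.frames[f, ai], ref_align)
            aligned[f] = apply_transform(traj.frames[f], R, t)
        out.append(aligned)
    return np.concatenate(out, axis=0)


def run_score(
    config: AnalysisConfig,
    calibration_path: str | Path,
    systems: list[str] | None = None,
    stages: tuple[str, ...] = ("rcv", "cluster", "residence", "contacts", "sasa"),
) -> dict[str, Path]:
    """Score systems against the calibration; write per-system result directories."""
    active_refs, inactive_refs, cutoffs = load_calibration(calibration_path)
    _topo, reference = read_structure(config.reference_path)
    labels = systems or list(config.systems)
    outdirs = {}
    errors = []
    contact_maps = {}
    for label in labels:
        outdir = config.output_dir / label
        outdir.mkdir(parents=True, exist_ok=True)
        outdirs[label] = outdir
        try:
            trajs = _load_system(config, label, reference.topology)
        except (OSError, ValueError) as exc:
            errors.append((label, "load", str(exc)))
            logger.error("system %s: failed to load: %s", label, exc)
            continue
        if "rcv" in stages and config.rcv_components:
            series_map = {c: _component_series(config, trajs, reference, c) for c in config.rcv_components}
            profile = rcv_profile(series_map, active_refs, inactive_refs)
            labels_map = classify_mutant(profile)
            pd.DataFrame(
                {
                    "system": label,
                    "component": [p.component_name for p in profile],
                    "score_median": [p.score_median for p in profile],
                    "score_q1": [p.score_iqr[0] for p in profile],
                    "score_q3": [p.score_iqr[1] for p in profile],
                    "rmsd_median_A": [p.mutant_summary.median for p in profile],
                    "n_frames": [p.mutant_summary.n_samples for p in profile],
                    "label": [labels_map[p.component_name] for p in profile],
                }
            ).to_csv(outdir / "rcv.csv", index=False)
        if "cluster" in stages:
            rows = []
            for comp, cutoff in cutoffs.items():
                if comp not in config.components:
                    continue
                for chain, comp_sel in _split_by_chain(config.components[comp]).items():
                    pooled = Trajectory(
                        reference.topology, _aligned_frames(config, trajs, reference, chain),
                        replica_id=f"{label}-pooled",
                    )
                    mat = pairwise_rmsd_matrix(pooled, comp_sel, align_mode="prealigned")
                    res = gromos_cluster(mat, cutoff, component_name=f"{comp}_{chain}")
                    df = cluster_report(res, pooled)
                    df.insert(0, "monomer", chain)
                    df.insert(0, "component", comp)
                    rows.append(df)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(outdir / "clusters.csv", index=False)
        if "residence" in stages and config.sites:
            rows = []
            for sid, site in config.sites.items():
                flags = []
                for traj in trajs:
                    try:
                        bound, _ion = assign_residence(traj, site)
                        flags.append(bound)
                    except ValueError as exc:
                        errors.append((label, f"residence:{sid}", str(exc)))
                if flags:
                    res = residence_probability(flags)
                    rows.append(
                        {"system": label, "site": sid, "residence_probability": res.residence_probability,
                         "n_sources": res.n_sources, "n_frames": res.n_frames_total}
                    )
            if rows:
                pd.DataFrame(rows).to_csv(outdir / "residence.csv", index=False)
        if "contacts" in stages:
            maps = [contact_map(t, cutoff=config.contact_cutoff, label=label) for t in trajs]
            # average frame-weighted over replicas
            weights = np.array([t.n_frames for t in trajs], dtype=float)
            avg = sum(w * m.values for w, m in zip(weights, maps)) / weights.sum()
            cmap = maps[0]
            cmap.values = avg
            contact_maps[label] = cmap
            res_labels = [f"{c}{r}" for c, r in cmap.residue_labels]
            pd.DataFrame(avg, index=res_labels, columns=res_labels).to_csv(outdir / "contact_map.csv")
        if "sasa" in stages and config.sasa_component:
            sel_idx = resolve_selection(reference.topology, config.components[config.sasa_component])
            values = np.concatenate(
                [sasa_series(t, sel_idx, name=config.sasa_component).values for t in trajs]
            )
            pd.DataFrame({"frame": np.arange(values.size), "sasa_A2": values}).to_csv(
                outdir / f"sasa_{config.sasa_component}.csv", index=False
            )
    if "contacts" in stages and config.active_system in contact_maps and config.inactive_system in contact_maps:
        diff = differential_contact_map(contact_maps[config.active_system], contact_maps[config.inactive_system])
        res_labels = [f"{c}{r}" for c, r in diff.residue_labels]
        pd.DataFrame(diff.values, index=res_labels, columns=res_labels).to_csv(
            config.output_dir / "differential_contact_map.csv"
        )
    _write_run_log(config, "score", {"systems": labels, "errors": errors})
    if errors:
        logger.warning("score finished with %d stage error(s): %s", len(errors), errors)
    return outdirs


def run_kinetics(config: AnalysisConfig) -> pd.DataFrame:
    """Fit kinetics CSVs per system and buffer; report folds where both buffers exist."""
    rows = []
    for label, buffers in config.kinetics.items():
        fits = {}
        for buf in ("calcium", "sodium"):
            if buf in buffers:
                df = pd.read_csv(buffers[buf])
                data = KineticsDataset(
                    concentrations_uM=df["concentration_uM"].to_numpy(),
                    rates_per_s=df["rate_per_s"].to_numpy(),
                    buffer=buf,
                )
                fits[buf] = fit_michaelis_menten(data)
        row = {"system": label, "complete": len(fits) == 2}
        for buf, fit in fits.items():
            row.update(
                {
                    f"kcat_{buf}": fit.kcat,
                    f"Km_{buf}": fit.Km,
                    f"kcat_{buf}_ci_lo": fit.kcat_ci[0],
                    f"kcat_{buf}_ci_hi": fit.kcat_ci[1],
                    f"Km_{buf}_ci_lo": fit.Km_ci[0],
                    f"Km_{buf}_ci_hi": fit.Km_ci[1],
                }
            )
        if len(fits) == 2:
            ca, na = fits["calcium"], fits["sodium"]
            row["fold_activation"] = round(fold_activation(ca.kcat, na.kcat), 1)
            row["fold_catalytic_efficiency"] = round(
                fold_catalytic_efficiency(ca.kcat, ca.Km, na.kcat, na.Km), 1
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(config.output_dir / "kinetics.csv", index=False)
    df.to_json(config.output_dir / "kinetics.json", orient="records", indent=2)
    _write_run_log(config, "kinetics", {"systems": list(config.kinetics)})
    return df


def run_melt(config: AnalysisConfig, smoothing_window: int = 5) -> pd.DataFrame:
    rows = []
    for label, path in config.melt_curves.items():
        df = pd.read_csv(path)
        curve = MeltCurve(df["temp_C"].to_numpy(), df["fluorescence"].to_numpy())
        result = melt_tm(curve, smoothing_window=smoothing_window)
        rows.append({"system": label, "tm_C": result.tm_C, "n_wells": len(result.wells)})
    out = pd.DataFrame(rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out.to_csv(config.output_dir / "melt.csv", index=False)
    return out


def _write_run_log(config: AnalysisConfig, stage: str, extra: dict) -> None:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    log = {"stage": stage, "version": __version__, "seed": config.seed,
           "config_hash": config.config_hash, **extra}
    with open(config.output_dir / f"runlog_{stage}.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Synthetic study generation (the `simulate` stage)
# ---------------------------------------------------------------------------

def simulate_study(
    output_dir: str | Path,
    seed: int = 0,
    n_frames: int = 150,
    n_replicas: int = 2,
    noise_sigma: float = 0.05,
    lid_offset: float = 3.0,
    rim_offset: float = 2.0,
) -> Path:
    """Write a complete synthetic study a scientist could score end to end.

    Three systems on the toy dimer: ``active`` (native, no offsets),
    ``inactive`` (lid and rim displaced by their full offsets) and
    ``midway`` (half offsets), each with ``n_replicas`` multi-model PDB
    trajectories, plus kinetics and melt CSVs; returns the config path.
    """
    from .synthetic import (
        StateMixtureSpec,
        StateSpec,
        ToyDimerSpec,
        default_selections,
        make_melt_curve,
        make_mm_dataset,
        make_state_mixture_trajectory,
        make_toy_dimer,
    )
    from .trajectory import write_pdb

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    dimer = ToyDimerSpec()
    topo, reference = make_toy_dimer(dimer)
    sels = default_selections(dimer)
    write_pdb(output_dir / "reference.pdb", reference)

    def offsets(scale):
        return (
            ("lid", (0.0, 0.0, scale * lid_offset)),
            ("rim", (scale * rim_offset, 0.0, 0.0)),
        )

    system_states = {
        "active": StateSpec(offsets=(), weight=1.0),
        "inactive": StateSpec(offsets=offsets(1.0), weight=1.0),
        "midway": StateSpec(offsets=offsets(0.5), weight=1.0),
    }
    systems_node = {}
    rng = np.random.default_rng(seed)
    for label, state in system_states.items():
        entries = []
        for r in range(n_replicas):
            spec = StateMixtureSpec(
                states=(state,), noise_sigma=noise_sigma, n_frames=n_frames,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            traj, _labels, _analytic = make_state_mixture_trajectory(
                topo, reference, spec, sels, replica_id=f"r{r}"
            )
            path = f"{label}_r{r}.pdb"
            write_pdb(output_dir / path, traj)
            entries.append({"path": path, "format": "pdb", "replica": f"r{r}"})
        systems_node[label] = {"trajectories": entries}

    # kinetics: an activated system (large Ca/Na kcat contrast) and a
    # site-broken variant whose contrast is mostly lost
    kin_params = {
        "WT": {"calcium": (0.51, 88.0), "sodium": (0.074, 64.0)},
        "SiteMT": {"calcium": (0.073, 513.0), "sodium": (0.038, 332.0)},
    }
    kinetics_node = {}
    for label, buffers in kin_params.items():
        kinetics_node[label] = {}
        for buf, (kcat, km) in buffers.items():
            ds = make_mm_dataset(kcat, km, noise_rel=0.05, seed=int(rng.integers(0, 2**31 - 1)), buffer=buf)
            path = f"kinetics_{label}_{buf}.csv"
            pd.DataFrame(
                {"concentration_uM": ds.concentrations_uM, "rate_per_s": ds.rates_per_s}
            ).to_csv(output_dir / path, index=False)
            kinetics_node[label][buf] = path

    melt_node = {}
    for label, tm in (("holo", 61.0), ("apo", 52.0)):
        curve = make_melt_curve(tms_C=(tm,), noise_sd=2.0, seed=int(rng.integers(0, 2**31 - 1)))
        path = f"melt_{label}.csv"
        pd.DataFrame({"temp_C": curve.temperatures_C, "fluorescence": curve.fluorescence}).to_csv(
            output_dir / path, index=False
        )
        melt_node[label] = path

    config = {
        "reference": "reference.pdb",
        "seed": seed,
        "output_dir": "results",
        "align_component": "core",
        "rcv_components": ["lid", "rim"],
        "cluster_cutoffs": {"lid": 1.8, "rim": 1.8},
        "contact_cutoff": 4.5,
        "sasa_component": "lid",
        "rcv_references": {"active": "active", "inactive": "inactive"},
        "components": {
            name: {"ranges": [list(r) for r in sel.ranges], "atom_filter": sel.atom_filter}
            for name, sel in sels.items()
        },
        "systems": systems_node,
        "kinetics": kinetics_node,
        "melt": melt_node,
    }
    config_path = output_dir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
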