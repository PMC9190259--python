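"""End-to-end orchestration: generate -> interactions -> states -> pca ->
correlate -> report.

A single configuration drives all stages; every random stage derives its
generator from the configured seed, so a rerun with the same config and
seed reproduces report.json exactly. All intermediate results are
written as CSV next to the machine-readable report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import affinity as aff
from .core import Ensemble, SelectionSpec, select
from .dihedrals import build_states, compare_sampling, compute_backbone_torsions, match_states
from .interactions import InteractionCriteria, nonsolvent_fraction, summarize_trajectory
from .pca import cluster_projections, dres, fit_pca, project, superpose
from .pdbio import load_config, read_ensemble, write_ensemble, write_table
from .synthetic import CDR_LOOPS, FRAMEWORK_RESIDS, ComplexSpec, PanelSpec, generate_panel

log = logging.getLogger("abensemble")

REPORT_SCHEMA_VERSION = 1

CORRELATION_COLUMNS = (
    "mean_holo_pca_clusters",
    "mean_holo_dash_states",
    "mean_apo_pca_clusters",
    "mean_apo_dash_states",
    "mean_dres",
    "apo_minus_holo_pca",
    "apo_minus_holo_dash",
    "nonsolvent_pct",
    "nonsolvent_nonhydrophobic_pct",
    "hydrophobic_pct",
)


def _criteria_from_config(config: Mapping[str, Any]) -> InteractionCriteria:
    overrides = dict(config.get("criteria", {}))
    if "cation_pi_angle_windows" in overrides:
        overrides["cation_pi_angle_windows"] = tuple(
            tuple(w) for w in overrides["cation_pi_angle_windows"]
        )
    if "hbond_angle_range" in overrides:
        overrides["hbond_angle_range"] = tuple(overrides["hbond_angle_range"])
    return InteractionCriteria(**overrides)


def _cdr_chain(config: Mapping[str, Any], model, cdr: str) -> str:
    role = "heavy" if cdr.upper().startswith("H") else "light"
    chains = model.chains_with_role(role)
    if not chains:
        raise ValueError(f"no chain with role {role} for CDR {cdr}")
    return chains[0]


def _align_selection(config: Mapping[str, Any], model) -> np.ndarray:
    """Backbone atoms of the V_H/V_L interface used as the rigid core.

    Defaults to the configured ``align.residue_range`` on the heavy and
    light chains."""
    align_cfg = config.get("align", {})
    rng = tuple(align_cfg.get("residue_range", (min(FRAMEWORK_RESIDS), max(FRAMEWORK_RESIDS))))
    chains = tuple(model.chains_with_role("heavy", "light"))
    return select(model, SelectionSpec.backbone(chain_ids=chains, residue_ranges=[rng]))


def analyze_antibody(
    apo: Ensemble,
    holo: Ensemble,
    config: Mapping[str, Any],
    seed: int = 0,
) -> dict[str, Any]:
    """All per-antibody metrics: interaction percentages (fluctuating
    interface) and per-CDR dihedral-state and PCA/cluster/DRES results."""
    criteria = _criteria_from_config(config)
    summary = summarize_trajectory(holo, mode="fluctuating_interface", criteria=criteria)
    fractions = nonsolvent_fraction(summary)

    # each form is fitted onto its own first frame; the rigid V_H/V_L core
    # occupies the same coordinates in both, so the frames are comparable
    apo_al = superpose(apo, apo.frames[0], _align_selection(config, apo.topology))
    holo_al = superpose(holo, holo.frames[0], _align_selection(config, holo.topology))

    bin_width = float(config.get("bin_width", 10.0))
    threshold = float(config.get("linkage_threshold", 11.0))
    sim_threshold = float(config.get("similarity_threshold", 0.8))
    cdr_results: dict[str, dict[str, float]] = {}
    classifications_dash: dict[str, str] = {}
    classifications_pca: dict[str, str] = {}
    cdrs = config.get("cdrs") or {name: [lo, hi] for name, (_, lo, hi) in CDR_LOOPS.items()}
    for k, (cdr, rng) in enumerate(sorted(cdrs.items())):
        lo, hi = int(rng[0]), int(rng[1])
        chain_apo = _cdr_chain(config, apo.topology, cdr)
        chain_holo = _cdr_chain(config, holo.topology, cdr)
        res: dict[str, float] = {}
        # dihedral states
        states = {}
        for form, ens, chain in (("apo", apo_al, chain_apo), ("holo", holo_al, chain_holo)):
            series = compute_backbone_torsions(ens, chain, (lo, hi), cdr_id=cdr)
            states[form] = build_states(series, bin_width=bin_width)
            res[f"{form}_dash_states"] = states[form].n_states
            res[f"{form}_rare_fraction"] = states[form].rare_fraction
        report = match_states(states["apo"], states["holo"], threshold=sim_threshold)
        res["dash_matched"] = len(report.matched)
        classifications_dash[cdr] = compare_sampling(states["apo"], states["holo"])
        # Cartesian PCA
        spec_a = SelectionSpec.backbone(chain_ids=(chain_apo,), residue_ranges=[(lo, hi)])
        spec_h = SelectionSpec.backbone(chain_ids=(chain_holo,), residue_ranges=[(lo, hi)])
        sel_a = select(apo_al.topology, spec_a)
        sel_h = select(holo_al.topology, spec_h)
        model = fit_pca(apo_al, holo_al, sel_a, cdr_sel_holo=sel_h)
        proj_a = project(model, apo_al, 3, "apo", sel=sel_a)
        proj_h = project(model, holo_al, 3, "holo", sel=sel_h)
        ca = cluster_projections(proj_a, threshold=threshold)
        ch = cluster_projections(proj_h, threshold=threshold)
        res["apo_pca_clusters"] = ca.n_clusters
        res["holo_pca_clusters"] = ch.n_clusters
        res["dres"] = dres(proj_a, proj_h, seed=seed + k).value
        if ca.n_clusters > ch.n_clusters:
            classifications_pca[cdr] = "more_apo"
        elif ca.n_clusters < ch.n_clusters:
            classifications_pca[cdr] = "more_holo"
        else:
            classifications_pca[cdr] = "equal"
        cdr_results[cdr] = res
    return {
        "interaction_means": summary.means.to_dict(),
        "interaction_sds": summary.sds.to_dict(),
        "fractions": fractions,
        "cdr_results": cdr_results,
        "sampling_class_dash": classifications_dash,
        "sampling_class_pca": classifications_pca,
    }


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage for every antibody in the config and write the
    report bundle. Returns the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    antibodies = config.get("antibodies", [])
    if not antibodies:
        raise ValueError("config lists no antibodies")
    for entry in antibodies:
        for key in ("holo", "apo"):
            if not Path(entry[key]).exists():
                raise FileNotFoundError(f"{entry['id']}: missing {key} file {entry[key]}")
    aff_path = config.get("affinities")
    affinities = aff.read_affinities(aff_path) if aff_path else []

    per_ab_cdr: dict[str, dict[str, dict[str, float]]] = {}
    interaction_pct: dict[str, dict[str, float]] = {}
    class_dash: list[str] = []
    class_pca: list[str] = []
    summary_rows = []
    for k, entry in enumerate(antibodies):
        ab_id = entry["id"]
        log.info("analyzing %s", ab_id)
        holo = read_ensemble(entry["holo"], config)
        apo = read_ensemble(entry["apo"], config)
        result = analyze_antibody(apo, holo, config, seed=seed + 1000 * k)
        per_ab_cdr[ab_id] = {
            cdr: {
                "holo_pca_clusters": r["holo_pca_clusters"],
                "apo_pca_clusters": r["apo_pca_clusters"],
                "holo_dash_states": r["holo_dash_states"],
                "apo_dash_states": r["apo_dash_states"],
                "dres": r["dres"],
            }
            for cdr, r in result["cdr_results"].items()
        }
        interaction_pct[ab_id] = result["fractions"]
        class_dash.extend(result["sampling_class_dash"].values())
        class_pca.extend(result["sampling_class_pca"].values())
        for kind, mean in result["interaction_means"].items():
            summary_rows.append(
                {"antibody_id": ab_id, "kind": kind, "mean": mean,
                 "sd": result["interaction_sds"][kind]}
            )
    write_table(pd.DataFrame(summary_rows), out / "interaction_summary.csv")

    table = aff.build_metric_table(per_ab_cdr, interaction_pct, affinities)
    write_table(table, out / "metrics.csv")
    correlations = aff.correlate_metrics(table, list(CORRELATION_COLUMNS), y_column="ln_kd")
    corr_rows = [
        {
            "x": c.x_name, "y": c.y_name, "n": c.n, "r_squared": c.r_squared,
            "slope": c.slope, "intercept": c.intercept,
            "max_delta_point": c.max_delta_point,
            "max_delta_r_squared": c.max_delta_r_squared,
        }
        for c in correlations
    ]
    write_table(pd.DataFrame(corr_rows), out / "correlations.csv")
    pct = {
        "pca": aff.sampling_class_percentages(class_pca) if class_pca else {},
        "dash": aff.sampling_class_percentages(class_dash) if class_dash else {},
    }
    write_table(
        pd.DataFrame([{"method": m, **{k: v for k, v in d.items() if k != "method"}} for m, d in pct.items()]),
        out / "sampling_classes.csv",
    )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "thresholds": {
            "bin_width": float(config.get("bin_width", 10.0)),
            "linkage_threshold": float(config.get("linkage_threshold", 11.0)),
            "similarity_threshold": float(config.get("similarity_threshold", 0.8)),
            "criteria": _criteria_from_config(config).__dict__.copy(),
        },
        "antibodies": {ab: interaction_pct[ab] for ab in interaction_pct},
        "metrics": json.loads(table.to_json(orient="records")),
        "correlations": corr_rows,
        "sampling_class_percentages": pct,
    }
    report["thresholds"]["criteria"]["hbond_angle_range"] = list(
        report["thresholds"]["criteria"]["hbond_angle_range"]
    )
    report["thresholds"]["criteria"]["cation_pi_angle_windows"] = [
        list(w) for w in report["thresholds"]["criteria"]["cation_pi_angle_windows"]
    ]
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def make_demo(out_dir: str | Path, seed: int = 0, n_antibodies: int = 4, n_frames: int = 120) -> Path:
    """Write a complete synthetic panel (apo/holo ensembles, affinities,
    pipeline config) ready for :func:`run_pipeline`. Returns the config
    path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = generate_panel(
        PanelSpec(n_antibodies=n_antibodies, noise_sd=0.3, seed=seed, n_frames=n_frames)
    )
    entries = []
    aff_rows = []
    for holo, apo, record, planted in panel:
        holo_path = out / f"{record.antibody_id}_holo.pdb"
        apo_path = out / f"{record.antibody_id}_apo.pdb"
        write_ensemble(holo, holo_path)
        write_ensemble(apo, apo_path)
        entries.append({"id": record.antibody_id, "holo": str(holo_path), "apo": str(apo_path)})
        aff_rows.append({"antibody_id": record.antibody_id, "kd_nM": record.kd_nM})
    aff_path = out / "affinities.csv"
    pd.DataFrame(aff_rows).to_csv(aff_path, index=False)
    config = {
        "antibodies": entries,
        "affinities": str(aff_path),
        "chains": {"heavy": "H", "light": "L", "antigen": ["A"]},
        "cdrs": {name: [lo, hi] for name, (_, lo, hi) in CDR_LOOPS.items()},
        "align": {"residue_range": [min(FRAMEWORK_RESIDS), max(FRAMEWORK_RESIDS)]},
        "seed": seed,
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return cfg_path
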