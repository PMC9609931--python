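"""Orchestration of the comparative workflow.

Conditions are (variant, partner) pose ensembles of one tagged residue.
For each variant with two or more partners the pipeline computes three
lines of evidence per partner — tagged-residue burial, tagged-residue
SASA, and mean interaction energy — and emits a partner-preference
verdict when at least 2 of the 3 metrics agree in direction with
Holm-adjusted p < alpha.  The 2-of-3 rule is this package's explicit
operationalisation of "preferential interaction"; raw and adjusted
p-values are both reported so the rule can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import energetics, flexnm, pocket as pocketmod, sasa as sasamod
from . import screenflow, trajectory as trajmod
from .dimers import PoseSet, classify_externalization, two_group_test
from .structio import ResidueKey, Structure

logger = logging.getLogger(__name__)

METRICS = ("buried_fraction", "tagged_sasa", "interaction_energy")


@dataclass
class RunConfig:
    """Inputs for one comparative run.

    ``conditions`` maps (variant, partner) labels to PoseSets sharing a
    tagged residue.  Monomers enable the flexibility and pocket stages;
    trajectories and candidates enable theirs.  Absent inputs skip their
    stage — but a verdict always requires the dimer-metrics stage.
    """
    conditions: dict[tuple[str, str], PoseSet] = field(default_factory=dict)
    tagged_residue: ResidueKey | None = None
    monomers: dict[str, Structure] = field(default_factory=dict)
    trajectories: dict[tuple[str, str], list[float]] = field(
        default_factory=dict)       # condition -> replicate summary RMSDs
    candidates: list = field(default_factory=list)
    filter_rules: list = field(default_factory=list)
    score_orientation: str = "fitness"
    sasa_params: sasamod.SASAParams = field(default_factory=sasamod.SASAParams)
    nb_params: energetics.NBParams = field(default_factory=energetics.NBParams)
    ddg_model: energetics.DDGModel = field(default_factory=energetics.DDGModel)
    enm_kind: str = "gnm"
    f_min: float = 0.25
    alpha: float = 0.05
    wt_residue: str = "ARG"
    mut_residue: str = "TRP"
    seed: int = 0
    output_dir: Path | None = None


def holm_adjust(pvals: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment over a small family of tests."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for i, (name, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adjusted[name] = running
    return adjusted


def _condition_metrics(ps: PoseSet, cfg: RunConfig) -> dict:
    report = classify_externalization(ps, cfg.sasa_params, cfg.f_min)
    fractions = report.per_pose["buried_fraction"].dropna().to_numpy()
    sasas = []
    ddgs = []
    energies = []
    for pose, bf in zip(ps.poses, report.per_pose["buried_fraction"]):
        if not np.isfinite(bf):
            continue
        area = sasamod.residue_sasa(pose.structure, ps.tagged_residue,
                                    cfg.sasa_params)
        sasas.append(area)
        res_name = pose.structure.residue_name_of(ps.tagged_residue)
        rel = energetics.relative_sasa(area, res_name)
        ddgs.append(energetics.ddg_mutation(rel, cfg.wt_residue,
                                            cfg.mut_residue, cfg.ddg_model))
        energies.append(energetics.interaction_energy(pose, cfg.nb_params).delta)
    return {
        "externalization": report,
        "buried_fraction": fractions,
        "tagged_sasa": np.array(sasas),
        "interaction_energy": np.array(energies),
        "ddg": np.array(ddgs),
    }


def _partner_preference(variant: str, partner_metrics: dict[str, dict],
                        alpha: float) -> dict:
    """2-of-3 verdict between exactly two partners of one variant."""
    (pa, ma), (pb, mb) = partner_metrics.items()
    raw_p: dict[str, float] = {}
    favored: dict[str, str | None] = {}
    for metric in METRICS:
        a, b = ma[metric], mb[metric]
        t, p = two_group_test(a, b, kind="welch_t")
        raw_p[metric] = p
        if metric == "buried_fraction":
            # deeper burial with a partner = preference for that partner
            favored[metric] = pa if a.mean() > b.mean() else pb
        else:
            # lower tagged SASA / lower energy = preference
            favored[metric] = pa if a.mean() < b.mean() else pb
    adj_p = holm_adjust(raw_p)
    votes: dict[str, int] = {pa: 0, pb: 0}
    for metric in METRICS:
        if adj_p[metric] < alpha:
            votes[favored[metric]] += 1
    preferred = None
    for partner, v in votes.items():
        if v >= 2:
            preferred = partner
    return {"variant": variant, "partners": [pa, pb], "raw_p": raw_p,
            "holm_p": adj_p, "favored": favored, "votes": votes,
            "preferred_partner": preferred}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the comparative stages and assemble the report.

    Stage order: flexibility -> dimer metrics -> energetics/ddG ->
    trajectory comparison -> pocket -> screening triage; stages with
    absent inputs are skipped and recorded as such.  The report is a
    plain dict (JSON-serialisable except for numpy scalars, which are
    converted) with full parameter provenance.
    """
    t_start = time.time()
    report: dict = {"stages": {}, "provenance": _provenance(cfg)}

    # flexibility
    if cfg.monomers:
        flex = {}
        profiles = {}
        for label, mono in cfg.monomers.items():
            weighting = ("sidechain" if label != "WT" else "uniform")
            model = flexnm.build_enm(mono, kind=cfg.enm_kind,
                                     contact_weighting=weighting)
            profiles[label] = flexnm.rmsf_profile(model)
        if "WT" in profiles:
            for label, prof in profiles.items():
                if label == "WT":
                    continue
                delta, flagged = flexnm.compare_profiles(profiles["WT"], prof)
                site_delta = None
                if cfg.tagged_residue is not None:
                    site_delta = delta.get(cfg.tagged_residue)
                flex[label] = {"site_delta": site_delta,
                               "n_flagged": len(flagged)}
        report["stages"]["flexibility"] = {"status": "ok", "comparisons": flex}
    else:
        report["stages"]["flexibility"] = {"status": "skipped"}

    # dimer metrics + energetics
    verdicts = []
    if cfg.conditions:
        per_condition = {}
        metrics_cache: dict[tuple[str, str], dict] = {}
        for (variant, partner), ps in cfg.conditions.items():
            m = _condition_metrics(ps, cfg)
            metrics_cache[(variant, partner)] = m
            per_condition[f"{variant}/{partner}"] = {
                "externalization_score": m["externalization"].score,
                "externalization_sensitivity":
                    {str(k): v for k, v in
                     m["externalization"].sensitivity.items()},
                "mean_buried_fraction": float(m["buried_fraction"].mean()),
                "mean_tagged_sasa": float(m["tagged_sasa"].mean()),
                "sd_tagged_sasa": float(m["tagged_sasa"].std(ddof=1)),
                "mean_interaction_energy":
                    float(m["interaction_energy"].mean()),
                "mean_ddg": float(m["ddg"].mean()),
                "n_poses": int(len(m["buried_fraction"])),
            }
        variants = sorted({v for v, _ in cfg.conditions})
        for variant in variants:
            partners = {p: metrics_cache[(v, p)]
                        for (v, p) in cfg.conditions if v == variant}
            if len(partners) == 2:
                verdicts.append(_partner_preference(variant, partners,
                                                    cfg.alpha))
        report["stages"]["dimer_metrics"] = {"status": "ok",
                                             "conditions": per_condition}
        report["verdicts"] = verdicts
    else:
        report["stages"]["dimer_metrics"] = {"status": "skipped"}
        report["verdicts"] = []

    # trajectory comparison
    if cfg.trajectories and len(cfg.trajectories) >= 2:
        results = {f"{v}/{p}": vals
                   for (v, p), vals in cfg.trajectories.items()}
        ranking, fstat, pval = trajmod.compare_conditions(results)
        report["stages"]["trajectory"] = {"status": "ok",
                                          "ranking": ranking,
                                          "anova_F": fstat, "anova_p": pval}
    else:
        report["stages"]["trajectory"] = {"status": "skipped"}

    # pocket (on the first monomer containing the tagged residue)
    pocket_done = False
    if cfg.monomers and cfg.tagged_residue is not None:
        for label, mono in cfg.monomers.items():
            try:
                mono.resolve(cfg.tagged_residue)
            except KeyError:
                continue
            shell = pocketmod.define_shell(mono, cfg.tagged_residue)
            rep = pocketmod.detect_pocket(mono, shell,
                                          target=cfg.tagged_residue)
            report["stages"]["pocket"] = {
                "status": "ok", "structure": label,
                "shell_size": len(shell),
                "pocket_found": rep.pocket_found,
                "volume": rep.volume,
                "box": pocketmod.emit_box(rep)}
            pocket_done = True
            break
    if not pocket_done:
        report["stages"]["pocket"] = {"status": "skipped"}

    # screening triage
    if cfg.candidates:
        passed, audit = screenflow.apply_filters(cfg.candidates,
                                                 cfg.filter_rules)
        stage = {"status": "ok", "n_input": len(cfg.candidates),
                 "n_passed": len(passed)}
        scored = [c for c in passed
                  if c.score_wt is not None and c.score_mut is not None]
        if scored:
            ranking = screenflow.specificity_differential(
                scored, cfg.score_orientation, top_k=10)
            stage["top_hits"] = ranking.to_dict(orient="records")
        report["stages"]["screen"] = stage
    else:
        report["stages"]["screen"] = {"status": "skipped"}

    report["runtime_s"] = time.time() - t_start
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        body = {k: v for k, v in report.items() if k != "runtime_s"}
        (out / "report.json").write_text(
            json.dumps(_jsonable(body), indent=2, sort_keys=True))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (ResidueKey,)):
        return str(obj)
    return obj


def _provenance(cfg: RunConfig) -> dict:
    params = {
        "sasa": repr(cfg.sasa_params),
        "nb": {"dielectric": cfg.nb_params.dielectric,
               "cutoff": cfg.nb_params.cutoff},
        "f_min": cfg.f_min, "alpha": cfg.alpha, "seed": cfg.seed,
        "enm_kind": cfg.enm_kind,
        "verdict_rule": "2-of-3 metrics with Holm-adjusted p < alpha",
    }
    digest = hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]
    params["parameter_hash"] = digest
    return params


def multi_mutant_compare(reports: dict[str, dict],
                         wt_label: str = "WT") -> dict:
    """Variant x metric matrix with nearest-to-WT ranking per metric.

    ``reports`` maps variant labels to run_pipeline outputs whose
    dimer-metrics stage ran on the same partner set.  Distance is the
    absolute difference of each per-condition metric from the WT value.
    """
    if wt_label not in reports:
        raise ValueError(f"missing reference variant {wt_label!r}")
    if len(reports) < 2:
        raise ValueError("need >= 2 variants")

    def flat_metrics(rep):
        stage = rep["stages"]["dimer_metrics"]
        if stage["status"] != "ok":
            raise ValueError("dimer metrics stage did not run")
        out = {}
        for cond, m in stage["conditions"].items():
            partner = cond.split("/")[-1]   # strip the variant prefix
            for name in ("externalization_score", "mean_tagged_sasa",
                         "mean_interaction_energy", "mean_ddg"):
                out[f"{partner}:{name}"] = m[name]
        return out

    wt = flat_metrics(reports[wt_label])
    matrix = {}
    for variant, rep in reports.items():
        fm = flat_metrics(rep)
        matrix[variant] = {k: fm.get(k) for k in wt}
    nearest = {}
    for metric in wt:
        dists = {v: abs(matrix[v][metric] - wt[metric])
                 for v in reports if v != wt_label
                 and matrix[v][metric] is not None}
        nearest[metric] = sorted(dists, key=dists.get)
    return {"matrix": matrix, "nearest_to_wt": nearest,
            "metrics": list(wt)}
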