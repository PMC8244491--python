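"""Template-selection cascade and stage-1 screening orchestration.

The selection cascade runs, in order: resolution/state filter ->
hydrophobicity-correspondence shortlist -> query-coverage shortlist ->
ligand-profile comparison -> pocket comparison, each stage reducing (never
growing) the surviving candidate set. The cascade reports every metric it
computes; the final ordering is a documented lexicographic ranking (pocket
score desc, mean per-helix SSD asc, coverage desc) rather than a
pretend-scalar objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import apf, hydro, ligands as ligmod, pocket as pocketmod
from .sequences import (
    HELIX_IDS,
    ReceptorSequence,
    TMAnnotation,
    assign_bw_numbers,
    query_coverage,
)

DEFAULT_CONFIG: dict[str, Any] = {
    "resolution_cutoff": 2.5,
    "activity_state": "inactive",
    "coverage": {"enabled": True, "top_k": 4},
    "ligand_profile": {"enabled": True, "aggregate": "median"},
    "pocket": {"enabled": True, "matrix": "BLOSUM62", "predicate": "positive"},
    "apf": {
        "kernel_sigma": 1.0,
        "spacing": 0.5,
        "padding": 3.0,
        "fraction": 0.75,
        "n_restarts": 8,
        "threshold": None,
    },
}


def merge_config(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    """Defaults overlaid with (possibly nested) user overrides."""

    def merge(base: dict, over: Mapping) -> dict:
        out = dict(base)
        for k, v in over.items():
            if isinstance(v, Mapping) and isinstance(out.get(k), dict):
                out[k] = merge(out[k], v)
            else:
                out[k] = v
        return out

    return merge(DEFAULT_CONFIG, overrides or {})


@dataclass
class TemplateCandidate:
    pdb_id: str
    receptor_name: str
    resolution: float
    activity_state: str
    sequence: ReceptorSequence
    tms: tuple[TMAnnotation, ...]
    anchors: dict[str, int]
    ligand: ligmod.Ligand | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"{self.pdb_id}: resolution must be positive")
        if len(self.tms) != 7:
            raise ValueError(f"{self.pdb_id}: expected 7 TM annotations")


@dataclass
class SelectionReport:
    stages: list[tuple[str, tuple[str, ...]]]  # (stage name, survivor ids)
    metrics: pd.DataFrame
    final_ranking: tuple[str, ...]
    stage_empty: str | None = None

    def survivors(self) -> tuple[str, ...]:
        return self.stages[-1][1] if self.stages else ()


def filter_resolution(
    candidates: Sequence[TemplateCandidate],
    cutoff: float = 2.5,
    state: str = "inactive",
) -> list[TemplateCandidate]:
    """Best-resolved structure per distinct receptor, at or under the cutoff
    and in the requested activity state."""
    eligible = [
        c
        for c in candidates
        if c.resolution <= cutoff and c.activity_state == state
    ]
    best: dict[str, TemplateCandidate] = {}
    for c in sorted(eligible, key=lambda c: (c.receptor_name, c.resolution, c.pdb_id)):
        best.setdefault(c.receptor_name, c)
    return sorted(best.values(), key=lambda c: c.pdb_id)


def hc_shortlist(correspondence: pd.DataFrame) -> list[str]:
    """Templates achieving the minimum per-residue SSD in >= 1 helix column
    (ties all retained); deterministic order by template id."""
    survivors: set[str] = set()
    for hid in HELIX_IDS:
        col = correspondence[hid]
        survivors.update(col.index[col == col.min()])
    return sorted(survivors)


def run_selection(
    target: tuple[ReceptorSequence, Sequence[TMAnnotation], Mapping[str, int]],
    candidates: Sequence[TemplateCandidate],
    config: Mapping[str, Any] | None = None,
    target_ligands: Sequence[ligmod.Ligand] | None = None,
) -> SelectionReport:
    """Run the full selection cascade and collect per-candidate metrics."""
    cfg = merge_config(config)
    tseq, ttms, tanchors = target
    stages: list[tuple[str, tuple[str, ...]]] = []
    metrics: dict[str, dict[str, Any]] = {
        c.pdb_id: {"receptor": c.receptor_name, "resolution": c.resolution}
        for c in candidates
    }
    by_id = {c.pdb_id: c for c in candidates}

    def record(name: str, ids: Sequence[str]) -> tuple[str, ...] | None:
        ids = tuple(sorted(ids))
        stages.append((name, ids))
        return ids or None

    # stage 1: resolution / activity state
    surv = record(
        "resolution",
        [c.pdb_id for c in filter_resolution(
            candidates, cfg["resolution_cutoff"], cfg["activity_state"]
        )],
    )
    if surv is None:
        return SelectionReport(stages, _metrics_frame(metrics), (), "resolution")

    # stage 2: hydrophobicity correspondence + identity
    corr = hydro.correspondence_table(
        (tseq, ttms), [(by_id[i].sequence, by_id[i].tms) for i in surv]
    )
    corr = corr.rename(index={by_id[i].sequence.id: i for i in surv})
    for pdb_id in surv:
        for hid in HELIX_IDS:
            metrics[pdb_id][f"ssd_{hid}"] = corr.loc[pdb_id, hid]
        metrics[pdb_id]["identity_pct"] = corr.loc[pdb_id, "identity_pct"]
        metrics[pdb_id]["mean_ssd"] = float(
            np.mean([corr.loc[pdb_id, h] for h in HELIX_IDS])
        )
    surv = record("hydrophobicity", hc_shortlist(corr))
    if surv is None:
        return SelectionReport(stages, _metrics_frame(metrics), (), "hydrophobicity")

    # stage 3: query coverage
    if cfg["coverage"]["enabled"]:
        cov = {i: query_coverage(tseq, by_id[i].sequence) for i in surv}
        for i, v in cov.items():
            metrics[i]["coverage_pct"] = v
        top_k = cfg["coverage"].get("top_k")
        if top_k:
            ranked = sorted(cov, key=lambda i: (-cov[i], i))
            keep_cut = sorted(cov.values(), reverse=True)[: int(top_k)][-1]
            surv = record("coverage", [i for i in ranked if cov[i] >= keep_cut])
        else:
            surv = record("coverage", list(surv))
        if surv is None:
            return SelectionReport(stages, _metrics_frame(metrics), (), "coverage")

    # stage 4: ligand profile (reported, not gating)
    if cfg["ligand_profile"]["enabled"] and target_ligands:
        with_ligand = [i for i in surv if by_id[i].ligand is not None]
        if with_ligand:
            comp = ligmod.profile_compare(
                list(target_ligands),
                [by_id[i].ligand for i in with_ligand],
                aggregate=cfg["ligand_profile"]["aggregate"],
            )
            for i in with_ligand:
                metrics[i]["ligand_profile"] = float(
                    comp.matrix.loc[by_id[i].ligand.id].median()
                    if cfg["ligand_profile"]["aggregate"] == "median"
                    else comp.matrix.loc[by_id[i].ligand.id].mean()
                )
        surv = record("ligand_profile", list(surv))

    # stage 5: pocket comparison
    if cfg["pocket"]["enabled"]:
        matrix = _resolve_matrix(cfg["pocket"]["matrix"])
        definition = _orthosteric_definition()
        tgt_bw = assign_bw_numbers(tseq, list(ttms), tanchors)
        tgt_pocket = pocketmod.extract_pocket(tseq, tgt_bw, definition)
        for i in surv:
            cand = by_id[i]
            bw = assign_bw_numbers(cand.sequence, list(cand.tms), cand.anchors)
            ext = pocketmod.extract_pocket(cand.sequence, bw, definition)
            comp = pocketmod.pocket_score(
                tgt_pocket.residues, ext.residues, matrix,
                predicate=cfg["pocket"]["predicate"],
            )
            metrics[i]["pocket_score"] = comp.score
            metrics[i]["pocket_similar_pct"] = comp.similar_pct
        surv = record("pocket", list(surv))

    frame = _metrics_frame(metrics)
    ranking = sorted(
        surv,
        key=lambda i: (
            -frame.loc[i].get("pocket_score", 0.0)
            if not pd.isna(frame.loc[i].get("pocket_score", np.nan))
            else math.inf,
            frame.loc[i].get("mean_ssd", math.inf),
            -frame.loc[i].get("coverage_pct", 0.0),
            i,
        ),
    )
    return SelectionReport(stages, frame, tuple(ranking))


def _metrics_frame(metrics: Mapping[str, Mapping[str, Any]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(metrics, orient="index").sort_index()
    df.index.name = "pdb_id"
    return df


def _resolve_matrix(spec: str) -> pocketmod.SubstitutionMatrix:
    from pathlib import Path

    if Path(spec).expanduser().exists():
        return pocketmod.SubstitutionMatrix.from_file(spec)
    if spec.lower() == "gpcrtm":
        from .fixtures import load_table

        return load_table("gpcrtm")
    return pocketmod.SubstitutionMatrix.from_biopython(spec)


def _orthosteric_definition() -> pocketmod.PocketDefinition:
    from .fixtures import load_table

    return load_table("orthosteric24")


# ---------------------------------------------------------------------------
# Stage-1 screen
# ---------------------------------------------------------------------------

@dataclass
class Stage1Result:
    hits: pd.DataFrame
    pharmacophore: apf.Pharmacophore
    provenance: dict[str, Any] = field(default_factory=dict)


def run_stage1_screen(
    actives: Sequence[ligmod.Ligand],
    library: Sequence[ligmod.Ligand],
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
    template_id: str | None = None,
) -> Stage1Result:
    """Build a consensus pharmacophore from the actives (superposed onto a
    designated template active) and screen the library against it."""
    cfg = merge_config(config)["apf"]
    if not actives:
        raise apf.APFError("no actives given")
    template_id = template_id or actives[0].id
    by_id = {l.id: l for l in actives}
    if template_id not in by_id:
        raise apf.APFError(f"template active {template_id!r} not among actives")
    template = by_id[template_id]
    if not template.has_conformer:
        raise apf.APFError(f"template active {template_id!r} lacks a conformer")

    sigma, spacing, padding = cfg["kernel_sigma"], cfg["spacing"], cfg["padding"]
    tpl_atoms = apf.assign_properties(template)
    tpl_field = apf.build_field([tpl_atoms], sigma, spacing, padding)

    aligned: list[tuple[np.ndarray, np.ndarray]] = [tpl_atoms]
    for lig in actives:
        if lig.id == template_id:
            continue
        if not lig.has_conformer:
            continue
        coords, props = apf.assign_properties(lig)
        transform, _ = apf.superpose(
            (coords, props), tpl_field,
            n_restarts=int(cfg["n_restarts"]),
            seed=apf._ligand_seed(seed, lig.id),
        )
        aligned.append((transform.apply(coords), props))

    geom = apf.grid_geometry([c for c, _ in aligned], spacing, padding)
    fields = [
        apf.build_field([s], sigma, spacing, padding, geometry=geom) for s in aligned
    ]
    if len(fields) >= 2:
        pharm = apf.consensus(fields, fraction=cfg["fraction"])
    else:
        pharm = apf.Pharmacophore(
            field=fields[0], included=(True,) * apf.N_CHANNELS,
            n_ligands=1, fraction=cfg["fraction"],
        )

    if library:
        hits = apf.screen(
            list(library), pharm, threshold=cfg["threshold"], seed=seed,
            n_restarts=int(cfg["n_restarts"]),
        )
    else:
        hits = pd.DataFrame(
            columns=["ligand_id", "score", "energy", "n_atoms_outside_grid"]
        )
    provenance = {
        "template_ligand": template_id,
        "n_actives": len(aligned),
        "included_channels": list(pharm.included_channels),
        "kernel": {"sigma": sigma, "spacing": spacing, "padding": padding},
        "fraction": cfg["fraction"],
        "threshold": cfg["threshold"],
        "n_restarts": int(cfg["n_restarts"]),
        "seed": seed,
    }
    return Stage1Result(hits=hits, pharmacophore=pharm, provenance=provenance)


def provenance_json(result: Stage1Result) -> str:
    return json.dumps(result.provenance, sort_keys=True, indent=2)
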