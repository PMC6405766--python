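"""One-stop per-structure analysis producing a machine-readable report.

Runs the full pipeline (axis fit, helical-parameter estimation, dihedrals
and strand assignment, twist statistic, neighbor counts, salt bridges,
stack-stack interface energy and optionally the layer-stability curve) and
collects everything into a JSON-serializable report.  Individual stage
failures are recorded per stage and do not abort the rest of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import (
    FibrilAxis,
    crossover_distance,
    detect_stacks,
    estimate_helical_parameters,
    fibril_width,
    fit_fibril_axis,
    strand_spacing,
)
from .interfaces import (
    interface_energy,
    layer_stability_curve,
    neighbor_count,
    salt_bridges,
)
from .model import MolecularModel
from .secondary import assign_strands, compute_dihedrals, twist_statistic


@dataclass
class AnalyzeConfig:
    """Configuration for :func:`analyze`.

    ``stack_a``/``stack_b`` give the stack partition explicitly; when both
    are None the partition is taken from model annotations or inferred by
    two-means clustering of the chain-centroid azimuths about the fibril
    axis.  ``layer_max > 0`` enables the layer-stability curve (built from
    the central chain of stack A and the estimated symmetry).
    """

    stack_a: list[str] | None = None
    stack_b: list[str] | None = None
    contact_cutoff: float = 5.0
    strand_method: str = "kabsch-sander"
    manual_ranges: dict[str, list[tuple[int, int]]] | None = None
    layer_max: int = 0
    t_delta_s: float = 12.0
    sasa_points: int = 960

    def to_dict(self) -> dict:
        return {
            "stack_a": self.stack_a,
            "stack_b": self.stack_b,
            "contact_cutoff": self.contact_cutoff,
            "strand_method": self.strand_method,
            "manual_ranges": self.manual_ranges,
            "layer_max": self.layer_max,
            "t_delta_s": self.t_delta_s,
            "sasa_points": self.sasa_points,
        }


@dataclass
class FibrilReport:
    """Structured analysis results; ``data`` is JSON-serializable."""

    data: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.data.get("stages", {}).values())

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.data, indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        """Flat key\\tvalue view of the scalar fields."""
        rows = []

        def walk(prefix: str, obj) -> None:
            if isinstance(obj, dict):
                for k in sorted(obj):
                    walk(f"{prefix}.{k}" if prefix else str(k), obj[k])
            elif isinstance(obj, (list, tuple)):
                rows.append((prefix, json.dumps(obj)))
            else:
                rows.append((prefix, obj))

        walk("", self.data)
        text = "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


REQUIRED_REPORT_KEYS = {
    "provenance": dict,
    "stages": dict,
    "symmetry": dict,
    "morphology": dict,
    "twist": dict,
    "neighbors": dict,
    "salt_bridges": list,
    "interface": dict,
}


def validate_report(data: dict) -> list[str]:
    """Return a list of schema violations (empty when valid)."""
    problems = []
    for key, typ in REQUIRED_REPORT_KEYS.items():
        if key not in data:
            problems.append(f"missing key: {key}")
        elif not isinstance(data[key], typ):
            problems.append(f"{key}: expected {typ.__name__}")
    return problems


def _central_chain(model: MolecularModel, stacks: dict[str, str],
                   axis: FibrilAxis, stack: str) -> str:
    members = [c for c in model.chains if stacks[c.chain_id] == stack]
    members.sort(key=lambda c: float(axis.axial(c.centroid())[0]))
    return members[len(members) // 2].chain_id


def analyze(model: MolecularModel, config: AnalyzeConfig | None = None) -> FibrilReport:
    """Run the full fibril analysis pipeline on a model.

    Deterministic for a given model+config.  Stage failures are caught and
    recorded under ``stages``; the remaining stages still run.
    """
    config = config or AnalyzeConfig()
    data: dict = {
        "provenance": {
            "input": model.metadata.get("source", "<in-memory>"),
            "version": __version__,
            "config": config.to_dict(),
        },
        "stages": {},
    }
    stages = data["stages"]

    axis = None
    try:
        axis = fit_fibril_axis(model)
        data["axis"] = {
            "point": [round(float(x), 4) for x in axis.point],
            "direction": [round(float(x), 6) for x in axis.direction],
        }
        stages["axis"] = "ok"
    except Exception as exc:  # noqa: BLE001 - per-stage error capture
        stages["axis"] = f"error: {exc}"

    if config.stack_a and config.stack_b:
        stacks = {c: "A" for c in config.stack_a}
        stacks.update({c: "B" for c in config.stack_b})
    elif axis is not None:
        stacks = detect_stacks(model, axis)
    else:
        stacks = model.stack_of()
    data["stacks"] = stacks

    sym = None
    try:
        annotated = model.copy()
        annotated.metadata["stack_of"] = stacks
        sym = estimate_helical_parameters(annotated, axis)
        data["symmetry"] = {
            "rise": round(sym.rise, 4),
            "twist": round(sym.twist, 4),
            "starts": sym.starts,
            "rise_sd": round(sym.rise_sd, 4),
            "twist_sd": round(sym.twist_sd, 4),
        }
        stages["symmetry"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["symmetry"] = f"error: {exc}"
        data["symmetry"] = {}

    try:
        morph = {}
        if sym is not None:
            co = crossover_distance(sym)
            morph["crossover_nm"] = (
                None if co.untwisted else round(co.distance_nm, 3)
            )
            morph["untwisted"] = co.untwisted
        if axis is not None:
            morph["width_nm"] = round(fibril_width(model, axis), 3)
            morph["strand_spacing"] = round(strand_spacing(annotated, axis), 4)
        data["morphology"] = morph
        stages["morphology"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["morphology"] = f"error: {exc}"
        data["morphology"] = {}

    try:
        dihedrals = compute_dihedrals(model)
        assignment = assign_strands(
            model, config.strand_method, config.manual_ranges
        )
        tw = twist_statistic(dihedrals, assignment)
        data["twist"] = {
            "n_residues": tw.n_residues,
            "mean_phi_plus_psi": round(tw.mean_phi_plus_psi, 3),
            "sd": round(tw.sd, 3),
            "handedness": tw.handedness,
        }
        stages["twist"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["twist"] = f"error: {exc}"
        data["twist"] = {}

    try:
        counts = {}
        if axis is not None:
            for stack in sorted(set(stacks.values())):
                cid = _central_chain(model, stacks, axis, stack)
                annotated2 = model.copy()
                annotated2.metadata["stack_of"] = stacks
                nc = neighbor_count(annotated2, cid, cutoff=config.contact_cutoff)
                counts[cid] = {
                    "total": nc.total,
                    "same_stack": nc.same_stack,
                    "cross_stack": nc.cross_stack,
                    "converged": nc.converged,
                }
        data["neighbors"] = counts
        stages["neighbors"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["neighbors"] = f"error: {exc}"
        data["neighbors"] = {}

    try:
        bridges = salt_bridges(model)
        data["salt_bridges"] = [
            {
                "acid": f"{sb.acid.chain_id}/{sb.acid.residue_name}{sb.acid.seq_id}",
                "base": f"{sb.base.chain_id}/{sb.base.residue_name}{sb.base.seq_id}",
                "min_distance": round(sb.min_distance, 3),
                "bidentate": sb.bidentate,
            }
            for sb in bridges
        ]
        stages["salt_bridges"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["salt_bridges"] = f"error: {exc}"
        data["salt_bridges"] = []

    try:
        groups = sorted(set(stacks.values()))
        if len(groups) == 2:
            a = {c for c, s in stacks.items() if s == groups[0]}
            b = {c for c, s in stacks.items() if s == groups[1]}
            ie = interface_energy(
                model, a, b, t_delta_s=config.t_delta_s, n_points=config.sasa_points
            )
            data["interface"] = {
                "buried_area": round(ie.buried_area, 2),
                "delta_g_int": round(ie.delta_g_int, 3),
                "t_delta_s": ie.t_delta_s,
                "delta_g_diss": round(ie.delta_g_diss, 3),
                "no_interface": ie.no_interface,
            }
        else:
            data["interface"] = {"no_interface": True, "note": "single stack"}
        stages["interface"] = "ok"
    except Exception as exc:  # noqa: BLE001
        stages["interface"] = f"error: {exc}"
        data["interface"] = {}

    if config.layer_max > 0 and sym is not None and axis is not None:
        try:
            cid = _central_chain(model, stacks, axis, sorted(set(stacks.values()))[0])
            subunit = MolecularModel([model.chain(cid).copy()])
            sym2 = sym if sym.starts == 2 else None
            if sym2 is None:
                raise ValueError("layer curve needs a two-stack fibril")
            curve = layer_stability_curve(
                subunit,
                sym2,
                range(1, config.layer_max + 1),
                t_delta_s=config.t_delta_s,
                n_points=config.sasa_points,
            )
            data["layer_curve"] = {
                "points": [[n, round(dg, 3)] for n, dg in curve.points],
                "crossing": curve.crossing_label,
                "per_layer_slope": round(curve.per_layer_slope, 3),
                "per_layer_mean": round(curve.per_layer_mean, 3),
            }
            stages["layer_curve"] = "ok"
        except Exception as exc:  # noqa: BLE001
            stages["layer_curve"] = f"error: {exc}"
            data["layer_curve"] = {}

    return FibrilReport(data)
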