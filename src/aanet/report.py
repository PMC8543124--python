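"""End-to-end analysis: parse -> profiles -> classification -> barcodes.

`run_analysis` executes the full pipeline on one structure file and writes a
deterministic set of exports: tidy profile table, plateau census, 1D/2D
barcodes, per-cutoff networks, fit diagnostics and a run manifest.  Re-running
with the same configuration and input yields byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .barcodes import Barcode1D, Barcode2D, build_barcode_1d, build_barcode_2d
from .classify import classify_structure, plateau_census
from .network import build_aan, write_edge_list, write_graphml
from .profiles import (DEFAULT_CUTOFFS, compute_profiles, fit_profile,
                       profiles_to_frame)
from .structure import AtomSelectionPolicy, Structure, parse_structure


@dataclass
class AnalysisConfig:
    input_path: str
    out_dir: str = "aanet_out"
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    include_hydrogens: bool = False
    chains: Optional[tuple[str, ...]] = None
    include_ligand: bool = True
    ligand_max_residues: int = 10
    plateau_rule: str = "strict"
    exclude_seq_adjacent: int = 0
    map_mse: bool = False
    write_networks: bool = True
    seed: int = 0  # recorded for fixture-producing commands; analysis is deterministic

    def policy(self) -> AtomSelectionPolicy:
        return AtomSelectionPolicy(
            include_hydrogens=self.include_hydrogens,
            chains=self.chains,
            map_nonstandard=(("MSE", "M"),) if self.map_mse else None,
        )


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    structure: Structure
    profiles: list
    calls: list
    census: dict
    barcode_1d: Barcode1D
    barcode_2d: Barcode2D
    fit_summary: dict
    manifest: dict
    paths: dict = field(default_factory=dict)


def analyze_structure(structure: Structure, config: AnalysisConfig) -> AnalysisReport:
    """Run the pipeline on an already-parsed structure (no file output)."""
    if not config.include_ligand:
        ligand = structure.ligand_chain_ids(config.ligand_max_residues)
        if ligand:
            keep = [c for c in structure.chain_ids() if c not in ligand]
            structure = structure.subset(keep)

    profiles = compute_profiles(structure, config.cutoffs,
                                exclude_seq_adjacent=config.exclude_seq_adjacent)
    calls = classify_structure(profiles, rule=config.plateau_rule)
    census = plateau_census(calls)
    barcode_1d = build_barcode_1d(calls)
    aans = {c: build_aan(structure, c, config.exclude_seq_adjacent)
            for c in config.cutoffs}
    barcode_2d = build_barcode_2d(structure, aans)

    weight_r2 = [fit_profile(p.weights, p.cutoffs, "quadratic").r_squared
                 for p in profiles]
    degree_r2 = [fit_profile(p.degrees, p.cutoffs, "linear").r_squared
                 for p in profiles]
    fit_summary = {
        "weight_quadratic_r2_median": float(np.median(weight_r2)),
        "weight_quadratic_r2_min": float(np.min(weight_r2)),
        "degree_linear_r2_median": float(np.median(degree_r2)),
    }

    manifest = {
        "tool": "aanet",
        "version": __version__,
        "config": _config_dict(config),
        "structure_id": structure.structure_id,
        "n_residues": len(structure),
        "n_atoms": structure.n_atoms(),
        "chains": structure.chain_ids(),
        "provenance": structure.provenance,
    }
    return AnalysisReport(config, structure, profiles, calls, census,
                          barcode_1d, barcode_2d, fit_summary, manifest)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Full pipeline on ``config.input_path`` plus deterministic file exports."""
    in_path = Path(config.input_path)
    pdb_text = in_path.read_text()
    structure = parse_structure(pdb_text, config.policy(),
                                structure_id=in_path.stem)
    report = analyze_structure(structure, config)
    report.manifest["input_sha256"] = hashlib.sha256(pdb_text.encode()).hexdigest()

    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        report.paths = _write_exports(report, out, config)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return report


def _config_dict(config: AnalysisConfig) -> dict:
    d = asdict(config)
    d["cutoffs"] = list(d["cutoffs"])
    if d["chains"] is not None:
        d["chains"] = list(d["chains"])
    return d


def _write_exports(report: AnalysisReport, out: Path, config: AnalysisConfig) -> dict:
    paths: dict[str, str] = {}

    def save(name: str, path: Path) -> Path:
        paths[name] = str(path)
        return path

    profiles_df = profiles_to_frame(report.profiles)
    profiles_df.to_csv(save("profiles", out / "profiles.csv"), index=False)

    with open(save("census", out / "census.json"), "w") as fh:
        json.dump(report.census, fh, indent=2, sort_keys=True)
        fh.write("\n")

    calls_rows = []
    for call in report.calls:
        calls_rows.append({
            "chain": call.residue_ref.chain_id,
            "resnum": call.residue_ref.seq_num,
            "restype": call.residue_ref.res_type,
            "label": call.label,
            "degenerate": call.degenerate,
            "segments": ";".join(call.segment_ranges),
            "deltas": ",".join(str(d) for d in call.deltas),
        })
    pd.DataFrame(calls_rows).to_csv(save("plateau_calls", out / "plateau_calls.tsv"),
                                    sep="\t", index=False)

    (save("barcode_1d_txt", out / "barcode_1d.txt")).write_text(
        report.barcode_1d.to_text() + "\n")
    with open(save("barcode_1d_json", out / "barcode_1d.json"), "w") as fh:
        fh.write(report.barcode_1d.to_json(indent=2))
        fh.write("\n")

    report.barcode_2d.to_frame().to_csv(
        save("barcode_2d", out / "barcode_2d.csv"), index=False,
        float_format="%.6f")

    with open(save("fits", out / "fit_summary.json"), "w") as fh:
        json.dump(report.fit_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if config.write_networks:
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for c in config.cutoffs:
            aan = build_aan(report.structure, c, config.exclude_seq_adjacent)
            label = f"{c:g}"
            (net_dir / f"edges_c{label}.tsv").write_text(
                write_edge_list(aan, report.structure))
            write_graphml(aan, report.structure, net_dir / f"aan_c{label}.graphml")
        paths["networks"] = str(net_dir)

    with open(save("manifest", out / "manifest.json"), "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
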