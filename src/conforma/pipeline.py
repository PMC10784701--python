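"""Orchestration: full conformational report and sequence/motif report.

``run_conformation_report`` loads the configured structures and, for every
configured (or discovered) protomer pair, runs the anchored superposition,
domain-rotation decomposition, displacement field, dihedral/kink table,
cavity volumes with the open/closed reduction matrix, interface areas and
ligand contacts, writing per-pair TSVs plus one machine-readable
``summary.json``. A failure in one pair is recorded and does not void the
rest of the report.

The default domain boundaries target a two-domain COMT-type methyltransferase
protomer: dimerization domain 5-131, interdomain helix 150-170, Rossmann-like
(cofactor-binding) domain 171-340. They are stated defaults, configurable per
structure, not facts about any particular deposition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Any

import numpy as np

from . import motion, surface
from .contacts import contacts_tsv, ligand_environment, salt_bridges
from .model import DomainDefinition, StructureModel, read_structure
from .motifs import (
    build_ssn,
    classify_catalytic,
    classify_motif_tier,
    map_positions,
    motif_fraction,
    read_fasta,
)

log = logging.getLogger("conforma.pipeline")

__all__ = ["RunConfig", "run_conformation_report", "run_motif_report", "DEFAULT_DOMAINS"]

#: default author-numbered domain boundaries for a COMT-type protomer
DEFAULT_DOMAINS = {
    "dimerization": (5, 131),
    "interdomain_helix": (150, 170),
    "rossmann": (171, 340),
}

#: a protomer counts as closed relative to another above this rotation (deg)
CLOSED_ANGLE_THRESHOLD = 5.0


@dataclass
class StructureEntry:
    label: str
    path: Path
    chains: list[str] | None = None  # None: all chains in the file
    ligands: list[str] = dataclass_field(default_factory=list)


@dataclass
class RunConfig:
    structures: list[StructureEntry]
    domains: dict[str, tuple[int, int]] = dataclass_field(
        default_factory=lambda: dict(DEFAULT_DOMAINS)
    )
    pairs: list[tuple[str, str]] | str = "all"  # ("label/chain", "label/chain") or "all"
    grid_spacing: float = 0.5
    probe_radius: float = 3.0
    sasa_probe: float = 1.4
    contact_cutoff: float = 4.0
    closed_angle_threshold: float = CLOSED_ANGLE_THRESHOLD
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        structures = []
        labels = set()
        for entry in raw.get("structures", []):
            label = entry["label"]
            if label in labels:
                raise ValueError(f"duplicate structure label {label!r}")
            labels.add(label)
            path = Path(entry["path"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            if not path.exists():
                raise FileNotFoundError(f"structure file not found: {path}")
            structures.append(
                StructureEntry(
                    label=label,
                    path=path,
                    chains=entry.get("chains"),
                    ligands=entry.get("ligands", []),
                )
            )
        if not structures:
            raise ValueError("config lists no structures")
        domains = {
            name: tuple(span) for name, span in raw.get("domains", DEFAULT_DOMAINS).items()
        }
        pairs = raw.get("pairs", "all")
        if pairs != "all":
            pairs = [tuple(p) for p in pairs]
        kwargs = {
            key: raw[key]
            for key in (
                "grid_spacing",
                "probe_radius",
                "sasa_probe",
                "contact_cutoff",
                "closed_angle_threshold",
                "seed",
            )
            if key in raw
        }
        return cls(structures=structures, domains=domains, pairs=pairs, **kwargs)


def _domain(config: RunConfig, name: str, chain_id: str) -> DomainDefinition:
    start, end = config.domains[name]
    return DomainDefinition(f"{name}:{chain_id}", [(chain_id, start, end)])


def _protomers(models: dict[str, StructureModel], config: RunConfig) -> list[tuple[str, str]]:
    out = []
    for entry in config.structures:
        model = models[entry.label]
        chains = entry.chains or sorted(model.chains)
        out.extend((entry.label, c) for c in chains)
    return out


def _analyse_pair(
    ref_model: StructureModel,
    ref_chain: str,
    mob_model: StructureModel,
    mob_chain: str,
    config: RunConfig,
    out_dir: Path,
    tag: str,
) -> dict[str, Any]:
    anchor = _domain(config, "dimerization", ref_chain)
    moving = _domain(config, "rossmann", ref_chain)

    # single-chain views so author numbering can be matched chain-to-chain
    ref_view = StructureModel(
        id=ref_model.id, chains={ref_chain: ref_model.chain(ref_chain)}
    )
    mob_view = StructureModel(
        id=mob_model.id, chains={ref_chain: mob_model.chain(mob_chain)}
    )

    mob_in_frame, anchor_fit = motion.domain_anchored_fit(ref_view, mob_view, anchor)
    rigid = motion.domain_rotation(ref_view, mob_in_frame, moving)
    disp = motion.displacement_field(ref_view, mob_in_frame, moving)
    (out_dir / f"{tag}.displacements.tsv").write_text(disp.to_tsv())

    dihed_ref = motion.backbone_dihedrals(ref_view, ref_chain)
    dihed_mob = motion.backbone_dihedrals(mob_in_frame, ref_chain)
    helix_span = config.domains.get("interdomain_helix")
    kinks = []
    if helix_span is not None:
        residues = [n for n in range(helix_span[0], helix_span[1] + 1) if n in dihed_ref.values]
        kinks = motion.kink_delta(dihed_ref, dihed_mob, residues)

    com_ref = motion.center_of_mass(ref_view, moving)
    com_mob = motion.center_of_mass(mob_in_frame, moving)

    return {
        "anchor_rmsd": anchor_fit.rmsd,
        "anchor_n_kept": anchor_fit.n_kept,
        "rotation": rigid.to_dict(),
        "displacement_stats": {
            k: (str(v) if not isinstance(v, (int, float)) else v)
            for k, v in disp.stats.items()
        },
        "rossmann_com_shift": float(np.linalg.norm(com_mob - com_ref)),
        "kinks": [
            {k: v for k, v in rec.items()}
            for rec in kinks
            if rec["max_delta"] is not None and rec["max_delta"] >= 10.0
        ],
        "is_closed_relative_to_ref": rigid.angle_deg >= config.closed_angle_threshold,
    }


def run_conformation_report(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run all pairwise conformational analyses; returns the summary dict.

    The summary (also written to ``summary.json``) indexes every per-pair
    output file and records every parameter actually used.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models = {e.label: read_structure(e.path) for e in config.structures}

    protomers = _protomers(models, config)
    if config.pairs == "all":
        pairs = [
            (a, b)
            for i, a in enumerate(protomers)
            for b in protomers[i + 1:]
        ]
    else:
        def parse(p: str) -> tuple[str, str]:
            label, chain = p.split("/")
            return label, chain

        pairs = [(parse(a), parse(b)) for a, b in config.pairs]

    summary: dict[str, Any] = {
        "parameters": {
            "domains": {k: list(v) for k, v in config.domains.items()},
            "grid_spacing": config.grid_spacing,
            "probe_radius": config.probe_radius,
            "sasa_probe": config.sasa_probe,
            "contact_cutoff": config.contact_cutoff,
            "closed_angle_threshold": config.closed_angle_threshold,
        },
        "pairs": {},
        "pockets": {},
        "cavity_reduction_pct": {},
        "interfaces": {},
        "contacts": {},
        "failures": {},
    }

    # per-protomer cavity volumes (ligands excluded by the detector)
    pocket_results = {}
    for label, chain in protomers:
        tag = f"{label}_{chain}"
        try:
            view = StructureModel(id=tag, chains={chain: models[label].chain(chain)})
            result = surface.pocket_volumes(
                view,
                grid_spacing=config.grid_spacing,
                probe_radius=config.probe_radius,
                keep_points=False,
            )
            pocket_results[(label, chain)] = result
            summary["pockets"][tag] = {
                "largest_volume_A3": result.pockets[0].volume if result.pockets else 0.0,
                "n_pockets": len(result.pockets),
            }
        except Exception as exc:  # noqa: BLE001 - failure isolation per protomer
            log.warning("pocket volumes failed for %s: %s", tag, exc)
            summary["failures"][f"pockets:{tag}"] = str(exc)

    for (ref_label, ref_chain), (mob_label, mob_chain) in pairs:
        tag = f"{ref_label}_{ref_chain}__{mob_label}_{mob_chain}"
        try:
            pair_summary = _analyse_pair(
                models[ref_label], ref_chain, models[mob_label], mob_chain,
                config, out_dir, tag,
            )
            ref_res = pocket_results.get((ref_label, ref_chain))
            mob_res = pocket_results.get((mob_label, mob_chain))
            if ref_res is not None and mob_res is not None and ref_res.pockets:
                try:
                    pair_summary["cavity_reduction_pct"] = surface.cavity_reduction(
                        ref_res, mob_res, "largest"
                    )
                    summary["cavity_reduction_pct"][tag] = pair_summary["cavity_reduction_pct"]
                except ValueError:
                    pass
            summary["pairs"][tag] = pair_summary
        except Exception as exc:  # noqa: BLE001
            log.warning("pair %s failed: %s", tag, exc)
            summary["failures"][tag] = str(exc)

    # homodimer interfaces and ligand contacts per structure
    for entry in config.structures:
        model = models[entry.label]
        chains = entry.chains or sorted(model.chains)
        if len(chains) >= 2:
            try:
                iface = surface.interface_area(
                    model, [chains[0]], [chains[1]], probe_radius=config.sasa_probe
                )
                summary["interfaces"][entry.label] = {
                    "chains": chains[:2],
                    "area_A2": iface.area,
                }
            except Exception as exc:  # noqa: BLE001
                summary["failures"][f"interface:{entry.label}"] = str(exc)
        for ligand in entry.ligands:
            try:
                records, per_res = ligand_environment(model, ligand, config.contact_cutoff)
                path = out_dir / f"{entry.label}.{ligand}.contacts.tsv"
                path.write_text(contacts_tsv(records))
                summary["contacts"][f"{entry.label}:{ligand}"] = {
                    "n_contacts": len(records),
                    "n_residues": len(per_res),
                    "table": path.name,
                }
            except Exception as exc:  # noqa: BLE001
                summary["failures"][f"contacts:{entry.label}:{ligand}"] = str(exc)
        try:
            bridges = salt_bridges(model)
            summary["contacts"][f"{entry.label}:salt_bridges"] = {"n": len(bridges)}
        except Exception as exc:  # noqa: BLE001
            summary["failures"][f"salt_bridges:{entry.label}"] = str(exc)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_motif_report(
    fasta_path: str | Path,
    out_dir: str | Path,
    reference_id: str | None = None,
    threshold: float = 29.0,
) -> dict[str, Any]:
    """Classify sequences against a reference and build the thresholded SSN.

    The reference is the named record (or the first record) in the FASTA;
    when the reference is a RedM-like sequence the mapped positions carry
    RedM numbering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(fasta_path)
    if reference_id is None:
        reference = records[0]
    else:
        matches = [r for r in records if r.id == reference_id]
        if not matches:
            raise ValueError(f"reference id {reference_id!r} not in FASTA")
        reference = matches[0]

    classifications, catalytic = {}, {}
    rows = ["id\ttier\this_253\ttyr_140\tpos153\tpos157\tpos297\tpos301"]
    for rec in records:
        pmap = map_positions(rec, reference)
        tier = classify_motif_tier(rec, pmap)
        flags = classify_catalytic(rec, pmap)
        classifications[rec.id] = tier
        catalytic[rec.id] = flags
        positions = "\t".join(
            str(pmap.mapping.get(p) if pmap.mapping.get(p) is not None else "gapped")
            for p in (153, 157, 297, 301)
        )
        rows.append(
            f"{rec.id}\t{tier.tier}\t{flags['his_253_equivalent']}\t"
            f"{flags['tyr_140_equivalent']}\t{positions}"
        )
    (out_dir / "classification.tsv").write_text("\n".join(rows) + "\n")

    summary: dict[str, Any] = {
        "n_sequences": len(records),
        "reference": reference.id,
        "threshold": threshold,
        "clusters": [],
    }
    if len(records) >= 2:
        ssn = build_ssn(records, threshold)
        (out_dir / "edges.tsv").write_text(ssn.edges_tsv())
        for i, cluster in enumerate(ssn.clusters):
            fractions = motif_fraction(cluster, classifications, catalytic)
            summary["clusters"].append(
                {"index": i, "size": len(cluster), "fractions": fractions}
            )
    (out_dir / "motif_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
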