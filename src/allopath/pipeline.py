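"""Two-state analysis workflow: per-state stage chain plus state comparison.

``run_state`` executes the full chain on one conformational ensemble —
frame slicing, alignment, PCA, cross-correlation, contact graph, edge
weighting, betweenness, Girvan-Newman communities, optional merging,
ball-and-stick graph and geometric probes — writing every intermediate as
TSV/JSON so each stage is inspectable. ``run_compare`` contrasts two state
bundles: differential cross-correlation map, per-community-pair summary and
signed stick-betweenness differences, the quantities that localise where a
perturbation rewires the communication network.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (
    CorrelationMatrix,
    ResidueLabel,
    block_summary,
    compute_dccm,
    differential_dccm,
)
from .errors import ConfigError, CongruenceError
from .essential_dynamics import PCModel, fit_pca, project_ensemble, variance_profile
from .geometry_probes import (
    HBondCriterion,
    dihedral_series,
    distance_series,
    group_distance_series,
    hbond_occupancy,
    series_stats,
)
from .network_analysis import (
    BetweennessMap,
    CommunityGraph,
    CommunityPartition,
    WeightedNetwork,
    build_contact_graph,
    community_graph,
    compare_networks,
    edge_betweenness,
    girvan_newman,
    merge_communities,
    weight_edges,
)
from .structure_io import (
    Ensemble,
    read_ensemble,
    read_structure,
    rmsd_series,
    select,
    slice_frames,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "reference", "chain", "dt", "window", "selection", "fit_selection",
    "align", "contact", "weighting", "modularity_weight", "merge",
    "exclude_residues", "probes", "states", "output_dir", "seed", "n_pcs",
}
_WINDOW_KEYS = {"t_start", "t_end", "stride"}
_CONTACT_KEYS = {"cutoff", "persistence", "exclude_neighbors"}
_WEIGHT_KEYS = {"scheme", "floor"}
_MERGE_KEYS = {"min_size", "plan"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_dict``)."""

    reference: str
    states: dict[str, dict]
    output_dir: str = "allopath_out"
    chain: str | None = None
    dt: float = 1.0
    window: dict = field(default_factory=lambda: {
        "t_start": 0.0, "t_end": float("inf"), "stride": 1})
    selection: str = "name CA"
    fit_selection: str = "name CA"
    align: bool = True
    contact: dict = field(default_factory=lambda: {
        "cutoff": None, "persistence": 0.75, "exclude_neighbors": 1})
    weighting: dict = field(default_factory=lambda: {
        "scheme": "log", "floor": 1e-4})
    modularity_weight: str = "coupling"
    merge: dict = field(default_factory=lambda: {"min_size": None, "plan": None})
    exclude_residues: list[str] = field(default_factory=list)
    probes: list[dict] = field(default_factory=list)
    seed: int = 0
    n_pcs: int = 2

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in (("window", _WINDOW_KEYS), ("contact", _CONTACT_KEYS),
                             ("weighting", _WEIGHT_KEYS), ("merge", _MERGE_KEYS)):
            sub = raw.get(key) or {}
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
        if "reference" not in raw or "states" not in raw:
            raise ConfigError("config must define 'reference' and 'states'")
        if not raw["states"]:
            raise ConfigError("'states' must name at least one state")
        cfg = cls(**{k: v for k, v in raw.items() if v is not None})
        merged_defaults = cls(reference=cfg.reference, states=cfg.states)
        for key in ("window", "contact", "weighting", "merge"):
            base = dict(getattr(merged_defaults, key))
            base.update(getattr(cfg, key) or {})
            setattr(cfg, key, base)
        if cfg.window["stride"] < 1:
            raise ConfigError("window.stride must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} is not a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StateBundle:
    """In-memory results of one per-state run (files live in ``outdir``)."""

    label: str
    outdir: Path
    ensemble: Ensemble
    dccm: CorrelationMatrix
    pca: PCModel
    network: WeightedNetwork
    betweenness: BetweennessMap
    partition: CommunityPartition
    graph: CommunityGraph
    probe_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _label_str(lab: ResidueLabel) -> str:
    return f"{lab[0]}:{lab[1]}"


def _parse_atom_spec(text: str) -> tuple:
    """Parse 'CHAIN RESNUM NAME' or 'RESNUM NAME' into an atom spec."""
    parts = text.split()
    if len(parts) == 3:
        return (parts[0], int(parts[1]), parts[2])
    if len(parts) == 2:
        return (None, int(parts[0]), parts[1])
    raise ConfigError(f"cannot parse atom spec {text!r}")


def _run_probes(cfg: RunConfig, ensemble: Ensemble) -> dict[str, pd.DataFrame]:
    rows = []
    summary = []
    for k, probe in enumerate(cfg.probes):
        kind = probe.get("type")
        label = probe.get("label", f"probe{k}")
        if kind == "distance":
            ser = distance_series(ensemble, _parse_atom_spec(probe["a"]),
                                  _parse_atom_spec(probe["b"]), label=label)
        elif kind == "group_distance":
            ser = group_distance_series(
                ensemble,
                select(ensemble.topology, probe["a_sel"]),
                select(ensemble.topology, probe["b_sel"]),
                mode=probe.get("mode", "min"), label=label)
        elif kind == "hbond":
            crit = HBondCriterion(
                donor=_parse_atom_spec(probe["donor"]),
                acceptor=_parse_atom_spec(probe["acceptor"]),
                hydrogen=(_parse_atom_spec(probe["hydrogen"])
                          if probe.get("hydrogen") else None),
                d_cutoff=probe.get("d_cutoff", HBondCriterion.d_cutoff),
                angle_cutoff=probe.get("angle_cutoff", HBondCriterion.angle_cutoff),
            )
            occ, series = hbond_occupancy(ensemble, crit)
            for t, v in zip(ensemble.times, series.astype(float)):
                rows.append((label, t, v))
            summary.append({"probe": label, "occupancy": occ})
            continue
        elif kind == "dihedral":
            specs = [_parse_atom_spec(s) for s in probe["atoms"]]
            ang = dihedral_series(ensemble, *specs)
            ser = None
            for t, v in zip(ensemble.times, ang):
                rows.append((label, t, v))
            summary.append({"probe": label, "mean": float(ang.mean()),
                            "sd": float(ang.std())})
            continue
        else:
            raise ConfigError(f"unknown probe type {kind!r}")
        for t, v in zip(ser.times, ser.values):
            rows.append((label, t, v))
        summary.append({"probe": label, **series_stats(ser)})
    tidy = pd.DataFrame(rows, columns=["probe", "time_ps", "value"])
    return {"probes": tidy, "probe_summary": pd.DataFrame(summary)}


def _write_dccm(path: Path, dccm: CorrelationMatrix) -> None:
    labels = [_label_str(l) for l in dccm.residue_labels]
    pd.DataFrame(dccm.values, index=labels, columns=labels) \
        .to_csv(path, sep="\t", float_format="%.6f")


def run_state(cfg: RunConfig, state_label: str) -> StateBundle:
    """Execute the full per-state chain and write its report files."""
    if state_label not in cfg.states:
        raise ConfigError(f"state {state_label!r} not in config")
    stage = "setup"
    try:
        outdir = Path(cfg.output_dir) / state_label
        outdir.mkdir(parents=True, exist_ok=True)
        reference = read_structure(cfg.reference, chain_id=cfg.chain)

        stage = "read"
        ens = read_ensemble(cfg.states[state_label]["trajectory"], dt=cfg.dt,
                            chain_id=cfg.chain)

        stage = "slice"
        ens = slice_frames(ens, cfg.window["t_start"], cfg.window["t_end"],
                           cfg.window["stride"])
        logger.info("[%s] %d frames after windowing", state_label, ens.n_frames)

        stage = "selection"
        sel = select(ens.topology, cfg.selection)
        fit = select(ens.topology, cfg.fit_selection)

        stage = "rmsd"
        rmsd = rmsd_series(ens, reference, fit)
        pd.DataFrame(rmsd, columns=["time_ps", "rmsd_A"]) \
            .to_csv(outdir / "rmsd.tsv", sep="\t", index=False)

        stage = "pca"
        ref_for_align = reference if cfg.align else None
        pca = fit_pca(ens, sel, reference, fit=fit, align=cfg.align)
        proj = project_ensemble(pca, ens, n_pcs=min(cfg.n_pcs, pca.n_components),
                                align=cfg.align)
        scatter = pd.DataFrame(proj, columns=[f"pc{i+1}" for i in range(proj.shape[1])])
        scatter.insert(0, "time_ps", ens.times)
        scatter.to_csv(outdir / "pc_projections.tsv", sep="\t", index=False)
        k = min(30, pca.n_components)
        spectrum = pd.DataFrame({
            "pc": np.arange(1, k + 1),
            "eigenvalue_A2": pca.eigenvalues[:k],
            "cumulative_variance": variance_profile(pca, k),
        })
        spectrum.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)

        stage = "dccm"
        dccm = compute_dccm(ens, sel, reference=ref_for_align, fit=fit)
        _write_dccm(outdir / "dccm.tsv", dccm)

        stage = "contact-graph"
        contacts = build_contact_graph(
            ens, cutoff=cfg.contact["cutoff"],
            persistence=cfg.contact["persistence"],
            exclude_neighbors=cfg.contact["exclude_neighbors"])

        stage = "weighting"
        network = weight_edges(contacts, dccm, scheme=cfg.weighting["scheme"],
                               floor=cfg.weighting["floor"])

        stage = "betweenness"
        bt = edge_betweenness(network)
        edge_rows = [
            (_label_str(a), _label_str(b), attrs["persistence"], attrs["corr"],
             attrs["length"], bt.values[(a, b)])
            for (a, b), attrs in sorted(network.edges.items())
        ]
        pd.DataFrame(edge_rows, columns=[
            "node_i", "node_j", "persistence", "corr", "length", "betweenness",
        ]).to_csv(outdir / "edges.tsv", sep="\t", index=False,
                  float_format="%.6f")

        stage = "communities"
        partition = girvan_newman(network, weight=cfg.modularity_weight)
        if cfg.merge.get("plan"):
            partition = merge_communities(
                partition, network,
                plan={int(k): int(v) for k, v in cfg.merge["plan"].items()},
                weight=cfg.modularity_weight)
        elif cfg.merge.get("min_size"):
            partition = merge_communities(partition, network,
                                          min_size=int(cfg.merge["min_size"]),
                                          weight=cfg.modularity_weight)
        comm_rows = [(lab[0], lab[1], c)
                     for lab, c in sorted(partition.labels.items())]
        pd.DataFrame(comm_rows, columns=["chain", "resnum", "community"]) \
            .to_csv(outdir / "communities.tsv", sep="\t", index=False)

        stage = "community-graph"
        exclude = {tuple([p.split(":")[0], int(p.split(":")[1])])
                   for p in cfg.exclude_residues}
        graph = community_graph(network, partition, bt, exclude_nodes=exclude)
        with open(outdir / "community_graph.json", "w") as fh:
            json.dump({
                "q": partition.q,
                "balls": {str(c): s for c, s in sorted(graph.balls.items())},
                "sticks": {f"{p}-{q}": v
                           for (p, q), v in sorted(graph.sticks.items())},
            }, fh, indent=2, sort_keys=True)

        stage = "probes"
        tables = _run_probes(cfg, ens)
        tables["probes"].to_csv(outdir / "probes.tsv", sep="\t", index=False)
        tables["probe_summary"].to_csv(outdir / "probe_summary.tsv", sep="\t",
                                       index=False)

        stage = "manifest"
        manifest = {
            "state": state_label,
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "allopath_version": __version__,
            "n_frames": int(ens.n_frames),
            "n_residues": len(dccm.residue_labels),
            "n_edges": len(network.edges),
            "modularity_q": partition.q,
            "n_communities": partition.n_communities(),
            "parameters": {
                "window": cfg.window, "contact": cfg.contact,
                "weighting": cfg.weighting,
                "modularity_weight": cfg.modularity_weight,
                "selection": cfg.selection, "align": cfg.align,
            },
            "files": sorted(p.name for p in outdir.iterdir()),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return StateBundle(state_label, outdir, ens, dccm, pca, network, bt,
                           partition, graph, tables, manifest)
    except Exception as exc:
        raise type(exc)(f"[state {state_label}, stage {stage}] {exc}") from exc


def run_compare(a: StateBundle, b: StateBundle,
                label_map: dict[int, int] | None = None,
                outdir: str | Path | None = None) -> dict:
    """Contrast two state bundles (b − a) and write the comparison report."""
    if a.dccm.residue_labels != b.dccm.residue_labels:
        raise CongruenceError("states analyse different residue sets")
    diff = differential_dccm(b.dccm, a.dccm)
    partition = {lab: a.partition.labels[lab] for lab in a.dccm.residue_labels}
    blocks = block_summary(diff, partition, a.dccm.residue_labels)
    sticks = compare_networks(a.graph, b.graph, label_map)
    result = {
        "labels": (a.label, b.label),
        "differential_dccm": diff,
        "block_summary": blocks,
        "stick_differences": sticks,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        labels = [_label_str(l) for l in a.dccm.residue_labels]
        pd.DataFrame(diff, index=labels, columns=labels) \
            .to_csv(outdir / "differential_dccm.tsv", sep="\t",
                    float_format="%.6f")
        pd.DataFrame(
            [(str(p), str(q), v) for (p, q), v in sorted(blocks.items())],
            columns=["community_i", "community_j", "mean_abs_dC"],
        ).to_csv(outdir / "dccm_block_summary.tsv", sep="\t", index=False,
                 float_format="%.6f")
        pd.DataFrame(
            [(p, q, v) for (p, q), v in sticks],
            columns=["community_i", "community_j", "stick_diff"],
        ).to_csv(outdir / "stick_differences.tsv", sep="\t", index=False,
                 float_format="%.6f")
    return result
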