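"""End-to-end orchestration of the descriptor → reactivity → chemometrics workflow."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .chemometrics import Dendrogram, PCAResult, cut_clusters, pca, ward_hca, zscore
from .descriptors import (
    DESCRIPTOR_NAMES,
    canonicalize,
    compute_descriptors,
    descriptor_frame,
    normalize,
)
from .multipole import (
    MoleculeMultipoles,
    read_energy_table,
    read_punch_file,
    write_descriptor_report,
)
from .reactivity import correlate_reactivity, reactivity_frame

__all__ = ["RunConfig", "load_molecules", "run_descriptors", "run_full_analysis"]

#: convention choices recorded into every run manifest
CONVENTIONS = {
    "magnitude": "euclidean norm of the five real spherical components (Stone)",
    "ring_atom_sums": "sum of per-site magnitudes over the six ring atoms",
    "translated_descriptors": "magnitude/Q20 of the summed translated tensor",
    "zscore_sd": "population (divide-by-n)",
    "ward_heights": "objective increase dESS; scipy Ward.D2 scale = sqrt(2*dESS)",
    "length_conversion_bohr_per_angstrom": 1.8897261254578281,
    "hartree_to_eV": 27.211386245988,
}


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run."""

    inputs: list[str] = field(default_factory=list)   # punch files
    energy_table: str | None = None
    unit: str | None = None                           # override file units
    ring_atoms: dict[str, list[int]] = field(default_factory=dict)  # per molecule name
    reference: str | None = None
    normalize: bool = True
    z_grid: tuple[float, float, float] = (0.1, 3.0, 0.05)
    k: int = 4
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.z_grid is not None:
            cfg.z_grid = tuple(cfg.z_grid)  # type: ignore[assignment]
        return cfg


def load_molecules(config: RunConfig) -> list[MoleculeMultipoles]:
    """Read, annotate and canonicalize every input molecule."""
    if not config.inputs:
        raise ValueError("no input molecules configured")
    molecules = []
    for path in config.inputs:
        kwargs = {}
        if config.unit is not None:
            kwargs["default_unit"] = config.unit
        mol = read_punch_file(path, **kwargs)
        override = config.ring_atoms.get(mol.name, config.ring_atoms.get(Path(path).stem))
        if override is not None:
            mol.ring_atom_indices = list(override)
        if not mol.ring_atom_indices:
            raise ValueError(
                f"{path}: no ring-atom designation (file 'ring' line or config ring_atoms)"
            )
        molecules.append(canonicalize(mol))
    return molecules


def run_descriptors(config: RunConfig) -> pd.DataFrame:
    """Compute the raw (and, if configured, normalized) descriptor table."""
    molecules = load_molecules(config)
    dsets = {m.name: compute_descriptors(m) for m in molecules}
    if config.normalize:
        if config.reference is None or config.reference not in dsets:
            raise ValueError(
                f"reference molecule {config.reference!r} not among inputs"
            )
        ref = dsets[config.reference]
        dsets = {name: normalize(d, ref) for name, d in dsets.items()}
    table = descriptor_frame(list(dsets.values()))
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_descriptor_report(table, out / "descriptors.csv")
        _write_manifest(out, config, stages=["descriptors"])
    return table


def run_full_analysis(config: RunConfig) -> dict:
    """Descriptors, reactivity, R² correlations, PCA, Ward HCA, k-cut.

    Returns a dict of artifacts; when ``config.outdir`` is set, every
    table is written as CSV, the dendrogram as JSON, and a run manifest
    records seeds, conventions and versions.
    """
    artifacts: dict = {}
    field_values = {f.name: getattr(config, f.name) for f in fields(RunConfig)}
    table = run_descriptors(RunConfig(**{**field_values, "outdir": None}))
    artifacts["descriptors"] = table

    norm_cols = [f"{c}_norm" for c in DESCRIPTOR_NAMES]
    cluster_input = table[norm_cols] if config.normalize else table[list(DESCRIPTOR_NAMES)]

    z = zscore(cluster_input)
    pca_result: PCAResult = pca(z)
    dendro: Dendrogram = ward_hca(z)
    labels = cut_clusters(dendro, config.k)
    artifacts["pca"] = pca_result
    artifacts["scores"] = pca_result.scores_frame(2)
    artifacts["dendrogram"] = dendro
    artifacts["labels"] = pd.Series(labels, index=cluster_input.index, name="cluster")

    if config.energy_table is not None:
        records = read_energy_table(config.energy_table)
        react = reactivity_frame(records)
        artifacts["reactivity"] = react
        r2, n_used = correlate_reactivity(cluster_input, react)
        artifacts["r2"] = r2
        artifacts["r2_n"] = n_used

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_descriptor_report(table, out / "descriptors.csv")
        artifacts["scores"].to_csv(out / "pca_scores.csv", float_format="%.17g")
        artifacts["labels"].to_csv(out / "clusters.csv")
        with open(out / "dendrogram.json", "w") as fh:
            json.dump({"labels": dendro.labels, "merges": dendro.to_records()}, fh, indent=1)
        if "reactivity" in artifacts:
            artifacts["reactivity"].to_csv(out / "reactivity.csv", float_format="%.17g")
            artifacts["r2"].to_csv(out / "r2.csv", float_format="%.17g")
            artifacts["r2_n"].to_csv(out / "r2_n.csv")
        _write_manifest(out, config, stages=sorted(artifacts))
        _write_plots(out, artifacts)
    return artifacts


def _write_manifest(out: Path, config: RunConfig, stages: Sequence[str]) -> None:
    manifest = {
        "package": "q2arom",
        "version": __version__,
        "seed": config.seed,
        "k": config.k,
        "reference": config.reference,
        "unit_override": config.unit,
        "stages": list(stages),
        "conventions": CONVENTIONS,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def _write_plots(out: Path, artifacts: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    scores = artifacts["scores"]
    labels = artifacts["labels"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for cl in sorted(labels.unique()):
        sel = labels == cl
        ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"], label=f"cluster {cl}", s=25)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "pca_clusters.png", dpi=150)
    plt.close(fig)

    dendro: Dendrogram = artifacts["dendrogram"]
    fig, ax = plt.subplots(figsize=(6, 4))
    scipy_dendrogram(dendro.to_scipy_linkage(), labels=dendro.labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel("Ward distance (sqrt(2*dESS))")
    fig.tight_layout()
    fig.savefig(out / "dendrogram.png", dpi=150)
    plt.close(fig)
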