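"""File formats, run configuration and seed management.

Everything on disk is plain text: phenotype and association tables are
UTF-8 TSV with '.' decimals and ``NA`` missing markers, gene networks are
edge-list TSV (gene_a, gene_b, weight) with a companion node-covariate
TSV, gene sets are GMT, ground truth and run reports are JSON.  One
global seed fans out to per-stage child seeds by stable hashing so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .catalogue import SECTIONS
from .cohort import METADATA_COLUMNS, GroundTruth

NA = "NA"


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------- phenotype

def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.17g")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Typed phenotype table from TSV; schema violations are errors."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if df["animal_id"].duplicated().any():
        dup = df["animal_id"][df["animal_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate animal_id {dup!r}")
    if df["necropsy_date"].isna().any():
        rows = (df.index[df["necropsy_date"].isna()] + 2).tolist()
        raise ValueError(f"necropsy_date missing on line(s) {rows}")
    # validate date format without altering the stored representation
    pd.to_datetime(df["necropsy_date"], format="%Y-%m-%d")
    pcols = [c for c in df.columns if c not in METADATA_COLUMNS]
    bad = []
    for c in pcols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            bad.append(c)
    if bad:
        raise ValueError(f"non-numeric values in parameter column(s): {bad}")
    return df


# ---------------------------------------------------------------- catalogue

def write_catalogue(cat: pd.DataFrame, path: str | Path) -> None:
    cat.to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t")
    required = {"parameter_id", "category", "section"}
    if not required <= set(cat.columns):
        raise ValueError(f"catalogue needs columns {sorted(required)}")
    unknown = set(cat["section"]) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown section(s) {sorted(unknown)}")
    return cat.set_index("parameter_id", drop=False)


# ---------------------------------------------------------------- networks

def write_network(net: nx.Graph, edges_path: str | Path,
                  nodes_path: str | Path | None = None) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d.get("weight", 1.0)}
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False, float_format="%.12g"
    )
    if nodes_path is not None:
        nrows = [
            {"gene": n, **{k: v for k, v in d.items()}}
            for n, d in net.nodes(data=True)
        ]
        pd.DataFrame(nrows).to_csv(nodes_path, sep="\t", index=False,
                                   float_format="%.12g")


def read_network(edges_path: str | Path,
                 nodes_path: str | Path | None = None) -> nx.Graph:
    edges = pd.read_csv(edges_path, sep="\t")
    g = nx.Graph()
    for _, r in edges.iterrows():
        g.add_edge(r["gene_a"], r["gene_b"], weight=float(r.get("weight", 1.0)))
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path, sep="\t")
        for _, r in nodes.iterrows():
            attrs = r.drop("gene").to_dict()
            if r["gene"] in g:
                g.nodes[r["gene"]].update(attrs)
            else:
                g.add_node(r["gene"], **attrs)
    return g


# ---------------------------------------------------------------- gene sets

def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------- truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_effects": [
            {"line_id": l, "parameter_id": p, "effect": e}
            for (l, p), e in truth.planted_effects.items()
        ],
        "planted_modules": truth.planted_modules,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_effects={
            (r["line_id"], r["parameter_id"]): r["effect"]
            for r in payload["planted_effects"]
        },
        planted_modules=payload.get("planted_modules", {}),
    )


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults follow the screen."""

    out_dir: str = "napmap_run"
    seed: int = 0
    # simulation
    n_lines: int = 100
    replicates_per_line: int = 3
    n_wt: int = 100
    n_batches: int = 10
    batch_sd_frac: float = 0.02
    fraction_nap: float = 0.1
    wt_cv: float = 0.05
    missing_rate: float = 0.0
    n_params_coronal: int = 24
    n_params_sagittal: int = 10
    # thresholds / permutation counts
    bh_threshold: float = 0.1
    binarize_cutoff: float = 0.05
    fdr_permutations: int = 100
    network_permutations: int = 1000
    convergence_permutations: int = 1000
    # flags
    impute: bool = False
    bh_family: str = "global"
    smoothed_p: bool = False
    # network simulation
    n_modules: int = 4
    p_in: float = 0.3
    p_out: float = 0.02

    def __post_init__(self) -> None:
        for name in ("bh_threshold", "binarize_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("fdr_permutations", "network_permutations",
                     "convergence_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
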