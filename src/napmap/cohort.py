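"""Synthetic screen generator.

Emulates the data structure of a large mouse neuroanatomical phenotyping
screen: many mutant lines, each with a handful of biological replicates,
measured against one large shared wild-type pool, with necropsy-date batch
structure, planted effect sizes stratified over the four severity bands,
and missing-at-random gaps.  Companion generators produce gene networks
with planted functional modules, gene-level annotation tables (CDS length,
constraint scores, ortholog map) and gene sets with controlled overlap
with the planted ground truth, so every downstream stage of the pipeline
can be exercised and validated without external data.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .catalogue import ParameterDef, catalogue_frame

#: Sentinel line_id of the shared wild-type pool.
WT_LINE = "WT"

METADATA_COLUMNS = [
    "animal_id",
    "line_id",
    "gene",
    "zygosity",
    "background",
    "necropsy_date",
]

#: Severity-band boundaries for |percent change| (half-open on the left).
SEVERITY_BANDS = {
    "mild": (0.0, 10.0),
    "moderate": (10.0, 20.0),
    "severe": (20.0, 40.0),
    "very_severe": (40.0, np.inf),
}
SEVERITY_ORDER = ("mild", "moderate", "severe", "very_severe")


class CohortSpecError(ValueError):
    """Raised when a cohort specification is invalid; names the field."""


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic screen.

    Parameters
    ----------
    n_lines
        Number of mutant lines (one gene per line).
    replicates_per_line
        Biological replicates per line; the screen design uses 3.
    n_wt
        Size of the shared wild-type pool.
    n_batches
        Number of necropsy-date batches; a line's replicates share one
        batch while wild types are spread round-robin over all batches,
        mirroring the shared-control design.
    batch_sd_frac
        SD of the multiplicative (log-scale) batch random effect, as a
        fraction of the wild-type mean.
    animal_sd_frac
        SD of an optional per-animal common size factor shared by all
        parameters (log scale).  Real parameter panels are positively
        correlated because brain structures scale together; switch this
        on to emulate that structure (it also makes covariance-aware
        imputation informative).  Default 0: parameters independent given
        batch, the baseline measurement model.
    fraction_nap
        Fraction of lines with a planted neuroanatomical phenotype.
    effect_band_weights
        Sampling weights over the four severity bands
        (mild, moderate, severe, very_severe); must sum to 1.
    direction_weights
        Per-line probabilities of the (decrease, increase, bidirectional)
        direction classes; defaults follow the proportions observed in
        the screen (46% / 38% / 16%).  A bidirectional line with at
        least two affected parameters always gets both signs.
    max_affected_params
        Planted lines affect 1..max_affected_params parameters, uniformly.
    missing_rate
        Probability each measurement cell is missing.
    seed
        Generator seed.
    """

    n_lines: int
    replicates_per_line: int = 3
    n_wt: int = 100
    n_batches: int = 10
    batch_sd_frac: float = 0.02
    animal_sd_frac: float = 0.0
    fraction_nap: float = 0.0
    effect_band_weights: tuple[float, float, float, float] = (0.1, 0.2, 0.4, 0.3)
    direction_weights: tuple[float, float, float] = (0.46, 0.38, 0.16)
    max_affected_params: int = 3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "replicates_per_line", "n_wt", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise CohortSpecError(f"{name} must be a positive integer")
        if self.batch_sd_frac < 0:
            raise CohortSpecError("batch_sd_frac must be non-negative")
        if self.animal_sd_frac < 0:
            raise CohortSpecError("animal_sd_frac must be non-negative")
        if not 0 <= self.fraction_nap <= 1:
            raise CohortSpecError("fraction_nap must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise CohortSpecError("missing_rate must be in [0, 1)")
        w = np.asarray(self.effect_band_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise CohortSpecError(
                "effect_band_weights must be 4 non-negative reals summing to 1"
            )
        if self.max_affected_params < 1:
            raise CohortSpecError("max_affected_params must be >= 1")
        dw = np.asarray(self.direction_weights, dtype=float)
        if dw.shape != (3,) or (dw < 0).any() or abs(dw.sum() - 1.0) > 1e-9:
            raise CohortSpecError(
                "direction_weights must be 3 non-negative reals summing to 1"
            )


@dataclass
class GroundTruth:
    """Planted signal of a synthetic screen."""

    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_modules: dict[str, int | None] = field(default_factory=dict)

    @property
    def nap_lines(self) -> set[str]:
        return {line for line, _ in self.planted_effects}

    @property
    def nap_genes(self) -> set[str]:
        """Gene ids of planted lines (line ``L0007`` carries gene ``Gene0007``)."""
        return {line_to_gene(line) for line in self.nap_lines}


def line_to_gene(line_id: str) -> str:
    return "Gene" + line_id[1:] if line_id.startswith("L") else line_id


def _sample_magnitude(rng: np.random.Generator, band_weights: np.ndarray) -> float:
    """Fractional effect magnitude drawn from a severity band."""
    band = SEVERITY_ORDER[rng.choice(4, p=band_weights)]
    lo, hi = SEVERITY_BANDS[band]
    hi = min(hi, 150.0)  # very-severe magnitudes capped at +150% / −75%
    return rng.uniform(lo, hi) / 100.0


def _sample_signs(rng: np.random.Generator, k: int,
                  direction_weights) -> np.ndarray:
    """Signs for a line's k planted effects given its direction class."""
    cls = rng.choice(3, p=np.asarray(direction_weights, dtype=float))
    if cls == 0:
        return -np.ones(k)
    if cls == 1:
        return np.ones(k)
    if k == 1:  # a one-parameter line cannot be bidirectional
        return np.array([-1.0 if rng.random() < 0.5 else 1.0])
    signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
    if (signs > 0).all() or (signs < 0).all():
        signs[rng.integers(k)] *= -1.0
    return signs


def simulate_cohort(
    spec: CohortSpec, params: list[ParameterDef]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic screen.

    Each measurement is
    ``wt_mean * (1 + effect) * exp(batch + animal + noise)`` with
    log-scale noise SD set so the parameter-specific multiplicative
    coefficient of variation equals ``wt_cv``, plus a per-animal common
    size factor shared by every parameter; wild types carry effect 0.
    Returns the animals × (metadata + parameters) table and the ground
    truth of planted effects.
    """
    if not params:
        raise CohortSpecError("params must be non-empty")
    cat = catalogue_frame(params)
    rng = np.random.default_rng(spec.seed)

    n_rep = spec.replicates_per_line
    n_rows = spec.n_wt + spec.n_lines * n_rep
    line_ids = [f"L{i:04d}" for i in range(1, spec.n_lines + 1)]

    lines = [WT_LINE] * spec.n_wt + [l for l in line_ids for _ in range(n_rep)]
    genes = [line_to_gene(l) for l in lines]
    # WTs round-robin over batches; a line's replicates share one batch.
    batch_of_line = {l: i % spec.n_batches for i, l in enumerate(line_ids)}
    batches = [i % spec.n_batches for i in range(spec.n_wt)] + [
        batch_of_line[l] for l in line_ids for _ in range(n_rep)
    ]
    dates = pd.to_datetime("2009-01-05") + pd.to_timedelta(
        np.asarray(batches) * 7, unit="D"
    )

    meta = pd.DataFrame(
        {
            "animal_id": [f"A{i:05d}" for i in range(1, n_rows + 1)],
            "line_id": lines,
            "gene": genes,
            "zygosity": ["wt" if l == WT_LINE else "hom" for l in lines],
            "background": "pure_B6N",
            "necropsy_date": dates.strftime("%Y-%m-%d"),
        }
    )

    # Plant effects: the first round(fraction_nap * n_lines) lines are NAP.
    truth = GroundTruth()
    n_nap = int(round(spec.fraction_nap * spec.n_lines))
    band_w = np.asarray(spec.effect_band_weights, dtype=float)
    pids = list(cat["parameter_id"])
    for line in line_ids[:n_nap]:
        k = min(int(rng.integers(1, spec.max_affected_params + 1)), len(pids))
        affected = rng.choice(len(pids), size=k, replace=False)
        signs = _sample_signs(rng, k, spec.direction_weights)
        for j, sign in zip(affected, signs):
            mag = _sample_magnitude(rng, band_w)
            if sign < 0:
                mag = min(mag, 0.75)  # areas stay positive
            truth.planted_effects[(line, pids[j])] = float(sign * mag)

    # date effects are parameter-specific: processing drift hits each
    # measurement differently even within one necropsy window
    batch_eff = rng.normal(0.0, spec.batch_sd_frac,
                           size=(spec.n_batches, len(pids)))
    animal_eff = rng.normal(0.0, spec.animal_sd_frac, size=n_rows)
    batch_arr = np.asarray(batches)
    effect = np.zeros((n_rows, len(pids)))
    for (line, pid), e in truth.planted_effects.items():
        effect[np.asarray(lines) == line, pids.index(pid)] = e

    wt_mean = cat["wt_mean"].to_numpy()
    sigma = np.sqrt(np.log1p(cat["wt_cv"].to_numpy() ** 2))
    noise = rng.normal(0.0, 1.0, size=(n_rows, len(pids))) * sigma
    values = wt_mean * (1.0 + effect) * np.exp(
        batch_eff[batch_arr, :] + animal_eff[:, None] + noise
    )

    table = pd.concat(
        [meta, pd.DataFrame(values, columns=pids)], axis=1
    )
    if spec.missing_rate > 0:
        table = inject_missingness(
            table, spec.missing_rate, seed=int(rng.integers(2**31))
        )
    return table, truth


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask each measurement cell independently with probability ``rate``.

    Metadata columns are never masked; the mask is reproducible under the
    seed.  ``rate >= 1`` is rejected.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    out = table.copy()
    if rate == 0:
        return out
    pcols = [c for c in table.columns if c not in METADATA_COLUMNS]
    rng = np.random.default_rng(seed)
    mask = rng.random((len(table), len(pcols))) < rate
    vals = out[pcols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[pcols] = vals
    return out


def simulate_network(
    n_genes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    seed: int,
    genes: list[str] | None = None,
) -> nx.Graph:
    """Planted-partition gene network.

    Nodes are split into ``n_modules`` near-equal modules; an edge appears
    within a module with probability ``p_in`` and between modules with
    ``p_out`` (requires ``p_out < p_in``, otherwise the planted structure
    is undetectable by construction).  Edge weights are uniform in (0, 1];
    each node carries a log-normal ``cds_length``, its planted ``module``
    label, and ``connectivity`` (weighted degree).
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"Gene{i:04d}" for i in range(1, n_genes + 1)]
    if len(genes) != n_genes:
        raise ValueError("len(genes) must equal n_genes")
    module = np.arange(n_genes) % n_modules
    g = nx.Graph()
    cds = np.exp(rng.normal(np.log(1500.0), 0.6, size=n_genes))
    for i, gene in enumerate(genes):
        g.add_node(gene, module=int(module[i]), cds_length=float(cds[i]))
    iu, ju = np.triu_indices(n_genes, k=1)
    p_edge = np.where(module[iu] == module[ju], p_in, p_out)
    present = rng.random(len(iu)) < p_edge
    w = 1.0 - rng.random(present.sum())  # uniform in (0, 1]
    for a, b, weight in zip(iu[present], ju[present], w):
        g.add_edge(genes[a], genes[b], weight=float(weight))
    for gene in g.nodes:
        g.nodes[gene]["connectivity"] = float(
            sum(d["weight"] for _, _, d in g.edges(gene, data=True))
        )
    return g


#: Constraint metrics and the direction in which stronger constraint moves
#: them: +1 means constrained genes score higher (pLI, s_het, HIS), −1 means
#: lower (dN/dS, RVIS).
CONSTRAINT_DIRECTIONS = {
    "dn_ds": -1, "s_het": +1, "rvis": -1, "pli": +1, "his": +1,
}


def simulate_gene_annotations(
    genes: list[str],
    truth: GroundTruth | set[str],
    assoc_strength: float,
    seed: int,
) -> pd.DataFrame:
    """Synthetic gene-level annotation table.

    Constraint scores are standard-normal latents; genes carrying a planted
    phenotype are shifted by ``assoc_strength`` SDs in each metric's
    constrained direction.  ``pli`` is squashed to (0, 1) through a
    logistic link to match its probability scale.  Every gene gets a CDS
    length and a 1:1 ortholog identifier.
    """
    if assoc_strength < 0:
        raise ValueError("assoc_strength must be >= 0")
    nap = truth.nap_genes if isinstance(truth, GroundTruth) else set(truth)
    rng = np.random.default_rng(seed)
    n = len(genes)
    is_nap = np.array([g in nap for g in genes])
    tab = pd.DataFrame({"gene_id": genes})
    for metric, direction in CONSTRAINT_DIRECTIONS.items():
        z = rng.normal(size=n) + assoc_strength * direction * is_nap
        tab[metric] = 1.0 / (1.0 + np.exp(-z)) if metric == "pli" else z
    tab["cds_length"] = np.exp(rng.normal(np.log(1500.0), 0.6, size=n)).round(0)
    tab["ortholog_id"] = [g.upper() for g in genes]
    return tab


def simulate_gene_sets(
    genes: list[str],
    set_specs: list[tuple[str, int, float]],
    truth: GroundTruth | set[str],
    seed: int,
) -> dict[str, list[str]]:
    """Named gene sets with controlled overlap with the planted NAP genes.

    Each spec is ``(name, size, overlap_with_truth)`` where the overlap is
    the fraction of the set drawn from planted-NAP genes (the rest from the
    remaining genes).  Sets are GMT-serialisable via :mod:`napmap.io`.
    """
    nap = sorted(truth.nap_genes if isinstance(truth, GroundTruth) else set(truth))
    non_nap = sorted(set(genes) - set(nap))
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for name, size, overlap in set_specs:
        if size < 1:
            raise ValueError(f"gene set {name!r} must have size >= 1")
        if size > len(genes):
            raise ValueError(f"gene set {name!r} larger than the gene universe")
        k = int(round(size * overlap))
        if k > len(nap) or size - k > len(non_nap):
            raise ValueError(
                f"gene set {name!r}: requested overlap exceeds available genes"
            )
        chosen = list(rng.choice(nap, size=k, replace=False)) + list(
            rng.choice(non_nap, size=size - k, replace=False)
        )
        out[name] = sorted(chosen)
    return out
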