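"""Synthetic response matrices and single-cell counts with planted truth.

The response simulator draws each drug's ln(IC50) profile from a log-normal
IC50 model (Normal on the ln scale with per-drug hyperparameters), shifts a
chosen refractory subset of lines upward for the primary drug, and plants
secondary drugs whose sensitive tertiles jointly cover that subset by
shifting an assigned partition of the refractory lines downward.  Because
tertile categorization is rank-based, the exact noise family only matters
through the separation the effect size buys.

The single-cell simulator emulates a droplet-style UMI count matrix:
negative-binomial counts with cluster-specific means and per-cluster
"program" gene sets whose means are elevated in their home cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .response_data import DoseResponseMatrix
from .sc_screen import SingleCellCounts

DEFAULT_PRIMARY = "PRIMARY"

# metadata values the default filtering criteria accept (B-cell blood cancer)
DEFAULT_CRITERIA: dict[str, list[str]] = {
    "target_cell": ["B-cell"],
    "cancer_type": ["blood"],
    "tissue": ["blood"],
    "histology": ["lymphoid_neoplasm", "haematopoietic_neoplasm"],
    "site": ["haematopoietic_and_lymphoid_tissue"],
}


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth of a simulated response matrix."""

    planted_combo: tuple[str, ...] = ("D01", "D02")
    effect_size: float = 3.0  # ln(IC50) shift, in ln units
    refractory_lines: frozenset[str] | None = None  # None: drawn at simulate time
    seed: int = 0
    missing_rate: float = 0.0
    primary_drug: str = DEFAULT_PRIMARY

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _default_metadata(line_ids) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "cell_line_id": list(line_ids),
            "target_cell": "B-cell",
            "cancer_type": "blood",
            "tissue": "blood",
            "histology": "lymphoid_neoplasm",
            "site": "haematopoietic_and_lymphoid_tissue",
        }
    )
    return meta.set_index("cell_line_id", drop=False)


def simulate_response_matrix(
    n_lines: int, n_drugs: int, truth: SimTruth
) -> tuple[DoseResponseMatrix, pd.DataFrame, SimTruth]:
    """GDSC-like ln(IC50) matrix with a planted secondary-drug combination.

    Per drug d: ln(IC50) ~ Normal(mu_d, sigma_d) with mu_d ~ Normal(2, 1.5)
    ln(uM) and sigma_d ~ Uniform(0.4, 0.7) (the narrower within-lineage
    spread of a drug's profile across a single disease-filtered panel, so
    that the default +3 ln-unit refractory shift dominates the noise).  The primary drug's refractory lines are
    shifted +effect_size; each planted secondary drug's assigned partition
    slice of the refractory lines is shifted -effect_size, so the planted
    combo's sensitive tertiles cover the refractory set.  Missing entries
    are masked uniformly at ``missing_rate``, never emptying a drug row.
    """
    if n_lines < 9:
        raise ValueError("n_lines must be >= 9")
    if n_drugs < 3:
        raise ValueError("n_drugs must be >= 3")
    rng = np.random.default_rng(truth.seed)
    line_ids = [f"CL{i:03d}" for i in range(1, n_lines + 1)]
    drug_ids = [truth.primary_drug] + [f"D{i:02d}" for i in range(1, n_drugs)]
    unknown = [d for d in truth.planted_combo if d not in drug_ids]
    if unknown:
        raise ValueError(f"planted drugs not in simulated panel: {unknown}")
    if truth.primary_drug in truth.planted_combo:
        raise ValueError("the primary drug cannot be planted as its own secondary")

    q = n_lines // 3
    if truth.refractory_lines is None:
        refractory = frozenset(rng.choice(line_ids, size=q, replace=False).tolist())
        truth = replace(truth, refractory_lines=refractory)
    else:
        refractory = frozenset(truth.refractory_lines)
        if not refractory <= set(line_ids):
            raise ValueError("refractory_lines must be simulated line ids")
    if len(truth.planted_combo) > len(refractory):
        raise ValueError("more planted drugs than refractory lines; partition infeasible")

    mu = rng.normal(2.0, 1.5, size=n_drugs)
    sigma = rng.uniform(0.4, 0.7, size=n_drugs)
    values = rng.normal(mu[:, None], sigma[:, None], size=(n_drugs, n_lines))
    df = pd.DataFrame(values, index=drug_ids, columns=line_ids)

    refr_sorted = sorted(refractory)
    df.loc[truth.primary_drug, refr_sorted] += truth.effect_size

    if truth.planted_combo:
        shuffled = list(refr_sorted)
        rng.shuffle(shuffled)
        n_planted = len(truth.planted_combo)
        for i, d in enumerate(sorted(truth.planted_combo)):
            slice_lines = shuffled[i::n_planted]
            df.loc[d, slice_lines] -= truth.effect_size

    if truth.missing_rate > 0:
        mask = rng.random(df.shape) < truth.missing_rate
        for r in range(n_drugs):  # keep every drug row imputable
            if mask[r].all():
                mask[r, rng.integers(0, n_lines)] = False
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))

    return DoseResponseMatrix(df), _default_metadata(line_ids), truth


def simulate_sc_counts(
    n_cells: int,
    n_genes: int,
    n_clusters: int,
    target_programs: dict[str, list[str]] | None = None,
    seed: int = 0,
    program_fold: float = 10.0,
    background_mean_range: tuple[float, float] = (0.05, 0.5),
    nb_dispersion: float = 2.0,
) -> SingleCellCounts:
    """Clustered negative-binomial UMI counts with planted gene programs.

    ``target_programs`` maps a cluster label (stringified 0..n_clusters-1)
    to gene symbols whose mean is multiplied by ``program_fold`` in that
    cluster.  Program genes are placed at the start of the simulated panel;
    remaining slots are filled with background genes G####.
    """
    if n_clusters > n_cells:
        raise ValueError("n_clusters cannot exceed n_cells")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    target_programs = {str(k): [g.upper() for g in v] for k, v in (target_programs or {}).items()}
    program_genes: list[str] = []
    for gs in target_programs.values():
        for g in gs:
            if g not in program_genes:
                program_genes.append(g)
    if len(program_genes) > n_genes:
        raise ValueError("more program genes than simulated genes")
    cluster_ids = [str(c) for c in range(n_clusters)]
    for c in target_programs:
        if c not in cluster_ids:
            raise ValueError(f"program cluster {c!r} not among simulated clusters")
    rng = np.random.default_rng(seed)
    genes = list(program_genes)
    i = 1
    while len(genes) < n_genes:
        g = f"G{i:04d}"
        if g not in program_genes:
            genes.append(g)
        i += 1
    cells = [f"CELL{i:05d}" for i in range(1, n_cells + 1)]
    labels = [cluster_ids[i % n_clusters] for i in range(n_cells)]

    lo, hi = background_mean_range
    base = rng.uniform(lo, hi, size=n_genes)
    gene_pos = {g: j for j, g in enumerate(genes)}
    means = np.tile(base, (n_clusters, 1))
    # mild cluster-to-cluster wobble so clusters differ beyond the programs
    means *= rng.lognormal(0.0, 0.2, size=means.shape)
    for c, gs in target_programs.items():
        ci = cluster_ids.index(c)
        for g in gs:
            means[ci, gene_pos[g]] *= program_fold

    r = nb_dispersion
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    for ci, c in enumerate(cluster_ids):
        rows = [i for i, lab in enumerate(labels) if lab == c]
        mu = means[ci]
        p = r / (r + mu)
        counts[rows, :] = rng.negative_binomial(r, p, size=(len(rows), n_genes))
    return SingleCellCounts(
        tuple(cells), tuple(genes), sp.csr_matrix(counts), dict(zip(cells, labels))
    )


def write_sc_counts(sc: SingleCellCounts, outdir) -> dict[str, str]:
    """Write the Matrix Market triplet + sidecars that ``load_sc_counts`` reads.

    Emits the droplet-platform convention: matrix rows are features,
    columns are barcodes."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "matrix.mtx"),
        "barcodes": os.path.join(outdir, "barcodes.tsv"),
        "features": os.path.join(outdir, "features.tsv"),
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(sc.counts.T), field="integer")
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(sc.cell_ids) + "\n")
    with open(paths["features"], "w") as fh:
        fh.write("\n".join(sc.gene_ids) + "\n")
    if sc.cluster_labels is not None:
        paths["labels"] = os.path.join(outdir, "labels.tsv")
        with open(paths["labels"], "w") as fh:
            for cl in sc.cell_ids:
                fh.write(f"{cl}\t{sc.cluster_labels[cl]}\n")
    return paths
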