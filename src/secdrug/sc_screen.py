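"""Single-cell target-gene coverage screening of candidate drug combinations.

A drug "covers" a single cell when enough of its target genes are detected
in that cell's counts (presence threshold on raw UMI counts, defaults: at
least 1 target gene with count >= 1).  Treating the cell set as a coverage
universe, the same greedy maximum-coverage engine used on cell-line kill
sets ranks drug combinations by the fraction of cells whose target genes
they reach, overall and per expression cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .sensitivity import Universe
from .setcover import CoverSolution, greedy_cover


@dataclass(frozen=True)
class SingleCellCounts:
    """Sparse cell x gene UMI counts with optional cluster labels."""

    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]  # uppercased symbols
    counts: sp.csr_matrix  # cells x genes, non-negative integers
    cluster_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene symbols")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_ids)} barcodes x {len(self.gene_ids)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cluster_labels is not None:
            missing = set(self.cell_ids) - set(self.cluster_labels)
            if missing:
                raise ValueError(f"cluster labels missing for {len(missing)} cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class CellCoverageResult:
    """Coverage of single cells by one drug's (or combo's) target genes."""

    name: str
    covered_cells: frozenset[str]
    fraction_overall: float
    fraction_by_cluster: dict[str, float]


def load_sc_counts(matrix_path, barcodes_path, features_path, labels_path=None) -> SingleCellCounts:
    """Read a Matrix Market triplet with barcode/feature sidecars.

    Both orientations are accepted: features x barcodes (the 10x
    convention, transposed internally) or barcodes x features.  Each
    sidecar is one entry per line; a features file may carry extra
    tab-separated columns, in which case the symbol is taken from the
    second column (10x ``features.tsv`` layout) or the first otherwise.
    """
    mat = scipy.io.mmread(matrix_path)
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("empty count matrix")
    barcodes = [ln.strip().split("\t")[0] for ln in open(barcodes_path) if ln.strip()]
    feat_rows = [ln.rstrip("\n").split("\t") for ln in open(features_path) if ln.strip()]
    genes = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    genes = [g.strip().upper() for g in genes]
    nb, ng = len(barcodes), len(genes)
    if mat.shape == (ng, nb) and ng != nb:
        mat = mat.T
    elif mat.shape != (nb, ng):
        if mat.shape == (ng, nb):  # square case: assume features x barcodes
            mat = mat.T
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither {nb} barcodes x "
                f"{ng} features nor its transpose"
            )
    counts = sp.csr_matrix(mat).astype(np.int64)
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", header=None, dtype=str,
                          names=["barcode", "cluster"])
        unknown = set(lab["barcode"]) - set(barcodes)
        if unknown:
            raise ValueError(f"labeled barcodes absent from matrix: {sorted(unknown)[:5]}")
        labels = dict(zip(lab["barcode"], lab["cluster"]))
        missing = set(barcodes) - set(labels)
        if missing:
            raise ValueError(f"cluster labels missing for {len(missing)} barcodes")
    return SingleCellCounts(tuple(barcodes), tuple(genes), counts, labels)


def load_target_map(path) -> dict[str, list[str]]:
    """Drug -> target-gene symbols, from JSON ({drug: [genes]}) or 2-col TSV."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        targets = {d: [str(g).upper() for g in gs] for d, gs in raw.items()}
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["drug", "gene"], dtype=str)
        targets = {}
        for d, g in zip(df["drug"], df["gene"]):
            targets.setdefault(d, []).append(g.upper())
    for d, gs in targets.items():
        if not gs:
            raise ValueError(f"empty target-gene list for drug {d!r}")
    return targets


def cell_target_coverage(
    sc: SingleCellCounts,
    genes: list[str],
    min_genes_expressed: int = 1,
    min_count: int = 1,
    name: str = "",
    normalize_cpm: bool = False,
) -> CellCoverageResult:
    """Cells in which a target-gene set is detected.

    A cell is covered iff at least ``min_genes_expressed`` of the listed
    genes have raw count >= ``min_count`` (or CPM >= ``min_count`` with
    ``normalize_cpm``).  Genes absent from the panel are skipped; if none
    remain the call is an error.
    """
    if not genes:
        raise ValueError("empty target-gene list")
    if min_genes_expressed < 1:
        raise ValueError("min_genes_expressed must be >= 1")
    wanted = [g.upper() for g in genes]
    gene_index = {g: i for i, g in enumerate(sc.gene_ids)}
    present = [g for g in wanted if g in gene_index]
    if not present:
        raise ValueError(f"none of the target genes present in the panel: {sorted(set(wanted))}")
    cols = [gene_index[g] for g in present]
    sub = sc.counts[:, cols]
    if normalize_cpm:
        totals = np.asarray(sc.counts.sum(axis=1)).ravel().astype(float)
        totals[totals == 0] = 1.0
        sub = sp.csr_matrix(sub.multiply(1e6 / totals[:, None]))
    expressed_per_cell = np.asarray((sub >= min_count).sum(axis=1)).ravel()
    covered_idx = np.where(expressed_per_cell >= min_genes_expressed)[0]
    covered = frozenset(sc.cell_ids[i] for i in covered_idx)
    frac = len(covered) / sc.n_cells
    by_cluster: dict[str, float] = {}
    if sc.cluster_labels is not None:
        sizes: dict[str, int] = {}
        hits: dict[str, int] = {}
        for cl in sc.cell_ids:
            c = sc.cluster_labels[cl]
            sizes[c] = sizes.get(c, 0) + 1
            if cl in covered:
                hits[c] = hits.get(c, 0) + 1
        by_cluster = {c: hits.get(c, 0) / n for c, n in sorted(sizes.items())}
    return CellCoverageResult(name or "+".join(present), covered, frac, by_cluster)


def sc_rank_combos(
    sc: SingleCellCounts,
    targets: dict[str, list[str]],
    k_max: int = 2,
    min_genes_expressed: int = 1,
    min_count: int = 1,
) -> tuple[CoverSolution, pd.DataFrame]:
    """Greedy drug-combination ranking by cumulative single-cell coverage.

    The universe is all cells and each drug's kill set is the cells its
    target genes cover; drugs with no panel gene are skipped.  Returns the
    greedy solution plus a per-step report with per-cluster coverage
    columns.
    """
    kill: dict[str, frozenset[str]] = {}
    per_drug: dict[str, CellCoverageResult] = {}
    for drug in sorted(targets):
        try:
            res = cell_target_coverage(
                sc, targets[drug], min_genes_expressed, min_count, name=drug
            )
        except ValueError:
            continue  # no target gene in the panel; drug not screenable
        per_drug[drug] = res
        kill[drug] = res.covered_cells
    if not kill:
        raise ValueError("no drug in the target map has a gene present in the panel")
    uni = Universe(mode="resistant_only", members=frozenset(sc.cell_ids),
                   n_total=sc.n_cells)
    sol = greedy_cover(kill, uni, k_max=k_max, primary_drug="")
    clusters = sorted(set(sc.cluster_labels.values())) if sc.cluster_labels else []
    sizes = {c: sum(1 for cl in sc.cell_ids if sc.cluster_labels[cl] == c)
             for c in clusters} if clusters else {}
    rows = []
    for step in range(1, len(sol.selected) + 1):
        covered = sol.covered_by_step[step]
        row = {
            "step": step,
            "drug_added": sol.selected[step - 1],
            "combo": " + ".join(sol.selected[:step]),
            "fraction_overall": len(covered) / sc.n_cells,
        }
        for c in clusters:
            hit = sum(1 for cl in covered if sc.cluster_labels[cl] == c)
            row[f"fraction_cluster_{c}"] = hit / sizes[c]
        rows.append(row)
    return sol, pd.DataFrame(rows)
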