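"""Drug-response matrix ingestion, lineage filtering, and imputation.

The central container is :class:`DoseResponseMatrix`, a drugs x cell-lines
table of natural-log IC50 values (ln of the concentration, in uM, producing
half-maximal inhibition) with an explicit missingness mask.  Downstream
tertile categorization is rank-based, so any strictly monotone transform of
the stored values is harmless; one canonical unit (ln uM) is enforced at
read time to avoid mixed files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_FIELDS = ("target_cell", "cancer_type", "tissue", "histology", "site")


@dataclass(frozen=True)
class DoseResponseMatrix:
    """Drugs x cell-lines ln(IC50) matrix with a missingness mask.

    Attributes
    ----------
    values : pandas.DataFrame
        Float matrix, index = drug ids, columns = cell-line ids.  Missing
        entries are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate drug id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate cell-line id: {dup!r}")
        if v.shape[0] < 2:
            raise ValueError(f"need at least 2 drugs, got {v.shape[0]}")
        if v.shape[1] < 3:
            raise ValueError(f"need at least 3 cell lines, got {v.shape[1]}")
        arr = v.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("ln(IC50) values must be finite where observed")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    def drug_row(self, drug: str) -> pd.Series:
        if drug not in self.values.index:
            raise KeyError(f"unknown drug: {drug!r}")
        return self.values.loc[drug]


def read_response_matrix(
    path,
    orientation: str = "drugs_as_rows",
    sep: str | None = None,
    raw_ic50: bool = False,
) -> DoseResponseMatrix:
    """Read a delimited ln(IC50) table into drugs-as-rows orientation.

    The file must have one header row and one leading id column; empty cells
    or ``NA`` mark missing values.  With ``orientation='lines_as_rows'`` the
    table is transposed after reading.  ``raw_ic50=True`` converts raw IC50
    (uM) input to ln(IC50) at read time; non-positive raw values are an error.
    """
    if orientation not in ("drugs_as_rows", "lines_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    with open(path) as fh:
        head = fh.readline()
    if sep is None:
        sep = "\t" if head.count("\t") >= head.count(",") else ","
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
    header = [str(c).strip() for c in raw.iloc[0, 1:]]
    row_ids = [str(r).strip() for r in raw.iloc[1:, 0]]
    for ids, what in ((header, "column"), (row_ids, "row")):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate {what} id: {i!r}")
            seen.add(i)
    # cells parsed with Python floats so finite doubles round-trip bit-for-bit
    data = np.empty((len(row_ids), len(header)))
    for i, rid in enumerate(row_ids):
        for j, cid in enumerate(header):
            cell = str(raw.iat[i + 1, j + 1]).strip()
            if cell in ("", "NA", "nan", "NaN"):
                data[i, j] = np.nan
                continue
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {rid!r}, column {cid!r}: {cell!r}"
                ) from None
    df = pd.DataFrame(data, index=row_ids, columns=header)
    if orientation == "lines_as_rows":
        df = df.T
    if raw_ic50:
        obs = df.to_numpy()
        if np.nanmin(obs) <= 0:
            raise ValueError("raw IC50 values must be positive for ln conversion")
        df = np.log(df)
    return DoseResponseMatrix(df)


def write_response_matrix(m: DoseResponseMatrix, path, sep: str = "\t") -> None:
    """Write a matrix in the same layout ``read_response_matrix`` consumes.

    Missing entries are written as ``NA``; finite doubles round-trip
    bit-for-bit via repr-precision formatting.
    """
    out = m.values.copy()
    out.index.name = "drug_id"
    out.to_csv(path, sep=sep, na_rep="NA", float_format=lambda x: repr(float(x)))


def read_metadata(path, sep: str | None = None) -> pd.DataFrame:
    """Read the cell-line metadata table; `cell_line_id` column is mandatory.

    Missing annotation fields are added as empty text so filtering criteria
    can always be evaluated.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "cell_line_id" not in df.columns:
        raise ValueError("metadata table must contain a `cell_line_id` column")
    df["cell_line_id"] = df["cell_line_id"].str.strip()
    if df["cell_line_id"].duplicated().any():
        dup = df.loc[df["cell_line_id"].duplicated(), "cell_line_id"].iloc[0]
        raise ValueError(f"duplicate metadata record for cell line {dup!r}")
    for f in METADATA_FIELDS:
        if f not in df.columns:
            df[f] = ""
    return df.fillna("").set_index("cell_line_id", drop=False)


def _norm(s: str) -> str:
    return str(s).strip().casefold()


def filter_cell_lines(
    m: DoseResponseMatrix,
    meta: pd.DataFrame,
    criteria: dict[str, list[str] | str] | None = None,
    require_complete: bool = False,
) -> DoseResponseMatrix:
    """Restrict the matrix to cell lines matching the metadata criteria.

    ``criteria`` maps a metadata field to one or more accepted values;
    multiple values within a field are OR-ed, fields are AND-ed.  Matching is
    exact after case-folding and whitespace stripping.  With
    ``require_complete`` lines carrying any missing value across the drug
    panel are additionally dropped, mirroring a no-missing-data selection.
    """
    criteria = criteria or {}
    if "cell_line_id" in getattr(meta, "columns", []):
        meta = meta.set_index(meta["cell_line_id"].str.strip(), drop=False)
    missing_meta = [c for c in m.cell_line_ids if c not in meta.index]
    if missing_meta:
        raise ValueError(
            f"cell lines absent from metadata: {missing_meta[:5]}"
            + ("..." if len(missing_meta) > 5 else "")
        )
    keep = []
    for cl in m.cell_line_ids:
        rec = meta.loc[cl]
        ok = True
        for fld, accepted in criteria.items():
            vals = [accepted] if isinstance(accepted, str) else list(accepted)
            have = _norm(rec[fld]) if fld in rec.index else ""
            if have not in {_norm(v) for v in vals}:
                ok = False
                break
        if ok:
            keep.append(cl)
    sub = m.values[keep]
    if require_complete:
        sub = sub.loc[:, ~sub.isna().any(axis=0)]
    if sub.shape[1] == 0:
        raise ValueError(
            "no cell lines survive the filtering criteria; review the "
            "criteria/metadata field values"
        )
    return DoseResponseMatrix(sub)


def impute_missing(
    m: DoseResponseMatrix, method: str = "drug_median", k: int = 5
) -> DoseResponseMatrix:
    """Fill missing ln(IC50) entries; observed values are never altered.

    ``drug_median`` (default, deterministic) fills each gap with that drug's
    median over its observed lines.  ``knn`` fills with the mean over the
    ``k`` nearest drug rows by Euclidean distance on shared observed lines.
    """
    v = m.values.copy()
    mask = v.isna()
    if not mask.to_numpy().any():
        return DoseResponseMatrix(v)
    empty_rows = v.index[v.notna().sum(axis=1) == 0]
    if len(empty_rows):
        raise ValueError(f"drug row entirely missing: {empty_rows[0]!r}")
    if method == "drug_median":
        med = v.median(axis=1, skipna=True)
        for drug in v.index[mask.any(axis=1)]:
            v.loc[drug] = v.loc[drug].fillna(med[drug])
    elif method == "knn":
        if (v.notna().sum(axis=1) < 2).any():
            bad = v.index[v.notna().sum(axis=1) < 2][0]
            raise ValueError(f"knn imputation needs >=2 observed values per drug ({bad!r})")
        arr = v.to_numpy()
        obs = ~np.isnan(arr)
        filled = arr.copy()
        for i in np.where(mask.any(axis=1))[0]:
            dists = np.full(arr.shape[0], np.inf)
            for j in range(arr.shape[0]):
                if j == i:
                    continue
                shared = obs[i] & obs[j]
                if shared.sum() == 0:
                    continue
                d = arr[i, shared] - arr[j, shared]
                dists[j] = float(np.sqrt(np.mean(d * d)))
            order = np.argsort(dists, kind="stable")
            nbrs = [j for j in order if np.isfinite(dists[j])][:k]
            for c in np.where(~obs[i])[0]:
                vals = [arr[j, c] for j in nbrs if obs[j, c]]
                if vals:
                    filled[i, c] = float(np.mean(vals))
                else:  # fall back to the drug median when no neighbor observed it
                    filled[i, c] = float(np.nanmedian(arr[i]))
        v = pd.DataFrame(filled, index=v.index, columns=v.columns)
    else:
        raise ValueError(f"unknown imputation method: {method!r}")
    return DoseResponseMatrix(v)
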