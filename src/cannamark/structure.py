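"""Diversity summaries, ordination and chemotype arithmetic.

* Gower distance over categorical loci: the fraction of compared loci at
  which two samples carry different allele symbols, skipping loci where
  either sample is missing.
* Classical (Torgerson) multidimensional scaling of that distance matrix
  for biplot coordinates.
* Per-locus Shannon entropy summaries of overall, within-group and
  between-group variation.
* THC/CBD ratio arithmetic and the four-way chemotype grouping
  (ratio <= 0.05; 0.05 < ratio <= 0.2; 0.2 < ratio <= 10; ratio > 10).
"""

from __future__ import annotations

import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .calling import GenotypeMatrix

MISSING_SYMBOLS = {"N", "", None}

GROUP_EDGES = (0.05, 0.2, 10.0)


def _code_matrix(cells: pd.DataFrame):
    """Integer-coded cells plus a validity mask (False where missing)."""
    flat = pd.unique(cells.to_numpy().ravel())
    mapping = {v: i for i, v in enumerate(flat)}
    codes = cells.apply(lambda col: col.map(mapping)).to_numpy(dtype=int)
    valid = ~cells.isin(MISSING_SYMBOLS).to_numpy() & ~cells.isna().to_numpy()
    return codes, valid


def gower_distance(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Gower distances over the categorical loci of a panel.

    For all-categorical loci the Gower coefficient reduces to the mismatch
    fraction over loci where both samples have observed alleles. A pair
    with no comparable loci is an error.
    """
    if len(matrix.cells) < 2:
        raise ValueError("need at least two samples")
    codes, valid = _code_matrix(matrix.cells)
    diff = codes[:, None, :] != codes[None, :, :]
    comparable = valid[:, None, :] & valid[None, :, :]
    denom = comparable.sum(axis=2)
    if np.any(denom == 0):
        i, j = np.argwhere(denom == 0)[0]
        raise ValueError(
            f"samples {matrix.cells.index[i]!r} and {matrix.cells.index[j]!r} "
            "share no comparable loci"
        )
    D = (diff & comparable).sum(axis=2) / denom
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.cells.index, columns=matrix.cells.index)


def classical_mds(D: pd.DataFrame | np.ndarray, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS: double-centered eigendecomposition.

    Coordinates are ordered by decreasing eigenvalue. Axis signs follow a
    deterministic convention (the largest-magnitude loading on each axis is
    positive). If fewer than ``dims`` positive eigenvalues exist, the
    remaining columns are zero-padded with a warning.
    """
    index = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(len(D))
    A = np.asarray(D, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-10, 1e-10 * abs(eigval[0]) if eigval.size else 0)
    n_pos = int(positive.sum())
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {dims - n_pos} "
            "zero coordinate(s)"
        )
    coords = np.zeros((n, dims))
    use = min(dims, n_pos)
    coords[:, :use] = eigvec[:, :use] * np.sqrt(eigval[:use])
    for j in range(use):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return pd.DataFrame(
        coords, index=index, columns=[f"axis{j + 1}" for j in range(dims)]
    )


def _mean_entropy(cells: pd.DataFrame, base: float = math.e) -> float:
    """Mean over loci of the Shannon entropy of allele frequencies."""
    ents = []
    for key in cells.columns:
        col = cells[key]
        col = col[~col.isin(MISSING_SYMBOLS) & ~col.isna()]
        if col.empty:
            continue
        p = col.value_counts(normalize=True).to_numpy()
        ents.append(float(-(p * np.log(p)).sum() / math.log(base)))
    return float(np.mean(ents)) if ents else 0.0


def entropy_summary(matrix: GenotypeMatrix, groups: pd.Series,
                    base: float = math.e) -> dict:
    """Entropy-based variation summary over a grouping of the samples.

    ``groups`` maps every sample id to a group label (a partition). Returns
    the overall mean per-locus entropy, the within-group means, and the
    between-group value defined as the mean per-locus entropy of the
    group-consensus (modal) alleles. Entropies use natural log by default
    (``base`` configurable).
    """
    groups = pd.Series(groups).reindex(matrix.cells.index)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a group: {missing}")
    overall = _mean_entropy(matrix.cells, base)
    within = {}
    consensus_rows = {}
    for g, block in matrix.cells.groupby(groups):
        if block.empty:
            raise ValueError(f"group {g!r} is empty")
        within[g] = _mean_entropy(block, base)
        consensus_rows[g] = {
            key: block[key].mode().sort_values().iloc[0] for key in block.columns
        }
    consensus = pd.DataFrame.from_dict(consensus_rows, orient="index")
    between = _mean_entropy(consensus, base)
    return {"overall": overall, "within": within, "between": between}


def chem_ratio(thc: float, cbd: float) -> float:
    """THC/CBD ratio with the zero-CBD convention (0/0 -> 0, x/0 -> inf)."""
    if thc < 0 or cbd < 0:
        raise ValueError("cannabinoid percentages must be non-negative")
    if cbd == 0:
        return 0.0 if thc == 0 else math.inf
    return thc / cbd


def chem_group(ratio: float) -> int:
    """Four-way chemotype group from the THC/CBD ratio (closed below)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    for g, edge in enumerate(GROUP_EDGES, start=1):
        if ratio <= edge:
            return g
    return 4


def chem_ratio_and_group(table: pd.DataFrame) -> pd.DataFrame:
    """Add ratio, group and (if absent) class columns to a chemotype table.

    Expects ``THC`` and ``CBD`` columns of per-variety means in percent of
    dry weight. The class column, when derived, assigns groups 1-2 (ratio
    at most 0.2) to fiber and groups 3-4 to drug.
    """
    out = table.copy()
    out["ratio"] = [chem_ratio(t, c) for t, c in zip(out["THC"], out["CBD"])]
    out["group"] = [chem_group(r) for r in out["ratio"]]
    if "class" not in out.columns:
        out["class"] = np.where(out["group"] <= 2, "fiber", "drug")
    return out


def load_reference_chemotypes() -> pd.DataFrame:
    """Published per-variety cannabinoid contents bundled with the package.

    Mean CBD and THC (% of inflorescence dry weight, with standard
    deviations and plant counts) for 10 fiber and 11 drug cultivars,
    including the printed THC/CBD ratio column.
    """
    with resources.files("cannamark.data").joinpath(
        "chemotype_reference.csv"
    ).open() as fh:
        return pd.read_csv(fh)
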