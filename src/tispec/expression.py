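"""Peak-based tissue-specificity scoring on double-Z-normalized expression.

Mean expression per tissue (RPKM-like, genes x tissues) is standardized
twice: first across tissues within each gene, then across genes within
each tissue so all scores share one scale.  A gene is called
tissue-specific at stringency ``x`` when its second-highest tissue score
falls strictly below ``1/x`` of its highest, for integer ``x`` in 2..10.
Stringencies nest: a gene specific at ``x`` is specific at every smaller
``x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

X_RANGE = range(2, 11)


@dataclass
class ExpressionMatrix:
    """Gene x tissue mean-expression table (non-negative, RPKM-like).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per tissue.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate tissue names: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if np.any(arr < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class ZScoreMatrix:
    """Double-Z-normalized scores with cached per-gene peak statistics.

    ``z_max`` is each gene's largest score, ``peak_tissue`` its argmax
    (ties broken by tissue order), ``z_second`` the second largest.
    ``flat_genes`` hold constant expression across tissues and are never
    tissue-specific.
    """

    z: pd.DataFrame
    flat_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        arr = self.z.to_numpy(dtype=float)
        order = np.argsort(-arr, axis=1, kind="stable")
        rows = np.arange(arr.shape[0])
        self._zmax = arr[rows, order[:, 0]]
        self._peak_idx = order[:, 0]
        if arr.shape[1] >= 2:
            self._z2nd = arr[rows, order[:, 1]]
        else:
            self._z2nd = np.full(arr.shape[0], -np.inf)

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.z.columns)

    @property
    def z_max(self) -> pd.Series:
        return pd.Series(self._zmax, index=self.z.index, name="z_max")

    @property
    def z_second(self) -> pd.Series:
        return pd.Series(self._z2nd, index=self.z.index, name="z_second")

    @property
    def peak_tissue(self) -> pd.Series:
        cols = np.asarray(self.z.columns)
        return pd.Series(cols[self._peak_idx], index=self.z.index, name="peak_tissue")

    @classmethod
    def from_tsv(cls, path) -> "ZScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        flat = frozenset(df.index[(df == 0).all(axis=1) & (df.std(axis=1) == 0)])
        # flat rows were zeroed on write; an all-zero row is only truly flat
        # if it was flagged, but all-zero rows are never specific either way
        return cls(df, flat_genes=flat)

    def to_tsv(self, path) -> None:
        self.z.to_csv(path, sep="\t", index_label="gene")


@dataclass
class TissueSpecificityCall:
    """Per-gene specificity call: peak tissue and the satisfied stringencies."""

    gene: str
    peak_tissue: str
    max_x: int
    satisfied_x: frozenset[int]

    def __post_init__(self) -> None:
        if self.satisfied_x:
            # downward closure: satisfying x implies all smaller stringencies
            assert self.satisfied_x == frozenset(range(2, max(self.satisfied_x) + 1))
            assert self.max_x == max(self.satisfied_x)
        else:
            assert self.max_x == 0


def per_tissue_means(
    sample_matrix: pd.DataFrame, sample_to_tissue: dict[str, str] | pd.Series
) -> ExpressionMatrix:
    """Collapse a gene x sample matrix to per-tissue arithmetic means.

    Every sample column must map to exactly one tissue; tissues with no
    samples are impossible by construction (the tissue set is derived
    from the mapping).
    """
    mapping = pd.Series(sample_to_tissue)
    unmapped = [s for s in sample_matrix.columns if s not in mapping.index]
    if unmapped:
        raise ValueError(f"samples without tissue assignment: {unmapped[:5]}")
    groups = mapping.loc[sample_matrix.columns]
    means = sample_matrix.T.groupby(groups).mean().T
    # preserve first-appearance tissue order rather than alphabetical
    order = list(dict.fromkeys(groups))
    return ExpressionMatrix(means[order])


def double_z(
    means: ExpressionMatrix,
    *,
    ddof: int = 1,
    log_transform: bool = False,
) -> ZScoreMatrix:
    """Standardize across tissues per gene, then across genes per tissue.

    The first pass puts each gene on a within-gene scale; the second pass
    brings all genes' scores to a common scale so peak heights are
    comparable.  ``ddof=1`` uses the sample standard deviation (default);
    set 0 for the population convention.  Rows with zero variance are
    flagged flat with all-zero scores; a zero-variance column after pass 1
    is left centered at zero with a warning.

    Parameters
    ----------
    log_transform
        Apply ``log2(v + 1)`` before standardizing.  Off by default: the
        criterion is defined on the linear expression scale.
    """
    v = means.values.to_numpy(dtype=float)
    if v.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if log_transform:
        v = np.log2(v + 1.0)

    row_mean = v.mean(axis=1, keepdims=True)
    row_sd = v.std(axis=1, ddof=ddof, keepdims=True)
    flat_mask = (row_sd == 0).ravel()
    row_sd_safe = np.where(row_sd == 0, 1.0, row_sd)
    z1 = (v - row_mean) / row_sd_safe
    z1[flat_mask, :] = 0.0

    col_mean = z1.mean(axis=0, keepdims=True)
    col_sd = z1.std(axis=0, ddof=ddof, keepdims=True)
    degenerate = (col_sd == 0).ravel()
    if degenerate.any():
        bad = [t for t, d in zip(means.tissues, degenerate) if d]
        warnings.warn(f"tissue columns with zero variance after pass 1: {bad}")
    col_sd_safe = np.where(col_sd == 0, 1.0, col_sd)
    z2 = (z1 - col_mean) / col_sd_safe
    z2[:, degenerate] = 0.0

    zdf = pd.DataFrame(z2, index=means.values.index, columns=means.values.columns)
    flat = frozenset(np.asarray(means.genes, dtype=object)[flat_mask])
    return ZScoreMatrix(zdf, flat_genes=flat)


def classify_at(z: ZScoreMatrix, x: int) -> set[str]:
    """Genes tissue-specific at stringency ``x``.

    Included iff ``z_max > 0`` and ``z_second < z_max / x`` (strict).
    The positivity guard matters: for a non-positive peak the inequality
    direction inverts and the nesting of stringencies would break.
    """
    if not (2 <= x <= 10):
        raise ValueError(f"x must be an integer in 2..10, got {x}")
    zmax = z._zmax
    z2nd = z._z2nd
    hit = (zmax > 0) & (z2nd < zmax / x)
    genes = np.asarray(z.genes, dtype=object)
    out = set(genes[hit])
    return out - set(z.flat_genes)


def specificity_profile(z: ZScoreMatrix) -> list[TissueSpecificityCall]:
    """Per-gene calls across all stringencies x = 2..10.

    ``satisfied_x`` is computed directly from the peak ratio, so
    ``classify_at(z, x) == {g : x in satisfied_x(g)}`` for every ``x``.
    """
    peak = z.peak_tissue
    zmax = z._zmax
    z2nd = z._z2nd
    calls = []
    for i, gene in enumerate(z.genes):
        if gene in z.flat_genes or zmax[i] <= 0:
            sat: frozenset[int] = frozenset()
        else:
            sat = frozenset(x for x in X_RANGE if z2nd[i] < zmax[i] / x)
        calls.append(
            TissueSpecificityCall(
                gene=gene,
                peak_tissue=peak.iloc[i],
                max_x=max(sat) if sat else 0,
                satisfied_x=sat,
            )
        )
    return calls


def calls_to_frame(calls: list[TissueSpecificityCall]) -> pd.DataFrame:
    """Tabular view of specificity calls (one row per gene)."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "peak_tissue": [c.peak_tissue for c in calls],
            "max_x": [c.max_x for c in calls],
            "satisfied_x": [
                ",".join(str(x) for x in sorted(c.satisfied_x)) for c in calls
            ],
        }
    ).set_index("gene")


def calls_from_frame(df: pd.DataFrame) -> list[TissueSpecificityCall]:
    calls = []
    for gene, row in df.iterrows():
        sat = frozenset(
            int(t) for t in str(row["satisfied_x"]).split(",") if t not in ("", "nan")
        )
        calls.append(
            TissueSpecificityCall(
                gene=str(gene),
                peak_tissue=row["peak_tissue"],
                max_x=int(row["max_x"]),
                satisfied_x=sat,
            )
        )
    return calls


def specific_genes(calls: list[TissueSpecificityCall], x: int) -> set[str]:
    """Genes whose calls satisfy stringency ``x``."""
    return {c.gene for c in calls if x in c.satisfied_x}


def nonspecific_genes(calls: list[TissueSpecificityCall]) -> set[str]:
    """Genes satisfying no stringency at all (max_x == 0)."""
    return {c.gene for c in calls if c.max_x == 0}
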