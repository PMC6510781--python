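"""Evolutionary-conservation comparisons of gene groups against the
all-protein-coding background.

Inputs are per-species ortholog tables (gene, homology type, Ka/Ks,
percent identity/similarity).  A gene "lacks a 1-to-1 ortholog" when its
homology type is one-to-many, many-to-many or absent — duplicated
orthologs tend to diverge in function, so only unique counterparts count
as conserved here.  Ka/Ks comparisons are restricted to mammalian
species; at larger evolutionary distances synonymous sites saturate and
the ratio stops being informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tispec.stats import fisher_enrichment, mann_whitney

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many", "none")

# species for which Ka/Ks is interpretable at default settings
DEFAULT_MAMMALS = frozenset({"mouse", "rat", "dog", "pig", "macaque"})

METRIC_COLUMNS = {
    "ka_ks": "ka_ks",
    "identity": "pct_identity",
    "similarity": "pct_similarity",
}


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a per-species ortholog TSV (gene, species, homology_type,
    ka_ks, pct_identity, pct_similarity)."""
    df = pd.read_csv(path, sep="\t")
    bad = set(df["homology_type"]) - set(HOMOLOGY_TYPES)
    if bad:
        raise ValueError(f"unknown homology types: {sorted(bad)}")
    return df


def _species_slice(orthologs: pd.DataFrame, species: str) -> pd.DataFrame:
    sub = orthologs[orthologs["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} absent from ortholog table")
    return sub


@dataclass
class CoverageReport:
    species: str
    n_group: int
    n_group_without: int
    n_background: int
    n_background_without: int
    p: float

    @property
    def pct_group_without(self) -> float:
        return 100.0 * self.n_group_without / self.n_group

    @property
    def pct_background_without(self) -> float:
        return 100.0 * self.n_background_without / self.n_background


def ortholog_coverage(
    group: set, orthologs: pd.DataFrame, species: str
) -> CoverageReport:
    """Percentage of group genes without a 1-to-1 ortholog in ``species``,
    with a one-tailed Fisher comparison against the whole table."""
    sub = _species_slice(orthologs, species)
    universe = set(sub["gene"])
    without = set(sub.loc[sub["homology_type"] != "one2one", "gene"])
    grp = group & universe
    res = fisher_enrichment(grp, without, universe, direction="enrichment")
    return CoverageReport(
        species=species,
        n_group=len(grp),
        n_group_without=len(grp & without),
        n_background=len(universe),
        n_background_without=len(without),
        p=res.p,
    )


@dataclass
class ConservationReport:
    species: str
    metric: str
    n_group: int
    n_background: int
    median_group: float
    median_background: float
    iqr_group: tuple[float, float]
    iqr_background: tuple[float, float]
    u: float
    p: float


def conservation_compare(
    group: set,
    metric: str,
    orthologs: pd.DataFrame,
    species: str,
    *,
    mammals: frozenset[str] = DEFAULT_MAMMALS,
) -> ConservationReport | None:
    """Compare a conservation metric of a gene group against the
    all-genes background (two-sided Mann-Whitney), on 1-to-1 orthologs.

    Returns None when fewer than 2 usable values exist in the group.
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(METRIC_COLUMNS)}")
    if metric == "ka_ks" and species not in mammals:
        raise ValueError(
            f"Ka/Ks comparison refused for non-mammalian species {species!r}"
        )
    col = METRIC_COLUMNS[metric]
    sub = _species_slice(orthologs, species)
    one2one = sub[sub["homology_type"] == "one2one"]
    if one2one["gene"].duplicated().any():
        warnings.warn(
            f"multiple 1-to-1 records per gene for {species}; keeping first"
        )
        one2one = one2one.drop_duplicates(subset="gene", keep="first")
    values = one2one.set_index("gene")[col].dropna()
    grp_vals = values[values.index.isin(group)]
    if len(grp_vals) < 2:
        return None
    u, p = mann_whitney(grp_vals.to_numpy(), values.to_numpy())
    q1g, q3g = np.percentile(grp_vals, [25, 75])
    q1b, q3b = np.percentile(values, [25, 75])
    return ConservationReport(
        species=species,
        metric=metric,
        n_group=len(grp_vals),
        n_background=len(values),
        median_group=float(np.median(grp_vals)),
        median_background=float(np.median(values)),
        iqr_group=(float(q1g), float(q3g)),
        iqr_background=(float(q1b), float(q3b)),
        u=u,
        p=p,
    )


def conservation_summary(
    groups: dict[str, set],
    orthologs: pd.DataFrame,
    species: str,
    *,
    mammals: frozenset[str] = DEFAULT_MAMMALS,
) -> pd.DataFrame:
    """Per-group conservation table: 1-to-1 coverage plus each metric's
    median and Mann-Whitney p against background."""
    rows = []
    metrics = ["ka_ks", "similarity", "identity"]
    if species not in mammals:
        metrics = ["similarity", "identity"]
    for name, members in groups.items():
        cov = ortholog_coverage(members, orthologs, species)
        row = dict(
            group=name,
            species=species,
            n=cov.n_group,
            pct_without_1to1=cov.pct_group_without,
            pct_without_1to1_background=cov.pct_background_without,
            p_coverage=cov.p,
        )
        for metric in metrics:
            rep = conservation_compare(
                members, metric, orthologs, species, mammals=mammals
            )
            if rep is None:
                row[f"median_{metric}"] = np.nan
                row[f"p_{metric}"] = np.nan
            else:
                row[f"median_{metric}"] = rep.median_group
                row[f"p_{metric}"] = rep.p
        rows.append(row)
    return pd.DataFrame(rows)
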