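"""Drug-target catalog: per-gene maximal clinical phase, oncology status,
target reuse and first-approval-year comparisons.

A drug record carries its mechanism-of-action target genes, the maximal
clinical phase the drug reached (1, 2, 3, marketed, or withdrawn after
marketing), its indication class (oncology / non-oncology) and, for
marketed or withdrawn drugs, its first approval year.  Targets inherit
the maximum phase over their drugs; a protein hit by at least one
oncology drug counts as an oncology target.  A marketed-drug target is
"reused" when a phase 1-3 candidate drug also targets it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from tispec.stats import exact_rank_sum_test

PHASES = ("1", "2", "3", "marketed", "withdrawn")
# withdrawn drugs were marketed first; their targets rank at marketed level
_PHASE_RANK = {"1": 1, "2": 2, "3": 3, "marketed": 4, "withdrawn": 4}
CANDIDATE_PHASES = frozenset({"1", "2", "3"})


@dataclass
class DrugRecord:
    drug_id: str
    targets: tuple[str, ...]
    max_phase: str  # one of PHASES
    oncology: bool
    approval_year: int | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.drug_id} has no targets")
        if self.max_phase not in PHASES:
            raise ValueError(
                f"drug {self.drug_id}: unknown phase {self.max_phase!r}"
            )
        marketed_level = self.max_phase in ("marketed", "withdrawn")
        if marketed_level and self.approval_year is None:
            raise ValueError(
                f"drug {self.drug_id}: approval year required for "
                f"{self.max_phase} drugs"
            )
        if not marketed_level and self.approval_year is not None:
            raise ValueError(
                f"drug {self.drug_id}: approval year only valid for "
                "marketed/withdrawn drugs"
            )


@dataclass
class TargetRecord:
    gene: str
    max_phase: str
    oncology: bool
    marketed: bool
    withdrawn: bool
    reused: bool
    candidate_drug_count: int
    first_approval_year: int | None = None

    def __post_init__(self) -> None:
        if self.reused and not self.marketed:
            raise ValueError(f"{self.gene}: reused target must be marketed")


def build_catalog(drugs: list[DrugRecord]) -> list[TargetRecord]:
    """Collapse drug records to one record per target gene.

    Phase order is 1 < 2 < 3 < marketed; withdrawn drugs keep their
    targets at marketed level with a separate withdrawn flag (withdrawal
    is a property of the drug, and nearly all such targets also have a
    still-marketed drug).  The oncology flag is global per protein: one
    oncology drug suffices.
    """
    per_gene: dict[str, list[DrugRecord]] = {}
    for drug in drugs:
        for gene in drug.targets:
            per_gene.setdefault(gene, []).append(drug)
    records = []
    for gene in per_gene:
        ds = per_gene[gene]
        best = max(ds, key=lambda d: _PHASE_RANK[d.max_phase])
        max_phase = "marketed" if best.max_phase == "withdrawn" else best.max_phase
        marketed = any(d.max_phase in ("marketed", "withdrawn") for d in ds)
        n_candidates = sum(d.max_phase in CANDIDATE_PHASES for d in ds)
        years = [
            d.approval_year for d in ds
            if d.max_phase in ("marketed", "withdrawn") and d.approval_year is not None
        ]
        records.append(
            TargetRecord(
                gene=gene,
                max_phase=max_phase,
                oncology=any(d.oncology for d in ds),
                marketed=marketed,
                withdrawn=any(d.max_phase == "withdrawn" for d in ds),
                reused=marketed and n_candidates >= 1,
                candidate_drug_count=n_candidates,
                first_approval_year=min(years) if years else None,
            )
        )
    return records


def catalog_to_frame(catalog: list[TargetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [t.gene for t in catalog],
            "max_phase": [t.max_phase for t in catalog],
            "oncology": [t.oncology for t in catalog],
            "marketed": [t.marketed for t in catalog],
            "withdrawn": [t.withdrawn for t in catalog],
            "reused": [t.reused for t in catalog],
            "candidate_drug_count": [t.candidate_drug_count for t in catalog],
            "first_approval_year": [t.first_approval_year for t in catalog],
        }
    ).set_index("gene")


def read_drug_table(path) -> list[DrugRecord]:
    """Read a drug TSV (drug_id, gene, phase, indication_class,
    approval_year); rows sharing a drug_id are one multi-target drug."""
    df = pd.read_csv(path, sep="\t", dtype={"phase": str})
    drugs = []
    for drug_id, rows in df.groupby("drug_id", sort=False):
        year = rows["approval_year"].iloc[0]
        drugs.append(
            DrugRecord(
                drug_id=str(drug_id),
                targets=tuple(rows["gene"].astype(str)),
                max_phase=str(rows["phase"].iloc[0]),
                oncology=rows["indication_class"].iloc[0] == "oncology",
                approval_year=None if pd.isna(year) else int(year),
            )
        )
    return drugs


def write_drug_table(drugs: list[DrugRecord], path) -> None:
    rows = []
    for d in drugs:
        for g in d.targets:
            rows.append(
                dict(
                    drug_id=d.drug_id,
                    gene=g,
                    phase=d.max_phase,
                    indication_class="oncology" if d.oncology else "non-oncology",
                    approval_year=d.approval_year,
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ReuseReport:
    """Reuse of marketed-drug targets by candidate drugs, tissue-specific
    vs never-tissue-specific."""

    x: int
    n_ts: int
    n_ts_reused: int
    n_nonts: int
    n_nonts_reused: int
    p: float
    candidate_counts_ts: list[int] = field(default_factory=list)
    candidate_counts_nonts: list[int] = field(default_factory=list)
    empty: bool = False

    @property
    def prevalence_ts(self) -> float:
        return self.n_ts_reused / self.n_ts if self.n_ts else float("nan")

    @property
    def prevalence_nonts(self) -> float:
        return self.n_nonts_reused / self.n_nonts if self.n_nonts else float("nan")

    @property
    def ratio(self) -> float:
        """Non-tissue-specific over tissue-specific reuse prevalence,
        reported to one decimal."""
        if not self.n_ts or not self.n_nonts or self.prevalence_ts == 0:
            return float("nan")
        return round(self.prevalence_nonts / self.prevalence_ts, 1)


def reuse_prevalence_ratio(pct_nonts: float, pct_ts: float) -> float:
    """Ratio of two reuse prevalences (percent scale), to one decimal."""
    return round(pct_nonts / pct_ts, 1)


def reuse_analysis(catalog: list[TargetRecord], ts_calls, x: int) -> ReuseReport:
    """Among marketed-drug targets, compare reuse of tissue-specific
    targets (at stringency ``x``) with targets specific at no stringency.

    One-tailed Fisher p tests whether tissue-specific targets are reused
    less often.
    """
    from tispec.expression import nonspecific_genes, specific_genes

    marketed = [t for t in catalog if t.marketed]
    if not marketed:
        return ReuseReport(x, 0, 0, 0, 0, float("nan"), empty=True)
    ts = specific_genes(ts_calls, x)
    non = nonspecific_genes(ts_calls)
    ts_targets = [t for t in marketed if t.gene in ts]
    non_targets = [t for t in marketed if t.gene in non]
    a = sum(t.reused for t in ts_targets)
    c = sum(t.reused for t in non_targets)
    table = [[a, len(ts_targets) - a], [c, len(non_targets) - c]]
    if ts_targets and non_targets:
        _, p = sps.fisher_exact(table, alternative="less")
    else:
        p = float("nan")
    return ReuseReport(
        x=x,
        n_ts=len(ts_targets),
        n_ts_reused=a,
        n_nonts=len(non_targets),
        n_nonts_reused=c,
        p=float(p),
        candidate_counts_ts=[t.candidate_drug_count for t in ts_targets if t.reused],
        candidate_counts_nonts=[
            t.candidate_drug_count for t in non_targets if t.reused
        ],
    )


@dataclass
class ApprovalYearReport:
    x: int
    median_ts: float
    median_nonts: float
    n_ts: int
    n_nonts: int
    w: float
    p: float


def approval_year_compare(
    catalog: list[TargetRecord], ts_calls, x: int
) -> ApprovalYearReport | None:
    """Compare first approval years of tissue-specific vs never-specific
    marketed-drug targets with an exact rank-sum test (tie-aware).

    Returns None when either group has no dated target.
    """
    from tispec.expression import nonspecific_genes, specific_genes

    ts = specific_genes(ts_calls, x)
    non = nonspecific_genes(ts_calls)
    years_ts = [
        t.first_approval_year
        for t in catalog
        if t.marketed and t.gene in ts and t.first_approval_year is not None
    ]
    years_non = [
        t.first_approval_year
        for t in catalog
        if t.marketed and t.gene in non and t.first_approval_year is not None
    ]
    if not years_ts or not years_non:
        return None
    w, p = exact_rank_sum_test(years_ts, years_non)
    return ApprovalYearReport(
        x=x,
        median_ts=float(np.median(years_ts)),
        median_nonts=float(np.median(years_non)),
        n_ts=len(years_ts),
        n_nonts=len(years_non),
        w=w,
        p=p,
    )
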