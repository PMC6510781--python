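"""Opportunity mapping: which tissue-specific genes remain unexplored as
drug targets, and which of those look druggable or carry human genetic
evidence.

"Explored" means targeted by any marketed or clinical-trial drug.
Druggability is the union of five indications: a Tchem development level
(potent chemical probes exist), secretion (antibody-accessible), a known
ChEMBL compound, a solved structure, or a drugged protein family.
Overlaps of these flags are reported as disjoint UpSet-style buckets so
no gene is double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

TDL_LEVELS = ("Tdark", "Tbio", "Tchem", "Tclin")

DRUGGABILITY_FLAGS = (
    "tchem",
    "secreted",
    "has_chembl_compound",
    "has_pdb_structure",
    "family_has_drug_target",
)

ANNOTATION_COLUMNS = [
    "omim", "ptvesc", "pli", "loeuf", "essential", "rhlof", "tdl",
    "secreted", "enzyme", "transporter", "transcription_factor",
    "has_chembl_compound", "has_pdb_structure", "family_has_drug_target",
]


def read_annotation_table(path) -> pd.DataFrame:
    """Read a per-gene annotation TSV (index column ``gene``)."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    bad_tdl = set(df["tdl"].dropna()) - set(TDL_LEVELS)
    if bad_tdl:
        raise ValueError(f"unknown TDL classes: {sorted(bad_tdl)}")
    return df


def lof_class(pli: float | None) -> str:
    """Loss-of-function tolerance class from pLI: tolerant (pli <= 0.1),
    intolerant (pli >= 0.9, boundary inclusive), else intermediate;
    missing pLI gives "unknown"."""
    if pli is None or pd.isna(pli):
        return "unknown"
    if pli <= 0.1:
        return "tolerant"
    if pli >= 0.9:
        return "intolerant"
    return "intermediate"


def genetic_evidence(omim: bool, ptvesc: bool) -> bool:
    """Human genetic evidence: a Mendelian disease entry (OMIM) or
    depletion of NMD-escaping truncating variants (PTVesc), or both."""
    return bool(omim) or bool(ptvesc)


def _druggability_vector(row: pd.Series) -> tuple[bool, ...]:
    return (
        row["tdl"] == "Tchem",
        bool(row["secreted"]),
        bool(row["has_chembl_compound"]),
        bool(row["has_pdb_structure"]),
        bool(row["family_has_drug_target"]),
    )


@dataclass
class OpportunityReport:
    """Counts over a tissue-specific gene set: exploration status, Tdark,
    druggability and genetic evidence among the unexplored, plus the
    disjoint druggability-flag buckets."""

    n_ts: int
    n_explored: int
    n_unexplored: int
    n_unannotated: int
    n_tdark_unexplored: int
    n_druggable_unexplored: int
    n_druggable_with_evidence: int
    upset_buckets: dict[frozenset[str], int]

    @property
    def pct_explored(self) -> float:
        return 100.0 * self.n_explored / self.n_ts if self.n_ts else float("nan")


def opportunity_report(
    ts_genes: set,
    catalog,
    annotations: pd.DataFrame,
) -> OpportunityReport:
    """Classify a tissue-specific gene set by exploration status and, for
    the unexplored remainder, by druggability and genetic evidence.

    ``catalog`` is a list of :class:`~tispec.targets.TargetRecord`; any
    record marks its gene as explored.  Genes missing from the annotation
    table are counted as unannotated and excluded from the flag buckets.
    """
    explored_genes = {t.gene for t in catalog}
    explored = ts_genes & explored_genes
    unexplored = ts_genes - explored_genes
    annotated = [g for g in sorted(unexplored) if g in annotations.index]
    n_unannotated = len(unexplored) - len(annotated)

    n_tdark = 0
    n_druggable = 0
    n_druggable_ev = 0
    buckets: dict[frozenset[str], int] = {}
    for g in annotated:
        row = annotations.loc[g]
        vec = _druggability_vector(row)
        if row["tdl"] == "Tdark":
            n_tdark += 1
        if any(vec):
            n_druggable += 1
            if genetic_evidence(row["omim"], row["ptvesc"]):
                n_druggable_ev += 1
            key = frozenset(
                flag for flag, on in zip(DRUGGABILITY_FLAGS, vec) if on
            )
            buckets[key] = buckets.get(key, 0) + 1

    return OpportunityReport(
        n_ts=len(ts_genes),
        n_explored=len(explored),
        n_unexplored=len(unexplored),
        n_unannotated=n_unannotated,
        n_tdark_unexplored=n_tdark,
        n_druggable_unexplored=n_druggable,
        n_druggable_with_evidence=n_druggable_ev,
        upset_buckets=buckets,
    )


def upset_table(report: OpportunityReport) -> pd.DataFrame:
    """Disjoint bucket counts as a membership matrix (one row per observed
    flag combination, boolean column per flag, plus ``count``)."""
    rows = []
    for key, count in sorted(
        report.upset_buckets.items(), key=lambda kv: -kv[1]
    ):
        row = {flag: flag in key for flag in DRUGGABILITY_FLAGS}
        row["count"] = count
        rows.append(row)
    return pd.DataFrame(rows, columns=[*DRUGGABILITY_FLAGS, "count"])


def all_flag_combinations() -> list[frozenset[str]]:
    """The 2^5 - 1 nonempty druggability-flag combinations."""
    out = []
    for r in range(1, len(DRUGGABILITY_FLAGS) + 1):
        out.extend(frozenset(c) for c in combinations(DRUGGABILITY_FLAGS, r))
    return out


def loeuf_distributions(
    groups: dict[str, set], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Long-format LOEUF values per gene group (violin-plot input);
    higher LOEUF means more tolerant of loss of function."""
    rows = []
    for name, members in groups.items():
        vals = annotations.loc[
            annotations.index.isin(members), "loeuf"
        ].dropna()
        for v in vals:
            rows.append(dict(group=name, loeuf=float(v)))
    return pd.DataFrame(rows, columns=["group", "loeuf"])
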