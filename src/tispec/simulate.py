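"""Seeded generators for all five input tables.

Each generator emulates the statistical structure the downstream analysis
assumes: background expression with planted single-tissue peaks,
annotation flags with controlled relative risk inside the planted set, a
phase-stratified drug catalog with controlled tissue-specific
overrepresentation and reuse rates, group-shifted ortholog conservation,
and a two-community confidence-weighted network joined only through
planted bridge nodes.

Default rates mirror a genome-scale human target landscape: an OMIM
Morbid Map base prevalence of 21.1% with a 1.27 relative risk inside the
planted tissue-specific set, PTVesc 10.4% with relative risk 1.5, a
2.3-fold overrepresentation of planted genes among marketed non-oncology
targets and depletion in phase 1, reuse probabilities of 66.3% / 34.3%
for broadly-expressed vs tissue-specific marketed targets, and clinical
phase-group sizes of a few hundred targets each.

A single root seed fans out to per-table child seeds by fixed offsets, so
regenerating one table never perturbs another; identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from tispec.expression import ExpressionMatrix
from tispec.targets import DrugRecord

# fixed per-table offsets for child seeds
_OFFSETS = {
    "expression": 11,
    "annotations": 23,
    "catalog": 37,
    "orthologs": 53,
    "network": 71,
}


@dataclass
class SimConfig:
    """Flat configuration for all generators (YAML-serializable)."""

    seed: int = 0

    # expression: per-gene baselines are log-normal across genes (the RPKM
    # dynamic range); across tissues a background gene fluctuates around its
    # baseline with bounded multiplicative noise.  Unbounded noise would
    # manufacture genuine single-tissue peaks in "null" genes, and a
    # single-tissue peak is exactly the planted signal.
    n_genes: int = 20_000
    n_tissues: int = 30
    rpkm_log_mean: float = 1.0
    rpkm_log_sd: float = 1.0
    tissue_cv: float = 0.25
    tissue_noise_clip: float = 2.0
    ts_fraction: float = 0.05
    peak_fold: float = 50.0

    # annotations: base rate outside the planted set, relative risk inside
    omim_rate: float = 0.211
    omim_rr: float = 1.27
    ptvesc_rate: float = 0.104
    ptvesc_rr: float = 1.5
    essential_rate: float = 0.0875
    essential_rr: float = 0.8
    rhlof_rate: float = 0.0055
    rhlof_rr: float = 1.0
    secreted_rate: float = 0.15
    secreted_rr: float = 1.6
    enzyme_rate: float = 0.12
    enzyme_rr: float = 1.2
    transporter_rate: float = 0.05
    transporter_rr: float = 1.3
    tf_rate: float = 0.08
    tf_rr: float = 1.1
    chembl_rate: float = 0.25
    chembl_rr: float = 1.0
    pdb_rate: float = 0.30
    pdb_rr: float = 0.9
    family_rate: float = 0.25
    family_rr: float = 1.0
    # TDL multinomial (Tdark, Tbio, Tchem, Tclin), background; planted set
    # shifts mass from Tclin/Tchem toward Tdark
    tdl_probs: tuple[float, float, float, float] = (0.35, 0.42, 0.20, 0.03)
    tdl_probs_ts: tuple[float, float, float, float] = (0.31, 0.47, 0.20, 0.02)
    pli_tolerant_frac: float = 0.45
    pli_tolerant_frac_ts: float = 0.58
    loeuf_log_mean: float = -0.1
    loeuf_log_sd: float = 0.5
    loeuf_ts_factor: float = 1.3

    # catalog: targets per (phase, indication) group
    phase_group_sizes: dict = field(
        default_factory=lambda: {
            ("1", "oncology"): 253,
            ("1", "non-oncology"): 78,
            ("2", "oncology"): 239,
            ("2", "non-oncology"): 314,
            ("3", "oncology"): 145,
            ("3", "non-oncology"): 26,
            ("marketed", "oncology"): 211,
            ("marketed", "non-oncology"): 476,
            ("withdrawn", "non-oncology"): 30,
        }
    )
    # planted-set sampling weight per group (overrepresentation)
    phase_group_ts_rr: dict = field(
        default_factory=lambda: {
            ("1", "oncology"): 0.4,
            ("1", "non-oncology"): 0.4,
            ("2", "oncology"): 0.7,
            ("2", "non-oncology"): 1.0,
            ("3", "oncology"): 1.5,
            ("3", "non-oncology"): 1.5,
            ("marketed", "oncology"): 0.7,
            ("marketed", "non-oncology"): 2.3,
            ("withdrawn", "non-oncology"): 2.3,
        }
    )
    # proportional shrink factor for all phase-group sizes (desk-scale runs)
    catalog_scale: float = 1.0
    reuse_prob_ts: float = 0.343
    reuse_prob_nonts: float = 0.663
    withdrawn_marketed_overlap: float = 0.95
    approval_year_mean_ts: float = 1978.0
    approval_year_mean_nonts: float = 1984.0
    approval_year_sd: float = 14.0

    # orthologs
    species: tuple[str, ...] = ("mouse",)
    no_1to1_rate: float = 0.20
    no_1to1_rate_ts: float = 0.30
    kaks_gamma_shape: float = 2.0
    kaks_gamma_scale: float = 0.07
    kaks_ts_shift: float = 0.1

    # network
    network_nodes: int = 2_000
    attachment_m: int = 3
    n_bridges: int = 4
    bridge_anchors: int = 6
    score_min: int = 150
    score_max: int = 999

    def child_seed(self, table: str) -> int:
        # keep derived seeds in the 32-bit range expected by downstream RNGs
        return (int(self.seed) * 1_000 + _OFFSETS[table]) % (2**31)

    def rng(self, table: str) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(table))

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def tissue_ids(self) -> list[str]:
        return [f"T{i:02d}" for i in range(self.n_tissues)]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("phase_group_sizes", "phase_group_ts_rr"):
            if key in raw:
                raw[key] = {
                    (str(p), str(c)): v
                    for (p, c, v) in (
                        (item["phase"], item["indication"], item["value"])
                        for item in raw[key]
                    )
                }
        for key in ("tdl_probs", "tdl_probs_ts", "species"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key in ("phase_group_sizes", "phase_group_ts_rr"):
            raw[key] = [
                dict(phase=p, indication=c, value=v)
                for (p, c), v in raw[key].items()
            ]
        for key in ("tdl_probs", "tdl_probs_ts", "species"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _planted_rate(base: float, rr: float) -> float:
    rate = base * rr
    if rate > 1:
        warnings.warn(f"relative risk pushes rate {rate:.3f} above 1; clamped")
        return 1.0
    return rate


def gen_expression(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Background expression with planted single-tissue peaks of fold
    ``peak_fold``.

    Background gene g in tissue t takes value
    ``baseline_g * (1 + cv * eps)`` with ``eps`` standard normal clipped
    at ``tissue_noise_clip`` sigma, i.i.d. across tissues; baselines are
    log-normal across genes.  Each planted gene gets one uniformly
    chosen peak tissue whose value is multiplied by ``peak_fold``.

    Returns the matrix and the truth table (gene, peak tissue) of
    planted genes.
    """
    if config.n_tissues < 3:
        raise ValueError("need at least 3 tissues")
    rng = config.rng("expression")
    genes = config.gene_ids()
    tissues = config.tissue_ids()
    baseline = rng.lognormal(
        config.rpkm_log_mean, config.rpkm_log_sd, (config.n_genes, 1)
    )
    eps = np.clip(
        rng.standard_normal((config.n_genes, config.n_tissues)),
        -config.tissue_noise_clip,
        config.tissue_noise_clip,
    )
    values = baseline * (1.0 + config.tissue_cv * eps)
    n_planted = int(config.ts_fraction * config.n_genes)
    if config.ts_fraction > 0 and n_planted < 1:
        warnings.warn("planted fraction below one gene; planting none")
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    peak_tissues = rng.integers(0, config.n_tissues, size=n_planted)
    for gi, ti in zip(planted_idx, peak_tissues):
        values[gi, ti] *= config.peak_fold
    truth = pd.DataFrame(
        {
            "gene": [genes[i] for i in planted_idx],
            "peak_tissue": [tissues[t] for t in peak_tissues],
        }
    ).sort_values("gene", ignore_index=True)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues))
    return matrix, truth


def gen_annotations(config: SimConfig, planted_ts: set) -> pd.DataFrame:
    """Per-gene annotation flags: Bernoulli(base rate) outside the planted
    set and Bernoulli(rate x relative risk) inside; pLI from a
    tolerant/intolerant two-component mixture and LOEUF log-normal, both
    with a configurable shift in the planted set."""
    rng = config.rng("annotations")
    genes = config.gene_ids()
    in_ts = np.array([g in planted_ts for g in genes])
    n = len(genes)

    def draw_flag(base: float, rr: float) -> np.ndarray:
        rates = np.where(in_ts, _planted_rate(base, rr), base)
        return rng.random(n) < rates

    flags = {
        "omim": draw_flag(config.omim_rate, config.omim_rr),
        "ptvesc": draw_flag(config.ptvesc_rate, config.ptvesc_rr),
        "essential": draw_flag(config.essential_rate, config.essential_rr),
        "rhlof": draw_flag(config.rhlof_rate, config.rhlof_rr),
        "secreted": draw_flag(config.secreted_rate, config.secreted_rr),
        "enzyme": draw_flag(config.enzyme_rate, config.enzyme_rr),
        "transporter": draw_flag(config.transporter_rate, config.transporter_rr),
        "transcription_factor": draw_flag(config.tf_rate, config.tf_rr),
        "has_chembl_compound": draw_flag(config.chembl_rate, config.chembl_rr),
        "has_pdb_structure": draw_flag(config.pdb_rate, config.pdb_rr),
        "family_has_drug_target": draw_flag(config.family_rate, config.family_rr),
    }

    tdl_levels = np.array(["Tdark", "Tbio", "Tchem", "Tclin"])
    probs_bg = np.asarray(config.tdl_probs, dtype=float)
    probs_ts = np.asarray(config.tdl_probs_ts, dtype=float)
    u = rng.random(n)
    cum_bg = np.cumsum(probs_bg / probs_bg.sum())
    cum_ts = np.cumsum(probs_ts / probs_ts.sum())
    idx = np.where(
        in_ts,
        np.searchsorted(cum_ts, u, side="right"),
        np.searchsorted(cum_bg, u, side="right"),
    ).clip(0, 3)
    tdl = tdl_levels[idx]

    tol_frac = np.where(
        in_ts, config.pli_tolerant_frac_ts, config.pli_tolerant_frac
    )
    tolerant = rng.random(n) < tol_frac
    pli = np.where(tolerant, rng.beta(0.5, 8.0, n), rng.beta(8.0, 0.5, n))

    loeuf = rng.lognormal(config.loeuf_log_mean, config.loeuf_log_sd, n)
    loeuf = np.where(in_ts, loeuf * config.loeuf_ts_factor, loeuf)

    return pd.DataFrame(
        {**{k: v for k, v in flags.items()},
         "pli": pli, "loeuf": loeuf, "tdl": tdl},
        index=pd.Index(genes, name="gene"),
    )[
        ["omim", "ptvesc", "pli", "loeuf", "essential", "rhlof", "tdl",
         "secreted", "enzyme", "transporter", "transcription_factor",
         "has_chembl_compound", "has_pdb_structure", "family_has_drug_target"]
    ]


def gen_catalog(config: SimConfig, planted_ts: set) -> list[DrugRecord]:
    """Phase-stratified drug catalog with controlled tissue-specific
    overrepresentation per phase group, reuse of marketed targets and
    per-group approval-year distributions.

    Phase-group target sets are sampled disjointly (a gene's group is its
    maximal phase, mirroring how the catalog collapses drugs), so target
    reuse is controlled solely by the reuse probabilities: each marketed
    target receives candidate (phase 1-3) drugs with probability
    ``reuse_prob_ts`` or ``reuse_prob_nonts`` depending on planted
    membership.  Withdrawn drugs draw their targets from the marketed set
    with probability ``withdrawn_marketed_overlap``, otherwise fresh.
    """
    rng = config.rng("catalog")
    genes = np.array(config.gene_ids())
    in_ts = np.array([g in planted_ts for g in genes])
    drugs: list[DrugRecord] = []
    drug_n = 0
    available = np.ones(len(genes), dtype=bool)
    marketed_pool: list[str] = []

    order = sorted(
        config.phase_group_sizes.items(),
        key=lambda kv: {"marketed": 0, "withdrawn": 1, "3": 2, "2": 3, "1": 4}[
            kv[0][0]
        ],
    )
    total = round(sum(config.phase_group_sizes.values()) * config.catalog_scale)
    if total > len(genes):
        raise ValueError(
            f"catalog of {total} targets exceeds the {len(genes)}-gene "
            "universe; lower catalog_scale or the group sizes"
        )
    for (phase, indication), size in order:
        if size < 0:
            raise ValueError("phase group sizes must be >= 0")
        size = round(size * config.catalog_scale)
        if size == 0:
            continue
        rr = config.phase_group_ts_rr.get((phase, indication), 1.0)
        weights = np.where(in_ts, rr, 1.0) * available
        weights = weights.astype(float) / weights.sum()
        targets = list(rng.choice(genes, size=size, replace=False, p=weights))
        if phase == "withdrawn" and marketed_pool:
            reuse_marketed = rng.random(size) < config.withdrawn_marketed_overlap
            picks = rng.choice(len(marketed_pool), size=size)
            targets = [
                marketed_pool[p] if r else t
                for t, r, p in zip(targets, reuse_marketed, picks)
            ]
        oncology = indication == "oncology"
        marketed_level = phase in ("marketed", "withdrawn")
        for gene in targets:
            available[np.searchsorted(genes, gene)] = False
            if phase == "marketed":
                marketed_pool.append(str(gene))
            drug_n += 1
            year = None
            if marketed_level:
                mean = (
                    config.approval_year_mean_ts
                    if gene in planted_ts
                    else config.approval_year_mean_nonts
                )
                year = int(
                    np.clip(rng.normal(mean, config.approval_year_sd), 1940, 2017)
                )
            drugs.append(
                DrugRecord(
                    drug_id=f"D{drug_n:05d}",
                    targets=(str(gene),),
                    max_phase=phase,
                    oncology=oncology,
                    approval_year=year,
                )
            )
            if marketed_level:
                p_reuse = (
                    config.reuse_prob_ts
                    if gene in planted_ts
                    else config.reuse_prob_nonts
                )
                if rng.random() < p_reuse:
                    for _ in range(int(rng.integers(1, 4))):
                        drug_n += 1
                        drugs.append(
                            DrugRecord(
                                drug_id=f"D{drug_n:05d}",
                                targets=(str(gene),),
                                max_phase=str(rng.integers(1, 4)),
                                oncology=oncology,
                                approval_year=None,
                            )
                        )
    return drugs


def gen_orthologs(config: SimConfig, planted_ts: set) -> pd.DataFrame:
    """Per-species ortholog table: homology type multinomial with a
    group-specific no-1-to-1 rate, gamma-distributed Ka/Ks with a planted
    shift in the tissue-specific group, and sequence similarity
    anti-correlated with Ka/Ks by construction."""
    rng = config.rng("orthologs")
    genes = config.gene_ids()
    in_ts = np.array([g in planted_ts for g in genes])
    n = len(genes)
    rows = []
    for species in config.species:
        no_rate = np.where(in_ts, config.no_1to1_rate_ts, config.no_1to1_rate)
        not_one2one = rng.random(n) < no_rate
        # split non-1to1 mass between duplicated orthologs and absence
        kind = rng.random(n)
        homology = np.where(
            not_one2one,
            np.where(kind < 0.5, "one2many",
                     np.where(kind < 0.8, "many2many", "none")),
            "one2one",
        )
        kaks = rng.gamma(config.kaks_gamma_shape, config.kaks_gamma_scale, n)
        kaks = np.where(in_ts, kaks + config.kaks_ts_shift, kaks)
        similarity = np.clip(
            95.0 - 120.0 * kaks + rng.normal(0, 3.0, n), 0.0, 100.0
        )
        identity = np.clip(similarity - 5.0 - np.abs(rng.normal(0, 2.0, n)),
                           0.0, 100.0)
        has_vals = homology != "none"
        df = pd.DataFrame(
            {
                "gene": genes,
                "species": species,
                "homology_type": homology,
                "ka_ks": np.where(has_vals, kaks, np.nan),
                "pct_identity": np.where(has_vals, identity, np.nan),
                "pct_similarity": np.where(has_vals, similarity, np.nan),
            }
        )
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def gen_network(
    config: SimConfig, bridge_nodes: list[str] | None = None
) -> pd.DataFrame:
    """Two preferential-attachment communities joined only through planted
    bridge nodes; returns a STRING-style edge table.

    Community nodes take the first ``network_nodes`` gene ids; bridge
    nodes default to ``BRIDGE_i`` labels (pass gene ids to plant them as
    specific genes).  Scores are uniform integers in
    [``score_min``, ``score_max``].
    """
    import networkx as nx

    if config.n_bridges > 0 and config.network_nodes < 4:
        raise ValueError("need two communities to plant bridges")
    rng = config.rng("network")
    half = config.network_nodes // 2
    seed_a = int(rng.integers(0, 2**31))
    seed_b = int(rng.integers(0, 2**31))
    com_a = nx.barabasi_albert_graph(half, config.attachment_m, seed=seed_a)
    com_b = nx.barabasi_albert_graph(
        config.network_nodes - half, config.attachment_m, seed=seed_b
    )
    genes = config.gene_ids()
    if config.network_nodes > len(genes):
        raise ValueError("network_nodes exceeds n_genes")
    names_a = {i: genes[i] for i in com_a.nodes}
    names_b = {i: genes[half + i] for i in com_b.nodes}
    edges: list[tuple[str, str]] = []
    edges += [(names_a[u], names_a[v]) for u, v in com_a.edges]
    edges += [(names_b[u], names_b[v]) for u, v in com_b.edges]

    if bridge_nodes is None:
        bridge_nodes = [f"BRIDGE{i}" for i in range(config.n_bridges)]
    else:
        bridge_nodes = list(bridge_nodes)[: config.n_bridges]
    for bn, (com, names) in zip(
        bridge_nodes * 2,
        [(com_a, names_a)] * len(bridge_nodes)
        + [(com_b, names_b)] * len(bridge_nodes),
    ):
        # anchor on peripheral (below-median-degree) nodes, several per
        # side, so no single community hub funnels the inter-community
        # traffic and outranks the bridge itself
        degrees = dict(com.degree)
        cutoff = float(np.median(list(degrees.values())))
        pool = sorted(n for n, d in degrees.items() if d <= cutoff)
        k = min(config.bridge_anchors, len(pool))
        anchors = rng.choice(len(pool), size=k, replace=False)
        edges += [
            (bn, names[pool[a]]) for a in anchors if names[pool[a]] != bn
        ]

    n_community = len(edges) - sum(
        1 for u, v in edges if u in set(bridge_nodes) or v in set(bridge_nodes)
    )
    scores = rng.integers(config.score_min, config.score_max + 1, len(edges))
    # bridge edges carry uniform top confidence: equal-length spokes keep
    # the inter-community traffic split across anchors
    scores[n_community:] = config.score_max
    return pd.DataFrame(
        {
            "protein1": [u for u, _ in edges],
            "protein2": [v for _, v in edges],
            "combined_score": scores,
        }
    )


def simulate_all(config: SimConfig, outdir) -> dict:
    """Generate all five tables, write them as TSVs under ``outdir`` and
    return the in-memory objects."""
    from pathlib import Path

    from tispec.targets import write_drug_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth = gen_expression(config)
    planted = set(truth["gene"])
    ann = gen_annotations(config, planted)
    drugs = gen_catalog(config, planted)
    orth = gen_orthologs(config, planted)
    bridge_pool = sorted(planted & set(config.gene_ids()[: config.network_nodes]))
    net = gen_network(config, bridge_nodes=bridge_pool or None)

    expr.to_tsv(out / "expression.tsv")
    truth.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
    ann.to_csv(out / "annotations.tsv", sep="\t")
    write_drug_table(drugs, out / "drugs.tsv")
    orth.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    net.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    return dict(
        expression=expr, truth=truth, annotations=ann, drugs=drugs,
        orthologs=orth, edges=net,
    )
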