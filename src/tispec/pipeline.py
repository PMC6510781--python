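"""End-to-end run: score -> classify -> enrich -> conserve -> network ->
opportunities, with a JSON manifest recording config hash, input
checksums and per-stage row counts so reruns are verifiable."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

import tispec
from tispec import (
    build_catalog,
    centralities,
    double_z,
    group_topology_compare,
    largest_component,
    load_edges,
    opportunity_report,
    specificity_profile,
)
from tispec.conservation import conservation_summary, read_ortholog_table
from tispec.expression import (
    ExpressionMatrix,
    calls_to_frame,
    nonspecific_genes,
    specific_genes,
)
from tispec.opportunities import read_annotation_table, upset_table
from tispec.simulate import SimConfig, simulate_all
from tispec.stats import prevalence_scan
from tispec.targets import catalog_to_frame, read_drug_table, reuse_analysis

INPUT_KEYS = ("expression", "drugs", "annotations", "orthologs", "edges")

OUTPUTS = (
    "z.tsv", "calls.tsv", "enrichment.tsv", "conservation.tsv", "topo.tsv",
    "table1.tsv", "table2.tsv", "opportunities.tsv", "manifest.json",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: dict, outdir) -> Path:
    """Run the whole pipeline.

    ``config`` either names all five input paths (keys ``expression``,
    ``drugs``, ``annotations``, ``orthologs``, ``edges``) or sets
    ``simulate: true`` (with optional ``seed`` and SimConfig overrides
    under ``sim``) to generate them first.  ``report_x`` (default
    ``[2, 6, 10]``) selects the stringencies for the reuse, conservation
    and opportunity reports.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report_x = config.get("report_x", [2, 6, 10])
    species = config.get("species", "mouse")

    if config.get("simulate"):
        sim = SimConfig(seed=int(config.get("seed", 0)),
                        **config.get("sim", {}))
        fixture_dir = out / "fixtures"
        simulate_all(sim, fixture_dir)
        paths = {k: fixture_dir / name for k, name in zip(
            INPUT_KEYS,
            ("expression.tsv", "drugs.tsv", "annotations.tsv",
             "orthologs.tsv", "network_edges.tsv"),
        )}
    else:
        missing = [k for k in INPUT_KEYS if k not in config]
        if missing:
            raise ValueError(f"config missing input paths: {missing}")
        paths = {k: Path(config[k]) for k in INPUT_KEYS}
        absent = [str(p) for p in paths.values() if not p.exists()]
        if absent:
            raise FileNotFoundError(f"missing input files: {absent}")

    counts: dict[str, int] = {}

    # expression scoring
    expr = ExpressionMatrix.from_tsv(paths["expression"])
    z = double_z(expr)
    z.to_tsv(out / "z.tsv")
    calls = specificity_profile(z)
    calls_df = calls_to_frame(calls)
    calls_df.to_csv(out / "calls.tsv", sep="\t")
    counts["genes"] = len(calls)
    universe = set(expr.genes)

    # target catalog + enrichment scan
    drugs = read_drug_table(paths["drugs"])
    catalog = build_catalog(drugs)
    catalog_to_frame(catalog).to_csv(out / "targets.tsv", sep="\t")
    counts["targets"] = len(catalog)
    groups = {}
    directions = {}
    for phase in ("1", "2", "3", "marketed"):
        for onc in (True, False):
            name = f"{'oncology' if onc else 'non-oncology'}_phase_{phase}"
            members = {
                t.gene for t in catalog if t.max_phase == phase and t.oncology == onc
            }
            groups[name] = members & universe
            directions[name] = "depletion" if phase == "1" else "enrichment"
    scan = prevalence_scan(calls, groups, universe, directions=directions)
    reuse_rows = []
    for x in report_x:
        rep = reuse_analysis(catalog, calls, x)
        reuse_rows.append(
            dict(x=x, n_ts=rep.n_ts, n_ts_reused=rep.n_ts_reused,
                 n_nonts=rep.n_nonts, n_nonts_reused=rep.n_nonts_reused,
                 ratio=rep.ratio, p=rep.p)
        )
    scan.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(reuse_rows).to_csv(out / "reuse.tsv", sep="\t", index=False)
    counts["enrichment_cells"] = len(scan)

    # conservation
    orth = read_ortholog_table(paths["orthologs"])
    cons_groups = {f"ts_x{x}": specific_genes(calls, x) for x in report_x}
    cons_groups["marketed_targets"] = {t.gene for t in catalog if t.marketed}
    cons = conservation_summary(cons_groups, orth, species)
    cons.to_csv(out / "conservation.tsv", sep="\t", index=False)
    counts["conservation_rows"] = len(cons)

    # network topology
    net = largest_component(load_edges(paths["edges"]))
    topo = centralities(net)
    topo.to_csv(out / "topo.tsv", sep="\t")
    counts["network_nodes"] = net.n_nodes
    ann = read_annotation_table(paths["annotations"])
    t1_groups = {
        "all": universe,
        **{f"ts_x{x}": specific_genes(calls, x) for x in report_x},
        "essential": set(ann.index[ann["essential"]]),
        "omim": set(ann.index[ann["omim"]]),
        "ptvesc": set(ann.index[ann["ptvesc"]]),
        "rhlof": set(ann.index[ann["rhlof"]]),
        "marketed": {t.gene for t in catalog if t.marketed},
    }
    table1 = group_topology_compare(
        topo, t1_groups, "betweenness", reference="all"
    )
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    x_mid = report_x[len(report_x) // 2]
    ts_mid = specific_genes(calls, x_mid)
    sec = set(ann.index[ann["secreted"]])
    enz = set(ann.index[ann["enzyme"]])
    tra = set(ann.index[ann["transporter"]])
    tf = set(ann.index[ann["transcription_factor"]])
    t2_groups = {
        "secreted_and_enzyme": ts_mid & sec & enz,
        "secreted": ts_mid & (sec - enz),
        "enzyme": ts_mid & (enz - sec),
        "transporter": ts_mid & tra - sec - enz,
        "transcription_factor": ts_mid & tf - sec - enz - tra,
        "neither": ts_mid - sec - enz - tra - tf,
    }
    table2 = group_topology_compare(
        topo, t2_groups, "betweenness", reference="neither"
    )
    table2.to_csv(out / "table2.tsv", sep="\t", index=False)

    # opportunities
    opp_rows = []
    upsets = []
    for x in report_x:
        rep = opportunity_report(specific_genes(calls, x), catalog, ann)
        opp_rows.append(
            dict(x=x, n_ts=rep.n_ts, explored=rep.n_explored,
                 unexplored=rep.n_unexplored, tdark=rep.n_tdark_unexplored,
                 druggable=rep.n_druggable_unexplored,
                 druggable_with_evidence=rep.n_druggable_with_evidence)
        )
        ut = upset_table(rep)
        ut.insert(0, "x", x)
        upsets.append(ut)
    pd.DataFrame(opp_rows).to_csv(out / "opportunities.tsv", sep="\t",
                                  index=False)
    pd.concat(upsets, ignore_index=True).to_csv(
        out / "upset.tsv", sep="\t", index=False
    )
    counts["opportunity_rows"] = len(opp_rows)

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = dict(
        tool_version=tispec.__version__,
        config_hash=config_hash,
        inputs={k: _sha256(p) for k, p in paths.items()},
        outputs={
            name: _sha256(out / name)
            for name in OUTPUTS
            if name != "manifest.json" and (out / name).exists()
        },
        counts=counts,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
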