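"""Readers and writers for the pipeline's interchange formats.

Formats: the record CSV dialect (``case_id,age,sex,ses,dx1..dxK``), planted
ground-truth CSV, full pair-test tables, GraphML networks (attribute-rich,
readable by Gephi/Cytoscape), flat edge-list CSVs, Table-1-style summary
CSVs, top-k ranking CSVs, and YAML/JSON synthetic-cohort configs. MI is
serialized at 6 decimal places in flat reports; GraphML keeps full
precision. All writers are deterministic given identical inputs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .inference import ComorbidityNetwork, PairTest, TEST_TABLE_COLUMNS
from .metrics import SUMMARY_COLUMNS, NetworkSummary
from .records import PatientRecord, StratumSpec
from .synthetic import PlantedPair, SyntheticConfig

__all__ = [
    "write_records_csv",
    "write_ground_truth_csv",
    "write_test_table_csv",
    "write_network_graphml",
    "read_network_graphml",
    "write_edge_list_csv",
    "write_summary_csv",
    "write_topk_csv",
    "write_exclusion_report_csv",
    "load_synthetic_config",
]


def write_records_csv(
    records: Iterable[PatientRecord], path, max_codes: int = 6
) -> None:
    """Write records in the record CSV dialect (codes sorted within a row)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["case_id", "age", "sex", "ses"] + [f"dx{i}" for i in range(1, max_codes + 1)]
        )
        for rec in records:
            codes = sorted(rec.codes)[:max_codes]
            codes += [""] * (max_codes - len(codes))
            writer.writerow([rec.case_id, rec.age, rec.sex, rec.ses] + codes)


def write_ground_truth_csv(config: SyntheticConfig, path) -> None:
    """Planted enrichments as CSV (stratum, code_a, code_b, rho)."""
    rows = sorted(
        (pp.stratum, *pp.pair, pp.rho) for pp in config.planted_pairs
    )
    pd.DataFrame(rows, columns=["stratum", "code_a", "code_b", "rho"]).to_csv(
        path, index=False
    )


def write_test_table_csv(tests: Sequence[PairTest] | pd.DataFrame, path) -> None:
    """Full pairwise test table (one row per tested pair)."""
    if isinstance(tests, pd.DataFrame):
        df = tests[TEST_TABLE_COLUMNS]
    else:
        df = pd.DataFrame([t.__dict__ for t in tests], columns=TEST_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def write_network_graphml(network: ComorbidityNetwork, path) -> None:
    """Serialize a network as GraphML with graph-level stratum/alpha attributes."""
    G = network.graph.copy()
    G.graph["stratum"] = network.stratum if network.stratum is not None else ""
    G.graph["alpha"] = float(network.alpha)
    nx.write_graphml(G, str(path))


def read_network_graphml(path) -> ComorbidityNetwork:
    """Read a network written by :func:`write_network_graphml`."""
    try:
        G = nx.read_graphml(str(path))
    except Exception as exc:  # malformed file: name it
        raise ValueError(f"cannot parse network file {path}: {exc}") from exc
    stratum = G.graph.pop("stratum", "") or None
    alpha = float(G.graph.pop("alpha", 0.05))
    return ComorbidityNetwork(graph=nx.Graph(G), stratum=stratum, alpha=alpha)


def write_edge_list_csv(network: ComorbidityNetwork, path) -> None:
    """Flat edge list (code_a, code_b, mi, p_value, q_value, k); MI at 6 dp."""
    rows = []
    for a, b, data in network.graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append(
            (
                a,
                b,
                f"{data['mi']:.6f}",
                f"{data['p_value']:.6g}",
                f"{data['q_value']:.6g}",
                int(data["k"]),
            )
        )
    rows.sort()
    pd.DataFrame(
        rows, columns=["code_a", "code_b", "mi", "p_value", "q_value", "k"]
    ).to_csv(path, index=False)


def write_summary_csv(summaries: Sequence[NetworkSummary], path) -> None:
    """Table-1-style topology summary, one row per stratum network."""
    pd.DataFrame([s.to_row() for s in summaries], columns=SUMMARY_COLUMNS).to_csv(
        path, index=False
    )


def write_topk_csv(entries: Sequence[tuple[str, float]], path) -> None:
    """Top-k ranking (code, pagerank) with PageRank at 6 dp."""
    rows = [(code, f"{score:.6f}") for code, score in entries]
    pd.DataFrame(rows, columns=["code", "pagerank"]).to_csv(path, index=False)


def write_exclusion_report_csv(report, path) -> None:
    """Exclusion accounting as CSV with columns reason,count."""
    report.to_frame().to_csv(path, index=False)


def _stratum_from_mapping(entry: Mapping) -> StratumSpec:
    return StratumSpec(
        label=str(entry["label"]),
        age_lo=int(entry["age_lo"]),
        age_hi=None if entry.get("age_hi") is None else int(entry["age_hi"]),
        sex=str(entry["sex"]),
        ses=str(entry["ses"]),
    )


def load_synthetic_config(path) -> SyntheticConfig:
    """Load a synthetic-cohort config from YAML or JSON.

    The file mirrors :class:`SyntheticConfig` fields; ``strata`` entries are
    mappings with label/age_lo/age_hi/sex/ses, ``planted_pairs`` entries are
    mappings with code_a/code_b/stratum/rho.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        config = SyntheticConfig(
            code_universe=list(raw["code_universe"]),
            strata=[_stratum_from_mapping(s) for s in raw["strata"]],
            n_per_stratum=int(raw["n_per_stratum"]),
            prevalence=raw["prevalence"],
            planted_pairs=[
                PlantedPair(
                    code_a=str(p["code_a"]),
                    code_b=str(p["code_b"]),
                    stratum=str(p["stratum"]),
                    rho=float(p["rho"]),
                )
                for p in raw.get("planted_pairs", [])
            ],
            max_codes_per_record=int(raw.get("max_codes_per_record", 6)),
            seed=int(raw.get("seed", 0)),
        )
    except KeyError as exc:
        raise ValueError(f"synthetic config {path} missing field {exc}") from exc
    config.validate()
    return config
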